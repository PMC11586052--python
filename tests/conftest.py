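import numpy as np
import pytest

from nicheprof.plate_io import (
    IsolateMeta,
    IsolateProfile,
    correct_and_threshold,
    default_layout,
    usage_mask,
)
from nicheprof.simulate import SimConfig, simulate_study

META = IsolateMeta("iso1", "Bacteria", "control", "L1", "P1")


def make_profile(od, isolate_id="iso1", kingdom="Bacteria", treatment="control",
                 leaf_id="L1", plot_id="P1", threshold=0.005):
    """Build an IsolateProfile directly from a 95-vector of corrected ODs."""
    od = np.asarray(od, dtype=float)
    assert od.shape == (95,)
    layout = default_layout()
    return IsolateProfile(
        isolate_id=isolate_id,
        meta=IsolateMeta(isolate_id, kingdom, treatment, leaf_id, plot_id),
        substrates=layout.substrates,
        corrected_od=od,
        usage=usage_mask(od, threshold),
        threshold=threshold,
    )


def vec(values_by_index, fill=0.0):
    """95-vector with selected indices set."""
    v = np.full(95, fill)
    for i, x in values_by_index.items():
        v[i] = x
    return v


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def study():
    """One full-size synthetic study (235 isolates) as corrected profiles."""
    plates, metadata, truth = simulate_study(SimConfig(seed=42))
    lay = default_layout()
    profiles = [correct_and_threshold(p, lay) for p in plates]
    return profiles, metadata, truth


@pytest.fixture(scope="session")
def small_study():
    """A reduced study: 2 leaves/treatment, 3 bacteria + 3 fungi per leaf."""
    cfg = SimConfig(seed=7, leaves_per_treatment=2, bacteria_per_leaf=3,
                    fungi_per_leaf=3, deficit=None)
    plates, metadata, truth = simulate_study(cfg)
    lay = default_layout()
    profiles = [correct_and_threshold(p, lay) for p in plates]
    return profiles, metadata, truth
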