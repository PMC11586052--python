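"""Per-isolate carbon-use metrics.

Niche width (NW) counts the substrates an isolate uses; total growth (TG)
sums corrected OD over those used substrates; growth efficiency (GE) is
their ratio TG/NW, the mean OD per used substrate. Pielou evenness J is the
Shannon entropy of the used-substrate OD proportions normalised by its
maximum ln(NW): J near 1 marks a generalist (homogeneous use), lower J a
specialist.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .plate_io import IsolateProfile, PlateError


def niche_width(profile: IsolateProfile) -> int:
    """Number of substrates meeting the usage criterion."""
    return int(profile.usage.sum())


def total_growth(profile: IsolateProfile) -> float:
    """Sum of corrected OD over used substrates only.

    Sub-threshold positives contribute nothing; used substrates are at or
    above the threshold, hence nonnegative.
    """
    return float(profile.corrected_od[profile.usage].sum())


def growth_efficiency(profile: IsolateProfile) -> float:
    """TG/NW, or NaN when no substrate is used."""
    nw = niche_width(profile)
    if nw == 0:
        return float("nan")
    return total_growth(profile) / nw


def evenness(profile: IsolateProfile) -> float:
    """Pielou J over used substrates; NaN when fewer than 2 are used.

    J = H' / ln(S) with S = NW and p_n the used-substrate OD proportions.
    """
    od = profile.corrected_od[profile.usage]
    s = od.size
    if s < 2:
        return float("nan")
    p = od / od.sum()
    h = -float(np.sum(p * np.log(p)))
    return h / np.log(s)


def metrics_table(profiles: Sequence[IsolateProfile]) -> pd.DataFrame:
    """One row per isolate (input order) with NW, TG, GE, J and metadata.

    Undefined GE/J are NaN; they are rendered as empty fields on write.
    """
    rows = []
    for p in profiles:
        rows.append(
            {
                "isolate_id": p.isolate_id,
                "kingdom": p.meta.kingdom,
                "treatment": p.meta.treatment,
                "leaf_id": p.meta.leaf_id,
                "plot_id": p.meta.plot_id,
                "NW": niche_width(p),
                "TG": total_growth(p),
                "GE": growth_efficiency(p),
                "J": evenness(p),
            }
        )
    return pd.DataFrame(rows)


def mean_substrate_growth(
    profiles: Sequence[IsolateProfile],
    where: Callable[[IsolateProfile], bool] | None = None,
) -> pd.Series:
    """Per-substrate mean corrected OD (clipped at 0) over selected isolates."""
    chosen = [p for p in profiles if where is None or where(p)]
    if not chosen:
        raise PlateError("empty selection")
    mat = np.vstack([p.corrected_od_nonneg for p in chosen])
    return pd.Series(mat.mean(axis=0), index=list(chosen[0].substrates))


def preferred_substrates(
    profiles: Sequence[IsolateProfile],
    where: Callable[[IsolateProfile], bool] | None = None,
    k: int = 10,
) -> list[str]:
    """Top-k substrates by mean corrected OD across the selected isolates.

    Ties are broken by substrate name ascending.
    """
    means = mean_substrate_growth(profiles, where)
    order = means.to_frame("mean").reset_index(names="substrate")
    order = order.sort_values(["mean", "substrate"], ascending=[False, True], kind="stable")
    return order["substrate"].head(k).tolist()


def write_metrics(table: pd.DataFrame, path) -> None:
    """Write the metrics table; NaN rendered as empty fields, never 0."""
    table.to_csv(path, index=False, na_rep="")
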