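"""Synthetic Biolog plate studies with known ground truth.

The generator emulates the sampling design the analysis is built around:
2 treatments (control, NPKμ) x 2 plots x 3 plants = 6
leaves per treatment, with 10 bacterial and 10 fungal isolates per leaf and
one deficient control leaf yielding only 5 bacteria — 115 bacteria + 120
fungi = 235 isolates.

Generative model per isolate: each of the 95 substrates is used with a
kingdom x treatment usage probability; used substrates receive a latent OD
drawn from a Gamma distribution whose mean is

    kingdom mean x treatment multiplier x substrate baseline
        x isolate factor / usage probability

(so the expected mean OD over all 95 wells equals kingdom mean x multiplier
x isolate factor) and whose shape is the evenness-concentration parameter —
higher shape gives more homogeneous used-substrate ODs, hence higher Pielou
J. The isolate factor is a lognormal random effect capturing between-isolate
heterogeneity. Raw well values add a water baseline and Gaussian read
noise; the water well is baseline + noise only.

Kingdom/treatment level defaults encode the emulated study conditions
(mean OD over the plate: bacteria 0.098 -> 0.107, fungi
0.273 -> 0.217 across control -> NPKμ; fungal niche widths 85.5 -> 79.2 of
95; evenness near 0.90-0.92); unreported quantities (noise, heterogeneity,
baseline spread) use values documented in the methods note. Everything is
deterministic under the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .plate_io import (
    WELLS,
    IsolateMeta,
    RawPlate,
    TREATMENT_AMENDED,
    TREATMENT_CONTROL,
    default_layout,
)

_B, _F = "Bacteria", "Fungi"
_CTL, _AMD = TREATMENT_CONTROL, TREATMENT_AMENDED


def _kt(bc, bn, fc, fn) -> dict:
    return {_B: {_CTL: bc, _AMD: bn}, _F: {_CTL: fc, _AMD: fn}}


@dataclass
class SimConfig:
    """Generator parameters; defaults encode the emulated study design."""

    seed: int = 0
    leaves_per_treatment: int = 6
    plots_per_treatment: int = 2
    bacteria_per_leaf: int = 10
    fungi_per_leaf: int = 10
    #: (treatment, leaf index, kingdom, count) — the study's one deficient
    #: leaf that yielded only 5 culturable bacteria; None disables it.
    deficit: tuple | None = (_CTL, 0, _B, 5)
    #: mean OD over the whole plate per kingdom (OD590 units)
    kingdom_mean_od: dict = field(default_factory=lambda: {_B: 0.103, _F: 0.245})
    #: multiplicative treatment effect on the kingdom mean
    treatment_multiplier: dict = field(
        default_factory=lambda: _kt(0.951, 1.039, 1.114, 0.886)
    )
    #: per-substrate usage probability
    usage_prob: dict = field(default_factory=lambda: _kt(0.845, 0.856, 0.900, 0.834))
    #: Gamma shape of used-substrate ODs (evenness dial; higher = more even)
    concentration: dict = field(default_factory=lambda: _kt(3.9, 4.9, 7.4, 3.2))
    #: lognormal sd of the per-isolate latent factor
    isolate_sigma: float = 0.30
    #: sd of the per-substrate lognormal baseline profile (mean fixed at 1)
    baseline_sigma: float = 0.9
    water_mean: float = 0.05
    noise_sd: float = 0.002

    def validate(self) -> None:
        if self.leaves_per_treatment < 1:
            raise ValueError("need at least one leaf per treatment")
        if self.bacteria_per_leaf + self.fungi_per_leaf < 1:
            raise ValueError("need at least one isolate per leaf")
        for kd in (_B, _F):
            for trt in (_CTL, _AMD):
                p = self.usage_prob[kd][trt]
                if not 0 <= p <= 1:
                    raise ValueError(f"usage probability out of [0,1]: {p}")
                if self.concentration[kd][trt] <= 0:
                    raise ValueError("concentration must be positive")
        if self.noise_sd < 0 or self.baseline_sigma < 0 or self.isolate_sigma < 0:
            raise ValueError("sd parameters must be nonnegative")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, allow_unicode=True, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "deficit" in raw and raw["deficit"] is not None:
            raw["deficit"] = tuple(raw["deficit"])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside a simulated study."""

    config: SimConfig
    seed: int
    #: per-isolate realized lognormal factor and expected plate-mean OD
    isolate_factors: pd.DataFrame
    #: per-kingdom fixed substrate baseline (mean-1 multiplicative profile)
    baselines: dict

    def expected_plate_mean(self, kingdom: str, treatment: str) -> float:
        c = self.config
        return c.kingdom_mean_od[kingdom] * c.treatment_multiplier[kingdom][treatment]


def _substrate_baselines(sigma: float) -> dict:
    """Fixed substrate-quality profile, shared across kingdoms.

    Substrate lability is treated as substrate-intrinsic (an easily
    metabolised sugar is easy for bacteria and fungi alike), so one
    mean-1 lognormal profile drives both kingdoms; the profile is a
    constant of the generator, not redrawn per study seed.
    """
    rng = np.random.default_rng(20240590)  # internal constant, not the study seed
    b = rng.lognormal(mean=0.0, sigma=sigma, size=95)
    b = b / b.mean()
    return {_B: b, _F: b}


def simulate_study(config: SimConfig | None = None):
    """Draw one synthetic study.

    Returns ``(plates, metadata, truth)``: a list of RawPlate in metadata
    order, the metadata DataFrame (isolate_id, kingdom, treatment, leaf_id,
    plot_id), and a SyntheticTruth record.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    layout = default_layout()
    sub_wells = layout.substrate_wells
    baselines = _substrate_baselines(cfg.baseline_sigma)

    plates: list[RawPlate] = []
    meta_rows = []
    truth_rows = []
    tcode = {_CTL: "C", _AMD: "N"}
    for trt in (_CTL, _AMD):
        leaves_per_plot = max(1, cfg.leaves_per_treatment // cfg.plots_per_treatment)
        for leaf_idx in range(cfg.leaves_per_treatment):
            leaf_id = f"{tcode[trt]}-L{leaf_idx + 1}"
            plot_id = f"{tcode[trt]}-P{min(leaf_idx // leaves_per_plot, cfg.plots_per_treatment - 1) + 1}"
            for kd, default_count in ((_B, cfg.bacteria_per_leaf), (_F, cfg.fungi_per_leaf)):
                count = default_count
                if cfg.deficit is not None:
                    d_trt, d_idx, d_kd, d_count = cfg.deficit
                    if (trt, leaf_idx, kd) == (d_trt, d_idx, d_kd):
                        count = d_count
                for k in range(count):
                    iso_id = f"{kd[0]}-{leaf_id}-{k + 1:02d}"
                    p_use = cfg.usage_prob[kd][trt]
                    shape = cfg.concentration[kd][trt]
                    mult = cfg.treatment_multiplier[kd][trt]
                    factor = rng.lognormal(-cfg.isolate_sigma**2 / 2, cfg.isolate_sigma)
                    used = rng.random(95) < p_use
                    mu = (
                        cfg.kingdom_mean_od[kd] * mult * factor / max(p_use, 1e-12)
                    ) * baselines[kd]
                    latent = np.zeros(95)
                    if used.any():
                        latent[used] = rng.gamma(shape, mu[used] / shape)
                    raw_sub = cfg.water_mean + latent + rng.normal(0.0, cfg.noise_sd, 95)
                    raw_water = cfg.water_mean + rng.normal(0.0, cfg.noise_sd)
                    absorbance = dict(zip(sub_wells, raw_sub))
                    absorbance[layout.water_well] = raw_water
                    meta = IsolateMeta(iso_id, kd, trt, leaf_id, plot_id)
                    plates.append(RawPlate(iso_id, absorbance, meta))
                    meta_rows.append(
                        {
                            "isolate_id": iso_id,
                            "kingdom": kd,
                            "treatment": trt,
                            "leaf_id": leaf_id,
                            "plot_id": plot_id,
                        }
                    )
                    truth_rows.append(
                        {
                            "isolate_id": iso_id,
                            "factor": factor,
                            "expected_plate_mean": cfg.kingdom_mean_od[kd] * mult * factor,
                            "drawn_niche_width": int(used.sum()),
                        }
                    )
    metadata = pd.DataFrame(meta_rows)
    truth = SyntheticTruth(
        config=cfg,
        seed=cfg.seed,
        isolate_factors=pd.DataFrame(truth_rows),
        baselines=baselines,
    )
    return plates, metadata, truth


def planted_effect_presets() -> dict[str, SimConfig]:
    """Named generator presets used by calibration and power analyses.

    'paper-like' is the default config (effect directions and magnitudes of
    the emulated study); 'null' removes every treatment effect; 'strong'
    doubles each effect on its natural scale (log for multiplicative
    parameters, additive for usage probabilities).
    """
    paper_like = SimConfig()

    null = SimConfig(
        treatment_multiplier=_kt(1.0, 1.0, 1.0, 1.0),
        usage_prob=_kt(0.85, 0.85, 0.90, 0.90),
        concentration=_kt(4.4, 4.4, 4.4, 4.4),
    )

    def _double_ratio(c, n):
        return c * (n / c) ** 2

    pl = paper_like
    strong = SimConfig(
        treatment_multiplier={
            kd: {
                _CTL: pl.treatment_multiplier[kd][_CTL],
                _AMD: _double_ratio(
                    pl.treatment_multiplier[kd][_CTL], pl.treatment_multiplier[kd][_AMD]
                ),
            }
            for kd in (_B, _F)
        },
        usage_prob={
            kd: {
                _CTL: pl.usage_prob[kd][_CTL],
                _AMD: min(1.0, max(0.0, pl.usage_prob[kd][_CTL]
                                   + 2 * (pl.usage_prob[kd][_AMD] - pl.usage_prob[kd][_CTL]))),
            }
            for kd in (_B, _F)
        },
        concentration={
            kd: {
                _CTL: pl.concentration[kd][_CTL],
                _AMD: _double_ratio(pl.concentration[kd][_CTL], pl.concentration[kd][_AMD]),
            }
            for kd in (_B, _F)
        },
    )
    return {"null": null, "paper-like": paper_like, "strong": strong}


def get_preset(name: str, seed: int | None = None) -> SimConfig:
    presets = planted_effect_presets()
    if name not in presets:
        raise ValueError(f"unknown preset '{name}' (have: {sorted(presets)})")
    cfg = presets[name]
    if seed is not None:
        cfg.seed = seed
    return cfg


def write_study(outdir, config: SimConfig | None = None) -> dict[str, Path]:
    """Simulate and write a study in the dialects plate_io reads.

    Emits plates.csv (wide raw absorbances), metadata.csv, layout.csv and
    truth.yaml; byte-identical for a given config (floats written with
    shortest round-trip repr).
    """
    cfg = config or SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plates, metadata, truth = simulate_study(cfg)
    layout = default_layout()

    paths = {
        "plates": outdir / "plates.csv",
        "metadata": outdir / "metadata.csv",
        "layout": outdir / "layout.csv",
        "truth": outdir / "truth.yaml",
        "config": outdir / "config.yaml",
    }
    with open(paths["plates"], "w") as fh:
        fh.write("isolate_id," + ",".join(WELLS) + "\n")
        for p in plates:
            fh.write(p.isolate_id + "," + ",".join(repr(float(p.absorbance[w])) for w in WELLS) + "\n")
    metadata.to_csv(paths["metadata"], index=False)
    with open(paths["layout"], "w") as fh:
        fh.write("well,substrate,is_water\n")
        for w in WELLS:
            if w == layout.water_well:
                fh.write(f"{w},water,1\n")
            else:
                fh.write(f"{w},{layout.substrate_by_well[w]},0\n")
    cfg.to_yaml(paths["config"])
    truth_doc = {
        "seed": truth.seed,
        "config": dataclasses.asdict(cfg),
        "isolate_factors": {
            r.isolate_id: float(r.factor) for r in truth.isolate_factors.itertuples()
        },
    }
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth_doc, fh, allow_unicode=True, sort_keys=True)
    return paths


def simulate_phylo_distances(d_pheno, r: float, seed=None):
    """Distance matrix with a planted linear relation to a phenotype matrix.

    Off-diagonal entries are r x (standardised phenotype distances) plus
    independent Gaussian noise scaled so the expected OLS/Mantel R^2 is r^2,
    then affinely mapped to a positive range. Used only to exercise Mantel
    and regression recovery; the output is symmetric with zero diagonal but
    not guaranteed metric.
    """
    from skbio import DistanceMatrix  # local import to keep module load light

    if not 0 <= r <= 1:
        raise ValueError("r must be in [0, 1]")
    rng = np.random.default_rng(seed)
    d = d_pheno.data
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    x = d[iu]
    z = (x - x.mean()) / x.std()
    y = r * z + np.sqrt(1 - r**2) * rng.standard_normal(x.size)
    y = 0.05 * (y - y.min()) + 0.01
    out = np.zeros_like(d)
    out[iu] = y
    out = out + out.T
    return DistanceMatrix(out, ids=list(d_pheno.ids))
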