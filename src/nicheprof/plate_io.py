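"""Reading, validation and water-correction of Biolog SF-P2 plate tables.

A plate is a 96-well absorbance record (OD590 at the 72-h endpoint): 95
single-carbon wells plus one water control. An isolate's carbon-use profile
is the vector of water-corrected ODs over the 95 substrate wells, and a
substrate counts as *used* when its corrected OD is at least the usage
threshold (0.005 by default, inclusive).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical well order: A1..A12, B1..B12, ... H12.
WELLS: tuple[str, ...] = tuple(f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13))

#: Default usage threshold on water-corrected OD (inclusive).
USAGE_THRESHOLD: float = 0.005

#: Tolerance making the inclusive threshold robust to float rounding
#: (e.g. 0.055 - 0.050 = 0.004999999999999997 must still count as used).
_THRESHOLD_EPS: float = 1e-12


def usage_mask(corrected_od: np.ndarray, threshold: float = USAGE_THRESHOLD) -> np.ndarray:
    """Inclusive usage criterion: corrected OD >= threshold (rounding-tolerant)."""
    return np.asarray(corrected_od) >= threshold - _THRESHOLD_EPS

KINGDOMS = ("Bacteria", "Fungi")
TREATMENT_CONTROL = "control"
TREATMENT_AMENDED = "NPKμ"
TREATMENTS = (TREATMENT_CONTROL, TREATMENT_AMENDED)

_KINGDOM_ALIASES = {"bacteria": "Bacteria", "fungi": "Fungi"}
_TREATMENT_ALIASES = {
    "control": TREATMENT_CONTROL,
    "npkμ": TREATMENT_AMENDED,
    "npku": TREATMENT_AMENDED,
    "npkmu": TREATMENT_AMENDED,
}

METADATA_COLUMNS = ("isolate_id", "kingdom", "treatment", "leaf_id", "plot_id")


class PlateError(ValueError):
    """Structured parse/validation error for plate inputs."""


def _read_table(path) -> pd.DataFrame:
    """Read a comma- or tab-delimited text table (delimiter sniffed)."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)


@dataclass(frozen=True)
class PlateLayout:
    """Mapping of the 96 wells to substrate names plus the water-control well."""

    substrate_by_well: Mapping[str, str]
    water_well: str

    def __post_init__(self) -> None:
        wells = set(self.substrate_by_well) | {self.water_well}
        if wells != set(WELLS):
            missing = sorted(set(WELLS) - wells)
            extra = sorted(wells - set(WELLS))
            raise PlateError(f"layout does not cover the 96 wells (missing={missing}, extra={extra})")
        if self.water_well in self.substrate_by_well:
            raise PlateError(f"water well {self.water_well} also mapped to a substrate")
        names = list(self.substrate_by_well.values())
        if len(set(names)) != 95:
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PlateError(f"substrate names not unique: {dupes}")

    @property
    def substrate_wells(self) -> tuple[str, ...]:
        """The 95 substrate wells in canonical order."""
        return tuple(w for w in WELLS if w != self.water_well)

    @property
    def substrates(self) -> tuple[str, ...]:
        """Substrate names in canonical well order."""
        return tuple(self.substrate_by_well[w] for w in self.substrate_wells)


@dataclass(frozen=True)
class IsolateMeta:
    isolate_id: str
    kingdom: str
    treatment: str
    leaf_id: str
    plot_id: str


@dataclass(frozen=True)
class RawPlate:
    """One isolate's uncorrected 96-well absorbance record."""

    isolate_id: str
    absorbance: Mapping[str, float]
    meta: IsolateMeta

    def __post_init__(self) -> None:
        missing = [w for w in WELLS if w not in self.absorbance]
        if missing:
            raise PlateError(f"isolate {self.isolate_id} missing wells: {', '.join(missing)}")
        extra = sorted(set(self.absorbance) - set(WELLS))
        if extra:
            raise PlateError(f"isolate {self.isolate_id} has unknown wells: {extra}")
        vals = np.asarray([self.absorbance[w] for w in WELLS], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise PlateError(f"isolate {self.isolate_id} has non-finite absorbance values")


@dataclass(frozen=True)
class IsolateProfile:
    """Water-corrected carbon-use profile over the 95 substrates (layout order)."""

    isolate_id: str
    meta: IsolateMeta
    substrates: tuple[str, ...]
    corrected_od: np.ndarray  # raw - water, may be negative
    usage: np.ndarray  # corrected_od >= threshold
    threshold: float = USAGE_THRESHOLD

    def __post_init__(self) -> None:
        if len(self.substrates) != 95 or self.corrected_od.shape != (95,) or self.usage.shape != (95,):
            raise PlateError("profile must cover exactly 95 substrates")

    @property
    def corrected_od_nonneg(self) -> np.ndarray:
        """Corrected ODs with negatives clipped to zero (for abundance-style math)."""
        return np.maximum(self.corrected_od, 0.0)


def default_layout() -> PlateLayout:
    """The SF-P2 layout shipped with the package (water control at A1)."""
    with importlib.resources.files("nicheprof.data").joinpath("sfp2_layout.csv").open() as fh:
        return read_layout(fh)


def read_layout(path) -> PlateLayout:
    """Read a `well,substrate,is_water` delimited layout table."""
    df = _read_table(path)
    required = {"well", "substrate", "is_water"}
    if not required.issubset(df.columns):
        raise PlateError(f"layout must have columns {sorted(required)}, found {list(df.columns)}")
    if len(df) != 96:
        raise PlateError(f"expected 96 wells, found {len(df)}")
    wells = df["well"].str.strip().tolist()
    dupes = sorted({w for w in wells if wells.count(w) > 1})
    if dupes:
        raise PlateError(f"duplicate wells in layout: {dupes}")
    is_water = df["is_water"].str.strip().str.lower().map(
        {"1": True, "0": False, "true": True, "false": False}
    )
    if is_water.isna().any():
        bad = df.loc[is_water.isna(), "well"].tolist()
        raise PlateError(f"unparseable is_water flag at wells: {bad}")
    n_water = int(is_water.sum())
    if n_water > 1:
        raise PlateError(f"multiple water wells: {df.loc[is_water, 'well'].tolist()}")
    if n_water == 0:
        raise PlateError("no water well marked in layout")
    water = df.loc[is_water, "well"].str.strip().iloc[0]
    mapping = {
        w: s.strip()
        for w, s, flag in zip(wells, df["substrate"], is_water)
        if not flag
    }
    return PlateLayout(substrate_by_well=mapping, water_well=water)


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the isolate metadata table.

    Kingdom and treatment labels are normalised to the canonical spellings
    ('Bacteria'/'Fungi', 'control'/'NPKμ'; ASCII 'NPKu' accepted).
    """
    df = _read_table(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise PlateError(f"metadata missing columns: {missing}")
    df = df[list(METADATA_COLUMNS)].copy()
    for col in METADATA_COLUMNS:
        df[col] = df[col].astype(str).str.strip()
    dupes = df.loc[df["isolate_id"].duplicated(), "isolate_id"].tolist()
    if dupes:
        raise PlateError(f"duplicate isolate_id in metadata: {sorted(set(dupes))}")
    kingdom = df["kingdom"].str.lower().map(_KINGDOM_ALIASES)
    if kingdom.isna().any():
        bad = sorted(df.loc[kingdom.isna(), "kingdom"].unique())
        raise PlateError(f"unknown kingdom values: {bad} (expected Bacteria or Fungi)")
    treatment = df["treatment"].str.lower().map(_TREATMENT_ALIASES)
    if treatment.isna().any():
        bad = sorted(df.loc[treatment.isna(), "treatment"].unique())
        raise PlateError(f"unknown treatment values: {bad} (expected control or NPKμ)")
    df["kingdom"] = kingdom
    df["treatment"] = treatment
    return df


def _plates_from_wide(df: pd.DataFrame, meta: pd.DataFrame) -> list[RawPlate]:
    missing_cols = [w for w in WELLS if w not in df.columns]
    if missing_cols:
        raise PlateError(f"wide plate table missing well columns: {missing_cols}")
    by_id = df.set_index("isolate_id")
    plates = []
    for row in meta.itertuples(index=False):
        if row.isolate_id not in by_id.index:
            raise PlateError(f"isolate {row.isolate_id} has metadata but no plate row")
        rec = by_id.loc[row.isolate_id]
        try:
            absorbance = {w: float(rec[w]) for w in WELLS}
        except (TypeError, ValueError) as exc:
            raise PlateError(f"isolate {row.isolate_id}: non-numeric absorbance ({exc})") from None
        plates.append(RawPlate(row.isolate_id, absorbance, IsolateMeta(**row._asdict())))
    return plates


def _plates_from_long(df: pd.DataFrame, meta: pd.DataFrame) -> list[RawPlate]:
    value_col = next((c for c in ("absorbance", "od", "value") if c in df.columns), None)
    if value_col is None:
        raise PlateError("long plate table needs an 'absorbance' (or 'od'/'value') column")
    plates = []
    grouped = dict(tuple(df.groupby("isolate_id", sort=False)))
    for row in meta.itertuples(index=False):
        sub = grouped.get(row.isolate_id)
        if sub is None:
            raise PlateError(f"isolate {row.isolate_id} has metadata but no plate rows")
        if sub["well"].duplicated().any():
            dupes = sorted(sub.loc[sub["well"].duplicated(), "well"].unique())
            raise PlateError(f"isolate {row.isolate_id} has duplicate wells: {dupes}")
        try:
            absorbance = {w: float(v) for w, v in zip(sub["well"].str.strip(), sub[value_col])}
        except (TypeError, ValueError) as exc:
            raise PlateError(f"isolate {row.isolate_id}: non-numeric absorbance ({exc})") from None
        plates.append(RawPlate(row.isolate_id, absorbance, IsolateMeta(**row._asdict())))
    return plates


def read_plates(path, layout: PlateLayout, metadata_path) -> list[RawPlate]:
    """Read plate absorbances (wide or long dialect) joined to metadata.

    Wide: one row per isolate with columns ``isolate_id,A1,...,H12``.
    Long: one row per isolate x well with columns ``isolate_id,well,absorbance``.
    Isolate order follows the metadata table; plate rows lacking metadata are
    ignored, metadata rows lacking a plate raise.
    """
    meta = metadata_path if isinstance(metadata_path, pd.DataFrame) else read_metadata(metadata_path)
    df = _read_table(path)
    if "isolate_id" not in df.columns:
        raise PlateError("plate table missing 'isolate_id' column")
    df["isolate_id"] = df["isolate_id"].astype(str).str.strip()
    if "well" in df.columns:
        return _plates_from_long(df, meta)
    return _plates_from_wide(df, meta)


def correct_and_threshold(
    plate: RawPlate, layout: PlateLayout, threshold: float = USAGE_THRESHOLD
) -> IsolateProfile:
    """Water-correct a raw plate and apply the usage criterion.

    corrected_od[n] = raw[n] - raw[water well]; usage is the inclusive
    comparison corrected_od >= threshold. Negative corrected values are
    legal and retained (clipping happens downstream where nonnegativity is
    mathematically required).
    """
    water = float(plate.absorbance[layout.water_well])
    corrected = np.asarray(
        [float(plate.absorbance[w]) - water for w in layout.substrate_wells], dtype=float
    )
    return IsolateProfile(
        isolate_id=plate.isolate_id,
        meta=plate.meta,
        substrates=layout.substrates,
        corrected_od=corrected,
        usage=usage_mask(corrected, threshold),
        threshold=threshold,
    )


def profiles_from_files(
    plates_path, layout_path=None, metadata_path=None, threshold: float = USAGE_THRESHOLD
) -> list[IsolateProfile]:
    """Convenience: layout + metadata + plates -> corrected profiles."""
    layout = default_layout() if layout_path is None else read_layout(layout_path)
    plates = read_plates(plates_path, layout, metadata_path)
    return [correct_and_threshold(p, layout, threshold) for p in plates]


def write_profiles(profiles: Sequence[IsolateProfile], path) -> None:
    """Write corrected profiles as wide delimited text (round-trip exact).

    Columns: isolate_id, kingdom, treatment, leaf_id, plot_id, then the 95
    substrate names in layout order. Floats are written with shortest
    round-trip repr so read_profiles(write_profiles(x)) reproduces the
    corrected matrix bit for bit.
    """
    ids = [p.isolate_id for p in profiles]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise PlateError(f"duplicate isolate_id: {dupes}")
    if not profiles:
        raise PlateError("no profiles to write")
    substrates = profiles[0].substrates
    with open(path, "w") as fh:
        fh.write(",".join(list(METADATA_COLUMNS) + list(substrates)) + "\n")
        for p in profiles:
            if p.substrates != substrates:
                raise PlateError("profiles disagree on substrate layout")
            m = p.meta
            fields = [p.isolate_id, m.kingdom, m.treatment, m.leaf_id, m.plot_id]
            fields += [repr(float(v)) for v in p.corrected_od]
            fh.write(",".join(fields) + "\n")


def read_profiles(path, threshold: float = USAGE_THRESHOLD) -> list[IsolateProfile]:
    """Read profiles written by :func:`write_profiles`."""
    df = _read_table(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise PlateError(f"profile table missing columns: {missing}")
    substrates = tuple(c for c in df.columns if c not in METADATA_COLUMNS)
    if len(substrates) != 95:
        raise PlateError(f"expected 95 substrate columns, found {len(substrates)}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        meta = IsolateMeta(*(str(d[c]) for c in METADATA_COLUMNS))
        corrected = np.asarray([float(d[s]) for s in substrates], dtype=float)
        out.append(
            IsolateProfile(
                isolate_id=meta.isolate_id,
                meta=meta,
                substrates=substrates,
                corrected_od=corrected,
                usage=usage_mask(corrected, threshold),
                threshold=threshold,
            )
        )
    return out


def profile_matrix(profiles: Sequence[IsolateProfile], clipped: bool = True) -> pd.DataFrame:
    """Stack profiles into an isolates x substrates DataFrame."""
    if not profiles:
        raise PlateError("empty profile list")
    data = np.vstack([
        p.corrected_od_nonneg if clipped else p.corrected_od for p in profiles
    ])
    return pd.DataFrame(data, index=[p.isolate_id for p in profiles], columns=list(profiles[0].substrates))


def metadata_frame(profiles: Sequence[IsolateProfile]) -> pd.DataFrame:
    """Metadata of a profile list as a DataFrame indexed by isolate_id."""
    rows = [
        {
            "isolate_id": p.isolate_id,
            "kingdom": p.meta.kingdom,
            "treatment": p.meta.treatment,
            "leaf_id": p.meta.leaf_id,
            "plot_id": p.meta.plot_id,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows).set_index("isolate_id")
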