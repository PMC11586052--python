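"""Directional pairwise niche overlap and sympatric pair enumeration.

For an ordered pair of isolates (i -> j), each substrate n on which both
meet the usage criterion contributes the capped ratio
min(OD_i,n / OD_j,n, 1) — the fraction of j's growth on n that i matches —
and every other substrate contributes 0. The mean over the full plate,

    omega_bar(i -> j) = (1/95) * sum_n omega_n,

is a proxy for i's competitive pressure on j. The statistic is directional:
omega_bar(i -> j) and omega_bar(j -> i) generally differ because the two
niches differ in width and in depth of use.

Pairs are restricted to sympatry (same leaf) by default, matching how the
summaries are reported; each directed pair carries a class tag
source-kingdom:target-kingdom (B:B, F:F, B:F, F:B).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .plate_io import IsolateProfile

N_SUBSTRATES = 95

PAIR_CLASSES = ("B:B", "F:F", "B:F", "F:B")

_KINGDOM_CODE = {"Bacteria": "B", "Fungi": "F"}


def pairwise_overlap(i: IsolateProfile, j: IsolateProfile) -> float:
    """omega_bar(i -> j): mean capped OD ratio over the 95 substrates.

    Substrates where either isolate fails the usage criterion contribute 0;
    the denominator is fixed at 95 regardless of how many are co-used.
    """
    both = i.usage & j.usage
    if not both.any():
        return 0.0
    oi = i.corrected_od_nonneg[both]
    oj = j.corrected_od_nonneg[both]
    return float(np.minimum(oi / oj, 1.0).sum()) / N_SUBSTRATES


@dataclass(frozen=True)
class PairUniverse:
    """All ordered within-leaf pairs with class and treatment tags."""

    pairs: pd.DataFrame  # leaf_id, treatment, source_id, target_id, pair_class

    def class_counts(self) -> pd.DataFrame:
        """Directed-pair counts per (pair_class, treatment)."""
        out = (
            self.pairs.groupby(["pair_class", "treatment"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )
        return out

    def count(self, pair_class: str, treatment: str) -> int:
        sel = (self.pairs["pair_class"] == pair_class) & (self.pairs["treatment"] == treatment)
        return int(sel.sum())


def sympatric_pairs(profiles: Sequence[IsolateProfile]) -> PairUniverse:
    """Enumerate all ordered pairs of isolates sharing a leaf.

    A leaf with m isolates yields m(m-1) ordered pairs. Deterministic order:
    leaf (input order of first appearance), then source, then target, both
    in input order.
    """
    rows = []
    by_leaf: dict[str, list[IsolateProfile]] = {}
    for p in profiles:
        by_leaf.setdefault(p.meta.leaf_id, []).append(p)
    for leaf, members in by_leaf.items():
        for src in members:
            for tgt in members:
                if src.isolate_id == tgt.isolate_id:
                    continue
                rows.append(
                    {
                        "leaf_id": leaf,
                        "treatment": src.meta.treatment,
                        "source_id": src.isolate_id,
                        "target_id": tgt.isolate_id,
                        "pair_class": f"{_KINGDOM_CODE[src.meta.kingdom]}:{_KINGDOM_CODE[tgt.meta.kingdom]}",
                    }
                )
    cols = ["leaf_id", "treatment", "source_id", "target_id", "pair_class"]
    return PairUniverse(pd.DataFrame(rows, columns=cols))


def overlap_table(profiles: Sequence[IsolateProfile], sympatric_only: bool = True) -> pd.DataFrame:
    """omega_bar for every ordered (by default within-leaf) pair.

    Vectorised per leaf: for the clipped OD matrix X and usage mask U of a
    leaf's isolates, omega_bar(i->j) = sum_n [U_i & U_j] * min(X_i/X_j, 1) / 95.
    Columns: source_id, target_id, leaf_id, treatment, pair_class, omega_bar.
    """
    groups: dict[str, list[IsolateProfile]]
    if sympatric_only:
        groups = {}
        for p in profiles:
            groups.setdefault(p.meta.leaf_id, []).append(p)
    else:
        groups = {"__all__": list(profiles)}

    frames = []
    for leaf, members in groups.items():
        m = len(members)
        if m < 2:
            continue
        x = np.vstack([p.corrected_od_nonneg for p in members])
        u = np.vstack([p.usage for p in members])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = x[:, None, :] / x[None, :, :]
        ratio = np.where(np.isfinite(ratio), np.minimum(ratio, 1.0), 0.0)
        contrib = ratio * (u[:, None, :] & u[None, :, :])
        omega = contrib.sum(axis=2) / N_SUBSTRATES
        ids = [p.isolate_id for p in members]
        codes = [_KINGDOM_CODE[p.meta.kingdom] for p in members]
        rows = []
        for a in range(m):
            for b in range(m):
                if a == b:
                    continue
                rows.append(
                    {
                        "source_id": ids[a],
                        "target_id": ids[b],
                        "leaf_id": members[a].meta.leaf_id,
                        "treatment": members[a].meta.treatment,
                        "pair_class": f"{codes[a]}:{codes[b]}",
                        "omega_bar": omega[a, b],
                    }
                )
        frames.append(pd.DataFrame(rows))
    cols = ["source_id", "target_id", "leaf_id", "treatment", "pair_class", "omega_bar"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


def group_overlap_summary(entries: pd.DataFrame) -> pd.DataFrame:
    """n, mean and sd of omega_bar per (pair_class, treatment) cell.

    The table covers the full pair_class x observed-treatment grid; empty
    cells report n=0 with NaN (undefined) mean/sd.
    """
    out = (
        entries.groupby(["pair_class", "treatment"], observed=True)["omega_bar"]
        .agg(n="size", mean="mean", sd="std")
    )
    treatments = pd.unique(entries["treatment"]) if len(entries) else []
    full = pd.MultiIndex.from_product([PAIR_CLASSES, treatments], names=["pair_class", "treatment"])
    out = out.reindex(full)
    out["n"] = out["n"].fillna(0).astype(int)
    return out.reset_index()
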