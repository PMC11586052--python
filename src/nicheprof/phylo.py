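"""Pairwise phylogenetic distances from marker-gene alignments.

Bacterial (16S) and fungal (ITS) alignments are handled separately and
never mixed. The default distance is the uncorrected p-distance — the
proportion of differing sites among pairwise-complete positions (sites
where both sequences carry an unambiguous A/C/G/T, with U read as T); the
Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3) is available for multiple
substitutions and is undefined (NaN) at p >= 0.75. Gap/ambiguity handling
is pairwise deletion by default, with complete deletion as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix


@dataclass(frozen=True)
class Alignment:
    labels: tuple[str, ...]
    matrix: np.ndarray  # (n_seqs, n_sites) of single characters, upper-case

    def __post_init__(self) -> None:
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("label/sequence count mismatch")
        if self.matrix.shape[1] < 1:
            raise ValueError("alignment has zero columns")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file; ragged lengths or duplicate labels raise."""
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    labels = [r.id for r in records]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValueError(f"duplicate sequence labels: {dupes}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    matrix = np.array([list(str(r.seq).upper().replace("U", "T")) for r in records])
    return Alignment(tuple(labels), matrix)


_VALID = np.array(list("ACGT"))


def _comparable(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.isin(a, _VALID) & np.isin(b, _VALID)


def p_distance(aln: Alignment, pair: tuple[str, str], complete_deletion: bool = False) -> float:
    """Uncorrected proportion of differing sites for one label pair."""
    ia, ib = (aln.labels.index(x) for x in pair)
    a, b = aln.matrix[ia], aln.matrix[ib]
    if complete_deletion:
        ok = np.isin(aln.matrix, _VALID).all(axis=0)
    else:
        ok = _comparable(a, b)
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"no comparable sites between {pair[0]} and {pair[1]}")
    return float((a[ok] != b[ok]).sum()) / n


def jc69_from_p(p: float) -> float:
    """Jukes-Cantor distance from a p-distance; NaN at the p >= 0.75 boundary."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def jc69_distance(aln: Alignment, pair: tuple[str, str], complete_deletion: bool = False) -> float:
    return jc69_from_p(p_distance(aln, pair, complete_deletion))


def distance_matrix(aln: Alignment, model: str = "p", complete_deletion: bool = False) -> DistanceMatrix:
    """Symmetric pairwise distance matrix over the alignment's labels.

    ``model`` is 'p' (uncorrected, default) or 'jc69'. Label order matches
    the alignment, so downstream Mantel alignment can reorder by metadata.
    """
    if model not in ("p", "jc69"):
        raise ValueError("model must be 'p' or 'jc69'")
    n = len(aln.labels)
    valid = np.isin(aln.matrix, _VALID)
    if complete_deletion:
        keep = valid.all(axis=0)
        valid = valid & keep  # broadcast: only fully-valid columns comparable
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {aln.labels[i]} and {aln.labels[j]}"
                )
            p = float((aln.matrix[i, ok] != aln.matrix[j, ok]).sum()) / m
            d[i, j] = d[j, i] = jc69_from_p(p) if model == "jc69" else p
    if model == "jc69" and np.isnan(d).any():
        raise ValueError("jc69 undefined for some pair (p >= 0.75); use model='p'")
    return DistanceMatrix(d, ids=list(aln.labels))
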