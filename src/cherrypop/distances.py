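"""Pairwise distances between haplotypes.

Two metrics are provided: raw pairwise differences (counting every recoded
character, including binary indel characters, in line with treating indels as
substitutions) and the Tamura–Nei 1993 corrected distance, which allows
unequal base frequencies and distinct rates for the two transition classes
(A<->G and C<->T) versus transversions.  TN93 is defined on nucleotides only,
so indel characters are excluded there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from cherrypop.errors import InputError
from cherrypop.seqdata import HaplotypeTable

_BASES = ("A", "C", "G", "T")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    metric_tag: Literal["p_differences", "tn93"]
    saturated: np.ndarray | None = None  # boolean mask of clamped TN93 pairs
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise InputError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise InputError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise InputError("distance matrix diagonal must be zero")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in self.d[i])
                fh.write(f"{name:<10s} {row}\n")


def _difference_matrix(rows: np.ndarray) -> np.ndarray:
    """Counts of differing sites with both states non-missing, all pairs."""
    H = rows.shape[0]
    valid = rows != "N"
    d = np.zeros((H, H), dtype=float)
    for i in range(H):
        both = valid[i] & valid[i + 1 :]
        diff = (rows[i] != rows[i + 1 :]) & both
        d[i, i + 1 :] = diff.sum(axis=1)
    return d + d.T


def pairwise_differences(ht: HaplotypeTable) -> DistanceMatrix:
    """Raw number of differing characters for every haplotype pair.

    Missing states (N) are skipped pairwise; indel characters are included.
    """
    if ht.n_haplotypes < 2:
        raise InputError("need at least 2 haplotypes")
    return DistanceMatrix(list(ht.ids), _difference_matrix(ht.rows), "p_differences")


def _empirical_base_frequencies(rows: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Base frequencies pooled over all individuals (haplotypes x counts)."""
    weights = counts.sum(axis=1).astype(float)
    freqs = np.zeros(4)
    for b, base in enumerate(_BASES):
        freqs[b] = ((rows == base).sum(axis=1) * weights).sum()
    total = freqs.sum()
    if total == 0:
        raise InputError("no nucleotide cells to estimate base frequencies")
    return freqs / total


def _tn93_pair(a: np.ndarray, b: np.ndarray, L: int, g: np.ndarray) -> float | None:
    """TN93 closed form for one pair; None when saturated (log arg <= 0)."""
    gA, gC, gG, gT = g
    gR, gY = gA + gG, gC + gT
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gT * gC / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    diff = a != b
    ag = np.sum(diff & (((a == "A") & (b == "G")) | ((a == "G") & (b == "A"))))
    ct = np.sum(diff & (((a == "C") & (b == "T")) | ((a == "T") & (b == "C"))))
    P1 = ag / L
    P2 = ct / L
    Q = (diff.sum() - ag - ct) / L
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return None
    return float(-k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3))


def tn93(
    ht: HaplotypeTable,
    pooled_frequencies: bool = True,
) -> DistanceMatrix:
    """Tamura–Nei (1993) distances between haplotypes.

    Uses the closed form with empirical base frequencies (pooled over the
    whole table by default, which is more stable than per-pair frequencies on
    short fragments), the two transition proportions P1 (A<->G) and
    P2 (C<->T), and the transversion proportion Q.  Saturated pairs, where a
    logarithm argument is non-positive, are flagged and assigned the largest
    finite distance in the matrix.  If any base class frequency (purines times
    pyrimidines etc.) is zero the correction is undefined and the function
    falls back to normalized p-distances with a warning.
    """
    if ht.n_haplotypes < 2:
        raise InputError("need at least 2 haplotypes")
    rows = ht.rows[:, : ht.n_base_columns]
    H = rows.shape[0]

    g = _empirical_base_frequencies(rows, ht.counts)
    gA, gC, gG, gT = g
    gR, gY = gA + gG, gC + gT
    if min(gA, gC, gG, gT) <= 0 or gR <= 0 or gY <= 0:
        warnings.warn(
            "zero base-class frequency; TN93 undefined, falling back to p-distance",
            stacklevel=2,
        )
        raw = _difference_matrix(rows)
        L = rows.shape[1]
        dm = DistanceMatrix(list(ht.ids), raw / max(L, 1), "tn93")
        dm.notes.append("fallback: per-site p-distance (TN93 undefined)")
        return dm

    d = np.zeros((H, H))
    saturated = np.zeros((H, H), dtype=bool)
    valid = rows != "N"
    for i in range(H):
        for j in range(i + 1, H):
            both = valid[i] & valid[j]
            L = int(both.sum())
            if L == 0:
                saturated[i, j] = saturated[j, i] = True
                continue
            a, b = rows[i][both], rows[j][both]
            if pooled_frequencies:
                gi = g
            else:
                cells = np.concatenate([a, b])
                gi = np.array([(cells == base).mean() for base in _BASES])
                if gi.min() <= 0:
                    saturated[i, j] = saturated[j, i] = True
                    continue
            val = _tn93_pair(a, b, L, gi)
            if val is None:
                saturated[i, j] = saturated[j, i] = True
            else:
                d[i, j] = d[j, i] = val

    if saturated.any():
        finite_max = d[~saturated].max() if np.any(~saturated & (d > 0)) else 1.0
        d[saturated] = finite_max
        np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(list(ht.ids), d, "tn93", saturated=saturated)
    if saturated.any():
        dm.notes.append(
            f"{int(saturated.sum() // 2)} saturated pairs set to max finite distance"
        )
    return dm
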