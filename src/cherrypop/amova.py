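"""Hierarchical analysis of molecular variance (AMOVA) and pairwise Phi_ST.

Distance-based AMOVA in the Excoffier–Smouse–Quattro (1992) framework:
sums of squares are computed from squared inter-individual genetic distances
(expanded from haplotype distances and per-deme counts), variance components
from the three-level expectations with unequal sample sizes, and significance
from the standard permutation schemes:

* F_ST — permute individuals among populations across the whole system;
* F_SC — permute individuals among populations within groups;
* F_CT — permute whole populations among groups.

Phi-statistics (not allele-frequency F-statistics) are reported because the
distances may be model-corrected (e.g. Tamura–Nei).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from cherrypop.errors import InputError, InsufficientDataError
from cherrypop.seqdata import HaplotypeTable
from cherrypop.distances import DistanceMatrix


@dataclass
class AmovaResult:
    sigma2_among_groups: float
    sigma2_among_pops: float
    sigma2_within: float
    pct: tuple[float, float, float]
    F_CT: float
    F_SC: float
    F_ST: float
    p_CT: float
    p_SC: float
    p_ST: float
    df: tuple[int, int, int]
    ss: tuple[float, float, float]
    n_perm: int
    seed: int | None
    notes: list[str] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "source": [
                    "among groups",
                    "among demes within groups",
                    "within demes",
                ],
                "df": list(self.df),
                "sum_of_squares": [round(x, 4) for x in self.ss],
                "variance_component": [
                    round(self.sigma2_among_groups, 6),
                    round(self.sigma2_among_pops, 6),
                    round(self.sigma2_within, 6),
                ],
                "pct_of_total": [round(x, 4) for x in self.pct],
                "fixation_index": ["F_CT", "F_SC", "F_ST"],
                "value": [round(self.F_CT, 4), round(self.F_SC, 4), round(self.F_ST, 4)],
                "p_value": [round(self.p_CT, 4), round(self.p_SC, 4), round(self.p_ST, 4)],
            }
        )


@dataclass
class FstMatrix:
    labels: list[str]
    fst: np.ndarray
    p: np.ndarray
    n_perm: int
    seed: int | None
    notes: list[str] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.fst, index=self.labels, columns=self.labels)

    def write_tsv(self, path, stars: bool = True) -> None:
        """Square TSV of Fst values; significance stars from permutation p."""
        with open(path, "w") as fh:
            fh.write("deme\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                cells = []
                for j in range(len(self.labels)):
                    if i == j:
                        cells.append("0")
                        continue
                    star = ""
                    if stars and self.n_perm > 0:
                        pv = self.p[i, j]
                        star = "**" if pv < 0.01 else ("*" if pv < 0.05 else "")
                    cells.append(f"{self.fst[i, j]:.4f}{star}")
                fh.write(lab + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# internals


def _quad(c: np.ndarray, d2: np.ndarray) -> float:
    """Sum of squared distances over unordered individual pairs for counts c."""
    return float(0.5 * c @ d2 @ c)


def _ss_components(counts: np.ndarray, d2: np.ndarray, pop_group: np.ndarray):
    """Sums of squares (among groups, among pops within groups, within pops)."""
    N = counts.sum()
    c_tot = counts.sum(axis=1)
    ss_total = _quad(c_tot, d2) / N
    n_p = counts.sum(axis=0)
    ss_wp = sum(
        _quad(counts[:, p], d2) / n_p[p]
        for p in range(counts.shape[1])
        if n_p[p] > 0
    )
    ss_groups = 0.0
    for g in np.unique(pop_group):
        cols = np.where(pop_group == g)[0]
        c_g = counts[:, cols].sum(axis=1)
        ss_groups += _quad(c_g, d2) / c_g.sum()
    return ss_total - ss_groups, ss_groups - ss_wp, ss_wp


def _variance_components(counts: np.ndarray, d2: np.ndarray, pop_group: np.ndarray):
    """Three-level variance components and Phi statistics (unequal sizes)."""
    N = counts.sum()
    n_p = counts.sum(axis=0)
    groups = np.unique(pop_group)
    G, P = len(groups), counts.shape[1]
    ss_ag, ss_ap, ss_wp = _ss_components(counts, d2, pop_group)
    df_ag, df_ap, df_wp = G - 1, P - G, int(N) - P

    sum_np2_over_ng = 0.0
    sum_ng2 = 0.0
    for g in groups:
        cols = np.where(pop_group == g)[0]
        n_g = n_p[cols].sum()
        sum_np2_over_ng += float(np.sum(n_p[cols] ** 2)) / n_g
        sum_ng2 += n_g**2
    sum_np2 = float(np.sum(n_p**2))

    sigma_c = ss_wp / df_wp if df_wp > 0 else float("nan")
    if df_ap > 0:
        n1 = (N - sum_np2_over_ng) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n1
    else:
        sigma_b = float("nan")
    if df_ag > 0:
        n2 = (sum_np2_over_ng - sum_np2 / N) / df_ag
        n3 = (N - sum_ng2 / N) / df_ag
        sb = 0.0 if np.isnan(sigma_b) else sigma_b
        sigma_a = (ss_ag / df_ag - sigma_c - n2 * sb) / n3
    else:
        sigma_a = float("nan")

    sb = 0.0 if np.isnan(sigma_b) else sigma_b
    total = sigma_a + sb + sigma_c
    F_CT = sigma_a / total if total != 0 else float("nan")
    F_ST = (sigma_a + sb) / total if total != 0 else float("nan")
    F_SC = sigma_b / (sigma_b + sigma_c) if sigma_b + sigma_c != 0 else float("nan")
    return (
        (sigma_a, sigma_b, sigma_c),
        (F_CT, F_SC, F_ST),
        (df_ag, df_ap, df_wp),
        (ss_ag, ss_ap, ss_wp),
    )


def _counts_from_individuals(
    hap_idx: np.ndarray, pop_idx: np.ndarray, H: int, P: int
) -> np.ndarray:
    counts = np.zeros((H, P))
    np.add.at(counts, (hap_idx, pop_idx), 1.0)
    return counts


def _perm_p(count_ge: int, n_perm: int) -> float:
    return (count_ge + 1.0) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# public operations


def amova(
    ht: HaplotypeTable,
    dm: DistanceMatrix,
    hierarchy: Mapping[str, str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    truncate_negative: bool = False,
) -> AmovaResult:
    """Three-level AMOVA: among groups / among demes within groups / within demes.

    ``hierarchy`` maps deme -> group; by default the group labels attached to
    the haplotype table are used.  Negative variance components are reported
    as computed unless ``truncate_negative`` (percentages always use the
    untruncated components).  Permutation p-values use (b + 1) / (n_perm + 1).
    """
    if list(dm.ids) != list(ht.ids):
        raise InputError("distance matrix ids do not match haplotype table")
    if hierarchy is None:
        hierarchy = {d: ht.deme_meta[d][1] for d in ht.demes}
    missing = [d for d in ht.demes if d not in hierarchy]
    if missing:
        raise InputError(f"demes missing from hierarchy: {missing}")
    group_labels = sorted({hierarchy[d] for d in ht.demes})
    if len(group_labels) < 2:
        raise InsufficientDataError("AMOVA needs at least 2 groups")
    pop_group = np.array([group_labels.index(hierarchy[d]) for d in ht.demes])

    d2 = dm.d**2
    counts = ht.counts.astype(float)
    comps, (F_CT, F_SC, F_ST), df, ss = _variance_components(counts, d2, pop_group)
    notes: list[str] = []
    if df[1] == 0:
        notes.append("F_SC/sigma2_among_pops undefined: one deme per group")

    hap_idx, pop_idx = ht.expand_rows()
    H, P = ht.n_haplotypes, len(ht.demes)
    rng = np.random.default_rng(seed)

    b_st = b_sc = b_ct = 0
    group_of_pop = pop_group.copy()
    pops_by_group = [np.where(pop_group == g)[0] for g in range(len(group_labels))]
    for _ in range(n_perm):
        # F_ST: shuffle individuals among all populations
        perm = rng.permutation(hap_idx)
        c = _counts_from_individuals(perm, pop_idx, H, P)
        _, (_, _, st), _, _ = _variance_components(c, d2, pop_group)
        if not np.isnan(st) and not np.isnan(F_ST) and st >= F_ST:
            b_st += 1
        # F_SC: shuffle individuals among populations within each group
        perm2 = hap_idx.copy()
        for g_pops in pops_by_group:
            sel = np.isin(pop_idx, g_pops)
            perm2[sel] = rng.permutation(perm2[sel])
        c2 = _counts_from_individuals(perm2, pop_idx, H, P)
        _, (_, sc, _), _, _ = _variance_components(c2, d2, pop_group)
        if not np.isnan(sc) and not np.isnan(F_SC) and sc >= F_SC:
            b_sc += 1
        # F_CT: shuffle whole populations among groups (keep group sizes)
        shuffled = rng.permutation(P)
        new_group = np.empty(P, dtype=int)
        new_group[shuffled] = group_of_pop
        _, (ct, _, _), _, _ = _variance_components(counts, d2, new_group)
        if not np.isnan(ct) and not np.isnan(F_CT) and ct >= F_CT:
            b_ct += 1

    sa, sb, sc_ = comps
    if truncate_negative:
        sa, sb, sc_ = (max(x, 0.0) if not np.isnan(x) else x for x in (sa, sb, sc_))
    sb0 = 0.0 if np.isnan(comps[1]) else comps[1]
    total = comps[0] + sb0 + comps[2]
    pct = tuple(
        100.0 * x / total if not np.isnan(x) else float("nan")
        for x in (comps[0], sb0, comps[2])
    )
    return AmovaResult(
        sigma2_among_groups=sa,
        sigma2_among_pops=sb,
        sigma2_within=sc_,
        pct=pct,  # type: ignore[arg-type]
        F_CT=F_CT,
        F_SC=F_SC,
        F_ST=F_ST,
        p_CT=_perm_p(b_ct, n_perm) if n_perm else float("nan"),
        p_SC=_perm_p(b_sc, n_perm) if n_perm else float("nan"),
        p_ST=_perm_p(b_st, n_perm) if n_perm else float("nan"),
        df=df,
        ss=ss,
        n_perm=n_perm,
        seed=seed,
        notes=notes,
    )


def _pair_phi_st(c1: np.ndarray, c2: np.ndarray, d2: np.ndarray) -> float:
    """Two-level Phi_ST between two demes given haplotype counts."""
    counts = np.stack([c1, c2], axis=1)
    n_p = counts.sum(axis=0)
    N = n_p.sum()
    c_tot = counts.sum(axis=1)
    ss_total = _quad(c_tot, d2) / N
    ss_wp = sum(_quad(counts[:, p], d2) / n_p[p] for p in range(2))
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = 1, int(N) - 2
    sigma_w = ss_wp / df_wp
    n_c = (N - float(np.sum(n_p**2)) / N) / df_ap
    sigma_a = (ss_ap / df_ap - sigma_w) / n_c
    denom = sigma_a + sigma_w
    return sigma_a / denom if denom != 0 else float("nan")


def pairwise_fst(
    ht: HaplotypeTable,
    dm: DistanceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    identity: bool = False,
) -> FstMatrix:
    """Pairwise Phi_ST between demes with permutation p-values.

    Each pair is a two-level AMOVA; p-values come from permuting individuals
    between the two demes.  With ``identity=True`` the distance matrix is
    replaced by haplotype identity (1 off-diagonal), giving the classical
    frequency-based Fst.  Demes with fewer than 2 samples are excluded.
    """
    if list(dm.ids) != list(ht.ids):
        raise InputError("distance matrix ids do not match haplotype table")
    d2 = np.ones_like(dm.d) - np.eye(len(dm.ids)) if identity else dm.d**2
    sizes = ht.counts.sum(axis=0)
    keep = [j for j, d in enumerate(ht.demes) if sizes[j] >= 2]
    dropped = [d for j, d in enumerate(ht.demes) if sizes[j] < 2]
    notes = []
    if dropped:
        warnings.warn(f"demes with n < 2 excluded from pairwise Fst: {dropped}",
                      stacklevel=2)
        notes.append(f"excluded demes with n < 2: {dropped}")
    labels = [ht.demes[j] for j in keep]
    D = len(keep)
    fst = np.zeros((D, D))
    pmat = np.full((D, D), np.nan)
    rng = np.random.default_rng(seed)
    for a in range(D):
        for b in range(a + 1, D):
            c1 = ht.counts[:, keep[a]].astype(float)
            c2 = ht.counts[:, keep[b]].astype(float)
            obs = _pair_phi_st(c1, c2, d2)
            fst[a, b] = fst[b, a] = obs
            if n_perm:
                hap_pool = np.repeat(
                    np.arange(ht.n_haplotypes), (c1 + c2).astype(int)
                )
                n1 = int(c1.sum())
                count_ge = 0
                for _ in range(n_perm):
                    rng.shuffle(hap_pool)
                    p1 = np.bincount(hap_pool[:n1], minlength=ht.n_haplotypes).astype(float)
                    p2 = np.bincount(hap_pool[n1:], minlength=ht.n_haplotypes).astype(float)
                    if _pair_phi_st(p1, p2, d2) >= obs:
                        count_ge += 1
                pmat[a, b] = pmat[b, a] = _perm_p(count_ge, n_perm)
    return FstMatrix(labels=labels, fst=fst, p=pmat, n_perm=n_perm, seed=seed, notes=notes)
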