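"""Diversity indices, neutrality tests and mismatch-distribution analysis.

Implements the per-group statistics of a classical phylogeography table:

* gene (haplotype) diversity ``h`` and nucleotide diversity ``pi`` with their
  sampling standard deviations (Nei 1987; Tajima's variance for ``pi``),
* Tajima's D and Fu's Fs, with p-values from neutral constant-size coalescent
  simulation conditioned on the observed number of segregating sites,
* the mismatch distribution with a sudden-expansion (Rogers–Harpending 1992)
  fit of (tau, theta0, theta1), Harpending's raggedness index, and parametric
  bootstrap p-values for the sum of squared deviations (SSD) and raggedness.

Fu's Fs uses the Ewens sampling distribution of the number of distinct
haplotypes K: Pr(K = j) = |s(n, j)| theta^j / (theta)_n with unsigned Stirling
numbers of the first kind, evaluated exactly in log space; Fs is the log-odds
of observing at least as many haplotypes as seen, given theta estimated by the
mean number of pairwise differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from cherrypop.errors import InsufficientDataError, InputError
from cherrypop.seqdata import HaplotypeTable
from cherrypop.distances import _difference_matrix


# ---------------------------------------------------------------------------
# result containers


@dataclass
class DiversityStats:
    n: int
    k: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    S: int
    mean_pairwise_diff: float


@dataclass
class NeutralityResult:
    tajima_D: float
    p_D: float
    fu_Fs: float
    p_Fs: float
    n_sims: int
    seed: int | None
    undefined_reason: str | None = None


@dataclass
class MismatchResult:
    observed: np.ndarray  # relative frequencies over classes 0..dmax
    tau: float
    theta0: float
    theta1: float
    ssd: float
    p_ssd: float
    raggedness: float
    p_rag: float
    n_boot: int
    seed: int | None
    converged: bool = True
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# subset handling


def _select(ht: HaplotypeTable, demes=None, group=None) -> HaplotypeTable:
    if demes is not None and group is not None:
        raise InputError("give either demes or group, not both")
    if group is not None:
        demes = [d for d in ht.demes if ht.deme_meta[d][1] == group]
        if not demes:
            raise InputError(f"no demes with group label {group!r}")
    if demes is not None:
        return ht.subset(list(demes))
    return ht


def _segregating_sites(rows: np.ndarray) -> int:
    S = 0
    for j in range(rows.shape[1]):
        states = set(rows[:, j]) - {"N", "-"}
        if len(states) >= 2:
            S += 1
    return S


def mean_pairwise_differences(ht: HaplotypeTable) -> float:
    """Mean number of character differences over all individual pairs."""
    n = ht.total_n
    if n < 2:
        raise InsufficientDataError("need n >= 2")
    c = ht.counts.sum(axis=1).astype(float)
    if ht.n_haplotypes == 1:
        return 0.0
    d = _difference_matrix(ht.rows)
    num = 0.5 * c @ d @ c  # sum over unordered pairs of distinct haplotypes
    return float(num / (n * (n - 1) / 2.0))


# ---------------------------------------------------------------------------
# diversity


def diversity(
    ht: HaplotypeTable,
    demes: Sequence[str] | None = None,
    group: str | None = None,
) -> DiversityStats:
    """Gene diversity, nucleotide diversity and related indices for a subset.

    ``h = n (1 - sum p_i^2) / (n - 1)`` over haplotype frequencies, with Nei's
    (1987) sampling variance; ``pi`` is the mean pairwise difference per
    character, with Tajima's sampling variance (which includes the
    evolutionary variance term, the convention of standard population-genetics
    software tables).
    """
    sub = _select(ht, demes, group)
    n = sub.total_n
    if n < 2:
        raise InsufficientDataError(f"diversity needs n >= 2, got {n}")
    c = sub.counts.sum(axis=1).astype(float)
    p = c / n
    sum_p2 = float(np.sum(p**2))
    h = n * (1.0 - sum_p2) / (n - 1.0)
    var_h = (
        2.0
        / (n * (n - 1.0))
        * (
            2.0 * (n - 2.0) * (float(np.sum(p**3)) - sum_p2**2)
            + sum_p2
            - sum_p2**2
        )
    )
    h_sd = math.sqrt(max(var_h, 0.0))

    mpd = mean_pairwise_differences(sub)
    L = sub.length
    pi = mpd / L
    var_pi = (n + 1.0) / (3.0 * (n - 1.0) * L) * pi + (
        2.0 * (n**2 + n + 3.0)
    ) / (9.0 * n * (n - 1.0)) * pi**2
    pi_sd = math.sqrt(max(var_pi, 0.0))

    return DiversityStats(
        n=n,
        k=sub.n_haplotypes,
        h=h,
        h_sd=h_sd,
        pi=pi,
        pi_sd=pi_sd,
        S=_segregating_sites(sub.rows),
        mean_pairwise_diff=mpd,
    )


# ---------------------------------------------------------------------------
# Tajima's D


@lru_cache(maxsize=None)
def _tajima_constants(n: int) -> tuple[float, float, float]:
    """(a1, e1, e2) for sample size n."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_D(n: int, S: int, mean_pairwise_diff: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise diff.

    Returns NaN when undefined (S = 0 or n < 4).
    """
    if S < 1 or n < 4:
        return float("nan")
    a1, e1, e2 = _tajima_constants(n)
    denom = math.sqrt(e1 * S + e2 * S * (S - 1.0))
    if denom == 0:
        return float("nan")
    return (mean_pairwise_diff - S / a1) / denom


# ---------------------------------------------------------------------------
# Fu's Fs


@lru_cache(maxsize=None)
def _log_stirling_first(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, j)|, j=0..n.

    Exact integer recurrence s(n+1, j) = s(n, j-1) + n s(n, j), then log.
    """
    row = [1]  # n = 0
    for m in range(n):
        new = [0] * (len(row) + 1)
        for j, v in enumerate(row):
            new[j] += m * v
            new[j + 1] += v
        row = new
    out = np.full(n + 1, -np.inf)
    for j, v in enumerate(row):
        if v > 0:
            out[j] = _log_of_int(v)
    return out


def _log_of_int(v: int) -> float:
    # math.log overflows for ints > float max; shift by bit length
    if v < 2**1000:
        return math.log(v)
    k = v.bit_length() - 900
    return math.log(v >> k) + k * math.log(2.0)


def _ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = j | theta) for j = 1..n under the Ewens sampling formula."""
    ls = _log_stirling_first(n)[1:]
    j = np.arange(1, n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    return ls + j * math.log(theta) - log_rising


def fu_fs(n: int, k: int, mean_pairwise_diff: float) -> float:
    """Fu's Fs statistic.

    ``Fs = ln(S' / (1 - S'))`` with ``S' = Pr(K >= k)`` under the Ewens
    distribution at ``theta`` equal to the mean pairwise difference.  Returns
    NaN when degenerate (theta <= 0, or k outside 2..n).
    """
    if mean_pairwise_diff <= 0 or k < 2 or k > n or n < 2:
        return float("nan")
    logp = _ewens_log_pmf(n, mean_pairwise_diff)
    log_upper = logsumexp(logp[k - 1 :])  # Pr(K >= k)
    log_lower = logsumexp(logp[: k - 1])  # Pr(K < k)
    return float(log_upper - log_lower)


# ---------------------------------------------------------------------------
# neutral coalescent null (single population, conditioned on S)


def _sim_topology(n: int, rng: np.random.Generator):
    """Kingman coalescent tree: returns (branch_lengths, leaf_masks) lists.

    Times are in units of 2N generations; only relative branch lengths matter
    for conditional mutation placement.  Leaf sets are integer bitmasks.
    """
    masks = [1 << i for i in range(n)]
    times = [0.0] * n
    branch_len: list[float] = []
    branch_mask: list[int] = []
    active = list(range(n))
    node_time = 0.0
    all_times = times[:]
    parent_of: dict[int, int] = {}
    nodes_masks = masks[:]
    while len(active) > 1:
        kk = len(active)
        node_time += rng.exponential(1.0 / (kk * (kk - 1) / 2.0))
        i, j = rng.choice(kk, size=2, replace=False)
        a, b = active[i], active[j]
        new = len(nodes_masks)
        nodes_masks.append(nodes_masks[a] | nodes_masks[b])
        all_times.append(node_time)
        for child in (a, b):
            branch_len.append(node_time - all_times[child])
            branch_mask.append(nodes_masks[child])
        active = [x for x in active if x not in (a, b)] + [new]
    return branch_len, branch_mask


def _null_replicate(n: int, S: int, rng: np.random.Generator):
    """One neutral constant-size replicate with exactly S mutations.

    Returns (mean_pairwise_diff, n_haplotypes).
    """
    blen, bmask = _sim_topology(n, rng)
    probs = np.asarray(blen)
    probs = probs / probs.sum()
    muts = rng.multinomial(S, probs)
    mpd = 0.0
    sigs = [0] * n
    bit = 0
    for count, mask in zip(muts, bmask):
        count = int(count)  # python int: the signature bitmask is unbounded
        if count == 0:
            continue
        c = mask.bit_count()
        mpd += count * 2.0 * c * (n - c)
        chunk = ((1 << count) - 1) << bit
        m = mask
        while m:
            low = m & -m
            leaf = low.bit_length() - 1
            sigs[leaf] |= chunk
            m ^= low
        bit += count
    mpd /= n * (n - 1.0)
    return mpd, len(set(sigs))


def neutrality_pvalues(
    ht: HaplotypeTable,
    demes: Sequence[str] | None = None,
    group: str | None = None,
    n_sims: int = 1000,
    seed: int | None = None,
    tail: str = "lower",
) -> NeutralityResult:
    """Tajima's D and Fu's Fs with coalescent-simulated p-values.

    The null is the constant-size neutral coalescent at the observed sample
    size, conditioned on the observed number of segregating sites S (mutations
    placed on the simulated genealogy in proportion to branch lengths).  The
    default p-values are lower-tail — the probability of a simulated statistic
    at least as negative as observed — matching the usual reading that
    significantly negative D/Fs indicate demographic expansion.  ``tail`` may
    be set to ``"two_sided"``.
    """
    import warnings

    if n_sims < 100:
        warnings.warn(f"n_sims={n_sims} < 100: p-values will be noisy", stacklevel=2)
    sub = _select(ht, demes, group)
    n = sub.total_n
    S = _segregating_sites(sub.rows)
    mpd = mean_pairwise_differences(sub)
    k = sub.n_haplotypes
    D_obs = tajimas_D(n, S, mpd)
    Fs_obs = fu_fs(n, k, mpd)
    if S < 1:
        return NeutralityResult(
            float("nan"), float("nan"), float("nan"), float("nan"),
            n_sims, seed, undefined_reason="no segregating sites",
        )
    rng = np.random.default_rng(seed)
    D_null = np.empty(n_sims)
    Fs_null = np.empty(n_sims)
    for r in range(n_sims):
        mpd_s, k_s = _null_replicate(n, S, rng)
        D_null[r] = tajimas_D(n, S, mpd_s)
        Fs_null[r] = fu_fs(n, k_s, mpd_s)

    def _p(null: np.ndarray, obs: float) -> float:
        if math.isnan(obs):
            return float("nan")
        ok = ~np.isnan(null)
        if not ok.any():
            return float("nan")
        lower = float(np.mean(null[ok] <= obs))
        if tail == "lower":
            return lower
        upper = float(np.mean(null[ok] >= obs))
        return min(1.0, 2.0 * min(lower, upper))

    return NeutralityResult(
        tajima_D=D_obs,
        p_D=_p(D_null, D_obs),
        fu_Fs=Fs_obs,
        p_Fs=_p(Fs_null, Fs_obs),
        n_sims=n_sims,
        seed=seed,
        undefined_reason=None if not math.isnan(Fs_obs) else "Fs degenerate",
    )


# ---------------------------------------------------------------------------
# mismatch distribution


def mismatch_observed(ht: HaplotypeTable) -> np.ndarray:
    """Relative frequencies of pairwise difference counts (classes 0..dmax)."""
    n = ht.total_n
    if n < 2:
        raise InsufficientDataError("need n >= 2")
    c = ht.counts.sum(axis=1).astype(float)
    d = _difference_matrix(ht.rows).astype(int)
    dmax = int(d.max())
    freq = np.zeros(dmax + 1)
    for i in range(len(c)):
        freq[0] += c[i] * (c[i] - 1) / 2.0
        for j in range(i + 1, len(c)):
            freq[d[i, j]] += c[i] * c[j]
    total = n * (n - 1) / 2.0
    return freq / total


@lru_cache(maxsize=64)
def _log_factorials(n: int) -> np.ndarray:
    out = np.zeros(n)
    out[1:] = np.cumsum(np.log(np.arange(1, n)))
    return out


def _stationary_mismatch(theta: float, classes: np.ndarray) -> np.ndarray:
    """Pr(j differences) between two genes in a stationary population."""
    if theta <= 0:
        return np.where(classes == 0, 1.0, 0.0)
    # log space: theta^j / (theta+1)^(j+1) overflows for large theta * classes
    return np.exp(classes * math.log(theta) - (classes + 1.0) * math.log(theta + 1.0))


def expected_mismatch(
    tau: float, theta0: float, theta1: float, n_classes: int
) -> np.ndarray:
    """Sudden-expansion expected mismatch distribution (Rogers–Harpending).

    A population at equilibrium theta0 grows instantaneously to theta1 at
    time tau (in units of 2u generations) before the present:

        F_j = F_j(theta1) + exp(-tau (theta1+1)/theta1)
                * sum_{i<=j} tau^(j-i)/(j-i)! [F_i(theta0) - F_i(theta1)]
    """
    j = np.arange(n_classes)
    f1 = _stationary_mismatch(theta1, j)
    if tau <= 0:
        return _stationary_mismatch(theta0, j)
    f0 = _stationary_mismatch(theta0, j)
    delta = f0 - f1
    # log-space Poisson weights tau^m / m!
    logw = j * math.log(tau) - _log_factorials(n_classes)
    with np.errstate(divide="ignore", over="ignore", under="ignore"):
        w = np.exp(logw - tau * (theta1 + 1.0) / max(theta1, 1e-12))
    # convolution sum_{i<=j} w[j-i] * delta[i]
    conv = np.convolve(w, delta)[:n_classes]
    return f1 + conv


def raggedness(observed: np.ndarray) -> float:
    """Harpending's raggedness index with zero padding at both ends."""
    x = np.concatenate([[0.0], np.asarray(observed, dtype=float), [0.0]])
    return float(np.sum(np.diff(x) ** 2))


def _fit_sudden_expansion(
    observed: np.ndarray, n_classes: int, theta1_max: float = 9999.0
):
    """Least-squares fit of (tau, theta0, theta1); returns params, ssd, ok."""
    obs = np.zeros(n_classes)
    obs[: len(observed)] = observed
    mean_d = float(np.sum(np.arange(len(observed)) * observed))

    def ssd_of(params):
        tau, theta0, dtheta = params
        theta1 = theta0 + dtheta
        exp = expected_mismatch(tau, theta0, theta1, n_classes)
        return float(np.sum((obs - exp) ** 2))

    # moments-informed start first; further deterministic starts only on failure
    starts = [
        (max(mean_d, 0.5), 0.1, 50.0),
        (max(mean_d / 2.0, 0.5), 0.01, 500.0),
        (max(mean_d * 1.5, 1.0), 1.0, 10.0),
        (0.5, 0.5, 1.0),
        (max(mean_d, 0.5), 0.001, theta1_max / 2.0),
    ]
    best = None
    for s0 in starts:
        res = minimize(
            ssd_of,
            x0=np.asarray(s0),
            method="Nelder-Mead",
            bounds=[(0.0, 3.0 * n_classes), (0.0, theta1_max), (0.0, theta1_max)],
            options={"xatol": 1e-7, "fatol": 1e-13, "maxiter": 1500},
        )
        if best is None or res.fun < best.fun - 1e-15:
            best = res
        if best.success:
            break
    tau, theta0, dtheta = best.x
    theta1 = min(theta0 + dtheta, 9999.0)
    return (float(tau), float(theta0), float(theta1)), float(best.fun), bool(best.success)


def _simulate_expansion_sample(
    n: int, tau: float, theta0: float, theta1: float, rng: np.random.Generator
) -> np.ndarray:
    """Mismatch frequencies of one coalescent sample under sudden expansion.

    Time is measured in mutational units (2u generations), in which a pair of
    lineages coalesces at rate 1/theta(t) and each lineage mutates at rate
    1/2 per unit.  theta steps from theta1 (present) to theta0 at time tau.
    """
    theta0 = max(theta0, 1e-6)
    theta1 = max(theta1, 1e-6)
    # coalescent with step change at tau
    active = list(range(n))
    masks = [1 << i for i in range(n)]
    times = [0.0] * n
    t = 0.0
    branches: list[tuple[float, int]] = []
    while len(active) > 1:
        kk = len(active)
        rate_now = kk * (kk - 1) / 2.0 / (theta1 if t < tau else theta0)
        wait = rng.exponential(1.0 / rate_now)
        if t < tau and t + wait > tau:
            t = tau  # re-draw under the ancestral size
            continue
        t += wait
        i, j = rng.choice(kk, size=2, replace=False)
        a, b = active[i], active[j]
        masks.append(masks[a] | masks[b])
        times.append(t)
        for child in (a, b):
            branches.append((t - times[child], masks[child]))
        active = [x for x in active if x not in (a, b)] + [len(masks) - 1]
    # Poisson mutations at rate 1/2 per branch unit; pairwise differences
    diff = np.zeros((n, n))
    for length, mask in branches:
        k = rng.poisson(length / 2.0)
        if k == 0:
            continue
        inside = np.array([(mask >> b) & 1 for b in range(n)], dtype=bool)
        diff[np.ix_(inside, ~inside)] += k
    diff = diff + diff.T
    diff = diff.astype(int)
    dmax = int(diff.max())
    freq = np.zeros(dmax + 1)
    iu = np.triu_indices(n, k=1)
    vals, cnts = np.unique(diff[iu], return_counts=True)
    freq[vals] = cnts
    return freq / freq.sum()


def mismatch_analysis(
    ht: HaplotypeTable,
    demes: Sequence[str] | None = None,
    group: str | None = None,
    n_boot: int = 5000,
    seed: int | None = None,
    extra_classes: int = 5,
) -> MismatchResult:
    """Mismatch-distribution analysis under the sudden-expansion model.

    Fits (tau, theta0, theta1) by least squares on the observed distribution
    of pairwise differences, computes the SSD goodness-of-fit and Harpending's
    raggedness, and derives p-values by parametric bootstrap: ``n_boot``
    coalescent samples are simulated under the fitted expansion model, each is
    refitted, and p is the fraction of replicates whose statistic is at least
    the observed one.  Difference classes are extended ``extra_classes`` past
    the observed maximum for fitting.
    """
    sub = _select(ht, demes, group)
    n = sub.total_n
    if n < 3:
        raise InsufficientDataError("mismatch analysis needs n >= 3")
    observed = mismatch_observed(sub)
    n_classes = len(observed) + extra_classes
    (tau, theta0, theta1), ssd, ok = _fit_sudden_expansion(observed, n_classes)
    rag = raggedness(observed)

    rng = np.random.default_rng(seed)
    ssd_null = np.empty(n_boot)
    rag_null = np.empty(n_boot)
    for r in range(n_boot):
        sim = _simulate_expansion_sample(n, tau, theta0, theta1, rng)
        # every replicate is fitted over its own support, exactly mirroring
        # the treatment of the observed distribution
        _, ssd_r, _ = _fit_sudden_expansion(sim, len(sim) + extra_classes)
        ssd_null[r] = ssd_r
        rag_null[r] = raggedness(sim)
    p_ssd = float(np.mean(ssd_null >= ssd)) if n_boot else float("nan")
    p_rag = float(np.mean(rag_null >= rag)) if n_boot else float("nan")

    return MismatchResult(
        observed=observed,
        tau=tau,
        theta0=theta0,
        theta1=theta1,
        ssd=ssd,
        p_ssd=p_ssd,
        raggedness=rag,
        p_rag=p_rag,
        n_boot=n_boot,
        seed=seed,
        converged=ok,
    )


# ---------------------------------------------------------------------------
# report table


def stats_table(
    ht: HaplotypeTable,
    partitions: dict[str, Sequence[str]],
    n_sims: int = 1000,
    n_boot: int = 200,
    seed: int | None = None,
):
    """Per-partition summary table in the style of a diversity/neutrality table.

    ``partitions`` maps a row label to a list of demes.  Columns: n, k,
    h +- sd, pi +- sd, D (p), Fs (p), SSD (p), raggedness (p).
    """
    import pandas as pd

    rows = []
    ss = np.random.SeedSequence(seed)
    for (label, demes), child in zip(partitions.items(), ss.spawn(len(partitions))):
        s1, s2 = child.spawn(2)
        div = diversity(ht, demes=demes)
        neut = neutrality_pvalues(
            ht, demes=demes, n_sims=n_sims, seed=int(s1.generate_state(1)[0] % 2**31)
        )
        mis = mismatch_analysis(
            ht, demes=demes, n_boot=n_boot, seed=int(s2.generate_state(1)[0] % 2**31)
        )
        rows.append(
            {
                "partition": label,
                "n": div.n,
                "k": div.k,
                "h": round(div.h, 4),
                "h_sd": round(div.h_sd, 4),
                "pi": round(div.pi, 4),
                "pi_sd": round(div.pi_sd, 4),
                "tajima_D": round(neut.tajima_D, 4),
                "p_D": round(neut.p_D, 4),
                "fu_Fs": round(neut.fu_Fs, 4) if not math.isnan(neut.fu_Fs) else float("nan"),
                "p_Fs": round(neut.p_Fs, 4) if not math.isnan(neut.p_Fs) else float("nan"),
                "SSD": round(mis.ssd, 4),
                "p_SSD": round(mis.p_ssd, 4),
                "raggedness": round(mis.raggedness, 4),
                "p_rag": round(mis.p_rag, 4),
            }
        )
    return pd.DataFrame(rows)
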