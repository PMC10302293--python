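"""Approximate Bayesian computation: scenario choice and parameter estimation.

The workflow follows standard rejection-plus-regression ABC for demographic
model choice.  A reference table is built by drawing parameters from each
candidate scenario's priors, simulating a dataset with the structured
coalescent, and recording a fixed vector of summary statistics.  Statistics
are z-normalized by the reference table's mean and standard deviation; the
Euclidean distance to the observed vector selects the closest fraction
(default 1%) of simulations; a multinomial logistic regression of the
scenario indicator on the centered statistics within the retained set yields
posterior scenario probabilities at the observed point with asymptotic 95%
confidence intervals (falling back to rejection-count proportions when the
regression is singular).  Parameter posteriors use local-linear regression
adjustment of the retained draws.  Confidence in the choice is quantified by
confusion error rates over pseudo-observed datasets simulated from each
scenario's prior.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cherrypop.errors import InputError
from cherrypop.simulate import Event, Scenario, SummaryStats, simulate_dataset, summarize


@dataclass
class ReferenceTable:
    scenario_names: list[str]
    scenario_idx: np.ndarray  # (R,) int index into scenario_names
    params: pd.DataFrame  # (R, P) drawn parameters, NaN where not applicable
    stats: np.ndarray  # (R, S) raw summary statistics
    stat_names: list[str]
    norm_mean: np.ndarray
    norm_sd: np.ndarray
    n_per_scenario: int
    sim_config: dict = field(default_factory=dict)
    dropped_stats: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.stats.shape[0]

    def normalized(self) -> np.ndarray:
        return (self.stats - self.norm_mean) / self.norm_sd

    def normalize_observed(self, observed: SummaryStats | np.ndarray) -> np.ndarray:
        vec = observed.values if isinstance(observed, SummaryStats) else np.asarray(observed)
        if isinstance(observed, SummaryStats):
            if observed.names != self.stat_names:
                # align by name, dropping statistics removed from the table
                pos = {n: i for i, n in enumerate(observed.names)}
                missing = [n for n in self.stat_names if n not in pos]
                if missing:
                    raise InputError(f"observed vector lacks statistics: {missing}")
                vec = vec[[pos[n] for n in self.stat_names]]
        if vec.shape[0] != len(self.stat_names):
            raise InputError("observed statistic vector has wrong length")
        return (vec - self.norm_mean) / self.norm_sd

    def save(self, table_path, sidecar_path) -> None:
        df = self.params.copy()
        df.insert(0, "scenario", [self.scenario_names[i] for i in self.scenario_idx])
        for j, name in enumerate(self.stat_names):
            df[f"stat:{name}"] = self.stats[:, j]
        df.to_csv(table_path, sep="\t", index=False)
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "scenario_names": self.scenario_names,
                    "stat_names": self.stat_names,
                    "norm_mean": self.norm_mean.tolist(),
                    "norm_sd": self.norm_sd.tolist(),
                    "n_per_scenario": self.n_per_scenario,
                    "sim_config": self.sim_config,
                    "dropped_stats": self.dropped_stats,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, table_path, sidecar_path) -> "ReferenceTable":
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        df = pd.read_csv(table_path, sep="\t")
        stat_cols = [f"stat:{n}" for n in meta["stat_names"]]
        stats = df[stat_cols].to_numpy()
        scen = df["scenario"].tolist()
        idx = np.array([meta["scenario_names"].index(s) for s in scen])
        params = df.drop(columns=["scenario"] + stat_cols)
        cfg = meta["sim_config"]
        if "scenarios" in cfg:
            cfg = dict(cfg)
        return cls(
            scenario_names=meta["scenario_names"],
            scenario_idx=idx,
            params=params,
            stats=stats,
            stat_names=meta["stat_names"],
            norm_mean=np.asarray(meta["norm_mean"]),
            norm_sd=np.asarray(meta["norm_sd"]),
            n_per_scenario=meta["n_per_scenario"],
            sim_config=cfg,
            dropped_stats=meta.get("dropped_stats", []),
        )


@dataclass
class ABCResult:
    posterior_prob: dict[str, tuple[float, float, float]]  # name -> (p, lo, hi)
    retained_fraction: float
    selected_scenario: str
    method: str  # "logistic_regression" | "rejection"
    n_retained: int
    seed: int | None = None
    parameter_posteriors: dict[str, tuple[float, float, float]] | None = None
    type1_error: dict[str, float] | None = None
    type2_error: dict[str, float] | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "posterior_prob": {
                k: {"p": p, "ci95": [lo, hi]}
                for k, (p, lo, hi) in self.posterior_prob.items()
            },
            "selected_scenario": self.selected_scenario,
            "retained_fraction": self.retained_fraction,
            "method": self.method,
            "n_retained": self.n_retained,
            "parameter_posteriors": self.parameter_posteriors,
            "type1_error": self.type1_error,
            "type2_error": self.type2_error,
            "notes": self.notes,
        }


# ---------------------------------------------------------------------------
# reference table


def build_reference(
    scenarios: Sequence[Scenario],
    n_per_scenario: int,
    sample_sizes: Mapping[str, int],
    seed: int | None = None,
    L: int = 800,
    model: str = "infinite_sites",
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` datasets per scenario and tabulate statistics.

    Statistics with zero variance across the table are dropped (recorded in
    ``dropped_stats``); the remaining ones are z-normalized, and the
    normalization constants are stored for reuse on observed data.
    """
    if len(scenarios) < 2:
        raise InputError("need at least 2 scenarios")
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise InputError("scenario names must be unique")
    rng = np.random.default_rng(seed)
    rows_stats: list[np.ndarray] = []
    rows_params: list[dict] = []
    idx: list[int] = []
    stat_names: list[str] | None = None
    for si, sc in enumerate(scenarios):
        for _ in range(n_per_scenario):
            sd = simulate_dataset(sc, sample_sizes, L=L, seed=rng, model=model)
            ss = summarize(sd)
            if stat_names is None:
                stat_names = ss.names
            rows_stats.append(ss.values)
            rows_params.append(sd.truth["params"])
            idx.append(si)
    stats = np.vstack(rows_stats)
    params = pd.DataFrame(rows_params)

    sd_ = stats.std(axis=0, ddof=0)
    keep = sd_ > 0
    # also drop statistics that exactly duplicate an earlier one (e.g. a
    # per-site diversity that is a fixed rescaling of the raw mean pairwise
    # difference at a single locus length) — they make regressions singular
    z = np.where(sd_ > 0, (stats - stats.mean(axis=0)) / np.where(sd_ > 0, sd_, 1.0), 0.0)
    for j in range(stats.shape[1]):
        if not keep[j]:
            continue
        for i in range(j):
            if keep[i] and abs(float(np.mean(z[:, i] * z[:, j]))) > 0.9999:
                keep[j] = False
                break
    dropped = [n for n, k in zip(stat_names, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping degenerate/duplicate statistics: {dropped}", stacklevel=2
        )
    stats = stats[:, keep]
    kept_names = [n for n, k in zip(stat_names, keep) if k]
    return ReferenceTable(
        scenario_names=names,
        scenario_idx=np.asarray(idx),
        params=params,
        stats=stats,
        stat_names=kept_names,
        norm_mean=stats.mean(axis=0),
        norm_sd=stats.std(axis=0, ddof=0),
        n_per_scenario=n_per_scenario,
        sim_config={
            "sample_sizes": dict(sample_sizes),
            "L": L,
            "model": model,
            "scenarios": [s.to_dict() for s in scenarios],
        },
        dropped_stats=dropped,
    )


# ---------------------------------------------------------------------------
# model choice


def _retained_indices(rt: ReferenceTable, obs_z: np.ndarray, retain: float) -> np.ndarray:
    z = rt.normalized()
    dist = np.sqrt(((z - obs_z) ** 2).sum(axis=1))
    n_keep = max(int(np.ceil(retain * rt.n_rows)), len(rt.scenario_names) + 2)
    order = np.argsort(dist, kind="stable")
    return order[:n_keep]


def _logistic_posteriors(
    z_ret: np.ndarray, obs_z: np.ndarray, scen_ret: np.ndarray, K: int
):
    """Multinomial logistic posterior probabilities at the observed point.

    Returns (probs, lo, hi) arrays over all K classes or None on failure.
    """
    import statsmodels.api as sm

    present = np.unique(scen_ret)
    if len(present) < 2:
        return None
    remap = {c: i for i, c in enumerate(present)}
    y = np.array([remap[c] for c in scen_ret])
    X = np.column_stack([np.ones(len(y)), z_ret - obs_z])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MNLogit(y, X)
            fit = model.fit(method="bfgs", maxiter=500, disp=0)
            beta = np.asarray(fit.params)  # (n_exog, Kp-1)
            cov = np.asarray(fit.cov_params())
    except Exception:
        return None
    if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(cov)):
        return None
    Kp = len(present)
    # linear predictors at the observed point: only intercepts survive
    eta = np.concatenate([[0.0], beta[0, :]])
    eta -= eta.max()
    p_local = np.exp(eta) / np.exp(eta).sum()
    # delta method on the intercept block; params are stacked per equation
    n_exog = beta.shape[0]
    icpt_pos = [j * n_exog for j in range(Kp - 1)]
    cov_icpt = cov[np.ix_(icpt_pos, icpt_pos)]
    grads = np.zeros((Kp, Kp - 1))
    for j in range(Kp):
        for m in range(1, Kp):
            grads[j, m - 1] = p_local[j] * ((1.0 if j == m else 0.0) - p_local[m])
    var = np.einsum("jm,mn,jn->j", grads, cov_icpt, grads)
    se = np.sqrt(np.maximum(var, 0.0))

    probs = np.zeros(K)
    lo = np.zeros(K)
    hi = np.zeros(K)
    for local, cls in enumerate(present):
        probs[cls] = p_local[local]
        lo[cls] = max(0.0, p_local[local] - 1.96 * se[local])
        hi[cls] = min(1.0, p_local[local] + 1.96 * se[local])
    return probs, lo, hi


def model_choice(
    rt: ReferenceTable,
    observed: SummaryStats | np.ndarray,
    retain: float = 0.01,
) -> ABCResult:
    """Posterior scenario probabilities for an observed statistic vector.

    Retains the closest ``retain`` fraction of reference simulations by
    Euclidean distance on z-normalized statistics and fits a multinomial
    logistic regression of the scenario label on the statistics centered at
    the observed point; the fitted probabilities at that point are the
    posteriors, with asymptotic 95% CIs.  Falls back to rejection-count
    proportions (binomial CIs) when the regression cannot be fitted.
    """
    K = len(rt.scenario_names)
    obs_z = rt.normalize_observed(observed)
    ret = _retained_indices(rt, obs_z, retain)
    scen_ret = rt.scenario_idx[ret]
    z_ret = rt.normalized()[ret]
    notes: list[str] = []
    missing = [rt.scenario_names[k] for k in range(K) if k not in set(scen_ret)]
    if missing:
        notes.append(f"scenarios absent from retained set (probability floored): {missing}")

    out = _logistic_posteriors(z_ret, obs_z, scen_ret, K)
    if out is not None:
        probs, lo, hi = out
        method = "logistic_regression"
    else:
        counts = np.bincount(scen_ret, minlength=K).astype(float)
        probs = counts / counts.sum()
        se = np.sqrt(probs * (1 - probs) / counts.sum())
        lo = np.clip(probs - 1.96 * se, 0.0, 1.0)
        hi = np.clip(probs + 1.96 * se, 0.0, 1.0)
        method = "rejection"
        notes.append("logistic regression singular; rejection proportions used")

    total = probs.sum()
    if total > 0:
        probs = probs / total
    best = int(np.argmax(probs))
    posterior = {
        rt.scenario_names[k]: (float(probs[k]), float(lo[k]), float(hi[k]))
        for k in range(K)
    }
    return ABCResult(
        posterior_prob=posterior,
        retained_fraction=retain,
        selected_scenario=rt.scenario_names[best],
        method=method,
        n_retained=len(ret),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# parameter estimation


def estimate_parameters(
    rt: ReferenceTable,
    observed: SummaryStats | np.ndarray,
    scenario: str,
    retain: float = 0.01,
    adjust: bool = True,
) -> dict[str, tuple[float, float, float]]:
    """Posterior (median, 2.5%, 97.5%) per parameter for one scenario.

    Retains the closest draws *within the scenario* and, with ``adjust``,
    applies the local-linear regression correction: each retained parameter
    draw is shifted by the fitted linear dependence of the parameter on the
    deviation of its statistics from the observed vector.
    """
    if scenario not in rt.scenario_names:
        raise InputError(f"unknown scenario {scenario!r}")
    k = rt.scenario_names.index(scenario)
    rows = np.where(rt.scenario_idx == k)[0]
    if len(rows) == 0:
        raise InputError(f"no reference rows for scenario {scenario!r}")
    obs_z = rt.normalize_observed(observed)
    z = rt.normalized()[rows]
    dist = np.sqrt(((z - obs_z) ** 2).sum(axis=1))
    n_keep = max(int(np.ceil(retain * len(rows))), 10)
    order = np.argsort(dist, kind="stable")[:n_keep]
    ret_rows = rows[order]
    z_ret = rt.normalized()[ret_rows]

    do_adjust = adjust and len(ret_rows) >= 50
    out: dict[str, tuple[float, float, float]] = {}
    X = np.column_stack([np.ones(len(ret_rows)), z_ret - obs_z])
    for name in rt.params.columns:
        vals = rt.params[name].to_numpy()[ret_rows].astype(float)
        if np.all(np.isnan(vals)):
            continue
        draws = vals
        if do_adjust and np.nanstd(vals) > 0:
            beta, *_ = np.linalg.lstsq(X, vals, rcond=None)
            draws = vals - (X[:, 1:] @ beta[1:])
        out[name] = (
            float(np.nanmedian(draws)),
            float(np.nanpercentile(draws, 2.5)),
            float(np.nanpercentile(draws, 97.5)),
        )
    return out


# ---------------------------------------------------------------------------
# confusion errors


def confusion_errors(
    scenarios: Sequence[Scenario],
    rt: ReferenceTable,
    n_pods: int = 100,
    retain: float = 0.01,
    seed: int | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Type I / type II error rates from pseudo-observed datasets (pods).

    For each scenario, ``n_pods`` datasets are simulated from its prior and
    classified with :func:`model_choice` against ``rt``.  type1(s) is the
    fraction of pods generated under s *not* assigned to s; type2(s) is the
    mean, over the other scenarios s', of the fraction of s'-pods assigned
    to s.
    """
    if n_pods < 20:
        warnings.warn(f"n_pods={n_pods} < 20: error rates will be noisy", stacklevel=2)
    cfg = rt.sim_config
    sample_sizes, L, model = cfg["sample_sizes"], cfg["L"], cfg["model"]
    rng = np.random.default_rng(seed)
    names = [s.name for s in scenarios]
    if names != rt.scenario_names:
        raise InputError("scenario list does not match the reference table")
    K = len(names)
    assigned = np.zeros((K, K))  # [true, assigned]
    for ti, sc in enumerate(scenarios):
        for _ in range(n_pods):
            sd = simulate_dataset(sc, sample_sizes, L=L, seed=rng, model=model)
            res = model_choice(rt, summarize(sd), retain=retain)
            assigned[ti, names.index(res.selected_scenario)] += 1
    frac = assigned / n_pods
    type1 = {names[s]: float(1.0 - frac[s, s]) for s in range(K)}
    type2 = {
        names[s]: float(np.mean([frac[t, s] for t in range(K) if t != s]))
        for s in range(K)
    }
    return type1, type2


# ---------------------------------------------------------------------------
# a small separable scenario system for demonstrations and calibration


def toy_abc_scenarios(
    n_demes_sizes: Mapping[str, float] | None = None,
) -> list[Scenario]:
    """Three competing domestication-style scenarios over demes A, B, C.

    * ``independent_splits`` — B and C each split directly from A;
    * ``serial_splits`` — C splits from B, B from A (stepwise);
    * ``serial_with_admixture`` — as serial, plus a pulse into B from A
      between the two splits.

    All share uniform priors on the split times (recent T1, older T2) and the
    per-locus mutation rate prior uniform on [1e-4, 1e-3].
    """
    sizes = dict(n_demes_sizes or {"A": 8000.0, "B": 3000.0, "C": 1500.0})
    t1 = ("uniform", 1000.0, 10000.0)
    t2 = ("uniform", 40000.0, 120000.0)
    s1 = Scenario(
        name="independent_splits",
        deme_sizes=dict(sizes),
        events=[
            Event(4000.0, "merge", {"source": "C", "dest": "A"}),
            Event(60000.0, "merge", {"source": "B", "dest": "A"}),
        ],
        priors={"T:0": t1, "T:1": t2},
    )
    s2 = Scenario(
        name="serial_splits",
        deme_sizes=dict(sizes),
        events=[
            Event(4000.0, "merge", {"source": "C", "dest": "B"}),
            Event(60000.0, "merge", {"source": "B", "dest": "A"}),
        ],
        priors={"T:0": t1, "T:1": t2},
    )
    s3 = Scenario(
        name="serial_with_admixture",
        deme_sizes=dict(sizes),
        events=[
            Event(4000.0, "merge", {"source": "C", "dest": "B"}),
            Event(20000.0, "admixture",
                  {"recipient": "B", "donor": "A", "fraction": 0.4}),
            Event(60000.0, "merge", {"source": "B", "dest": "A"}),
        ],
        priors={"T:0": t1, "T:2": t2, "frac:1": ("uniform", 0.2, 0.6)},
    )
    return [s1, s2, s3]
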