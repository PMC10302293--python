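"""Structured-coalescent scenario simulation with sequence mutation.

A :class:`Scenario` is a forward-time demographic history — present-day deme
sizes plus a time-ordered list of events (population splits, size changes,
admixture pulses), with times given in years and converted to generations via
the generation time (default 4 years, appropriate for perennial woody
plants).  Simulation runs backward in time: within a deme carrying k lineages
of effective size N, pairs coalesce at rate k(k-1)/2 / (2N) per generation; a
forward-time split of deme A from deme B at time T is, backwards, a merge of
A's lineages into B; a forward-time admixture pulse into A from B with
fraction f reassigns each of A's lineages to B with probability f.

Mutations are laid on the genealogy as a Poisson process.  Two models are
offered: infinite sites (every mutation hits a fresh column; the default, the
natural model for non-recombining organellar and ribosomal spacer sequence at
these divergence scales) and a finite-sites equal-rate (Jukes–Cantor) model.

Scenario priors support ABC: any present size, event time, admixture fraction
or the locus mutation rate can carry a uniform or log-uniform prior and be
drawn per simulated dataset.  The default mutation-rate prior is uniform on
[1e-4, 1e-3] per locus per generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from cherrypop.errors import InputError, ScenarioError
from cherrypop.seqdata import AlignedDataset, RecodedAlignment, Sample, collapse_haplotypes

DEFAULT_MU_PRIOR = ("uniform", 1e-4, 1e-3)  # per locus per generation
DEFAULT_GENERATION_TIME = 4.0  # years


@dataclass
class Event:
    time_years: float
    kind: str  # "merge" | "size_change" | "admixture"
    params: dict

    def to_dict(self) -> dict:
        return {"time_years": self.time_years, "kind": self.kind, **self.params}


@dataclass
class Scenario:
    """A demographic history with optional priors on its parameters.

    Prior keys: ``"N:<deme>"`` for a present size, ``"T:<event_index>"`` for
    an event time (years), ``"frac:<event_index>"`` for an admixture
    fraction, ``"mu"`` for the per-locus mutation rate.  Prior specs are
    ``("uniform", lo, hi)`` or ``("loguniform", lo, hi)``.
    """

    name: str
    deme_sizes: dict[str, float]
    events: list[Event]
    generation_time_years: float = DEFAULT_GENERATION_TIME
    mutation_rate: float | None = None  # per locus per generation
    priors: dict[str, tuple] = field(default_factory=dict)
    deme_groups: dict[str, str] | None = None
    # continuous migration, backward in time: key "A>B" moves a lineage
    # currently in A to B at the given rate per lineage per generation
    # (equal to the forward-time B->A migration rate)
    migration_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [e.time_years for e in self.events]
        if any(t <= 0 for t in times):
            raise ScenarioError("event times must be strictly positive")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ScenarioError("event times must be strictly increasing")
        for e in self.events:
            if e.kind == "admixture":
                f = e.params["fraction"]
                if not (0.0 < f < 1.0):
                    raise ScenarioError("admixture fractions must lie in (0, 1)")

    # -- validation ---------------------------------------------------------

    def validate_connectivity(self, sampled_demes: Sequence[str]) -> None:
        """All sampled demes must reach a single root lineage through merges."""
        parent = {d: d for d in self.deme_sizes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for e in self.events:
            if e.kind == "merge":
                parent[find(e.params["source"])] = find(e.params["dest"])
        for key in self.migration_rates:
            a, b = key.split(">")
            parent[find(a)] = find(b)
        roots = {find(d) for d in sampled_demes}
        if len(roots) > 1:
            raise ScenarioError(
                f"sampled demes never share a common ancestor (roots {sorted(roots)}); "
                "add merge events"
            )

    # -- priors -------------------------------------------------------------

    def draw(self, rng: np.random.Generator, max_tries: int = 1000):
        """Draw one parameter set from the priors; returns (params, scenario).

        Event-time draws are rejected until the drawn times respect the
        scenario's strict time ordering.
        """
        priors = dict(self.priors)
        if self.mutation_rate is None and "mu" not in priors:
            priors["mu"] = DEFAULT_MU_PRIOR
        for _ in range(max_tries):
            params: dict[str, float] = {}
            for key, spec in priors.items():
                kind, lo, hi = spec
                if kind == "uniform":
                    params[key] = float(rng.uniform(lo, hi))
                elif kind == "loguniform":
                    params[key] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                else:
                    raise InputError(f"unknown prior kind {kind!r}")
            try:
                return params, self.with_params(params)
            except ScenarioError:
                continue
        raise ScenarioError(
            f"could not draw ordered event times in {max_tries} tries"
        )

    def with_params(self, params: Mapping[str, float]) -> "Scenario":
        """Concrete scenario with drawn parameter values substituted."""
        sizes = dict(self.deme_sizes)
        events = [Event(e.time_years, e.kind, dict(e.params)) for e in self.events]
        mu = self.mutation_rate
        for key, val in params.items():
            if key == "mu":
                mu = val
            elif key.startswith("N:"):
                sizes[key[2:]] = val
            elif key.startswith("T:"):
                events[int(key[2:])].time_years = val
            elif key.startswith("frac:"):
                events[int(key[5:])].params["fraction"] = val
            else:
                raise InputError(f"unknown parameter key {key!r}")
        return Scenario(
            name=self.name,
            deme_sizes=sizes,
            events=events,
            generation_time_years=self.generation_time_years,
            mutation_rate=mu,
            priors={},
            deme_groups=self.deme_groups,
            migration_rates=dict(self.migration_rates),
        )

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "deme_sizes": self.deme_sizes,
            "events": [e.to_dict() for e in self.events],
            "generation_time_years": self.generation_time_years,
            "mutation_rate": self.mutation_rate,
            "priors": {k: list(v) for k, v in self.priors.items()},
            "deme_groups": self.deme_groups,
            "migration_rates": self.migration_rates,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        events = []
        for e in d["events"]:
            e = dict(e)
            events.append(
                Event(
                    time_years=e.pop("time_years"),
                    kind=e.pop("kind"),
                    params=e,
                )
            )
        return cls(
            name=d["name"],
            deme_sizes=dict(d["deme_sizes"]),
            events=events,
            generation_time_years=d.get("generation_time_years", DEFAULT_GENERATION_TIME),
            mutation_rate=d.get("mutation_rate"),
            priors={k: tuple(v) for k, v in d.get("priors", {}).items()},
            deme_groups=d.get("deme_groups"),
            migration_rates=dict(d.get("migration_rates", {})),
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def read(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Genealogy:
    """Rooted binary genealogy; node 0..n-1 are leaves, 2n-2 is the root."""

    n_samples: int
    parent: np.ndarray  # parent[i] = -1 for root
    time: np.ndarray  # node times in generations
    sample_demes: list[str]

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(len(self.parent))
        nonroot = self.parent >= 0
        bl[nonroot] = self.time[self.parent[nonroot]] - self.time[nonroot]
        return bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_masks(self) -> list[int]:
        """Integer bitmask of descendant leaves for every node."""
        masks = [0] * len(self.parent)
        for i in range(self.n_samples):
            masks[i] = 1 << i
        for i in np.argsort(self.time, kind="stable"):
            p = self.parent[i]
            if p >= 0:
                masks[p] |= masks[i]
        return masks


@dataclass
class SimulatedDataset:
    dataset: AlignedDataset
    truth: dict

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


@dataclass
class SummaryStats:
    names: list[str]
    values: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


# ---------------------------------------------------------------------------
# genealogy simulation


def simulate_genealogy(
    sc: Scenario,
    sample_sizes: Mapping[str, int],
    seed: int | np.random.Generator | None = None,
) -> Genealogy:
    """Backward-time structured coalescent under the scenario.

    ``sample_sizes`` maps deme name to number of sampled lineages.  Returns a
    rooted genealogy with node times in generations.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sampled = [d for d, n in sample_sizes.items() if n > 0]
    unknown = [d for d in sampled if d not in sc.deme_sizes]
    if unknown:
        raise ScenarioError(f"sampled demes not in scenario: {unknown}")
    sc.validate_connectivity(sampled)

    gen_time = sc.generation_time_years
    events = [
        (e.time_years / gen_time, e.kind, e.params) for e in sc.events
    ]
    n_total = sum(sample_sizes[d] for d in sampled)
    parent = np.full(2 * n_total - 1, -1, dtype=int)
    times = np.zeros(2 * n_total - 1)
    sample_demes: list[str] = []
    active: dict[str, list[int]] = {d: [] for d in sc.deme_sizes}
    node = 0
    for d in sampled:
        for _ in range(sample_sizes[d]):
            active[d].append(node)
            sample_demes.append(d)
            node += 1
    sizes = dict(sc.deme_sizes)

    mig = [
        (key.split(">")[0], key.split(">")[1], rate)
        for key, rate in sc.migration_rates.items()
        if rate > 0
    ]
    t = 0.0
    ev_idx = 0
    next_node = n_total
    n_live = n_total
    while n_live > 1:
        rates = {
            d: len(l) * (len(l) - 1) / 2.0 / (2.0 * sizes[d])
            for d, l in active.items()
            if len(l) >= 2
        }
        mig_rates = [
            (src, dst, len(active[src]) * rate)
            for src, dst, rate in mig
            if active[src]
        ]
        total_rate = sum(rates.values()) + sum(r for _, _, r in mig_rates)
        next_ev_t = events[ev_idx][0] if ev_idx < len(events) else np.inf
        if total_rate > 0:
            wait = rng.exponential(1.0 / total_rate)
        else:
            wait = np.inf
        if t + wait >= next_ev_t:
            if not np.isfinite(next_ev_t):
                raise ScenarioError(
                    "lineages in disconnected demes cannot coalesce; "
                    "scenario lacks the required merge events"
                )
            t = next_ev_t
            _, kind, p = events[ev_idx]
            ev_idx += 1
            if kind == "merge":
                src, dst = p["source"], p["dest"]
                active[dst].extend(active[src])
                active[src] = []
            elif kind == "size_change":
                sizes[p["deme"]] = p["size"]
            elif kind == "admixture":
                rec, don, f = p["recipient"], p["donor"], p["fraction"]
                stay, move = [], []
                for x in active[rec]:
                    (move if rng.random() < f else stay).append(x)
                active[rec] = stay
                active[don].extend(move)
            else:
                raise ScenarioError(f"unknown event kind {kind!r}")
            continue
        t += wait
        # choose coalescence-in-deme or a migration move, proportional to rate
        labels = list(rates) + [("mig", i) for i in range(len(mig_rates))]
        weights = np.array(
            [rates[d] for d in rates] + [r for _, _, r in mig_rates]
        )
        pick = labels[rng.choice(len(labels), p=weights / total_rate)]
        if isinstance(pick, tuple):
            src, dst, _ = mig_rates[pick[1]]
            i = rng.integers(len(active[src]))
            active[dst].append(active[src].pop(i))
            continue
        d = pick
        lng = active[d]
        i, j = rng.choice(len(lng), size=2, replace=False)
        a, b = lng[i], lng[j]
        parent[a] = parent[b] = next_node
        times[next_node] = t
        active[d] = [x for x in lng if x not in (a, b)] + [next_node]
        next_node += 1
        n_live -= 1

    return Genealogy(
        n_samples=n_total, parent=parent, time=times, sample_demes=sample_demes
    )


# ---------------------------------------------------------------------------
# mutation


def mutate(
    gen: Genealogy,
    L: int,
    mu: float,
    model: str = "infinite_sites",
    seed: int | np.random.Generator | None = None,
    scenario_name: str = "",
    deme_groups: Mapping[str, str] | None = None,
    locus_name: str = "simulated",
) -> SimulatedDataset:
    """Drop Poisson mutations on the genealogy and emit aligned sequences.

    ``mu`` is the rate per site per generation.  Under ``infinite_sites``
    every mutation occupies a fresh column (random ancestral base, one random
    derived base); under ``jukes_cantor`` sites are drawn uniformly with
    equal-rate changes and may be hit repeatedly.
    """
    if mu <= 0:
        raise InputError("mutation rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = gen.n_samples
    bl = gen.branch_lengths()
    bases = np.array(["A", "C", "G", "T"])

    if model == "infinite_sites":
        ancestral = bases[rng.integers(0, 4, size=L)]
        matrix = np.tile(ancestral, (n, 1))
        total = gen.total_branch_length
        M = rng.poisson(mu * L * total)
        if M > L:
            raise InputError(
                f"{M} mutations exceed {L} sites under infinite sites; "
                "increase L or lower mu"
            )
        if M > 0:
            probs = bl / bl.sum()
            branch_of = rng.choice(len(bl), size=M, p=probs)
            masks = gen.leaf_masks()
            for col, br in enumerate(branch_of):
                anc = matrix[0, col]
                derived = bases[bases != anc][rng.integers(0, 3)]
                m = masks[br]
                while m:
                    low = m & -m
                    matrix[low.bit_length() - 1, col] = derived
                    m ^= low
    elif model == "jukes_cantor":
        matrix = np.empty((n, L), dtype="<U1")
        order = np.argsort(-gen.time, kind="stable")  # root first
        seqs: dict[int, np.ndarray] = {}
        root = int(order[0])
        seqs[root] = bases[rng.integers(0, 4, size=L)]
        for i in order:
            i = int(i)
            p = gen.parent[i]
            if p < 0:
                continue
            seq = seqs[p].copy()
            k = rng.poisson(mu * L * bl[i])
            for _ in range(k):
                site = rng.integers(0, L)
                cur = seq[site]
                others = [b for b in "ACGT" if b != cur]
                seq[site] = others[rng.integers(0, 3)]
            seqs[i] = seq
        for leaf in range(n):
            matrix[leaf] = seqs[leaf]
    else:
        raise InputError(f"unknown mutation model {model!r}")

    counters: dict[str, int] = {}
    samples = []
    for deme in gen.sample_demes:
        counters[deme] = counters.get(deme, 0) + 1
        group = deme_groups[deme] if deme_groups else deme
        samples.append(Sample(f"{deme}_{counters[deme]}", deme, deme, group))
    ds = AlignedDataset(locus_name=locus_name, samples=samples, matrix=matrix)
    truth = {
        "scenario": scenario_name,
        "mu_per_site_per_generation": mu,
        "L": L,
        "model": model,
    }
    return SimulatedDataset(dataset=ds, truth=truth)


def simulate_dataset(
    sc: Scenario,
    sample_sizes: Mapping[str, int],
    L: int,
    seed: int | np.random.Generator | None = None,
    model: str = "infinite_sites",
    params: Mapping[str, float] | None = None,
) -> SimulatedDataset:
    """Draw parameters (if priors are set), simulate genealogy and sequences."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if params is not None:
        concrete = sc.with_params(params)
        drawn = dict(params)
    elif sc.priors or sc.mutation_rate is None:
        drawn, concrete = sc.draw(rng)
    else:
        drawn, concrete = {}, sc
    gen = simulate_genealogy(concrete, sample_sizes, rng)
    mu_locus = concrete.mutation_rate
    sd = mutate(
        gen,
        L=L,
        mu=mu_locus / L,  # scenario rates are per locus per generation
        model=model,
        seed=rng,
        scenario_name=sc.name,
        deme_groups=sc.deme_groups,
    )
    sd.truth["params"] = dict(drawn)
    sd.truth["seed"] = seed if isinstance(seed, int) else None
    return sd


def simulate_two_locus_dataset(
    sc: Scenario,
    sample_sizes: Mapping[str, int],
    L_nuclear: int,
    L_organelle: int,
    seed: int | np.random.Generator | None = None,
    model: str = "infinite_sites",
) -> tuple[SimulatedDataset, SimulatedDataset]:
    """Paired nuclear + organellar datasets under one demographic history.

    The two marker systems share the scenario and its drawn parameters but
    have independent genealogies; the organellar (chloroplast-style) locus is
    uniparentally inherited and effectively non-recombining, simulated with
    every deme at half the nuclear effective size.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sc.priors or sc.mutation_rate is None:
        drawn, concrete = sc.draw(rng)
    else:
        drawn, concrete = {}, sc
    nuc = simulate_dataset(concrete, sample_sizes, L=L_nuclear, seed=rng,
                           model=model, params={})
    half = Scenario(
        name=f"{concrete.name}_organelle",
        deme_sizes={d: n / 2.0 for d, n in concrete.deme_sizes.items()},
        events=[
            Event(e.time_years, e.kind,
                  {**e.params, **({"size": e.params["size"] / 2.0}
                                  if e.kind == "size_change" else {})})
            for e in concrete.events
        ],
        generation_time_years=concrete.generation_time_years,
        mutation_rate=concrete.mutation_rate,
        deme_groups=concrete.deme_groups,
        migration_rates=dict(concrete.migration_rates),
    )
    org = simulate_dataset(half, sample_sizes, L=L_organelle, seed=rng,
                           model=model, params={})
    for sd in (nuc, org):
        sd.truth["params"] = dict(drawn)
    nuc.dataset.locus_name = "nuclear"
    org.dataset.locus_name = "organelle"
    return nuc, org


# ---------------------------------------------------------------------------
# summary statistics


def _phi_st_from_matrix(sub: np.ndarray, n1: int) -> float:
    """Two-level Phi_ST from a 0/1-coded difference matrix of individuals."""
    n = sub.shape[0]
    d2 = sub**2
    ss_total = d2.sum() / (2.0 * n)
    g1 = d2[:n1, :n1].sum() / (2.0 * n1)
    g2 = d2[n1:, n1:].sum() / (2.0 * (n - n1))
    ss_wp = g1 + g2
    ss_ap = ss_total - ss_wp
    sigma_w = ss_wp / (n - 2)
    n_c = (n - (n1**2 + (n - n1) ** 2) / n)
    sigma_a = (ss_ap - sigma_w) / n_c
    denom = sigma_a + sigma_w
    return sigma_a / denom if denom != 0 else 0.0


def summarize(sd: SimulatedDataset | AlignedDataset) -> SummaryStats:
    """Fixed-layout summary-statistic vector for ABC.

    Per deme: number of haplotypes k, gene diversity h, nucleotide diversity
    per site, segregating sites S, mean pairwise differences.  Per deme pair:
    Phi_ST (raw-difference based) and the mean number of between-deme
    differences.  The layout is deterministic given the deme labels.  The
    computation is a vectorized equivalent of the per-subset diversity and
    two-deme AMOVA operations (asserted against them in the test suite).
    """
    ds = sd.dataset if isinstance(sd, SimulatedDataset) else sd
    demes = ds.demes
    L = ds.length
    mat = ds.matrix
    n = mat.shape[0]
    # only variant columns contribute to differences
    variable = np.any(mat != mat[0], axis=0)
    var = np.ascontiguousarray(mat[:, variable])
    diff = np.zeros((n, n))
    for i in range(n):
        diff[i, i + 1 :] = (var[i] != var[i + 1 :]).sum(axis=1)
    diff = diff + diff.T

    deme_of = np.array([s.deme for s in ds.samples])
    names: list[str] = []
    values: list[float] = []
    for d in demes:
        sel = np.where(deme_of == d)[0]
        nd = len(sel)
        sub = var[sel]
        seg = np.any(sub != sub[0], axis=0)
        S = int(seg.sum())
        # haplotype counts via grouping of identical variant rows
        if S:
            segrows = np.ascontiguousarray(sub[:, seg])
            keyed = segrows.view(
                np.dtype((np.void, segrows.dtype.itemsize * S))
            ).ravel()
            _, counts = np.unique(keyed, return_counts=True)
        else:
            counts = np.array([nd])
        k = len(counts)
        p = counts / nd
        h = nd * (1.0 - float(np.sum(p**2))) / (nd - 1.0) if nd > 1 else 0.0
        dsub = diff[np.ix_(sel, sel)]
        mpd = float(dsub.sum() / (nd * (nd - 1.0))) if nd > 1 else 0.0
        names += [f"{d}:k", f"{d}:h", f"{d}:pi", f"{d}:S", f"{d}:mpd"]
        values += [k, h, mpd / L, S, mpd]
    for i, a in enumerate(demes):
        for b in demes[i + 1 :]:
            sel = np.concatenate([np.where(deme_of == a)[0], np.where(deme_of == b)[0]])
            n1 = int((deme_of == a).sum())
            sub = diff[np.ix_(sel, sel)]
            phi = _phi_st_from_matrix(sub, n1)
            between = sub[:n1, n1:].mean()
            names += [f"{a}|{b}:fst", f"{a}|{b}:dxy"]
            values += [phi, float(between)]
    return SummaryStats(names=names, values=np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# fixtures


def _five_group_scenario() -> Scenario:
    """Five groups, three deep lineages: (CC+WC+RC), EC, MC.

    Present sizes follow the magnitudes a cherry-like perennial system would
    show (strong domestication bottleneck in the cultivated group, large wild
    relative pools); the deepest split (the Microcerasus-like lineage) is set
    at 3.52 Ma and the European-lineage split midway, with recent splits and
    admixture inside the Chinese-cherry complex.
    """
    my = 1_000_000.0
    return Scenario(
        name="five_group",
        deme_sizes={"CC": 1530.0, "WC": 5890.0, "RC": 37500.0,
                    "EC": 1610.0, "MC": 37300.0},
        events=[
            Event(2660.0, "merge", {"source": "CC", "dest": "WC"}),
            Event(34200.0, "merge", {"source": "WC", "dest": "RC"}),
            Event(1.76 * my, "merge", {"source": "EC", "dest": "RC"}),
            Event(3.52 * my, "merge", {"source": "RC", "dest": "MC"}),
        ],
        # per-locus rate consistent with nuclear ribosomal spacer substitution
        # rates at Ma divergence scales (~3.5e-9/site/year x 4 y/gen x 710 bp)
        mutation_rate=1e-5,
        deme_groups={d: d for d in ("CC", "WC", "RC", "EC", "MC")},
    )


def _three_group_scenario() -> Scenario:
    """Domestication-style history: WC splits from RC with later gene flow,
    the cultivated group splits from WC recently."""
    return Scenario(
        name="three_group",
        deme_sizes={"CC": 1530.0, "WC": 5890.0, "RC": 37500.0},
        events=[
            Event(2660.0, "merge", {"source": "CC", "dest": "WC"}),
            Event(17000.0, "admixture",
                  {"recipient": "WC", "donor": "RC", "fraction": 0.1}),
            Event(34200.0, "merge", {"source": "WC", "dest": "RC"}),
        ],
        # geometric middle of the uniform [1e-4, 1e-3] per-locus prior
        mutation_rate=3e-4,
        deme_groups={d: d for d in ("CC", "WC", "RC")},
    )


FIXTURE_SAMPLE_SIZES = {
    "five_group_fig_system": {"CC": 60, "WC": 60, "RC": 60, "EC": 60, "MC": 60},
    "three_group_system": {"CC": 60, "WC": 60, "RC": 60},
    "toy": {"A": 8, "B": 8},
}


def fixture_scenario(preset: str) -> Scenario:
    if preset in ("five_group", "five_group_fig_system"):
        return _five_group_scenario()
    if preset in ("three_group", "three_group_system"):
        return _three_group_scenario()
    if preset == "toy":
        return Scenario(
            name="toy",
            deme_sizes={"A": 2000.0, "B": 2000.0},
            events=[Event(8000.0, "merge", {"source": "A", "dest": "B"})],
            mutation_rate=5e-4,
        )
    raise InputError(f"unknown preset {preset!r}")


def make_fixture(
    preset: str = "toy",
    seed: int | None = None,
    sample_sizes: Mapping[str, int] | None = None,
    L: int | None = None,
) -> SimulatedDataset:
    """Generate a study-shaped synthetic dataset.

    Presets: ``five_group`` (five labelled groups with three deep lineages),
    ``three_group`` (recent domestication-style history with admixture), and
    ``toy`` (two demes, small n).  Sample sizes default to 60 per group
    (tens-to-hundreds scale) for the named systems and 8 per deme for the toy.
    """
    sc = fixture_scenario(preset)
    if sample_sizes is None:
        key = {"five_group": "five_group_fig_system",
               "three_group": "three_group_system"}.get(preset, preset)
        sample_sizes = FIXTURE_SAMPLE_SIZES.get(key)
        if sample_sizes is None:
            sample_sizes = {d: 20 for d in sc.deme_sizes}
    if L is None:
        L = {"five_group": 710, "three_group": 2313}.get(preset, 300)
    sd = simulate_dataset(sc, sample_sizes, L=L, seed=seed)
    sd.truth["preset"] = preset
    sd.truth["sample_sizes"] = dict(sample_sizes)
    return sd
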