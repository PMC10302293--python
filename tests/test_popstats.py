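import math

import numpy as np
import pytest

from cherrypop.errors import InsufficientDataError
from cherrypop.popstats import (
    diversity,
    expected_mismatch,
    fu_fs,
    mismatch_analysis,
    mismatch_observed,
    neutrality_pvalues,
    raggedness,
    tajimas_D,
    _fit_sudden_expansion,
    _simulate_expansion_sample,
)
from tests.conftest import make_ht


class TestDiversity:
    def test_two_distinct_haplotypes(self):
        d = diversity(make_ht(["AAA", "AAT"], [[1], [1]]))
        assert d.h == pytest.approx(1.0)

    def test_nei_formula_by_hand(self):
        # counts (2,1,1), n=4: h = (4/3)(1 - (0.25 + 0.0625 + 0.0625))
        d = diversity(make_ht(["AAA", "AAT", "ATT"], [[2], [1], [1]]))
        assert d.h == pytest.approx((4 / 3) * (1 - 0.375), abs=1e-12)

    def test_monomorphic(self):
        d = diversity(make_ht(["AAA"], [[5]]))
        assert d.h == 0.0 and d.pi == 0.0

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            diversity(make_ht(["AAA"], [[1]]))

    def test_h_and_pi_match_bruteforce(self, rng):
        for _ in range(20):
            H = rng.integers(2, 6)
            L = 15
            rows = []
            while len(set(rows)) < H:
                rows = list({"".join(rng.choice(list("ACGT"), size=L)) for _ in range(H)})
            counts = rng.integers(1, 5, size=(len(rows), 1))
            ht = make_ht(rows, counts)
            d = diversity(ht)
            # brute force over expanded individuals
            inds = [r for r, c in zip(rows, counts[:, 0]) for _ in range(c)]
            n = len(inds)
            freqs = {}
            for r in inds:
                freqs[r] = freqs.get(r, 0) + 1
            h_bf = n / (n - 1) * (1 - sum((c / n) ** 2 for c in freqs.values()))
            pairs = [
                sum(a != b for a, b in zip(inds[i], inds[j]))
                for i in range(n)
                for j in range(i + 1, n)
            ]
            pi_bf = sum(pairs) / len(pairs) / L
            assert d.h == pytest.approx(h_bf, abs=1e-12)
            assert d.pi == pytest.approx(pi_bf, abs=1e-12)
            assert d.mean_pairwise_diff == pytest.approx(pi_bf * L, abs=1e-12)

    def test_group_selector(self):
        ht = make_ht(
            ["AAA", "AAT"],
            [[2, 0], [0, 2]],
            demes=["P1", "P2"],
            groups={"P1": "CC", "P2": "WC"},
        )
        d = diversity(ht, group="CC")
        assert d.n == 2 and d.h == 0.0


class TestTajimasD:
    def test_undefined_without_segregating_sites(self):
        assert math.isnan(tajimas_D(10, 0, 0.0))

    def test_textbook_constants_by_hand(self):
        # independent evaluation of every constant for n = 10
        n, S, khat = 10, 16, 3.888888888888889
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        expected = (khat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert tajimas_D(n, S, khat) == pytest.approx(expected, abs=1e-12)

    def test_zero_when_khat_equals_watterson(self):
        n, S = 12, 9
        a1 = sum(1 / i for i in range(1, n))
        assert tajimas_D(n, S, S / a1) == pytest.approx(0.0, abs=1e-12)


def crp_K_distribution(n, theta):
    """Pr(K = k) by the Chinese-restaurant-process recursion (oracle)."""
    probs = {1: 1.0}
    for m in range(1, n):
        new = {}
        for k, p in probs.items():
            new[k] = new.get(k, 0.0) + p * m / (theta + m)
            new[k + 1] = new.get(k + 1, 0.0) + p * theta / (theta + m)
        probs = new
    return probs


class TestFuFs:
    def test_degenerate_cases(self):
        assert math.isnan(fu_fs(5, 1, 2.0))  # single haplotype
        assert math.isnan(fu_fs(5, 3, 0.0))  # no pairwise differences

    @pytest.mark.parametrize("n,k,theta", [(5, 3, 1.7), (6, 2, 0.4), (6, 6, 3.0)])
    def test_matches_crp_enumeration(self, n, k, theta):
        dist = crp_K_distribution(n, theta)
        sprime = sum(p for kk, p in dist.items() if kk >= k)
        expected = math.log(sprime / (1 - sprime))
        assert fu_fs(n, k, theta) == pytest.approx(expected, abs=1e-9)


class TestNeutralityPvalues:
    def make_neutral_table(self, rng):
        from cherrypop.simulate import Scenario, simulate_dataset
        from cherrypop.seqdata import RecodedAlignment, collapse_haplotypes

        sc = Scenario(name="c", deme_sizes={"A": 5000.0}, events=[],
                      mutation_rate=2.5e-4)
        sd = simulate_dataset(sc, {"A": 15}, L=500, seed=rng)
        ds = sd.dataset
        ra = RecodedAlignment(ds.locus_name, list(ds.samples), ds.matrix,
                              np.empty((ds.n_samples, 0), dtype="<U1"), [])
        return collapse_haplotypes(ra)

    def test_neutral_data_not_extreme_and_deterministic(self, rng):
        ht = self.make_neutral_table(rng)
        r1 = neutrality_pvalues(ht, n_sims=300, seed=11)
        r2 = neutrality_pvalues(ht, n_sims=300, seed=11)
        assert (r1.tajima_D, r1.p_D, r1.fu_Fs, r1.p_Fs) == (
            r2.tajima_D, r2.p_D, r2.fu_Fs, r2.p_Fs
        )
        assert 0.0 <= r1.p_D <= 1.0 and 0.0 <= r1.p_Fs <= 1.0

    def test_small_n_sims_warns(self, rng):
        ht = self.make_neutral_table(rng)
        with pytest.warns(UserWarning, match="noisy"):
            neutrality_pvalues(ht, n_sims=50, seed=0)

    def test_no_segregating_sites_flagged(self):
        ht = make_ht(["AAA"], [[6]])
        r = neutrality_pvalues(ht, n_sims=100, seed=0)
        assert r.undefined_reason == "no segregating sites"
        assert math.isnan(r.tajima_D)


class TestMismatch:
    def test_observed_distribution_degenerate(self):
        ht = make_ht(["AAA"], [[5]])
        obs = mismatch_observed(ht)
        assert obs.tolist() == [1.0]
        assert raggedness(obs) == pytest.approx(2.0)  # boundary under padding

    def test_raggedness_hand_value(self):
        assert raggedness(np.array([0.0, 1.0, 0.0])) == pytest.approx(2.0)

    def test_expected_mismatch_limits(self):
        j = np.arange(20)
        stat5 = 5.0**j / 6.0 ** (j + 1)
        # tau = 0 collapses to the stationary distribution at theta0
        assert np.allclose(expected_mismatch(0.0, 5.0, 50.0, 20), stat5)
        # huge tau forgets theta0
        assert np.allclose(expected_mismatch(200.0, 1.0, 5.0, 20), stat5, atol=1e-9)
        assert expected_mismatch(3.0, 1.0, 20.0, 60).sum() == pytest.approx(1.0, abs=1e-6)

    def test_fit_recovers_exact_expectation(self):
        exp = expected_mismatch(4.0, 0.5, 30.0, 40)
        (tau, th0, th1), ssd, ok = _fit_sudden_expansion(exp, 40)
        assert ssd < 1e-8
        assert tau == pytest.approx(4.0, abs=0.3)

    def test_analysis_deterministic_and_bounded(self, rng):
        freq = _simulate_expansion_sample(25, 4.0, 1.0, 30.0, np.random.default_rng(2))
        # build a haplotype table realizing roughly this data via simulation
        from cherrypop.simulate import Scenario, Event, simulate_dataset
        from cherrypop.seqdata import RecodedAlignment, collapse_haplotypes

        mu = 2e-4
        sc = Scenario(
            name="exp", deme_sizes={"A": 4.0 / (4 * mu) * 10},
            events=[Event(4.0 / (2 * mu) * 4.0, "size_change",
                          {"deme": "A", "size": 0.5 / (4 * mu)})],
        )
        sc.mutation_rate = mu
        sd = simulate_dataset(sc, {"A": 20}, L=600, seed=rng)
        ds = sd.dataset
        ra = RecodedAlignment(ds.locus_name, list(ds.samples), ds.matrix,
                              np.empty((ds.n_samples, 0), dtype="<U1"), [])
        ht = collapse_haplotypes(ra)
        r1 = mismatch_analysis(ht, n_boot=50, seed=3)
        r2 = mismatch_analysis(ht, n_boot=50, seed=3)
        assert r1.tau == r2.tau and r1.p_ssd == r2.p_ssd and r1.p_rag == r2.p_rag
        assert 0 <= r1.p_ssd <= 1 and 0 <= r1.p_rag <= 1
        assert r1.theta0 <= r1.theta1
        assert r1.observed.sum() == pytest.approx(1.0)
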