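import numpy as np
import pytest

from cherrypop.errors import InputError, ScenarioError
from cherrypop.seqdata import RecodedAlignment, collapse_haplotypes
from cherrypop.simulate import (
    Event,
    Scenario,
    fixture_scenario,
    make_fixture,
    mutate,
    simulate_dataset,
    simulate_genealogy,
    summarize,
)


def one_deme(N=1000.0, mu=None):
    return Scenario(name="c", deme_sizes={"A": N}, events=[], mutation_rate=mu)


class TestScenario:
    def test_time_ordering_enforced(self):
        with pytest.raises(ScenarioError, match="increasing"):
            Scenario(
                name="bad",
                deme_sizes={"A": 1.0, "B": 1.0},
                events=[
                    Event(500.0, "merge", {"source": "A", "dest": "B"}),
                    Event(100.0, "size_change", {"deme": "B", "size": 2.0}),
                ],
            )

    def test_draw_respects_ordering(self, rng):
        sc = Scenario(
            name="p",
            deme_sizes={"A": 1000.0, "B": 1000.0},
            events=[Event(500.0, "merge", {"source": "A", "dest": "B"})],
            mutation_rate=1e-4,
            priors={"T:0": ("uniform", 100.0, 1000.0), "N:A": ("loguniform", 100, 10000)},
        )
        for _ in range(20):
            params, concrete = sc.draw(rng)
            assert 100 <= params["T:0"] <= 1000
            assert concrete.events[0].time_years == params["T:0"]
            assert concrete.deme_sizes["A"] == params["N:A"]

    def test_serialization_roundtrip(self, tmp_path):
        sc = fixture_scenario("three_group")
        sc.write(tmp_path / "sc.json")
        back = Scenario.read(tmp_path / "sc.json")
        assert back.to_dict() == sc.to_dict()

    def test_disconnected_demes_rejected(self):
        sc = Scenario(name="x", deme_sizes={"A": 1.0, "B": 1.0}, events=[])
        with pytest.raises(ScenarioError, match="common ancestor"):
            simulate_genealogy(sc, {"A": 2, "B": 2}, seed=0)


class TestGenealogy:
    def test_pairwise_tmrca_expectation(self, rng):
        N = 500.0
        t = [simulate_genealogy(one_deme(N), {"A": 2}, rng).tmrca for _ in range(4000)]
        assert np.mean(t) == pytest.approx(2 * N, rel=0.08)

    def test_total_length_expectation(self, rng):
        N, n = 500.0, 10
        a1 = sum(1.0 / i for i in range(1, n))
        tl = [
            simulate_genealogy(one_deme(N), {"A": n}, rng).total_branch_length
            for _ in range(3000)
        ]
        assert np.mean(tl) == pytest.approx(4 * N * a1, rel=0.08)

    def test_merge_bounds_divergence(self, rng):
        sc = Scenario(
            name="two",
            deme_sizes={"A": 100.0, "B": 100.0},
            events=[Event(4000.0, "merge", {"source": "A", "dest": "B"})],
        )
        g = simulate_genealogy(sc, {"A": 3, "B": 3}, rng)
        assert g.tmrca >= 1000.0  # cross-deme coalescence only after the merge


class TestMutate:
    def test_low_rate_gives_identical_sequences(self, rng):
        g = simulate_genealogy(one_deme(100.0), {"A": 6}, rng)
        sd = mutate(g, L=100, mu=1e-12, seed=1)
        assert len(set(map("".join, sd.dataset.matrix))) == 1

    def test_watterson_expectation(self, rng):
        N, n, L, mu = 400.0, 8, 2000, 2.5e-7
        theta = 4 * N * mu * L
        a1 = sum(1.0 / i for i in range(1, n))
        S = []
        for _ in range(2000):
            g = simulate_genealogy(one_deme(N), {"A": n}, rng)
            mat = mutate(g, L=L, mu=mu, seed=rng).dataset.matrix
            S.append(int(np.any(mat != mat[0], axis=0).sum()))
        assert np.mean(S) == pytest.approx(theta * a1, rel=0.08)

    def test_seed_reproducibility(self):
        g = simulate_genealogy(one_deme(), {"A": 5}, seed=7)
        m1 = mutate(g, L=200, mu=1e-5, seed=9).dataset.matrix
        m2 = mutate(g, L=200, mu=1e-5, seed=9).dataset.matrix
        assert np.array_equal(m1, m2)

    def test_infinite_sites_overflow_error(self, rng):
        g = simulate_genealogy(one_deme(5000.0), {"A": 10}, rng)
        with pytest.raises(InputError, match="increase L"):
            mutate(g, L=5, mu=1e-3, seed=0)

    def test_jukes_cantor_model(self, rng):
        g = simulate_genealogy(one_deme(500.0), {"A": 6}, rng)
        ds = mutate(g, L=300, mu=5e-6, model="jukes_cantor", seed=3).dataset
        assert set(ds.matrix.ravel()) <= set("ACGT")


class TestSummarize:
    def test_identical_demes_low_fst(self, rng):
        sc = Scenario(
            name="pan",
            deme_sizes={"A": 1000.0, "B": 1000.0},
            events=[Event(4.0, "merge", {"source": "A", "dest": "B"})],
            mutation_rate=3e-4,
        )
        fsts = []
        for _ in range(30):
            ss = summarize(simulate_dataset(sc, {"A": 8, "B": 8}, L=500, seed=rng))
            fsts.append(ss.as_dict()["A|B:fst"])
        assert abs(np.mean(fsts)) < 0.05

    def test_deep_divergence_high_fst(self, rng):
        sc = Scenario(
            name="deep",
            deme_sizes={"A": 500.0, "B": 500.0},
            events=[Event(200000.0, "merge", {"source": "A", "dest": "B"})],
            mutation_rate=3e-4,
        )
        fsts = []
        for _ in range(20):
            ss = summarize(simulate_dataset(sc, {"A": 8, "B": 8}, L=800, seed=rng))
            fsts.append(ss.as_dict()["A|B:fst"])
        assert np.mean(fsts) > 0.8

    def test_layout_stable(self, rng):
        sc = fixture_scenario("toy")
        s1 = summarize(simulate_dataset(sc, {"A": 5, "B": 5}, L=300, seed=1))
        s2 = summarize(simulate_dataset(sc, {"A": 5, "B": 5}, L=300, seed=2))
        assert s1.names == s2.names

    def test_agrees_with_popstats_path(self, rng):
        """The vectorized summary must equal the library's per-subset stats."""
        from cherrypop.popstats import diversity
        from cherrypop.amova import pairwise_fst
        from cherrypop.distances import pairwise_differences

        sd = make_fixture("toy", seed=5)
        ss = summarize(sd).as_dict()
        ds = sd.dataset
        ra = RecodedAlignment(ds.locus_name, list(ds.samples), ds.matrix,
                              np.empty((ds.n_samples, 0), dtype="<U1"), [])
        ht = collapse_haplotypes(ra)
        for d in ds.demes:
            div = diversity(ht, demes=[d])
            assert ss[f"{d}:k"] == div.k
            assert ss[f"{d}:h"] == pytest.approx(div.h, abs=1e-12)
            assert ss[f"{d}:pi"] == pytest.approx(div.pi, abs=1e-12)
            assert ss[f"{d}:S"] == div.S
        fst = pairwise_fst(ht, pairwise_differences(ht), n_perm=0)
        a, b = ds.demes
        assert ss[f"{a}|{b}:fst"] == pytest.approx(fst.fst[0, 1], abs=1e-10)

    def test_exchangeable_within_deme(self):
        sd = make_fixture("toy", seed=3)
        ss1 = summarize(sd)
        # permute rows within each deme
        ds = sd.dataset
        idx = np.arange(ds.n_samples)
        demes = np.array([s.deme for s in ds.samples])
        rng = np.random.default_rng(0)
        for d in set(demes):
            sel = np.where(demes == d)[0]
            idx[sel] = rng.permutation(idx[sel])
        from cherrypop.seqdata import AlignedDataset

        ds2 = AlignedDataset(ds.locus_name,
                             [ds.samples[i] for i in idx], ds.matrix[idx])
        ss2 = summarize(ds2)
        assert np.allclose(ss1.values, ss2.values)


class TestTwoLocusSimulation:
    def test_paired_loci_share_history(self, rng):
        from cherrypop.simulate import simulate_two_locus_dataset

        sc = fixture_scenario("toy")
        nuc, org = simulate_two_locus_dataset(
            sc, {"A": 6, "B": 6}, L_nuclear=400, L_organelle=300, seed=rng
        )
        assert nuc.dataset.length == 400 and org.dataset.length == 300
        assert [s.deme for s in nuc.dataset.samples] == [
            s.deme for s in org.dataset.samples
        ]
        assert nuc.truth["params"] == org.truth["params"]

    def test_organelle_diversity_reduced(self, rng):
        # half the effective size halves expected pairwise differences
        from cherrypop.simulate import simulate_two_locus_dataset

        sc = Scenario(name="c", deme_sizes={"A": 2000.0}, events=[],
                      mutation_rate=4e-4)
        nuc_mpd, org_mpd = [], []
        for _ in range(60):
            nuc, org = simulate_two_locus_dataset(
                sc, {"A": 8}, L_nuclear=800, L_organelle=800, seed=rng
            )
            for sd, acc in ((nuc, nuc_mpd), (org, org_mpd)):
                mat = sd.dataset.matrix
                d = sum(
                    (mat[i] != mat[j]).sum()
                    for i in range(8) for j in range(i + 1, 8)
                ) / 28.0
                acc.append(d)
        assert np.mean(org_mpd) < 0.75 * np.mean(nuc_mpd)


class TestFixtures:
    def test_toy_reproducible(self, tmp_path):
        from cherrypop.seqdata import write_dataset_fasta

        sd1 = make_fixture("toy", seed=42)
        sd2 = make_fixture("toy", seed=42)
        f1, f2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_dataset_fasta(sd1.dataset, f1, tmp_path / "a.tsv")
        write_dataset_fasta(sd2.dataset, f2, tmp_path / "b.tsv")
        assert f1.read_bytes() == f2.read_bytes()

    def test_five_group_labels_and_sizes(self):
        sizes = {"CC": 10, "WC": 10, "RC": 10, "EC": 10, "MC": 10}
        sd = make_fixture("five_group", seed=1, sample_sizes=sizes, L=710)
        ds = sd.dataset
        assert sorted(ds.demes) == sorted(sizes)
        for d, n in sizes.items():
            assert sum(1 for s in ds.samples if s.deme == d) == n
        groups = {s.group for s in ds.samples}
        assert groups == {"CC", "WC", "RC", "EC", "MC"}

    def test_domestication_split_in_generations(self):
        # a 2660-year split at 4-year generations is 665 generations
        sc = fixture_scenario("three_group")
        split = sc.events[0]
        assert split.kind == "merge" and split.params["source"] == "CC"
        assert split.time_years / sc.generation_time_years == pytest.approx(665.0)
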