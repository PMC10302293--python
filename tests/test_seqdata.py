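import numpy as np
import pytest

from cherrypop.errors import AlignmentError, InputError
from cherrypop.seqdata import (
    AlignedDataset,
    Sample,
    collapse_haplotypes,
    read_dataset,
    recode_indels,
    summarize_alignment,
    write_dataset_fasta,
)


def write_inputs(tmp_path, seqs, meta_rows, meta_header="sample_id\tdeme\tsubgroup\tgroup"):
    fasta = tmp_path / "aln.fasta"
    fasta.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
    meta = tmp_path / "meta.tsv"
    meta.write_text(meta_header + "\n" + "".join(r + "\n" for r in meta_rows))
    return fasta, meta


def make_ds(rows, demes=None):
    rows = np.array([list(r) for r in rows], dtype="<U1")
    n = rows.shape[0]
    demes = demes or ["d1"] * n
    samples = [Sample(f"s{i+1}", demes[i], demes[i], demes[i]) for i in range(n)]
    return AlignedDataset("test", samples, rows)


class TestReadDataset:
    def test_identity_ingestion(self, tmp_path):
        fasta, meta = write_inputs(
            tmp_path,
            {"a": "ACGTACGTAC", "b": "ACGTACGTAA", "c": "ACGTACGTAT"},
            ["a\tP1\tN\tCC", "b\tP1\tN\tCC", "c\tP2\tS\tWC"],
        )
        ds = read_dataset(fasta, meta)
        assert ds.length == 10 and ds.n_samples == 3
        assert ds.samples[2].group == "WC"
        assert ds.demes == ["P1", "P2"]

    def test_ragged_alignment_rejected(self, tmp_path):
        fasta, meta = write_inputs(
            tmp_path, {"a": "ACGTACGTAC", "b": "ACGTACGTA"}, ["a\tP1\tN\tCC", "b\tP1\tN\tCC"]
        )
        with pytest.raises(AlignmentError, match="ragged"):
            read_dataset(fasta, meta)

    def test_missing_metadata_id_reported(self, tmp_path):
        fasta, meta = write_inputs(
            tmp_path, {"a": "ACGT", "orphan": "ACGA"}, ["a\tP1\tN\tCC"]
        )
        with pytest.raises(InputError, match="orphan"):
            read_dataset(fasta, meta)

    def test_unknown_group_label(self, tmp_path):
        fasta, meta = write_inputs(tmp_path, {"a": "ACGT"}, ["a\tP1\tN\tXX"])
        with pytest.raises(InputError, match="XX"):
            read_dataset(fasta, meta, allowed_groups=["CC", "WC", "RC", "EC", "MC"])

    def test_roundtrip_through_writer(self, tmp_path):
        ds = make_ds(["ACGT", "ACGA"], ["P1", "P2"])
        write_dataset_fasta(ds, tmp_path / "o.fasta", tmp_path / "o.tsv")
        back = read_dataset(tmp_path / "o.fasta", tmp_path / "o.tsv")
        assert np.array_equal(back.matrix, ds.matrix)
        assert back.samples == ds.samples


class TestRecodeIndels:
    def test_single_gap_becomes_binary_character(self):
        ra = recode_indels(make_ds(["ACG-T", "ACGAT"]))
        assert ra.n_base_columns == 4
        assert ra.n_indel_characters == 1
        assert list(ra.indel[:, 0]) == ["1", "0"]
        assert ("indel", (3, 4)) in ra.provenance

    def test_gap_free_is_identity(self):
        ds = make_ds(["ACGT", "ACGA"])
        ra = recode_indels(ds)
        assert ra.n_indel_characters == 0
        assert np.array_equal(ra.base, ds.matrix)

    def test_shared_gap_run_is_one_event(self):
        ra = recode_indels(make_ds(["AC--T", "AC--T", "ACGAT"]))
        assert ra.n_indel_characters == 1
        assert list(ra.indel[:, 0]) == ["1", "1", "0"]

    def test_subsumed_gap_scored_missing(self):
        # the long deletion hides whether the short event happened
        ra = recode_indels(make_ds(["A---T", "AC--T", "ACGAT"]))
        assert ra.n_indel_characters == 2
        col = {ev: list(ra.indel[:, j])
               for j, (kind, ev) in enumerate(p for p in ra.provenance if p[0] == "indel")}
        assert col[(2, 4)] == ["N", "1", "0"]
        # the second row's own (shorter) gap overlaps the long event's span,
        # so presence of the long event is unobservable for it
        assert col[(1, 4)] == ["1", "N", "0"]

    def test_drop_mode_length_identity(self):
        ds = make_ds(["AC--T", "ACG-T", "ACGAT"])
        ra = recode_indels(ds, mode="drop_gapped_columns")
        n_dropped = ds.length - ra.n_base_columns
        assert ra.n_indel_characters == 0
        assert ra.n_base_columns + n_dropped == ds.length
        assert "-" not in set(ra.base.ravel())

    def test_all_gap_row_rejected(self):
        with pytest.raises(InputError, match="all-gap"):
            recode_indels(make_ds(["----", "ACGT"]))


class TestCollapseHaplotypes:
    def test_single_haplotype_two_demes(self):
        ra = recode_indels(make_ds(["AAA"] * 4, ["P1", "P1", "P2", "P2"]))
        ht = collapse_haplotypes(ra)
        assert ht.n_haplotypes == 1
        assert ht.counts.tolist() == [[2, 2]]

    def test_direct_collapse(self):
        ht = collapse_haplotypes(recode_indels(make_ds(["AAA", "AAT", "AAA"])))
        assert ht.n_haplotypes == 2
        assert ht.counts.sum(axis=1).tolist() == [2, 1]

    def test_ambiguous_N_row_stays_distinct(self):
        ra = recode_indels(make_ds(["AAT", "AAA", "AAN"]))
        ht = collapse_haplotypes(ra, missing_policy="match_ignoring_N")
        assert ht.n_haplotypes == 3  # two compatible matches -> ambiguous

    def test_unique_N_match_merges(self):
        ra = recode_indels(make_ds(["AAT", "CCC", "AAN"]))
        ht = collapse_haplotypes(ra, missing_policy="match_ignoring_N")
        assert ht.n_haplotypes == 2
        assert sorted(ht.counts.sum(axis=1).tolist()) == [1, 2]

    def test_strict_expand_roundtrip(self, rng):
        rows = rng.choice(list("ACGT"), size=(12, 6))
        demes = [f"P{i%3}" for i in range(12)]
        ra = recode_indels(make_ds(["".join(r) for r in rows], demes))
        ht = collapse_haplotypes(ra)
        expanded = []
        for i in range(ht.n_haplotypes):
            for j, d in enumerate(ht.demes):
                expanded += [("".join(ht.rows[i]), d)] * ht.counts[i, j]
        original = [("".join(r), d) for r, d in zip(rows, demes)]
        assert sorted(expanded) == sorted(original)

    def test_relabel_by_frequency(self):
        ra = recode_indels(make_ds(["AAT", "AAA", "AAA"]))
        ht = collapse_haplotypes(ra, relabel_by_frequency=True)
        assert ht.counts.sum(axis=1).tolist() == [2, 1]
        assert "".join(ht.rows[0]) == "AAA"


class TestSummarizeAlignment:
    def test_invariant_alignment(self):
        s = summarize_alignment(recode_indels(make_ds(["ACGT"] * 3)))
        assert (s.S, s.S_pi) == (0, 0)

    def test_polymorphic_vs_informative(self):
        # column 1: A:3/T:1 (polymorphic only); column 2: A:2/T:2 (informative)
        s = summarize_alignment(
            recode_indels(make_ds(["AAG", "AAG", "ATG", "TTG"]))
        )
        assert (s.S, s.S_pi) == (2, 1)

    def test_all_gc(self):
        s = summarize_alignment(recode_indels(make_ds(["GCGC", "CCGG"])))
        assert s.gc_content == 1.0

    def test_matches_bruteforce_tally(self, rng):
        for _ in range(10):
            rows = rng.choice(list("ACGTN"), size=(10, 20), p=[0.24] * 4 + [0.04])
            ra = recode_indels(make_ds(["".join(r) for r in rows]))
            s = summarize_alignment(ra)
            S = Spi = 0
            for j in range(20):
                col = [r[j] for r in rows if r[j] != "N"]
                states = {c: col.count(c) for c in set(col)}
                if len(states) >= 2:
                    S += 1
                    if sum(1 for v in states.values() if v >= 2) >= 2:
                        Spi += 1
            assert (s.S, s.S_pi) == (S, Spi)

    def test_indel_characters_counted_optionally(self):
        ra = recode_indels(make_ds(["AC-T", "ACAT", "ACAT"]))
        with_indels = summarize_alignment(ra, include_indel_characters=True)
        without = summarize_alignment(ra, include_indel_characters=False)
        assert with_indels.S == without.S + 1
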