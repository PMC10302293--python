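"""Aligned sequence data: ingestion, indel recoding, haplotype collapsing.

The entry object is :class:`AlignedDataset` — an aligned character matrix over
``{A, C, G, T, -, N}`` plus per-sample metadata (deme, geographic subgroup and
group labels, e.g. cultivated vs wild vs related taxa).  Gaps can be recoded as
binary presence/absence characters (simple indel coding: each distinct maximal
shared gap run becomes one character) or the gapped columns simply dropped.
Identical rows are then collapsed into haplotypes with per-deme counts, the
container every downstream statistic consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from cherrypop.errors import AlignmentError, InputError

VALID_CHARS = frozenset("ACGTN-")
BASE_CHARS = frozenset("ACGT")


class Sample(NamedTuple):
    sample_id: str
    deme: str
    subgroup: str
    group: str


@dataclass
class AlignedDataset:
    """An alignment with one row per sample and attached population metadata."""

    locus_name: str
    samples: list[Sample]
    matrix: np.ndarray  # (n_samples, L) single characters

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2 or self.matrix.shape[1] == 0:
            raise AlignmentError("alignment matrix must be 2-D with L > 0")
        if self.matrix.shape[0] != len(self.samples):
            raise InputError(
                f"{len(self.samples)} metadata rows but {self.matrix.shape[0]} sequences"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sample ids: {dupes}")
        bad = set(np.unique(self.matrix)) - VALID_CHARS
        if bad:
            raise AlignmentError(f"invalid alignment characters: {sorted(bad)}")
        # deme -> (subgroup, group) must be a function
        seen: dict[str, tuple[str, str]] = {}
        for s in self.samples:
            key = (s.subgroup, s.group)
            if seen.setdefault(s.deme, key) != key:
                raise InputError(
                    f"deme {s.deme!r} maps to more than one subgroup/group"
                )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def demes(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.deme not in out:
                out.append(s.deme)
        return out

    def deme_meta(self) -> dict[str, tuple[str, str]]:
        """deme -> (subgroup, group)."""
        return {s.deme: (s.subgroup, s.group) for s in self.samples}


@dataclass
class RecodedAlignment:
    """Gap-free base matrix plus appended binary indel characters.

    ``provenance`` maps every output column (base columns first, indel
    characters after) to its origin: ``("base", original_column)`` or
    ``("indel", (start, end))`` with 0-based half-open coordinates in the
    input alignment.
    """

    locus_name: str
    samples: list[Sample]
    base: np.ndarray  # (n, L_base) in {A,C,G,T,N}
    indel: np.ndarray  # (n, K) in {'0','1','N'}
    provenance: list[tuple[str, object]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.base.shape[0]

    @property
    def n_base_columns(self) -> int:
        return self.base.shape[1]

    @property
    def n_indel_characters(self) -> int:
        return self.indel.shape[1]

    def full_matrix(self) -> np.ndarray:
        """Base columns with indel characters appended (the recoded rows)."""
        if self.indel.shape[1] == 0:
            return self.base
        return np.concatenate([self.base, self.indel], axis=1)

    @property
    def demes(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.deme not in out:
                out.append(s.deme)
        return out

    def deme_meta(self) -> dict[str, tuple[str, str]]:
        return {s.deme: (s.subgroup, s.group) for s in self.samples}


@dataclass
class HaplotypeTable:
    """Distinct sequences with per-deme counts.

    ``rows`` holds one character row per haplotype; the first
    ``n_base_columns`` columns are nucleotides, the rest binary indel
    characters.  ``counts[i, j]`` is the number of samples of haplotype i in
    deme ``demes[j]``.
    """

    ids: list[str]
    rows: np.ndarray  # (H, L) characters
    counts: np.ndarray  # (H, D) non-negative ints
    demes: list[str]
    deme_meta: dict[str, tuple[str, str]]
    n_base_columns: int
    locus_name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise InputError("negative haplotype counts")
        keys = {tuple(r) for r in self.rows}
        if len(keys) != self.rows.shape[0]:
            raise InputError("haplotype rows are not pairwise distinct")

    @property
    def n_haplotypes(self) -> int:
        return self.rows.shape[0]

    @property
    def total_n(self) -> int:
        return int(self.counts.sum())

    @property
    def length(self) -> int:
        return self.rows.shape[1]

    def haplotype_frequencies(self) -> np.ndarray:
        """Relative frequency of each haplotype over the whole table."""
        return self.counts.sum(axis=1) / self.total_n

    def subset(self, demes: Sequence[str]) -> "HaplotypeTable":
        """Restrict to the given demes, dropping haplotypes absent from them."""
        missing = [d for d in demes if d not in self.demes]
        if missing:
            raise InputError(f"unknown demes: {missing}")
        cols = [self.demes.index(d) for d in demes]
        counts = self.counts[:, cols]
        keep = counts.sum(axis=1) > 0
        return HaplotypeTable(
            ids=[h for h, k in zip(self.ids, keep) if k],
            rows=self.rows[keep],
            counts=counts[keep],
            demes=list(demes),
            deme_meta={d: self.deme_meta[d] for d in demes},
            n_base_columns=self.n_base_columns,
            locus_name=self.locus_name,
        )

    def groups(self) -> dict[str, list[str]]:
        """group label -> list of member demes (insertion order)."""
        out: dict[str, list[str]] = {}
        for d in self.demes:
            out.setdefault(self.deme_meta[d][1], []).append(d)
        return out

    def expand_rows(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand to per-individual (haplotype_index, deme_index) arrays."""
        hap_idx: list[int] = []
        deme_idx: list[int] = []
        for i in range(self.n_haplotypes):
            for j in range(len(self.demes)):
                c = int(self.counts[i, j])
                hap_idx.extend([i] * c)
                deme_idx.extend([j] * c)
        return np.asarray(hap_idx, dtype=int), np.asarray(deme_idx, dtype=int)


@dataclass
class AlignmentSummary:
    length_bp: int
    gc_content: float
    S: int
    S_pi: int
    n_haplotypes: int


# ---------------------------------------------------------------------------
# ingestion


def read_dataset(
    fasta_path,
    metadata_path,
    locus_name: str | None = None,
    allowed_groups: Iterable[str] | None = None,
) -> AlignedDataset:
    """Read an aligned FASTA plus a tab-separated metadata table.

    The metadata table must have columns ``sample_id``, ``deme``,
    ``subgroup`` and ``group``.  Every FASTA record id must appear in the
    metadata; metadata rows without a sequence are reported with a warning.

    Parameters
    ----------
    allowed_groups:
        Optional whitelist of group labels (e.g. the study design's groups);
        any other label raises :class:`InputError`.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {fasta_path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise AlignmentError(
            f"ragged alignment: sequence lengths {sorted(lengths)} in {fasta_path}"
        )
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = ["sample_id", "deme", "subgroup", "group"]
    missing_cols = [c for c in required if c not in meta.columns]
    if missing_cols:
        raise InputError(f"metadata missing columns: {missing_cols}")
    if meta["sample_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise InputError(f"duplicate sample ids in metadata: {dupes}")
    meta = meta.set_index("sample_id")
    if allowed_groups is not None:
        allowed = set(allowed_groups)
        bad = sorted(set(meta["group"]) - allowed)
        if bad:
            raise InputError(f"unknown group labels: {bad} (allowed: {sorted(allowed)})")

    fasta_ids = [r.id for r in records]
    if len(set(fasta_ids)) != len(fasta_ids):
        dupes = sorted({i for i in fasta_ids if fasta_ids.count(i) > 1})
        raise InputError(f"duplicate record ids in FASTA: {dupes}")
    absent = [i for i in fasta_ids if i not in meta.index]
    if absent:
        raise InputError(f"FASTA ids absent from metadata: {absent}")
    unsequenced = sorted(set(meta.index) - set(fasta_ids))
    if unsequenced:
        warnings.warn(f"metadata rows without sequences: {unsequenced}", stacklevel=2)

    samples = [
        Sample(i, meta.at[i, "deme"], meta.at[i, "subgroup"], meta.at[i, "group"])
        for i in fasta_ids
    ]
    matrix = np.array([list(str(r.seq).upper()) for r in records], dtype="<U1")
    name = locus_name if locus_name is not None else str(fasta_path)
    return AlignedDataset(locus_name=name, samples=samples, matrix=matrix)


# ---------------------------------------------------------------------------
# indel recoding


def _gap_runs(row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of '-' in a row, as 0-based half-open (start, end)."""
    runs: list[tuple[int, int]] = []
    start = None
    for j, c in enumerate(row):
        if c == "-":
            if start is None:
                start = j
        elif start is not None:
            runs.append((start, j))
            start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def recode_indels(
    ds: AlignedDataset,
    mode: Literal["simple_indel_coding", "drop_gapped_columns"] = "simple_indel_coding",
) -> RecodedAlignment:
    """Remove gap columns, optionally recoding shared gaps as binary characters.

    ``simple_indel_coding`` applies simple indel coding: every distinct maximal
    gap run (start, end) observed in any row becomes one binary character —
    state 1 for rows carrying exactly that run, 0 for rows with no gap over the
    run's span, and missing for rows whose own gap strictly extends over it
    (the longer deletion makes the shorter event unobservable).

    ``drop_gapped_columns`` simply deletes every column containing a gap.
    """
    mat = ds.matrix
    all_gap = np.all(mat == "-", axis=1)
    if np.any(all_gap):
        bad = [ds.samples[i].sample_id for i in np.where(all_gap)[0]]
        raise InputError(f"all-gap rows: {bad}")

    gap_cols = np.any(mat == "-", axis=0)
    base = mat[:, ~gap_cols]
    provenance: list[tuple[str, object]] = [
        ("base", int(j)) for j in np.where(~gap_cols)[0]
    ]

    if mode == "drop_gapped_columns":
        indel = np.empty((mat.shape[0], 0), dtype="<U1")
        return RecodedAlignment(ds.locus_name, list(ds.samples), base, indel, provenance)
    if mode != "simple_indel_coding":
        raise InputError(f"unknown indel recoding mode: {mode!r}")

    per_row_runs = [_gap_runs(mat[i]) for i in range(mat.shape[0])]
    events = sorted({run for runs in per_row_runs for run in runs})
    cols: list[np.ndarray] = []
    for (s, e) in events:
        states = np.empty(mat.shape[0], dtype="<U1")
        for i, runs in enumerate(per_row_runs):
            if (s, e) in runs:
                states[i] = "1"
            elif not np.any(mat[i, s:e] == "-"):
                states[i] = "0"
            else:  # subsumed by a longer gap in this row
                states[i] = "N"
        cols.append(states)
    indel = (
        np.stack(cols, axis=1) if cols else np.empty((mat.shape[0], 0), dtype="<U1")
    )
    provenance.extend(("indel", ev) for ev in events)
    return RecodedAlignment(ds.locus_name, list(ds.samples), base, indel, provenance)


# ---------------------------------------------------------------------------
# haplotype collapsing


def collapse_haplotypes(
    ra: RecodedAlignment,
    missing_policy: Literal["strict", "match_ignoring_N"] = "strict",
    relabel_by_frequency: bool = False,
    id_prefix: str = "H",
) -> HaplotypeTable:
    """Collapse identical rows into haplotypes with per-deme counts.

    Under ``strict`` only byte-identical rows merge.  Under
    ``match_ignoring_N`` a row containing N merges into an existing haplotype
    when exactly one is compatible at every non-missing position; with zero or
    several compatible haplotypes the row stays distinct (the match would be
    ambiguous).  Haplotypes are numbered in first-seen order, or by descending
    total frequency when ``relabel_by_frequency`` is set (ties keep first-seen
    order), mirroring the convention that H1 is the commonest haplotype.
    """
    full = ra.full_matrix()
    demes = ra.demes
    deme_index = {d: j for j, d in enumerate(demes)}
    hap_rows: list[np.ndarray] = []
    key_to_idx: dict[tuple, int] = {}
    counts: list[np.ndarray] = []

    for i in range(full.shape[0]):
        row = full[i]
        key = tuple(row)
        idx = key_to_idx.get(key)
        if idx is None and missing_policy == "match_ignoring_N" and "N" in key:
            compatible = [
                j
                for j, h in enumerate(hap_rows)
                if np.all((row == h) | (row == "N") | (h == "N"))
            ]
            if len(compatible) == 1:
                idx = compatible[0]
        if idx is None:
            idx = len(hap_rows)
            hap_rows.append(row)
            key_to_idx[key] = idx
            counts.append(np.zeros(len(demes), dtype=int))
        counts[idx][deme_index[ra.samples[i].deme]] += 1

    rows = np.stack(hap_rows, axis=0)
    cmat = np.stack(counts, axis=0)
    order = np.arange(rows.shape[0])
    if relabel_by_frequency:
        totals = cmat.sum(axis=1)
        order = np.argsort(-totals, kind="stable")
        rows, cmat = rows[order], cmat[order]
    ids = [f"{id_prefix}{i + 1}" for i in range(rows.shape[0])]
    return HaplotypeTable(
        ids=ids,
        rows=rows,
        counts=cmat,
        demes=demes,
        deme_meta=ra.deme_meta(),
        n_base_columns=ra.n_base_columns,
        locus_name=ra.locus_name,
    )


# ---------------------------------------------------------------------------
# alignment summaries


def _column_state_counts(col: np.ndarray) -> dict[str, int]:
    vals, cnts = np.unique(col, return_counts=True)
    return {v: int(c) for v, c in zip(vals, cnts) if v not in ("N", "-")}


def summarize_alignment(
    ra: RecodedAlignment, include_indel_characters: bool = True
) -> AlignmentSummary:
    """Polymorphic/informative site counts, GC content and haplotype count.

    A site is polymorphic when at least two distinct non-missing states are
    observed (missing data never creates a state); parsimony-informative when
    at least two states are each carried by at least two rows.  GC content is
    computed over nucleotide cells only.  Indel characters count toward S and
    S_pi by default, matching the treat-indels-as-substitutions convention.
    """
    mat = ra.full_matrix() if include_indel_characters else ra.base
    S = 0
    S_pi = 0
    for j in range(mat.shape[1]):
        states = _column_state_counts(mat[:, j])
        if len(states) >= 2:
            S += 1
            if sum(1 for c in states.values() if c >= 2) >= 2:
                S_pi += 1
    base_cells = ra.base[np.isin(ra.base, ["A", "C", "G", "T"])]
    gc = (
        float(np.isin(base_cells, ["G", "C"]).mean()) if base_cells.size else float("nan")
    )
    n_hap = collapse_haplotypes(ra).n_haplotypes
    return AlignmentSummary(
        length_bp=ra.n_base_columns,
        gc_content=gc,
        S=S,
        S_pi=S_pi,
        n_haplotypes=n_hap,
    )


# ---------------------------------------------------------------------------
# writers


def write_haplotype_table(ht: HaplotypeTable, path) -> None:
    """Write the haplotype x deme count matrix as TSV."""
    df = pd.DataFrame(ht.counts, index=ht.ids, columns=ht.demes)
    df.index.name = "haplotype"
    df.to_csv(path, sep="\t")


def write_haplotype_fasta(ht: HaplotypeTable, path) -> None:
    with open(path, "w") as fh:
        for hid, row in zip(ht.ids, ht.rows):
            fh.write(f">{hid}\n{''.join(row)}\n")


def write_dataset_fasta(ds: AlignedDataset, fasta_path, metadata_path) -> None:
    """Write an AlignedDataset back to FASTA + metadata TSV (round-trippable)."""
    with open(fasta_path, "w") as fh:
        for s, row in zip(ds.samples, ds.matrix):
            fh.write(f">{s.sample_id}\n{''.join(row)}\n")
    with open(metadata_path, "w") as fh:
        fh.write("sample_id\tdeme\tsubgroup\tgroup\n")
        for s in ds.samples:
            fh.write(f"{s.sample_id}\t{s.deme}\t{s.subgroup}\t{s.group}\n")
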