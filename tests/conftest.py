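import numpy as np
import pytest

from cherrypop.seqdata import HaplotypeTable, RecodedAlignment, Sample


def make_ht(rows, counts=None, demes=None, groups=None, n_base=None):
    """HaplotypeTable from row strings and an (H x D) count matrix."""
    rows = [list(r) for r in rows]
    H = len(rows)
    if counts is None:
        counts = np.ones((H, 1), dtype=int)
    counts = np.asarray(counts, dtype=int)
    D = counts.shape[1]
    if demes is None:
        demes = [f"d{j+1}" for j in range(D)]
    if groups is None:
        groups = {d: d for d in demes}
    return HaplotypeTable(
        ids=[f"H{i+1}" for i in range(H)],
        rows=np.array(rows, dtype="<U1"),
        counts=counts,
        demes=list(demes),
        deme_meta={d: (d, groups[d]) for d in demes},
        n_base_columns=len(rows[0]) if n_base is None else n_base,
    )


def make_ra(rows, demes=None):
    """Gap-free RecodedAlignment from per-sample row strings."""
    rows = np.array([list(r) for r in rows], dtype="<U1")
    n = rows.shape[0]
    if demes is None:
        demes = ["d1"] * n
    samples = [Sample(f"s{i+1}", demes[i], demes[i], demes[i]) for i in range(n)]
    return RecodedAlignment(
        "test", samples, rows, np.empty((n, 0), dtype="<U1"), []
    )


@pytest.fixture
def ht_factory():
    return make_ht


@pytest.fixture
def ra_factory():
    return make_ra


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
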