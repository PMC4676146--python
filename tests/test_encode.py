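import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoclust.encode import (
    GenotypeMatrix,
    GenotypeVectorizer,
    VariantColumn,
    columns_to_matrix,
    filter_singletons,
    hamming_dosage,
    records_to_columns,
    sample_columns,
)
from genoclust.vcf_io import VariantRecord, VcfFormatError, read_vcf

from oracles import dense_dosage_matrix, dense_filter_singletons


@pytest.mark.parametrize(
    "gt,expected",
    [
        ("0|1", 1),  # heterozygous
        ("1|1", 2),  # homozygous variant
        ("0|0", 0),  # no variant
        ("0/1", 1),  # phasing carries no dosage information
        ("1/1", 2),
        ("1|2", 2),  # both alleles differ from reference
        ("0|2", 1),
        ("2|2", 2),
        ("./.", 0),  # missing counts as reference
        (".|1", 1),
        ("1", 1),  # haploid call
        ("0", 0),
        (".", 0),
    ],
)
def test_hamming_dosage_table(gt, expected):
    assert hamming_dosage(gt) == expected


def test_hamming_dosage_rejects_garbage():
    with pytest.raises(VcfFormatError):
        hamming_dosage("0|x")


def test_records_to_columns(toy_records):
    _, records = toy_records
    cols = list(records_to_columns(records))
    assert [c.variant_index for c in cols] == [0, 1, 2]
    assert cols[0].entries == ((0, 1), (2, 2))  # 0|1, 0|0, 1|1
    assert cols[1].entries == ((1, 2),)  # 0|0, 1|2, 0|0 -> singleton
    assert cols[2].entries == ()  # all-reference site keeps its index


def test_filter_singletons_rule():
    cols = [
        VariantColumn(0, ((0, 1),)),  # singleton -> dropped
        VariantColumn(1, ((0, 1), (1, 2))),
        VariantColumn(2, ((2, 2),)),  # singleton -> dropped
        VariantColumn(3, ((0, 1), (1, 1), (2, 1))),
        VariantColumn(4, ()),  # empty -> dropped
    ]
    kept = list(filter_singletons(cols))
    assert [c.variant_index for c in kept] == [0, 1], "survivors re-indexed"
    assert [c.entries for c in kept] == [cols[1].entries, cols[3].entries]


def test_filter_singletons_idempotent_and_preserving():
    cols = [
        VariantColumn(0, ((0, 1), (1, 2))),
        VariantColumn(1, ((1, 1), (2, 1))),
    ]
    once = list(filter_singletons(cols))
    twice = list(filter_singletons(once))
    assert once == twice == cols
    assert list(filter_singletons([])) == []


class TestSampleColumns:
    def make(self, n):
        return [VariantColumn(i, ((0, 1), (1, 1))) for i in range(n)]

    def test_fraction_one_is_passthrough(self):
        cols = self.make(50)
        assert list(sample_columns(cols, 1.0, seed=3)) == cols

    def test_fraction_zero_is_empty(self):
        assert list(sample_columns(self.make(50), 0.0, seed=3)) == []

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            list(sample_columns(self.make(5), 1.5, seed=0))

    def test_seeded_reproducibility(self):
        cols = self.make(500)
        a = list(sample_columns(cols, 0.3, seed=42))
        b = list(sample_columns(cols, 0.3, seed=42))
        c = list(sample_columns(cols, 0.3, seed=43))
        assert a == b
        assert a != c

    def test_binomial_band_at_20_percent(self):
        # 10,000 columns at fraction 0.2: 3 sigma band around 2,000
        cols = self.make(10_000)
        kept = sum(1 for _ in sample_columns(cols, 0.2, seed=7))
        sigma = np.sqrt(10_000 * 0.2 * 0.8)
        assert abs(kept - 2000) <= 3 * sigma

    def test_chunking_independence(self):
        """The retain/drop decision for a variant depends only on (seed,
        incoming variant index), not on how the stream was consumed: a
        truncated stream reproduces a prefix of the full pass."""
        cols = [VariantColumn(i, ((i % 3, 1),)) for i in range(200)]
        kept_full = list(sample_columns(cols, 0.5, seed=9))
        kept_prefix = list(sample_columns(cols[:100], 0.5, seed=9))
        assert [c.entries for c in kept_prefix] == [
            c.entries for c in kept_full[: len(kept_prefix)]
        ]


def test_columns_to_matrix_transpose_by_hand():
    cols = [
        VariantColumn(0, ((0, 1), (2, 2))),
        VariantColumn(1, ((0, 2),)),
    ]
    m = columns_to_matrix(cols, ["a", "b", "c"])
    assert m.n_variants == 2
    assert m.row_entries(0) == [(0, 1), (1, 2)]
    assert m.row_entries(1) == []
    assert m.row_entries(2) == [(0, 2)]


def test_columns_to_matrix_empty_and_errors():
    m = columns_to_matrix([], ["a", "b"])
    assert m.n_variants == 0 and m.X.nnz == 0
    with pytest.raises(ValueError, match="out of range"):
        columns_to_matrix([VariantColumn(0, ((5, 1),))], ["a", "b"])


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_double_transpose_identity(seed):
    """Transposing random sparse columns to a matrix and back returns the
    original columns (mass and structure conserved)."""
    rng = np.random.default_rng(seed)
    n_samples, n_variants = 50, 200
    cols = []
    for j in range(n_variants):
        carriers = rng.choice(n_samples, size=rng.integers(0, 6), replace=False)
        entries = tuple(
            (int(s), int(rng.integers(1, 3))) for s in sorted(carriers)
        )
        cols.append(VariantColumn(j, entries))
    m = columns_to_matrix(cols, [f"s{i}" for i in range(n_samples)])
    # rebuild columns from the matrix rows
    rebuilt: dict[int, list] = {j: [] for j in range(n_variants)}
    for i in range(n_samples):
        for j, d in m.row_entries(i):
            rebuilt[j].append((i, d))
    assert all(tuple(rebuilt[j]) == cols[j].entries for j in range(n_variants))
    assert m.total_dosage() == sum(d for c in cols for _, d in c.entries)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=15, deadline=None, derandomize=True)
def test_pipeline_matches_dense_oracle(seed):
    """Sparse streaming pipeline == naive dense matrix on random cohorts."""
    rng = np.random.default_rng(seed)
    n_samples, n_variants = rng.integers(5, 60), rng.integers(5, 300)
    gt_pool = ["0|0", "0|1", "1|1", "0/1", "./.", "1|2"]
    records = [
        VariantRecord(
            "1",
            j + 1,
            ".",
            "A",
            ("C", "T"),
            tuple(rng.choice(gt_pool, size=n_samples)),
        )
        for j in range(n_variants)
    ]
    dense = dense_dosage_matrix(records)
    m = columns_to_matrix(
        records_to_columns(records), [f"s{i}" for i in range(n_samples)]
    )
    assert np.array_equal(m.X.toarray(), dense[:, : m.n_variants])
    # with singleton filtering
    m2 = columns_to_matrix(
        filter_singletons(records_to_columns(records)),
        [f"s{i}" for i in range(n_samples)],
    )
    assert np.array_equal(m2.X.toarray(), dense_filter_singletons(dense))


def test_dosage_mass_conservation(toy_records):
    header, records = toy_records
    total = sum(hamming_dosage(gt) for r in records for gt in r.gt_strings)
    m = columns_to_matrix(records_to_columns(records), header.sample_ids)
    assert m.total_dosage() == total


def test_matrix_round_trip_file(tmp_path, small_cohort):
    _, header, records, _ = small_cohort
    m = columns_to_matrix(records_to_columns(records), header.sample_ids)
    dest = tmp_path / "m.txt"
    m.to_file(dest)
    m2 = GenotypeMatrix.from_file(dest)
    assert m2.sample_ids == m.sample_ids
    assert m2.n_variants == m.n_variants
    assert (m2.X != m.X).nnz == 0


class TestGenotypeVectorizer:
    def test_counters_and_equivalence(self, toy_records):
        header, records = toy_records
        vec = GenotypeVectorizer(drop_singletons=True)
        m = vec.fit_transform((header, records))
        assert vec.n_variants_in_ == 3
        assert vec.n_dropped_singletons_ == 2  # one singleton + one empty site
        assert vec.n_variants_out_ == 1
        assert m.n_variants == 1

    def test_sklearn_params_round_trip(self):
        vec = GenotypeVectorizer(sample_fraction=0.5, drop_singletons=True, seed=3)
        params = vec.get_params()
        clone = GenotypeVectorizer(**params)
        assert clone.get_params() == params

    def test_vcf_text_to_matrix(self, toy_vcf_text):
        header, records = read_vcf(io.StringIO(toy_vcf_text))
        m = GenotypeVectorizer().fit_transform((header, records))
        assert m.n_samples == 3 and m.n_variants == 3
        assert m.total_dosage() == 5  # 1+2 at site 1, 2 at site 2, 0 at site 3
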