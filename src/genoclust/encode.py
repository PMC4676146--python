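"""Genotypes to a sample-major sparse dosage matrix.

Each VCF site becomes a sparse column of per-sample dosages, where the dosage
is the Hamming distance of the genotype to the homozygous-reference genotype:
0 for ``0|0``, 1 for a heterozygote such as ``0|1``, 2 for a homozygous
variant such as ``1|1``. Zero dosages are never stored. Columns can be
filtered (singleton sites, carried by exactly one individual, are dropped)
and subsampled genome-wide at a fixed fraction with a seeded, chunking-
independent pseudo-random stream. Finally the columns are transposed into one
sparse row per individual — the feature vectors handed to k-means.

The :class:`GenotypeVectorizer` wraps the whole chain as a scikit-learn style
transformer; the module functions are the individual streaming stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .vcf_io import VariantRecord, VcfFormatError, VcfHeader

__all__ = [
    "VariantColumn",
    "GenotypeMatrix",
    "GenotypeVectorizer",
    "hamming_dosage",
    "records_to_columns",
    "filter_singletons",
    "sample_columns",
    "columns_to_matrix",
]


@dataclass(frozen=True)
class VariantColumn:
    """Sparse dosages of one variant: (sample_index, dosage) pairs, dosage > 0."""

    variant_index: int
    entries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        idx = [s for s, _ in self.entries]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate sample_index within a variant column")
        if any(d == 0 for _, d in self.entries):
            raise ValueError("zero dosages must not be stored in a sparse column")


@dataclass(frozen=True)
class GenotypeMatrix:
    """Sample-major sparse dosage matrix.

    ``X`` is an ``n_samples x n_variants`` CSR matrix of integer dosages
    (1 or 2 for diploid input; explicit zeros are never stored). Row order
    follows ``sample_ids``; column order is the sequential variant index,
    which preserves genome locus order.
    """

    sample_ids: tuple[str, ...]
    X: sp.csr_matrix

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"matrix has {self.X.shape[0]} rows for {len(self.sample_ids)} samples"
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variants(self) -> int:
        return self.X.shape[1]

    def row_entries(self, i: int) -> list[tuple[int, int]]:
        """(variant_index, dosage) pairs of sample ``i``, sorted by index."""
        row = self.X.getrow(i).tocoo()
        order = np.argsort(row.col)
        return [(int(row.col[j]), int(row.data[j])) for j in order]

    def total_dosage(self) -> int:
        return int(self.X.sum())

    def subset_rows(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            sample_ids=tuple(self.sample_ids[i] for i in keep),
            X=sp.csr_matrix(self.X[keep, :]),
        )

    # -- on-disk triplet format ------------------------------------------
    # Plain text, bit-exact round trip:
    #   #genoclust-matrix v1
    #   #samples <TAB> comma-joined sample IDs
    #   #n_variants <TAB> N
    #   sample_index <TAB> variant_index <TAB> dosage   (one line per entry)

    def to_file(self, dest: str | Path) -> None:
        coo = self.X.tocoo()
        order = np.lexsort((coo.col, coo.row))
        with open(dest, "wt") as out:
            out.write("#genoclust-matrix v1\n")
            out.write("#samples\t" + ",".join(self.sample_ids) + "\n")
            out.write(f"#n_variants\t{self.n_variants}\n")
            for j in order:
                out.write(f"{coo.row[j]}\t{coo.col[j]}\t{int(coo.data[j])}\n")

    @classmethod
    def from_file(cls, source: str | Path) -> "GenotypeMatrix":
        with open(source, "rt") as fh:
            magic = fh.readline().rstrip("\n")
            if magic != "#genoclust-matrix v1":
                raise ValueError(f"{source}: not a genoclust matrix file")
            tag, _, samples_str = fh.readline().rstrip("\n").partition("\t")
            if tag != "#samples":
                raise ValueError(f"{source}: missing #samples line")
            sample_ids = tuple(samples_str.split(",")) if samples_str else ()
            tag, _, nvar_str = fh.readline().rstrip("\n").partition("\t")
            if tag != "#n_variants":
                raise ValueError(f"{source}: missing #n_variants line")
            n_variants = int(nvar_str)
            rows, cols, data = [], [], []
            for line in fh:
                r, c, d = line.split("\t")
                rows.append(int(r))
                cols.append(int(c))
                data.append(int(d))
        X = sp.csr_matrix(
            (data, (rows, cols)),
            shape=(len(sample_ids), n_variants),
            dtype=np.float64,
        )
        return cls(sample_ids=sample_ids, X=X)


# Fast path for the handful of genotype strings that dominate real cohorts.
_DOSAGE_CACHE: dict[str, int] = {}


def hamming_dosage(gt: str) -> int:
    """Dosage of a GT string: its Hamming distance to the reference genotype.

    Counts allele tokens that are present, numeric and non-zero — so ``0|1``
    gives 1, ``1|1`` gives 2, ``0|0`` gives 0, and phasing (``|`` vs ``/``)
    is irrelevant. Missing tokens (``.``) count as reference. Alternate
    allele identity is discarded: ``1|2`` gives 2, like any genotype whose
    two alleles both differ from the reference.
    """
    cached = _DOSAGE_CACHE.get(gt)
    if cached is not None:
        return cached
    tokens = gt.replace("/", "|").split("|")
    dosage = 0
    for tok in tokens:
        if tok == "." or tok == "":
            continue
        if not tok.isdigit():
            raise VcfFormatError(f"malformed genotype token {tok!r} in {gt!r}")
        if tok != "0":
            dosage += 1
    if len(_DOSAGE_CACHE) < 4096:
        _DOSAGE_CACHE[gt] = dosage
    return dosage


def records_to_columns(
    records: Iterable[VariantRecord],
) -> Iterator[VariantColumn]:
    """One sparse column per record, indexed sequentially from 0 in stream
    order so the genome locus order is preserved. Columns with no non-zero
    dosage still consume an index but carry no entries."""
    for index, rec in enumerate(records):
        entries = []
        for sample_index, gt in enumerate(rec.gt_strings):
            dosage = hamming_dosage(gt)
            if dosage:
                entries.append((sample_index, dosage))
        yield VariantColumn(variant_index=index, entries=tuple(entries))


def filter_singletons(
    columns: Iterable[VariantColumn],
) -> Iterator[VariantColumn]:
    """Drop sites carried by exactly one individual (and empty sites).

    A sparse column's length equals the number of individuals with a variant
    there, so singletons are exactly the length-one columns. Zero-length
    columns carry no signal and are dropped too. Survivors are re-indexed
    sequentially from 0, preserving order.
    """
    out_index = 0
    for col in columns:
        if len(col.entries) <= 1:
            continue
        yield VariantColumn(variant_index=out_index, entries=col.entries)
        out_index += 1


class _IndexedUniforms:
    """Uniform(0,1) stream addressable by non-decreasing integer index.

    Backed by a counter-based Philox generator so u[i] depends only on
    (seed, i): the sampling decision for a variant never depends on how the
    column iterator was chunked upstream.
    """

    _BLOCK = 8192

    def __init__(self, seed: int) -> None:
        self._gen = np.random.Generator(np.random.Philox(key=seed))
        self._buf = np.empty(0)
        self._offset = 0  # index of _buf[0]

    def at(self, index: int) -> float:
        if index < self._offset:
            raise ValueError("variant indices must be non-decreasing")
        while index >= self._offset + len(self._buf):
            self._offset += len(self._buf)
            self._buf = self._gen.random(self._BLOCK)
        return float(self._buf[index - self._offset])


def sample_columns(
    columns: Iterable[VariantColumn], fraction: float, seed: int
) -> Iterator[VariantColumn]:
    """Retain each column independently with probability ``fraction``.

    Deterministic given ``seed``; the per-column decision is keyed on the
    column's incoming variant index. Fraction 1 is an exact pass-through
    (same pseudo-random draws are made, every column survives), fraction 0
    yields nothing. Survivors are re-indexed sequentially.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"sampling fraction must be in [0, 1], got {fraction}")
    uniforms = _IndexedUniforms(seed)
    out_index = 0
    for col in columns:
        if uniforms.at(col.variant_index) < fraction or fraction == 1.0:
            yield VariantColumn(variant_index=out_index, entries=col.entries)
            out_index += 1


def columns_to_matrix(
    columns: Iterable[VariantColumn], sample_ids: Sequence[str]
) -> GenotypeMatrix:
    """Transpose variant columns into per-sample sparse rows.

    Entry count is conserved exactly: every stored (sample, dosage) pair of
    every column appears once in the resulting matrix.
    """
    n_samples = len(sample_ids)
    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    n_variants = 0
    for col in columns:
        n_variants = max(n_variants, col.variant_index + 1)
        for sample_index, dosage in col.entries:
            if not 0 <= sample_index < n_samples:
                raise ValueError(
                    f"sample_index {sample_index} out of range for "
                    f"{n_samples} samples (variant {col.variant_index})"
                )
            rows.append(sample_index)
            cols.append(col.variant_index)
            data.append(dosage)
    X = sp.csr_matrix(
        (data, (rows, cols)), shape=(n_samples, n_variants), dtype=np.float64
    )
    return GenotypeMatrix(sample_ids=tuple(sample_ids), X=X)


class GenotypeVectorizer(BaseEstimator, TransformerMixin):
    """Transformer from streamed VCF records to a :class:`GenotypeMatrix`.

    Chains the streaming stages — dosage encoding, optional genome-wide
    variant subsampling, optional singleton filtering, transpose — in that
    order (sampling happens first, so the singleton filter describes the set
    of variants actually clustered).

    Parameters
    ----------
    sample_fraction : float, default 1.0
        Probability of retaining each variant; 1.0 disables subsampling.
    drop_singletons : bool, default False
        Drop sites carried by exactly one individual (and empty sites).
    seed : int, default 0
        Seed for the variant-sampling stream.

    Attributes
    ----------
    n_variants_in_ : int
        Sites read from the input stream.
    n_variants_out_ : int
        Columns retained in the output matrix.
    n_dropped_sampling_ : int
        Sites removed by subsampling.
    n_dropped_singletons_ : int
        Sites removed by the singleton/empty filter (0 when disabled).
    matrix_ : GenotypeMatrix
        The encoded matrix from the last ``transform``.
    """

    def __init__(
        self,
        sample_fraction: float = 1.0,
        drop_singletons: bool = False,
        seed: int = 0,
    ) -> None:
        self.sample_fraction = sample_fraction
        self.drop_singletons = drop_singletons
        self.seed = seed

    def fit(self, X=None, y=None) -> "GenotypeVectorizer":  # noqa: D102 - stateless
        return self

    def transform(
        self, X: tuple[VcfHeader | Sequence[str], Iterable[VariantRecord]]
    ) -> GenotypeMatrix:
        """Encode ``X = (header_or_sample_ids, record_iterable)``.

        The record iterable is consumed exactly once, streaming.
        """
        header, records = X
        sample_ids: Sequence[str]
        if isinstance(header, VcfHeader):
            sample_ids = header.sample_ids
        else:
            sample_ids = tuple(header)

        counters = {"in": 0, "sampled": 0, "filtered": 0}

        def _count(cols: Iterable[VariantColumn], key: str) -> Iterator[VariantColumn]:
            for col in cols:
                counters[key] += 1
                yield col

        stage: Iterable[VariantColumn] = _count(records_to_columns(records), "in")
        if self.sample_fraction != 1.0:
            stage = sample_columns(stage, self.sample_fraction, self.seed)
        stage = _count(stage, "sampled")
        if self.drop_singletons:
            stage = filter_singletons(stage)
        stage = _count(stage, "filtered")

        matrix = columns_to_matrix(stage, sample_ids)
        self.n_variants_in_ = counters["in"]
        self.n_dropped_sampling_ = counters["in"] - counters["sampled"]
        self.n_dropped_singletons_ = counters["sampled"] - counters["filtered"]
        self.n_variants_out_ = counters["filtered"]
        self.matrix_ = matrix
        return matrix
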