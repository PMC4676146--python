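"""Scoring a clustering against annotated population labels.

The metric is the Hubert–Arabie adjusted Rand index (ARI): the pair-counting
Rand index corrected for chance agreement, computed from the cluster x label
contingency table. It is 1 for identical partitions, near 0 for independent
labelings, and bounded below by -1.

Panel files follow the 1000 Genomes dialect: a tab-separated table with a
header naming at least a ``sample`` column and one or more label columns
(``pop``, ``super_pop``), in any column order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .encode import GenotypeMatrix

__all__ = [
    "PopulationTruth",
    "ContingencyTable",
    "contingency_table",
    "adjusted_rand_index",
    "read_panel",
    "subset_samples",
]


@dataclass(frozen=True)
class PopulationTruth:
    """Mapping sample ID -> annotated population label."""

    labels: Mapping[str, str]

    def labels_for(self, sample_ids: Sequence[str]) -> list[str]:
        """Labels in matrix row order; unknown samples fail loudly.

        Silently dropping unlabelled samples would corrupt any accuracy
        claim, so a missing sample is an error naming the sample.
        """
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise KeyError(
                f"samples absent from the panel: {', '.join(missing[:5])}"
                + (f" (+{len(missing) - 5} more)" if len(missing) > 5 else "")
            )
        return [self.labels[s] for s in sample_ids]


@dataclass(frozen=True)
class ContingencyTable:
    """Cluster x true-label co-occurrence counts underlying the ARI."""

    counts: np.ndarray  # (n_clusters, n_labels)
    cluster_values: tuple
    label_values: tuple

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=list(self.cluster_values),
            columns=list(self.label_values),
        )


def contingency_table(pred: Sequence, truth: Sequence) -> ContingencyTable:
    """Cross-tabulate predicted cluster indices against true labels."""
    if len(pred) != len(truth):
        raise ValueError(
            f"length mismatch: {len(pred)} predictions vs {len(truth)} labels"
        )
    if len(pred) == 0:
        raise ValueError("cannot tabulate empty labelings")
    pred_vals, pred_codes = np.unique(np.asarray(pred), return_inverse=True)
    truth_vals, truth_codes = np.unique(np.asarray(truth), return_inverse=True)
    counts = np.zeros((len(pred_vals), len(truth_vals)), dtype=np.int64)
    np.add.at(counts, (pred_codes, truth_codes), 1)
    return ContingencyTable(
        counts=counts,
        cluster_values=tuple(pred_vals.tolist()),
        label_values=tuple(truth_vals.tolist()),
    )


def adjusted_rand_index(pred: Sequence, truth: Sequence) -> float:
    """Hubert–Arabie ARI between two labelings of the same samples.

    From the contingency table with cells ``n_ij``, row sums ``a_i`` and
    column sums ``b_j`` over ``n`` samples::

        index    = sum_ij C(n_ij, 2)
        expected = sum_i C(a_i, 2) * sum_j C(b_j, 2) / C(n, 2)
        maximum  = (sum_i C(a_i, 2) + sum_j C(b_j, 2)) / 2
        ARI      = (index - expected) / (maximum - expected)

    When ``maximum == expected`` (both partitions are a single cluster, or
    both are all singletons) the ratio is 0/0; by convention the result is
    1.0 if the partitions are identical as set partitions and 0.0 otherwise.
    """
    table = contingency_table(pred, truth)
    if table.n < 2:
        raise ValueError("ARI needs at least 2 samples")
    index = sum(comb(int(nij), 2) for nij in table.counts.ravel())
    sum_a = sum(comb(int(a), 2) for a in table.row_sums)
    sum_b = sum(comb(int(b), 2) for b in table.col_sums)
    expected = sum_a * sum_b / comb(table.n, 2)
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:
        # degenerate: identical set partitions iff the table is a
        # permutation-like matrix (each row and column has one nonzero block)
        identical = (
            table.counts.shape[0] == table.counts.shape[1]
            and (np.count_nonzero(table.counts, axis=0) == 1).all()
            and (np.count_nonzero(table.counts, axis=1) == 1).all()
        )
        return 1.0 if identical else 0.0
    return float((index - expected) / (maximum - expected))


def read_panel(source: str | Path, column: str = "super_pop") -> PopulationTruth:
    """Read a 1000 Genomes style panel TSV into a :class:`PopulationTruth`.

    ``column`` selects the label granularity (``pop`` or ``super_pop`` in
    the standard panel). Duplicate sample IDs are an error.
    """
    df = pd.read_csv(source, sep="\t")
    df.columns = [c.strip() for c in df.columns]
    if "sample" not in df.columns:
        raise ValueError(f"{source}: panel has no 'sample' column")
    if column not in df.columns:
        raise ValueError(
            f"{source}: no column {column!r}; available: {list(df.columns)}"
        )
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"{source}: duplicate sample IDs: {dupes[:5]}")
    return PopulationTruth(
        labels=dict(zip(df["sample"].astype(str), df[column].astype(str)))
    )


def subset_samples(
    matrix: GenotypeMatrix,
    truth: PopulationTruth,
    exclude_labels: set[str],
) -> tuple[GenotypeMatrix, PopulationTruth]:
    """Drop samples whose true label is excluded (e.g. the admixed AMR
    super-population); variant indices are untouched."""
    observed = set(truth.labels_for(matrix.sample_ids))
    unknown = set(exclude_labels) - observed
    if unknown:
        warnings.warn(
            f"exclude labels not present in the cohort: {sorted(unknown)}",
            stacklevel=2,
        )
    keep = [
        i
        for i, s in enumerate(matrix.sample_ids)
        if truth.labels[s] not in exclude_labels
    ]
    sub = matrix.subset_rows(keep)
    sub_truth = PopulationTruth(
        labels={s: truth.labels[s] for s in sub.sample_ids}
    )
    return sub, sub_truth
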