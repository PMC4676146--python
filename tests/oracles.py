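"""Independent reference implementations used only by the test suite.

Each oracle recomputes a pipeline quantity by a different route than the
package (dense instead of sparse, pair counting instead of contingency
table, naive loops instead of vectorised algebra) so agreement is evidence,
not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np

from genoclust.vcf_io import VariantRecord


def dense_dosage_matrix(records: list[VariantRecord]) -> np.ndarray:
    """Naive dense encoding: samples x variants, dosage per genotype."""

    def dosage(gt: str) -> int:
        return sum(
            1
            for tok in gt.replace("/", "|").split("|")
            if tok not in (".", "") and int(tok) != 0
        )

    if not records:
        return np.zeros((0, 0))
    n_samples = len(records[0].gt_strings)
    M = np.zeros((n_samples, len(records)))
    for j, rec in enumerate(records):
        for i, gt in enumerate(rec.gt_strings):
            M[i, j] = dosage(gt)
    return M


def dense_filter_singletons(M: np.ndarray) -> np.ndarray:
    """Keep columns carried by at least two individuals."""
    carriers = (M > 0).sum(axis=0)
    return M[:, carriers >= 2]


def dense_lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int = 100, tol: float = 1e-4
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Plain dense Lloyd's k-means from given initial centroids.

    Same contract as the package implementation: nearest centroid by squared
    Euclidean distance with ties to the lowest index, empty clusters reseeded
    to the point farthest from its own centroid, stop when the max centroid
    displacement is below tol. Distances are computed pointwise with plain
    loops over centroids (no norm-expansion trick).
    """
    centers = centers.astype(float).copy()
    k = centers.shape[0]
    n = X.shape[0]
    trace: list[float] = []
    for _ in range(max_iter):
        d = np.empty((n, k))
        for c in range(k):
            diff = X - centers[c]
            d[:, c] = (diff * diff).sum(axis=1)
        labels = d.argmin(axis=1)
        trace.append(float(d[np.arange(n), labels].sum()))
        missing = [c for c in range(k) if c not in set(labels.tolist())]
        if missing:
            worst = np.argsort(d[np.arange(n), labels])[::-1]
            for taken, c in enumerate(missing):
                labels[worst[taken]] = c
        new_centers = centers.copy()
        for c in range(k):
            members = X[labels == c]
            if len(members):
                new_centers[c] = members.mean(axis=0)
        shift = max(np.linalg.norm(new_centers[c] - centers[c]) for c in range(k))
        centers = new_centers
        if shift < tol:
            break
    d = np.empty((n, k))
    for c in range(k):
        diff = X - centers[c]
        d[:, c] = (diff * diff).sum(axis=1)
    labels = d.argmin(axis=1)
    objective = float(d[np.arange(n), labels].sum())
    trace.append(objective)
    return centers, labels, objective, trace


def pair_counting_ari(pred, truth) -> float:
    """ARI by brute-force pair counting over all C(n,2) sample pairs.

    With a = pairs co-clustered in both labelings, b = in pred only,
    c = in truth only, d = in neither:
    ARI = 2(ad - bc) / ((a+b)(b+d) + (a+c)(c+d)).
    """
    n = len(pred)
    a = b = c = d = 0
    for i, j in itertools.combinations(range(n), 2):
        same_p = pred[i] == pred[j]
        same_t = truth[i] == truth[j]
        if same_p and same_t:
            a += 1
        elif same_p:
            b += 1
        elif same_t:
            c += 1
        else:
            d += 1
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        # both partitions all-together or both all-apart; identical iff b == c == 0
        return 1.0 if (b == 0 and c == 0) else 0.0
    return 2.0 * (a * d - b * c) / denom


def partitions_into_at_most(n_items: int, max_groups: int):
    """All labelings of n items into at most max_groups blocks, one per set
    partition (restricted growth strings)."""

    def grow(prefix: list[int], used: int):
        if len(prefix) == n_items:
            yield tuple(prefix)
            return
        for lab in range(min(used + 1, max_groups)):
            yield from grow(prefix + [lab], max(used, lab + 1))

    yield from grow([0], 1)


def hudson_fst(freqs: np.ndarray, n_per_pop: np.ndarray) -> float:
    """Hudson-style F_ST (ratio of averages) over loci and population pairs.

    ``freqs``: (n_pops, n_loci) sample allele frequencies; ``n_per_pop``:
    haploid sample sizes. Numerator per pair/locus: (p1-p2)^2 - p1(1-p1)/(n1-1)
    - p2(1-p2)/(n2-1); denominator: p1(1-p2) + p2(1-p1).
    """
    n_pops = freqs.shape[0]
    num = 0.0
    den = 0.0
    for i, j in itertools.combinations(range(n_pops), 2):
        p1, p2 = freqs[i], freqs[j]
        n1, n2 = n_per_pop[i], n_per_pop[j]
        num += np.sum(
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )
        den += np.sum(p1 * (1 - p2) + p2 * (1 - p1))
    return float(num / den)
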