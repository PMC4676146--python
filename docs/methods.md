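# Methods

## Genotype encoding

A diploid GT string is reduced to the count of its allele tokens that are
present, numeric and non-zero — the Hamming distance between the genotype
and the homozygous-reference genotype. Consequences that are deliberate,
not incidental:

- **Phase is discarded**: `0|1` and `0/1` and `1|0` all encode 1.
- **Alternate-allele identity is discarded**: `1|2` encodes 2, `0|2`
  encodes 1. A multi-allelic site contributes a single feature.
- **Missing tokens (`.`) count as reference** (dosage contribution 0).
  Fully imputed reference panels have no missing calls; for sparser data
  this choice keeps sparsity and biases toward the reference, which is the
  conservative direction for a presence-of-variation encoding.
- **Haploid calls** (`1`) are accepted with dosage in [0, 1].

Variants are indexed sequentially in stream order, preserving genome locus
order; multiple input files are concatenated in caller order. Coordinates
stay 1-based; no coordinate arithmetic is ever done.

## Filtering and genome-wide sampling

Two independent, optional column filters, applied in a fixed order:
**sampling first, then singleton filtering**, so the singleton property
describes the set of variants actually clustered.

- *Singleton filter*: a sparse column's length is the number of carriers,
  so singletons are exactly the length-1 columns. Length-0 columns
  (all-reference sites, which the simulator produces on purpose) carry no
  signal and are dropped by the same pass. The filter is idempotent.
- *Sampling*: each column is retained independently with probability f.
  The decision for a column is u(seed, incoming index) < f with u drawn
  from a counter-based (Philox) stream indexed by the incoming variant
  index, so results cannot depend on how the stream was chunked, and a
  truncated stream reproduces a prefix of the full run. f = 1 short-circuits
  to an exact pass-through.

## k-means

Standard Lloyd iterations over sparse rows with dense centroids:

- distance via ‖x−c‖² = ‖x‖² − 2x·c + ‖c‖² with cached row norms; cost per
  iteration scales with stored entries. The clipped-at-zero expansion
  agrees with densified distances to ≤1e−9 (tested at 100×1000).
- assignment ties break to the lowest centroid index (numpy argmin
  semantics, asserted in tests).
- stop when the maximum per-centroid Euclidean displacement < `tol`
  (default 1e−4) or after `max_iter` (default 100) iterations.
- **Initialisation**: sequential k-means++ (default) or random partition;
  an explicit centroid array is accepted so tests can drive the
  implementation and an independent dense oracle from identical starts.
- **Empty clusters** are reseeded to the point farthest from its own
  centroid, deterministically (sorted by distance, descending). The
  recorded objective trace is the optimal-assignment WCSS before any
  repair; without repairs the trace is provably non-increasing, and the
  suite asserts monotonicity on every fit it runs.
- **Restarts**: `n_restarts` seeded restarts (child seeds spawned from the
  main seed); lowest final WCSS wins. Default 1 for the library function;
  analysis examples and the recovery tests use 3, which removed the
  occasional k-means++ local optimum observed at 1 restart without
  affecting the failure cases that are supposed to fail.

k is a user input — for population structure, the number of annotated
(super-)populations; the tool does not select k.

## Adjusted Rand index

Hubert–Arabie form from the contingency table (see README for the
formula). Degenerate pairs, where max = E (both partitions a single
cluster, or both all singletons — provably the only two cases), return 1.0
when the partitions are identical as set partitions and 0.0 otherwise,
keeping the [−1, 1] range statement true. Samples present in the matrix but
absent from the panel raise an error naming the samples; silent dropping
would corrupt the score.

## Synthetic cohorts

Balding–Nichols: ancestral frequency p ~ U(0.05, 0.95) per site;
population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) (mean p, variance
p(1−p)F); genotype ~ Binomial(2, pop frequency), emitted as `0|0/0|1/1|1`
(phasing fixed arbitrarily — the encoding is phase-blind). Defaults: 4
populations × 100 samples, 2,000 sites, F = 0.2, no missing calls.
F = 0.2 models cleanly separable continental-scale divergence (real
super-population F_ST is roughly 0.05–0.15); F = 0.01 models closely
related groups that should merge. An empirical Hudson-style F_ST estimator
recovers the nominal F to within ±0.03 at 4×50×2,000 in the tests.

What the generator does **not** emulate: linkage disequilibrium,
recombination, realistic site-frequency spectra, admixed individuals. A
green recovery test therefore establishes that the pipeline separates
frequency-level population structure — not that it would resolve admixture
(the hard case in real cohorts, where admixed groups merge with their
closest ancestral population, mirrored here only qualitatively by the
low-F regime). Sites fixed in every population after drift are retained so
the empty-column path is exercised end to end.

## File formats

- VCF 4.x in (plain/gzip), VCF 4.2 out (FORMAT column `GT`), bit-exact
  round trip for generator output. BCF, tabix, INFO/QUAL/FILTER semantics
  are out of scope.
- Matrix: plain-text triplet format (`#genoclust-matrix v1` header, sample
  IDs, n_variants, then `sample_index TAB variant_index TAB dosage` rows),
  bit-exact round trip.
- Model: single JSON object (k, centroids, assignments, objective, trace,
  seed).
- Graph: GEXF 1.2 star topology — one hub node per cluster, one edge per
  sample with weight 1/(1+distance to centroid). Byte-identical for
  identical inputs (no timestamps). All-pairs similarity edges were
  rejected as quadratic and unneeded for hub-shaped cluster pictures.

## Determinism

Every source of randomness flows from an explicit seed (sampling stream,
k-means init and restarts, simulator); identical inputs and seeds produce
byte-identical files throughout the CLI.

## Known limitations

- Lloyd's algorithm finds local optima; use restarts for analysis runs.
- Dosages are taken from GT only; genotype likelihoods (GL/PL) are ignored.
- No LD pruning or frequency standardisation — the clustering operates on
  raw dosages.
- The singleton filter and sampler re-index variants, so column indices in
  a filtered matrix do not map back to loci; keep the unfiltered matrix if
  you need the mapping.
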