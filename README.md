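# genoclust

Population-structure clustering of multi-sample VCF genotype cohorts on a
single machine with bounded memory.

Given thousands of individuals genotyped at up to millions of variant sites,
a recurring task in population and medical genomics is to group individuals
by their genomic profile and compare the grouping to annotated ancestry
labels (e.g. the 1000 Genomes super-populations AFR, AMR, EAS, EUR, SAS).
`genoclust` implements that pipeline end to end:

1. **Stream** VCF files (plain or gzip) record by record — only the GT
   subfield of each sample column is kept, so memory never depends on file
   length.
2. **Encode** each genotype as its *Hamming distance to the reference
   genotype*: a dosage d ∈ {0, 1, 2} with `0|0 → 0`, `0|1 → 1`, `1|1 → 2`
   (phase and alternate-allele identity are irrelevant). Zero dosages are
   never stored; each individual becomes a sparse vector over sequentially
   indexed variants, preserving genome locus order.
3. Optionally **filter singleton variants** (sites carried by exactly one
   individual — in the sparse representation, columns of length one) and
   **subsample variants genome-wide** at a fixed fraction with a seeded,
   order-independent pseudo-random stream.
4. **Cluster** individuals with Lloyd's k-means over the sparse rows
   (dense centroids, distances via ‖x−c‖² = ‖x‖² − 2x·c + ‖c‖², k-means++
   or random-partition seeding, seeded restarts), minimising the
   within-cluster sum of squares (WCSS).
5. **Score** the clustering against a population panel with the
   Hubert–Arabie **adjusted Rand index**,

   ARI = (Σᵢⱼ C(nᵢⱼ,2) − E) / (½[Σᵢ C(aᵢ,2) + Σⱼ C(bⱼ,2)] − E),
   E = Σᵢ C(aᵢ,2) · Σⱼ C(bⱼ,2) / C(n,2),

   where nᵢⱼ is the cluster × label contingency table with margins aᵢ, bⱼ.
   ARI is 1 for identical partitions, ≈0 for independent ones, ≥ −1 always.
6. **Export** the clustering as a Gephi-loadable GEXF graph: one node per
   individual (annotated with predicted cluster and true label) joined to
   its cluster hub, edge weight 1/(1+distance to centroid).

A **Balding–Nichols simulator** generates structured diploid cohorts with
ground-truth labels, so everything is testable offline: per site an
ancestral frequency p is drawn uniformly, each population's frequency comes
from Beta(p(1−F)/F, (1−p)(1−F)/F) — mean p, variance p(1−p)F — and
genotypes are Binomial(2, pop frequency). F is an F_ST-style divergence
knob.

The library is organised as scikit-learn style estimators
(`GenotypeVectorizer`, `SparseKMeans` with `fit`/`predict`/`get_params`)
plus functional wrappers, behind a `genoclust` command-line tool.

## Worked example

Simulate a 4-population cohort (50 individuals per population, 1,000 sites,
F = 0.15), encode it with singleton filtering, cluster with k = 4, score and
export:

```sh
genoclust simulate --pops 4 --samples 50 --variants 1000 --fst 0.15 \
    --seed 42 --out-vcf demo.vcf --out-panel demo.panel
genoclust preprocess --vcf demo.vcf --drop-singletons --out demo.matrix
genoclust cluster --matrix demo.matrix --k 4 --restarts 3 --seed 42 \
    --out demo.model
genoclust evaluate --model demo.model --panel demo.panel \
    --out demo.metrics.json
genoclust export --model demo.model --matrix demo.matrix \
    --panel demo.panel --out demo.gexf
```

Logged output (stderr) and the metrics file:

```
INFO genoclust: variants: 1000 read, 0 dropped by sampling, 2 singleton/empty dropped, 998 retained; samples: 200; stored dosages: 133099
INFO genoclust: k=4 on 200 samples x 998 variants: WCSS 61609.2000 after 4 iterations
INFO genoclust: ARI 1.0000 over 200 samples
INFO genoclust: wrote 204 nodes, 200 edges
```

`demo.metrics.json` records `"ari": 1.0` with the full contingency table —
each of the four clusters contains exactly the 50 individuals of one
population, i.e. at F = 0.15 (continental-scale divergence) the pipeline
recovers the population structure perfectly. At F ≈ 0.01 closely related
populations merge and the ARI drops well below 1 — the analogue of
admixed/low-divergence groups sharing a cluster in real cohorts. The GEXF
file loads directly into Gephi; colour nodes by `true_label` and size by
`cluster` to see where the two partitions disagree.

Every command is deterministic given `--seed`: identical inputs and seeds
give byte-identical outputs.

## Reproducing a real-data run

The pipeline applies unchanged to real 1000 Genomes data (not shipped here;
the genotype VCFs are multi-GB downloads). For chromosome 22, phase 1:
download `ALL.chr22.*.genotypes.vcf.gz` and the
`integrated_call_samples*.panel` file, then

```sh
genoclust preprocess --vcf ALL.chr22...vcf.gz --out chr22.matrix
genoclust cluster --matrix chr22.matrix --k 4 --restarts 5 --seed 0 --out chr22.model
genoclust evaluate --model chr22.model --panel integrated_call_samples.panel --out chr22.json
```

Add `--exclude AMR` to `evaluate` to score only the three well-separated
super-populations; use `--drop-singletons` when preprocessing phase 3.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, by running the package from scratch, the canonical dosage
encodings of the genotype strings `0|1`, `1|1` and `0|0`, and the minimum
adjusted Rand index over an exhaustive enumeration of all pairs of set
partitions of 6 items into at most 3 groups (a direct check of the metric's
lower bound), and writes them as JSON.

See `docs/methods.md` for the model details, defaults, numerical choices
and limitations.
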