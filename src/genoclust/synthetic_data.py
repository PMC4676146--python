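"""Synthetic structured-population cohorts (Balding–Nichols model).

Generates diploid multi-population VCF cohorts with ground-truth labels so
the whole pipeline is testable without real reference data. Per variant, an
ancestral allele frequency ``p`` is drawn uniformly; each population's
frequency is then Beta-distributed with mean ``p`` and variance
``p(1-p) * F`` — the Balding–Nichols drift model, where ``F`` plays the role
of F_ST: small F gives nearly identical populations, large F strongly
diverged ones. Individual genotypes are Binomial(2, population frequency).

What this emulates: population-differentiated allele frequency spectra and
the resulting separability of individuals in dosage space. What it does not:
linkage disequilibrium, recombination, admixed individuals, or realistic
site-frequency spectra — a clustering that succeeds here shows the pipeline
recovers frequency-level structure, nothing finer.

Sites fixed everywhere after drift are retained on purpose: downstream
encoding must cope with all-reference (empty) and uninformative columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .evaluate import PopulationTruth
from .vcf_io import VariantRecord, VcfHeader, write_vcf

__all__ = [
    "SimulationConfig",
    "simulate_records",
    "simulate_cohort",
    "truth_to_panel",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated cohort.

    Defaults mirror a desk-scale stand-in for a multi-super-population
    cohort: 4 populations of 100 individuals, 2,000 biallelic SNPs, F = 0.2
    (strong continental-scale divergence; 1000 Genomes super-populations sit
    roughly in the 0.05-0.15 range, so 0.2 gives cleanly separable clusters
    while 0.01 models closely related groups that should merge).
    """

    n_pops: int = 4
    samples_per_pop: tuple[int, ...] = (100, 100, 100, 100)
    n_variants: int = 2000
    fst: float = 0.2
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0
    chrom_name: str = "1"
    missing_rate: float = 0.0
    pop_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must be in (0, 1), got {self.fst}")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if len(self.samples_per_pop) != self.n_pops:
            raise ValueError(
                f"samples_per_pop has {len(self.samples_per_pop)} entries "
                f"for {self.n_pops} populations"
            )
        if any(c < 1 for c in self.samples_per_pop):
            raise ValueError("every population needs at least one sample")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("ancestral_freq_range must be inside (0, 1)")
        if self.pop_names and len(self.pop_names) != self.n_pops:
            raise ValueError("pop_names length must equal n_pops")

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_pop)

    def population_names(self) -> tuple[str, ...]:
        if self.pop_names:
            return self.pop_names
        return tuple(f"POP{p}" for p in range(self.n_pops))

    def sample_ids(self) -> tuple[str, ...]:
        names = self.population_names()
        ids = []
        for p, count in enumerate(self.samples_per_pop):
            ids.extend(f"{names[p]}_{i:04d}" for i in range(count))
        return tuple(ids)


_GT_BY_DOSAGE = ("0|0", "0|1", "1|1")  # phasing arbitrary, dosage is phase-blind


def simulate_records(
    config: SimulationConfig,
) -> tuple[VcfHeader, Iterator[VariantRecord], PopulationTruth]:
    """Generate the cohort lazily: header, record iterator, truth labels.

    Fully reproducible from ``config.seed``; records stream one variant at a
    time so arbitrarily long cohorts never occupy memory.
    """
    header = VcfHeader(sample_ids=config.sample_ids())
    names = config.population_names()
    truth = PopulationTruth(
        labels={
            sid: names[p]
            for p, count in enumerate(config.samples_per_pop)
            for sid in header.sample_ids[
                sum(config.samples_per_pop[:p]) : sum(config.samples_per_pop[: p + 1])
            ]
        }
    )

    def _records() -> Iterator[VariantRecord]:
        rng = np.random.default_rng(config.seed)
        lo, hi = config.ancestral_freq_range
        F = config.fst
        shape_scale = (1.0 - F) / F
        pop_sizes = np.asarray(config.samples_per_pop)
        for v in range(config.n_variants):
            p_anc = rng.uniform(lo, hi)
            # Beta with mean p and variance p(1-p)F
            pop_freqs = rng.beta(
                p_anc * shape_scale, (1.0 - p_anc) * shape_scale, size=config.n_pops
            )
            dosages = np.concatenate(
                [
                    rng.binomial(2, pop_freqs[p], size=pop_sizes[p])
                    for p in range(config.n_pops)
                ]
            )
            gts = [_GT_BY_DOSAGE[d] for d in dosages]
            if config.missing_rate > 0.0:
                miss = rng.random(len(gts)) < config.missing_rate
                gts = ["./." if m else g for g, m in zip(gts, miss)]
            yield VariantRecord(
                chrom=config.chrom_name,
                pos=v + 1,
                var_id=f"snp{v}",
                ref="A",
                alts=("G",),
                gt_strings=tuple(gts),
            )

    return header, _records(), truth


def simulate_cohort(
    config: SimulationConfig, vcf_dest: str | Path, gzipped: bool | None = None
) -> tuple[Path, PopulationTruth]:
    """Simulate and write the cohort as VCF; returns (path, truth)."""
    header, records, truth = simulate_records(config)
    write_vcf(header, records, vcf_dest, gzipped=gzipped)
    return Path(vcf_dest), truth


def truth_to_panel(truth: PopulationTruth, dest: str | Path) -> int:
    """Write truth labels as a 1000 Genomes style panel TSV; returns rows.

    The label is written to both ``pop`` and ``super_pop`` so either
    granularity reads back identically.
    """
    if not truth.labels:
        raise ValueError("cannot write a panel for empty truth")
    count = 0
    with open(dest, "wt") as out:
        out.write("sample\tpop\tsuper_pop\tgender\n")
        for sample, label in truth.labels.items():
            out.write(f"{sample}\t{label}\t{label}\tunknown\n")
            count += 1
    return count
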