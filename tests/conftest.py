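import io

import pytest

from genoclust.synthetic_data import SimulationConfig, simulate_records
from genoclust.vcf_io import read_vcf

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=22>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
22\t100\trs1\tA\tG\t.\tPASS\t.\tGT:DP\t0|1:12\t0|0:9\t1|1:20
22\t200\t.\tC\tT,G\t50\t.\tAF=0.1\tGT\t0|0\t1|2\t0|0
22\t300\trs3\tG\tA\t.\t.\t.\tGT\t0|0\t0|0\t0|0
"""


@pytest.fixture
def toy_vcf_text() -> str:
    """Three samples, three sites: a mixed site, a multi-allelic singleton
    site, and an all-reference site."""
    return TOY_VCF


@pytest.fixture
def toy_records(toy_vcf_text):
    header, records = read_vcf(io.StringIO(toy_vcf_text))
    return header, list(records)


@pytest.fixture
def small_cohort():
    """In-memory 3-population cohort, strongly diverged, fixed seed."""
    config = SimulationConfig(
        n_pops=3,
        samples_per_pop=(20, 20, 20),
        n_variants=300,
        fst=0.3,
        seed=11,
    )
    header, records, truth = simulate_records(config)
    return config, header, list(records), truth
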