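import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vcbench.vcfio import VariantKey, VariantRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_record(chrom="1", pos=100, ref="C", alts=("T",), qual=60.0, depth=30,
                genotype=(0, 1), effects=(), **kw):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), qual=qual,
        depth=depth, genotype=genotype, effects=tuple(effects), **kw,
    )


def make_key(chrom="1", pos=100, ref="C", alt="T"):
    return VariantKey(chrom, pos, ref, alt)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


SITES_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    "##contig=<ID=2>\n"
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
    '##FILTER=<ID=q10,Description="low qual">\n'
)
FORMAT_LINES = (
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
)


@pytest.fixture
def write_vcf_text(tmp_path):
    """Write a small VCF from raw data lines, independent of vcbench's writer."""

    def _write(lines, samples=(), name="test.vcf"):
        header = SITES_HEADER
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if samples:
            header += FORMAT_LINES
            cols += "\tFORMAT\t" + "\t".join(samples)
        path = tmp_path / name
        body = "".join(line.rstrip("\n") + "\n" for line in lines)
        path.write_text(header + cols + "\n" + body)
        return path

    return _write
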