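import pandas as pd
import pytest

from snpveracity import synthetic
from snpveracity.concordance import ArrayGenotype, NgsCall


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Small synthetic VCF/array/FASTA/truth quadruple plus its config."""
    cfg = synthetic.SyntheticConfig(
        n_sites=400, seed=11, array_missing_fraction=0.05
    )
    out = tmp_path_factory.mktemp("fixtures")
    paths = synthetic.generate_fixture_files(cfg, str(out))
    return cfg, paths


@pytest.fixture(scope="session")
def fixture_truth(fixture_bundle):
    _, paths = fixture_bundle
    return pd.read_csv(
        paths["truth"], sep="\t", dtype={"chrom": str, "sample": str}
    )


def make_call(
    ref="A",
    alts=("G",),
    gt=(0, 1),
    chrom="1",
    pos=100,
    qual=50.0,
    gq=40.0,
    dp=30,
    dp2=10,
    sample="S1",
):
    return NgsCall(
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_alleles=tuple(alts),
        genotype=gt,
        qual=qual,
        gq=gq,
        dp_site=dp,
        dp_sample=dp2,
        sample_id=sample,
    )


def make_array(alleles, chrom="1", pos=100):
    return ArrayGenotype(chrom=chrom, pos=pos, alleles=alleles)
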