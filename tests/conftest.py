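import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pqtlmr.gwas_io import SummaryStats, VariantAssociation

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_variant(
    variant_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.02,
    pvalue=1e-9,
    n=10_000,
    chrom="1",
    pos=1_000_000,
    eaf=0.3,
    **kwargs,
):
    return VariantAssociation(
        variant_id=variant_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
        chrom=chrom,
        pos=pos,
        eaf=eaf,
        **kwargs,
    )


def make_stats(variants, trait_id="trait", trait_type="quantitative", build="GRCh37"):
    stats = SummaryStats(trait_id=trait_id, trait_type=trait_type, genome_build=build)
    for v in variants:
        stats.add(v)
    return stats


@pytest.fixture
def rng():
    return np.random.default_rng(42)
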