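import pytest

from mosaicbench.core import PileupSite, QualityTier, TIER_MAIN


def make_pileup(
    chrom="chr1",
    pos=100,
    ref="A",
    sample="s",
    tier: QualityTier = TIER_MAIN,
    depth=None,
    **allele_counts,
):
    """Pileup builder: allele counts as kwargs; depth defaults to their sum,
    with any shortfall credited to the reference allele."""
    total = sum(allele_counts.values())
    if depth is None:
        depth = total
    elif depth > total:
        allele_counts[ref] = allele_counts.get(ref, 0) + depth - total
    return PileupSite(
        chrom=chrom,
        pos=pos,
        ref=ref,
        sample=sample,
        depth=depth,
        allele_counts=allele_counts,
        tier=tier,
    )


@pytest.fixture
def pileup_factory():
    return make_pileup
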