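import numpy as np
import pytest

from sexscan.genome import GenomeModel
from sexscan.variants import SiteRecord

SEXES_3V3 = ("F", "F", "F", "M", "M", "M")


def make_site(gts, dp=30, gq=90, ad=None, sexes=SEXES_3V3, chrom="chr1",
              pos=100, ref="A", alt="C"):
    """Construct a SiteRecord from compact per-sample genotype codes."""
    n = len(gts)
    gts = np.asarray(gts)
    dp = np.full(n, dp) if np.isscalar(dp) else np.asarray(dp)
    gq = np.full(n, gq) if np.isscalar(gq) else np.asarray(gq)
    if ad is None:
        ad = np.array([(d // 2, d - d // 2) if g == 1
                       else ((d, 0) if g == 0 else (0, d))
                       for g, d in zip(gts, dp)])
    else:
        ad = np.asarray(ad)
    samples = tuple(f"{s}{i + 1}" for i, s in enumerate(sexes))
    return SiteRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                      samples=samples, sexes=tuple(sexes),
                      gt=gts, dp=dp, gq=gq, ad=ad)


@pytest.fixture
def tiny_genome():
    """Two short chromosomes for hand-computable window arithmetic."""
    return GenomeModel((("chrA", 10), ("chrB", 12)))


@pytest.fixture
def small_genome():
    """Ten 50 kb chromosomes: the study karyotype at desk scale."""
    return GenomeModel.default(n_chromosomes=10, length=50_000)
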