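import numpy as np
import pytest

from mutsel import MALine, VariantRecord


def make_record(**kwargs) -> VariantRecord:
    """A record that passes every retention filter unless overridden."""
    defaults = dict(
        chrom="chrI",
        pos=100,
        ref="C",
        alt="T",
        depth_sample=30,
        depth_ancestor=25,
        forward_support=14,
        reverse_support=16,
        quality=900.0,
        genotype_homogeneous=True,
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)


@pytest.fixture
def passing_record() -> VariantRecord:
    return make_record()


def make_line(line_id: str, variants, generations=1000.0, callable_sites=10**7,
              ploidy="haploid") -> MALine:
    return MALine(line_id=line_id, generations=generations,
                  callable_sites=callable_sites, variants=list(variants),
                  ploidy=ploidy)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
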