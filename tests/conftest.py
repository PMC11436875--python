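import numpy as np
import pytest

from crevar.intervals import GenomicInterval
from crevar.pedigree import Individual, Pedigree
from crevar.variants import Genotype, Variant


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trio():
    """Sporadic trio: unaffected parents, affected child."""
    father = Individual("fa", None, None, 1, affected=False)
    mother = Individual("mo", None, None, 2, affected=False)
    child = Individual("ch", "fa", "mo", 1, affected=True)
    return Pedigree("FAM1", {i.individual_id: i for i in (father, mother, child)},
                    disease_group="DRS", subgroup="sporadic-trio/isolated")


def make_variant(chrom="chr1", pos=100, ref="A", alt="T", gts=None, **kw):
    """Variant with clean annotations; gts maps sample -> call string or Genotype."""
    defaults = dict(gnomad_af=0.0, topmed_af=0.0, cohort_af=0.0, gerp=4.0,
                    filter_status="PASS")
    defaults.update(kw)
    genotypes = {}
    for s, g in (gts or {}).items():
        if isinstance(g, Genotype):
            genotypes[s] = g
        else:
            ad = {"hom_ref": (30, 0), "het": (15, 15), "hom_alt": (0, 30),
                  "missing": (0, 0)}[g]
            genotypes[s] = Genotype(g, 60.0, ad)
    return Variant(chrom, pos, ref, alt, genotypes=genotypes, **defaults)


@pytest.fixture
def make_var():
    return make_variant


@pytest.fixture
def iv():
    return lambda c, s, e: GenomicInterval(c, s, e)
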