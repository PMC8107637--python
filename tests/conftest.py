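from __future__ import annotations

import pytest

from founderhap.io import GenotypeCall, VariantSite
from founderhap.phasing import PhasedHaplotype
from founderhap.synthetic_data import paper_shaped_config, simulate_cohort
from founderhap.tables import table1_cohort, table_fixtures

CHROM = "chr17"


def make_site(pos: int, af=None, ref="A", alt="G", **kw) -> VariantSite:
    return VariantSite(chrom=CHROM, pos=pos, ref=ref, alt=alt, population_af=af, **kw)


def make_call(sample: str, site: VariantSite, a, b, **kw) -> GenotypeCall:
    return GenotypeCall(sample=sample, site=site, alleles=(a, b), **kw)


def make_hap(alleles, sites=None, family="FAM", individual="ind") -> PhasedHaplotype:
    if sites is None:
        sites = tuple(1000 * (i + 1) for i in range(len(alleles)))
    return PhasedHaplotype(
        individual=individual,
        family=family,
        sites=tuple(sites),
        alleles=tuple(alleles),
        origin=tuple(
            "unresolved" if a is None else "maternal" for a in alleles
        ),
        chrom=CHROM,
    )


@pytest.fixture(scope="session")
def paper_tables():
    return table_fixtures()


@pytest.fixture(scope="session")
def cohort():
    return table1_cohort()


@pytest.fixture(scope="session")
def sim_paper():
    """One study-shaped simulated cohort, error-free, fixed seed."""
    cfg = paper_shaped_config()
    return cfg, simulate_cohort(cfg, seed=1)
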