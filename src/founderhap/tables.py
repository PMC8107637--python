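"""Packaged cohort tables and a genotype-level cohort built from them.

Two TSVs ship with the package:

* ``table1_genotypes.tsv`` — the cohort's candidate genotypes: 8 families,
  11 distinct alleles with HGVS (NM_024417.4 coding nomenclature),
  segregation, population (gnomAD v3.1) MAF and protein-domain columns;
* ``table2_phenotypes.tsv`` — per-individual phenotype statuses
  (Yes/No/Possible/ND) with onset ages, stored verbatim.

:func:`table1_cohort` additionally lowers the genotype table to VCF-level
objects (variant sites, genotype calls, a pedigree and the whole-gene
deletion call) so that the assembly logic can be exercised end to end.
The genomic *positions* used there are synthetic: the coding HGVS labels
are real, but their chr17 coordinates are placed deterministically inside
the target gene interval because per-variant genomic coordinates are not
part of the table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io import (
    DeletionCall,
    GenomicInterval,
    GenotypeCall,
    Individual,
    Pedigree,
    VariantSite,
)

__all__ = [
    "GENE_SYMBOL",
    "GENE_INTERVAL",
    "DELETION_INTERVAL",
    "INDEX_HGVS",
    "table_fixtures",
    "table1_cohort",
    "Table1Cohort",
]

GENE_SYMBOL = "FDXR"
#: synthetic-but-consistent target gene interval; it contains every coding
#: variant position generated below and lies inside the deletion interval
GENE_INTERVAL = GenomicInterval("chr17", 74_860_000, 74_875_000)
#: the whole-gene deletion as printed (chr17:74818633-74888183del)
DELETION_INTERVAL = GenomicInterval("chr17", 74_818_633, 74_888_183)
INDEX_HGVS = "c.1115C>A"

_HGVS_SNV = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")


def _data_text(name: str) -> str:
    return resources.files("founderhap.data").joinpath(name).read_text()


def table_fixtures() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return the packaged (genotype table, phenotype table) as DataFrames."""
    from io import StringIO

    t1 = pd.read_csv(StringIO(_data_text("table1_genotypes.tsv")), sep="\t")
    t2 = pd.read_csv(StringIO(_data_text("table2_phenotypes.tsv")), sep="\t")
    return t1, t2


def hgvs_position(hgvs_c: str) -> int:
    """Deterministic synthetic genomic position for a coding HGVS label."""
    m = _HGVS_SNV.match(hgvs_c)
    if m is None:
        raise ValueError(f"not a coding SNV HGVS label: {hgvs_c!r}")
    return GENE_INTERVAL.start + 2_000 + int(m.group(1)) * 10


def site_from_hgvs(hgvs_c: str, population_af: float | None, domain: str | None) -> VariantSite:
    m = _HGVS_SNV.match(hgvs_c)
    if m is None:
        raise ValueError(f"not a coding SNV HGVS label: {hgvs_c!r}")
    return VariantSite(
        chrom=GENE_INTERVAL.chrom,
        pos=hgvs_position(hgvs_c),
        ref=m.group(2),
        alt=m.group(3),
        id=hgvs_c,
        population_af=population_af,
        consequence="stop_gain" if "*" in hgvs_c else "missense",
        gene=GENE_SYMBOL,
        domain=domain,
    )


@dataclass
class Table1Cohort:
    """VCF-level rendering of the cohort genotype table (synthetic positions)."""

    sites: list[VariantSite]
    calls: list[GenotypeCall]
    pedigree: Pedigree
    deletions: list[DeletionCall]
    probands: dict[str, list[str]]  # family -> affected individual ids
    sites_by_hgvs: dict[str, VariantSite]


def _het(sample: str, site: VariantSite) -> GenotypeCall:
    return GenotypeCall(sample, site, (0, 1))


def _ref(sample: str, site: VariantSite) -> GenotypeCall:
    return GenotypeCall(sample, site, (0, 0))


def table1_cohort() -> Table1Cohort:
    """Build sites, calls, pedigree and deletion calls for the 8 families.

    Relatives named in the segregation column are genotyped explicitly
    (including their homozygous-reference calls at the family's other
    candidate site); parents recorded as unavailable are absent from the
    pedigree.  The family with the whole-gene deletion carries the index
    variant as an apparently homozygous call whose depths are consistent
    with copy loss.
    """
    t1, _ = table_fixtures()
    by_hgvs: dict[str, VariantSite] = {}
    for row in t1.itertuples(index=False):
        if row.consequence == "whole_gene_deletion":
            continue
        if row.hgvs_c not in by_hgvs:
            af = float(row.gnomad_af)
            by_hgvs[row.hgvs_c] = site_from_hgvs(
                row.hgvs_c, af, row.domain if isinstance(row.domain, str) else None
            )

    individuals: list[Individual] = []
    calls: list[GenotypeCall] = []
    deletions: list[DeletionCall] = []
    probands: dict[str, list[str]] = {}

    def add(ind: Individual) -> str:
        individuals.append(ind)
        return ind.id

    def family_sites(fam: str) -> list[VariantSite]:
        labels = t1.loc[
            (t1.family == fam) & (t1.consequence != "whole_gene_deletion"), "hgvs_c"
        ]
        return [by_hgvs[h] for h in labels]

    # family 1: proband + mother (carries c.577C>T only); father unavailable
    s577, s1115 = by_hgvs["c.577C>T"], by_hgvs["c.1115C>A"]
    mo = add(Individual("family_1-I:2", "family_1", sex=2))
    ch = add(Individual("family_1-II:1", "family_1", mother=mo, sex=1, affected=True))
    probands["family_1"] = [ch]
    calls += [_het(mo, s577), _ref(mo, s1115), _het(ch, s577), _het(ch, s1115)]

    # family 2: two affected sibs + both parents
    s925 = by_hgvs["c.925C>T"]
    fa = add(Individual("family_2-I:1", "family_2", sex=1))
    mo = add(Individual("family_2-I:2", "family_2", sex=2))
    sib1 = add(Individual("family_2-II:1", "family_2", father=fa, mother=mo, sex=1, affected=True))
    sib2 = add(Individual("family_2-II:2", "family_2", father=fa, mother=mo, sex=1, affected=True))
    probands["family_2"] = [sib1, sib2]
    calls += [_het(fa, s925), _ref(fa, s1115), _ref(mo, s925), _het(mo, s1115)]
    for sib in (sib1, sib2):
        calls += [_het(sib, s925), _het(sib, s1115)]

    # family 3: proband + mother (carries c.823C>T only)
    s461, s823 = by_hgvs["c.461C>T"], by_hgvs["c.823C>T"]
    mo = add(Individual("family_3-I:2", "family_3", sex=2))
    ch = add(Individual("family_3-II:1", "family_3", mother=mo, sex=1, affected=True))
    probands["family_3"] = [ch]
    calls += [_ref(mo, s461), _het(mo, s823), _het(ch, s461), _het(ch, s823)]

    # family 4: proband + father (carries c.1279G>C only); mother unavailable
    s1279 = by_hgvs["c.1279G>C"]
    fa = add(Individual("family_4-I:1", "family_4", sex=1))
    ch = add(Individual("family_4-II:1", "family_4", father=fa, sex=1, affected=True))
    probands["family_4"] = [ch]
    calls += [_het(fa, s1279), _ref(fa, s1115), _het(ch, s1115), _het(ch, s1279)]

    # family 5: proband + three genotyped siblings; parents in the pedigree
    # but without DNA.  Sibling II:2 carries p.(Thr205Met) alone, which
    # places the proband's two alleles on different parental haplotypes.
    s614 = by_hgvs["c.614C>T"]
    fa = add(Individual("family_5-I:1", "family_5", sex=1))
    mo = add(Individual("family_5-I:2", "family_5", sex=2))
    sibs = [
        add(Individual(f"family_5-II:{i}", "family_5", father=fa, mother=mo, sex=0))
        for i in (1, 2, 3)
    ]
    ch = add(Individual("family_5-II:4", "family_5", father=fa, mother=mo, sex=2, affected=True))
    probands["family_5"] = [ch]
    calls += [_ref(sibs[0], s614), _ref(sibs[0], s823)]
    calls += [_het(sibs[1], s614), _ref(sibs[1], s823)]
    calls += [_ref(sibs[2], s614), _ref(sibs[2], s823)]
    calls += [_het(ch, s614), _het(ch, s823)]

    # family 6: singleton carrying the index variant hemizygously opposite
    # the whole-gene deletion (apparently homozygous call, depths consistent
    # with a single retained copy)
    ch = add(Individual("family_6-II:1", "family_6", sex=1, affected=True))
    probands["family_6"] = [ch]
    calls.append(GenotypeCall(ch, s1115, (1, 1), depth=28, alt_depth=28))
    deletions.append(
        DeletionCall(sample=ch, interval=DELETION_INTERVAL, copy_number=1, evidence="read_depth")
    )

    # family 7: two affected sibs + mother (carries c.1189G>A only)
    s1189 = by_hgvs["c.1189G>A"]
    mo = add(Individual("family_7-I:2", "family_7", sex=2))
    sib1 = add(Individual("family_7-II:1", "family_7", mother=mo, sex=2, affected=True))
    sib2 = add(Individual("family_7-II:2", "family_7", mother=mo, sex=1, affected=True))
    probands["family_7"] = [sib1, sib2]
    calls += [_ref(mo, s1115), _het(mo, s1189)]
    for sib in (sib1, sib2):
        calls += [_het(sib, s1115), _het(sib, s1189)]

    # family 8: singleton, no relatives; segregation impossible
    s724, s916 = by_hgvs["c.724C>T"], by_hgvs["c.916C>T"]
    ch = add(Individual("family_8-II:1", "family_8", sex=2, affected=True))
    probands["family_8"] = [ch]
    calls += [_het(ch, s724), _het(ch, s916)]

    sites = sorted(by_hgvs.values(), key=lambda s: s.pos)
    return Table1Cohort(
        sites=sites,
        calls=calls,
        pedigree=Pedigree(individuals),
        deletions=deletions,
        probands=probands,
        sites_by_hgvs=by_hgvs,
    )
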