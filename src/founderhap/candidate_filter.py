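"""Multistep rare-variant filtering and biallelic genotype assembly.

Recessive candidate discovery proceeds in two steps:

1. :func:`filter_rare` keeps protein-altering variants that are rare in the
   reference population (below a configurable MAF cutoff; unknown
   frequencies pass, since genuinely novel alleles are reported with
   frequency 0 or absent) and not explained by a virtual panel of known
   disease genes.
2. :func:`assemble_biallelic` combines the surviving per-individual calls
   into candidate biallelic genotypes: homozygous alternates, compound
   heterozygotes whose trans configuration is supported by segregation, and
   heterozygous variants rendered hemizygous by a deletion of the other
   allele.

Cis/trans assignment is strictly genotype + pedigree based (plus deletion
anchoring); no read-backed phasing is attempted.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .io import (
    DeletionCall,
    GenomicInterval,
    GenotypeCall,
    Individual,
    Pedigree,
    VariantSite,
)
from .phasing import MATERNAL, PATERNAL, resolve_trio_site

__all__ = [
    "FilterConfig",
    "BiallelicGenotype",
    "AssemblyResult",
    "HOM_ALT",
    "COMPOUND_HET_TRANS",
    "COMPOUND_HET_UNRESOLVED",
    "HET_PLUS_DELETION_HEMIZYGOUS",
    "CIS_EXCLUDED",
    "DEFAULT_PROTEIN_ALTERING",
    "filter_rare",
    "assemble_biallelic",
]

HOM_ALT = "hom_alt"
COMPOUND_HET_TRANS = "compound_het_trans"
COMPOUND_HET_UNRESOLVED = "compound_het_unresolved"
HET_PLUS_DELETION_HEMIZYGOUS = "het_plus_deletion_hemizygous"
CIS_EXCLUDED = "cis_excluded"

#: consequence classes counted as protein altering by default.  The set is a
#: package decision: it covers the canonical coding/splice-disrupting classes
#: and deliberately leaves out synonymous and deep-intronic labels.
DEFAULT_PROTEIN_ALTERING = frozenset(
    {
        "missense",
        "stop_gain",
        "frameshift",
        "splice_donor",
        "splice_acceptor",
        "inframe_indel",
        "start_lost",
        "stop_lost",
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and annotations driving the rare-variant filter.

    ``maf_rare`` (default 0.001) is the genome-wide rarity cutoff;
    ``maf_rare_exome`` (default 0.003) the looser cutoff used for
    exome-sequenced input.  ``panel_genes`` are excluded as already-known
    explanations ("virtual gene panel").
    """

    maf_rare: float = 0.001
    maf_rare_exome: float = 0.003
    protein_altering_classes: frozenset[str] = DEFAULT_PROTEIN_ALTERING
    panel_genes: frozenset[str] = frozenset()
    target_gene: Optional[str] = None
    target_interval: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_rare <= self.maf_rare_exome < 1.0):
            raise ValueError(
                "thresholds must satisfy 0 < maf_rare <= maf_rare_exome < 1, "
                f"got {self.maf_rare} and {self.maf_rare_exome}"
            )


def filter_rare(
    sites: Sequence[VariantSite],
    cfg: FilterConfig,
    threshold: Optional[float] = None,
) -> list[VariantSite]:
    """Keep rare, protein-altering variants outside the exclusion panel.

    A site passes when its consequence is a protein-altering class, its
    population AF is unknown or strictly below ``threshold`` (default
    ``cfg.maf_rare``), and its gene is not on the panel.  Input order is
    preserved and the result is a subset of the input; filtering is
    idempotent.
    """
    thr = cfg.maf_rare if threshold is None else threshold
    out = []
    for site in sites:
        if site.consequence not in cfg.protein_altering_classes:
            continue
        if site.population_af is not None and site.population_af >= thr:
            continue
        if site.gene is not None and site.gene in cfg.panel_genes:
            continue
        out.append(site)
    return out


AlleleLike = Union[VariantSite, DeletionCall]


@dataclass
class BiallelicGenotype:
    """A candidate biallelic genotype configuration for one individual.

    ``segregation_evidence`` records per-relative carrier status
    (``carrier`` / ``non_carrier`` / ``unavailable``); ``evidence_grade``
    summarises how the configuration was established: ``parental`` (both
    origins forced), ``parental_supported`` (one allele excluded from one
    parent, the other carried by the other parent), ``sibling`` (a sibling
    carries exactly one allele of the pair), ``homozygous``, ``deletion``,
    or ``unavailable``.
    """

    individual: str
    family: str
    allele_a: AlleleLike
    allele_b: AlleleLike
    configuration: str
    segregation_evidence: dict[str, str] = field(default_factory=dict)
    evidence_grade: str = "unavailable"
    flags: list[str] = field(default_factory=list)


@dataclass
class AssemblyResult:
    candidates: list[BiallelicGenotype]
    excluded: list[BiallelicGenotype]


def _call_for(calls_by_key, sample: str, site: VariantSite) -> Optional[GenotypeCall]:
    return calls_by_key.get((sample, site.key))


def _carrier_status(calls_by_key, sample_id: Optional[str], site: VariantSite) -> str:
    if sample_id is None:
        return "unavailable"
    call = calls_by_key.get((sample_id, site.key))
    if call is None or call.is_missing:
        return "unavailable"
    return "carrier" if call.has_alt else "non_carrier"


def _depth_contradicts_copy_loss(call: GenotypeCall, min_support: int = 3) -> bool:
    """True when AD shows solid support for both alleles at a deleted site."""
    if call.depth is None or call.alt_depth is None:
        return False
    ref_depth = call.depth - call.alt_depth
    return ref_depth >= min_support and call.alt_depth >= min_support


def assemble_biallelic(
    individual: Individual,
    calls: Sequence[GenotypeCall],
    deletions: Sequence[DeletionCall],
    pedigree: Pedigree,
) -> AssemblyResult:
    """Assemble candidate biallelic genotypes for one affected individual.

    ``calls`` should already be restricted to candidate sites in one gene.
    Emits ``hom_alt`` for homozygous candidates, ``het_plus_deletion_hemizygous``
    when a het or apparently-hom SNV lies inside a deletion carried by the
    same sample (the diploid GT string is not trusted at such sites, and a
    warning is raised when read depths contradict copy loss), and classifies
    het pairs as trans, cis-excluded or unresolved from pedigree evidence.
    """
    calls_by_key = {(c.sample, c.site.key): c for c in calls}
    mine = [c for c in calls if c.sample == individual.id and c.has_alt]
    my_dels = [d for d in deletions if d.sample == individual.id]

    father = pedigree.father_of(individual.id) if individual.id in pedigree else None
    mother = pedigree.mother_of(individual.id) if individual.id in pedigree else None
    father_id = father.id if father is not None else None
    mother_id = mother.id if mother is not None else None
    has_parent_data = any(
        key[0] in (father_id, mother_id) for key in calls_by_key
    )
    siblings = (
        pedigree.full_siblings_of(individual.id) if individual.id in pedigree else []
    )

    candidates: list[BiallelicGenotype] = []
    excluded: list[BiallelicGenotype] = []

    def seg_evidence(*sites: VariantSite) -> dict[str, str]:
        ev: dict[str, str] = {}
        for site in sites:
            label = str(site)
            ev[f"father:{label}"] = _carrier_status(calls_by_key, father_id, site)
            ev[f"mother:{label}"] = _carrier_status(calls_by_key, mother_id, site)
        return ev

    # hemizygous candidates: any carried SNV inside this sample's deletion
    hemi_sites: set[tuple] = set()
    for deletion in my_dels:
        for call in mine:
            if deletion.interval.contains(call.site.chrom, call.site.pos):
                hemi_sites.add(call.site.key)
                if _depth_contradicts_copy_loss(call):
                    warnings.warn(
                        f"read depths at {call.site} in {individual.id} support "
                        "both alleles, contradicting copy loss over the "
                        "deletion; hemizygous reclassification may be wrong",
                        stacklevel=2,
                    )
                candidates.append(
                    BiallelicGenotype(
                        individual=individual.id,
                        family=individual.family,
                        allele_a=call.site,
                        allele_b=deletion,
                        configuration=HET_PLUS_DELETION_HEMIZYGOUS,
                        segregation_evidence=seg_evidence(call.site),
                        evidence_grade="deletion",
                    )
                )

    remaining = [c for c in mine if c.site.key not in hemi_sites]
    homs = [c for c in remaining if c.is_hom_alt]
    hets = [c for c in remaining if c.is_het]

    for call in homs:
        ev = seg_evidence(call.site)
        grade = "homozygous" if has_parent_data else "unavailable"
        candidates.append(
            BiallelicGenotype(
                individual=individual.id,
                family=individual.family,
                allele_a=call.site,
                allele_b=call.site,
                configuration=HOM_ALT,
                segregation_evidence=ev,
                evidence_grade=grade,
            )
        )

    for call_a, call_b in itertools.combinations(hets, 2):
        genotype = _classify_het_pair(
            individual,
            call_a,
            call_b,
            calls_by_key,
            father_id,
            mother_id,
            siblings,
            seg_evidence,
        )
        if genotype.configuration == CIS_EXCLUDED:
            excluded.append(genotype)
        else:
            candidates.append(genotype)
    return AssemblyResult(candidates=candidates, excluded=excluded)


def _forced_origin(
    child_call: GenotypeCall,
    calls_by_key,
    father_id: Optional[str],
    mother_id: Optional[str],
) -> Optional[str]:
    """Parental origin of the alt allele when Mendelian logic forces it."""
    phase = resolve_trio_site(
        child_call,
        calls_by_key.get((father_id, child_call.site.key)) if father_id else None,
        calls_by_key.get((mother_id, child_call.site.key)) if mother_id else None,
    )
    if phase.status == "resolved":
        return PATERNAL if phase.paternal == 1 else MATERNAL
    return None


def _classify_het_pair(
    individual: Individual,
    call_a: GenotypeCall,
    call_b: GenotypeCall,
    calls_by_key,
    father_id: Optional[str],
    mother_id: Optional[str],
    siblings: Sequence[Individual],
    seg_evidence,
) -> BiallelicGenotype:
    site_a, site_b = call_a.site, call_b.site
    ev = seg_evidence(site_a, site_b)
    flags: list[str] = []

    origin_a = _forced_origin(call_a, calls_by_key, father_id, mother_id)
    origin_b = _forced_origin(call_b, calls_by_key, father_id, mother_id)

    def make(config: str, grade: str) -> BiallelicGenotype:
        return BiallelicGenotype(
            individual=individual.id,
            family=individual.family,
            allele_a=site_a,
            allele_b=site_b,
            configuration=config,
            segregation_evidence=ev,
            evidence_grade=grade,
            flags=flags,
        )

    if origin_a is not None and origin_b is not None:
        if origin_a != origin_b:
            return make(COMPOUND_HET_TRANS, "parental")
        return make(CIS_EXCLUDED, "parental")

    other = {PATERNAL: mother_id, MATERNAL: father_id}
    if origin_a is not None:
        if _carrier_status(calls_by_key, other[origin_a], site_b) == "carrier":
            # b is excluded from the parent transmitting a and carried by the
            # other parent: the parsimonious configuration is trans
            return make(COMPOUND_HET_TRANS, "parental_supported")
    if origin_b is not None:
        if _carrier_status(calls_by_key, other[origin_b], site_a) == "carrier":
            return make(COMPOUND_HET_TRANS, "parental_supported")

    for parent_id in (father_id, mother_id):
        if parent_id is None:
            continue
        status_a = _carrier_status(calls_by_key, parent_id, site_a)
        status_b = _carrier_status(calls_by_key, parent_id, site_b)
        if status_a == "carrier" and status_b == "carrier":
            flags.append("single_parent_carries_both")
            return make(CIS_EXCLUDED, "parental")

    for sib in siblings:
        status_a = _carrier_status(calls_by_key, sib.id, site_a)
        status_b = _carrier_status(calls_by_key, sib.id, site_b)
        ev[f"sibling {sib.id}:{site_a}"] = status_a
        ev[f"sibling {sib.id}:{site_b}"] = status_b
        if {status_a, status_b} == {"carrier", "non_carrier"}:
            # a sibling carrying exactly one allele of the pair places the two
            # alleles on different parental haplotypes
            return make(COMPOUND_HET_TRANS, "sibling")

    has_any_relative_data = any(
        v != "unavailable" for v in ev.values()
    )
    grade = "uninformative" if has_any_relative_data else "unavailable"
    return make(COMPOUND_HET_UNRESOLVED, grade)
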