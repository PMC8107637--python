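"""Local haplotype phasing of an index variant by segregation and deletion anchoring.

Given genotypes in a window around a target gene, this module

1. selects *informative* SNVs — rare enough (population AF below a cutoff,
   default 0.1) that sharing them across chromosomes is evidence of common
   descent rather than chance;
2. assigns each index-variant carrier's local haplotype, i.e. the allele the
   index-carrying chromosome bears at each informative site, using
   deterministic Mendelian trio logic, homozygosity, or hemizygosity over a
   whole-gene deletion (every variant observed inside a heterozygous
   deletion must lie on the single retained chromosome — the one carrying
   the index variant when the deletion is in trans).

There is no statistical phasing: no LD model, no reference panel and no
read-backed evidence.  Sites that cannot be resolved are carried as
wildcards rather than dropped, so downstream core detection can treat them
as non-breaking but still report them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io import (
    Allele,
    DeletionCall,
    FreqKey,
    GenomicInterval,
    GenotypeCall,
    Pedigree,
    VariantSite,
)

__all__ = [
    "PhaseConfig",
    "PhasedHaplotype",
    "SitePhase",
    "AnchorError",
    "PATERNAL",
    "MATERNAL",
    "HOMOZYGOUS",
    "HEMIZYGOUS_ANCHOR",
    "UNRESOLVED",
    "MENDEL_CONFLICT",
    "select_informative",
    "resolve_trio_site",
    "phase_by_segregation",
    "anchor_hemizygous",
    "build_carrier_haplotypes",
]

PATERNAL = "paternal"
MATERNAL = "maternal"
HOMOZYGOUS = "homozygous"
HEMIZYGOUS_ANCHOR = "hemizygous_anchor"
UNRESOLVED = "unresolved"
MENDEL_CONFLICT = "mendel_conflict"


class AnchorError(ValueError):
    """Hemizygous anchoring was requested in a configuration it cannot support."""


@dataclass(frozen=True)
class PhaseConfig:
    """Parameters of the phasing window.

    ``window_bp`` is applied up- and downstream of the target gene interval
    (default 150 kb each side).  ``maf_informative`` is the population-AF
    cutoff below which an SNV counts as informative for descent (default 0.1).
    """

    window_bp: int = 150_000
    maf_informative: float = 0.1

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError(f"window_bp must be positive, got {self.window_bp}")
        if not (0.0 < self.maf_informative < 1.0):
            raise ValueError(
                f"maf_informative must lie in (0, 1), got {self.maf_informative}"
            )


@dataclass
class PhasedHaplotype:
    """The allele vector of one index-carrying chromosome.

    ``sites`` are the informative site positions (strictly increasing);
    ``alleles`` holds the allele on the index-carrying chromosome at each
    site (0 ref, 1 alt, ``None`` unresolved) and ``origin`` records how each
    entry was resolved (paternal/maternal segregation, homozygosity,
    hemizygous anchoring, or unresolved).
    """

    individual: str
    family: str
    sites: tuple[int, ...]
    alleles: tuple[Allele, ...]
    origin: tuple[str, ...]
    carries_index: bool = True
    chrom: str = "chr?"
    site_ids: Optional[tuple[Optional[str], ...]] = None
    flags: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.sites) == len(self.alleles) == len(self.origin)):
            raise ValueError("sites, alleles and origin must have equal length")
        if any(b <= a for a, b in zip(self.sites, self.sites[1:])):
            raise ValueError("sites must be strictly increasing by position")

    @property
    def n_resolved(self) -> int:
        return sum(a is not None for a in self.alleles)


def select_informative(
    sites: Sequence[VariantSite],
    freq: Mapping[FreqKey, float],
    cfg: PhaseConfig,
    gene: GenomicInterval,
    index_site: VariantSite,
) -> list[VariantSite]:
    """Select position-sorted informative SNVs in the window around ``gene``.

    Retains SNVs with a *known* population AF below ``cfg.maf_informative``
    lying within ``gene`` extended by ``cfg.window_bp`` on each side.  The
    index variant is always included regardless of its frequency.
    """
    lo = max(1, gene.start - cfg.window_bp)
    hi = gene.end + cfg.window_bp
    chosen: dict[tuple, VariantSite] = {}
    for site in sites:
        if site.chrom != gene.chrom or not (lo <= site.pos <= hi):
            continue
        if site.key == index_site.key:
            chosen[site.key] = site
            continue
        af = freq.get(site.key, site.population_af)
        if af is not None and af < cfg.maf_informative:
            chosen[site.key] = site
    if index_site.key not in chosen:
        chosen[index_site.key] = index_site
    result = sorted(chosen.values(), key=lambda s: s.pos)
    if len(result) <= 1:
        warnings.warn(
            "no informative SNVs besides the index variant; the shared core "
            "will span only the index site",
            stacklevel=2,
        )
    return result


@dataclass(frozen=True)
class SitePhase:
    """Per-site outcome of trio phasing.

    ``paternal``/``maternal`` hold the child's alleles assigned to each
    parental chromosome when the assignment is known; both are ``None`` when
    the site is unresolved, in conflict or missing.
    """

    pos: int
    paternal: Allele
    maternal: Allele
    status: str  # 'resolved' | 'homozygous' | 'unresolved' | 'mendel_conflict' | 'missing'


def _parent_can_transmit(parent: Optional[GenotypeCall], allele: int) -> bool:
    """Whether a parent genotype is compatible with transmitting ``allele``.

    An absent or (partially) missing parent genotype is permissive.
    """
    if parent is None or parent.is_missing:
        return True
    if None in parent.alleles:
        return True
    return allele in parent.alleles


def resolve_trio_site(
    child: Optional[GenotypeCall],
    father: Optional[GenotypeCall],
    mother: Optional[GenotypeCall],
) -> SitePhase:
    """Deterministic Mendelian phase resolution at a single site.

    The child's two alleles are assigned to paternal/maternal origin whenever
    Mendelian logic forces it.  A heterozygous child with both orderings
    compatible (e.g. an all-het trio, or a needed parent unavailable) is
    unresolved; an ordering incompatible with both parents is a Mendelian
    conflict and the site is excluded from the haplotype.
    """
    if child is None or child.is_missing or None in child.alleles:
        pos = child.site.pos if child is not None else -1
        return SitePhase(pos, None, None, "missing")
    a, b = child.alleles
    pos = child.site.pos
    if a == b:
        # homozygosity resolves the allele on every chromosome
        ok = _parent_can_transmit(father, a) and _parent_can_transmit(mother, a)
        if not ok:
            return SitePhase(pos, None, None, MENDEL_CONFLICT)
        return SitePhase(pos, a, a, HOMOZYGOUS)
    consistent = [
        (p, m)
        for (p, m) in ((a, b), (b, a))
        if _parent_can_transmit(father, p) and _parent_can_transmit(mother, m)
    ]
    if not consistent:
        return SitePhase(pos, None, None, MENDEL_CONFLICT)
    if len(consistent) == 1:
        p, m = consistent[0]
        return SitePhase(pos, p, m, "resolved")
    return SitePhase(pos, None, None, UNRESOLVED)


def _index_calls(calls: Iterable[GenotypeCall]) -> dict[tuple, GenotypeCall]:
    return {c.site.key: c for c in calls}


def phase_by_segregation(
    child_calls: Sequence[GenotypeCall],
    father_calls: Optional[Sequence[GenotypeCall]],
    mother_calls: Optional[Sequence[GenotypeCall]],
    sites: Sequence[VariantSite],
) -> list[SitePhase]:
    """Apply :func:`resolve_trio_site` over an informative site list."""
    child_by_key = _index_calls(child_calls)
    father_by_key = _index_calls(father_calls) if father_calls is not None else {}
    mother_by_key = _index_calls(mother_calls) if mother_calls is not None else {}
    out = []
    for site in sites:
        phase = resolve_trio_site(
            child_by_key.get(site.key),
            father_by_key.get(site.key),
            mother_by_key.get(site.key),
        )
        if phase.pos == -1:
            phase = SitePhase(site.pos, None, None, "missing")
        out.append(phase)
    return out


def anchor_hemizygous(
    sample_calls: Sequence[GenotypeCall],
    deletion: DeletionCall,
    sites: Sequence[VariantSite],
    index_site: VariantSite,
    segregation: Optional[Sequence[SitePhase]] = None,
    index_origin: Optional[str] = None,
    individual: str = "",
    family: str = "",
) -> PhasedHaplotype:
    """Build the retained-chromosome haplotype of a hemizygous index carrier.

    Every variant call at a site inside the deletion interval comes from the
    single retained chromosome — the one carrying the index variant when the
    deletion lies in trans — so its (non-missing) allele is assigned with
    origin ``hemizygous_anchor`` regardless of the diploid GT string.  Sites
    outside the deletion fall back to segregation phases (when supplied) or
    homozygosity, and are otherwise unresolved.
    """
    if not deletion.interval.contains(index_site.chrom, index_site.pos):
        raise AnchorError(
            f"index variant {index_site} lies outside the deletion interval "
            f"{deletion.interval}; hemizygous anchoring is only valid when the "
            "deletion removes the index locus on the trans allele"
        )
    calls_by_key = _index_calls(sample_calls)
    if index_site.key not in calls_by_key or not calls_by_key[index_site.key].has_alt:
        raise AnchorError(
            f"sample {individual or deletion.sample!r} does not carry the index "
            f"variant {index_site}; nothing to anchor"
        )
    seg_by_pos = {p.pos: p for p in segregation} if segregation is not None else {}
    alleles: list[Allele] = []
    origins: list[str] = []
    for site in sites:
        call = calls_by_key.get(site.key)
        if deletion.interval.contains(site.chrom, site.pos):
            if call is None or call.is_missing:
                alleles.append(None)
                origins.append(UNRESOLVED)
            else:
                alleles.append(1 if call.has_alt else 0)
                origins.append(HEMIZYGOUS_ANCHOR)
        else:
            allele, origin = _allele_from_segregation(
                seg_by_pos.get(site.pos), index_origin, call
            )
            alleles.append(allele)
            origins.append(origin)
    return PhasedHaplotype(
        individual=individual or deletion.sample,
        family=family,
        sites=tuple(s.pos for s in sites),
        alleles=tuple(alleles),
        origin=tuple(origins),
        carries_index=True,
        chrom=sites[0].chrom if sites else deletion.interval.chrom,
        site_ids=tuple(s.id for s in sites),
    )


def _allele_from_segregation(
    phase: Optional[SitePhase],
    index_origin: Optional[str],
    call: Optional[GenotypeCall],
) -> tuple[Allele, str]:
    """Allele on the index-carrying chromosome from one site's evidence."""
    if phase is not None:
        if phase.status == HOMOZYGOUS:
            return phase.paternal, HOMOZYGOUS
        if phase.status == "resolved" and index_origin in (PATERNAL, MATERNAL):
            allele = phase.paternal if index_origin == PATERNAL else phase.maternal
            return allele, index_origin
        if phase.status == MENDEL_CONFLICT:
            return None, MENDEL_CONFLICT
        return None, UNRESOLVED
    # no pedigree evidence at all: homozygosity still resolves the site
    if call is not None and not call.is_missing and call.alleles[0] == call.alleles[1]:
        return call.alleles[0], HOMOZYGOUS
    return None, UNRESOLVED


def _haplotype_from_trio(
    individual: str,
    family: str,
    sites: Sequence[VariantSite],
    index_site: VariantSite,
    child_calls: Sequence[GenotypeCall],
    father_calls: Optional[Sequence[GenotypeCall]],
    mother_calls: Optional[Sequence[GenotypeCall]],
) -> tuple[PhasedHaplotype, Optional[str]]:
    """One carrier's haplotype from segregation; returns (haplotype, index origin)."""
    phases = phase_by_segregation(child_calls, father_calls, mother_calls, sites)
    by_pos = {p.pos: p for p in phases}
    index_phase = by_pos.get(index_site.pos)
    index_origin: Optional[str] = None
    if index_phase is not None and index_phase.status == "resolved":
        index_origin = PATERNAL if index_phase.paternal == 1 else MATERNAL
    elif index_phase is not None and index_phase.status == HOMOZYGOUS:
        index_origin = HOMOZYGOUS
    calls_by_key = _index_calls(child_calls)
    calls_by_pos = {c.site.pos: c for c in calls_by_key.values()}
    alleles: list[Allele] = []
    origins: list[str] = []
    flags: dict[int, str] = {}
    for site in sites:
        phase = by_pos.get(site.pos)
        origin_for_lookup = index_origin if index_origin in (PATERNAL, MATERNAL) else None
        allele, origin = _allele_from_segregation(
            phase, origin_for_lookup, calls_by_pos.get(site.pos)
        )
        if origin == MENDEL_CONFLICT:
            flags[site.pos] = MENDEL_CONFLICT
            allele, origin = None, UNRESOLVED
        if site.pos == index_site.pos and allele is None:
            # the haplotype is defined as the index-carrying chromosome, so
            # its own site carries alt even when segregation cannot phase it
            allele = 1
        alleles.append(allele)
        origins.append(origin)
    hap = PhasedHaplotype(
        individual=individual,
        family=family,
        sites=tuple(s.pos for s in sites),
        alleles=tuple(alleles),
        origin=tuple(origins),
        carries_index=True,
        chrom=sites[0].chrom if sites else "chr?",
        site_ids=tuple(s.id for s in sites),
        flags=flags,
    )
    return hap, index_origin


def _merge_sib_haplotypes(haps: list[PhasedHaplotype]) -> PhasedHaplotype:
    """Merge haplotypes of siblings sharing one transmitted chromosome.

    Resolved alleles are combined site-wise; a resolved disagreement (only
    possible through genotyping error) reverts the site to a flagged
    wildcard.
    """
    base = haps[0]
    alleles = list(base.alleles)
    origins = list(base.origin)
    flags = dict(base.flags)
    for other in haps[1:]:
        for i, pos in enumerate(base.sites):
            a, b = alleles[i], other.alleles[i]
            if a is None and b is not None:
                alleles[i], origins[i] = b, other.origin[i]
            elif a is not None and b is not None and a != b:
                alleles[i], origins[i] = None, UNRESOLVED
                flags[pos] = "sib_discordant"
        flags.update(other.flags)
    return PhasedHaplotype(
        individual="+".join(h.individual for h in haps),
        family=base.family,
        sites=base.sites,
        alleles=tuple(alleles),
        origin=tuple(origins),
        carries_index=True,
        chrom=base.chrom,
        site_ids=base.site_ids,
        flags=flags,
    )


def build_carrier_haplotypes(
    sites: Sequence[VariantSite],
    calls: Sequence[GenotypeCall],
    pedigree: Pedigree,
    deletions: Sequence[DeletionCall],
    index_site: VariantSite,
) -> list[PhasedHaplotype]:
    """One :class:`PhasedHaplotype` per independent index-carrying chromosome.

    Affected carriers are phased per family: hemizygous carriers (an
    overlapping deletion call spanning the index locus) are anchored;
    others use trio segregation.  Affected siblings whose index allele has
    the same parental origin share one transmitted chromosome and contribute
    a single merged haplotype; siblings with differing (or undetermined)
    origins are kept separate.  A family with no resolvable sites is
    retained as an all-unresolved haplotype with a warning.
    """
    calls_by_sample: dict[str, list[GenotypeCall]] = {}
    site_keys = {s.key for s in sites}
    for call in calls:
        if call.site.key in site_keys:
            calls_by_sample.setdefault(call.sample, []).append(call)
    dels_by_sample: dict[str, list[DeletionCall]] = {}
    for d in deletions:
        dels_by_sample.setdefault(d.sample, []).append(d)

    def carries_index(sample: str) -> bool:
        for c in calls_by_sample.get(sample, []):
            if c.site.key == index_site.key and c.has_alt:
                return True
        return False

    haplotypes: list[PhasedHaplotype] = []
    for family_id in pedigree.families():
        members = pedigree.family(family_id)
        carriers = [m for m in members if m.affected and carries_index(m.id)]
        if not carriers:
            continue
        by_origin: dict[str, list[PhasedHaplotype]] = {}
        unkeyed: list[PhasedHaplotype] = []
        for ind in carriers:
            my_calls = calls_by_sample.get(ind.id, [])
            anchor_del = next(
                (
                    d
                    for d in dels_by_sample.get(ind.id, [])
                    if d.interval.contains(index_site.chrom, index_site.pos)
                ),
                None,
            )
            if anchor_del is not None:
                father = pedigree.father_of(ind.id)
                mother = pedigree.mother_of(ind.id)
                seg = None
                if father is not None or mother is not None:
                    seg = phase_by_segregation(
                        my_calls,
                        calls_by_sample.get(father.id) if father else None,
                        calls_by_sample.get(mother.id) if mother else None,
                        sites,
                    )
                hap = anchor_hemizygous(
                    my_calls,
                    anchor_del,
                    sites,
                    index_site,
                    segregation=seg,
                    individual=ind.id,
                    family=family_id,
                )
                unkeyed.append(hap)
                continue
            father = pedigree.father_of(ind.id)
            mother = pedigree.mother_of(ind.id)
            hap, origin = _haplotype_from_trio(
                ind.id,
                family_id,
                sites,
                index_site,
                my_calls,
                calls_by_sample.get(father.id) if father else None,
                calls_by_sample.get(mother.id) if mother else None,
            )
            if origin in (PATERNAL, MATERNAL):
                by_origin.setdefault(origin, []).append(hap)
            else:
                unkeyed.append(hap)
        for origin, group in by_origin.items():
            # one haplotype per transmitting lineage, not per individual
            haplotypes.append(group[0] if len(group) == 1 else _merge_sib_haplotypes(group))
        haplotypes.extend(unkeyed)
    for hap in haplotypes:
        if hap.n_resolved == 0:
            warnings.warn(
                f"haplotype for {hap.individual} (family {hap.family}) has no "
                "resolvable sites; retained as all-unresolved",
                stacklevel=2,
            )
    return haplotypes
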