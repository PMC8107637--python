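"""Shared ancestral core detection, breakpoint localization and singleton interrogation.

Carrier haplotypes (one per independent index-carrying chromosome) are
intersected to find the maximal contiguous run of informative sites,
containing the index variant, at which every haplotype carries the same
resolved allele or a wildcard.  The first resolved discordance on each side
ends the run; a column where every haplotype is a wildcard contributes no
evidence and never terminates the core, but is reported as unresolved
support.  Core boundaries are reported at the outermost *concordant*
informative sites (marker-to-marker, the convention used when a shared
haplotype is tabulated rsID-to-rsID), and the span between two boundary
point coordinates is their coordinate difference.

Per family, the side of the nearest resolved discordance relative to the
core gives the recombination breakpoint side: ``centromeric`` (lower
coordinate) or ``telomeric`` (higher coordinate).

Singletons that cannot be phased are checked by *direct interrogation*:
the unphased genotype is tested for presence of the consensus allele at
every core-defining site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io import GenomicInterval, GenotypeCall, VariantSite
from .phasing import PhasedHaplotype

__all__ = [
    "Breakpoint",
    "CoreResult",
    "SingletonReport",
    "shared_core",
    "span_kb",
    "interrogate_singleton",
    "CENTROMERIC",
    "TELOMERIC",
]

CENTROMERIC = "centromeric"
TELOMERIC = "telomeric"


@dataclass(frozen=True)
class Breakpoint:
    """Per-family recombination evidence relative to the core."""

    side: str  # 'centromeric' | 'telomeric' | 'none'
    first_discordant_pos: Optional[int] = None


@dataclass
class CoreResult:
    """The maximal shared interval across carrier haplotypes."""

    core: GenomicInterval
    boundary_sites: tuple[Optional[str], Optional[str]]
    consensus: dict[int, int]  # position -> consensus allele over core columns
    unresolved_sites: list[int]  # wildcard-only core columns (no evidence)
    per_family_breakpoints: dict[str, Breakpoint]
    discordant_sites: list[int]
    n_haplotypes: int

    @property
    def span_bp(self) -> int:
        return self.core.span_bp


def span_kb(core: GenomicInterval) -> int:
    """Span between the two boundary coordinates in whole kb (floor)."""
    return core.span_bp // 1000


def _column_status(haplotypes: Sequence[PhasedHaplotype], col: int) -> tuple[str, Optional[int]]:
    """Classify one site column: ('concordant', allele) | ('wildcard', None) | ('discordant', None)."""
    resolved = {h.alleles[col] for h in haplotypes if h.alleles[col] is not None}
    if not resolved:
        return "wildcard", None
    if len(resolved) == 1:
        return "concordant", next(iter(resolved))
    return "discordant", None


def _modal_allele(haplotypes: Sequence[PhasedHaplotype], col: int) -> Optional[int]:
    """Strict-majority resolved allele at a column.

    ``None`` when no allele is resolved or the resolved alleles tie — an
    evenly split column cannot say which haplotype broke away from the
    founder, so it never supports a breakpoint call.
    """
    counts = {0: 0, 1: 0}
    for h in haplotypes:
        a = h.alleles[col]
        if a is not None:
            counts[a] += 1
    if counts[0] == counts[1]:
        return None
    return 0 if counts[0] > counts[1] else 1


def shared_core(
    haplotypes: Sequence[PhasedHaplotype],
    index_pos: int,
    tolerance: int = 0,
) -> CoreResult:
    """Maximal concordant run of informative sites containing the index variant.

    ``tolerance`` resolved-discordant columns may be absorbed on each side
    before extension stops (default 0: any resolved mismatch ends the core;
    the parameter exists for genotyping-error robustness only).
    """
    if not haplotypes:
        raise ValueError("shared_core requires at least one haplotype")
    sites = haplotypes[0].sites
    for h in haplotypes[1:]:
        if h.sites != sites:
            raise ValueError(
                "all haplotypes must share the same informative site list "
                f"({h.individual} differs)"
            )
    if index_pos not in sites:
        raise ValueError(f"index position {index_pos} is not an informative site")
    idx = sites.index(index_pos)
    n = len(sites)

    status = [_column_status(haplotypes, col) for col in range(n)]

    def extend(direction: int) -> int:
        col = idx
        budget = tolerance
        last_ok = idx
        nxt = col + direction
        while 0 <= nxt < n:
            if status[nxt][0] == "discordant":
                if budget == 0:
                    break
                budget -= 1
            last_ok = nxt
            nxt += direction
        return last_ok

    lo = extend(-1)
    hi = extend(+1)

    # boundaries at the outermost concordant (resolved) sites within the run
    lo_b = next((c for c in range(lo, idx + 1) if status[c][0] == "concordant"), idx)
    hi_b = next((c for c in range(hi, idx - 1, -1) if status[c][0] == "concordant"), idx)

    chrom = _haplotype_chrom(haplotypes)
    core = GenomicInterval(chrom, sites[lo_b], sites[hi_b])
    consensus = {
        sites[c]: status[c][1]
        for c in range(lo_b, hi_b + 1)
        if status[c][0] == "concordant"
    }
    unresolved = [sites[c] for c in range(lo, hi + 1) if status[c][0] == "wildcard"]
    discordant = [sites[c] for c in range(n) if status[c][0] == "discordant"]

    per_family = _family_breakpoints(haplotypes, sites, idx, lo_b, hi_b)
    return CoreResult(
        core=core,
        boundary_sites=(
            _site_label(haplotypes, lo_b),
            _site_label(haplotypes, hi_b),
        ),
        consensus=consensus,
        unresolved_sites=unresolved,
        per_family_breakpoints=per_family,
        discordant_sites=discordant,
        n_haplotypes=len(haplotypes),
    )


def _haplotype_chrom(haplotypes: Sequence[PhasedHaplotype]) -> str:
    # haplotypes carry positions only; the chromosome label travels with the
    # family metadata, so fall back to a generic label when absent
    chrom = getattr(haplotypes[0], "chrom", None)
    return chrom if chrom else "chr?"


def _site_label(haplotypes: Sequence[PhasedHaplotype], col: int) -> str:
    return str(haplotypes[0].sites[col])


def _family_breakpoints(
    haplotypes: Sequence[PhasedHaplotype],
    sites: tuple[int, ...],
    idx: int,
    lo_b: int,
    hi_b: int,
) -> dict[str, Breakpoint]:
    """Nearest resolved strict-minority discordance per family, by side.

    A family is discordant at a column when its resolved allele differs from
    the modal resolved allele there.  The nearest such column below the core
    start is a centromeric breakpoint, above the core end a telomeric one;
    when both exist the nearer (in informative-site count, ties centromeric)
    is reported, since beyond its first recombination a haplotype carries no
    further information about the founder segment.
    """
    n = len(sites)
    out: dict[str, Breakpoint] = {}
    for hap in haplotypes:
        fam = hap.family or hap.individual
        left = None
        for col in range(lo_b - 1, -1, -1):
            a = hap.alleles[col]
            modal = _modal_allele(haplotypes, col)
            if a is not None and modal is not None and a != modal:
                left = col
                break
        right = None
        for col in range(hi_b + 1, n):
            a = hap.alleles[col]
            modal = _modal_allele(haplotypes, col)
            if a is not None and modal is not None and a != modal:
                right = col
                break
        if left is None and right is None:
            out[fam] = Breakpoint("none", None)
        elif right is None or (
            left is not None and (lo_b - left) <= (right - hi_b)
        ):
            out[fam] = Breakpoint(CENTROMERIC, sites[left])
        else:
            out[fam] = Breakpoint(TELOMERIC, sites[right])
    return out


@dataclass
class SingletonReport:
    """Outcome of direct variant interrogation of an unphased genotype."""

    verdict: str  # 'consistent' | 'inconsistent' | 'indeterminate'
    per_site: list[tuple[int, int, Optional[bool]]]  # (pos, consensus allele, present)
    inconsistent_sites: list[int]
    n_resolved: int
    n_untestable: int


def interrogate_singleton(
    calls: Sequence[GenotypeCall],
    consensus: dict[int, int],
) -> SingletonReport:
    """Check an unphased carrier genotype against the core consensus.

    For each core-defining site the consensus allele must be *present* in
    the genotype (het or hom); phase is not used, since a singleton cannot
    be phased.  The verdict is ``consistent`` iff the consensus allele is
    present at every testable site, ``indeterminate`` when no site is
    testable.
    """
    calls_by_pos = {c.site.pos: c for c in calls}
    per_site: list[tuple[int, int, Optional[bool]]] = []
    bad: list[int] = []
    n_resolved = 0
    n_untestable = 0
    for pos in sorted(consensus):
        allele = consensus[pos]
        call = calls_by_pos.get(pos)
        if call is None or call.is_missing:
            per_site.append((pos, allele, None))
            n_untestable += 1
            continue
        present = allele in call.alleles
        per_site.append((pos, allele, present))
        n_resolved += 1
        if not present:
            bad.append(pos)
    if n_resolved == 0:
        verdict = "indeterminate"
    else:
        verdict = "inconsistent" if bad else "consistent"
    return SingletonReport(
        verdict=verdict,
        per_site=per_site,
        inconsistent_sites=bad,
        n_resolved=n_resolved,
        n_untestable=n_untestable,
    )
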