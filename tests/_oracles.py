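"""Independent brute-force oracles used to check the pipeline's logic.

These deliberately re-derive results by exhaustive enumeration or naive
recounting, sharing no code with the implementation paths they check.
"""

from __future__ import annotations

from typing import Optional, Sequence


def enumerate_trio_phase(
    child: tuple[int, int],
    father: Optional[tuple[int, int]],
    mother: Optional[tuple[int, int]],
) -> set[tuple[int, int]]:
    """All (paternal, maternal) transmissions consistent with the trio.

    Enumerates every allele each parent could transmit (an unavailable
    parent may transmit either allele) and keeps the combinations matching
    the child's unordered genotype.  An empty set means the trio is
    Mendelian-impossible; two distinct orderings mean the phase cannot be
    determined.
    """
    f_alleles = father if father is not None else (0, 1)
    m_alleles = mother if mother is not None else (0, 1)
    sols = set()
    for ft in f_alleles:
        for mt in m_alleles:
            if sorted((ft, mt)) == sorted(child):
                sols.add((ft, mt))
    return sols


def longest_concordant_run(
    haplotypes: Sequence[Sequence[Optional[int]]],
    idx: int,
) -> tuple[int, int]:
    """Exhaustive scan for the maximal concordant run containing column idx.

    Tries every contiguous column range containing ``idx`` and keeps the
    longest in which no column shows two different resolved alleles, then
    shrinks its ends to the outermost columns with exactly one resolved
    allele (the reportable boundary markers).  Returns (lo, hi) column
    indices.
    """
    n = len(haplotypes[0])

    def resolved(col: int) -> set[int]:
        return {h[col] for h in haplotypes if h[col] is not None}

    best: Optional[tuple[int, int]] = None
    for lo in range(0, idx + 1):
        for hi in range(idx, n):
            if any(len(resolved(c)) > 1 for c in range(lo, hi + 1)):
                continue
            if best is None or hi - lo > best[1] - best[0]:
                best = (lo, hi)
    assert best is not None, "column idx itself is discordant"
    lo, hi = best
    lo_b = next((c for c in range(lo, idx + 1) if len(resolved(c)) == 1), idx)
    hi_b = next((c for c in range(hi, idx - 1, -1) if len(resolved(c)) == 1), idx)
    return lo_b, hi_b


def recount_variant_table(rows: Sequence[dict], index_label: str) -> dict:
    """Naive set-based recount of a genotype table.

    ``rows`` carry keys family, hgvs, consequence, domain.
    """
    seen: dict[str, dict] = {}
    for row in rows:
        seen.setdefault(row["hgvs"], row)
    families = {row["family"] for row in rows}
    with_index = {row["family"] for row in rows if row["hgvs"] == index_label}
    n_missense = sum(1 for r in seen.values() if r["consequence"] == "missense")
    coding = [r for r in seen.values() if r["consequence"] != "whole_gene_deletion"]
    domains: dict[str, int] = {}
    for r in coding:
        if r.get("domain"):
            domains[r["domain"]] = domains.get(r["domain"], 0) + 1
    return {
        "n_distinct": len(seen),
        "n_missense": n_missense,
        "n_families": len(families),
        "n_with_index": len(with_index),
        "domains": domains,
        "n_coding": len(coding),
    }
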