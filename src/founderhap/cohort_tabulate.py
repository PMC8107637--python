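"""Cohort summary statistics from the genotype and phenotype tables.

Counts distinct candidate alleles (by normalized coding-HGVS identity, so a
whole-gene deletion is a single allele), their consequence and
protein-domain breakdown, the fraction of families carrying the index
variant, and per-feature affected counts from the phenotype table.
``Possible`` phenotype entries count as affected by default (configurable),
and onset-age strings are stored verbatim — they are labels, not numbers
the pipeline computes with.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "PhenotypeRecord",
    "CohortSummary",
    "FeatureCount",
    "AlleleFrequency",
    "STATUS_LABELS",
    "phenotype_records",
    "summarize_variants",
    "count_feature",
    "compute_af",
]

STATUS_LABELS = ("yes", "no", "possible", "no_data")

#: columns of the phenotype table that are not yes/no feature statuses
_NON_FEATURE_COLUMNS = {
    "individual",
    "family",
    "sex",
    "age_of_initial_presentation",
    "age_of_examination",
    "latest_bcva",
}

_HGVS_CODING = re.compile(r"^c\.\d+(_\d+)?(?:[ACGT]+>[ACGT]+|del|dup|ins[ACGT]+)$")
_HGVS_SV = re.compile(r"^chr[\w]+:\d+-\d+del$")


@dataclass(frozen=True)
class PhenotypeRecord:
    """One individual's per-feature statuses with optional onset labels."""

    individual: str
    family: str
    statuses: dict  # feature -> status label in STATUS_LABELS
    onsets: dict  # feature -> verbatim onset string (may be empty)

    def __post_init__(self) -> None:
        bad = {s for s in self.statuses.values()} - set(STATUS_LABELS)
        if bad:
            raise ValueError(
                f"unknown status labels {sorted(bad)} for {self.individual}; "
                f"allowed: {STATUS_LABELS}"
            )


def parse_status(cell: str) -> tuple[str, str]:
    """Split a table cell like ``'Yes (3)'`` into (label, onset string)."""
    text = str(cell).strip()
    m = re.match(r"^(yes|no|possible|nd)\s*(?:\((.*)\))?$", text, flags=re.IGNORECASE)
    if m is None:
        raise ValueError(f"unparseable phenotype status {cell!r}")
    label = m.group(1).lower()
    if label == "nd":
        label = "no_data"
    return label, (m.group(2) or "").strip()


def phenotype_records(table: pd.DataFrame) -> list[PhenotypeRecord]:
    """Lower a wide phenotype table into :class:`PhenotypeRecord` objects."""
    records = []
    features = [c for c in table.columns if c not in _NON_FEATURE_COLUMNS]
    for row in table.itertuples(index=False):
        statuses, onsets = {}, {}
        for feature in features:
            label, onset = parse_status(getattr(row, feature))
            statuses[feature] = label
            onsets[feature] = onset
        records.append(
            PhenotypeRecord(
                individual=str(row.individual),
                family=str(row.family),
                statuses=statuses,
                onsets=onsets,
            )
        )
    return records


@dataclass
class CohortSummary:
    """Cohort-level variant statistics."""

    n_individuals: int
    n_families: int
    n_distinct_variants: int
    n_missense: int
    pct_missense: float
    n_families_with_index: int
    pct_families_with_index: float
    per_consequence: dict
    per_domain: dict  # over coding alleles only (the deletion is excluded)
    n_coding_variants: int


def _normalize_hgvs(label: str) -> str:
    text = str(label).strip().replace(" ", "")
    if not (_HGVS_CODING.match(text) or _HGVS_SV.match(text)):
        raise ValueError(f"malformed variant label {label!r}")
    return text


def summarize_variants(table: pd.DataFrame, index_hgvs: str) -> CohortSummary:
    """Summarize the genotype table.

    Distinct alleles are counted by normalized HGVS identity; percentages
    are reported to one decimal.  Domain counts cover coding alleles only.
    """
    index_key = _normalize_hgvs(index_hgvs)
    table = table.assign(_key=[_normalize_hgvs(h) for h in table["hgvs_c"]])
    distinct = table.drop_duplicates("_key")
    n_distinct = len(distinct)
    per_consequence = distinct["consequence"].value_counts().to_dict()
    n_missense = int(per_consequence.get("missense", 0))
    coding = distinct[distinct["consequence"] != "whole_gene_deletion"]
    per_domain = (
        coding["domain"].dropna().value_counts().to_dict() if "domain" in coding else {}
    )
    families = list(dict.fromkeys(table["family"]))
    with_index = list(
        dict.fromkeys(table.loc[table["_key"] == index_key, "family"])
    )
    n_individuals = int(
        table.drop_duplicates("family")["n_affected"].sum()
    ) if "n_affected" in table else 0
    return CohortSummary(
        n_individuals=n_individuals,
        n_families=len(families),
        n_distinct_variants=n_distinct,
        n_missense=n_missense,
        pct_missense=round(100.0 * n_missense / n_distinct, 1) if n_distinct else 0.0,
        n_families_with_index=len(with_index),
        pct_families_with_index=(
            round(100.0 * len(with_index) / len(families), 1) if families else 0.0
        ),
        per_consequence=per_consequence,
        per_domain=per_domain,
        n_coding_variants=len(coding),
    )


@dataclass(frozen=True)
class FeatureCount:
    feature: str
    n_affected: int
    n_total: int

    @property
    def fraction(self) -> Optional[float]:
        """Affected fraction; ``None`` (undefined) for an empty cohort."""
        return self.n_affected / self.n_total if self.n_total else None


def count_feature(
    records: Sequence[PhenotypeRecord],
    feature: str,
    affected_labels: Iterable[str] = ("yes", "possible"),
    include_no_data: bool = True,
) -> FeatureCount:
    """Count individuals affected for one phenotype feature.

    ``possible`` counts as affected by default.  Individuals whose status is
    ``no_data`` stay in the denominator unless ``include_no_data`` is False.
    The count is invariant to record order and status-label case.
    """
    affected_set = {str(lbl).lower() for lbl in affected_labels}
    unknown = affected_set - set(STATUS_LABELS)
    if unknown:
        raise ValueError(f"unknown affected labels {sorted(unknown)}")
    n_affected = 0
    n_total = 0
    available: set[str] = set()
    found = False
    for rec in records:
        available.update(rec.statuses)
        if feature not in rec.statuses:
            continue
        found = True
        status = rec.statuses[feature]
        if status == "no_data" and not include_no_data:
            continue
        n_total += 1
        if status in affected_set:
            n_affected += 1
    if records and not found:
        raise KeyError(
            f"unknown feature {feature!r}; available features: {sorted(available)}"
        )
    return FeatureCount(feature=feature, n_affected=n_affected, n_total=n_total)


@dataclass(frozen=True)
class AlleleFrequency:
    allele_count: int
    allele_number: int
    value: float
    display: str


def _one_significant_figure(value: float) -> str:
    if value == 0.0:
        return "0"
    exponent = math.floor(math.log10(abs(value)))
    rounded = round(value, -exponent)
    if exponent >= 0:
        return f"{rounded:g}"
    return f"{rounded:.{-exponent}f}"


def compute_af(allele_count: int, allele_number: int) -> AlleleFrequency:
    """Exact allele frequency with a one-significant-figure display value.

    The display convention matches how population databases print very rare
    frequencies (e.g. 2/68025 -> 0.00003); the exact ratio is always
    retained.
    """
    if allele_number <= 0:
        raise ValueError(f"allele_number must be positive, got {allele_number}")
    if not (0 <= allele_count <= allele_number):
        raise ValueError(
            f"allele_count must lie in [0, allele_number], got "
            f"{allele_count}/{allele_number}"
        )
    value = allele_count / allele_number
    return AlleleFrequency(
        allele_count=allele_count,
        allele_number=allele_number,
        value=value,
        display=_one_significant_figure(value),
    )
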