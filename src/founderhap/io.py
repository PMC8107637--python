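"""Shared genomic data model and readers/writers for the pipeline's file formats.

The pipeline touches four plain-text formats:

* a VCF v4.2 subset (``CHROM POS ID REF ALT QUAL FILTER INFO FORMAT`` plus
  per-sample ``GT`` and optional ``DP``/``AD``), parsed with :mod:`pysam`;
* 6-column PED pedigrees;
* a TSV population allele-frequency table (``chrom pos ref alt af``);
* a TSV deletion/CNV call table (``sample chrom start end cn [evidence]``).

All coordinates at this interface are 1-based and inclusive, following VCF
convention.  The genome assembly is treated as an opaque, internally
consistent coordinate system; no liftover is performed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

__all__ = [
    "GenomicInterval",
    "VariantSite",
    "GenotypeCall",
    "Individual",
    "Pedigree",
    "DeletionCall",
    "VcfParseError",
    "VcfFormatError",
    "PedigreeError",
    "FrequencyTableError",
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_frequency_table",
    "write_frequency_table",
    "read_deletions",
    "write_deletions",
]


class VcfParseError(ValueError):
    """A VCF file could not be parsed (malformed header or record)."""


class VcfFormatError(ValueError):
    """A structurally valid VCF violates the subset this pipeline accepts."""


class PedigreeError(ValueError):
    """A PED file or pedigree structure is inconsistent."""


class FrequencyTableError(ValueError):
    """An allele-frequency table failed validation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval on a single chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end {self.end} precedes start {self.start}"
            )

    @property
    def length_bp(self) -> int:
        """Inclusive length in base pairs (``end - start + 1``)."""
        return self.end - self.start + 1

    @property
    def span_bp(self) -> int:
        """Distance between the two endpoint coordinates (``end - start``).

        This is the convention used when a span is reported between two
        point positions (e.g. two boundary SNVs), as opposed to the
        inclusive length of a deleted segment.
        """
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class VariantSite:
    """One alternate allele at a genomic position.

    ``population_af`` is the population (minor/alternate) allele frequency;
    ``None`` means unknown.  ``consequence``, ``gene`` and ``domain`` are
    optional annotation labels consumed from the input; no annotation engine
    is run by this package.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = None
    population_af: Optional[float] = None
    consequence: Optional[str] = None
    gene: Optional[str] = None
    domain: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")
        if self.population_af is not None and not (0.0 <= self.population_af <= 1.0):
            raise ValueError(
                f"population_af {self.population_af} outside [0, 1] at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


#: allele codes inside a GenotypeCall: 0 = ref, 1 = alt, None = missing
Allele = Optional[int]


@dataclass
class GenotypeCall:
    """One sample's diploid genotype at one :class:`VariantSite`.

    ``alleles`` is an ordered pair with entries 0 (ref), 1 (alt) or ``None``
    (missing).  When ``phased`` is true the order is (paternal-derived,
    maternal-derived) wherever an upstream step established it; VCF input
    merely records the ``|`` separator.
    """

    sample: str
    site: VariantSite
    alleles: tuple[Allele, Allele]
    phased: bool = False
    depth: Optional[int] = None
    alt_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError(
                f"genotype for {self.sample} at {self.site} must have exactly "
                f"two alleles, got {self.alleles!r}"
            )

    @property
    def is_missing(self) -> bool:
        return self.alleles[0] is None and self.alleles[1] is None

    @property
    def has_alt(self) -> bool:
        return 1 in self.alleles

    @property
    def is_het(self) -> bool:
        return set(self.alleles) == {0, 1}

    @property
    def is_hom_alt(self) -> bool:
        return self.alleles == (1, 1)

    @property
    def is_hom_ref(self) -> bool:
        return self.alleles == (0, 0)


MISSING_PARENT = "0"


@dataclass(frozen=True)
class Individual:
    """One pedigree member.  A parent id of ``None`` means unavailable."""

    id: str
    family: str
    father: Optional[str] = None
    mother: Optional[str] = None
    sex: int = 0  # 1 male, 2 female, 0 unknown
    affected: bool = False


class Pedigree:
    """A set of individuals closed under (available) parent references."""

    def __init__(self, individuals: Iterable[Individual]):
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._members:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self._members.values():
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self._members:
                    raise PedigreeError(
                        f"individual {ind.id!r} names parent {parent!r} which is "
                        "neither in the pedigree nor marked unavailable"
                    )
        # no individual may be its own ancestor
        for ind in self._members.values():
            seen: set[str] = set()
            stack = [p for p in (ind.father, ind.mother) if p is not None]
            while stack:
                cur = stack.pop()
                if cur == ind.id:
                    raise PedigreeError(f"individual {ind.id!r} is its own ancestor")
                if cur in seen:
                    continue
                seen.add(cur)
                member = self._members[cur]
                stack.extend(p for p in (member.father, member.mother) if p is not None)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._members

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self):
        return iter(self._members.values())

    def __getitem__(self, individual_id: str) -> Individual:
        return self._members[individual_id]

    def get(self, individual_id: str) -> Optional[Individual]:
        return self._members.get(individual_id)

    def father_of(self, individual_id: str) -> Optional[Individual]:
        fid = self._members[individual_id].father
        return self._members[fid] if fid is not None else None

    def mother_of(self, individual_id: str) -> Optional[Individual]:
        mid = self._members[individual_id].mother
        return self._members[mid] if mid is not None else None

    def children_of(self, individual_id: str) -> list[Individual]:
        return [
            ind
            for ind in self._members.values()
            if individual_id in (ind.father, ind.mother)
        ]

    def full_siblings_of(self, individual_id: str) -> list[Individual]:
        ind = self._members[individual_id]
        if ind.father is None or ind.mother is None:
            return []
        return [
            other
            for other in self._members.values()
            if other.id != ind.id
            and other.father == ind.father
            and other.mother == ind.mother
        ]

    def family(self, family_id: str) -> list[Individual]:
        return [ind for ind in self._members.values() if ind.family == family_id]

    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self._members.values():
            seen.setdefault(ind.family, None)
        return list(seen)

    def affected(self) -> list[Individual]:
        return [ind for ind in self._members.values() if ind.affected]


@dataclass(frozen=True)
class DeletionCall:
    """A consumed deletion/CNV call (the pipeline does not discover CNVs)."""

    sample: str
    interval: GenomicInterval
    copy_number: int = 1
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.copy_number not in (0, 1):
            raise ValueError(
                f"deletion copy number must be 0 or 1, got {self.copy_number}"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _scan_vcf_lines(path: Path) -> list[int]:
    """Light structural pre-scan: return 1-based line numbers of data rows.

    Raises :class:`VcfParseError` naming the first malformed line so that
    downstream errors can be reported usefully; semantic parsing is done by
    pysam/htslib afterwards.
    """
    data_lines: list[int] = []
    saw_columns = False
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if saw_columns:
                    raise VcfParseError(
                        f"{path}: line {lineno}: meta line after #CHROM header"
                    )
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 8:
                    raise VcfParseError(
                        f"{path}: line {lineno}: #CHROM header has {len(cols)} "
                        "columns, expected at least 8"
                    )
                saw_columns = True
                continue
            if not saw_columns:
                raise VcfParseError(
                    f"{path}: line {lineno}: data before #CHROM header"
                )
            cols = line.split("\t")
            if len(cols) < 8:
                raise VcfParseError(
                    f"{path}: line {lineno}: record has {len(cols)} columns, "
                    "expected at least 8"
                )
            try:
                int(cols[1])
            except ValueError:
                raise VcfParseError(
                    f"{path}: line {lineno}: POS {cols[1]!r} is not an integer"
                ) from None
            data_lines.append(lineno)
    if not saw_columns:
        raise VcfParseError(f"{path}: no #CHROM header line found")
    return data_lines


def read_vcf(
    path: str | Path,
    split_multiallelic: bool = False,
) -> tuple[list[VariantSite], list[GenotypeCall]]:
    """Read a VCF into variant sites and per-sample genotype calls.

    One :class:`VariantSite` is emitted per (position, alt allele) and one
    :class:`GenotypeCall` per sample per site, in file/sample order.
    Multiallelic records are rejected unless ``split_multiallelic`` is set,
    in which case each alternate allele becomes its own site and genotype
    indices pointing at *other* alternate alleles are recoded as ref.
    A ``|`` genotype separator sets the ``phased`` flag; ``./.`` maps to
    ``(None, None)``.
    """
    path = Path(path)
    data_lines = _scan_vcf_lines(path)
    sites: list[VariantSite] = []
    calls: list[GenotypeCall] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:  # pragma: no cover - defensive
        raise VcfParseError(f"{path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        for rec_idx, rec in enumerate(vf):
            lineno = data_lines[rec_idx] if rec_idx < len(data_lines) else -1
            alts = rec.alts or ()
            if not alts:
                raise VcfFormatError(
                    f"{path}: line {lineno}: record without ALT allele"
                )
            if len(alts) > 1 and not split_multiallelic:
                raise VcfFormatError(
                    f"{path}: line {lineno}: multiallelic record at "
                    f"{rec.chrom}:{rec.pos}; split it or pass "
                    "split_multiallelic=True"
                )
            if "GT" not in rec.format:
                raise VcfFormatError(
                    f"{path}: line {lineno}: record without GT in FORMAT"
                )
            for alt_index, alt in enumerate(alts, start=1):
                site = VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    id=rec.id,
                )
                sites.append(site)
                for sample in samples:
                    fmt = rec.samples[sample]
                    gt = fmt["GT"]
                    if gt is None or len(gt) != 2:
                        raise VcfFormatError(
                            f"{path}: line {lineno}: sample {sample} has a "
                            f"non-diploid genotype {gt!r}"
                        )
                    alleles = tuple(
                        None if a is None else (1 if a == alt_index else 0)
                        for a in gt
                    )
                    depth = fmt.get("DP")
                    ad = fmt.get("AD")
                    alt_depth = None
                    if ad is not None and len(ad) > alt_index:
                        alt_depth = ad[alt_index]
                    calls.append(
                        GenotypeCall(
                            sample=sample,
                            site=site,
                            alleles=alleles,  # type: ignore[arg-type]
                            phased=fmt.phased,
                            depth=depth,
                            alt_depth=alt_depth,
                        )
                    )
    return sites, calls


def _gt_string(call: GenotypeCall) -> str:
    sep = "|" if call.phased else "/"
    return sep.join("." if a is None else str(a) for a in call.alleles)


def write_vcf(
    sites: Sequence[VariantSite],
    calls: Sequence[GenotypeCall],
    path: str | Path,
    sample_order: Optional[Sequence[str]] = None,
) -> Path:
    """Write sites and calls as a minimal VCF v4.2 file.

    The writer is canonical: reading its output with :func:`read_vcf` and
    writing again reproduces the file byte for byte.  ``DP``/``AD`` FORMAT
    fields are emitted only when at least one call carries them.
    """
    path = Path(path)
    if sample_order is None:
        seen: dict[str, None] = {}
        for call in calls:
            seen.setdefault(call.sample, None)
        sample_order = list(seen)
    by_site: dict[tuple, dict[str, GenotypeCall]] = {}
    for call in calls:
        by_site.setdefault(call.site.key, {})[call.sample] = call
    has_dp = any(c.depth is not None for c in calls)
    has_ad = any(c.alt_depth is not None for c in calls)
    fmt_keys = ["GT"] + (["DP"] if has_dp else []) + (["AD"] if has_ad else [])

    contigs: dict[str, None] = {}
    for site in sites:
        contigs.setdefault(site.chrom, None)

    lines = ["##fileformat=VCFv4.2"]
    for contig in contigs:
        lines.append(f"##contig=<ID={contig}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if has_dp:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    if has_ad:
        lines.append(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">'
        )
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if sample_order:
        header += ["FORMAT", *sample_order]
    lines.append("\t".join(header))

    for site in sites:
        row = [
            site.chrom,
            str(site.pos),
            site.id or ".",
            site.ref,
            site.alt,
            ".",
            ".",
            ".",
        ]
        if sample_order:
            row.append(":".join(fmt_keys))
            site_calls = by_site.get(site.key, {})
            for sample in sample_order:
                call = site_calls.get(sample)
                if call is None:
                    fields = ["./."] + ["."] * (len(fmt_keys) - 1)
                else:
                    fields = [_gt_string(call)]
                    if has_dp:
                        fields.append("." if call.depth is None else str(call.depth))
                    if has_ad:
                        if call.alt_depth is None or call.depth is None:
                            fields.append(".")
                        else:
                            fields.append(f"{call.depth - call.alt_depth},{call.alt_depth}")
                row.append(":".join(fields))
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------


def read_ped(path: str | Path) -> Pedigree:
    """Read a 6-column whitespace-delimited PED file.

    Column order is family, individual, father, mother, sex, phenotype;
    ``0`` denotes a missing parent and phenotype ``2`` flags an affected
    individual.
    """
    path = Path(path)
    individuals: list[Individual] = []
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise PedigreeError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(cols)}"
                )
            family, iid, father, mother, sex, phen = cols[:6]
            individuals.append(
                Individual(
                    id=iid,
                    family=family,
                    father=None if father == MISSING_PARENT else father,
                    mother=None if mother == MISSING_PARENT else mother,
                    sex=int(sex) if sex in ("1", "2") else 0,
                    affected=phen == "2",
                )
            )
    return Pedigree(individuals)


def write_ped(pedigree: Pedigree, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for ind in pedigree:
        rows.append(
            "\t".join(
                [
                    ind.family,
                    ind.id,
                    ind.father or MISSING_PARENT,
                    ind.mother or MISSING_PARENT,
                    str(ind.sex),
                    "2" if ind.affected else "1",
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n")
    return path


# ---------------------------------------------------------------------------
# frequency and deletion tables
# ---------------------------------------------------------------------------

FreqKey = tuple[str, int, str, str]


def read_frequency_table(path: str | Path) -> dict[FreqKey, float]:
    """Read a TSV of population allele frequencies keyed by (chrom, pos, ref, alt).

    Sites absent from the table are treated downstream as frequency-unknown.
    Duplicate keys with conflicting frequencies are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt", "af"}
    missing = required - set(df.columns)
    if missing:
        raise FrequencyTableError(
            f"{path}: missing columns {sorted(missing)}; expected {sorted(required)}"
        )
    mapping: dict[FreqKey, float] = {}
    for row in df.itertuples(index=False):
        af = float(row.af)
        if not (0.0 <= af <= 1.0):
            raise FrequencyTableError(
                f"{path}: af {af} outside [0, 1] at {row.chrom}:{row.pos}"
            )
        key: FreqKey = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        if key in mapping and mapping[key] != af:
            raise FrequencyTableError(
                f"{path}: duplicate key {key} with conflicting af "
                f"{mapping[key]} vs {af}"
            )
        mapping[key] = af
    return mapping


def write_frequency_table(mapping: Mapping[FreqKey, float], path: str | Path) -> Path:
    path = Path(path)
    lines = ["chrom\tpos\tref\talt\taf"]
    for (chrom, pos, ref, alt), af in mapping.items():
        lines.append(f"{chrom}\t{pos}\t{ref}\t{alt}\t{af!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_deletions(path: str | Path) -> list[DeletionCall]:
    """Read a TSV of deletion calls (sample, chrom, start, end, cn[, evidence])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    required = {"sample", "chrom", "start", "end", "cn"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing columns {sorted(missing)}; expected {sorted(required)}"
        )
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DeletionCall(
                sample=str(row.sample),
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                copy_number=int(row.cn),
                evidence=str(getattr(row, "evidence", "") or ""),
            )
        )
    return out


def write_deletions(deletions: Sequence[DeletionCall], path: str | Path) -> Path:
    path = Path(path)
    lines = ["sample\tchrom\tstart\tend\tcn\tevidence"]
    for d in deletions:
        lines.append(
            f"{d.sample}\t{d.interval.chrom}\t{d.interval.start}\t"
            f"{d.interval.end}\t{d.copy_number}\t{d.evidence}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
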