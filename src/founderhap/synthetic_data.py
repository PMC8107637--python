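"""Synthetic multi-family cohorts with a planted founder haplotype.

The generator emulates the statistical structure the haplotype analysis
assumes: a founder (ancestral) haplotype around an index variant, shared
identical-by-descent by a subset of families and truncated per family by
recombination, embedded among frequency-stratified background SNVs.  One
family may carry the index variant hemizygously opposite a whole-gene
deletion, and families may be singletons (no parental DNA).

Modelling choices (see the package methods note for rationale):

* Background chromosomes are sampled site-independently from the configured
  allele frequencies — no linkage disequilibrium.  The analysis rests on
  rare-allele sharing, for which independent sampling is the relevant
  chance-sharing null.
* Informative sites (population AF below ``maf_informative``) double as the
  founder haplotype's marker panel: the founder carries the minor allele at
  each such site with probability ``founder_marker_rate``.  This mirrors
  marker ascertainment in practice — the sites worth tabulating for a
  shared haplotype are those where it differs from the major allele.
* Recombination breakpoints are specified positions (controllable truth),
  with an optional uniform-random mode; they are not drawn from a genetic
  map.
* A single integer seed drives one generator stream, so identical seeds
  give byte-identical output files.

Every run returns a machine-readable :class:`SimTruth` ledger recording the
founder allele vector, each family's transmitted segment, the realized
deletion and the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import (
    DeletionCall,
    GenomicInterval,
    GenotypeCall,
    Individual,
    Pedigree,
    VariantSite,
    write_deletions,
    write_frequency_table,
    write_ped,
    write_vcf,
)
from .tables import table_fixtures  # noqa: F401  (re-exported: cohort table fixtures)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate_cohort",
    "write_cohort",
    "paper_shaped_config",
    "table_fixtures",
    "RANDOM_BREAKPOINTS",
]

RANDOM_BREAKPOINTS = "random"

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated cohort.

    Carrier families are the first ``n_carrier_families`` of ``n_families``
    (labels ``FAM1`` ... ``FAMn``).  ``recombination_spec`` maps a carrier
    family label to ``(side, position)`` where ``side`` is ``centromeric``
    (the founder segment is lost below the breakpoint) or ``telomeric``
    (lost above); families without an entry transmit the full-window founder
    segment.  Passing the string ``"random"`` instead of a mapping draws one
    breakpoint per carrier family uniformly, on a uniform side, constrained
    to keep the index variant on the transmitted segment.
    """

    window: GenomicInterval = GenomicInterval("chr17", 74_710_000, 75_025_000)
    gene: GenomicInterval = GenomicInterval("chr17", 74_860_000, 74_875_000)
    n_sites: int = 300
    af_low: float = 0.0005
    af_high: float = 0.5
    n_families: int = 8
    n_carrier_families: int = 5
    index_pos: int = 74_864_337
    index_ref: str = "C"
    index_alt: str = "A"
    index_af: float = 1.315e-5
    maf_informative: float = 0.1
    founder_marker_rate: float = 1.0
    recombination_spec: object = field(default_factory=dict)  # mapping or "random"
    deletion_family: Optional[str] = None
    deletion_interval: GenomicInterval = GenomicInterval("chr17", 74_818_633, 74_888_183)
    singleton_families: frozenset[str] = frozenset()
    sib_family: Optional[str] = None
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.window.contains_interval(self.gene):
            raise ValueError("gene interval must lie inside the window")
        if not (self.gene.start < self.index_pos < self.gene.end):
            raise ValueError(
                f"index position {self.index_pos} must lie strictly inside the "
                f"gene interval {self.gene}"
            )
        if self.n_carrier_families > self.n_families:
            raise ValueError("n_carrier_families cannot exceed n_families")
        for rate in (self.genotype_error_rate, self.missing_rate):
            if not (0.0 <= rate <= 0.5):
                raise ValueError(f"rates must lie in [0, 0.5], got {rate}")
        if not (0.0 < self.af_low <= self.af_high < 1.0):
            raise ValueError("af distribution bounds must satisfy 0 < low <= high < 1")
        if isinstance(self.recombination_spec, dict):
            for fam, (side, pos) in self.recombination_spec.items():
                if side not in ("centromeric", "telomeric"):
                    raise ValueError(f"unknown breakpoint side {side!r} for {fam}")
                if not (self.window.start <= pos <= self.window.end):
                    raise ValueError(f"breakpoint {pos} outside window for {fam}")
                seg = self._segment_for(side, pos)
                if not (seg[0] <= self.index_pos <= seg[1]):
                    raise ValueError(
                        f"breakpoint for {fam} removes the index variant from "
                        "the transmitted segment"
                    )
        elif self.recombination_spec != RANDOM_BREAKPOINTS:
            raise ValueError(
                "recombination_spec must be a mapping or the string 'random'"
            )
        if self.deletion_family is not None and not self.deletion_interval.contains_interval(self.gene):
            raise ValueError("deletion interval must contain the gene")

    def _segment_for(self, side: str, pos: int) -> tuple[int, int]:
        if side == "centromeric":
            return (pos, self.window.end)
        return (self.window.start, pos)

    def carrier_families(self) -> list[str]:
        return [f"FAM{i + 1}" for i in range(self.n_carrier_families)]

    def family_labels(self) -> list[str]:
        return [f"FAM{i + 1}" for i in range(self.n_families)]


@dataclass
class FamilyTruth:
    carrier: bool
    segment: Optional[tuple[int, int]]  # positions [lo, hi] carrying founder alleles
    breakpoint_side: Optional[str]
    breakpoint_pos: Optional[int]
    singleton: bool
    has_deletion: bool
    transmitting_parent: Optional[str]  # 'mother' in every carrier trio


@dataclass
class SimTruth:
    """The generator's ledger of planted truth."""

    seed: int
    positions: list[int]  # all site positions, ascending (index site included)
    afs: list[float]
    founder_alleles: list[int]
    informative_positions: list[int]
    index_pos: int
    families: dict[str, FamilyTruth]
    deletion: Optional[dict]
    config: dict

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return path

    @staticmethod
    def from_json(path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        payload["families"] = {
            fam: FamilyTruth(**ft) for fam, ft in payload["families"].items()
        }
        for ft in payload["families"].values():
            if ft.segment is not None:
                ft.segment = tuple(ft.segment)
        return SimTruth(**payload)


@dataclass
class SimResult:
    sites: list[VariantSite]
    calls: list[GenotypeCall]
    pedigree: Pedigree
    deletions: list[DeletionCall]
    frequencies: dict
    truth: SimTruth
    index_site: VariantSite


def paper_shaped_config(**overrides) -> SimConfig:
    """The default study-shaped cohort: 8 families, 5 index carriers.

    Carriers: one trio with two affected siblings sharing the transmitted
    chromosome, one trio truncated centromerically and one telomerically
    (breakpoints placed so the full-sharers' core spans roughly 128 kb),
    one singleton carrying the index hemizygously opposite the whole-gene
    deletion, and one plain singleton for direct interrogation.  The three
    remaining families are non-carrier trios.
    """
    defaults = dict(
        n_families=8,
        n_carrier_families=5,
        recombination_spec={
            "FAM2": ("centromeric", 74_819_000),
            "FAM3": ("telomeric", 74_947_400),
        },
        deletion_family="FAM4",
        singleton_families=frozenset({"FAM4", "FAM5"}),
        sib_family="FAM1",
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def _background(rng: np.random.Generator, afs: np.ndarray) -> np.ndarray:
    """One background chromosome: site-independent Bernoulli(af) alleles."""
    return (rng.random(afs.shape[0]) < afs).astype(np.int8)


def simulate_cohort(cfg: SimConfig, seed: int) -> SimResult:
    """Simulate one cohort; identical (cfg, seed) give identical results."""
    rng = np.random.default_rng(seed)

    # --- sites -------------------------------------------------------------
    span = np.arange(cfg.window.start, cfg.window.end + 1)
    span = span[span != cfg.index_pos]
    positions = np.sort(rng.choice(span, size=cfg.n_sites, replace=False))
    afs = rng.uniform(cfg.af_low, cfg.af_high, size=cfg.n_sites)
    refs = rng.integers(0, 4, size=cfg.n_sites)
    alt_shift = rng.integers(1, 4, size=cfg.n_sites)

    all_pos = np.concatenate([positions, [cfg.index_pos]])
    order = np.argsort(all_pos)
    all_afs = np.concatenate([afs, [cfg.index_af]])[order]
    all_refs = np.concatenate([refs, [-1]])[order]
    all_shift = np.concatenate([alt_shift, [-1]])[order]
    all_pos = all_pos[order]
    idx = int(np.flatnonzero(all_pos == cfg.index_pos)[0])

    sites: list[VariantSite] = []
    for i, pos in enumerate(all_pos):
        if i == idx:
            sites.append(
                VariantSite(
                    chrom=cfg.window.chrom,
                    pos=int(pos),
                    ref=cfg.index_ref,
                    alt=cfg.index_alt,
                    id="index",
                    population_af=cfg.index_af,
                )
            )
        else:
            ref = _BASES[int(all_refs[i])]
            alt = _BASES[(int(all_refs[i]) + int(all_shift[i])) % 4]
            sites.append(
                VariantSite(
                    chrom=cfg.window.chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    id=f"snv{i}",
                    population_af=float(all_afs[i]),
                )
            )

    informative = all_afs < cfg.maf_informative

    # --- founder haplotype -------------------------------------------------
    founder = _background(rng, all_afs)
    marker_draw = rng.random(len(all_pos)) < cfg.founder_marker_rate
    founder[informative & marker_draw] = 1
    founder[~informative] = _background(rng, all_afs)[~informative]
    founder[idx] = 1

    # --- per-family structure ----------------------------------------------
    if cfg.recombination_spec == RANDOM_BREAKPOINTS:
        recomb: dict[str, tuple[str, int]] = {}
        for fam in cfg.carrier_families():
            side = "centromeric" if rng.random() < 0.5 else "telomeric"
            if side == "centromeric":
                pos = int(rng.integers(cfg.window.start, cfg.index_pos))
            else:
                pos = int(rng.integers(cfg.index_pos + 1, cfg.window.end + 1))
            recomb[fam] = (side, pos)
    else:
        recomb = dict(cfg.recombination_spec)  # type: ignore[arg-type]

    calls: list[GenotypeCall] = []
    individuals: list[Individual] = []
    deletions: list[DeletionCall] = []
    families: dict[str, FamilyTruth] = {}
    del_mask = np.array(
        [cfg.deletion_interval.contains(cfg.window.chrom, int(p)) for p in all_pos]
    )

    def truncated_founder(segment: tuple[int, int]) -> np.ndarray:
        hap = _background(rng, all_afs)
        inside = (all_pos >= segment[0]) & (all_pos <= segment[1])
        hap[inside] = founder[inside]
        return hap

    def emit(sample: str, a: np.ndarray, b: np.ndarray, hemizygous: Optional[np.ndarray] = None):
        for i, site in enumerate(sites):
            if hemizygous is not None and hemizygous[i]:
                alleles = (int(a[i]), int(a[i]))  # single retained copy
            else:
                alleles = (int(a[i]), int(b[i]))
            if cfg.genotype_error_rate > 0.0:
                flip = rng.random(2) < cfg.genotype_error_rate
                alleles = tuple(
                    1 - al if fl else al for al, fl in zip(alleles, flip)
                )
            if cfg.missing_rate > 0.0 and rng.random() < cfg.missing_rate:
                alleles = (None, None)
            calls.append(GenotypeCall(sample, site, alleles))  # type: ignore[arg-type]

    full_segment = (cfg.window.start, cfg.window.end)
    for fam in cfg.family_labels():
        carrier = fam in cfg.carrier_families()
        singleton = fam in cfg.singleton_families
        has_del = fam == cfg.deletion_family
        if carrier:
            side_pos = recomb.get(fam)
            segment = (
                cfg._segment_for(*side_pos) if side_pos is not None else full_segment
            )
            founder_hap = truncated_founder(segment)
        else:
            side_pos = None
            segment = None
            founder_hap = None

        if singleton:
            child = f"{fam}_II1"
            individuals.append(Individual(child, fam, sex=1, affected=True))
            if carrier and has_del:
                emit(child, founder_hap, _background(rng, all_afs), hemizygous=del_mask)
                deletions.append(
                    DeletionCall(child, cfg.deletion_interval, copy_number=1, evidence="synthetic")
                )
            elif carrier:
                emit(child, founder_hap, _background(rng, all_afs))
            else:
                emit(child, _background(rng, all_afs), _background(rng, all_afs))
            families[fam] = FamilyTruth(
                carrier=carrier,
                segment=segment,
                breakpoint_side=side_pos[0] if side_pos else None,
                breakpoint_pos=side_pos[1] if side_pos else None,
                singleton=True,
                has_deletion=has_del,
                transmitting_parent=None,
            )
            continue

        father, mother = f"{fam}_I1", f"{fam}_I2"
        individuals.append(Individual(father, fam, sex=1))
        individuals.append(Individual(mother, fam, sex=2))
        father_haps = (_background(rng, all_afs), _background(rng, all_afs))
        if carrier:
            mother_haps = (founder_hap, _background(rng, all_afs))
        else:
            mother_haps = (_background(rng, all_afs), _background(rng, all_afs))
        emit(father, *father_haps)
        emit(mother, *mother_haps)
        n_children = 2 if fam == cfg.sib_family else 1
        for c in range(n_children):
            child = f"{fam}_II{c + 1}"
            individuals.append(
                Individual(child, fam, father=father, mother=mother, sex=1, affected=True)
            )
            pat = father_haps[int(rng.integers(0, 2))]
            # in carrier trios the mother transmits the founder chromosome to
            # every affected child (they share it identical by descent)
            mat = mother_haps[0] if carrier else mother_haps[int(rng.integers(0, 2))]
            emit(child, pat, mat)
        families[fam] = FamilyTruth(
            carrier=carrier,
            segment=segment,
            breakpoint_side=side_pos[0] if side_pos else None,
            breakpoint_pos=side_pos[1] if side_pos else None,
            singleton=False,
            has_deletion=False,
            transmitting_parent="mother" if carrier else None,
        )

    for fam, ft in families.items():
        if ft.carrier:
            assert ft.segment is not None and ft.segment[0] <= cfg.index_pos <= ft.segment[1]

    frequencies = {s.key: float(s.population_af) for s in sites}
    truth = SimTruth(
        seed=seed,
        positions=[int(p) for p in all_pos],
        afs=[float(a) for a in all_afs],
        founder_alleles=[int(a) for a in founder],
        informative_positions=[int(p) for p, inf in zip(all_pos, informative) if inf],
        index_pos=cfg.index_pos,
        families=families,
        deletion=(
            {
                "family": cfg.deletion_family,
                "chrom": cfg.deletion_interval.chrom,
                "start": cfg.deletion_interval.start,
                "end": cfg.deletion_interval.end,
            }
            if cfg.deletion_family is not None
            else None
        ),
        config=_config_echo(cfg),
    )
    return SimResult(
        sites=sites,
        calls=calls,
        pedigree=Pedigree(individuals),
        deletions=deletions,
        frequencies=frequencies,
        truth=truth,
        index_site=sites[idx],
    )


def _config_echo(cfg: SimConfig) -> dict:
    echo = {}
    for f in dataclasses.fields(cfg):
        value = getattr(cfg, f.name)
        if isinstance(value, GenomicInterval):
            value = {"chrom": value.chrom, "start": value.start, "end": value.end}
        elif isinstance(value, frozenset):
            value = sorted(value)
        elif isinstance(value, dict):
            value = {k: list(v) for k, v in value.items()}
        echo[f.name] = value
    return echo


def write_cohort(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write VCF, PED, frequency TSV, deletion TSV and truth JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": write_vcf(result.sites, result.calls, outdir / "cohort.vcf"),
        "ped": write_ped(result.pedigree, outdir / "cohort.ped"),
        "freq": write_frequency_table(result.frequencies, outdir / "frequencies.tsv"),
        "deletions": write_deletions(result.deletions, outdir / "deletions.tsv"),
        "truth": result.truth.to_json(outdir / "truth.json"),
    }
    return paths
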