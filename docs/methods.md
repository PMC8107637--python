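# Methods

## Problem and model

`founderhap` reconstructs the local haplotype background of an *index
variant* — a candidate recessive disease allele observed in several
unrelated families — and asks whether the carrier chromosomes share a
segment identical by descent (a founder haplotype), and where each
family's copy of that segment was truncated by historical recombination.

The model is deliberately deterministic.  A carrier chromosome is an
allele vector over *informative SNVs*: variants rare enough in the
reference population that sharing them is evidence of common descent
rather than chance.  Phase is established only where genotype data force
it — Mendelian trio logic, homozygosity, or hemizygosity over a deletion —
and everything else is carried as an explicit wildcard.  There is no
LD model, no reference-panel imputation, no read-backed phasing, and no
probabilistic error model: genotyping error surfaces as per-site
Mendelian-conflict flags, not as posterior probabilities.

## Pipeline stages and parameters

### Candidate filtering (`candidate_filter`)

* `maf_rare` (default 0.001) — population-MAF cutoff for genome-wide
  rarity; `maf_rare_exome` (default 0.003) is the looser cutoff intended
  for exome-derived input.  Both are fractions; the filter is strict
  (`af < cutoff`).  A site with *unknown* frequency passes: truly novel
  alleles are reported as frequency 0 or absent from frequency tables, and
  discarding them would remove exactly the candidates of interest.
* `protein_altering_classes` — defaults to {missense, stop_gain,
  frameshift, splice_donor, splice_acceptor, inframe_indel, start_lost,
  stop_lost}.  The boundary cases (synonymous-near-splice, deep intronic)
  are excluded by default; the set is configurable because "protein
  altering" has no single field-wide definition.
* `panel_genes` — a virtual panel of genes already known to cause the
  phenotype; variants in them are excluded as alternative explanations.
* Consequence, gene and domain labels are consumed from input columns; the
  package runs no annotation engine.

Biallelic assembly emits, per affected individual: `hom_alt`;
`compound_het_trans` with an evidence grade; `compound_het_unresolved`;
or `het_plus_deletion_hemizygous` when a carried SNV lies inside a
deletion call for the same sample.  At such sites the diploid GT string is
not trusted (callers emit 0/1 or 1/1 over a hemizygous locus more or less
arbitrarily); a warning is raised if allele depths show solid support for
both alleles, contradicting copy loss.  Trans evidence grades:

* `parental` — both alleles' parental origins are Mendelian-forced (or a
  forced pair shows *cis*, which excludes the pair from candidacy);
* `parental_supported` — one allele is forced to the unavailable parent
  (the available parent cannot transmit it) and the other is carried by
  the available parent.  Strictly, the second allele *could* sit on the
  same chromosome as the first with the available parent's copy
  untransmitted; the grade records that the call is parsimony, not proof.
  This is the standard clinical reading of single-parent segregation and
  is required to reproduce cohorts where one parent is unavailable.
* `sibling` — a full sibling carries exactly one allele of the pair.
  Without recombination between the two sites (they sit within one gene),
  a cis pair travels together, so a sibling with exactly one proves trans.
* A single available parent carrying *both* alleles flags the pair
  `cis_excluded` (again parsimony: trans would require the unavailable
  parent to carry one of them independently).

### Phasing (`phasing`)

* `window_bp` (default 150,000) — applied up- and downstream of the gene
  interval.  "Roughly 150 kb" is implemented as exactly 150,000 bp for
  reproducibility; the window is a pre-filter only and never truncates a
  reported core from inside.
* `maf_informative` (default 0.1) — strict cutoff for informative SNVs;
  sites with unknown frequency are not informative.  The index variant is
  always retained regardless of frequency.

Per-site trio resolution enumerates the two orderings of a heterozygous
child's alleles against what each parent can transmit; an unavailable or
missing-genotype parent is permissive.  Exactly one consistent ordering →
resolved; two → unresolved; zero → `mendel_conflict` (site excluded from
the haplotype, flagged).  Homozygous sites are resolved on every
chromosome regardless of pedigree availability.  Hemizygous anchoring
assigns every non-missing call inside the deletion interval to the
retained chromosome; it refuses to run when the index variant lies outside
the deletion (the retained chromosome would then not be identifiable as
the index-carrying one).

One haplotype is emitted per independent index-carrying chromosome:
affected siblings whose index allele has the same forced parental origin
share one transmitted chromosome and are merged (site-wise union of
resolved alleles; resolved disagreements — possible only through
genotyping error — revert to flagged wildcards).  Siblings whose index
origins differ or cannot be determined are kept separate.

A fifth per-site origin label, `homozygous`, is used alongside paternal /
maternal / hemizygous_anchor / unresolved: a homozygous site has a known
allele but no meaningful parental origin, and folding it into
`unresolved` would make "resolved allele" ambiguous.

### Core detection (`founder_core`)

The shared core is the maximal contiguous run of informative sites
containing the index position in which every haplotype carries the same
resolved allele or a wildcard.  Design choices:

* Consensus at a column requires at least one resolved allele; a
  wildcard-only column contributes no evidence, never terminates the core,
  and is reported as unresolved support (mirroring how an undetermined SNP
  inside a shared haplotype is tabulated rather than treated as a break).
* Boundaries are reported at the outermost *concordant* sites
  (marker-to-marker, as shared haplotypes are reported rsID-to-rsID), not
  at midpoints between concordant and discordant sites.  The reported
  span is the difference of the two boundary coordinates (point-to-point),
  distinct from the inclusive length used for deleted segments.
* Discordance tolerance defaults to 0 — any resolved mismatch ends
  extension.  A `tolerance` parameter exists for genotyping-error
  robustness but is off by default.
* Per-family breakpoints: a family is discordant at a column when its
  resolved allele differs from the strict-majority allele there; an evenly
  split column has no majority and supports no call.  The nearest such
  column below the core start is a centromeric breakpoint, above the core
  end telomeric; if both exist the nearer one (ties centromeric) is
  reported, because beyond its first recombination a haplotype is
  background and carries no further information about the founder segment.
  This guarantees every discordant family is centromeric xor telomeric.

Singleton interrogation is presence-based: for each core-defining site the
consensus allele must appear in the unphased genotype (het or hom).  The
verdict is `consistent` only if it appears at every testable site,
`indeterminate` if nothing is testable.  Presence, not phase, is the only
evidence a singleton can provide.

### Cohort tabulation (`cohort_tabulate`)

Distinct alleles are counted by normalized HGVS identity, so a whole-gene
deletion is one allele; domain counts cover coding alleles only.
`Possible` phenotype entries count as affected by default (the flag is
configurable) and `ND` (no data) individuals stay in the denominator
unless excluded explicitly.  Onset-age strings ("late teens", "40s") are
stored verbatim — the pipeline never computes with them.  Allele
frequencies keep the exact ratio and add a one-significant-figure display
value, matching how population databases print very rare frequencies.

## The synthetic-data generator

`synthetic_data.simulate_cohort` emulates the WGS input the haplotype
analysis consumes.  Defaults: a 315 kb window around a 15 kb gene on
chr17 (coordinates consistent with the printed deletion and core
endpoints), 300 background SNVs with allele frequencies uniform on
[0.0005, 0.5], 8 families of which 5 carry the index variant
(frequency 1.315e-5).  The study-shaped configuration
(`paper_shaped_config`) comprises one carrier trio with two affected
siblings, carrier trios truncated centromerically at 74,819,000 and
telomerically at 74,947,400 (bracketing a ~128 kb truth core), one
singleton carrying the index hemizygously opposite the whole-gene deletion
chr17:74,818,633–74,888,183, one plain carrier singleton, and three
non-carrier trios.

What the generator emulates, and what it does not:

* Background chromosomes are sampled site-independently — **no LD**.  The
  analysis rests on rare-allele sharing, for which independent sampling is
  the correct chance-sharing null; but this means passing tests say
  nothing about confounding by population LD structure around a real gene.
* The founder chromosome carries the minor allele at each informative-range
  site with probability `founder_marker_rate` (default 1.0).  This encodes
  marker ascertainment: the sites worth tabulating for a shared haplotype
  are exactly those where it differs from the major allele (a tabulated
  founder haplotype is a list of minor alleles in cis).  Lowering the rate
  weakens the signal and is useful for stress tests.
* Recombination breakpoints are specified positions (controllable truth) or
  drawn uniformly in `"random"` mode — not from a genetic map, so breakpoint
  *positions* carry no realistic distribution, only sides and ordering.
* Carrier trios always transmit through the mother, one child per trio
  except the designated two-sibling family.  Genotype error and missingness
  are i.i.d. per allele/genotype at configurable rates (defaults 0).
* A single `numpy` generator stream seeded once drives every draw, and the
  writers are canonical, so identical (config, seed) give byte-identical
  output files.

The truth ledger (`SimTruth`) records positions, frequencies, the founder
vector, each family's transmitted segment, the realized deletion, the seed
and a config echo, and round-trips through JSON.

## Numerical and formatting conventions

* Coordinates are 1-based inclusive at every interface (VCF convention);
  the genome assembly is an opaque label and no liftover is performed.
* Genotype alleles are coded 0 (ref) / 1 (alt) / `None` (missing);
  multiallelic records are rejected by default, and with splitting enabled
  the non-focal alternate is recoded as ref for the focal site.
* Percentages are reported to one decimal; display frequencies to one
  significant figure; spans floor-divided to whole kb.
* Empty edge cases are explicit: an empty cohort yields an undefined
  (`None`) fraction rather than 0; a window with no informative SNVs
  besides the index is a warning, not an error; a family with no
  resolvable sites is retained as an all-unresolved haplotype.

## Validation strategy and problem sizes

The suite validates logic against independent oracles rather than fixed
expectations wherever possible: per-site phase assignments against
exhaustive enumeration of Mendelian-consistent transmissions (500 random
error-free trios, ≤10 sites, plus a property-based test); the shared core
against an O(n²) scan of every contiguous run containing the index (500
random haplotype sets, ≤20 sites × ≤8 haplotypes); tabulation counts
against naive set-based recounts.  Parameter recovery runs the full
pipeline on the study-shaped simulation at error rate 0 and fixed seed:
recovered core boundaries must lie within one informative-site spacing of
the truth ledger, breakpoint sides must match the planted recombinations,
the deletion family's anchored haplotype must equal the founder vector,
and direct interrogation must accept the simulated founder-carrier
singleton while rejecting 100/100 simulated background non-carriers.
These sizes keep the whole suite in a few seconds on one CPU while leaving
the per-case search spaces (≤2^20 runs, ≤4 phase configurations per site)
exhaustively coverable by the oracles.

## Known limitations

* No statistical phasing: sites unresolvable by pedigree, homozygosity or
  deletion anchoring stay wildcards, which widens cores on sparse data
  rather than mis-assigning them.
* Breakpoint localization is bounded by informative-site spacing; between
  the last concordant and first discordant marker the crossover position is
  unknowable from genotypes.
* The sibling trans rule assumes no intragenic recombination between the
  two candidate sites.
* Deletions are consumed as calls; the package does not discover CNVs, and
  hemizygosity inference trusts the deletion interval's endpoints.
* Founder *age* and population frequency of the shared haplotype are out
  of scope — the core is reported, not dated.
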