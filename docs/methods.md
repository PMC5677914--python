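# Methods

## Scope and model

`pgxcall` implements the analysis chain used to mine pharmacogenetic
information out of clinical sequencing data: per-sample genotype calls at a
fixed 67-locus, 19-gene panel (GRCh37) are turned into star-allele
diplotypes, a CYP2D6 copy-number call, metabolizer phenotypes and a clinical
actionability category, with concordance reports across sequencing and
targeted-genotyping platforms. The controlled-access cohort that motivated
the design cannot be redistributed, so a synthetic cohort generator with a
full ground-truth manifest stands in for it; every pipeline stage has a
recovery test against that manifest.

### Diplotype inference

Genotypes are unphased. For each gene the caller enumerates all star pairs
(a, b) such that at every passing locus the unordered pair of alleles implied
by (a, b) — each haplotype contributing its defining allele or reference —
equals the observed genotype. Loci with missing or failed calls impose no
constraint, so dropout can only widen the candidate set (this monotonicity is
property-tested). Resolution of a multi-candidate set formalizes a manual
clinical judgement: maximize the product of population star frequencies when
supplied, else prefer the pair with fewest non-*1 haplotypes, then canonical
star order; the full candidate list is always retained on the call.

A sample is demoted from *ambiguous* to *no call* when the missing loci leave
candidates spanning more than `key_span` (default 3) distinct activity
scores. This is the operational definition of a missing "key position": with
that much functional spread no single diplotype can responsibly be reported,
and the sample is routed to reflex targeted testing.

Star-allele definitions ship as data files, pre-collapsed to the resolution
the panel's tag variants can discriminate (e.g. *2 sub-alleles sharing
rs16947 fold into *2; *4 is keyed to rs3892097). An observed alt allele
belonging to no definition yields *no call* with the offending rsid reported
rather than inventing a novel allele. The CYP2D6 deletion *5 is never called
from SNP data; it is attached only by copy-number integration (one copy
means the surviving haplotype is paired with *5; hemizygous genotypes look
homozygous, which is why that substitution is always consistent).

### CYP2D6 copy number

Relative coverage (1 = diploid) over three 2 kb windows spanning
chr22:42,522,000–42,528,000 is averaged and classified by inclusive bands:

| copies | band |
|---|---|
| 0 | [0, 0.1] |
| 1 | [0.4, 0.6] |
| 2 | [0.8, 1.2] |
| 3 | [1.4, 1.6] |
| 4 | [1.8, ∞) |

Values in the gaps are *inconclusive* and flagged for reflex testing rather
than forced into a class. Band edges are configuration, validated to be
disjoint and monotone; per-window dispersion is carried as evidence but does
not affect the call.

### Duplication phasing from allelic read ratios

For a copy-number gain with a heterozygous diplotype, the amplified
haplotype is deduced from ref/alt read counts at informative positions
(passing het sites whose alleles distinguish the two haplotypes). With one
haplotype in k−1 of k copies its allele is expected in (k−1)/k of reads
(2/3 at three copies), so a site votes for the haplotype whose allele holds
the major read fraction, provided total depth ≥ `min_depth` (default 75)
and the major fraction ≥ `skew_threshold` (default 0.6). Sites below depth
or skew abstain; conflicting votes give *indeterminate*. A flag switches the
threshold rule to a one-sided binomial test; the default fraction rule stays
closer to visual inspection of read counts. The same rule applies to any
k ≥ 3 under a single-amplified-haplotype model; which haplotype is amplified
at k = 4 is therefore reported, but no attempt is made to distinguish 3+1
from 2+2 copy arrangements.

### Phenotype and actionability

CYP2D6 phenotype comes from the activity score: sum over haplotypes of
allele activity (1 normal, 0.5 decreased, 0 none/*5) times copy
multiplicity, mapped as 0 → poor, (0,1) → intermediate, [1,2] → extensive,
\>2 → ultrarapid. When a gain's amplified haplotype is unassigned, the score
is computed under both assignments; if the classes agree the class is
reported (score left blank), otherwise the phenotype is indeterminate.
Other metabolizer genes are classified from their two alleles' function
classes (two no-function → poor; one no-function or any decreased →
intermediate; any increased otherwise → ultrarapid; else extensive).
Single-tag genes (SLCO1B1, VKORC1, IFNL3, the HLA-A*31:01 / HLA-B*57:01
proxies) use a bundled genotype lookup.

Actionability rules live in a YAML file keyed by gene: each rule lists
triggering phenotype classes, a category (2 = dosing/selection guidance
helps; 3 = associated with serious or life-threatening reactions), drugs,
specialty tags and guideline source. A sample's category is the maximum over
triggered rules; category 1 means nothing triggered. Indeterminate
phenotypes never trigger; they accumulate in a reflex-testing list.
Specialty percentages use the whole cohort as denominator. The borderline
CYP2D6 ultrarapid mapping (codeine-class toxicity) is carried as category 3
and is editable in the rules file.

### Concordance

Cells are compared as unordered allele pairs over the full sample × locus
grid; any cell lacking a passing call on either platform is excluded from
the denominator and counted (`strict_missing` flips those to discordant for
sensitivity analysis). Copy-number comparisons list inconclusive-vs-integer
pairs as "resolved by the other platform", not discordances. Percentages are
half-up rounded (one decimal for concordance, integers for cohort
summaries).

## Synthetic cohorts

The generator draws, per sample: two haplotypes per gene from configurable
star frequencies; a CYP2D6 copy number from the cohort-calibrated
distribution (7:81:9:1 over 1–4 copies, ≈17% CNV carriers), with the
amplified or deleted haplotype chosen uniformly; Hardy–Weinberg genotypes at
loci outside the star tables. Platform call sets derive deterministically
from that truth, then noise is layered on: per-(platform, locus) no-call
probabilities (WGS rs16947 dropout 60/98, a small CYP2D6-wide and global
floor), extra CYP2D6 dropout when a *4 haplotype is present (a deliberate
simplification of homology-driven misalignment), a small WGS
quality-fail rate (encoded in VCFs as half-called genotypes, matching how
ambiguous single-allele calls present), exome capture that omits the two
upstream CYP2D6 promoter loci, and near-complete targeted genotyping.
Read depth is Poisson around `depth_mean` scaled by CN/2 at CYP2D6 loci, with
binomial allelic counts at the copy-composition fraction; window coverage is
Normal(CN/2, σ), truncated at zero, with σ = 0.05 by default. A noise-free
preset zeroes all dropout and makes depths exact for end-to-end recovery
tests. All randomness flows from one integer seed; identical configurations
produce byte-identical fixture files.

`depth_mean` defaults to 150. At the default phasing thresholds (0.6
fraction, 75-read floor) the binomial operating characteristics require
roughly ≥ 135 reads for ≥ 95% recovery of a 2:1 skew and ≥ 100 reads to hold
false assignment on balanced reads below 5%; 150 (hence ~225 at three
copies) satisfies both with margin. Shallower sequencing — common in
practice — degrades recovery gracefully toward *indeterminate*, never toward
confident wrong calls (the null calibration property).

What the generator does **not** emulate: linkage between genes, CYP2D6/CYP2D7
hybrid structural alleles and complex tandem arrangements, GC or mapping
bias in coverage, per-cycle sequencing error, or read-level data. Passing
recovery tests therefore demonstrates the correctness of the calling logic
under the stated noise model, not robustness to structural-variant
interference, which in real data is precisely what produces inconclusive
coverage profiles.

## Numerical and degenerate-input choices

- Rounding is half-up everywhere a percentage is reported (banker's
  rounding would misreport e.g. 96.5).
- Band edges are inclusive on both sides; bands are validated disjoint, so
  every non-negative mean maps to exactly one outcome.
- Half-missing VCF genotypes ("0/.") are `fail_quality` (one allele
  confidently called is not a usable genotype); fully missing genotypes and
  absent records are `missing`. The three statuses partition the grid.
- Star pairs are canonically ordered by star number; resolution tie-breaks
  end in that order, so outputs are deterministic.
- A heterozygous diplotype combined with a one-copy call is contradictory;
  the call keeps its genotype evidence, is flagged for reflex testing, and
  is never silently rewritten.
- Empty cohorts, header-only panels and single-sample inputs are exercised
  in tests; division by zero in any rate reports "not applicable" (None)
  rather than raising.

## Problem sizes in the test suite

Recovery tests use cohorts of 500 (noise-free end-to-end), 1000 (copy-number
class recovery at σ = 0.05), 600 all-duplication samples (phasing recovery),
and 1000 balanced-read impostor trials (null calibration); oracle-equivalence
checks run 100 seeded 20 × 20 matrices and 30 random draws per gene table.
These sizes put binomial sampling error well inside the asserted margins
while keeping the default suite under half a minute.

## Known limitations

- Panel coordinates were transcribed from public GRCh37 annotation; the
  pipeline keys every computation on rsid and the panel's own declared
  coordinates, so coordinate slips would affect only matching of external
  VCFs, not any result computed here.
- Quality is taken from the VCF FILTER column (and half-calls) as given; no
  recalibration is attempted, and vendor-specific native formats are out of
  scope — a thin conversion to VCF + coverage TSV is assumed upstream.
- Phenotype is genotype-derived only; developmental/ontogeny effects on
  enzyme activity are explicitly not modeled.
- No statistical phasing or imputation; no HLA typing beyond tag SNPs; no
  liftover between genome builds.
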