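# Methods

`lintseg` models the stepwise genetic dissection of cotton lint percentage
(lint%): a small number of major loci — the At and Dt homoeologs of
*MYB25-like* and *HD1* in tetraploid cotton — segregate functional and
loss-of-function alleles that jointly determine lint% and the seed-fuzz
phenotype. The package provides (1) a cross simulator that generates such
populations, (2) an extreme-pool bulk-segregant scan, (3) genotype-class
statistics, and (4) diversity-panel haplotype and allele-pyramiding
analysis. This note records the models, parameter choices and numerical
conventions.

## Genetic model

**Genome.** A desk-scale stand-in genome of 4 chromosomes x 100 Mbp
(Chr-A12, Chr-D12, Chr-A06, Chr-D06) with markers every 100 kb and one
causal locus mid-chromosome, in place of the 26-chromosome tetraploid
genome. Nothing downstream depends on genome size beyond window counts; the
four causal loci are unlinked in both.

**Meiosis.** Haldane map function without interference: between adjacent
markers at map distance `d` Morgans, the recombination fraction is
`r = (1 - e^(-2d))/2`, with `d = rate_cM_per_Mbp * delta_bp / 1e6 / 100`.
One genome-wide rate (default 1 cM/Mbp) is used because no cross-specific
genetic map is available; chromosomes assort independently. Crossovers are
drawn per interval as independent Bernoulli events, which reproduces the
Haldane counts exactly.

**Cross types.** `F1`; `F2` (self of one simulated F1); `BC1F2` (self of
one (F1 x recurrent parent) offspring — parent A is recurrent); `F2:3`
(self of a *named* plant, passed as the first parent); `SIBCROSS_F2` (cross
of two named segregants, then self of one F1). Founder lines are fully
inbred, so allele values double as parental-origin tags.

**Genotype -> lint%.** The expected lint% of a joint genotype is
`baseline - sum of per-locus penalties`, each locus contributing a penalty
indexed by its loss-of-function dosage (0/1/2), clipped at 0; lint% of
exactly 0 encodes the fiberless class. Epistatic masking is a rule
`(masked, masking, required_dosage)`: the masked locus's penalty is applied
only when the masking locus has the stated dosage. An explicit
joint-genotype table can replace the additive combination. Observed lint%
adds Gaussian noise (default sd = 2 lint points, consistent with
within-class spreads that span roughly 5-point bins) and re-clips at 0.

The default four-locus calibration sets baseline 25.33 and homozygous
penalties 13.25 (*MYB25-like_At*), 8.50 (*HD1_At*), 6.23 (*MYB25-like_Dt*)
and 5.31 (*HD1_Dt*) — reproducing the observed ordering of single-locus
homozygous-mutant class means — with one masking rule: the *HD1_Dt* penalty
is expressed only when *MYB25-like_At* is homozygous loss-of-function.
This is a calibration chosen to reproduce reported class means, not a
measured genetic model, and every number is overridable in config. The
all-mutant genotype's expected lint% clips to 0 (fiberless), matching the
observation that only fully (or nearly fully) mutant segregants are
fiberless.

**Seed fuzz.** Fuzzless iff the individual carries >=1 loss-of-function
allele at the dominant-fuzzless locus (*MYB25-like_At*) OR is homozygous
loss-of-function at the recessive-fuzzless locus (*MYB25-like_Dt*). The
fiberless class is the subset with lint% = 0.

**Founders.** 'SL1-7-1' carries loss-of-function *MYB25-like_At* and
*HD1_At*; 'T586' *MYB25-like_At*; 'Pima S-7' *MYB25-like_Dt* and *HD1_At*;
'Sicala V-2' none. Whether 'SL1-7-1' also carries a defective *HD1_Dt* is
unresolved (its expression is consistently low); the default leaves it
functional, with a `sl_hd1dt_dysfunctional` switch.

## Pooled sequencing model

Counts, not reads: per SNP, depth ~ Poisson(mean depth, default 25x,
floored at 1) and alternate count ~ Binomial(depth, f), where f is the
alternate-allele fraction among the `2 x pool size` pooled chromosomes.
"Alternate" is defined against a named reference parent (the mapping
reference in a real scan); the CLI/pipeline default treats parent B as
reference. Not modelled: sequencing error, mapping bias, index hopping and
depth overdispersion — so synthetic pool frequencies are slightly cleaner
than real ones, and passing calibration here does not bound real-data error
rates.

## Extreme-pool scan

Per-SNP pool frequencies (alt/(ref+alt), SNPs below `min_depth` dropped)
are averaged, unweighted, in overlapping windows: 1-Mbp windows with
0.5-Mbp step by default (500-kb/250-kb for the backcross designs). The window
sizes follow the study designs being emulated; the overlap step is not
fixed there, and 50% (step = window/2) is the package's reading,
configurable. Windows start at 1, 1+step, ...;
if the last full window stops short of the chromosome end one truncated
window is appended. Windows with fewer than `min_snps_per_window` (default
10) SNPs in either pool are flagged and never seed a region.

A window is a candidate iff one pool's mean exceeds `high_threshold`
(default 0.8) while the other pool's lies in `mid_band` (default
[0.35, 0.65] — the "~0.5" condition formalised as the band reaching halfway
toward both 0 and the 0.8 threshold). Maximal runs of consecutive candidate
windows with the same extreme pool merge into regions; the top region is
the one with the highest peak frequency.

**Why ~0.5, mechanistically.** The signature arises from trait-conditioned
bulk selection. With a locus that is dominant for the fuzzless seed trait
and (near-)recessive for low lint%, bulks drawn from fuzzless segregants
all carry >=1 mutant allele: the low-lint% bulk is homozygous mutant
(frequency ~1.0) and the high-lint% bulk heterozygous (~0.5). The
detection scenario (`lintseg.scenarios.detection_scan`) therefore simulates
101 F2 with one such locus (class means 39/39/6, noise sd 2) and draws both
19-member bulks from the fuzzless segregants by lint% rank. Without that
conditioning — e.g. a purely lint-recessive locus with bulks ranked on
lint% alone — the high bulk's expected frequency is 1/3 (the 1:2
homozygous:heterozygous ratio among non-mutant F2), which sits on the edge
of the band and makes the stated rule unreliable; the ST-type preset with
an intermediate heterozygote (class means 20.47/13.75/5.14) drives the high
bulk to ~0.1, where the rule cannot fire at all. Both presets are shipped;
the rule-based caller is validated on the conditioned design, and the
ST-type design is validated on the low-bulk signal it does produce.

**Null calibration.** On a no-effect F2 split into two random bulks of
~50, windowed frequencies stay in [0.35, 0.65] for >=99% of windows and
essentially no windows pass the candidate rule. Bulk size matters here:
the window-level standard deviation of a bulk's allele frequency is
dominated by genotype sampling (~`sqrt(p(1-p)/2m)` for m individuals), so
19-member bulks fluctuate with sd ~0.08 and would leave ~6% of null
windows outside the band with a fully correct implementation; the
calibration therefore uses whole-population random halves (sd ~0.046).

## Genotype-class statistics

* `lint_percent` = 100 x lint weight / unginned seed-cotton weight.
* Segregation chi-square: `sum (obs-exp)^2 / exp` with the ratio scaled to
  the observed total, no continuity correction (the worked example
  0.011 for 95:31 vs 3:1 requires the uncorrected statistic), p from the
  upper chi-square tail with k-1 df. At n=126 the exact size of the
  nominal-0.05 test is 3.9% — below nominal, as expected for a discrete
  statistic.
* Pairwise class comparisons: two-tailed two-sample t-tests, Welch by
  default (the variance assumption behind the original tables is
  unstated; pooled-variance is a switch). No multiple-testing correction,
  matching the tables being reproduced. Compact letters use the
  insert-and-absorb algorithm, so two classes share a letter iff their
  pairwise p >= alpha; letters are named in ascending-mean order ('a' on
  the lowest mean, the tables' printed convention). Classes with n < 2 are
  reported without a letter and flagged. Two zero-variance identical
  samples get p = 1 (indistinguishable), differing constants p = 0.
* Distribution tables: first bin counts exactly-zero (fiberless) values;
  remaining bins are half-open (lo, hi] with an overflow bin above the last
  edge, inferred from the "0" vs "0.01-5%" column convention.

## Panel analysis

* SNP filters: MAF >= 0.05, depth in [3, 50], quality >= 20, missing rate
  <= 20%; a site must pass all four.
* Haplotype assignment per gene (+/- 2 kb site set): accessions
  heterozygous at > 20% of the gene's polymorphic sites are HET (the
  threshold is the package's choice; no standard quantification exists);
  the rest cluster by exact SNP pattern, the two largest groups are the
  major haplotypes, the higher-mean-lint% group is labelled LP, minor
  patterns join the nearer major by Hamming distance (ties -> HET).
  Deterministic pattern clustering replaces the original NJ-tree grouping:
  the grouping, not the tree, is what downstream analysis consumes, and
  exact-pattern clustering is reproducible without tie-break ambiguity.
  A gene with no polymorphic site yields no calls and a warning (the
  *G. barbadense* *MYB25-like_Dt* situation). A single-SNP locus is just a
  degenerate one-site "gene".
* Mann-Whitney: U from midrank sums; for n1+n2 <= 12 the two-sided p is the
  doubled exact tail over all rank assignments (ties handled exactly);
  otherwise a tie-corrected normal approximation with continuity
  correction. The exact cut-off at 12 keeps enumeration under C(12,6)=924
  assignments.
* Pyramiding: LP-allele count per accession over the four genes, compared
  with exact Binomial(4, 1/2) percentages (6.25/25/37.5/25/6.25, computed
  from integer combinatorics so they are exact in floating point).
  Heterozygous loci either do not count as LP (default — keeps per-locus LP
  a binary carrier state consistent with the binomial reference) or drop
  the accession (`exclude_het_accessions`); both policies are exposed
  because the original accession filtering is not fully specified.
  Panel lint% values are consumed as given (in real data they would be
  BLUPs; the generator emits them directly — BLUP fitting is out of scope).

## Synthetic panel generator

Each accession draws per gene: HET with probability `het_rate` (default
0.07, matching observed heterozygous shares of ~5-12%), otherwise lp with
probability `lp_freqs[gene]`, else LP. Haplotypes are realised as fixed
per-gene SNP-code vectors (LP = all 0, lp = a random 0/2 vector with >=1
alternate site, HET = 1 at differing sites). lint% = baseline (default 31)
+ per-gene group-mean effects (het = midpoint) - fuzzless penalty (default
12 points, the approximate fuzzless-vs-fuzzy gap) + Gaussian noise
(default sd 4), clipped at 0. The fuzzless fraction defaults to 81/723.
Not emulated: linkage disequilibrium between genes, population structure,
kinship, missing genotypes and genotyping error — so panel tests validate
the calling and counting machinery, not robustness to those artefacts.

## Reproducibility and problem sizes

All randomness flows from one root seed through named child streams
(pipeline stages hash `root_seed:stage`); identical config gives
byte-identical TSV outputs, hash-recorded in the manifest. Validation
problem sizes: 50 seeded scan replicates for detection power, 20 for null
false-call rate, 10 for band coverage; 10 x 101 F2 for Mendelian
conservation (the per-marker "within 3 SD" invariant is asserted as
genome-wide mean within 3 SD plus >=99% of per-marker z-scores within 3,
the well-posed form for thousands of linked markers); 20,000 F2 for noisy
class-mean recovery; 1,000 random tables and all group sizes with
n1+n2 <= 10 for the statistic oracles.

## Known limitations

Counts-only sequencing (no reads, no alignment, no caller artefacts); a
single genome-wide recombination rate with no interference; additive
penalties with at most rule-based epistasis; panel genes drawn
independently (no LD); the candidate rule is a threshold rule — no
confidence interval or G'-style statistic is attached to regions, by
design. Real-data tables and p-values depend on unreleased phenotypes and
read sets and are represented here only through the worked examples,
qualitative patterns and calibrations above.
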