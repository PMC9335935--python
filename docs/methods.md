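# Methods

## The inference problem

In an XY system, a nonrecombining sex-determining region (SDR) fixes one
haplotype on the X and one on the Y.  With short-read resequencing of males
and females (no phased sex chromosomes), X–Y differentiation must be read
off sex-stratified genotype patterns: males carry one copy of each
gametolog, females two X copies.  sdrkit implements three layers — window
statistics, per-site sex-linkage calls, and cross-species allele-sharing —
plus a generator that simulates the genotype and depth structure those
layers assume.

## Window statistics

Windows tile each chromosome without overlap at a configured width; the
last window may be short.  Coordinates in outputs are BED-style 0-based
half-open; VCF positions stay 1-based internally.  Undefined windows are
written as `NA`, never dropped.

* **F_ST between the sexes.**  Per-site Weir & Cockerham (1984) variance
  components (a, b, c) for two groups (males, females) computed from group
  sample sizes, allele frequencies and observed heterozygote frequencies;
  window values are the ratio of sums Σa / Σ(a+b+c) over informative sites.
  Sites monomorphic across both sexes return (0,0,0) and are excluded;
  sites where a sex has no called genotype (or the pooled size cannot
  support the estimator) are undefined.  Negative values are reported as
  computed, not clamped, matching the estimator's behaviour.
* **Read-depth ratio.**  Each sample's per-window depth is divided by that
  sample's autosome-wide mean before averaging within sexes, so library-size
  differences cancel — important with the very small cohorts this analysis
  runs at.  Raw fold-coverage mode is available (`normalize=False`) for
  parity with coverage tools.  A fully deleted Y halves male depth, putting
  the M:F ratio at 0.5.
* **SNP density ratio.**  Sites polymorphic *within* the male samples over
  sites polymorphic within the female samples.  "Polymorphic within sex"
  (both alleles observed among that sex's called genotypes) was chosen over
  "called within sex"; the alternative changes only the shared denominator.
* **Densities** of SDR-like and female-specific SNPs per window (counts).
* **Envelope.**  Empirical 2.5%/97.5% quantiles over autosomal windows,
  linear interpolation between order statistics (stated so results are
  reproducible across languages).  At least 40 defined windows are required.
  By construction such an envelope flags ~5% of autosomal windows; the test
  suite checks this calibration rather than treating envelope excursions as
  evidence on their own.
* **Smoothing.**  Tricube-weighted local linear regression (LOWESS, span
  0.3 of points, no robustness iterations), for display only; no
  classification consumes smoothed values.

## Per-site sex-linkage calls

SDR-like: one allele appears in every called male, always heterozygous, and
in no called female; requires ≥ 2 called individuals per sex (configurable).
Either ref or alt may qualify and the call records which.  Female-specific:
an allele carried by ≥ 1 female and 0 males (the ≥ 1 threshold is
configurable; requiring all females would be stricter).  Sites with all of
one sex missing are `insufficient_data`, never positive calls.  The two
labels are mutually exclusive at a site because the Y-like allele and its
partner both occur in every male.  The autosomal SDR-like rate is the
empirical false-positive control; exact enumeration under Hardy–Weinberg
(e.g. 3.125% at p = 0.5 with 2 + 2 individuals) shows how quickly it falls
as cohorts grow.

## Allele sharing and the ten trees

Per species, a site is accepted only if all called females are homozygous
for one allele (the X allele) and all called males are either all
heterozygous (the other allele is on the Y) or all homozygous for the
females' allele (X and Y share it).  All-males-opposite-homozygote, mixed
males, polymorphic females, and under-sampled sites are rejected with
recorded reasons.  Outgroup polarization requires every called outgroup
individual, across both outgroup species, homozygous for the same allele.
The derived allele's presence pattern over {Xp, Yp, Xw, Yw} is informative
at sizes 2–3 and maps bijectively onto trees 1–10 via one editable table
(`tree_share.TREE_OF_PATTERN`).  Trees 1–5 and 7 are pinned by their
descriptions (Y–Y and X–X sharing for 1–2, species-private pairs for 3–4,
{Xp,Xw,Yw} for 5, {Yp,Xw,Yw} for 7); 6 and 8 are their partners differing in
which wingei chromosomes join, and 9–10 are the two implausible
cross-pairings.  The table is data, so the numbering can be realigned
without code changes.

No minor-allele-frequency or missingness prefilter is applied inside the
tree-share stage: a per-species MAF filter would discard precisely the
sites fixed for different alleles in the two species — the dominant
informative class.  Optional per-species prefilters exist in the filter
cascade for the per-sex frequency analyses where they belong.

The hypothesis summary maps counts onto four histories with an explicitly
reported rule: homologous if (n1+n2)/N ≥ 0.5; else turnover-in-wingei if n5
exceeds the homoplasy expectation (n9+n10)/2 by more than 3√(expectation+1)
(a Poisson-tail heuristic — trees 9–10 can arise only from homoplasy,
error or introgression, so they estimate the homoplasy floor); else
independent if (n3+n4)/N ≥ 0.5; else ambiguous.  This rule is a labelled
reporting heuristic; all fractions are emitted regardless, under both the
informative-site denominator and the all-sites denominator, since the two
are easy to conflate when comparing studies.

## Filter cascade

Fixed order: quality → indel → biallelic SNP → per-genotype depth masking →
singleton → missingness → MAF.  The order mirrors how the underlying tools
are usually chained (quality at calling; indel/biallelic selection;
genotype-level depth; site-level cohort filters).  Depth below the
threshold masks the genotype to missing rather than dropping the site,
which then falls to the missingness rule.  A singleton is a site whose
minor allele occurs exactly once over called alleles (one heterozygote
carrying the only copy); a single homozygote carries two copies and is not
a singleton.  MAF uses called alleles only.  Defaults: quality ≥ 20; the
genotype-depth threshold is 3 for multi-species mapping to a distant
high-quality reference and 10 for conspecific mapping, following the two
pipeline variants this analysis is used in.  The report reconciles input,
per-stage removals, and output exactly, and a second pass removes nothing.
The singleton filter runs on the full cohort; species subsets are
re-filtered after splitting (the alternative — per-species singleton
filtering first — is not offered, to keep reports comparable).

All genotypes are treated as diploid calls.  Hemizygosity never appears
directly: variant callers impute a homozygote at sites deleted from the Y,
and that is exactly how the simulator's artifact layer produces it.

## The simulator

A per-site generative model on a fixed four-tip gametolog tree, not a full
coalescent: adequate to produce the allele-sharing patterns, depth
degeneration and caller artifacts the analysis consumes, but it has no
recombination graph, no linkage between sites, no selection, and no
sequence-level reads.  Within-species polymorphism enters only through
genotype error and exchangeable (PAR/autosome) sites, so fixation-filter
rejections are exercised but realistic within-SDR diversity is not
represented.  Passing tests therefore validate the analysis logic under the
stated model, not its behaviour on every feature of real data.

* **Trees.**  homologous: ((Yp,Yw),(Xp,Xw)), X–Y split at `t_sdr`, species
  splits at `t_s`.  independent: ((Xp,Yp),(Xw,Yw)) with per-species X–Y
  splits `t_p`, `t_w`.  turnover_wingei: (((Xw,Yw),Xp),Yp) — the old Y
  survives in *picta* (terminal length `t_sdr`), the wingei Y derives from
  an X at `t_to`.  Y-labelled branches multiply the mutation rate by α.
* **Mutations.**  Per site, Poisson counts per branch with rate
  μ × length × (α on Y branches); the derived allele is carried by the tips
  below every mutated branch.  With homoplasy off, sites with more than one
  mutated branch are discarded, so observed informative fractions equal the
  internal-branch rate shares computed by `expected_internal_fractions`
  exactly in expectation.  With homoplasy on, multi-branch sites are kept
  and generate the rare trees 5–10.
* **Exchangeable sites.**  Allele frequency from Beta(0.5, 0.5) (a U-shaped
  site-frequency spectrum typical of resequencing SNP sets), Hardy–Weinberg
  genotypes, X and Y exchangeable, outgroups included — which also
  exercises outgroup-rejection paths.
* **Artifacts.**  With probability `d_p`, an SDR site is deleted on Yp:
  every picta male becomes the homozygote for his X allele and his per-site
  depth halves (likewise `d_w`).  `mapping_failure` additionally thins male
  window depth in the SDR.  Genotype error flips a single allele copy per
  affected genotype.  Per-site read depth is Poisson(λ × copies/2) and a
  zero-depth genotype is recorded as missing; per-window depth is
  Poisson(λ × window × copies/2)/window.
* **Determinism.**  One master seed; each site and window uses a
  counter-derived Philox substream, so enlarging a simulation never
  perturbs earlier sites, and identical configs give byte-identical output
  bundles.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| t_s | 1.0 | focal-species split (arbitrary time units; only ratios matter) |
| t_sdr | 2.0 | ancestral SDR origin (homologous / turnover) |
| t_p, t_w | 0.5 | per-species SDR origins (independent) |
| t_to | 0.5 | turnover time |
| μ | 0.05 | mutations per site per unit time per branch |
| α | 1.0 | Y-branch rate multiplier (male-biased mutation) |
| λ | 30 | mean depth, reads per bp per diploid genome |
| samples | 3M+3F per focal species; 1 per outgroup | resequencing design the analysis targets |
| chromosome | 2 Mb with a 1 Mb SDR; two 1 Mb autosomes | desk-scale geometry |
| SNP density | 0.013/bp | segregating-site density of dense resequencing data |

The divergence times are not biological estimates: no calibrated times
exist for these splits at SDR resolution, so the defaults are round values
chosen once to give comparable internal and terminal branches, and they are
shipped in the test configurations rather than presented as inferences.
Validation simulations scale the chromosome to 3 Mb with a 2.8 Mb SDR at
density 0.02 so that each history yields well over 2000 informative sites
for tight binomial comparisons.

## Numerical conventions and degenerate inputs

Quantiles: linear interpolation between order statistics.  F_ST windows
with no informative site, depth windows with zero female mean, and density
ratios with a zero denominator are NaN/`NA`.  Missing VCF QUAL passes the
quality filter (unknown is not evidence of low quality).  Empty tables
filter to empty tables with zeroed reports.  The smoother passes through
series shorter than 10 points with a warning.  Sites reaching the tree
stage must be biallelic SNPs (asserted), which the upstream cascade
guarantees.

## Known limitations

* The ten-tree logic covers exactly two focal species with XY systems and
  two outgroup species; more species or ZW systems need a different table.
* The simulator's SDR is a single block — no strata with distinct ages, no
  partial recombination within the SDR, and no polymorphic inversions of
  the kind that can produce localized female-specific allele excesses.
* Depth tables and per-site DP are drawn independently; real coverage is
  autocorrelated along the genome.
* The verdict rule is a reporting heuristic for simulated-scale counts;
  on real data the tree counts and rejection tallies, not the one-word
  verdict, are the result.
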