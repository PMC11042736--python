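# Methods

## Problem setting

A target-activated ribonuclease (the motivating case is a Cas13a-type
effector expressed in *E. coli*) cleaves bystander RNAs once triggered.
Each cleavage produces a 5′-monophosphate end that ligation-based RNA-seq
library preparation captures, so comparing per-nucleotide 5′-end counts
between RNase-active ("targeting") and control ("nontargeting") libraries
localizes cleavage to single phosphodiester bonds. Two confounders shape
the design: (i) transcription starts also concentrate 5′ ends, so an
independent contrast of RppH-treated vs untreated libraries (RppH converts
5′-PPP primary ends into ligatable 5′-P) flags TSS positions; and (ii)
count overdispersion across biological replicates, handled with a
negative-binomial model.

## Statistical model

Counts at retained position *p* in library *l* are modeled
NB(μ_pl, φ) with log μ_pl = β_p,g(l) + o_l, where o_l = log(N_l·f_l)
combines the library size N_l (number of retained fragments) and the TMM
factor f_l, and g(l) is a two-level condition. This is a one-way GLM per
position; nothing beyond a single two-level factor is supported by design.

**Filtering.** Positions with < 10 CPM in fewer than 3 targeting-role
replicates are dropped before any model fitting. CPM uses raw library
sizes (the filter precedes normalization), and only the signal-bearing
group's columns enter the criterion, so a position present only in
controls never reaches the test.

**TMM.** The scaling factor of library *j* against the reference library
(the one whose 75th-percentile count fraction is closest to the mean of
those) is 2 to the precision-weighted mean of per-position log2 ratios M,
after discarding the top and bottom 30% of M and 5% of average abundance A;
weights are inverse delta-method variances; factors are rescaled to unit
geometric mean. Positions with a zero in either library are excluded from
M; a library with no positive overlap with the reference keeps factor 1
with a warning. The implementation was checked against an independent
step-by-step recomputation (tests) to 1e-8.

**Dispersion.** A single common φ is estimated by maximizing the Cox–Reid
adjusted profile likelihood Σ_p [ll_p(φ) − ½ log det(XᵀWX)_p] over a
log-spaced grid (1e-6 … 10, 19 points) refined by golden-section search;
the lower bound is 1e-6. For the one-way design the determinant reduces to
the product of within-group weight sums with W = μ/(1+φμ). A per-position
method-of-moments mode exists for sensitivity analysis (misspecification
stress tests), not for routine use. On simulated data the estimator
recovers φ = 0.2 within ±0.01 at 2000 positions and collapses to the lower
bound on Poisson data.

**Testing.** With φ fixed, group means are fit by vectorized Fisher scoring
(tolerance 1e-8 on the step, 100 iterations; all-zero groups take the
boundary MLE μ = 0). The statistic 2(ll_full − ll_null) is referred to
χ²(1); at φ = 0 the fit is the closed-form Poisson MLE and the statistic
equals the Poisson deviance. Non-converged positions get p = NA and are
excluded from BH. log2FC is the difference of group intercepts in log2
units; when one group has zero counts the infinite estimate is reported as
±20 — a sentinel that keeps the ordering total without inserting
pseudocounts into the likelihood (an optional `prior_count` provides
conventional shrinkage instead). BH correction is applied once per
contrast over all retained positions.

**Calling.** Positions are ordered by FDR ascending with a deterministic
tie-break (|log2FC| descending, then reference/strand/position); the top
100 are taken first, then those with log2FC strictly above 4 are kept —
possibly none. This order of operations (rank first, threshold second)
means the called set can be much smaller than 100.

**TSS contrast.** Identical machinery with RppH-treated libraries in the
targeting role, run within one condition so condition-driven variance does
not contaminate the treatment contrast. Because the treated/untreated
ratio at a TSS is bounded by the RppH conversion efficiency (8-fold in the
default generator, hence log2FC ≤ 3), the TSS contrast uses a lower
fold-change threshold (2.0 by default in the CLI) — the cleavage
threshold of 4 would be unreachable in principle. The positional
cross-check intersects the top-k positions of the two ranked sets and is
the package's guard that called cleavage sites are not relabeled
transcription starts.

## Coordinates and conventions

Internally 0-based half-open; all report files 1-based. A called 5′ end at
position p means the bond 5′ of p (transcript orientation) was cut; the
logo window is the 5 transcript-sense nucleotides on each side of that
bond, i.e. genomic [p−5, p+5) on the plus strand and the reverse
complement of [p−4, p+6) on the minus strand. The window convention (5+5
around the scissile bond) is a package choice among the two defensible
readings of a "10 nt surrounding" window. tRNA anticodon loops use the
structural numbering 32–38 with the anticodon (N1–N3) at 34–36; loop
coordinates come from the annotation's N1 offset, not from alignment or
structure prediction — for the anticodon loop itself this is exact, and it
keeps the package free of a multiple-alignment dependency. Identical-
sequence tRNA genes are collapsed for transcript-level set operations by
longest-common-prefix naming (glnU + glnW → glnUW); intersections across
experiments are computed on transcripts because the same RNA may be cut at
different positions in different experiments.

## Synthetic data generator

The generator emulates the statistical structure the test assumes, at desk
scale:

- **Genome**: one random reference (~16 kb at defaults) with 12 CDSs
  (200–600 nt) and 24 tRNA genes (76 nt, anticodon N1 at transcript offset
  34). tRNA gene copies are allocated with a 5:1 bias toward U-rich
  anticodons (UUU/UUC/UUG/UGU vs four others), mirroring multi-copy
  bacterial tRNA families; copies within a family are byte-identical so
  collapsing is exercised.
- **Abundance**: per-position weights of 75 (tRNA), 8 (CDS) with a
  lognormal feature-level spread (σ = 0.08), plus 800 sparse background
  positions carrying 0.3% of the mass. At the default depth of 180,000
  fragments per library this puts tRNA positions at a baseline mean of
  ~55–80 counts and CDS positions at ~8 — comfortably above and safely
  below/above the 10-CPM filter respectively. Deliberately absent are
  positions hovering at the filter boundary: in deep real libraries the
  CPM filter corresponds to tens of counts, and the generator reproduces
  that regime rather than the boundary artifacts of shallow sampling.
- **Libraries**: 3 replicates per condition (and per RppH treatment when
  enabled), NB dispersion 0.15 shared by all positions (a per-position
  gamma-dispersed mode exists to stress misspecification). Library sizes
  are realized column sums.
- **TSS signal**: every feature 5′ start carries concentrated mass
  (12× the local background) present in both conditions; untreated
  libraries see that mass reduced 8-fold (the RppH conversion efficiency).
  Explicit extra TSSs can be implanted with their own strength/enrichment.
- **Cleavage signal**: implants at named tRNA loop positions multiply the
  targeting-condition mean by 2^effect (default 20 implants, effect 6, at
  N1); nontargeting libraries are untouched. Fragment counts rise
  accordingly, as they do in real libraries — the condition groups differ
  in size and TMM absorbs the composition shift.
- **Alignments**: every counted 5′ end becomes one properly paired 2×35 nt
  read pair (fragment lengths 60–180 nt) whose 5′-most base sits exactly at
  the counted position, so re-counting the SAM reproduces the count table
  bit for bit. Sequencing errors, quality variation and adapters are out
  of scope.

All randomness flows from a single seed through named per-stage
generators; identical seeds give byte-identical FASTA/BED/SAM/TSV outputs.

What passing tests on these data do *not* show: robustness to mapping
artifacts (multi-mapping tRNA reads collapse here because counts are
generated per locus), to position-correlated fragmentation bias, to
5′-end chemistry differences between cleavage products, or to dispersion
that varies systematically with abundance. The generator's NB assumption
matches the test's; real-data dispersion misspecification is only probed
by the optional per-position mode.

## Problem sizes used in validation

Recovery checks run the full SAM → count → call path on 10 seeds (20
implants each); null calibration uses 50 seeds of ~6,000 retained
positions; the TSS discrimination check implants 5 standalone TSSs and 3
dual (TSS + cleavage) positions. The acceptance script scales recovery to
3 seeds and null calibration to 20 seeds, which reproduces the same
quantities in about a minute.

## Known limitations

- Only two-group contrasts; no multi-factor designs, quasi-likelihood F
  tests or exact tests.
- Common dispersion is the default; no empirical-Bayes moderation toward a
  trend.
- Fragment reconstruction ignores splicing (no spliced transcripts in
  scope) and does not deduplicate.
- The ±20 sentinel for infinite fold changes is a reporting convention;
  ranking among multiple all-zero-control sites then falls back to the
  statistic via the FDR ordering.
- The logo renderer is a minimal matplotlib letter plot intended for quick
  inspection, not publication graphics.
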