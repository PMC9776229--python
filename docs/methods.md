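# Methods

## Coverage model and conventions

All coordinates are BED-convention 0-based half-open; region length is
`end − start`. This convention is chosen because BED is both an input
(target regions, per-base tracks) and the main output format (blacklists,
drops, browser tracks); covdata region starts are interpreted the same way,
and users whose upstream counter emits 1-based starts must shift them.

Percent coverage is kept on the 0–100 scale throughout (the quality rules
are phrased in percent). Counts are validated on load: a count may not
exceed the region length, and counts must be non-increasing across the
depth grid for each (region, sample) — a base covered at ≥500X is covered
at ≥250X. Violations are hard errors by default; a lenient flag demotes
them to warnings for exploratory use. Duplicate region keys within one
sample are always hard errors, because silent aggregation could mask
panel-design bugs.

Medians use the mean of the two central order statistics for even counts;
quartiles interpolate linearly between order statistics (the type-7
convention, the default of the common statistical environments). All
rule comparisons are inclusive: a value exactly at the bound passes
(MPC ≥ 75, Q1 ≥ 75, DV200 ≥ 20, ΔCq ≤ 5, MAD ≤ 0.21, insert size ≥ 70).
Correspondingly, blacklisting uses the strict complement (MPC < 75
blacklists), so a region at exactly 75 is kept.

### Run-level MPC summary

MPC is a per-region quantity; the run rule needs a scalar per depth. The
default aggregation is the median of MPC over regions, selectable per
config as the mean or as the percent of regions at or above the rule
threshold ("fraction"). The median reading was chosen as the most robust
single-number summary and because it makes the run rule structurally
parallel to the sample rule (both are order statistics of a per-exon
distribution); the alternatives remain one config switch away.

### Blacklisting

Blacklists are computed from the cohort MPC (cross-sample), not per-sample
values: they are run-level artifacts describing where the *panel* is
unreliable. Per-sample depletion is reported separately by the Q1 sample
rule. Because percent coverage is non-increasing in depth, blacklists are
nested: anything blacklisted at 250X is blacklisted at 500X. BED scores
are `round(10 × MPC)` so the rule boundary is visible at score 750.

### Coverage MAD

For one sample, per-region mean depths over the CNV region set are divided
by their median (so the normalized median is 1); the statistic is the
median of |x − 1|, compliant when ≤ 0.21. The definition is linear-scale
and scale-invariant by construction. Whether upstream CNV pipelines
compute their MAD on log-fold changes is not observable from the outside;
the linear robust definition above is this package's definition and the
0.21 bound is a config default, not hard-coded.

### Coverage drops

Narrow and highly covered are not self-defining; the implemented criterion
is: an exon is eligible when its per-base median depth is ≥ the
eligibility depth (default 100X); a drop is a maximal run of ≥ `min_width`
(default 10 bp) consecutive bases each strictly below `drop_ratio`
(default 0.5) × the exon median depth; runs separated by at least one
passing base are distinct. All three parameters are exposed in config and
CLI help. The exon median is computed per sample per exon from the
per-base profile — region-level counts cannot localize drops. Drops are
clipped to exon boundaries, which excludes boundary-decay ramps by
construction. Detected drops are maximal (extendable by no base on either
side) and pairwise disjoint; raising `drop_ratio` can only widen or add
drops, raising `min_width` can only remove them.

## Statistics layer

- **Descriptives**: sd uses the n−1 denominator; a single-value group
  reports sd as missing, never 0.
- **Kruskal–Wallis**: tie-corrected H with a chi-square reference
  (k−1 df); an all-constant metric returns H = 0, p = 1 rather than an
  error. With two groups the statistic is the square of the tie-corrected
  rank-sum z, so p-values coincide with the asymptotic Mann–Whitney test.
- **Pairwise follow-ups**: all k(k−1)/2 pairs, Mann–Whitney by default or
  the Brown–Mood median test (counts above the pooled grand median,
  two-sided Fisher exact on the 2×2 table). FDR adjustment is
  Benjamini–Hochberg over the pair family (Benjamini–Yekutieli
  selectable). Group labels with no observations are skipped with a
  warning record and excluded from the adjustment family.
- **Paired library test**: Wilcoxon signed-rank on pre-capture vs enriched
  concentrations per nucleic type; zero differences are dropped before
  ranking (classic convention; the Pratt signed-zero method is a flag).
  The p-value is exact for ≤ 25 untied non-zero differences, otherwise a
  tie-corrected normal approximation. The direction of the median change
  is reported alongside the p-value.
- **Kendall tau**: tau-b with tie correction. The 95% CI is the normal
  approximation tau ± 1.96·SE with the asymptotic null standard error
  √(2(2n+5)/(9n(n−1))), clipped to [−1, 1]; this CI formula is this
  package's declared choice. Strata with fewer than 3 complete pairs are
  skipped with a warning; missing values are dropped pairwise.
- All tests are two-sided; 0.05 is the significance convention.

Two compliance-rule presets ship: `inclusion` (sample-inclusion bounds:
absorbance windows 1.6–1.8 for DNA and 1.8–2.0 for RNA at 260/280,
260/230 ≥ 2.0, DV200 ≥ 20%, ΔCq ≤ 5) and `compliant_value` (per-metric
run-QC bounds, including insert size ≥ 70 bp and coverage MAD ≤ 0.21).
The two sets disagree on the DNA 260/280 bound and are deliberately never
merged; the user picks a preset.

## Synthetic data generator

The generator emulates two coverage-profile classes: high-coverage exons
(flat plateau, linear decay ramps over the outer 15 bp starting at half
the plateau — the within-target tail of the decay beyond the exon–intron
boundary — plus integer Gaussian noise, sd 5% of the plateau) and
low-coverage exons (plateau scaled to 5–40%, irregular, with near-zero
breakoff segments growing inward from the edges). Per-region plateaus are
lognormal around a median of 648X with sigma 0.30 (a DNA-like deep-panel
scale with realistic heterogeneity, under which depletion at 500X is
common and at 50–100X rare); per-sample factors are lognormal with sigma
0.08. Covdata counts are always derived from the per-base profiles by
direct thresholding, so region-level and base-level modules see one
consistent world.

Controlled injections, all recorded in the ground-truth manifest:

- **rectangular drops** into high-coverage exons (defaults: width 11–30 bp,
  depth 5–25% of the plateau, placed clear of the edge ramps), giving the
  detector at ratio 0.5 / width 10 a ≥2× ratio margin and ≥1 base width
  margin;
- **forced region depletion**: slightly over half the bases are set between
  the next-lower grid depth and the target depth, the rest far above the
  grid, so percent coverage is 100 at shallower depths and <75 at the
  target depth. Because percent coverage is monotone in depth, depletion
  at depth D necessarily propagates to all deeper grid depths; exclusive
  single-depth depletion is therefore only constructible at the deepest
  grid depth, and the controlled scenarios use 500X (tests pairing this
  with a clean background use a high, tight plateau — median 1200X, sigma
  0.1 — so the forced regions are the only depleted ones);
- **forced sample flagging**: the same split applied, for the chosen
  samples only, to 35% of regions (safely above the 25% that Q1 responds
  to), so the sample fails the Q1 rule at the target depth and nowhere
  shallower.

Wet metrics are drawn per run (five runs of 16 preparations by default)
around configured per-run medians — lognormal for positive-valued metrics,
normal for sign-indefinite ones (ΔCq) or ratio-like ones (260/280) — with
optional multiplicative run effects. Paired pre-capture/enriched library
concentrations use a default enriched/pre-capture median ratio of 0.38
(DNA-like; an RNA-like world would sit near 0.13), reflecting the strong
concentration decrease that hybridization capture produces. All
randomness flows through one seeded generator; identical configs give
byte-identical output files.

**What the simulator does not model**: read-level sampling (no FASTQ/BAM,
no mapping-quality or GC structure), correlated noise along the genome,
probe-specific efficiency, or any relationship between the wet metrics and
the coverage world (the two generators are independent unless the user
couples them). Passing tests therefore demonstrate the correctness of the
diagnostics on data with the stated structure, not that real panels have
that structure.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
1,000 exon profiles for the brute-force percent-coverage check, 200 exons
with ~115 injected drops for the recovery check, 30 regions × 8 samples
for blacklist recovery, 500 null replicates of 5×16 samples for the
Kruskal–Wallis calibration (nominal 5% ± 2 percentage points). Everything
completes in seconds on one CPU.

## Known limitations

- The run-level MPC aggregation and the blacklist criterion are this
  package's readings of informally stated rules; both are config-exposed.
- The Kendall CI uses the null asymptotic SE, which is conservative for
  strong correlations.
- Exclusive-depth forced depletion is mathematically restricted to the
  deepest grid depth (see above).
- The drop detector's exon-median reference assumes the drop occupies a
  minority of the exon; a drop covering most of an exon lowers the median
  and is better caught by the region-level rules.
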