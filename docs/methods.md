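# Methods

This note documents the statistical models, the defaults and their
rationale, the synthetic-data generators, and the numerical choices made
where the procedure left room for interpretation.

## Selection coefficients

The selection coefficient of a test strain against a labelled reference
over one competition episode is the change in natural-log odds,
`S = ln(test_f/ref_f) − ln(test_i/ref_i)`. It is invariant to the
acquisition size at either timepoint (only the proportions matter) and
antisymmetric under exchanging the competitor labels. Inputs may be raw
event counts or per-timepoint proportions; proportions are converted
with a stated total (default 10,000 events, the standard fixed-event
cytometry acquisition) purely so counts are inspectable — S is
unaffected.

Zero counts make S undefined; the default is a hard error naming the
offending field. An explicit `pseudocount=True` applies the Haldane
correction (+0.5 to all four counts). It is opt-in because a silent
pseudocount biases S when counts are small.

Normalisation subtracts the mean S of parent-vs-tagged-tester control
competitions (not a ratio): the controls define S = 0, so normalised
values express fitness relative to the parent and cancel the marker's
expression cost. Replicate-level normalised reference values are
retained for dispersion estimates.

Two log bases coexist by definition and are never mixed implicitly:
**S is natural-log**; **doublings are log₂** of the density fold change,
`d = log₂(density_final / (density_initial × inoculum/culture))`. The
dilution correction uses the transfer volumes; if a table omits them the
densities are assumed directly comparable. A per-doubling fitness on the
log₂-odds scale is an ln-scale slope divided by ln 2.

### Serial transfers and the reference-slope correction

Cumulative tracks anchor at (0, 0) at the end of passage 1 and
accumulate per-passage S and d over passages 2..p. Per-doubling fitness
is the OLS slope of cumulative S on cumulative doublings. The default
fit has a free intercept — the spreadsheet "trendline" convention — and
a `through_origin` option honours the (0, 0) anchor; both are exposed
because published per-doubling values rarely state the intercept
treatment, and on clean tracks the two differ by less than the sampling
spread.

The reference correction subtracts the reference competition's slope
from the test slope. This is the slope-level reading of "correcting for
cumulative doublings at each passage"; a per-passage variant (subtract
`reference_slope × cumulative_doublings(p)` from the test track point by
point before fitting) is provided and coincides with the slope-level
correction whenever the two doubling schedules match. Degenerate
regressions (no spread in cumulative doublings) are an error, not a NaN.

## Growth kinetics

µmax is the OLS slope of ln(OD600) against time (h) over the
**first contiguous run** of points inside the OD window 0.4–0.9. The
first-run rule avoids diauxic second rises; a `segment_policy="best"`
option instead selects the in-window run with the highest r². Curves
whose plateau falls below the window top are fitted in the fallback
window 0.1–0.5 and flagged (`window_fallback_used`). If the
rule-selected window holds fewer than 3 points the other window is
tried; if both fail the error reports the curve's OD range.

"Stationary phase" is operationalised for ODmax as the terminal run of
points whose pairwise relative OD change stays below 2% per hour; ODmax
is the mean OD over that run. A curve still rising at its end has no
plateau: the final OD is returned with a warning. Blank subtraction is
off by default (plate exports are often pre-blanked); values that are
non-positive after blanking are dropped with a warning before the log
transform.

## Variant triage

Coordinates are 1-based as in VCF. Alleles are reduced to a minimal
representation before any comparison — shared suffix trimmed, then
shared prefix trimmed with the position advanced, always keeping one
base per allele — so equivalent indel spellings compare equal without a
reference genome. The de novo subtraction keys on the full normalised
(chrom, pos, ref, alt) tuple by default; a position-only mode mirrors
coordinate-spreadsheet comparisons but will also discard co-located
distinct alleles, so it is not the default. Child records on contigs
absent from the parental catalogue warn (configurable to error), as they
usually indicate mismatched reference genomes.

The frequency cut-off (default 0.50) is inclusive. Parallelism groups
genes by the exact set of clones carrying at least one variant in them;
genes hit in ≥ 2 clones are reported as parallel, and the full
membership partition (the Venn regions over clones) is exposed.
Intergenic records are excluded from gene-level parallelism unless
requested. Gene assignment is taken from the input annotation; the
package does not re-annotate.

## Biosensor normalisation

The per-sample statistic is the median event intensity (even-length
samples use the midpoint of the central order statistics). Log₂ fold
changes versus the reference strain are computed per matched
(timepoint, condition) group, averaging replicate medians **before**
forming the ratio; a `per_replicate` option pairs replicates, takes log₂
per pair, and averages the logs (for strain/reference ratios around 2,
the two orderings differ by a few hundredths of a log₂ unit).
Autofluorescence subtraction is not applied; intensities must be
positive for the log ratios to exist.

## Synthetic data

Generators are pure functions of their parameters including the seed,
and their outputs satisfy the consuming modules' invariants by
construction.

**Competition.** Fitness is parameterised per doubling on the log₂-odds
scale: over d doublings the true odds multiply by `2^(s·d)`, so one
passage has expected `S = s·d·ln 2` on the natural-log scale and an
ideal ln-scale slope of `s·ln 2` — the ln↔log₂ conversion constant is
ln 2 throughout. Measurement noise is binomial sampling of the true
fraction at 10,000 events per timepoint; the transfer itself preserves
proportions, and the density schedule (stationary mixture at 10⁸
cells/mL, 20 µL into 20 mL, then 2^d growth) makes the doubling
estimator exact. A gating-misclassification hook exists but defaults to
0, since the analysis cannot identify it. Defaults mirror the study
regime: 1:1 starting mixture, 5 passages, 6 doublings/passage (ethanol
propagations run ~5–7; ethanol-free ~8–10).

**Growth.** The trajectory is a generalised saturating curve
`OD(t) = K·x/(1+x^p)^(1/p)` with `x = x0·e^{µ(t−lag)}` and
`x0 = od0/(K^p − od0^p)^(1/p)`; p = 1 is the textbook logistic. The
default sharpness p = 6 keeps the curve log-linear through the 0.4–0.9
fitting window (deceleration bias < 2% at K = 1.8) before bending into
the plateau. This models what windowed log-linear fitting presumes of
real plate-reader curves: measured OD under-reports dense cultures, so
the measured series stays exponential well past the point where an
OD-scale logistic would have decelerated — under a textbook logistic
with K = 1.8 the window slope is ~36% below µ and the estimator would be
structurally unable to recover the growth rate. Noise is multiplicative
Gaussian (default sd 1%); sampling is every 0.25 h.

**Variants.** The child table is the union of the parental catalogue and
the planted de novo set at disjoint sites, so subtraction must recover
exactly the planted records. About one variant in six is an indel
emitted in a padded, non-minimal spelling to exercise representation
normalisation. De novo frequencies default to a point mass at 1.0
(haploid single-colony isolates).

**Survival.** Plate counts are Poisson with means
`n_cells × dilution` (control) and `n_cells × survival × dilution`
(treated); defaults 10⁸ cells and a 10⁻⁵ dilution give ~10³-count
plates.

What passing recovery tests shows — and does not. The generators
reproduce the sampling noise the estimators are designed for (binomial
proportions, multiplicative OD noise, Poisson counts) but none of the
systematic structure of real experiments: gating misclassification,
cytometer carry-over, condensation and edge effects in plates, aggregate
(snowflake-type) cells that break single-cell counting, or mapping and
calling artefacts in variant tables. Recovery within tolerance therefore
validates the estimators, not the robustness of any particular wet-lab
dataset.

## Ethanol titer arithmetic

Expected titer uses the theoretical yield 0.511 g ethanol per g of
reducing sugars scaled by a conversion efficiency (default 0.90, the
typical industrial fraction of theoretical). Conversion to % v/v divides
by 7.89 g/L per percentage point, i.e. ethanol density 0.789 g/mL at
20 °C; the density is a parameter since g↔%v/v conversions often leave
it implicit.

## Problem sizes

Recovery checks in the test suite and acceptance script use 20 seeds for
competition and growth recovery, 50 for survival means, 200 randomized
tables for the subtraction oracle, and 1,000 randomized observations for
the S property sweep — sizes at which the Monte-Carlo standard error of
each reported mean is several times smaller than the tolerance asserted
on it (e.g. per-series corrected-slope sd ≈ 0.001–0.002 per doubling at
10⁴ events, so a 20-seed mean carries SE ≈ 0.0004).

## Known limitations

- No lag-time or full parametric (Gompertz/Baranyi) growth fitting; only
  the windowed log-linear slope and plateau mean.
- No FCS parsing or gating: inputs are already-gated counts and medians.
- No read mapping, variant calling or effect prediction; triage operates
  on call tables against a stated annotation.
- The reference correction assumes the reference competition shares the
  test competition's condition and doubling schedule; strongly
  mismatched schedules should use the per-passage correction variant.
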