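# Methods

## The measurement model

An MPRA library element `e` carries a set of barcodes; in each sample `s` we
observe DNA counts (integration depth) and RNA counts (transcription) per
barcode. Element activity is defined on the log2 scale from barcode-summed,
depth-normalised counts:

    a[e, s] = log2( (CPM_rna(e, s) + p) / (CPM_dna(e, s) + p) ),   p = 1 CPM

The ratio-of-sums estimator is used instead of the mean of per-barcode ratios
because individual barcodes can have very small DNA counts, which make
per-barcode ratios unstable; summing first pools the evidence. This is a
deliberately simple replacement for GLM-based normalisation (which is out of
scope for this package). Replicates within a time point are combined by the
arithmetic mean of log2 activities — calls are then made per time point.

**Identifiability.** CPM scaling divides by the per-sample totals, so `a` is
identified only up to a per-sample additive constant, namely −log2 of the
depth-weighted mean linear activity of the whole library. All downstream
inference is anchored on the *fitted* background component and is therefore
invariant to this offset. Simulation-based recovery checks that compare
estimated activity to generator truth first remove the offset using a
truth-derived oracle (`simulate.sample_offset_oracle`).

## Background model

Negative controls (nucleotide-shuffled candidates) need not be silent: TF
binding is probabilistic and shuffled sequence occasionally recreates
functional motifs. Their activity distribution is therefore modelled as a sum
of two Gaussians on the log2 scale — a background component (lower mean) and
a signal component (higher mean). The signal excess reported is
`2^(μ_sig − μ_bg) − 1`, the fractional excess of the components' geometric
means on the linear RNA/DNA scale.

Two fit routes:

- `histogram_ls` (primary): bin the values (Freedman–Diaconis, minimum 8
  bins so the 5-parameter fit stays determined) and fit the mixture density
  to the bin densities by nonlinear least squares with 20 starts (one
  moment-based split at the median, the rest randomised between the 5th and
  95th percentiles). Optimisation uses an analytic Jacobian;
  each start first runs unbounded Levenberg–Marquardt (weights slightly
  outside [0, 1] are clipped and re-scored) and falls back to a bounded
  trust-region fit; the best sum of squares wins. Components are ordered by
  mean and labelled background (lower) / signal (higher), so labels never
  depend on initialisation. A component sd collapsing to the 1e-4 floor in
  every start raises a degenerate-fit error.
- `em` (cross-check): standard 2-component EM (scikit-learn), best
  log-likelihood of `n_starts` initialisations.

**Small-sample caution.** At the scale of ~150 values with moderately
separated components, the binned-density least-squares objective is weakly
identified: solutions that park one broad component on the bulk and a small
component on histogram noise can have *lower* SSE than the truth-shaped
solution, so no optimiser or weighting fixes it. The EM route is
substantially more reliable there (median |error| of the background mean
≈ 0.04 at n=150 versus ≈ 0.24 for histogram LS with the default truth) and
is the recommended method for small samples; at n ≥ ~1000 both routes agree
to within ±0.05 per parameter.

**Goodness of fit.** Because the mixture parameters are estimated from the
same data, asymptotic KS/AD p-values would be badly conservative. Both
statistics are computed against the fitted mixture CDF and calibrated by
parametric bootstrap: simulate `n_boot` (default 999) samples of the same
size from the fitted mixture, refit each (5 starts), and use
p = (1 + #{boot ≥ obs})/(n_boot + 1). The KS statistic is centre-weighted and
has limited power against tail misfit once five mixture parameters have been
refitted; the AD statistic is tail-weighted and carries most of the power
against heavy-tailed alternatives.

The mixture is fitted to negative controls pooled across samples by default
(per-sample fitting is available by flag); pooling mirrors treating each
(element, sample) activity as one observation of the null.

## Calling, temporal classes, sensitivity

An element is active at a time point when its activity is significantly
above the background: one-sided p = 1 − Φ((a − μ_bg)/σ_bg), significant when
p < α/N with α = 0.05 and N = the number of QC-passing tested elements
(candidates + positive controls — both are "tested"; negatives are the null
and are excluded). The equivalent activity cutoff
c = μ_bg + σ_bg·Φ⁻¹(1 − α/N) is computed too and the two routes are asserted
to agree on every call. One pooled background is applied to all time points.

Active elements are classified into the seven non-empty Venn cells over
{iPSC, TD0, TD30}; "specific" means active at exactly one time point.

Assay sensitivity is the signal-component mass above the cutoff,
S = 1 − Φ((c − μ_sig)/σ_sig): the probability that a truly active element is
called. In the pipeline the signal component is taken from the mixture
fitted to the tested elements' activities, so S is an *operational*
sensitivity under the same measurement noise as the calls; the end-to-end
suite checks that realised recall of truly active elements matches it.

## Synthetic-data generator

The generator emulates the statistical structure of the experiment, not its
sequences: 3 time points × 3 replicate samples; barcodes per element
~ Poisson(39.9) (minimum 1), 15 bp; DNA counts per barcode and sample
~ negative binomial with mean 50 and dispersion 0.3 (variance m + 0.3 m²);
RNA counts ~ Poisson(dna × 2^(a + ε_b)) with a unit-mean lognormal barcode
effect (sd 0.25 in log2). True activity per (element, time point) draws from
the background N(0, 0.35) or signal N(0.65, 0.35) component — the signal
component sits ≈ 57% above background on the linear scale. Negative controls
always draw background; positive controls are active with probability 0.9;
candidates with probability 0.15 per time point, independently, giving
~39% of candidates active in at least one of the three stages. Linked-gene
log2 expression is baseline + β × (mean true activity, relative to
background, of ever-active linked enhancers) + N(0, 0.2) noise, with β = 1,
so expression changes between time points track true activity changes.

What the generator does **not** model: sequencing error and UMI structure
(counts are post-UMI), barcode dropout/recovery failure, lentiviral
silencing over differentiation, cell-type heterogeneity within organoids,
correlated activity across time points, and real genomic sequence. Passing
tests therefore demonstrate the correctness and internal consistency of the
statistical pipeline under a faithful noise model — not that any particular
biological dataset meets the model's assumptions.

## Numerical choices and scales

- All activity modelling is on log2; the mixture components convert back to
  the linear scale only for the signal-excess and display quantities.
- Clustering uses Euclidean distance on *linear* (2^a) per-sample activity
  with Ward linkage; the display cap at 4 truncates the returned heat-map
  matrix only, never the distances.
- Problem sizes in the test and acceptance suites are desk-scale by design:
  mixture recovery at n=5000 and n=150, family-wise error over 500
  experiments of 7000 tests, end-to-end runs at ~2000 candidates, and
  concordance over 50 seeds of ~500-candidate experiments. These sizes give
  stable pass/fail behaviour while keeping a full run in minutes.
- QC defaults: a barcode needs DNA ≥ 1 in a sample to count there; an
  element needs ≥ 10 surviving barcodes in every sample. The thresholds are
  package choices (deep simulated coverage passes ~100%).
- Fisher exact tests are two-sided with the sample odds ratio; raw p-values
  are reported with a Bonferroni column across external sets.
- "Concordant pair" at cutoff t means |Δ activity| ≥ t AND |Δ expression| ≥ t
  in any sign combination; sign concordance is reported separately.
- Expression contrasts require measured expression at both conditions; iPSC
  contrasts are refused unless iPSC expression is supplied (no imputation).

## Known limitations

- The histogram least-squares route needs n ≳ 1000 or strong component
  separation; use EM below that.
- The single pooled background assumes the null is stable across time
  points; per-time-point fitting exists but is not the default.
- Mixtures with more than two components, skewed or heavy-tailed components
  are out of scope; the AD goodness-of-fit statistic is the intended guard
  against such misfit.
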