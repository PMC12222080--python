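# Methods

## Overview

`tvgc` implements a time-variant directed-connectivity analysis for
event-aligned multichannel electrophysiology, of the kind used to compare
EEG network dynamics between subject groups around a discrete event (here:
the anticipated collision moment in simulated driving trials). The chain is

1. **synth** — synthetic sessions from a vector-autoregressive (VAR)
   generator with a known directed coupling graph per group;
2. **preprocess** — resampling, band filtering, epoching, behavioral and
   statistical trial rejection;
3. **gc** — sliding-window pairwise Granger causality (GC) with AIC model
   order selection;
4. **netmetrics** — node- and graph-level quantification of each directed
   weighted network, aggregated into intrinsic functional networks;
5. **stats** — tiered group statistics with BH-FDR control.

Because no real recordings ship with the package, every quantitative claim
is validated against planted ground truth: known edges must be recovered,
known group differences must surface through the entire pipeline, and all
null calibrations must hold at their nominal levels.

## Generative model

Each subject's continuous signal is a stable VAR(p) process

    x_t = sum_{l=1..p} A_l x_{t-l} + e_t,    e_t ~ N(0, diag(sigma^2)),

with `A_l[i, i]` the per-lag self-terms (default `(0.45, 0.15)`, giving
low-pass AR coloration) and off-diagonal entries placed verbatim from the
coupling graph's `(source, target, magnitude, lag)` edges. Stability is
checked via the companion-matrix spectral radius; if the radius reaches the
0.98 margin the self-terms are shrunk geometrically, and a graph that cannot
be stabilized even with zero self-terms raises an error naming the coupling
magnitudes. Ten model orders of burn-in are simulated and discarded so the
retained segment is effectively stationary.

Sessions default to the emulated study conditions: 64 channels, 1 kHz
acquisition, 40 trials at 50% collision incidence, the event at each trial's
temporal midpoint, and two groups ("experienced", "novice") of 10 subjects.
The novice graph is a strict superset of the experienced graph with 1.5x as
many edges and 1.5x larger magnitudes — the between-group magnitudes are
free parameters of the generator (nothing pins them externally), and this
choice plants the qualitative effect of interest (higher novice
connectivity) with a single knob in each direction. Trial conditions
(collision vs non-collision) share the same dynamics: the planted factor is
group, and condition serves as a realistic design axis for the statistics
tiers.

White measurement noise at 5% of each channel's signal SD is added on top
of the VAR process. Real recordings always carry a broadband sensor-noise
floor, and that floor matters here: a noise-free narrowband-filtered signal
is almost perfectly linearly predictable, which would make residual
variances degenerate. What the generator deliberately does **not** emulate:
volume conduction, realistic 1/f spectra, ocular/muscle artifacts beyond
the statistical screen's reach, or any biophysical head geometry. Passing
tests therefore demonstrate correctness of the estimators and pipeline
mechanics under the linear-AR model class, not robustness to those real-data
complications.

## Preprocessing

Fixed stage order: resample → bandpass → epoch → correctness filter →
artifact screen; every stage is deterministic.

* **Resampling** to 500 Hz by anti-aliased polyphase filtering; upsampling
  is refused.
* **Band filtering** with a 4th-order Butterworth bandpass applied forward
  and backward (zero phase). Zero-phase application is essential: a causal
  filter's group delay would shift the event alignment that the sliding
  windows depend on. Band edges are configuration, defaulting to the
  clinical conventions alpha = 8–13 Hz and beta = 13–30 Hz.
* **Epochs** span 2 s before to 1 s after the event (half-open in samples:
  1500 samples at 500 Hz, event at index 1000). Events without full support
  are dropped with a logged warning.
* **Trial rejection** keeps correct trials only, then applies a statistical
  screen: per-trial variance, excess kurtosis and peak amplitude are
  z-scored across trials and any |z| > 3 rejects the trial. This is the
  trial-level analogue of the z-score screening used by automated EEG
  cleaning tools; full ICA-based artifact decomposition is out of scope
  (its component-classification criteria are not reproducible from a
  threshold alone, and the synthetic data contain no ocular sources).

## Granger causality

For channels X, Y and order p, the univariate model regresses X on its own
p lags; the bivariate model adds the p lags of Y (no intercepts — windows
are mean-subtracted first). The statistic is

    F_{Y->X} = ln( var(eps_uni) / var(eps_biv) ),

estimated by OLS so that the nested-model inequality RSS_biv <= RSS_uni is
an in-sample identity. Numerically this identity is preserved *exactly*:
residual sums of squares come from orthogonal projections sharing the
target's own-lag basis, so the bivariate RSS is the univariate RSS minus a
sum of squared projections and F >= 0 holds in floating point, not merely
to tolerance. The matrix path factors each channel's own-lag block once,
projects all source blocks against it in one matrix product, and QR-factors
the residual blocks batched; it agrees with the independent two-channel QR
path to ~1e-15 and with a naive normal-equations implementation to 1e-8.

Rank-deficient designs (duplicated or constant channels) raise an error
naming the pair. The guards are calibrated to the narrowband regime:
band-limited signals are legitimately predictable down to residual/power
ratios of ~1e-21, while exact collinearity lands at the machine-epsilon
scale, so the rank tolerance is 1e-13 (relative R-diagonal) and the
degenerate-residual threshold 1e-24 (relative to series power).

GC is computed **per trial** per window and averaged across trials within a
(subject, band, condition, window) cell. Per-trial fitting respects the
500-sample window limit at p = 12 (488 effective observations against 24
bivariate coefficients); concatenating trials would mix epochs across
nonstationary trial boundaries. The symmetric variant
max(F_{Y->X}, F_{X->Y}) is stored alongside, but all network analysis uses
the directed matrix.

**Sliding windows** default to 1 s length at 50% overlap over the
[-2, +1] s epoch: exactly five windows of 500 samples, [-2,-1],
[-1.5,-0.5], [-1,0], [-0.5,+0.5], [0,+1].

**Order selection** minimizes AIC = n ln(RSS/n) + 2k of the bivariate fits,
where n is the effective observation count after lag truncation and k the
coefficient count of the scored model (2p per bivariate target equation),
averaged over channel pairs, sliding windows, the lead collision trials
(default: first five) and a 10% random trial subsample. Ties break toward
the smaller order. The default order is p = 12 with a 1–15 search range;
both are configuration. On synthetic generative-order-3 pairs the selector
recovers 3 (occasionally 4, the usual mild AIC overshoot) — see the
acceptance suite.

## Network metrics

Edge weights are the nonnegative F values; the diagonal is zero.

* **Strength**: in-strength = column sums, out-strength = row sums, total =
  their sum. Conservation (sum of in = sum of out = total edge weight) is a
  tested invariant.
* **Weighted clustering** uses the ratio sum w_ij w_ik w_jk / sum w_ij w_ik
  over ordered neighbor pairs. The indexing is inherently undirected, so
  the input is symmetrized as (W + W')/2; this is isolated in one function
  so a directed-clustering variant could be substituted.
* **Path metrics** convert each edge to a distance 1/w (absent edge =
  unreachable) and take shortest directed paths — summing per-edge inverses
  rather than inverting a path's weight sum, since the latter is not a
  metric and breaks shortest-path optimality. Global efficiency averages
  1/d over ordered pairs with 1/inf = 0; characteristic path length
  averages d over reachable pairs only and flags disconnected graphs. Both
  therefore stay finite on heavily thresholded networks.
* **Edge retention** for visualization keeps the ceil(fraction x nnz)
  largest weights (default 5%), retaining all ties at the cutoff so the
  result is independent of sort order.
* **Network aggregation** maps channels to the seven canonical intrinsic
  functional networks (Visual, DMN, DAN, VAN, FCN, Limbic, Somatomotor) via
  the atlas and takes unweighted means of total node strength. Modularity
  is deliberately not implemented: no specific community algorithm is
  pinned down by the analysis this package operationalizes, and guessing
  one would produce unverifiable numbers.

## Group statistics

* **Tier 1** — Welch's unequal-variance t-tests (Satterthwaite df) on the
  two graph-level metrics, per band, condition and window.
* **Tier 2** — mixed-design ANOVA on node-level metrics with experience as
  the between-subjects factor and intrinsic network (seven levels, not
  individual channels) as the within-subjects factor, on complete balanced
  repeated measures; the experience main effect is the primary readout.
  The implementation delegates to `pingouin.mixed_anova` and is verified
  against a hand-worked sums-of-squares decomposition.
* **Tier 3** — per-node Welch follow-ups, run only in cells whose ANOVA
  experience effect survives FDR, summarized by network affiliation and
  window.

p-values are pooled into Benjamini–Hochberg families per (tier, metric,
band, condition) across windows and units; the family definition is written
into the outputs since reasonable alternatives exist. Stars follow
p_FDR < 0.05/0.01/0.001. Cohen's d uses the pooled SD and is signed
experienced minus novice, so higher novice connectivity appears as
negative d.

The testing unit is the subject (one value per subject and cell). Designs
that pool trial-level observations would yield much larger degrees of
freedom; that pooling is not implemented, and no claim is made about
reproducing statistics computed under it.

## Problem sizes and seeds

Validation experiments run at sizes chosen to give stable Monte-Carlo
estimates while keeping the whole suite desk-scale: direction recovery on
5-channel VAR(3) graphs (4 planted edges, coupling 0.4, n = 2000, 50
seeds), order recovery on 20 seeded VAR(3) pairs, 200 random 6-node graphs
against brute-force oracles, 500 null simulations for statistical
calibration, and one full pipeline run at 16 channels and 10 subjects per
group for effect recovery. All randomness flows from explicit seeds; reruns
are bit-identical.

## Known limitations

* Pairwise (bivariate) GC only: indirect influence through a third channel
  produces nonzero pairwise F. Direction-recovery checks therefore compare
  planted edges against all non-edges by ranking rather than thresholding.
* Filtering before AR-based GC compresses residual variances and is known
  to distort GC magnitudes; within this package the comparison of interest
  (between groups, same band) is unaffected, but absolute F values in
  narrow bands should not be interpreted physically.
* The mixed ANOVA assumes complete balanced within-subject data; subjects
  missing any network level are a hard error rather than being imputed.
* Continuous recordings are written as FIF (one file per subject); EDF
  export is not provided.
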