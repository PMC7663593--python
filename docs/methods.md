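# Methods

This note documents the models, parameter choices and numerical decisions
behind `rgstress`, and what the synthetic validation does and does not
establish about real recordings.

## Protocol and analysis window

The standard session is RS1 (120 s), MIST training (180 s), MIST task
(360 s), relaxation (300 s), RS2 (120 s) — about 18 minutes.  Only the
central minute of each resting block enters the analysis, so the
concatenated window is 16 minutes; at 2 s per epoch this gives exactly
480 epochs (16 · 60 / 2).  Block boundaries are carried through the whole
chain as 0-based half-open `[start, end)` index maps, first in samples,
then in epoch units, and are rescaled if a series is resampled.

The sampling rate defaults to 250 Hz (the acquisition hardware's rate is
not documented; 250 Hz is a common choice that comfortably represents the
45 Hz gamma edge) and is configurable.  Rates below 90 Hz are rejected
because the gamma band would alias.

## Filtering

The bandpass is a Butterworth prototype of order 2 applied
forward-backward (`sosfiltfilt`), i.e. an effective 4th-order magnitude
response with exactly zero phase — "order 2" names the prototype, matching
common practice for zero-phase filtering.  Edges are handled by
odd-symmetric padding.  The notch is an IIR design of quality factor 30 at
50 Hz, also applied zero-phase; the quality factor is a conventional value
(≈1.7 Hz −3 dB width) since no design is prescribed by the protocol.
Filtering happens after concatenation, so block joins can carry small edge
transients; with 16-minute windows and 2 s epochs the affected span is a
negligible fraction of any phase.

## Epoching, artifact rule, normalisation

Epochs are non-overlapping; a trailing remainder shorter than 2 s is
dropped with a warning (the standard protocol has none).  The artifact
rule — zero any epoch-channel whose peak absolute amplitude exceeds
100 µV — is evaluated **before** detrending/z-scoring, because
normalisation destroys the amplitude scale the rule is defined on.  Zeroed
epoch-channels are excluded from the channel average (including them as
zeros would bias power downward); an epoch with all channels zeroed yields
a missing RG value, which is linearly interpolated from its neighbours
before smoothing.  A channel whose detrended residual is at floating-point
noise level relative to its raw amplitude (e.g. an exactly linear segment)
is treated as zero-variance and left at zeros rather than amplified.

## Band power and relative gamma

Each 2 s epoch-channel gets a raw rectangular-window periodogram
(`scaling='spectrum'`, so bins sum to the mean square — Parseval holds to
numerical precision; no averaging estimator is
possible inside a 2 s window at its 0.5 Hz resolution).  Band power sums the bins with `low ≤ f < high`; the
half-open convention makes the five bands (delta 1–4, theta 4–8, alpha
8–13, beta 13–25, gamma 25–45 Hz) partition the spectrum without
double-counting the shared edges.  Delta and beta are computed and
exportable although only alpha, theta and gamma enter
RG = P_gamma / (P_alpha + P_theta).  Because every epoch is z-scored
first, band powers are dimensionless; RG is unaffected, being a ratio of
same-epoch powers, and is invariant under any common positive rescaling of
the channels.

## Subject conditioning and group curves

Smoothing is a centred 19-point moving average (the span stated with its
centring is adopted over the round "20 samples" mention; configurable, odd
spans only).  The window shrinks symmetrically at the edges, so the series
keeps its length and no phase shift is introduced; a step is smeared over
±9 epochs = ±18 s, which is why curve extrema lag their true onsets by
roughly 20 s.  Resampling to the common 480-point grid is linear
interpolation over the original index range (endpoint-preserving,
affine-preserving; identity when the input is already 480 long).

Responder classification automates the per-subject visual inspection: the
decision statistic is mean(RG | MIST task) − mean(RG | relaxation), with
ties classed as direct; the statistic is kept for audit.  Inversion is
implemented as reflection about the series mean (x → 2·mean − x), which
preserves location and scale — unlike a sign flip or reciprocal — so
oriented series remain averageable; it is an involution.

Group curves are pointwise means with SEM = sd/√n (ddof 1).  The degree-6
polynomial is fitted by least squares on an abscissa rescaled to [−1, 1]
(`numpy.polynomial.Polynomial.fit`); degree-6 Vandermonde systems on raw
indices 0–479 are numerically hostile.  Curve similarity is the Pearson
correlation with a Fisher-z interval, tanh(atanh r ± z*/√(n−3)), using
n = 480 curve points.  The interval treats points as independent; the
strong autocorrelation of smoothed and fitted curves makes it optimistic.
This caveat is documented deliberately rather than corrected, to keep the
construction identical to the analysis it reimplements (the n = 480
bounds for r = 0.60 and 0.89 reproduce the published 0.54/0.65 and
0.87/0.91 to two decimals).

## Survey statistics

SPSL responses are ordinal 1–5 integers, so the decision test is always
the Wilcoxon signed-rank test; a Lilliefors gate (KS statistic with
estimated mean/sd) is computed per comparison and reported.  The
Lilliefors p-value comes from a seeded Monte-Carlo null (default 10 000
draws, p = (1 + #{D_mc ≥ D})/(M+1)), which is exact-in-the-limit, fine at
small n where printed tables are coarse, and bit-reproducible.

The Wilcoxon implementation discards zero differences (reducing and
noting the effective n — small printed p-values such as 0.1250 and 0.2500
are only reachable on the discrete null this produces), mid-ranks tied
absolute differences, and computes the exact two-sided p for effective
n ≤ 25 from the full null distribution of the positive rank sum
(dynamic-programming convolution over doubled ranks, equivalent to
enumerating all 2ⁿ sign assignments).  Above n = 25 it switches to the
normal approximation with tie correction and a 0.5 continuity correction.
Two-sided p = min(1, 2·min(P(W ≤ w), P(W ≥ w))).  Between-group
comparisons at each instant follow the same signed-rank construction by
pairing subjects positionally (sorted subject order) — a statistical
idiosyncrasy of the original analysis that is mirrored rather than
replaced by a rank-sum test; it requires equal group sizes.  No
multiple-testing correction is applied, and this is stated in outputs.

RG at the survey instants T1–T4 is the mean over the minute (30 epochs)
centred on each instant's epoch (T1 at the window start, clipped; T2 at
the end of the MIST task; T3 45 epochs into relaxation; T4 at its end).
The SPSL–RG correlation at the four instants is a plain Pearson
coefficient; no interval is reported at n = 4.

## Synthetic cohort generator

The generator emulates only the statistical structure the pipeline
consumes.  Each channel is a sum of five band-limited Gaussian components
(white noise through a zero-phase 4th-order Butterworth bandpass per band,
renormalised to unit variance, then scaled).  Baseline amplitudes are
conventional resting-EEG-like spectral densities in µV/√Hz — delta 2.0,
theta 1.5, alpha 2.0, beta 0.8, gamma 0.5 (the study reports no amplitude
or SNR figures, so these are a realistic one-time choice, giving a total
RMS near 7 µV that never trips the 100 µV rule on its own).  The gamma
amplitude is modulated by 1 + d·s(t) and alpha/theta by 1 − d·s(t) for a
direct responder (sign-flipped for inverse), with modulation depth
d = 0.4 by default.

The latent stress trajectory s(t) ∈ [0, 1] is piecewise smooth: a resting
baseline of 0.15, an exponential rise during MIST training (τ = 30 s)
toward 0.6, a continued monotone rise over the task normalised to end at
exactly 1, an exponential dip during the first two minutes of relaxation
(τ = 45 s, chosen so s < 0.1 two minutes in), then a slow linear drift up
(boredom/residual cognitive activity) and a return toward baseline in RS2.
The resting baseline sits above the relaxation minimum on purpose: deep
relaxation drives arousal below the ordinary eyes-closed level, which is
what places the group-curve minimum about two minutes into the relaxation
block rather than in RS1 — the qualitative shape the pipeline is expected
to recover.

Artifacts are Poisson-placed (default 2/min) 200 ms raised-cosine
transients of 150–300 µV on 1–3 random channels — guaranteed to fire the
zeroing rule while keeping zeroed epoch-channels well below the 9 %
bookkeeping bound.  Line noise is a 2 µV 50 Hz sinusoid with random phase
per channel.  Surveys are rounded, clipped Gaussians around per-instant
means (2, 4, 2, 2) with sd 0.5, encoding the intended rise after the
stressor and recovery during relaxation.  The default cohort is 20
subjects, 10 control / 10 test, with responder polarity drawn at
P(direct) = 7/17 to echo the observed proportion.

**What the generator does not model:** physiological artifact morphology
(blinks as dipolar fronto-polar deflections), 1/f background beyond the
band mixture, inter-channel correlation structure, non-stationarity beyond
the stress modulation, or any mechanism behind responder polarity.
Passing tests therefore demonstrate that the pipeline's operations are
correct and well-calibrated on signals with the assumed band structure —
not that the biomarker itself is valid on real EEG.

## Verification design

Tests avoid re-deriving the implementation: the exact Wilcoxon is checked
against an independent full enumeration over sign patterns (including
ties and zeros), the Lilliefors statistic against `statsmodels`, band
powers against brick-wall periodogram integration, the EDF writer against
MNE's reader, and Fisher intervals against their coverage (93–97 % at
ρ = 0.6, n = 480 over 1000 replicates).  Calibration checks run at reduced
but statistically meaningful sizes — 200 subjects for polarity recovery
(≥ 95 % required at depth 0.3), 2000 null replicates for the Wilcoxon
level (≤ 6 % at nominal 5 %; the exact test is conservative on discrete
data), 100 replicates for the Lilliefors level — sizes chosen to keep the
suite routinely runnable while leaving Monte-Carlo error well inside the
asserted margins.

## Known limitations

- Fisher intervals on autocorrelated curves are optimistic (above).
- The between-group signed-rank pairing is arbitrary; an independent-samples
  test would be the orthodox choice.
- Block-join filtering transients are accepted rather than filtered
  per block.
- The EDF writer implements only the continuous (EDF+C) subset needed for
  fixtures: identical rates across signals, one-second records, integer
  total duration.
- Published per-subject outcomes (individual p-values, survey tables,
  polarity split) depend on unreleased recordings and are emulated, not
  reproduced; only structural quantities (epoch accounting, interval
  bounds) are exact targets.
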