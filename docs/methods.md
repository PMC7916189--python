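# Methods

## Signal model and acquisition front end

A dual-photodiode LDF channel records two a.c. photocurrents plus a d.c.
level. The differential signal `d(t) = iac2(t) − iac1(t)` removes
common-mode artefacts (probe motion couples identically into both
channels, Doppler speckle does not). Each frame of `N = 2500` samples at
`fs = 50 kHz` is transformed at its native resolution `fs/N = 20 Hz` — no
zero padding, because the 20 Hz bin grid is exactly what makes the
"640 bins up to 12 800 Hz" layout and the 20 Hz output rate consistent.
The DC bin is dropped and the spectrum truncated at the 12 800 Hz cut-off
(configurable up to Nyquist).

**Spectrum normalisation.** The estimator is the one-sided periodogram in
power-spectral-density scaling (`scipy.signal.periodogram`,
`scaling="density"`): with the rectangular window, the summed one-sided
power times the bin width equals the mean squared differential signal
(discrete Parseval identity, used as an oracle test). Any consistent
convention would do — every downstream quantity in this package is either
a ratio (mean speed, cumulative curves) or in arbitrary units absorbed by
the gain `K` — but the density convention is stated and tested. A Hann
taper is available; the rectangular window is the default and the only one
for which the Parseval check is exact.

**Moments.** Band membership is decided on bin centres, both interval ends
closed; the DC bin is excluded from all moments. `idc` is a per-frame
scalar (one normalisation per spectrum). Gain default `K = 1` (perfusion
is in arbitrary units throughout). The differential order is fixed as
`iac2 − iac1`; the sign is irrelevant to the power spectrum and fixed only
for reproducibility.

## Cumulative-sum curves and AbC

The curve is computed as partial sums of `f·S(f)` over their total —
algebraically identical to the per-bin recursion, which the test suite
verifies against a literal per-bin implementation to 1e-12 on 1000 random
spectra. Degenerate all-zero weighted spectra raise an error rather than
returning a curve.

**Averaging order.** Stage curves are the pointwise mean of the per-frame
cumulative curves, not the curve of the mean spectrum. The per-frame curves
are each scale-invariant, so slow amplitude modulation (pulse, breathing)
cancels before averaging; the alternative (`mode="spectrum-mean"`)
weights frames by their power and is kept behind a flag.

**First-intersection rule.** With `D(f) = C_a − C_b` followed from the
starting frequency (default 60 Hz, the lower edge of the physiological
band), the first sign change ends the integration; the crossing frequency
is located by linear interpolation between the bracketing bins, an exact
zero at a bin counts as the crossing at that bin, and if the curves never
cross the integral runs to the upper grid edge with `crossed = False`.
Both curves end at exactly 1, so their structural meeting at the upper
edge is not counted as a crossing.
The area is the absolute trapezoidal integral, in units of Hz × cumulative
fraction; the scale is absorbed by downstream classifier coefficients.

**Numerical zero.** Differences with `|D| ≤ 1e-12` are treated as zero.
Curves of a spectrum and its rescaled copy agree only to floating-point
rounding, and without the threshold the sign of 1e-16-level noise would
fabricate spurious crossings; with it, a pure amplitude change yields an
AbC of exactly 0, which is the analytically correct value. The cost is
that genuine areas below ~1e-12·bandwidth are reported as 0 — far below
any physiological signal.

## Heating protocol and features

Stages are half-open `[t_start, t_end)` windows; a boundary sample belongs
to the later stage. Stage 2's printed description ("ramp at 2 °C/min to
42 °C for 5 min") is encoded as a 4.5 min ramp followed by a 0.5 min hold;
the choice only affects the simulator because stage 2 is excluded from all
features. Stage averages are plain arithmetic means over the 20 Hz samples
(equivalent to a trapezoidal time integral divided by duration for uniform
sampling, up to the half-weight endpoints); no initial-transient trimming
is applied. Samples with an undefined mean speed are excluded from the
`⟨v⟩31` averages and counted in the log. The default moment band is
60–12 800 Hz, with 60–400, 400–800 and 60–6400 Hz presets for
band-resolved perfusion traces.

## Classification

Two-class LDA with pooled within-class covariance and equal priors
(group-size priors are deliberately not used; cohorts in this application
are small and unbalanced by recruitment, not by prevalence). The fitted
hyperplane is stored as an explicit affine score with decision boundary 0,
the same shape as the two stored reference discriminants
(`patients-vs-older`, `younger-vs-older`). The reference coefficients'
feature order is not recoverable from their source, which labels them only
as first and second input; the default mapping is `(abc, dbp)` — DBP has
the larger numeric range, so the small coefficient plausibly belongs to
it — and the mapping is a constructor argument, flagged as unresolved.

A singular pooled covariance raises an error unless the ridge fallback
(Ledoit–Wolf shrinkage) is enabled. AUC is the rank-based Mann–Whitney
statistic with ties credited 0.5; a brute-force all-pairs count serves as
the independent oracle in tests. Evaluation is in-sample by default —
matching how a small-cohort feasibility analysis reports — and every
report labels it as such.

## Synthetic data generator

**What it emulates.** A single scatterer population with a unit-area
spectral line shape of width `v_scale` (Hz, proportional to mean scatterer
speed) and amplitude `conc` (moving-cell concentration), plus a flat noise
floor. The truncated Lorentzian is the default family (heavy-tailed
Doppler broadening is the conventional description for tissue); Gaussian
and mixtures exist for robustness checks. Unit-area normalisation makes
CMBC exactly proportional to `conc` and makes a narrowing line raise
low-frequency amplitudes, the physically expected redistribution at fixed
scatterer count.

**Sampling noise** is mean-preserving per-bin gamma noise (shape 6,
relative SD ≈ 41%), mimicking periodogram estimation variance.
Physiological modulation (cardiac ≈ 1 Hz, respiratory ≈ 0.3 Hz, slow
≈ 0.1 Hz) multiplies the concentration only; this keeps a pure amplitude
responder's cumulative curves exactly constant, preserving the
amplitude-vs-broadening dichotomy at its analytically exact point.

**Time-domain route.** `synth_frame` shapes white Gaussian noise in the
frequency domain to the model PSD, splits it anti-symmetrically between
the channels, adds independent channel noise realising the noise floor and
an identical common-mode sinusoid that the differential step cancels
exactly. It exists to test the FFT front end; the spectrum-domain route is
the fast path for recordings and cohorts.

**Archetypes** encode the stage-3 response as (v_scale, conc) multipliers:
broadening (1.5, 1.3), amplitude (1.0, 3.0), mixed (1.4, 2.2) and
non-responder (1.05, 1.15) — the blunted pattern used for the simulated
patient group. Between-subject variation is log-normal (σ = 0.15 on
baseline parameters, 0.08 on multipliers). These effect sizes are free
parameters chosen to give a clearly separated two-group geometry
(responders up-and-right of non-responders in the (DBP, AbC) plane); they
are not claimed to match any clinical cohort. Provocation defaults —
breath hold: `v_scale ×0.45`, `conc ×1.5`; occlusion: both `×0.4` — were
chosen so the truncated-line-shape moments reproduce the qualitative
directions these manoeuvres show in vivo (low-band perfusion up and
broad-band perfusion down during a hold; the occlusion-stage cumulative
curve growing faster than baseline).

**What passing tests do not show.** The simulator has a known line shape,
a single population, stationary stages and well-behaved noise. Passing its
tests demonstrates the *processing* is correct and the features respond in
the right directions for the right reasons; it says nothing about effect
sizes, inter-subject overlap, artefact profiles, or classifier AUCs on
real skin recordings.

## Problem sizes

The cohort default is 50 subjects per group run through a 1/10-timescale
heating plan (60/30/18 s stages at the native 20 Hz spectral tick, 2160
spectra × 640 bins per subject). Stage-average features are insensitive to
the compression because stages remain internally stationary; the
full-length 1080 s plan stays the default for everything except cohort
simulation. Provocation simulations use 80–90 s series.

## Known limitations

- No photon-transport or multi-layer tissue modelling; simulator claims
  are restricted to qualitative directions.
- No motion-artefact handling beyond the channel subtraction.
- The mapping of (AbC, DBP) onto the stored reference coefficients is
  unresolved at the source; both mappings are constructible.
- In-sample AUC on small cohorts is optimistic by construction; the
  cross-validated alternative is not implemented, only flagged in reports.
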