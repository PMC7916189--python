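# ldflow

Signal processing for **laser Doppler flowmetry (LDF)**: a non-invasive
optical technique that measures skin blood perfusion from the Doppler
broadening of laser light scattered by moving red blood cells. `ldflow`
implements the full analysis chain of a dual-photodiode digital LDF
channel — frame-wise Doppler power spectra, idc²-normalised spectral
moments, cumulative-sum curves with the **Area between Curves (AbC)**
statistic, thermal-provocation features, and linear discriminant
classification — together with a synthetic Doppler simulator so that every
stage is testable without clinical recordings.

## The method

Each 0.05 s frame holds 2500 samples per channel at 50 kHz. The channel
difference `iac2 − iac1` suppresses common-mode motion artefacts; its
one-sided power spectrum `S(f)` is truncated at 12 800 Hz, giving 640 bins
of 20 Hz and a 20 Hz output rate for the moment series:

- perfusion `PU = (K/idc²) ∫ f·S(f) df` — first spectral moment;
- `CMBC = (1/idc²) ∫ S(f) df` — zeroth moment, concentration of moving
  blood cells;
- mean speed `⟨v⟩ = ∫ f·S df / ∫ S df` — scale-free speed estimate.

The cumulative-sum curve

```
C_n = C_{n−1} + f_n·S(f_n) / Σ_i f_i·S(f_i),   C_0 = 0
```

gives the fraction of the perfusion signal localised below each frequency.
It is invariant under amplitude scaling of the spectrum, so it isolates
*redistribution* of spectral mass (a change in the scatterer speed
distribution) from proportional amplification. **AbC** is the area enclosed
between two stage-averaged curves from a starting frequency (default
60 Hz) to their first intersection; it vanishes exactly under pure
amplitude change and grows under spectral broadening.

For the three-stage local-heating test (10 min at 33 °C, 5 min ramping at
2 °C/min to 42 °C, 3 min at 42 °C) the per-subject features are

```
DBP  = ⟨PU⟩_stage3 − ⟨PU⟩_stage1        ⟨v⟩31 = ⟨v⟩_stage3 − ⟨v⟩_stage1
```

plus the AbC between the stage-1 and stage-3 averaged curves. Two-class
LDA (pooled covariance, equal priors) over these features separates
blunted microvascular responses — the pattern associated with type 2
diabetes — from healthy responders; AUC is the tie-aware Mann–Whitney
statistic.

## Worked example

```python
import numpy as np
from ldflow import (make_profile, scaled_heating_plan, synth_recording,
                    extract_features, reference_classifier, discriminant_score)

plan = scaled_heating_plan(0.1)               # 1/10-timescale heating test
profile = make_profile("broadening")          # speed-redistribution responder
spectra = synth_recording(profile, plan=plan, rng=np.random.default_rng(1))
fv = extract_features(spectra, plan=plan)
print(f"AbC = {fv.abc:.1f}, DBP = {fv.dbp:.1f}, dv31 = {fv.dv31:.1f}")

y1 = reference_classifier("patients-vs-older")
print(f"Y1(0,0) = {discriminant_score(y1, (0.0, 0.0))}")
```

prints

```
AbC = 470.8, DBP = 1058.8, dv31 = 448.1
Y1(0,0) = -5.0622
```

The positive AbC and `dv31` say the simulated heating response moved
spectral mass to higher Doppler frequencies (faster scatterers), not just
amplified it; DBP is the plain perfusion rise. The stored discriminant `Y1`
reduces to its intercept at the zero feature vector.

The same pipeline runs from the shell:

```
ldflow simulate --kind cohort --seed 7 --n-per-group 5 --out cohort/
ldflow features cohort/ --out features.tsv
ldflow report features.tsv
```

which prints an in-sample AUC table over the feature subsets
(`dbp`, `abc`, `dv31`, their pairs, and the full triple).

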