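"""Synthetic Doppler photocurrent frames, spectra, recordings and cohorts.

No clinical laser-Doppler recordings are publicly deposited, so every
pipeline stage is exercised against a forward model with controlled
structure: a single-scatterer population whose Doppler line shape has a
width proportional to the mean scatterer speed (``v_scale``, Hz) and an
amplitude proportional to the moving-scatterer concentration (``conc``).
The line shape is normalised to unit area over the spectral grid, so the
zeroth moment (CMBC) is exactly proportional to ``conc`` and narrowing the
line raises the low-frequency amplitudes — the redistribution the
cumulative-sum analysis is designed to detect.

Two simulation routes exist.  The spectrum-domain route draws per-bin
sampling noise around the model spectrum and is the fast path used for
recordings and cohorts.  The time-domain route synthesises the two a.c.
photocurrent channels (shared Doppler-broadened component from spectrally
shaped white noise, independent channel noise, and a common-mode artefact
that the differential step cancels) and exists to test the FFT front end
end-to-end.

Claims made with this simulator are restricted to qualitative directions
(curve shifts under occlusion, band redistribution under breath holding,
the amplitude-vs-broadening dichotomy of the heating response); it is not a
photon-transport model of tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .protocol import (
    FeatureVector,
    StagePlan,
    extract_features,
    scaled_heating_plan,
)
from .spectral import (
    DEFAULT_BAND,
    DEFAULT_CUTOFF,
    DEFAULT_FRAME_LENGTH,
    DEFAULT_FS,
    Band,
    PhotocurrentFrame,
    PowerSpectrum,
)

__all__ = [
    "ScattererModel",
    "SubjectProfile",
    "Oscillation",
    "ARCHETYPES",
    "default_grid",
    "line_shape",
    "model_spectrum",
    "synth_spectrum",
    "synth_frame",
    "make_profile",
    "synth_recording",
    "synth_cohort",
    "synth_breath_hold",
    "synth_occlusion",
    "DEFAULT_GROUP_MIXES",
]

#: Tick period of the acquisition cycle (s); one spectrum per tick.
TICK = 0.05

#: Shape parameter of the per-bin gamma sampling noise (mean-preserving;
#: relative standard deviation 1/sqrt(k), here about 41%).
NOISE_SHAPE = 6.0


def default_grid(cutoff: float = DEFAULT_CUTOFF, df: float = 20.0) -> np.ndarray:
    """The standard spectral grid: bin centres df, 2*df, ..., cutoff."""
    n = int(round(cutoff / df))
    return np.arange(1, n + 1) * df


@dataclass(frozen=True)
class ScattererModel:
    """Moving-scatterer population behind one Doppler spectrum.

    ``shape`` is ``"lorentzian"`` (heavy-tailed, the conventional choice
    for Doppler broadening in tissue), ``"gaussian"``, or a mapping of
    shape names to mixture weights summing to 1.
    """

    v_scale: float = 800.0
    conc: float = 1.0
    shape: str | Mapping[str, float] = "lorentzian"
    noise_floor: float = 0.0
    idc: float = 1.0

    def __post_init__(self) -> None:
        if self.v_scale <= 0:
            raise ConfigurationError(f"v_scale must be positive, got {self.v_scale}")
        if self.conc < 0:
            raise ConfigurationError(f"conc must be non-negative, got {self.conc}")
        if self.noise_floor < 0:
            raise ConfigurationError("noise_floor must be non-negative")
        if isinstance(self.shape, Mapping):
            total = sum(self.shape.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ConfigurationError(f"mixture weights sum to {total}, not 1")


_PROFILES = {
    "lorentzian": lambda f, v: 1.0 / (1.0 + (f / v) ** 2),
    "gaussian": lambda f, v: np.exp(-0.5 * (f / v) ** 2),
}


def line_shape(
    f: np.ndarray, v_scale, shape: str | Mapping[str, float] = "lorentzian"
) -> np.ndarray:
    """Unit-area spectral line shape on the grid `f`.

    `v_scale` may be a scalar or an array broadcast against a leading time
    axis (then the result has shape ``(len(v_scale), len(f))`` with each row
    normalised to unit trapezoidal area).
    """
    v = np.asarray(v_scale, dtype=float)
    fv = f[np.newaxis, :] if v.ndim else f
    vv = v[:, np.newaxis] if v.ndim else v
    if isinstance(shape, Mapping):
        L = sum(w * _normalised(_PROFILES[name](fv, vv), f) for name, w in shape.items())
        return L
    return _normalised(_PROFILES[shape](fv, vv), f)


def _normalised(L: np.ndarray, f: np.ndarray) -> np.ndarray:
    area = np.trapezoid(L, f, axis=-1)
    return L / np.expand_dims(area, -1) if L.ndim > 1 else L / area


def model_spectrum(model: ScattererModel, f: np.ndarray | None = None) -> np.ndarray:
    """Expected (noise-free) spectrum ``conc * L(f; v_scale) + noise_floor``."""
    if f is None:
        f = default_grid()
    return model.conc * line_shape(f, model.v_scale, model.shape) + model.noise_floor


def synth_spectrum(
    model: ScattererModel,
    f: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    t0: float = 0.0,
    noise_shape: float = NOISE_SHAPE,
) -> PowerSpectrum:
    """One spectrum from the forward model.

    With an `rng`, each bin is drawn from a mean-preserving gamma
    distribution around the model value (multiplicative sampling noise,
    mimicking periodogram estimation variance); without one the expected
    spectrum is returned.
    """
    if f is None:
        f = default_grid()
    S = model_spectrum(model, f)
    if rng is not None and np.any(S > 0):
        S = np.where(S > 0, rng.gamma(noise_shape, 1.0 / noise_shape, size=len(f)) * S, 0.0)
    return PowerSpectrum(f=f, S=S, idc=model.idc, t0=t0)


def synth_frame(
    model: ScattererModel,
    fs: float = DEFAULT_FS,
    n_samples: int = DEFAULT_FRAME_LENGTH,
    rng: np.random.Generator | None = None,
    common_mode_amplitude: float = 0.0,
    t0: float = 0.0,
) -> PhotocurrentFrame:
    """Two-channel photocurrent frame whose differential spectrum follows the model.

    The Doppler component is white Gaussian noise shaped in the frequency
    domain to the model's one-sided power spectral density and split with
    opposite signs between the channels; each channel adds independent
    white noise realising the model's ``noise_floor`` in the differential
    spectrum, plus an identical common-mode artefact (a low-frequency
    sinusoid of the given amplitude) that the channel subtraction removes
    exactly.
    """
    if n_samples < 2:
        raise ConfigurationError(f"n_samples must be >= 2, got {n_samples}")
    rng = rng if rng is not None else np.random.default_rng()
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    # target one-sided PSD of the differential Doppler component
    G = model.conc * line_shape(freqs[1:], model.v_scale, model.shape)
    G = np.concatenate([[0.0], G])  # no DC power in the a.c. component
    W = np.fft.rfft(rng.standard_normal(n_samples))
    doppler = np.fft.irfft(W * np.sqrt(G * fs / 2.0), n=n_samples)

    sigma_ch = math.sqrt(model.noise_floor * fs) / 2.0
    n1 = sigma_ch * rng.standard_normal(n_samples) if sigma_ch else np.zeros(n_samples)
    n2 = sigma_ch * rng.standard_normal(n_samples) if sigma_ch else np.zeros(n_samples)

    t = t0 + np.arange(n_samples) / fs
    if common_mode_amplitude:
        cm = common_mode_amplitude * np.sin(
            2 * np.pi * 7.3 * t + rng.uniform(0, 2 * np.pi)
        )
    else:
        cm = np.zeros(n_samples)

    return PhotocurrentFrame(
        iac1=cm - 0.5 * doppler + n1,
        iac2=cm + 0.5 * doppler + n2,
        idc=model.idc,
        fs=fs,
        t0=t0,
    )


@dataclass(frozen=True)
class Oscillation:
    """One physiological modulation component of the concentration."""

    freq: float
    amplitude: float


#: Default slow physiological modulations: cardiac, respiratory and
#: slow (endothelial/neurogenic range) components.
DEFAULT_OSCILLATIONS = (
    Oscillation(1.0, 0.10),
    Oscillation(0.3, 0.05),
    Oscillation(0.1, 0.08),
)

#: Stage-3 response multipliers (v_scale, conc) per subject archetype.
#: Broadening responders shift spectral mass to higher frequencies, amplitude
#: responders scale it proportionally, mixed do both, non-responders (the
#: diabetic-patient pattern) barely react.
ARCHETYPES: dict[str, tuple[float, float]] = {
    "broadening": (1.5, 1.3),
    "amplitude": (1.0, 3.0),
    "mixed": (1.4, 2.2),
    "non-responder": (1.05, 1.15),
}


@dataclass(frozen=True)
class SubjectProfile:
    """Baseline scatterer model plus heating response and modulations."""

    archetype: str
    baseline: ScattererModel = field(default_factory=ScattererModel)
    v_mult: float = 1.0
    conc_mult: float = 1.0
    oscillations: tuple[Oscillation, ...] = DEFAULT_OSCILLATIONS
    seed: int | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.v_mult <= 0 or self.conc_mult <= 0:
            raise ConfigurationError("response multipliers must be positive")


def make_profile(
    archetype: str,
    rng: np.random.Generator | None = None,
    baseline: ScattererModel | None = None,
    subject_id: str | None = None,
) -> SubjectProfile:
    """Subject profile of the given archetype with between-subject variation.

    With an `rng`, the baseline width/concentration and the response
    multipliers receive moderate log-normal jitter (sigma 0.15 and 0.08)
    emulating inter-individual spread; without one the archetype's nominal
    parameters are returned.
    """
    if archetype not in ARCHETYPES:
        raise ConfigurationError(
            f"unknown archetype {archetype!r}; choose from {sorted(ARCHETYPES)}"
        )
    v_mult, conc_mult = ARCHETYPES[archetype]
    base = baseline if baseline is not None else ScattererModel()
    if rng is not None:
        base = replace(
            base,
            v_scale=base.v_scale * rng.lognormal(0.0, 0.15),
            conc=base.conc * rng.lognormal(0.0, 0.15),
        )
        v_mult = 1.0 + (v_mult - 1.0) * rng.lognormal(0.0, 0.08)
        conc_mult = 1.0 + (conc_mult - 1.0) * rng.lognormal(0.0, 0.08)
    return SubjectProfile(
        archetype=archetype,
        baseline=base,
        v_mult=v_mult,
        conc_mult=conc_mult,
        subject_id=subject_id,
    )


def _modulated_series(
    profile: SubjectProfile,
    t: np.ndarray,
    response: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tick (v_scale, conc) trajectories.

    `response` in [0, 1] interpolates the stage-3 multipliers; the
    physiological oscillations modulate the concentration only, so a pure
    amplitude responder leaves the cumulative curves exactly unchanged.
    """
    v = profile.baseline.v_scale * (1.0 + (profile.v_mult - 1.0) * response)
    osc = np.ones_like(t)
    for o in profile.oscillations:
        # deterministic phase offset per component keeps the series reproducible
        osc += o.amplitude * np.sin(2 * np.pi * o.freq * t + o.freq)
    conc = profile.baseline.conc * (1.0 + (profile.conc_mult - 1.0) * response) * np.clip(osc, 0.05, None)
    return v, conc


def _spectra_matrix(
    profile: SubjectProfile,
    t: np.ndarray,
    v: np.ndarray,
    conc: np.ndarray,
    f: np.ndarray,
    rng: np.random.Generator | None,
    noise_shape: float,
) -> list[PowerSpectrum]:
    L = line_shape(f, v, profile.baseline.shape)
    S = conc[:, np.newaxis] * L + profile.baseline.noise_floor
    if rng is not None:
        S = S * rng.gamma(noise_shape, 1.0 / noise_shape, size=S.shape)
    idc = profile.baseline.idc
    return [
        PowerSpectrum(f=f, S=S[i], idc=idc, t0=float(t[i])) for i in range(len(t))
    ]


def synth_recording(
    profile: SubjectProfile,
    plan: StagePlan | None = None,
    f: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    dt: float = TICK,
    noise_shape: float = NOISE_SHAPE,
) -> list[PowerSpectrum]:
    """Protocol-shaped spectra series for one subject.

    One spectrum per `dt` tick over the plan's duration.  The heating
    response follows the plan's temperature trajectory: the stage-3
    multipliers are scaled by the normalised temperature rise, giving a
    smooth transition through the ramp stage.  Sampling noise is applied
    when an `rng` is given (or the profile carries a seed).
    """
    if plan is None:
        plan = scaled_heating_plan()
    if f is None:
        f = default_grid()
    if rng is None and profile.seed is not None:
        rng = np.random.default_rng(profile.seed)
    t = np.arange(plan.stages[0].t_start, plan.stages[-1].t_end - dt / 2, dt)
    temp0 = plan.stages[0].temperature_at(t[0])
    temp3 = plan.stages[-1].temperature_at(plan.stages[-1].t_start)
    temps = np.array([plan.temperature_at(ti) for ti in t])
    span = temp3 - temp0
    response = (temps - temp0) / span if span else np.zeros_like(t)
    v, conc = _modulated_series(profile, t, response)
    return _spectra_matrix(profile, t, v, conc, f, rng, noise_shape)


#: Archetype mixture per group in the default two-group cohort: healthy
#: responders span both response mechanisms; the patient group shows the
#: blunted (non-responder) pattern.
DEFAULT_GROUP_MIXES: dict[str, dict[str, float]] = {
    "responder": {"broadening": 0.4, "amplitude": 0.3, "mixed": 0.3},
    "patient": {"non-responder": 1.0},
}


def synth_cohort(
    n_per_group: int = 50,
    group_mixes: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    plan: StagePlan | None = None,
    band: Band = DEFAULT_BAND,
    f_start: float = 60.0,
    dt: float = TICK,
) -> pd.DataFrame:
    """Labelled feature table for a simulated cohort.

    Every subject's features are produced by running the full pipeline —
    protocol-shaped spectra through moment extraction, stage-averaged
    cumulative curves and the stage differences — never by sampling
    features directly.  Deterministic given `seed`.  The default plan is
    the 1/10-timescale heating plan, keeping a 100-subject cohort at
    desk scale.
    """
    if n_per_group < 2:
        raise ConfigurationError(f"n_per_group must be >= 2, got {n_per_group}")
    if group_mixes is None:
        group_mixes = DEFAULT_GROUP_MIXES
    if plan is None:
        plan = scaled_heating_plan()
    f = default_grid()
    root = np.random.default_rng(seed)
    rows = []
    for group, mix in group_mixes.items():
        names = list(mix)
        probs = np.array([mix[n] for n in names], dtype=float)
        probs = probs / probs.sum()
        for i in range(n_per_group):
            rng = np.random.default_rng(root.integers(2**31))
            archetype = names[rng.choice(len(names), p=probs)]
            sid = f"{group}-{i:03d}"
            profile = make_profile(archetype, rng=rng, subject_id=sid)
            spectra = synth_recording(profile, plan=plan, f=f, rng=rng, dt=dt)
            fv = extract_features(
                spectra, plan=plan, band=band, f_start=f_start,
                subject_id=sid, group=group,
            )
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "archetype": archetype,
                    "abc": fv.abc,
                    "dbp": fv.dbp,
                    "dv31": fv.dv31,
                }
            )
    return pd.DataFrame(rows)


def _transition(t: np.ndarray, start: float, end: float, ramp: float) -> np.ndarray:
    """Raised-cosine gate: 0 before `start`, 1 inside, 0 after `end`."""
    up = np.clip((t - start) / ramp, 0.0, 1.0)
    down = np.clip((end - t) / ramp, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))


def _provocation_series(
    profile: SubjectProfile,
    timings: tuple[float, float, float],
    v_factor: float,
    conc_factor: float,
    f: np.ndarray | None,
    rng: np.random.Generator | None,
    dt: float,
    noise_shape: float,
) -> list[PowerSpectrum]:
    baseline_s, hold_s, recovery_s = timings
    if min(timings) < 0 or hold_s == 0:
        raise ConfigurationError(f"invalid timings {timings}")
    if f is None:
        f = default_grid()
    total = baseline_s + hold_s + recovery_s
    t = np.arange(0.0, total - dt / 2, dt)
    gate = _transition(t, baseline_s, baseline_s + hold_s, ramp=min(2.0, hold_s / 4))
    v = profile.baseline.v_scale * (1.0 + (v_factor - 1.0) * gate)
    osc = np.ones_like(t)
    for o in profile.oscillations:
        osc += o.amplitude * np.sin(2 * np.pi * o.freq * t + o.freq)
    conc = profile.baseline.conc * (1.0 + (conc_factor - 1.0) * gate) * np.clip(osc, 0.05, None)
    return _spectra_matrix(profile, t, v, conc, f, rng, noise_shape)


def synth_breath_hold(
    profile: SubjectProfile,
    timings: tuple[float, float, float] = (30.0, 20.0, 30.0),
    f: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    dt: float = TICK,
    v_factor: float = 0.45,
    conc_factor: float = 1.5,
    noise_shape: float = NOISE_SHAPE,
) -> list[PowerSpectrum]:
    """Breath-holding test series: (baseline, hold, recovery) seconds.

    During the hold the bulk of red cells slows while their concentration
    in the sampled volume rises; with the default factors the 60-400 Hz
    band perfusion increases while the 60-6400 Hz perfusion decreases,
    the characteristic low-frequency redistribution of the manoeuvre.
    """
    return _provocation_series(
        profile, timings, v_factor, conc_factor, f, rng, dt, noise_shape
    )


def synth_occlusion(
    profile: SubjectProfile,
    timings: tuple[float, float, float] = (30.0, 30.0, 30.0),
    f: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    dt: float = TICK,
    v_factor: float = 0.4,
    conc_factor: float = 0.4,
    noise_shape: float = NOISE_SHAPE,
) -> list[PowerSpectrum]:
    """Arterial-occlusion test series: flow nearly stops during the cuff.

    Both speed and moving-cell concentration drop, so spectral mass shifts
    to low frequencies and the occlusion-stage cumulative curve grows
    faster (lies above baseline pointwise).
    """
    return _provocation_series(
        profile, timings, v_factor, conc_factor, f, rng, dt, noise_shape
    )
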