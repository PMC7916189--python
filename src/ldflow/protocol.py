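"""Thermal provocation protocol: stage segmentation and stage-difference features.

The local-heating test records skin perfusion through three stages: a
baseline at 33 °C (10 min), a ramp at 2 °C/min up to 42 °C (5 min stage:
4.5 min of ramping, then hold), and a 42 °C plateau (3 min).  Moderate
heating activates nociceptive C-fibres and endothelial nitric-oxide
release, raising perfusion in healthy skin; the stage-difference features

    DBP     = <PU>_stage3  - <PU>_stage1      (perfusion units)
    <v>31   = <v>_stage3   - <v>_stage1       (speed units, Hz)

capture the amplitude and speed components of that response, and the AbC
statistic between the stage-averaged cumulative curves captures the
spectral redistribution.  Type 2 diabetes blunts all three.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import cumsum
from .errors import ConfigurationError, EmptyStageError
from .spectral import Band, DEFAULT_BAND, PerfusionSample, PowerSpectrum, spectra_to_series

__all__ = [
    "TemperatureRamp",
    "Stage",
    "StagePlan",
    "FeatureVector",
    "default_heating_plan",
    "scaled_heating_plan",
    "dbp",
    "dv31",
    "extract_features",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemperatureRamp:
    """Linear temperature ramp: start temperature, rate in °C/min, target."""

    start: float
    rate: float
    target: float

    def at(self, elapsed: float) -> float:
        """Temperature after `elapsed` seconds, clipped at the target."""
        t = self.start + self.rate / 60.0 * elapsed
        return min(t, self.target) if self.rate >= 0 else max(t, self.target)


@dataclass(frozen=True)
class Stage:
    """One protocol stage: half-open window [t_start, t_end) at a set
    temperature or ramp."""

    name: str
    t_start: float
    t_end: float
    temperature: float | TemperatureRamp

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ConfigurationError(
                f"stage {self.name!r}: t_start must precede t_end"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def contains(self, t: float) -> bool:
        return self.t_start <= t < self.t_end

    def temperature_at(self, t: float) -> float:
        if isinstance(self.temperature, TemperatureRamp):
            return self.temperature.at(t - self.t_start)
        return self.temperature

    @property
    def window(self) -> tuple[float, float]:
        return (self.t_start, self.t_end)


@dataclass(frozen=True)
class StagePlan:
    """Ordered, non-overlapping protocol stages."""

    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        for a, b in zip(self.stages, self.stages[1:]):
            if b.t_start < a.t_end:
                raise ConfigurationError(
                    f"stages {a.name!r} and {b.name!r} overlap or are out of order"
                )

    def __getitem__(self, name: str) -> Stage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def duration(self) -> float:
        return self.stages[-1].t_end - self.stages[0].t_start

    def temperature_at(self, t: float) -> float:
        """Set temperature at time `t`; outside any stage, the nearest
        stage's boundary temperature."""
        for s in self.stages:
            if s.contains(t):
                return s.temperature_at(t)
        if t < self.stages[0].t_start:
            return self.stages[0].temperature_at(self.stages[0].t_start)
        return self.stages[-1].temperature_at(self.stages[-1].t_end)


def default_heating_plan() -> StagePlan:
    """The standard three-stage heating protocol.

    stage1: 0–600 s at 33 °C; stage2: 600–900 s ramping at 2 °C/min from
    33 to 42 °C (target reached at 870 s, then held); stage3: 900–1080 s
    at 42 °C.
    """
    return StagePlan(
        stages=(
            Stage("stage1", 0.0, 600.0, 33.0),
            Stage("stage2", 600.0, 900.0, TemperatureRamp(33.0, 2.0, 42.0)),
            Stage("stage3", 900.0, 1080.0, 42.0),
        )
    )


def scaled_heating_plan(scale: float = 0.1) -> StagePlan:
    """Time-compressed heating plan for desk-scale simulation.

    Stage durations shrink by `scale` while the temperature trajectory is
    preserved (the ramp rate grows by 1/scale), so stage-relative dynamics
    are unchanged.  Features derived from stage averages are insensitive to
    the compression because stages remain internally stationary.
    """
    if not 0 < scale <= 1:
        raise ConfigurationError(f"scale must be in (0, 1], got {scale}")
    return StagePlan(
        stages=(
            Stage("stage1", 0.0, 600.0 * scale, 33.0),
            Stage(
                "stage2",
                600.0 * scale,
                900.0 * scale,
                TemperatureRamp(33.0, 2.0 / scale, 42.0),
            ),
            Stage("stage3", 900.0 * scale, 1080.0 * scale, 42.0),
        )
    )


def _stage_values(
    series: Sequence[PerfusionSample], stage: Stage, attr: str
) -> np.ndarray:
    vals = np.array(
        [getattr(s, attr) for s in series if stage.contains(s.t)], dtype=float
    )
    if len(vals) == 0:
        raise EmptyStageError(
            f"stage {stage.name!r} [{stage.t_start}, {stage.t_end}) s contains no samples"
        )
    return vals


def dbp(series: Sequence[PerfusionSample], stage1: Stage, stage3: Stage) -> float:
    """Heating response of perfusion: time-averaged PU in stage3 minus stage1."""
    return float(
        np.mean(_stage_values(series, stage3, "pu"))
        - np.mean(_stage_values(series, stage1, "pu"))
    )


def dv31(series: Sequence[PerfusionSample], stage1: Stage, stage3: Stage) -> float:
    """Heating response of mean speed: stage3 minus stage1 stage averages.

    Samples with undefined mean speed (NaN) are excluded from the averages;
    the exclusion count is logged.  Raises
    :class:`~ldflow.errors.EmptyStageError` if a stage holds no defined
    samples at all.
    """
    means = []
    for stage in (stage1, stage3):
        vals = _stage_values(series, stage, "vmean")
        defined = vals[~np.isnan(vals)]
        n_excluded = len(vals) - len(defined)
        if n_excluded:
            logger.warning(
                "stage %r: %d of %d samples had undefined mean speed and were excluded",
                stage.name, n_excluded, len(vals),
            )
        if len(defined) == 0:
            raise EmptyStageError(
                f"stage {stage.name!r} has no samples with a defined mean speed"
            )
        means.append(float(np.mean(defined)))
    return means[1] - means[0]


@dataclass(frozen=True)
class FeatureVector:
    """Per-subject feature triple (AbC, DBP, <v>31) fed to the classifiers."""

    abc: float
    dbp: float
    dv31: float
    subject_id: str | None = None
    group: str | None = None
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {"abc": self.abc, "dbp": self.dbp, "dv31": self.dv31}


def extract_features(
    spectra: Sequence[PowerSpectrum],
    plan: StagePlan | None = None,
    band: Band = DEFAULT_BAND,
    f_start: float = cumsum.DEFAULT_F_START,
    K: float = 1.0,
    subject_id: str | None = None,
    group: str | None = None,
    curve_mode: str = "curve-mean",
) -> FeatureVector:
    """Full feature extraction for one recording.

    Composes the spectral moments, the stage-averaged cumulative curves and
    the stage-difference statistics into one :class:`FeatureVector` for the
    plan's first and last stages.
    """
    if plan is None:
        plan = default_heating_plan()
    stage1, stage3 = plan.stages[0], plan.stages[-1]
    series = spectra_to_series(spectra, band=band, K=K)
    abc_res = cumsum.abc_between_stages(
        spectra, stage1, stage3, f_start=f_start, mode=curve_mode
    )
    return FeatureVector(
        abc=abc_res.abc,
        dbp=dbp(series, stage1, stage3),
        dv31=dv31(series, stage1, stage3),
        subject_id=subject_id,
        group=group,
        meta={
            "f_cross": abc_res.f_cross,
            "crossed": abc_res.crossed,
            "f_start": f_start,
            "band": (band.fmin, band.fmax),
        },
    )
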