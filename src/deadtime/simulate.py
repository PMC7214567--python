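"""Synthetic counting experiments for a paralyzable gamma camera.

The generator works at rate level: for every scheduled frame it composes the
open-window true rate from the decaying sources (exact frame-averaged
activities) and the ambient rate, pushes it through the paralyzable response
R' = Rt*exp(-Rt*tau), derives each photopeak window by the rate-dependent
window fraction, and draws Poisson counts for the frame (or rounds the
expectation when noise is off).  An optional phenomenological "breakdown"
multiplies all windows by (1 - drop) above a threshold open-window rate,
mimicking the step-like response collapse real cameras show beyond the
paralyzable regime.

Two presets emulate the canonical calibration experiments: an *intrinsic*
run (no collimator; three 99mTc sources of 125/125/250 MBq measured through
decay in 60-s frames over ~29 h, 300-s background frames, 49 source frames)
and an *extrinsic phantom* run (two ~1.4 GBq sources behind a LEHR
collimator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DetectorConfig,
    EnergyWindow,
    RadioactiveSource,
    WindowChannel,
    frame_average_activity,
    observed_rate,
    window_fraction_at_rate,
)
from .estimation import CalibrationPoint, CountMeasurement, MeasurementSeries

__all__ = [
    "Frame",
    "BreakdownModel",
    "SimulationConfig",
    "expected_observed_rates",
    "simulate_series",
    "noiseless_calibration_points",
    "make_intrinsic_preset",
    "make_phantom_preset",
    "TC99M_HALF_LIFE_S",
]

TC99M_HALF_LIFE_S = 6.01 * 3600.0


@dataclass(frozen=True)
class Frame:
    """One scheduled acquisition: which sources are up, which windows record."""

    t_start: float
    duration: float
    source_ids: frozenset[str] = frozenset()
    windows: tuple[str, ...] = ("OW",)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        object.__setattr__(self, "source_ids", frozenset(self.source_ids))


@dataclass(frozen=True)
class BreakdownModel:
    """Step-like response collapse above a threshold open-window rate."""

    threshold_ow_rate: float
    drop_fraction: float

    def __post_init__(self) -> None:
        if self.threshold_ow_rate <= 0:
            raise ValueError("threshold_ow_rate must be > 0")
        if not (0 < self.drop_fraction < 1):
            raise ValueError("drop_fraction must be in (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    detector: DetectorConfig
    sources: tuple[RadioactiveSource, ...]
    schedule: tuple[Frame, ...]
    poisson_noise: bool = True
    seed: int = 0
    breakdown: BreakdownModel | None = None

    def __post_init__(self) -> None:
        # frames must not overlap in time on the one detector
        spans = sorted((f.t_start, f.t_start + f.duration) for f in self.schedule)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping frames at t={s1}")
        known = {s.source_id for s in self.sources}
        for f in self.schedule:
            missing = f.source_ids - known
            if missing:
                raise ValueError(f"frame at t={f.t_start}: unknown sources {sorted(missing)}")

    def source(self, source_id: str) -> RadioactiveSource:
        for s in self.sources:
            if s.source_id == source_id:
                return s
        raise KeyError(source_id)


def _ow_channel(detector: DetectorConfig) -> WindowChannel:
    ch = detector.channel(detector.open_window)
    if ch is None:
        raise ValueError(
            f"detector {detector.detector_id!r} has no open-window channel "
            f"{detector.open_window!r}; the simulator needs one"
        )
    return ch


def expected_observed_rates(config: SimulationConfig, frame: Frame) -> dict[str, float]:
    """Noise-free observed rate (cps) in every window the frame records.

    The open-window true rate is the sum of source contributions (sensitivity
    times exact frame-averaged activity) plus the ambient rate; dead time
    acts on that whole-spectrum rate, and each photopeak window is the
    open-window observed rate scaled by its rate-dependent window fraction.
    """
    det = config.detector
    ow = _ow_channel(det)
    true_ow = ow.background_rate + sum(
        ow.sensitivity * frame_average_activity(config.source(sid), frame.t_start, frame.duration)
        for sid in frame.source_ids
    )
    obs_ow = observed_rate(true_ow, det.tau_system)
    factor = 1.0
    if config.breakdown is not None and obs_ow > config.breakdown.threshold_ow_rate:
        factor = 1.0 - config.breakdown.drop_fraction
    rates = {}
    for name in frame.windows:
        ch = det.require_channel(name)
        if name == det.open_window:
            rates[name] = obs_ow * factor
        else:
            wf = window_fraction_at_rate(ch.base_window_fraction, ch.fraction_slope, obs_ow)
            rates[name] = obs_ow * wf * factor
    return rates


def simulate_series(config: SimulationConfig) -> MeasurementSeries:
    """Generate a measurement series from the schedule.

    Counts are Poisson draws from rate*duration under a generator seeded by
    ``config.seed`` (identical config => identical series), or rounded
    expectations with noise off.  The series metadata carries the generating
    truth — dead time, sensitivities, fraction model, seed, and which frames
    hit the breakdown regime — so estimators can be checked against it.
    """
    rng = np.random.default_rng(config.seed)
    det = config.detector
    measurements: list[CountMeasurement] = []
    breakdown_frames: list[float] = []
    for frame in sorted(config.schedule, key=lambda f: f.t_start):
        rates = expected_observed_rates(config, frame)
        if config.breakdown is not None:
            ow = _ow_channel(det)
            true_ow = ow.background_rate + sum(
                ow.sensitivity
                * frame_average_activity(config.source(sid), frame.t_start, frame.duration)
                for sid in frame.source_ids
            )
            if observed_rate(true_ow, det.tau_system) > config.breakdown.threshold_ow_rate:
                breakdown_frames.append(frame.t_start)
        for name in frame.windows:
            mu = rates[name] * frame.duration
            counts = int(rng.poisson(mu)) if config.poisson_noise else int(round(mu))
            measurements.append(
                CountMeasurement(
                    detector_id=det.detector_id,
                    window=name,
                    t_start=frame.t_start,
                    duration=frame.duration,
                    counts=counts,
                    source_ids=frame.source_ids,
                )
            )
    truth = {
        "tau_system": det.tau_system,
        "open_window": det.open_window,
        "channels": {
            ch.window.name: {
                "sensitivity": ch.sensitivity,
                "base_window_fraction": ch.base_window_fraction,
                "fraction_slope": ch.fraction_slope,
                "background_rate": ch.background_rate,
            }
            for ch in det.channels
        },
        "breakdown_frames": sorted(breakdown_frames),
    }
    metadata = {
        "generator": "deadtime.simulate",
        "seed": config.seed,
        "poisson_noise": config.poisson_noise,
        "truth": truth,
    }
    return MeasurementSeries(
        measurements=measurements, sources=list(config.sources), metadata=metadata
    )


def noiseless_calibration_points(config: SimulationConfig, window: str) -> list[CalibrationPoint]:
    """Exact (activity, rate) pairs for the source frames of a schedule.

    This is the rate-level output before counts are quantized to integers —
    the generator's own exact curve, used to check estimators to solver
    precision.  Ambient background is subtracted exactly as a constant, i.e.
    the pairs are net of the open-window ambient contribution only when it
    is zero; with nonzero ambient the returned rates are raw.
    """
    pts = []
    for frame in sorted(config.schedule, key=lambda f: f.t_start):
        if not frame.source_ids:
            continue
        if window not in frame.windows:
            continue
        rates = expected_observed_rates(config, frame)
        activity = sum(
            frame_average_activity(config.source(sid), frame.t_start, frame.duration)
            for sid in frame.source_ids
        )
        ow_rate = rates.get(config.detector.open_window)
        if ow_rate is None:
            ow_frame = Frame(
                t_start=frame.t_start,
                duration=frame.duration,
                source_ids=frame.source_ids,
                windows=(config.detector.open_window,),
            )
            ow_rate = expected_observed_rates(config, ow_frame)[config.detector.open_window]
        pts.append(
            CalibrationPoint(
                activity=activity,
                net_rate=rates[window],
                t_start=frame.t_start,
                ow_rate=ow_rate,
            )
        )
    return pts


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_MBQ = 1e6
_KCPS_PER_MBQ = 1e3 / 1e6  # cps/Bq


def _session_frames(
    t0: float,
    combos: list[frozenset[str]],
    windows: tuple[str, ...],
    frame_s: float = 60.0,
    gap_s: float = 60.0,
    bg_s: float = 300.0,
) -> list[Frame]:
    """One measurement session: background, the source combinations, background."""
    frames = [Frame(t_start=t0, duration=bg_s, windows=windows)]
    t = t0 + bg_s + gap_s
    for combo in combos:
        frames.append(Frame(t_start=t, duration=frame_s, source_ids=combo, windows=windows))
        t += frame_s + gap_s
    frames.append(Frame(t_start=t, duration=bg_s, windows=windows))
    return frames


def make_intrinsic_preset(
    seed: int = 0,
    poisson_noise: bool = True,
    background_ow: float = 0.0,
    breakdown: BreakdownModel | None = BreakdownModel(2.0e5, 0.30),
) -> SimulationConfig:
    """Intrinsic (no collimator) triple-source calibration run.

    Three 99mTc sources (125, 125 and 250 MBq at t=0) are cycled through the
    combinations 1, 2, 1+2, 3, 1+2+3 in ten sessions spread over ~28.6 h
    (the last session stops before the three-source frame), giving 49 60-s
    source frames per energy window bracketed by 300-s background frames.
    Detector parameters: tau = 1.30 us, C_OW = 0.78 kcps/MBq,
    C_Tc = 0.48 kcps/MBq (window fraction 0.48/0.78 at low rate) and a
    window-fraction loss of 9.5 percentage points per 100 kcps.  Breakdown
    is on by default at 200 kcps open-window rate so the highest-activity
    frame leaves the paralyzable regime, as a real camera's does.
    """
    windows = ("OW", "Tc")
    c_ow = 0.78 * _KCPS_PER_MBQ
    base_wf = 0.48 / 0.78
    detector = DetectorConfig(
        detector_id="det1",
        tau_system=1.30e-6,
        channels=(
            WindowChannel(
                window=EnergyWindow("OW", 0.0, 1022.0),
                sensitivity=c_ow,
                background_rate=background_ow,
            ),
            WindowChannel(
                window=EnergyWindow("Tc", 126.5, 154.6),
                sensitivity=base_wf * c_ow,
                base_window_fraction=base_wf,
                fraction_slope=-0.095 / 1e5,
            ),
        ),
        breakdown_threshold=None if breakdown is None else breakdown.threshold_ow_rate,
    )
    sources = (
        RadioactiveSource("s1", 125 * _MBQ, 0.0, TC99M_HALF_LIFE_S),
        RadioactiveSource("s2", 125 * _MBQ, 0.0, TC99M_HALF_LIFE_S),
        RadioactiveSource("s3", 250 * _MBQ, 0.0, TC99M_HALF_LIFE_S),
    )
    full = [
        frozenset({"s1"}),
        frozenset({"s2"}),
        frozenset({"s1", "s2"}),
        frozenset({"s3"}),
        frozenset({"s1", "s2", "s3"}),
    ]
    schedule: list[Frame] = []
    session_spacing = 11440.0  # ~0.53 half-lives; 10 sessions span ~28.6 h
    for k in range(10):
        combos = full if k < 9 else full[:4]
        schedule.extend(_session_frames(k * session_spacing, combos, windows))
    return SimulationConfig(
        detector=detector,
        sources=sources,
        schedule=tuple(schedule),
        poisson_noise=poisson_noise,
        seed=seed,
        breakdown=breakdown,
    )


def make_phantom_preset(
    seed: int = 0,
    poisson_noise: bool = True,
    background_ow: float = 0.0,
) -> SimulationConfig:
    """Extrinsic scatter-phantom run behind a LEHR collimator.

    Two ~1.4 GBq 99mTc sources measured separately and together in eight
    sessions over ~29 h.  tau = 0.92 us; the collimated open-window
    sensitivity of 0.075 kcps/MBq puts the combined 2.8 GBq start near
    200 kcps, representative of post-therapy patient rates; in-scatter the
    photopeak holds ~40% of the spectrum and loses 5.1 percentage points of
    window fraction per 100 kcps.
    """
    windows = ("OW", "Tc")
    c_ow = 0.075 * _KCPS_PER_MBQ
    base_wf = 0.40
    detector = DetectorConfig(
        detector_id="det1",
        tau_system=0.92e-6,
        channels=(
            WindowChannel(
                window=EnergyWindow("OW", 0.0, 1022.0),
                sensitivity=c_ow,
                background_rate=background_ow,
            ),
            WindowChannel(
                window=EnergyWindow("Tc", 126.5, 154.6),
                sensitivity=base_wf * c_ow,
                base_window_fraction=base_wf,
                fraction_slope=-0.051 / 1e5,
            ),
        ),
    )
    sources = (
        RadioactiveSource("p1", 1400 * _MBQ, 0.0, TC99M_HALF_LIFE_S),
        RadioactiveSource("p2", 1400 * _MBQ, 0.0, TC99M_HALF_LIFE_S),
    )
    combos = [frozenset({"p1"}), frozenset({"p2"}), frozenset({"p1", "p2"})]
    schedule: list[Frame] = []
    for k in range(8):
        schedule.extend(_session_frames(k * 15000.0, combos, windows))
    return SimulationConfig(
        detector=detector,
        sources=sources,
        schedule=tuple(schedule),
        poisson_noise=poisson_noise,
        seed=seed,
    )
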