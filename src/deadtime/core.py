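"""Paralyzable-detector forward model, decay arithmetic and window dead time.

A paralyzable (extendable) detector with resolving time ``tau`` records an
event only if no other event — recorded or not — arrived within ``tau``
before it.  For Poisson arrivals at true rate ``Rt`` the observed rate is

    R' = Rt * exp(-Rt * tau)

which rises to a maximum ``R'_max = 1/(e*tau)`` at ``Rt = 1/tau`` and then
falls back towards zero: a single observed rate is compatible with two true
rates, one on each side of the peak.

Everything in this module works in strict internal units: seconds, counts
per second (cps) and becquerel.  Presentation units (µs, kcps, MBq) belong
to the I/O layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnergyWindow",
    "RadioactiveSource",
    "WindowChannel",
    "DetectorConfig",
    "QuantificationFactors",
    "observed_rate",
    "max_observed_rate",
    "peak_true_rate",
    "decay_activity",
    "frame_average_activity",
    "window_tau",
    "estimate_eta",
    "window_fraction_at_rate",
]

_LN2 = math.log(2.0)


def _maybe_scalar(out: np.ndarray, *inputs) -> "float | np.ndarray":
    if all(np.isscalar(x) or getattr(x, "ndim", 1) == 0 for x in inputs):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyWindow:
    """A named energy acceptance interval, edges in keV."""

    name: str
    lower_kev: float
    upper_kev: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("energy window needs a non-empty name")
        if not (0 <= self.lower_kev < self.upper_kev):
            raise ValueError(
                f"window {self.name!r}: need 0 <= lower < upper, "
                f"got [{self.lower_kev}, {self.upper_kev}]"
            )

    @property
    def width_kev(self) -> float:
        return self.upper_kev - self.lower_kev


@dataclass(frozen=True)
class RadioactiveSource:
    """A decaying source described by a single reference point.

    Parameters
    ----------
    source_id : str
        Label used to reference the source from measurement frames.
    reference_activity : float
        Activity in Bq at ``reference_time``.
    reference_time : float
        Time (s, experiment clock) the reference activity refers to.
    half_life : float
        Physical half-life in seconds (99mTc: 6.01 h = 21636 s).
    """

    source_id: str
    reference_activity: float
    reference_time: float
    half_life: float

    def __post_init__(self) -> None:
        if self.reference_activity <= 0:
            raise ValueError("reference_activity must be > 0")
        if self.half_life <= 0:
            raise ValueError("half_life must be > 0")

    def activity(self, t: float) -> float:
        """Decay-corrected activity at time ``t`` (may precede the reference)."""
        return decay_activity(self, t)


@dataclass(frozen=True)
class WindowChannel:
    """Per-energy-window response of one detector.

    ``sensitivity`` is the low-rate count rate per unit activity (cps/Bq) for
    the geometry the configuration describes.  ``base_window_fraction`` and
    ``fraction_slope`` describe the pile-up driven decline of the window
    fraction with the *open-window observed* rate: fraction(R'_OW) =
    base + slope * R'_OW, clipped to [0, 1].  ``background_rate`` is the
    ambient (no-source) rate in this window, in cps.
    """

    window: EnergyWindow
    sensitivity: float
    base_window_fraction: float = 1.0
    fraction_slope: float = 0.0
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError(f"channel {self.window.name!r}: sensitivity must be > 0")
        if not (0 < self.base_window_fraction <= 1):
            raise ValueError(
                f"channel {self.window.name!r}: base_window_fraction must be in (0, 1]"
            )
        if self.background_rate < 0:
            raise ValueError(f"channel {self.window.name!r}: background_rate must be >= 0")


@dataclass(frozen=True)
class DetectorConfig:
    """One detector head: system dead time plus its energy-window channels.

    The dead time is a property of the detector as a whole, driven by every
    photon it stops — hence a single ``tau_system`` that applies to the open
    window, with narrower windows inheriting losses through their window
    fraction.  ``breakdown_threshold`` (optional) is the open-window observed
    rate above which the paralyzable model is known not to apply for this
    camera; it is metadata for validity filtering, not part of the model.
    """

    detector_id: str
    tau_system: float
    channels: tuple[WindowChannel, ...]
    open_window: str = "OW"
    breakdown_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.tau_system <= 0:
            raise ValueError("tau_system must be > 0")
        names = [ch.window.name for ch in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate window names in detector {self.detector_id!r}")
        ow = self.channel(self.open_window)
        if ow is not None and (ow.base_window_fraction != 1.0 or ow.fraction_slope != 0.0):
            raise ValueError(
                "the open window channel must have base_window_fraction = 1 "
                "and fraction_slope = 0"
            )

    def channel(self, name: str) -> WindowChannel | None:
        for ch in self.channels:
            if ch.window.name == name:
                return ch
        return None

    def require_channel(self, name: str) -> WindowChannel:
        ch = self.channel(name)
        if ch is None:
            raise KeyError(f"detector {self.detector_id!r} has no window {name!r}")
        return ch


@dataclass(frozen=True)
class QuantificationFactors:
    """Optional scalar factors relating detector counts to in-vivo activity.

    ``background_tissue_factor`` (F) corrects for activity in over/underlying
    tissue; ``absorption_factor`` (exp(mu_e * d)) for attenuation inside the
    object.  Both default to 1, the point-source-in-air case.
    """

    background_tissue_factor: float = 1.0
    absorption_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.background_tissue_factor < 1 or self.absorption_factor < 1:
            raise ValueError("quantification factors must be >= 1")

    @property
    def combined(self) -> float:
        return self.background_tissue_factor * self.absorption_factor


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def observed_rate(true_rate, tau):
    """Observed count rate of a paralyzable detector, R' = Rt * exp(-Rt*tau).

    Accepts scalars or arrays (broadcast).  ``tau = 0`` is the ideal
    detector: the observed rate equals the true rate.
    """
    rt = np.asarray(true_rate, dtype=float)
    tv = np.asarray(tau, dtype=float)
    if np.any(rt < 0):
        raise ValueError("true_rate must be >= 0")
    if np.any(tv < 0):
        raise ValueError("tau must be >= 0")
    out = rt * np.exp(-rt * tv)
    return _maybe_scalar(out, true_rate, tau)


def max_observed_rate(tau: float) -> float:
    """Peak observed rate (e*tau)^-1 a paralyzable detector can show."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return 1.0 / (math.e * tau)


def peak_true_rate(tau: float) -> float:
    """True rate 1/tau at which the observed rate peaks."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return 1.0 / tau


def decay_activity(source: RadioactiveSource, t) -> "float | np.ndarray":
    """Activity of ``source`` at time ``t`` (s): A0 * 2**(-(t - t0)/T1/2)."""
    tt = np.asarray(t, dtype=float)
    out = source.reference_activity * np.exp2(-(tt - source.reference_time) / source.half_life)
    return _maybe_scalar(out, t)


def frame_average_activity(source: RadioactiveSource, t_start: float, duration: float) -> float:
    """Exact time-averaged activity over the frame [t_start, t_start+duration].

    Integrating the decay law gives
    A(t_start) * (1 - 2**(-d/T)) * T / (d * ln 2); evaluated through expm1
    so the short-frame limit degrades gracefully to A(t_start).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    x = duration / source.half_life * _LN2
    a0 = decay_activity(source, t_start)
    # (1 - exp(-x))/x, stable for tiny x
    factor = -math.expm1(-x) / x
    return a0 * factor


# ---------------------------------------------------------------------------
# energy-window dead time
# ---------------------------------------------------------------------------

def window_tau(tau_ow: float, window_fraction: float, eta: float) -> float:
    """Apparent dead time of a narrower window: tau_EW = tau_OW / w_f**eta.

    With ``eta = 1`` this is the classical counting-system relation
    tau_EW = tau_OW / w_f; larger eta absorbs the extra photopeak losses
    caused by pulse pile-up.
    """
    if tau_ow <= 0:
        raise ValueError("tau_ow must be > 0")
    if not (0 < window_fraction <= 1):
        raise ValueError("window_fraction must be in (0, 1]")
    if eta < 0:
        raise ValueError("eta must be >= 0")
    return tau_ow / window_fraction ** eta


def estimate_eta(tau_ew: float, tau_ow: float, window_fraction: float) -> float:
    """Exponent eta solving tau_EW = tau_OW / w_f**eta for measured dead times."""
    if tau_ow <= 0 or tau_ew < tau_ow:
        raise ValueError("need tau_ew >= tau_ow > 0")
    if not (0 < window_fraction <= 1):
        raise ValueError("window_fraction must be in (0, 1]")
    if window_fraction == 1.0:
        if tau_ew != tau_ow:
            raise ValueError("window_fraction = 1 cannot explain tau_ew != tau_ow")
        return 0.0
    return math.log(tau_ew / tau_ow) / math.log(1.0 / window_fraction)


def window_fraction_at_rate(base_fraction: float, fraction_slope: float, ow_observed_rate):
    """Window fraction at a given open-window observed rate, clipped to [0, 1].

    The slope convention is absolute change in the fraction per cps of
    open-window observed rate, so a loss of 9.5 percentage points per
    100 kcps is ``fraction_slope = -0.095 / 1e5``.
    """
    if not (0 < base_fraction <= 1):
        raise ValueError("base_fraction must be in (0, 1]")
    r = np.asarray(ow_observed_rate, dtype=float)
    out = np.clip(base_fraction + fraction_slope * r, 0.0, 1.0)
    return _maybe_scalar(out, ow_observed_rate)
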