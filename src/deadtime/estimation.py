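"""Dead-time and sensitivity estimation from timed count measurements.

Three estimators for the resolving time tau of a paralyzable detector:

* **dual-source** — two sources measured separately and together; under the
  paralyzable model the three background-subtracted rates give
  ``tau = 2*R12'/(R1'+R2')**2 * ln((R1'+R2')/R12')``, exact for equal
  sources.  A triple-source schedule chains this: tau at the two-source
  activity level from frames {1},{2},{1,2} and at the three-source level
  from {1,2},{3},{1,2,3}.
* **graphical** — for a decaying source, ``ln(R'/A) = ln(C) - C*tau*A`` is
  linear in activity; an unweighted least-squares line yields both the
  sensitivity C (intercept) and tau (slope), with no low-rate "no-loss"
  assumption.
* **MCR** — the peak of the observed count-rate curve fixes
  ``tau = 1/(e * R'_max)``.

Window-fraction diagnostics quantify pile-up: the photopeak/open-window
count ratio declines roughly linearly with open-window rate, reported as
percent loss per 100 kcps.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import RadioactiveSource, frame_average_activity

__all__ = [
    "CountMeasurement",
    "MeasurementSeries",
    "DualSourceResult",
    "GraphicalFitResult",
    "WindowFractionResult",
    "CalibrationPoint",
    "LowCountWarning",
    "net_rate",
    "background_rate",
    "dual_source_tau",
    "dual_source_error_bound",
    "dual_source_error_scan",
    "triple_source_schedule",
    "calibration_points",
    "graphical_fit",
    "fit_series_graphical",
    "tau_from_mcr",
    "window_fraction_series",
    "window_fraction_fit",
    "pdm_validity_filter",
]

logger = logging.getLogger(__name__)


class LowCountWarning(UserWarning):
    """A background-subtracted rate fell below zero and was floored."""


# ---------------------------------------------------------------------------
# measurement containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMeasurement:
    """One timed counting frame for one detector and energy window.

    An empty ``source_ids`` set marks a background frame.
    """

    detector_id: str
    window: str
    t_start: float
    duration: float
    counts: int
    source_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.counts < 0:
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "source_ids", frozenset(self.source_ids))

    @property
    def raw_rate(self) -> float:
        return self.counts / self.duration

    @property
    def is_background(self) -> bool:
        return not self.source_ids


@dataclass
class MeasurementSeries:
    """An ordered collection of frames plus the source table behind them."""

    measurements: list[CountMeasurement]
    sources: list[RadioactiveSource]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = {s.source_id for s in self.sources}
        for m in self.measurements:
            missing = m.source_ids - known
            if missing:
                raise ValueError(
                    f"frame at t={m.t_start} references unknown source(s) {sorted(missing)}"
                )

    def source(self, source_id: str) -> RadioactiveSource:
        for s in self.sources:
            if s.source_id == source_id:
                return s
        raise KeyError(source_id)

    def frames(self, detector_id: str, window: str) -> list[CountMeasurement]:
        out = [
            m
            for m in self.measurements
            if m.detector_id == detector_id and m.window == window
        ]
        return sorted(out, key=lambda m: m.t_start)

    def detectors(self) -> list[str]:
        return sorted({m.detector_id for m in self.measurements})

    def windows(self, detector_id: str) -> list[str]:
        return sorted({m.window for m in self.measurements if m.detector_id == detector_id})

    def frame_activity(self, m: CountMeasurement) -> float:
        """Exact frame-averaged total activity of the sources present (Bq)."""
        return sum(
            frame_average_activity(self.source(sid), m.t_start, m.duration)
            for sid in m.source_ids
        )


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def net_rate(measurement: CountMeasurement, background_rate: float) -> float:
    """Background-subtracted rate (cps), floored at zero with a warning."""
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    r = measurement.raw_rate - background_rate
    if r < 0:
        warnings.warn(
            f"frame at t={measurement.t_start}: rate below background, floored to 0",
            LowCountWarning,
            stacklevel=2,
        )
        return 0.0
    return r


def background_rate(series: MeasurementSeries, detector_id: str, window: str) -> float:
    """Pooled ambient rate: total background counts over total background time."""
    bg = [m for m in series.frames(detector_id, window) if m.is_background]
    if not bg:
        raise ValueError(
            f"no background frames for detector {detector_id!r}, window {window!r}"
        )
    return sum(m.counts for m in bg) / sum(m.duration for m in bg)


def _background_or_zero(series: MeasurementSeries, detector_id: str, window: str) -> float:
    try:
        return background_rate(series, detector_id, window)
    except ValueError:
        return 0.0


# ---------------------------------------------------------------------------
# dual / triple source
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DualSourceResult:
    """One dual-source tau estimate and the rates that produced it."""

    tau: float
    total_activity: float = float("nan")
    component_rates: tuple[float, float, float] = (float("nan"),) * 3
    valid: bool = True
    detector_id: str | None = None
    window: str | None = None
    t_start: float | None = None


def dual_source_tau(r1: float, r2: float, r12: float) -> DualSourceResult:
    """Resolving time from two sources measured apart and together.

    All three rates must be background-subtracted.  When the combined rate is
    not below the sum of the single rates the estimate would be non-positive;
    the result is then flagged invalid rather than raised, since Poisson
    noise at low rates produces such triples routinely.
    """
    if min(r1, r2, r12) <= 0:
        raise ValueError("all three rates must be > 0")
    s = r1 + r2
    tau = 2.0 * r12 / s**2 * math.log(s / r12)
    return DualSourceResult(tau=tau, component_rates=(r1, r2, r12), valid=tau > 0)


def dual_source_error_bound(rt1: float, rt2: float) -> float:
    """Leading-order relative error of the dual-source estimate for unequal
    sources: (Rt1 - Rt2)**2 / (4 * (Rt1 + Rt2)**2)."""
    if rt1 <= 0 or rt2 <= 0:
        raise ValueError("true rates must be > 0")
    return (rt1 - rt2) ** 2 / (4.0 * (rt1 + rt2) ** 2)


def dual_source_error_scan(
    tau: float = 1e-6,
    fractions=None,
    n_levels: int = 20,
    level_lo: float = 0.35,
    level_hi: float = 0.95,
):
    """Noiseless worst-case scan of the dual-source estimator.

    For each source-1 activity share ``f`` and each combined observed rate
    level (fraction of the peak rate (e*tau)^-1), generate the three exact
    paralyzable-model rates, re-estimate tau, and record the relative error.

    Returns ``(max_relative_error, grid)`` with grid rows
    ``(fraction, level, relative_error)``.
    """
    from .correction import correct_rate  # local import avoids a cycle

    if fractions is None:
        fractions = np.arange(0.44, 0.55 + 1e-9, 0.01)
    levels = np.linspace(level_lo, level_hi, n_levels)
    rmax = 1.0 / (math.e * tau)
    grid = []
    for f in np.asarray(fractions, dtype=float):
        for lv in levels:
            r12 = lv * rmax
            rt12 = correct_rate(r12, tau)
            rt1, rt2 = f * rt12, (1.0 - f) * rt12
            r1 = rt1 * math.exp(-rt1 * tau)
            r2 = rt2 * math.exp(-rt2 * tau)
            est = dual_source_tau(r1, r2, r12)
            grid.append((f, lv, abs(est.tau - tau) / tau))
    grid = np.array(grid)
    return float(grid[:, 2].max()), grid


def _decay_scale(
    series: MeasurementSeries, component: CountMeasurement, combined: CountMeasurement
) -> float:
    """Activity ratio moving a component frame's rate to the combined frame's time."""
    a_at_combined = sum(
        frame_average_activity(series.source(sid), combined.t_start, combined.duration)
        for sid in component.source_ids
    )
    a_at_component = sum(
        frame_average_activity(series.source(sid), component.t_start, component.duration)
        for sid in component.source_ids
    )
    return a_at_combined / a_at_component


def triple_source_schedule(
    series: MeasurementSeries, detector_id: str, window: str
) -> list[DualSourceResult]:
    """All dual-source tau estimates a combination schedule supports.

    Every frame whose source set splits into two separately measured subsets
    yields one estimate: {1},{2} -> {1,2} and {1,2},{3} -> {1,2,3} for the
    canonical five-frame pattern.  Component frames are matched by nearest
    acquisition time and their rates decay-aligned (scaled by the activity
    ratio) to the combined frame before the estimate; combinations lacking a
    usable split are skipped with a logged reason.
    """
    frames = [m for m in series.frames(detector_id, window) if not m.is_background]
    bg = _background_or_zero(series, detector_id, window)
    by_set: dict[frozenset, list[CountMeasurement]] = {}
    for m in frames:
        by_set.setdefault(m.source_ids, []).append(m)

    results: list[DualSourceResult] = []
    for combined in frames:
        if len(combined.source_ids) < 2:
            continue
        # candidate partitions into two measured, disjoint subsets
        partitions = []
        for sa in by_set:
            if sa and sa < combined.source_ids:
                sb = combined.source_ids - sa
                if sb in by_set and (sa, sb) not in partitions and (sb, sa) not in partitions:
                    partitions.append((sa, sb))
        if not partitions:
            logger.info(
                "no measured split for combination %s at t=%s; skipped",
                sorted(combined.source_ids), combined.t_start,
            )
            continue

        def nearest(subset):
            return min(by_set[subset], key=lambda m: abs(m.t_start - combined.t_start))

        sa, sb = min(
            partitions,
            key=lambda p: abs(nearest(p[0]).t_start - combined.t_start)
            + abs(nearest(p[1]).t_start - combined.t_start),
        )
        fa, fb = nearest(sa), nearest(sb)
        try:
            r1 = net_rate(fa, bg) * _decay_scale(series, fa, combined)
            r2 = net_rate(fb, bg) * _decay_scale(series, fb, combined)
            r12 = net_rate(combined, bg)
            res = dual_source_tau(r1, r2, r12)
        except ValueError as exc:
            logger.info(
                "combination %s at t=%s unusable (%s); skipped",
                sorted(combined.source_ids), combined.t_start, exc,
            )
            continue
        results.append(
            replace(
                res,
                total_activity=series.frame_activity(combined),
                detector_id=detector_id,
                window=window,
                t_start=combined.t_start,
            )
        )
    return results


# ---------------------------------------------------------------------------
# graphical (decaying-source) fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationPoint:
    """(activity, net rate) pair for the graphical fit, with context."""

    activity: float
    net_rate: float
    t_start: float = float("nan")
    ow_rate: float | None = None


@dataclass(frozen=True)
class GraphicalFitResult:
    """Outcome of the log-linear decaying-source fit.

    ``sensitivity`` = exp(intercept) in cps/Bq, ``tau`` = -slope/sensitivity
    in seconds; standard errors by first-order propagation of the linear-fit
    covariance (``nan`` with only two points, where the line is exact).
    """

    sensitivity: float
    tau: float
    se_sensitivity: float
    se_tau: float
    r_squared: float
    n_used: int
    n_excluded: int
    intercept: float = float("nan")
    slope: float = float("nan")

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("fitted sensitivity must be > 0")
        if self.n_used < 2:
            raise ValueError("a graphical fit needs at least 2 points")


def _as_pairs(points):
    out = []
    for p in points:
        if isinstance(p, CalibrationPoint):
            out.append((p.activity, p.net_rate))
        else:
            a, r = p[0], p[1]
            out.append((float(a), float(r)))
    return out


def graphical_fit(points, exclusions=None) -> GraphicalFitResult:
    """Unweighted least squares of ln(net_rate/activity) against activity.

    ``points`` is an iterable of (activity, net_rate) pairs or
    :class:`CalibrationPoint`; ``exclusions``, if given, is a predicate on
    the original points marking those to leave out.  Points with
    non-positive activity or rate are excluded and counted.
    """
    raw = list(points)
    keep = []
    n_excluded = 0
    for p in raw:
        if exclusions is not None and exclusions(p):
            n_excluded += 1
            continue
        keep.append(p)
    pairs = _as_pairs(keep)
    usable = [(a, r) for a, r in pairs if a > 0 and r > 0]
    n_excluded += len(pairs) - len(usable)
    if len(usable) < 2:
        raise ValueError(
            f"fewer than 2 usable points after exclusions ({len(usable)} left)"
        )

    a = np.array([p[0] for p in usable])
    y = np.log(np.array([p[1] for p in usable]) / a)
    n = len(a)

    # two-parameter OLS with covariance via the normal equations
    x = np.column_stack([np.ones(n), a])
    xtx = x.T @ x
    beta = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    if n > 2:
        cov = rss / (n - 2) * np.linalg.inv(xtx)
    else:
        cov = np.full((2, 2), np.nan)

    b0, b1 = beta
    sens = math.exp(b0)
    tau = -b1 / sens
    # first-order propagation: C = e^{b0}; tau = -b1 * e^{-b0}
    g_c = np.array([sens, 0.0])
    g_tau = np.array([-tau, -1.0 / sens])
    se_c = float(np.sqrt(g_c @ cov @ g_c)) if n > 2 else float("nan")
    se_tau = float(np.sqrt(g_tau @ cov @ g_tau)) if n > 2 else float("nan")

    return GraphicalFitResult(
        sensitivity=sens,
        tau=tau,
        se_sensitivity=se_c,
        se_tau=se_tau,
        r_squared=r2,
        n_used=n,
        n_excluded=n_excluded,
        intercept=float(b0),
        slope=float(b1),
    )


def calibration_points(
    series: MeasurementSeries,
    detector_id: str,
    window: str,
    open_window: str = "OW",
) -> list[CalibrationPoint]:
    """Build (activity, net rate) pairs for the graphical fit from a series.

    The open-window observed rate of the simultaneous frame, when present,
    is attached so validity filtering by rate is possible.
    """
    bg = _background_or_zero(series, detector_id, window)
    ow_frames = {}
    if window != open_window:
        bg_ow = _background_or_zero(series, detector_id, open_window)
        for m in series.frames(detector_id, open_window):
            if not m.is_background:
                ow_frames[(m.t_start, m.duration)] = net_rate(m, bg_ow)
    pts = []
    for m in series.frames(detector_id, window):
        if m.is_background:
            continue
        r = net_rate(m, bg)
        ow = r if window == open_window else ow_frames.get((m.t_start, m.duration))
        pts.append(
            CalibrationPoint(
                activity=series.frame_activity(m),
                net_rate=r,
                t_start=m.t_start,
                ow_rate=ow,
            )
        )
    return pts


def fit_series_graphical(
    series: MeasurementSeries,
    detector_id: str,
    window: str,
    exclusions=None,
    open_window: str = "OW",
) -> GraphicalFitResult:
    """Convenience: calibration points from a series, then the graphical fit."""
    return graphical_fit(
        calibration_points(series, detector_id, window, open_window), exclusions
    )


# ---------------------------------------------------------------------------
# MCR
# ---------------------------------------------------------------------------

def tau_from_mcr(max_observed_rate: float) -> float:
    """Resolving time from the peak of the observed count-rate curve:
    tau = 1 / (e * R'_max)."""
    if max_observed_rate <= 0:
        raise ValueError("max_observed_rate must be > 0")
    return 1.0 / (math.e * max_observed_rate)


# ---------------------------------------------------------------------------
# window fraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowFractionResult:
    """Per-frame window fractions and the fitted loss per 100 kcps."""

    points: tuple[tuple[float, float], ...]  # (ow_rate_cps, fraction)
    slope_per_cps: float
    se_slope_per_cps: float
    intercept: float
    loss_pct_per_100kcps: float
    se_loss_pct_per_100kcps: float
    n_pairs: int
    n_skipped: int


def window_fraction_fit(points) -> WindowFractionResult:
    """Unweighted linear fit of window fraction against open-window rate.

    The headline number is the fit slope expressed as percent change of the
    fraction per 100 kcps of open-window rate (the scale on which pile-up
    losses are usually quoted).
    """
    pts = [(float(r), float(f)) for r, f in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 (rate, fraction) points")
    r = np.array([p[0] for p in pts])
    f = np.array([p[1] for p in pts])
    n = len(r)
    x = np.column_stack([np.ones(n), r])
    xtx = x.T @ x
    beta = np.linalg.solve(xtx, x.T @ f)
    resid = f - x @ beta
    rss = float(resid @ resid)
    if n > 2:
        cov = rss / (n - 2) * np.linalg.inv(xtx)
        se_slope = float(np.sqrt(cov[1, 1]))
    else:
        se_slope = float("nan")
    slope = float(beta[1])
    to_pct = 1e5 * 100.0  # fraction/cps -> percent per 100 kcps
    return WindowFractionResult(
        points=tuple(pts),
        slope_per_cps=slope,
        se_slope_per_cps=se_slope,
        intercept=float(beta[0]),
        loss_pct_per_100kcps=slope * to_pct,
        se_loss_pct_per_100kcps=se_slope * to_pct,
        n_pairs=n,
        n_skipped=0,
    )


def window_fraction_series(
    series: MeasurementSeries,
    detector_id: str,
    photopeak_window: str,
    open_window: str = "OW",
) -> WindowFractionResult:
    """Window-fraction curve from simultaneously acquired frame pairs.

    Frames are paired by identical (t_start, duration); pairs missing either
    window, or with non-positive open-window net rate, are skipped and
    counted.
    """
    bg_pk = _background_or_zero(series, detector_id, photopeak_window)
    bg_ow = _background_or_zero(series, detector_id, open_window)
    pk = {
        (m.t_start, m.duration): m
        for m in series.frames(detector_id, photopeak_window)
        if not m.is_background
    }
    ow = {
        (m.t_start, m.duration): m
        for m in series.frames(detector_id, open_window)
        if not m.is_background
    }
    points = []
    n_skipped = 0
    for key in sorted(set(pk) | set(ow)):
        if key not in pk or key not in ow:
            n_skipped += 1
            logger.info("frame %s present in only one window; skipped", key)
            continue
        r_ow = net_rate(ow[key], bg_ow)
        if r_ow <= 0:
            n_skipped += 1
            continue
        points.append((r_ow, net_rate(pk[key], bg_pk) / r_ow))
    fit = window_fraction_fit(points)
    return replace(fit, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# validity filtering
# ---------------------------------------------------------------------------

def pdm_validity_filter(
    points,
    ow_rate_cutoff: float | None = None,
    activity_cutoff: float | None = None,
):
    """Partition calibration points into (included, excluded) by an explicit
    cutoff on open-window rate (cps) or activity (Bq).

    The paralyzable model is known to break down above a camera-specific
    rate; the cutoff is the analyst's, never detected automatically, and
    excluded points are returned rather than dropped.
    """
    if ow_rate_cutoff is None and activity_cutoff is None:
        raise ValueError("provide ow_rate_cutoff and/or activity_cutoff")
    included, excluded = [], []
    for p in points:
        over = False
        if activity_cutoff is not None and p.activity > activity_cutoff:
            over = True
        if ow_rate_cutoff is not None:
            if p.ow_rate is None:
                raise ValueError(
                    "ow_rate_cutoff given but a point has no open-window rate"
                )
            if p.ow_rate > ow_rate_cutoff:
                over = True
        (excluded if over else included).append(p)
    return included, excluded
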