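import math

import pytest
from hypothesis import settings

import deadtime as dt

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def bisect_w0(z: float, tol: float = 1e-14) -> float:
    """Independent oracle for W0 on [-1/e, 0]: bisection on w*e^w = z."""
    lo, hi = -1.0, 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid * math.exp(mid) < z:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def bisect_true_rate(observed: float, tau: float, tol: float = 1e-14) -> float:
    """Independent oracle for the sub-peak inversion of R' = Rt*exp(-Rt*tau)."""
    lo, hi = 0.0, 1.0 / tau
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid * math.exp(-mid * tau) < observed:
            lo = mid
        else:
            hi = mid
        if (hi - lo) * tau < tol:
            break
    return 0.5 * (lo + hi)


@pytest.fixture(scope="session")
def table1_series():
    """Noiseless five-frame combination series (1, 2, 1+2, 3, 1+2+3).

    Sources are effectively constant in activity (very long half-life) and
    frames are long (600 s), so neither decay misalignment nor integer-count
    quantization obscures the purely algebraic properties under test.
    """
    hl = 1e12
    sources = (
        dt.RadioactiveSource("s1", 125e6, 0.0, hl),
        dt.RadioactiveSource("s2", 125e6, 0.0, hl),
        dt.RadioactiveSource("s3", 250e6, 0.0, hl),
    )
    det = dt.DetectorConfig(
        "det1",
        1.2e-6,
        (dt.WindowChannel(dt.EnergyWindow("OW", 0.0, 1022.0), 7.8e-4),),
    )
    combos = [{"s1"}, {"s2"}, {"s1", "s2"}, {"s3"}, {"s1", "s2", "s3"}]
    frames = tuple(
        dt.Frame(t_start=700.0 * i, duration=600.0, source_ids=frozenset(c), windows=("OW",))
        for i, c in enumerate(combos)
    )
    cfg = dt.SimulationConfig(det, sources, frames, poisson_noise=False, seed=0)
    return dt.simulate_series(cfg)


@pytest.fixture(scope="session")
def intrinsic_noiseless_series():
    return dt.simulate_series(dt.make_intrinsic_preset(poisson_noise=False))
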