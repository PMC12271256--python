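"""Measurements on simulated colonies.

Front position (threshold crossing of the living-cell density), expansion
speed (least-squares slope of the front trace after the transient), pulse vs
wave-front classification of 1D profiles, and the amplitude of a transverse
cosine mode of a 2D front contour — the quantity that tracks the floral
(petal) instability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import Grid, State, Trajectory, _check_admissible

__all__ = [
    "NoFrontError",
    "FrontTrace",
    "SpeedEstimate",
    "ProfileMetrics",
    "ModeAmplitudeTrace",
    "front_position",
    "front_trace",
    "expansion_speed",
    "profile_metrics",
    "front_contour",
    "mode_amplitude",
]

#: default living-cell density marking the colony edge
DEFAULT_FRONT_THRESHOLD = 0.05


class NoFrontError(ValueError):
    """The profile never reaches the front threshold."""


@dataclass
class FrontTrace:
    """Front position x_f(t) sampled at snapshot times."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.shape != self.positions.shape:
            raise ValueError("times and positions must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class SpeedEstimate:
    """Fitted expansion speed with fit quality indicators.

    ``relative_variation`` measures how much the speed is still changing
    across the fit window: the fitted slopes of the two window halves are
    compared relative to the full-window slope (least squares averages out
    the sub-cell wobble of the interpolated front marker; with fewer than 6
    points it falls back to the spread of the instantaneous finite-difference
    speeds).  Small values indicate settled travelling-wave propagation.
    """

    speed: float
    window: tuple[float, float]
    residual_std: float
    relative_variation: float


@dataclass
class ProfileMetrics:
    """Shape summary of a 1D living-cell profile.

    ``classification`` is ``"pulse"`` when the colony core has lost most of
    its living cells (core density below half the peak: a proliferating rim
    around a necrotic interior), ``"wavefront"`` when living cells span the
    colony, and ``"extinct"`` when the profile is identically zero.
    """

    classification: str
    peak: float
    peak_location: float
    fwhm: float | None
    core_value: float
    core_nutrient: float


@dataclass
class ModeAmplitudeTrace:
    """Amplitude a_q(t) of the cos(q*y) component of the front contour."""

    times: np.ndarray
    amplitudes: np.ndarray
    q: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.amplitudes < 0):
            raise ValueError("mode amplitudes are magnitudes and must be >= 0")


def front_position(
    x: np.ndarray, n: np.ndarray, threshold: float = DEFAULT_FRONT_THRESHOLD
) -> float:
    """Largest x at which ``n`` crosses the threshold, linearly interpolated.

    Taking the outermost crossing makes the marker robust to interior
    structure (e.g. a dip behind the front).  If the profile is still above
    threshold at the wall, the wall position is returned.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    above = n >= threshold
    if not above.any():
        raise NoFrontError(f"profile never reaches the front threshold {threshold:g}")
    i = int(np.max(np.nonzero(above)))
    if i == n.size - 1:
        return float(x[-1])
    # interpolate within the bracketing cell [x_i, x_{i+1}]
    frac = (n[i] - threshold) / (n[i] - n[i + 1])
    return float(x[i] + frac * (x[i + 1] - x[i]))


def front_trace(traj: Trajectory, threshold: float = DEFAULT_FRONT_THRESHOLD) -> FrontTrace:
    """Front position at every snapshot of a 1D trajectory."""
    if traj.grid.ndim != 1:
        raise ValueError("front_trace expects a 1D trajectory")
    times, pos = [], []
    for s in traj.snapshots:
        times.append(s.t)
        pos.append(front_position(traj.grid.x, s.n, threshold))
    return FrontTrace(np.array(times), np.array(pos))


def expansion_speed(trace: FrontTrace, window_fraction: float = 0.5) -> SpeedEstimate:
    """Least-squares expansion speed over the final fraction of the trace.

    Restricting the fit to the late-time window discards the transient during
    which the inoculum relaxes onto the travelling front.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must lie in (0, 1]")
    t, xf = trace.times, trace.positions
    t0 = t[-1] - window_fraction * (t[-1] - t[0])
    sel = t >= t0 - 1e-12
    if sel.sum() < 5:
        raise ValueError("speed fit needs >= 5 trace points in the window")
    tw, xw = t[sel], xf[sel]
    slope, intercept = np.polyfit(tw, xw, 1)
    resid = xw - (slope * tw + intercept)
    dof = max(tw.size - 2, 1)
    if tw.size >= 6:
        mid = tw.size // 2
        c1 = np.polyfit(tw[: mid + 1], xw[: mid + 1], 1)[0]
        c2 = np.polyfit(tw[mid:], xw[mid:], 1)[0]
        if abs(slope) < 1e-14:
            rel_var = 0.0 if abs(c2 - c1) < 1e-14 else np.inf
        else:
            rel_var = float(abs(c2 - c1) / abs(slope))
    else:
        inst = np.diff(xw) / np.diff(tw)
        mean = inst.mean()
        if abs(mean) < 1e-14:
            rel_var = 0.0 if np.ptp(inst) < 1e-14 else np.inf
        else:
            rel_var = float(np.ptp(inst) / abs(mean))
    return SpeedEstimate(
        speed=float(slope),
        window=(float(tw[0]), float(tw[-1])),
        residual_std=float(np.sqrt(np.sum(resid**2) / dof)),
        relative_variation=rel_var,
    )


def _half_crossing(x: np.ndarray, n: np.ndarray, level: float, i_peak: int, side: int) -> float | None:
    """Interpolated crossing of ``level`` walking out from the peak; None if
    the profile never falls below the level on that side."""
    i = i_peak
    while 0 <= i + side < n.size:
        j = i + side
        if n[j] < level:
            frac = (n[i] - level) / (n[i] - n[j])
            return float(x[i] + frac * (x[j] - x[i]))
        i = j
    return None


def profile_metrics(state: State, grid: Grid) -> ProfileMetrics:
    """Classify a 1D living-cell profile and summarise its shape."""
    if grid.ndim != 1:
        raise ValueError("profile_metrics expects a 1D state")
    n = state.n
    peak = float(n.max())
    if peak <= 0.0:
        return ProfileMetrics("extinct", 0.0, float(grid.x[0]), None, 0.0, float(state.g[0]))
    i_peak = int(np.argmax(n))
    core = float(n[0])
    classification = "pulse" if core < 0.5 * peak else "wavefront"
    fwhm = None
    if classification == "pulse":
        half = 0.5 * peak
        left = _half_crossing(grid.x, n, half, i_peak, -1)
        right = _half_crossing(grid.x, n, half, i_peak, +1)
        if left is not None and right is not None:
            fwhm = right - left
    return ProfileMetrics(
        classification=classification,
        peak=peak,
        peak_location=float(grid.x[i_peak]),
        fwhm=fwhm,
        core_value=core,
        core_nutrient=float(state.g[0]),
    )


def front_contour(
    state: State, grid: Grid, threshold: float = DEFAULT_FRONT_THRESHOLD
) -> np.ndarray:
    """Front position x_f(y) along every transverse line of a 2D state."""
    if grid.ndim != 2:
        raise ValueError("front_contour expects a 2D state")
    out = np.empty(grid.y.size)
    for j in range(grid.y.size):
        try:
            out[j] = front_position(grid.x, state.n[:, j], threshold)
        except NoFrontError as err:
            raise NoFrontError(f"no contour: y-line {j} has no front") from err
    return out


def mode_amplitude(contour: np.ndarray, y: np.ndarray, q: float) -> float:
    """Amplitude of the cos(q*y) Fourier component of a front contour.

    ``|(2/Ly) * integral x_f(y) cos(q*y) dy|`` by the trapezoid rule, which is
    spectrally accurate for whole cosine periods; a flat contour gives 0 and
    modes at other admissible wavenumbers are orthogonal.
    """
    contour = np.asarray(contour, dtype=float)
    y = np.asarray(y, dtype=float)
    ly = float(y[-1] - y[0])
    _check_admissible(q, ly)
    return float(abs(2.0 / ly * np.trapezoid(contour * np.cos(q * y), y)))
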