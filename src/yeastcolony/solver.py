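"""Spatial discretisation and explicit method-of-lines time integration.

Space is discretised on a uniform mesh with second-order centred differences;
every boundary face carries a zero-normal-derivative closure, which serves
both the no-flux Petri-dish wall and the symmetry plane at a coordinate-zero
face (the two are numerically identical for this system).  The closure is
implemented with reflected ghost nodes, equivalent on smooth fields to a
differentiation matrix with second-order one-sided boundary stencils.

Living cells move by degenerate nonlinear diffusion, flux ``D_n * n * grad n``,
which vanishes where ``n = 0`` and therefore produces compactly supported
colony fronts.  It is discretised through the identity
``div(n grad n) = 0.5 * lap(n^2)``, so the degenerate operator inherits the
Laplacian's boundary closure and its summation-by-parts conservation property
(with trapezoid quadrature weights).  Dead cells and nutrient diffuse
linearly.  Time stepping is plain first-order Euler under a diffusive
stability bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import DimensionlessParameters, reaction_terms

__all__ = [
    "Grid",
    "State",
    "Trajectory",
    "IntegratorError",
    "initial_condition_1d",
    "perturbed_initial_condition_2d",
    "laplacian",
    "degenerate_diffusion",
    "stable_dt",
    "step_euler",
    "run",
]

#: fields more negative than this indicate integrator failure; anything in
#: (-NEGATIVITY_TOL, 0) is a rounding artifact and is clamped to zero.
NEGATIVITY_TOL = 1e-12

FIELD_NAMES = ("n", "m1", "m2", "g")


class IntegratorError(RuntimeError):
    """Raised when time integration produces NaN/Inf or genuine negativity."""


@dataclass(frozen=True)
class Grid:
    """Uniform 1D or 2D mesh with zero-normal-derivative boundary closures.

    1D fields have shape ``(nx,)``; 2D fields ``(nx, ny)`` with x along axis
    0.  A face at coordinate zero is conventionally a symmetry plane and any
    other face the Petri-dish wall; both impose a vanishing first derivative.
    """

    x: np.ndarray
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.ndim != 1 or x.size < 5:
            raise ValueError("grid needs >= 5 nodes per axis for the stencils")
        dx = np.diff(x)
        if not np.allclose(dx, dx[0], rtol=1e-10) or dx[0] <= 0:
            raise ValueError("grid spacing must be uniform and positive")
        if self.y is not None:
            y = np.asarray(self.y, dtype=float)
            object.__setattr__(self, "y", y)
            if y.ndim != 1 or y.size < 5:
                raise ValueError("grid needs >= 5 nodes per axis for the stencils")
            dy = np.diff(y)
            if not np.allclose(dy, dy[0], rtol=1e-10) or dy[0] <= 0:
                raise ValueError("grid spacing must be uniform and positive")

    @classmethod
    def line(cls, x_max: float, dx: float, x_min: float = 0.0) -> "Grid":
        n = int(round((x_max - x_min) / dx)) + 1
        return cls(x=np.linspace(x_min, x_max, n))

    @classmethod
    def rectangle(
        cls,
        x_max: float,
        y_half_width: float,
        dx: float,
        dy: float | None = None,
        x_min: float = 0.0,
    ) -> "Grid":
        """Half-domain in x (symmetry at ``x_min = 0``), full span in y."""
        dy = dx if dy is None else dy
        nx = int(round((x_max - x_min) / dx)) + 1
        ny = int(round(2 * y_half_width / dy)) + 1
        return cls(
            x=np.linspace(x_min, x_max, nx),
            y=np.linspace(-y_half_width, y_half_width, ny),
        )

    @property
    def ndim(self) -> int:
        return 1 if self.y is None else 2

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        if self.y is None:
            raise AttributeError("1D grid has no dy")
        return float(self.y[1] - self.y[0])

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.x.size,) if self.y is None else (self.x.size, self.y.size)

    @property
    def y_extent(self) -> float:
        if self.y is None:
            raise AttributeError("1D grid has no y extent")
        return float(self.y[-1] - self.y[0])

    def quadrature_weights(self) -> np.ndarray:
        """Trapezoid cell volumes; the weights under which the semi-discrete
        diffusion operators conserve mass exactly."""
        wx = np.full(self.x.size, self.dx)
        wx[0] = wx[-1] = self.dx / 2
        if self.y is None:
            return wx
        wy = np.full(self.y.size, self.dy)
        wy[0] = wy[-1] = self.dy / 2
        return np.outer(wx, wy)

    def spec(self) -> dict:
        d = {"dx": self.dx, "x_min": float(self.x[0]), "x_max": float(self.x[-1])}
        if self.y is not None:
            d.update(dy=self.dy, y_min=float(self.y[0]), y_max=float(self.y[-1]))
        return d


@dataclass
class State:
    """The four model fields on a grid at one instant of dimensionless time."""

    t: float
    n: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    g: np.ndarray

    def fields(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (self.n, self.m1, self.m2, self.g)

    def copy(self) -> "State":
        return State(self.t, self.n.copy(), self.m1.copy(), self.m2.copy(), self.g.copy())

    def validate(self, grid: Grid) -> None:
        for name, f in zip(FIELD_NAMES, self.fields()):
            if f.shape != grid.shape:
                raise ValueError(f"field {name!r} shape {f.shape} != grid {grid.shape}")
            if not np.all(np.isfinite(f)):
                raise ValueError(f"field {name!r} contains non-finite values")


@dataclass
class Trajectory:
    """Ordered snapshots of a run plus the metadata needed to repeat it."""

    grid: Grid
    params: DimensionlessParameters
    snapshots: list[State] = field(default_factory=list)
    requested_times: list[float] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])

    def __len__(self) -> int:
        return len(self.snapshots)


def initial_condition_1d(
    grid: Grid, profile: Callable[[np.ndarray], np.ndarray] | None = None
) -> State:
    """Inoculum state: ``n = f(x)`` (default Gaussian ``exp(-x^2)``), no dead
    cells, spatially uniform nutrient ``g = 1``."""
    if grid.ndim != 1:
        raise ValueError("initial_condition_1d requires a 1D grid")
    f = profile if profile is not None else (lambda x: np.exp(-(x**2)))
    n = np.asarray(f(grid.x), dtype=float)
    if n.shape != grid.shape or not np.all(np.isfinite(n)):
        raise ValueError("initial profile must be finite on the grid")
    zeros = np.zeros_like(n)
    return State(t=0.0, n=n, m1=zeros.copy(), m2=zeros.copy(), g=np.ones_like(n))


def admissible_wavenumbers(y_extent: float, k_max: int = 12) -> np.ndarray:
    """Transverse wavenumbers compatible with no-flux walls: ``q = 2*pi*k/Ly``
    (an integer number of full cosine periods across the width)."""
    return 2 * np.pi * np.arange(1, k_max + 1) / y_extent


def _check_admissible(q: float, y_extent: float) -> None:
    # cos(q*y) must have zero derivative at y = +/- Ly/2, i.e. q*Ly/2 = k*pi
    k = q * y_extent / (2 * np.pi)
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        qs = admissible_wavenumbers(y_extent, 6)
        raise ValueError(
            f"wavenumber q={q:g} incompatible with no-flux walls on width "
            f"{y_extent:g}; admissible q = 2*pi*k/Ly, e.g. {np.round(qs, 4).tolist()}"
        )


def perturbed_initial_condition_2d(
    base: State, base_grid: Grid, grid2d: Grid, delta: float, q: float
) -> State:
    """Extend a 1D base state into 2D with a transverse cosine modulation.

    Every field becomes ``phi0(x) * (1 + delta*cos(q*y))`` — a planar front
    gently corrugated along the wall direction, used to probe the floral
    (petal-forming) front instability.  ``q`` must fit an integer number of
    periods in the width so the perturbation respects the no-flux walls.
    The base profile is interpolated onto the 2D grid's x axis with
    edge-value extension (cell tail -> 0, nutrient -> its far-field value),
    and the clock is reset to ``t = 0``.
    """
    if grid2d.ndim != 2:
        raise ValueError("perturbed_initial_condition_2d requires a 2D grid")
    if base_grid.ndim != 1 or base.n.ndim != 1:
        raise ValueError("base state must live on a 1D grid")
    if delta < 0:
        raise ValueError("perturbation amplitude delta must be >= 0")
    _check_admissible(q, grid2d.y_extent)
    mod = 1.0 + delta * np.cos(q * grid2d.y)[np.newaxis, :]

    def extend(phi0: np.ndarray) -> np.ndarray:
        return np.interp(grid2d.x, base_grid.x, phi0)[:, np.newaxis] * mod

    return State(
        t=0.0,
        n=extend(base.n),
        m1=extend(base.m1),
        m2=extend(base.m2),
        g=extend(base.g),
    )


def laplacian(f: np.ndarray, grid: Grid) -> np.ndarray:
    """Second-order centred Laplacian with reflected-ghost (zero normal
    derivative) boundary closure on every face."""
    f = np.asarray(f, dtype=float)
    if f.shape != grid.shape:
        raise ValueError(f"field shape {f.shape} does not match grid {grid.shape}")
    p = np.pad(f, 1, mode="reflect")
    if grid.ndim == 1:
        return (p[:-2] - 2.0 * f + p[2:]) / grid.dx**2
    core = p[1:-1, 1:-1]
    lap_x = (p[:-2, 1:-1] - 2.0 * core + p[2:, 1:-1]) / grid.dx**2
    lap_y = (p[1:-1, :-2] - 2.0 * core + p[1:-1, 2:]) / grid.dy**2
    return lap_x + lap_y


def degenerate_diffusion(n: np.ndarray, grid: Grid) -> np.ndarray:
    """Discrete ``div(n grad n)`` via the identity ``0.5 * lap(n^2)``.

    Shares the Laplacian's boundary closure, hence the same conservation
    property.  Negative ``n`` beyond the rounding tolerance signals that the
    integrator has already failed and is rejected here.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < -NEGATIVITY_TOL):
        raise IntegratorError(
            f"degenerate diffusion received n < {-NEGATIVITY_TOL:g} "
            f"(min {n.min():.3e}); reduce dt"
        )
    return 0.5 * laplacian(n * n, grid)


def _reaction_scale(params: DimensionlessParameters, state: State) -> float:
    """Crude upper estimate of the fastest pointwise reaction rate constant,
    used to cap dt away from the diffusive limit when kinetics are stiff."""
    g_max = float(np.max(state.g, initial=0.0))
    n_max = float(np.max(state.n, initial=0.0))
    half_window = 0.5 * (params.g_2 - params.g_1)
    return max(
        g_max + params.Lambda1 * params.g_dag + params.Lambda2 * half_window**2,
        params.Gamma1,
        params.Gamma2,
        params.C * n_max,
    )


def stable_dt(
    params: DimensionlessParameters,
    grid: Grid,
    state: State,
    safety: float = 0.2,
    cell_diffusion: str = "degenerate",
) -> float:
    """Explicit-Euler step bound: ``safety * h^2 / (2 * ndim * D_eff_max)``.

    ``D_eff`` is 1 for the nutrient, ``D_m1``/``D_m2`` for dead cells, and
    ``D_n * max(n)`` for the degenerate living-cell term (whose local
    diffusivity is proportional to the density).  Additionally capped at
    ``0.1 / J`` where ``J`` estimates the fastest reaction rate.
    """
    n_max = float(np.max(state.n, initial=0.0))
    d_n = params.D_n * n_max if cell_diffusion == "degenerate" else params.D_n
    d_max = max(d_n, params.D_m1, params.D_m2, 1.0)
    h2 = grid.dx**2 if grid.ndim == 1 else min(grid.dx, grid.dy) ** 2
    dt = safety * h2 / (2.0 * grid.ndim * d_max)
    j = _reaction_scale(params, state)
    if j > 0:
        dt = min(dt, 0.1 / j)
    return dt


def _rhs(
    state: State,
    params: DimensionlessParameters,
    grid: Grid,
    cell_diffusion: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Semi-discrete right-hand side (method of lines)."""
    n, m1, m2, g = state.fields()
    r = reaction_terms(n, m1, m2, g, params)
    if cell_diffusion == "degenerate":
        n_diff = params.D_n * degenerate_diffusion(n, grid)
    elif cell_diffusion == "linear":
        n_diff = params.D_n * laplacian(n, grid)
    else:
        raise ValueError(f"unknown cell_diffusion {cell_diffusion!r}")
    return (
        n_diff + r.dn_dt,
        params.D_m1 * laplacian(m1, grid) + r.dm1_dt,
        params.D_m2 * laplacian(m2, grid) + r.dm2_dt,
        laplacian(g, grid) + r.dg_dt,
    )


def _clamp_or_fail(arr: np.ndarray, name: str, t: float) -> np.ndarray:
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = np.unravel_index(np.argmax(bad), arr.shape)
        raise IntegratorError(f"field {name!r} non-finite at node {idx} (t={t:.6g})")
    neg = arr < -NEGATIVITY_TOL
    if neg.any():
        idx = np.unravel_index(np.argmax(neg), arr.shape)
        raise IntegratorError(
            f"field {name!r} = {arr[idx]:.3e} < {-NEGATIVITY_TOL:g} at node {idx} "
            f"(t={t:.6g}); reduce dt"
        )
    # rounding-level undershoots are clamped, anything larger errored above
    np.maximum(arr, 0.0, out=arr)
    return arr


def step_euler(
    state: State,
    params: DimensionlessParameters,
    grid: Grid,
    dt: float,
    cell_diffusion: str = "degenerate",
    enforce_stability: bool = True,
) -> State:
    """One forward-Euler step of the full semi-discretisation."""
    if enforce_stability:
        bound = stable_dt(params, grid, state, safety=1.0, cell_diffusion=cell_diffusion)
        if dt > bound * (1 + 1e-12):
            raise ValueError(f"dt={dt:g} exceeds stability bound {bound:g}")
    dn, dm1, dm2, dg = _rhs(state, params, grid, cell_diffusion)
    t_new = state.t + dt
    return State(
        t=t_new,
        n=_clamp_or_fail(state.n + dt * dn, "n", t_new),
        m1=_clamp_or_fail(state.m1 + dt * dm1, "m1", t_new),
        m2=_clamp_or_fail(state.m2 + dt * dm2, "m2", t_new),
        g=_clamp_or_fail(state.g + dt * dg, "g", t_new),
    )


def run(
    params: DimensionlessParameters,
    grid: Grid,
    initial: State,
    t_end: float,
    snapshot_times: Sequence[float] | None = None,
    cell_diffusion: str = "degenerate",
    safety: float = 0.2,
) -> Trajectory:
    """Integrate to ``t_end``, recording snapshots at the requested times.

    The step size is recomputed from :func:`stable_dt` whenever ``max(n)``
    grows by more than 10% (the degenerate diffusivity scales with density);
    otherwise it is held fixed for reproducibility.  Each snapshot is the
    state after the first step at or beyond its requested time; the actual
    time is stored.  The run is fully deterministic.
    """
    initial.validate(grid)
    if snapshot_times is None:
        snapshot_times = [t_end]
    requested = sorted(float(t) for t in snapshot_times)
    if requested and (requested[0] < -1e-12 or requested[-1] > t_end + 1e-9):
        raise ValueError("snapshot times must lie within [0, t_end]")

    traj = Trajectory(grid=grid, params=params, requested_times=list(requested))
    state = initial.copy()
    # the first snapshot is always the initial condition
    traj.snapshots.append(state.copy())
    pending = [t for t in requested if t > 1e-12]

    dt = stable_dt(params, grid, state, safety=safety, cell_diffusion=cell_diffusion)
    n_ref = float(np.max(state.n, initial=0.0))
    traj.metadata.update(
        dt_initial=dt,
        safety=safety,
        cell_diffusion=cell_diffusion,
        grid=grid.spec(),
        params=params.to_dict(),
        t_end=float(t_end),
    )

    while state.t < t_end - 1e-12:
        n_max = float(np.max(state.n, initial=0.0))
        if n_max > 1.1 * n_ref:
            dt = stable_dt(params, grid, state, safety=safety, cell_diffusion=cell_diffusion)
            n_ref = n_max
        try:
            state = step_euler(
                state, params, grid, dt, cell_diffusion=cell_diffusion, enforce_stability=False
            )
        except IntegratorError as err:
            raise IntegratorError(f"integration failed at t={state.t:.6g}: {err}") from err
        while pending and state.t >= pending[0] - 1e-12:
            traj.snapshots.append(state.copy())
            pending.pop(0)
    traj.metadata["dt_final"] = dt
    traj.metadata["t_final"] = state.t
    return traj
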