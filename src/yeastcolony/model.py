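"""Parameter sets and pointwise reaction kinetics.

The model describes a yeast colony biofilm growing on a Petri dish as four
coupled fields: living-cell density ``n``, two dead-cell densities ``m1``
(accidental cell death, ACD) and ``m2`` (regulated cell death, RCD), and the
nutrient concentration ``g``.  ACD is triggered when the nutrient drops below
a threshold ``g_dag`` (necrotic morphotype); RCD occurs inside a nutrient
window ``(g_1, g_2)`` and is hypothesised to be altruistic: broken-down dead
cells return a fraction of their mass to the nutrient pool.

The dimensionless reaction terms (diffusion excluded) are::

    dn/dt  =  n*g - L1*n*(g_dag - g)*H(g_dag - g)
                  - L2*n*(g - g_1)*(g_2 - g)*H(g - g_1)*H(g_2 - g)
    dm1/dt =  L1*n*(g_dag - g)*H(g_dag - g)        - G1*m1
    dm2/dt =  L2*n*(g - g_1)*(g_2 - g)*H(..)*H(..) - G2*m2
    dg/dt  = -C*n*g + K1*G1*m1 + K2*G2*m2

where ``H`` is the Heaviside step function (here ``H(0) = 0``; the choice is
unobservable because the multiplying factor vanishes at each threshold),
``L1``/``L2`` are the ACD/RCD rates, ``G1``/``G2`` the breakdown rates,
``C`` the nutrient consumption constant, and ``K1``/``K2`` the amount of
nutrient released per broken-down dead cell.

All simulations run on the dimensionless system; dimensional inputs are
converted once at the boundary via :func:`nondimensionalize`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DimensionalParameters",
    "DimensionlessParameters",
    "Nondimensionalization",
    "ReactionRates",
    "nondimensionalize",
    "acd_rate",
    "rcd_rate",
    "reaction_terms",
]


@dataclass(frozen=True)
class DimensionalParameters:
    """Dimensional model constants, as a biologist would estimate them.

    Units: diffusivities in area/time, ``alpha`` per nutrient concentration
    per time, ``c`` nutrient per new cell, ``lambda1`` per concentration per
    time, ``lambda2`` per concentration^2 per time, thresholds in nutrient
    concentration, ``gamma1``/``gamma2`` per time, ``k1``/``k2`` nutrient mass
    per dead cell, ``N0`` initial cell density, ``G0`` initial nutrient
    concentration.
    """

    D_n: float
    D_g: float
    D_m1: float
    D_m2: float
    alpha: float
    c: float
    lambda1: float
    lambda2: float
    g_dag: float
    g_1: float
    g_2: float
    gamma1: float
    gamma2: float
    k1: float
    k2: float
    N0: float
    G0: float

    _NONNEGATIVE = ("lambda1", "lambda2", "gamma1", "gamma2", "k1", "k2")

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be finite, got {v}")
            if f.name in self._NONNEGATIVE:
                if v < 0:
                    raise ValueError(f"parameter {f.name!r} must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"parameter {f.name!r} must be > 0, got {v}")
        if self.g_1 > self.g_2:
            raise ValueError("RCD window requires g_1 <= g_2")
        if self.g_dag > self.G0:
            raise ValueError("ACD threshold g_dag must not exceed G0")


@dataclass(frozen=True)
class DimensionlessParameters:
    """The thirteen dimensionless groups that fully parameterise the model.

    ``D_n`` is the (density-scaled) ratio of living-cell to nutrient
    diffusivity; ``D_m1``/``D_m2`` the dead-cell diffusivity ratios;
    ``Lambda1``/``Lambda2`` the ACD/RCD rates relative to proliferation;
    ``g_dag``, ``g_1``, ``g_2`` the nutrient thresholds on the [0, 1] scaled
    nutrient; ``Gamma1``/``Gamma2`` breakdown rates relative to nutrient
    uptake; ``C`` the consumption constant; ``K1``/``K2`` the nutrient
    released per dead cell that breaks down.
    """

    D_n: float = 0.47
    D_m1: float = 0.001
    D_m2: float = 0.001
    Lambda1: float = 0.0
    Lambda2: float = 0.0
    g_dag: float = 0.25
    g_1: float = 0.0
    g_2: float = 1.0
    Gamma1: float = 0.0
    Gamma2: float = 0.0
    C: float = 1.0
    K1: float = 0.0
    K2: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"group {f.name!r} must be finite and >= 0, got {v}")
        if self.g_1 > self.g_2:
            raise ValueError("RCD window requires g_1 <= g_2")

    def replace(self, **changes: float) -> "DimensionlessParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


# sanity: the group count is part of the model definition
assert len(dataclasses.fields(DimensionlessParameters)) == 13


@dataclass(frozen=True)
class Nondimensionalization:
    """Result of scaling a dimensional parameter set.

    ``space_scale`` (length) and ``time_scale`` (time) convert dimensionless
    coordinates back to dimensional ones: ``x* = space_scale * x``,
    ``t* = time_scale * t``.  Densities scale by ``N0`` and nutrient by ``G0``.
    """

    params: DimensionlessParameters
    space_scale: float
    time_scale: float


def nondimensionalize(p: DimensionalParameters) -> Nondimensionalization:
    """Map dimensional constants onto the thirteen dimensionless groups.

    Densities are scaled by the initial cell density ``N0``, nutrient by the
    initial concentration ``G0``, space by ``sqrt(D_g / (alpha * G0))`` (the
    ratio of nutrient diffusion to uptake) and time by ``1 / (alpha * G0)``.
    """
    groups = DimensionlessParameters(
        D_n=p.N0 * p.D_n / p.D_g,
        D_m1=p.D_m1 / p.D_g,
        D_m2=p.D_m2 / p.D_g,
        Lambda1=p.lambda1 / p.alpha,
        Lambda2=p.lambda2 * p.G0 / p.alpha,
        g_dag=p.g_dag / p.G0,
        g_1=p.g_1 / p.G0,
        g_2=p.g_2 / p.G0,
        Gamma1=p.gamma1 / (p.alpha * p.G0),
        Gamma2=p.gamma2 / (p.alpha * p.G0),
        C=p.c * p.N0 / p.G0,
        K1=p.k1 * p.N0 / p.G0,
        K2=p.k2 * p.N0 / p.G0,
    )
    return Nondimensionalization(
        params=groups,
        space_scale=float(np.sqrt(p.D_g / (p.alpha * p.G0))),
        time_scale=1.0 / (p.alpha * p.G0),
    )


@dataclass(frozen=True)
class ReactionRates:
    """Pointwise source terms (per dimensionless time, diffusion excluded)."""

    dn_dt: np.ndarray
    dm1_dt: np.ndarray
    dm2_dt: np.ndarray
    dg_dt: np.ndarray


def acd_rate(n, g, params: DimensionlessParameters):
    """Rate of accidental cell death: ``Lambda1 * n * (g_dag - g)`` for
    ``g < g_dag``, zero otherwise.

    Starvation-triggered necrosis: the rate grows with the nutrient deficit
    below the survival threshold.  Continuous in ``g`` (vanishes at the
    threshold), so the Heaviside convention at 0 is unobservable.
    """
    n = np.asarray(n, dtype=float)
    g = np.asarray(g, dtype=float)
    deficit = params.g_dag - g
    return params.Lambda1 * n * np.where(deficit > 0.0, deficit, 0.0)


def rcd_rate(n, g, params: DimensionlessParameters):
    """Rate of regulated cell death: ``Lambda2 * n * (g - g_1) * (g_2 - g)``
    inside the open nutrient window ``(g_1, g_2)``, zero outside.

    The quadratic window peaks at ``g = (g_1 + g_2) / 2``: programmed death
    responds to mild stress, not to outright starvation or plenty.
    """
    n = np.asarray(n, dtype=float)
    g = np.asarray(g, dtype=float)
    window = (g - params.g_1) * (params.g_2 - g)
    inside = (g > params.g_1) & (g < params.g_2)
    return params.Lambda2 * n * np.where(inside, window, 0.0)


def reaction_terms(n, m1, m2, g, params: DimensionlessParameters) -> ReactionRates:
    """All four pointwise source terms.

    Cells proliferate at rate ``n*g`` and die into ``m1``/``m2``; dead cells
    break down at first-order rates ``Gamma1``/``Gamma2``; the nutrient is
    consumed at ``C*n*g`` and replenished by ``K_i * Gamma_i * m_i`` from
    broken-down dead cells.  Death transfers mass from ``n`` to ``m_i``
    exactly, so ``dn + dm1 + dm2 = n*g - Gamma1*m1 - Gamma2*m2``.
    """
    n = np.asarray(n, dtype=float)
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    g = np.asarray(g, dtype=float)
    a = acd_rate(n, g, params)
    r = rcd_rate(n, g, params)
    growth = n * g
    b1 = params.Gamma1 * m1
    b2 = params.Gamma2 * m2
    return ReactionRates(
        dn_dt=growth - a - r,
        dm1_dt=a - b1,
        dm2_dt=r - b2,
        dg_dt=-params.C * growth + params.K1 * b1 + params.K2 * b2,
    )
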