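"""Body velocity from metabolic rate via the cost-of-transport model.

For a submerged swimmer, the cost of transport ``C`` (energy to move one
Newton of body weight one metre) scales allometrically with body mass,
``C = 1.1 * m**-0.38`` with ``m`` in kg.  Converting an oxygen
consumption rate ``B`` (mol O2/s) to power with the oxycalorific
coefficient ``gamma`` (J per mol O2) and dividing by the weight-specific
cost gives body velocity::

    v = B * gamma / (C * m * g)

All metabolic power is assumed available for locomotion by default (a
deliberate upper-bound simplification); an allocation fraction < 1 can
be configured.  Because v is a monotone positive transform of B at fixed
mass, velocity inherits the full thermal response of the respiration
TPC, including its bootstrap uncertainty band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KG_PER_MG, celsius_to_kelvin
from .tpc import CurveBand, TPCFit, sharpe_schoolfield

__all__ = [
    "LocomotionConstants",
    "VelocityCurve",
    "cost_of_transport",
    "velocity_from_respiration",
    "velocity_tpc",
    "velocity_normalisation",
]


@dataclass(frozen=True)
class LocomotionConstants:
    """Physical constants of the velocity model.

    ``gamma`` is the oxycalorific equivalent, J released per mol O2
    consumed under aerobic combustion of a mixed substrate (default
    4.5e5 J/mol, the standard ~450 kJ/mol value).  ``allocation`` is the
    fraction of metabolic power invested in locomotion.
    """

    gamma: float = 4.5e5  # J per mol O2
    g: float = 9.81  # m s^-2
    cot_coeff: float = 1.1  # J N^-1 m^-1 at 1 kg
    cot_exp: float = -0.38
    allocation: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.g <= 0:
            raise ValueError("gamma and g must be positive")
        if not 0 < self.allocation <= 1:
            raise ValueError("allocation must be in (0, 1]")


@dataclass
class VelocityCurve:
    """A taxon-site velocity TPC with its 95% band and normalisation.

    ``v0`` is the velocity normalisation at Tref (m s^-1 per mg^beta of
    dry mass), defined from the Arrhenius numerator of the respiration
    model only (deactivation excluded) so that
    ``v0 * m**beta * exp(-E/k (1/T - 1/Tref))`` reproduces the
    rising-portion velocity.  ``replicates`` holds per-bootstrap
    (v0, beta, E) triples for downstream uncertainty propagation.
    """

    taxon: str | None
    site: str | None
    band: CurveBand
    v0: float
    beta: float
    E: float
    Tref: float  # K
    mass_mg: float  # representative dry mass used for the curve
    mass_kg: float  # body mass entering the cost-of-transport terms
    replicates: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        if np.any(self.band.estimate < 0):
            raise ValueError("velocities must be non-negative")


def cost_of_transport(
    m: float, coeff: float = 1.1, exponent: float = -0.38
) -> float:
    """Cost of transport C = coeff * m**exponent, J N^-1 m^-1; m in kg."""
    if np.any(np.asarray(m) <= 0):
        raise ValueError("mass must be positive")
    return coeff * m**exponent


def velocity_from_respiration(
    B, m: float, consts: LocomotionConstants | None = None
):
    """Body velocity (m/s) from oxygen consumption B (mol O2/s), mass m (kg)."""
    if consts is None:
        consts = LocomotionConstants()
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise ValueError("metabolic rate must be >= 0")
    if m <= 0:
        raise ValueError("mass must be positive")
    C = cost_of_transport(m, consts.cot_coeff, consts.cot_exp)
    v = consts.allocation * B * consts.gamma / (C * m * consts.g)
    return v if v.ndim else float(v)


def _velocity_factor(mass_kg: float, consts: LocomotionConstants) -> float:
    """Multiplier turning a metabolic rate into a velocity at this mass."""
    C = cost_of_transport(mass_kg, consts.cot_coeff, consts.cot_exp)
    return consts.allocation * consts.gamma / (C * mass_kg * consts.g)


def velocity_tpc(
    fit: TPCFit,
    mass_mg: float,
    consts: LocomotionConstants | None = None,
    temp_grid=None,
    mass_kg: float | None = None,
) -> VelocityCurve:
    """Velocity TPC for a population: Eq.-of-motion transform of its
    respiration fit, with the bootstrap band propagated pointwise.

    ``mass_mg`` is the representative dry mass the respiration curve is
    evaluated at; ``mass_kg`` the body mass entering the cost-of-transport
    terms (default: dry mass converted at 1 mg = 1e-6 kg).
    """
    if consts is None:
        consts = LocomotionConstants()
    if temp_grid is None:
        temp_grid = np.arange(10.0, 45.5, 0.5)
    temp_grid = np.asarray(temp_grid, dtype=float)
    if temp_grid.size == 0:
        raise ValueError("temperature grid is empty")
    if mass_mg <= 0:
        raise ValueError("mass must be positive")
    if mass_kg is None:
        mass_kg = mass_mg * KG_PER_MG
    factor = _velocity_factor(mass_kg, consts)

    T = celsius_to_kelvin(temp_grid)
    est = factor * sharpe_schoolfield(T, mass_mg, fit.params)
    if fit.bootstrap_params:
        curves = factor * np.array(
            [sharpe_schoolfield(T, mass_mg, p) for p in fit.bootstrap_params]
        )
        lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
        reps = np.array(
            [[factor * p.B0, p.beta, p.E] for p in fit.bootstrap_params]
        )
    else:
        lo = hi = np.asarray(est)
        reps = np.empty((0, 3))

    band = CurveBand(temps=temp_grid, estimate=np.asarray(est), lower=lo, upper=hi)
    return VelocityCurve(
        taxon=fit.taxon,
        site=fit.site,
        band=band,
        v0=factor * fit.params.B0,
        beta=fit.params.beta,
        E=fit.params.E,
        Tref=fit.params.Tref,
        mass_mg=float(mass_mg),
        mass_kg=float(mass_kg),
        replicates=reps,
    )


def velocity_normalisation(
    fit: TPCFit,
    mass_mg: float,
    consts: LocomotionConstants | None = None,
    mass_kg: float | None = None,
) -> float:
    """Velocity normalisation v0 at Tref, per unit mg^beta of dry mass.

    Uses the Arrhenius numerator of the respiration model only (the
    deactivation term is excluded), so v0 describes the rising portion:
    at T = Tref the Arrhenius rate is exactly B0 * m**beta, hence
    ``v0 = velocity(B0) / 1`` per mg^beta.
    """
    if consts is None:
        consts = LocomotionConstants()
    if mass_mg <= 0:
        raise ValueError("mass must be positive")
    if mass_kg is None:
        mass_kg = mass_mg * KG_PER_MG
    return _velocity_factor(mass_kg, consts) * fit.params.B0
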