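"""Sharpe-Schoolfield thermal performance curves (TPCs) for respiration.

The model describes a unimodal dependence of whole-organism oxygen
consumption rate ``B`` on body temperature ``T`` (in Kelvin) and body
mass ``m``::

    B(T, m) = B0 * m**beta * exp(-E/k * (1/T - 1/Tref))
              / (1 + exp(Ed/k * (1/Tpk - 1/T)))

``B0`` is the mass-normalised rate at the reference temperature ``Tref``
(here the mean habitat temperature of a population's site), ``E`` the
activation energy of the rising portion (eV), ``Ed`` the deactivation
energy controlling the decline past the thermal optimum, ``Tpk`` the
temperature of peak performance and ``beta`` the mass-scaling exponent.
``k`` is Boltzmann's constant in eV/K.

Fitting follows the multistart nonlinear-least-squares protocol used in
field thermal-ecology studies: starting values are estimated from an
Arrhenius plot of the rising portion, perturbed many times, and the
converged run with the lowest residual sum of squares is retained.
Uncertainty comes from nonparametric (case-resampling) bootstrap of
individuals, with pointwise 2.5/97.5 percentile curve bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import BOLTZMANN_EV, celsius_to_kelvin

__all__ = [
    "TPCParameters",
    "TPCFit",
    "CurveBand",
    "sharpe_schoolfield",
    "arrhenius_start_estimates",
    "fit_tpc_multistart",
    "bootstrap_tpc",
    "curve_band",
    "compare_parameters",
    "compute_otr",
]

# Fallback starting values when the Arrhenius plot is under-determined:
# canonical metabolic-theory activation energy and 3/4-power mass scaling.
FALLBACK_E = 0.65
FALLBACK_BETA = 0.75

_PARAM_NAMES = ("B0", "E", "Ed", "Tpk", "beta")


@dataclass(frozen=True)
class TPCParameters:
    """Parameter set of the mass-dependent Sharpe-Schoolfield model.

    Units: ``B0`` mol O2 s^-1 mg^-beta, ``E`` and ``Ed`` eV, ``Tpk`` and
    ``Tref`` K, ``beta`` dimensionless.
    """

    B0: float
    E: float
    Ed: float
    Tpk: float
    beta: float
    Tref: float

    def __post_init__(self) -> None:
        if not self.B0 > 0:
            raise ValueError(f"B0 must be positive, got {self.B0}")
        if not self.E > 0:
            raise ValueError(f"E must be positive, got {self.E}")
        if not self.Ed > self.E:
            raise ValueError(f"Ed ({self.Ed}) must exceed E ({self.E})")
        if not self.Tpk > 0:
            raise ValueError(f"Tpk must be positive Kelvin, got {self.Tpk}")
        if not self.Tref > 0:
            raise ValueError(f"Tref must be positive Kelvin, got {self.Tref}")

    def as_array(self) -> np.ndarray:
        return np.array([self.B0, self.E, self.Ed, self.Tpk, self.beta])


@dataclass
class TPCFit:
    """Result of a multistart Sharpe-Schoolfield fit to one population."""

    params: TPCParameters
    standard_errors: dict[str, float]
    r_squared: float
    n_obs: int
    n_starts: int
    n_converged: int
    residual_ss: float
    seed: int | None
    taxon: str | None = None
    site: str | None = None
    bootstrap_params: list[TPCParameters] = field(default_factory=list)
    n_boot_requested: int = 0
    n_boot_failed: int = 0
    warnings: list[str] = field(default_factory=list)
    covariance: np.ndarray | None = None

    @property
    def bootstrap_array(self) -> np.ndarray:
        """Bootstrap replicates as an (n_ok, 5) array ordered B0,E,Ed,Tpk,beta."""
        return np.array([p.as_array() for p in self.bootstrap_params])


@dataclass
class CurveBand:
    """A temperature grid with point estimate and 95% CI for a derived curve."""

    temps: np.ndarray  # °C grid
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        n = len(self.temps)
        if not (len(self.estimate) == len(self.lower) == len(self.upper) == n):
            raise ValueError("CurveBand grids must be aligned")
        if np.any(self.lower > self.upper + 1e-300):
            raise ValueError("CurveBand lower bound exceeds upper bound")


def sharpe_schoolfield(T, m, p: TPCParameters):
    """Evaluate the Sharpe-Schoolfield rate at temperature(s) T (K) and mass m.

    Parameters
    ----------
    T : float or array
        Temperature in Kelvin; must be positive.
    m : float or array
        Body mass (same unit B0 was normalised with, here mg dry mass).
    p : TPCParameters

    Returns
    -------
    float or ndarray
        Rate in the units of ``B0 * m**beta``.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive Kelvin")
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be positive")
    k = BOLTZMANN_EV
    rise = p.B0 * m**p.beta * np.exp(-p.E / k * (1.0 / T - 1.0 / p.Tref))
    fall = 1.0 + np.exp(p.Ed / k * (1.0 / p.Tpk - 1.0 / T))
    out = rise / fall
    return out if out.ndim else float(out)


def _check_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    required = {"acute_temp_C", "rate_mol_O2_per_s", "dry_mass_mg"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    df = measurements.loc[measurements["rate_mol_O2_per_s"] > 0].copy()
    if df["dry_mass_mg"].le(0).any():
        raise ValueError("dry_mass_mg must be positive")
    return df


def arrhenius_start_estimates(
    measurements: pd.DataFrame, Tref: float
) -> TPCParameters:
    """Starting values for the NLLS fit, from an Arrhenius plot.

    On the rising portion of the curve (acute temperatures at or below the
    temperature of maximum mean mass-corrected rate), ln(rate) is regressed
    jointly on ln(mass) and the inverse thermal-energy difference
    ``1/kT - 1/kTref``: the intercept estimates ln(B0), the mass coefficient
    beta, and the negative temperature coefficient E.  The Tpk start is the
    peak temperature plus 2 K and the Ed start is 3E.

    Falls back to E = 0.65 eV and beta = 0.75 when fewer than three rising
    temperatures are available or the slope estimate is non-positive.
    """
    df = _check_measurements(measurements)
    if df["acute_temp_C"].nunique() < 3:
        raise ValueError("need measurements at >=3 distinct acute temperatures")
    k = BOLTZMANN_EV

    # Peak of the mean mass-corrected rate (provisional 3/4 scaling).
    mc = df["rate_mol_O2_per_s"] / df["dry_mass_mg"] ** FALLBACK_BETA
    mean_by_temp = mc.groupby(df["acute_temp_C"]).mean()
    tpk_c = float(mean_by_temp.idxmax())
    tpk_start = celsius_to_kelvin(tpk_c) + 2.0

    rising = df[df["acute_temp_C"] <= tpk_c]
    T = celsius_to_kelvin(rising["acute_temp_C"].to_numpy())
    x = 1.0 / (k * T) - 1.0 / (k * Tref)
    ln_rate = np.log(rising["rate_mol_O2_per_s"].to_numpy())
    ln_mass = np.log(rising["dry_mass_mg"].to_numpy())

    E = beta = ln_b0 = None
    if rising["acute_temp_C"].nunique() >= 3:
        X = np.column_stack([np.ones_like(x), ln_mass, x])
        try:
            coef, *_ = np.linalg.lstsq(X, ln_rate, rcond=None)
            if -coef[2] > 0:
                ln_b0, beta, E = coef[0], coef[1], -coef[2]
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
            pass
    if E is None:
        E, beta = FALLBACK_E, FALLBACK_BETA
        # B0 from the mean Arrhenius-detrended, mass-corrected rate.
        T_all = celsius_to_kelvin(df["acute_temp_C"].to_numpy())
        x_all = 1.0 / (k * T_all) - 1.0 / (k * Tref)
        ln_b0 = float(
            np.mean(
                np.log(df["rate_mol_O2_per_s"].to_numpy())
                - beta * np.log(df["dry_mass_mg"].to_numpy())
                + E * x_all
            )
        )
    return TPCParameters(
        B0=float(np.exp(ln_b0)),
        E=float(E),
        Ed=float(3.0 * E),
        Tpk=float(tpk_start),
        beta=float(beta),
        Tref=float(Tref),
    )


def _model_theta(theta: np.ndarray, T: np.ndarray, m: np.ndarray, Tref: float):
    """Model in the fitting parametrisation (lnB0, E, dEd, Tpk, beta).

    dEd = Ed - E keeps the Ed > E constraint a simple box bound.
    """
    ln_b0, E, d_ed, tpk, beta = theta
    k = BOLTZMANN_EV
    log_rise = ln_b0 + beta * np.log(m) - E / k * (1.0 / T - 1.0 / Tref)
    fall = 1.0 + np.exp((E + d_ed) / k * (1.0 / tpk - 1.0 / T))
    return np.exp(log_rise) / fall


def _theta_to_params(theta: np.ndarray, Tref: float) -> TPCParameters:
    ln_b0, E, d_ed, tpk, beta = theta
    return TPCParameters(
        B0=float(np.exp(ln_b0)),
        E=float(E),
        Ed=float(E + d_ed),
        Tpk=float(tpk),
        beta=float(beta),
        Tref=float(Tref),
    )


def _params_to_theta(p: TPCParameters) -> np.ndarray:
    return np.array([np.log(p.B0), p.E, p.Ed - p.E, p.Tpk, p.beta])


def fit_tpc_multistart(
    measurements: pd.DataFrame,
    Tref: float,
    n_starts: int = 200,
    seed: int | None = None,
    taxon: str | None = None,
    site: str | None = None,
) -> TPCFit:
    """Fit the Sharpe-Schoolfield model by multistart bounded NLLS.

    Start values come from :func:`arrhenius_start_estimates`; the first run
    uses them unperturbed and every further run perturbs each natural
    parameter with Gaussian noise of SD 25% of its start value (clipped to
    the bounds).  The converged run with the lowest residual sum of squares
    is retained.  Perturbations are drawn sequentially from one seeded
    generator, so a run with more starts extends — never replaces — the
    start sequence of a shorter run with the same seed.

    Parameters
    ----------
    measurements : DataFrame
        Columns ``acute_temp_C``, ``rate_mol_O2_per_s``, ``dry_mass_mg``.
    Tref : float
        Reference temperature in Kelvin (mean habitat temperature).
    n_starts : int
        Number of NLLS starts (field protocol uses 10,000; the default is
        scaled down and is configurable).
    seed : int, optional
        Seed for the start perturbations.

    Raises
    ------
    RuntimeError
        If no start converges.
    """
    df = _check_measurements(measurements)
    if len(df) < 5 or df["acute_temp_C"].nunique() < 4:
        raise ValueError(
            "need >=5 measurements spanning >=4 acute temperatures"
        )
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    T = celsius_to_kelvin(df["acute_temp_C"].to_numpy(dtype=float))
    m = df["dry_mass_mg"].to_numpy(dtype=float)
    y = df["rate_mol_O2_per_s"].to_numpy(dtype=float)
    # Uniform residual scaling for conditioning; does not move the argmin.
    y_scale = float(np.std(y)) or float(np.mean(y)) or 1.0

    start = arrhenius_start_estimates(df, Tref)
    start_nat = start.as_array()

    t_lo, t_hi = float(T.min()) - 10.0, float(T.max()) + 10.0
    lower = np.array([-np.inf, 1e-8, 1e-8, t_lo, -5.0])
    upper = np.array([np.inf, 15.0, 30.0, t_hi, 5.0])

    def residuals(theta):
        return (_model_theta(theta, T, m, Tref) - y) / y_scale

    rng = np.random.default_rng(seed)
    best = None
    n_converged = 0
    for i in range(n_starts):
        if i == 0:
            nat = start_nat
        else:
            nat = rng.normal(start_nat, 0.25 * np.abs(start_nat))
        b0, E, ed, tpk, beta = nat
        theta0 = np.array(
            [
                np.log(b0) if b0 > 0 else np.log(start.B0),
                E,
                ed - E,
                tpk,
                beta,
            ]
        )
        theta0 = np.clip(theta0, lower + 1e-9, upper - 1e-9)
        try:
            res = least_squares(
                residuals, theta0, bounds=(lower, upper), method="trf"
            )
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if not res.success or not np.isfinite(res.cost):
            continue
        n_converged += 1
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        label = f"{taxon or '?'}@{site or '?'}"
        raise RuntimeError(f"no converged NLLS run for population {label}")

    ssr = float(2.0 * best.cost * y_scale**2)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    r2 = float(min(max(r2, 0.0), 1.0))

    params = _theta_to_params(best.x, Tref)
    cov_nat, ses = _covariance(best, y_scale, len(y))
    return TPCFit(
        params=params,
        standard_errors=ses,
        r_squared=r2,
        n_obs=len(y),
        n_starts=n_starts,
        n_converged=n_converged,
        residual_ss=ssr,
        seed=seed,
        taxon=taxon,
        site=site,
        covariance=cov_nat,
    )


def _covariance(res, y_scale: float, n: int):
    """Delta-method covariance of (B0, E, Ed, Tpk, beta) from the jacobian."""
    p = len(res.x)
    ses = {name: float("nan") for name in _PARAM_NAMES}
    if n <= p:
        return None, ses
    jtj = res.jac.T @ res.jac
    try:
        cov_theta = np.linalg.pinv(jtj) * (2.0 * res.cost / (n - p))
    except np.linalg.LinAlgError:  # pragma: no cover
        return None, ses
    # theta = (lnB0, E, dEd, Tpk, beta) -> natural (B0, E, Ed, Tpk, beta)
    b0 = float(np.exp(res.x[0]))
    J = np.array(
        [
            [b0, 0, 0, 0, 0],
            [0, 1, 0, 0, 0],
            [0, 1, 1, 0, 0],
            [0, 0, 0, 1, 0],
            [0, 0, 0, 0, 1],
        ],
        dtype=float,
    )
    cov_nat = J @ cov_theta @ J.T
    diag = np.clip(np.diag(cov_nat), 0.0, None)
    for name, v in zip(_PARAM_NAMES, diag):
        ses[name] = float(np.sqrt(v))
    return cov_nat, ses


def curve_band(
    fit: TPCFit, temps_c, mass: float, quantiles=(2.5, 97.5)
) -> CurveBand:
    """Pointwise bootstrap percentile band for the respiration curve.

    ``mass`` fixes the body mass the curve is drawn at (mg dry mass); pass
    1.0 for a mass-normalised curve.
    """
    temps_c = np.asarray(temps_c, dtype=float)
    if temps_c.size == 0:
        raise ValueError("temperature grid is empty")
    T = celsius_to_kelvin(temps_c)
    est = sharpe_schoolfield(T, mass, fit.params)
    if fit.bootstrap_params:
        curves = np.array(
            [sharpe_schoolfield(T, mass, p) for p in fit.bootstrap_params]
        )
        lo, hi = np.percentile(curves, quantiles, axis=0)
    else:
        lo = hi = np.asarray(est)
    return CurveBand(temps=temps_c, estimate=np.asarray(est), lower=lo, upper=hi)


def bootstrap_tpc(
    fit: TPCFit,
    measurements: pd.DataFrame,
    n_boot: int = 200,
    seed: int | None = None,
    temps_c=None,
    mass: float | None = None,
) -> tuple[TPCFit, CurveBand]:
    """Nonparametric case-resampling bootstrap of a fitted TPC.

    Individuals (rows) are resampled with replacement; each replicate is
    refit by a single NLLS run warm-started at the best-fit parameters.
    Failed refits are counted, never fabricated; more than 20% failures
    records a warning in the fit diagnostics.  Returns the fit augmented
    with replicates plus the pointwise 95% curve band.
    """
    df = _check_measurements(measurements)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    Tref = fit.params.Tref
    theta_best = _params_to_theta(fit.params)
    T_all = celsius_to_kelvin(df["acute_temp_C"].to_numpy(dtype=float))
    m_all = df["dry_mass_mg"].to_numpy(dtype=float)
    y_all = df["rate_mol_O2_per_s"].to_numpy(dtype=float)
    y_scale = float(np.std(y_all)) or float(np.mean(y_all)) or 1.0

    t_lo, t_hi = float(T_all.min()) - 10.0, float(T_all.max()) + 10.0
    lower = np.array([-np.inf, 1e-8, 1e-8, t_lo, -5.0])
    upper = np.array([np.inf, 15.0, 30.0, t_hi, 5.0])
    theta0 = np.clip(theta_best, lower + 1e-9, upper - 1e-9)

    rng = np.random.default_rng(seed)
    n = len(df)
    reps: list[TPCParameters] = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        T, m, y = T_all[idx], m_all[idx], y_all[idx]

        def residuals(theta):
            return (_model_theta(theta, T, m, Tref) - y) / y_scale

        try:
            res = least_squares(
                residuals, theta0, bounds=(lower, upper), method="trf"
            )
            if res.success and np.all(np.isfinite(res.x)):
                reps.append(_theta_to_params(res.x, Tref))
            else:
                n_failed += 1
        except (ValueError, FloatingPointError):  # pragma: no cover
            n_failed += 1

    out = replace(fit)
    out.bootstrap_params = reps
    out.n_boot_requested = n_boot
    out.n_boot_failed = n_failed
    out.warnings = list(fit.warnings)
    if n_failed > 0.2 * n_boot:
        msg = f"{n_failed}/{n_boot} bootstrap refits failed"
        out.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)

    if temps_c is None:
        temps_c = np.arange(
            float(df["acute_temp_C"].min()), float(df["acute_temp_C"].max()) + 0.5, 0.5
        )
    if mass is None:
        mass = float(df["dry_mass_mg"].mean())
    band = curve_band(out, temps_c, mass)
    return out, band


def compare_parameters(fit_a: TPCFit, fit_b: TPCFit) -> pd.DataFrame:
    """Parameter-wise comparison of two population fits.

    For each parameter: the difference (a - b), the z statistic
    ``diff / sqrt(SE_a**2 + SE_b**2)`` and, when both fits carry bootstrap
    replicates, whether the 95% bootstrap CIs overlap.  Fits with different
    reference temperatures are not comparable (B0 is Tref-specific).
    """
    if abs(fit_a.params.Tref - fit_b.params.Tref) > 1e-9:
        raise ValueError(
            "fits have different Tref; B0 values are not comparable"
        )
    rows = []
    arr_a = fit_a.bootstrap_array if fit_a.bootstrap_params else None
    arr_b = fit_b.bootstrap_array if fit_b.bootstrap_params else None
    for i, name in enumerate(_PARAM_NAMES):
        va = getattr(fit_a.params, name)
        vb = getattr(fit_b.params, name)
        sa = fit_a.standard_errors.get(name, float("nan"))
        sb = fit_b.standard_errors.get(name, float("nan"))
        diff = va - vb
        denom = np.sqrt(sa**2 + sb**2)
        z = diff / denom if denom > 0 else (0.0 if diff == 0 else float("inf"))
        overlap = None
        if arr_a is not None and arr_b is not None and len(arr_a) and len(arr_b):
            lo_a, hi_a = np.percentile(arr_a[:, i], [2.5, 97.5])
            lo_b, hi_b = np.percentile(arr_b[:, i], [2.5, 97.5])
            overlap = bool(lo_a <= hi_b and lo_b <= hi_a)
        rows.append(
            {
                "parameter": name,
                "value_a": va,
                "value_b": vb,
                "difference": diff,
                "se_a": sa,
                "se_b": sb,
                "z": float(z),
                "ci_overlap": overlap,
            }
        )
    return pd.DataFrame(rows)


def compute_otr(series: pd.DataFrame, window=None) -> tuple[float, float]:
    """Operational temperature range: (min, max) recorded °C within a window.

    ``series`` is a DataFrame with ``timestamp`` and ``temp_C`` columns (the
    logger schema); ``window`` an optional (start, end) pair of timestamps,
    inclusive.
    """
    df = series
    if window is not None:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        ts = pd.to_datetime(df["timestamp"])
        df = df[(ts >= start) & (ts <= end)]
    if len(df) == 0:
        raise ValueError("no logger records inside the requested window")
    temps = df["temp_C"].to_numpy(dtype=float)
    return float(temps.min()), float(temps.max())
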