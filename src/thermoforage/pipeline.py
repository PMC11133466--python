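"""End-to-end orchestration: simulate -> rates -> TPC fits -> velocity ->
mismatch -> search rates, from one structured config.

The pipeline is a pure function of (config, seed).  Stages communicate
through documented CSV schemas (including a bootstrap-replicate table)
so they can be run independently from the CLI, and a manifest records
the config hash, seed, package version and the SHA-256 of every output
so reruns can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import KG_PER_MG, celsius_to_kelvin
from .interaction import (
    ForagingPair,
    fit_search_rate_arrhenius,
    mismatch_over_otr,
    search_rate_curve,
)
from .locomotion import LocomotionConstants, VelocityCurve, velocity_tpc
from .respirometry import compute_rates
from .synthdata import (
    SiteConfig,
    default_design,
    default_sites,
    default_taxa,
    generate_respiration_dataset,
    generate_site_temperatures,
)
from .tpc import TPCFit, TPCParameters, bootstrap_tpc, compute_otr, fit_tpc_multistart

__all__ = [
    "RunConfig",
    "run_pipeline",
    "validate_inputs",
    "default_run_config",
    "fit_populations",
    "velocity_curves_from_fits",
    "load_fits",
]


@dataclass
class RunConfig:
    """Run configuration; exactly one of ``inputs`` / ``synthetic`` active."""

    seed: int = 0
    outdir: str = "thermoforage_out"
    synthetic: dict | None = None  # generator overrides, or {} for defaults
    inputs: dict | None = None  # paths: traces, individuals, loggers
    n_starts: int = 200
    n_boot: int = 200
    temp_grid: dict = field(
        default_factory=lambda: {"start": 10.0, "stop": 45.0, "step": 0.5}
    )
    locomotion: dict = field(default_factory=dict)
    pairs: list[dict] = field(
        default_factory=lambda: [
            {
                "consumer": "S_striolatum",
                "resource": "Chironomus",
                "strategy": "sessile",
                "dimensionality": 2,
            },
            {
                "consumer": "S_striolatum",
                "resource": "C_dipterum",
                "strategy": "active",
                "dimensionality": 3,
            },
        ]
    )

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'synthetic' and 'inputs' must be configured"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def grid(self) -> np.ndarray:
        g = self.temp_grid
        return np.arange(
            float(g["start"]),
            float(g["stop"]) + float(g["step"]) / 2,
            float(g["step"]),
        )


def default_run_config(**overrides) -> RunConfig:
    """A small, fast synthetic demo configuration."""
    base = dict(
        seed=42,
        synthetic={"n_per_temp": 4, "noise_cv": 0.2},
        n_starts=30,
        n_boot=50,
    )
    base.update(overrides)
    return RunConfig.from_dict(base)


TRACE_COLUMNS = [
    "trial_id",
    "vial_id",
    "is_control",
    "acute_temp_C",
    "vial_volume_L",
    "time_s",
    "o2_umol_per_L",
]
INDIVIDUAL_COLUMNS = ["individual_id", "taxon", "site", "length_mm", "dry_mass_mg"]
LOGGER_COLUMNS = ["site", "timestamp", "temp_C"]


def validate_inputs(paths: dict) -> list[str]:
    """Schema checks on input CSVs; returns a list of problem strings."""
    report: list[str] = []
    frames = {}
    for key, cols in (
        ("traces", TRACE_COLUMNS),
        ("individuals", INDIVIDUAL_COLUMNS),
        ("loggers", LOGGER_COLUMNS),
    ):
        if key not in paths:
            report.append(f"missing input path: {key}")
            continue
        try:
            df = pd.read_csv(paths[key])
        except OSError as exc:
            report.append(f"{key}: unreadable ({exc})")
            continue
        missing = set(cols) - set(df.columns)
        if missing:
            report.append(f"{key}: missing columns {sorted(missing)}")
            continue
        frames[key] = df

    traces = frames.get("traces")
    if traces is not None:
        if (traces["vial_volume_L"] <= 0).any():
            report.append("traces: non-positive vial volume")
        for (trial, vial), grp in traces.groupby(["trial_id", "vial_id"]):
            t = grp["time_s"].to_numpy()
            if len(t) != len(np.unique(t)):
                report.append(f"traces: duplicated timestamps in {trial}/{vial}")
        for trial, grp in traces.groupby("trial_id"):
            n_ctrl = grp.loc[grp["is_control"], "vial_id"].nunique()
            if n_ctrl != 1:
                report.append(
                    f"traces: trial {trial!r} has {n_ctrl} control vials (need 1)"
                )
    inds = frames.get("individuals")
    if inds is not None:
        if (inds["length_mm"] <= 0).any():
            report.append("individuals: non-positive body length")
        if (inds["dry_mass_mg"] <= 0).any():
            report.append("individuals: non-positive dry mass")
    return report


def _load_inputs(cfg: RunConfig):
    report = validate_inputs(cfg.inputs)
    if report:
        raise ValueError("input validation failed:\n" + "\n".join(report))
    traces = pd.read_csv(cfg.inputs["traces"])
    individuals = pd.read_csv(cfg.inputs["individuals"])
    loggers = pd.read_csv(cfg.inputs["loggers"])
    tref = tref_from_loggers(loggers)
    return traces, individuals, loggers, tref, None


def tref_from_loggers(loggers: pd.DataFrame) -> dict[str, float]:
    """Per-site reference temperature (K): mean recorded habitat temperature."""
    return {
        str(site): celsius_to_kelvin(float(grp["temp_C"].mean()))
        for site, grp in loggers.groupby("site")
    }


def _simulate_inputs(cfg: RunConfig):
    opts = dict(cfg.synthetic or {})
    noise_cv = float(opts.pop("noise_cv", 0.2))
    site_list = opts.pop("sites", None)
    design_keys = {
        "acute_temps",
        "n_per_temp",
        "vial_volume",
        "control_drift",
        "trace_duration",
        "trace_interval",
        "start_conc",
        "o2_noise_sd",
    }
    design_opts = {k: opts.pop(k) for k in list(opts) if k in design_keys}
    if "acute_temps" in design_opts:
        design_opts["acute_temps"] = tuple(design_opts["acute_temps"])
    if opts:
        raise ValueError(f"unknown synthetic options: {sorted(opts)}")

    if site_list is None:
        sites = default_sites(seed=cfg.seed)
    else:
        sites = [SiteConfig(**s) for s in site_list]
    taxa = default_taxa(noise_cv=noise_cv)
    design = default_design(**design_opts)
    traces, individuals, truth = generate_respiration_dataset(
        sites, taxa, design, seed=cfg.seed
    )
    loggers = pd.concat(
        [generate_site_temperatures(s) for s in sites], ignore_index=True
    )
    # Tref is the known window-mean habitat temperature of each site.
    tref = {s.site_id: celsius_to_kelvin(s.mean_temp) for s in sites}
    return traces, individuals, loggers, tref, truth


# ---------------------------------------------------------------------------
# Stage: TPC fitting
# ---------------------------------------------------------------------------


def fit_populations(
    rates: pd.DataFrame,
    tref: dict[str, float],
    n_starts: int,
    n_boot: int,
    seed: int,
    grid: np.ndarray,
    log=lambda msg: None,
):
    """Fit and bootstrap one TPC per (taxon, site) population.

    Returns ``(fits, params_df, curves_df, boot_df)`` where ``boot_df``
    holds one row per bootstrap replicate so downstream stages can rebuild
    uncertainty bands from CSV alone.
    """
    pops = sorted(rates.groupby(["taxon", "site"]).groups)
    seeds = np.random.SeedSequence(seed).spawn(2 * len(pops))
    fits: dict[tuple[str, str], TPCFit] = {}
    param_rows, band_rows, boot_rows = [], [], []
    for i, (taxon, site) in enumerate(pops):
        sub = rates[(rates["taxon"] == taxon) & (rates["site"] == site)]
        log(f"fitting TPC for {taxon} @ {site} (n={len(sub)})")
        fit = fit_tpc_multistart(
            sub,
            Tref=tref[site],
            n_starts=n_starts,
            seed=int(seeds[2 * i].generate_state(1)[0] % (2**31)),
            taxon=taxon,
            site=site,
        )
        mass = float(sub["dry_mass_mg"].mean())
        fit, band = bootstrap_tpc(
            fit,
            sub,
            n_boot=n_boot,
            seed=int(seeds[2 * i + 1].generate_state(1)[0] % (2**31)),
            temps_c=grid,
            mass=mass,
        )
        log(
            f"  converged {fit.n_converged}/{fit.n_starts}, "
            f"R2={fit.r_squared:.3f}, boot failures {fit.n_boot_failed}"
        )
        fits[(taxon, site)] = fit
        p = fit.params
        param_rows.append(
            {
                "taxon": taxon,
                "site": site,
                "B0": p.B0,
                "E": p.E,
                "Ed": p.Ed,
                "Tpk_K": p.Tpk,
                "beta": p.beta,
                "Tref_K": p.Tref,
                **{f"se_{k}": v for k, v in fit.standard_errors.items()},
                "r_squared": fit.r_squared,
                "n_obs": fit.n_obs,
                "n_converged": fit.n_converged,
                "n_boot_failed": fit.n_boot_failed,
                "mass_mg": mass,
            }
        )
        band_rows.extend(
            {
                "taxon": taxon,
                "site": site,
                "temp_C": t,
                "estimate": est,
                "lower": lo,
                "upper": hi,
            }
            for t, est, lo, hi in zip(
                band.temps, band.estimate, band.lower, band.upper
            )
        )
        boot_rows.extend(
            {
                "taxon": taxon,
                "site": site,
                "replicate": r,
                "B0": bp.B0,
                "E": bp.E,
                "Ed": bp.Ed,
                "Tpk_K": bp.Tpk,
                "beta": bp.beta,
            }
            for r, bp in enumerate(fit.bootstrap_params)
        )
    return (
        fits,
        pd.DataFrame(param_rows),
        pd.DataFrame(band_rows),
        pd.DataFrame(
            boot_rows,
            columns=["taxon", "site", "replicate", "B0", "E", "Ed", "Tpk_K", "beta"],
        ),
    )


def load_fits(
    params_df: pd.DataFrame, boot_df: pd.DataFrame | None = None
) -> dict[tuple[str, str], TPCFit]:
    """Rebuild TPCFit objects from the parameter and replicate tables."""
    fits = {}
    for row in params_df.itertuples(index=False):
        params = TPCParameters(
            B0=row.B0, E=row.E, Ed=row.Ed, Tpk=row.Tpk_K, beta=row.beta,
            Tref=row.Tref_K,
        )
        reps = []
        if boot_df is not None and len(boot_df):
            sub = boot_df[
                (boot_df["taxon"] == row.taxon) & (boot_df["site"] == row.site)
            ].sort_values("replicate")
            reps = [
                TPCParameters(
                    B0=b.B0, E=b.E, Ed=b.Ed, Tpk=b.Tpk_K, beta=b.beta,
                    Tref=row.Tref_K,
                )
                for b in sub.itertuples(index=False)
            ]
        ses = {
            k[3:]: getattr(row, k)
            for k in params_df.columns
            if k.startswith("se_")
        }
        fits[(row.taxon, row.site)] = TPCFit(
            params=params,
            standard_errors=ses,
            r_squared=float(row.r_squared),
            n_obs=int(row.n_obs),
            n_starts=0,
            n_converged=int(row.n_converged),
            residual_ss=float("nan"),
            seed=None,
            taxon=row.taxon,
            site=row.site,
            bootstrap_params=reps,
        )
    return fits


# ---------------------------------------------------------------------------
# Stage: velocity curves
# ---------------------------------------------------------------------------


def velocity_curves_from_fits(
    fits: dict[tuple[str, str], TPCFit],
    masses: dict[tuple[str, str], float],
    consts: LocomotionConstants,
    grid: np.ndarray,
):
    """Velocity TPCs for every population; returns (curves, table)."""
    vcurves: dict[tuple[str, str], VelocityCurve] = {}
    rows = []
    for (taxon, site), fit in sorted(fits.items()):
        vc = velocity_tpc(fit, mass_mg=masses[(taxon, site)], consts=consts,
                          temp_grid=grid)
        vcurves[(taxon, site)] = vc
        rows.extend(
            {
                "taxon": taxon,
                "site": site,
                "temp_C": t,
                "v_est": est,
                "v_lo": lo,
                "v_hi": hi,
            }
            for t, est, lo, hi in zip(
                vc.band.temps, vc.band.estimate, vc.band.lower, vc.band.upper
            )
        )
    return vcurves, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage: mismatch and search rates
# ---------------------------------------------------------------------------


def interaction_tables(
    vcurves: dict[tuple[str, str], VelocityCurve],
    pairs: list[dict],
    otr_by_site: dict[str, tuple[float, float]],
    grid: np.ndarray,
    log=lambda msg: None,
):
    mismatch_rows, search_rows, arrh_rows = [], [], []
    sites_present = sorted({site for _, site in vcurves})
    for pair_cfg in pairs:
        consumer, resource = pair_cfg["consumer"], pair_cfg["resource"]
        for site in sites_present:
            if (consumer, site) not in vcurves or (resource, site) not in vcurves:
                continue
            vc, vr = vcurves[(consumer, site)], vcurves[(resource, site)]
            otr = otr_by_site[site]
            otr_c = (max(otr[0], grid.min()), min(otr[1], grid.max()))
            log(f"mismatch & search rate for {consumer}->{resource} @ {site}")
            mm = mismatch_over_otr(vc, vr, otr_c)
            mismatch_rows.append(
                {
                    "consumer": consumer,
                    "resource": resource,
                    "site": site,
                    "otr_lo_C": mm["otr"][0],
                    "otr_hi_C": mm["otr"][1],
                    "mean_delta_v": mm["mean_delta_v"],
                    "sign_consistency": mm["sign_consistency"],
                    "band_non_overlap_fraction": mm["band_non_overlap_fraction"],
                }
            )
            pair = ForagingPair(
                consumer=consumer,
                resource=resource,
                strategy=pair_cfg["strategy"],
                dimensionality=int(pair_cfg["dimensionality"]),
                m_c=vc.mass_mg * KG_PER_MG,
                m_r=vr.mass_mg * KG_PER_MG,
                d0=float(pair_cfg.get("d0", 0.01)),
                p_d=pair_cfg.get("p_d"),
                d0_squared=bool(pair_cfg.get("d0_squared", False)),
            )
            sr = search_rate_curve(
                pair,
                vc,
                vr if pair.strategy == "active" else None,
                temp_grid=grid,
                site=site,
            )
            search_rows.extend(
                {
                    "consumer": consumer,
                    "resource": resource,
                    "site": site,
                    "strategy": pair.strategy,
                    "dimensionality": pair.dimensionality,
                    "temp_C": t,
                    "a_est": est,
                    "a_lo": lo,
                    "a_hi": hi,
                }
                for t, est, lo, hi in zip(
                    sr.band.temps, sr.band.estimate, sr.band.lower, sr.band.upper
                )
            )
            summ = fit_search_rate_arrhenius(sr, temp_range=otr_c)
            arrh_rows.append(
                {
                    "consumer": consumer,
                    "resource": resource,
                    "site": site,
                    "strategy": pair.strategy,
                    "E": summ.E,
                    "lnB0": summ.lnB0,
                    "r_squared": summ.r_squared,
                    "range_lo_C": summ.temp_range[0],
                    "range_hi_C": summ.temp_range[1],
                }
            )
    return (
        pd.DataFrame(mismatch_rows),
        pd.DataFrame(search_rows),
        pd.DataFrame(arrh_rows),
    )


def run_pipeline(cfg: RunConfig, quiet: bool = True) -> dict:
    """Run the full chain and write all output tables under ``cfg.outdir``.

    Returns the manifest (also written as ``manifest.json``).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def log(msg):
        if not quiet:
            print(f"[thermoforage] {msg}")

    if cfg.synthetic is not None:
        log("simulating synthetic respirometry campaign")
        traces, individuals, loggers, tref, truth = _simulate_inputs(cfg)
    else:
        log("loading input tables")
        traces, individuals, loggers, tref, truth = _load_inputs(cfg)

    outputs: dict[str, pd.DataFrame] = {
        "traces.csv": traces,
        "individuals.csv": individuals,
        "loggers.csv": loggers,
    }
    if truth is not None:
        outputs["truth.csv"] = truth

    log("extracting corrected respiration rates")
    rates, rejects = compute_rates(traces, individuals)
    outputs["rates.csv"] = rates
    outputs["rejected_traces.csv"] = rejects

    grid = cfg.grid()
    fits, params_df, curves_df, boot_df = fit_populations(
        rates, tref, cfg.n_starts, cfg.n_boot, cfg.seed, grid, log=log
    )
    outputs["tpc_parameters.csv"] = params_df
    outputs["tpc_curves.csv"] = curves_df
    outputs["tpc_bootstrap.csv"] = boot_df

    masses = {
        (row.taxon, row.site): row.mass_mg
        for row in params_df.itertuples(index=False)
    }
    loco = LocomotionConstants(**cfg.locomotion)
    vcurves, vel_df = velocity_curves_from_fits(fits, masses, loco, grid)
    outputs["velocity_curves.csv"] = vel_df

    otr_by_site = {
        str(site): compute_otr(grp) for site, grp in loggers.groupby("site")
    }
    mismatch_df, search_df, arrh_df = interaction_tables(
        vcurves, cfg.pairs, otr_by_site, grid, log=log
    )
    outputs["mismatch.csv"] = mismatch_df
    outputs["search_rates.csv"] = search_df
    outputs["search_arrhenius.csv"] = arrh_df

    file_hashes = {}
    for name, df in outputs.items():
        path = outdir / name
        df.to_csv(path, index=False)
        file_hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    cfg_text = json.dumps(
        {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
        sort_keys=True,
        default=str,
    )
    manifest = {
        "package": "thermoforage",
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "outputs": file_hashes,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log(f"wrote {len(file_hashes)} tables to {outdir}")
    return manifest
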