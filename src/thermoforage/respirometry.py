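"""Raw respirometry processing: O2 traces to corrected per-individual rates.

A trial seals individuals in water-filled glass vials at one acute
temperature, with one animal-free control vial per batch accounting for
sensor drift and microbial oxygen use.  The oxygen consumption rate of an
individual is the OLS slope of its O2-concentration trace, corrected by
the control slope and scaled by vial volume.  Trials are stopped once the
O2 concentration reaches 70% of its starting value; traces that over-ran
that rule are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import UMOL_PER_MOL

__all__ = [
    "RespirationTrace",
    "IndividualRecord",
    "TraceVerdict",
    "trace_slope",
    "correct_rate",
    "length_to_mass",
    "validate_trace",
    "compute_rates",
]

#: Trials stop once O2 reaches this fraction of the starting concentration;
#: the boundary is inclusive (a trace ending exactly at 70% is valid).
STOPPING_FRACTION = 0.70


@dataclass(frozen=True)
class RespirationTrace:
    """One vial's O2 concentration time series at one acute temperature."""

    trial_id: str
    vial_id: str
    is_control: bool
    acute_temp: float  # °C
    vial_volume: float  # L
    times: np.ndarray  # s, strictly increasing
    o2: np.ndarray  # µmol L^-1

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "o2", np.asarray(self.o2, dtype=float))
        if len(self.times) != len(self.o2):
            raise ValueError("times and o2 must have equal length")
        if self.vial_volume <= 0:
            raise ValueError("vial_volume must be positive")


@dataclass(frozen=True)
class IndividualRecord:
    individual_id: str
    taxon: str
    site: str
    body_length: float  # mm
    dry_mass: float  # mg

    def __post_init__(self) -> None:
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")
        if self.dry_mass <= 0:
            raise ValueError("dry_mass must be positive")


@dataclass(frozen=True)
class TraceVerdict:
    accepted: bool
    reason: str
    flagged: bool = False  # positive sample slope: kept but marked for review


def trace_slope(trace: RespirationTrace) -> float:
    """OLS slope (µmol L^-1 s^-1) of O2 concentration on time.

    All data points of the trace enter one linear regression.
    """
    t, y = trace.times, trace.o2
    if len(t) < 2:
        raise ValueError("need at least 2 points for a slope")
    if np.ptp(t) == 0:
        raise ValueError("all time points identical; slope undefined")
    return float(stats.linregress(t, y).slope)


def correct_rate(
    sample_slope: float, control_slope: float, vial_volume: float
) -> float:
    """Control- and volume-corrected oxygen consumption rate, mol O2 s^-1.

    Slopes are in µmol L^-1 s^-1; consumption is reported positive for
    declining O2, so ``rate = -(sample - control) * volume`` converted to
    moles.
    """
    if vial_volume <= 0:
        raise ValueError("vial_volume must be positive")
    return -(sample_slope - control_slope) * vial_volume / UMOL_PER_MOL


def length_to_mass(length: float, allometry: tuple[float, float]) -> float:
    """Convert body length (mm) to dry mass (mg) via ``a * length**b``."""
    a, b = allometry
    if length <= 0:
        raise ValueError("length must be positive")
    if a <= 0:
        raise ValueError("allometric coefficient a must be positive")
    return a * length**b


def validate_trace(trace: RespirationTrace) -> TraceVerdict:
    """Screen a trace against the trial-validity rules.

    Rejects traces with fewer than two points, non-increasing times, or a
    final O2 concentration below 70% of the start (the trial over-ran its
    stopping rule, stressing the animal).  Positive-slope sample traces are
    flagged for review but not rejected.
    """
    if len(trace.times) < 2:
        return TraceVerdict(False, "fewer than 2 data points")
    if np.any(np.diff(trace.times) <= 0):
        return TraceVerdict(False, "time points not strictly increasing")
    start = trace.o2[0]
    if start <= 0:
        return TraceVerdict(False, "non-positive starting O2 concentration")
    if trace.o2[-1] < STOPPING_FRACTION * start:
        return TraceVerdict(
            False,
            f"final O2 below {STOPPING_FRACTION:.0%} of start (over-run trial)",
        )
    if not trace.is_control and trace_slope(trace) > 0:
        return TraceVerdict(True, "ok", flagged=True)
    return TraceVerdict(True, "ok")


def _traces_from_table(traces: pd.DataFrame) -> list[RespirationTrace]:
    out = []
    keys = ["trial_id", "vial_id", "is_control", "acute_temp_C", "vial_volume_L"]
    for (trial, vial, ctrl, temp, vol), grp in traces.groupby(keys, sort=True):
        grp = grp.sort_values("time_s")
        out.append(
            RespirationTrace(
                trial_id=str(trial),
                vial_id=str(vial),
                is_control=bool(ctrl),
                acute_temp=float(temp),
                vial_volume=float(vol),
                times=grp["time_s"].to_numpy(),
                o2=grp["o2_umol_per_L"].to_numpy(),
            )
        )
    return out


def compute_rates(
    traces: pd.DataFrame, individuals: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Batch-process a long-format trace table into a rates table.

    Each trial batch must contain exactly one control vial; every sample
    vial's slope is corrected by its batch control slope and joined to the
    individual's taxon, site and dry mass (``vial_id`` is the individual id
    for sample vials).

    Returns
    -------
    (rates, rejects)
        ``rates``: individual_id, taxon, site, acute_temp_C,
        rate_mol_O2_per_s, dry_mass_mg, flagged.
        ``rejects``: trial_id, vial_id, reason for every discarded trace.
    """
    trace_objs = _traces_from_table(traces)
    by_trial: dict[str, list[RespirationTrace]] = {}
    for tr in trace_objs:
        by_trial.setdefault(tr.trial_id, []).append(tr)

    ind = individuals.set_index("individual_id")
    rows, rejects = [], []
    for trial_id in sorted(by_trial):
        batch = by_trial[trial_id]
        controls = [t for t in batch if t.is_control]
        if len(controls) != 1:
            raise ValueError(
                f"trial {trial_id!r} has {len(controls)} control vials; expected 1"
            )
        cverdict = validate_trace(controls[0])
        if not cverdict.accepted:
            rejects.append(
                {
                    "trial_id": trial_id,
                    "vial_id": controls[0].vial_id,
                    "reason": f"control: {cverdict.reason}",
                }
            )
            continue
        control_slope = trace_slope(controls[0])
        for tr in batch:
            if tr.is_control:
                continue
            verdict = validate_trace(tr)
            if not verdict.accepted:
                rejects.append(
                    {
                        "trial_id": trial_id,
                        "vial_id": tr.vial_id,
                        "reason": verdict.reason,
                    }
                )
                continue
            rate = correct_rate(trace_slope(tr), control_slope, tr.vial_volume)
            if tr.vial_id not in ind.index:
                rejects.append(
                    {
                        "trial_id": trial_id,
                        "vial_id": tr.vial_id,
                        "reason": "no matching individual record",
                    }
                )
                continue
            rec = ind.loc[tr.vial_id]
            rows.append(
                {
                    "individual_id": tr.vial_id,
                    "taxon": rec["taxon"],
                    "site": rec["site"],
                    "acute_temp_C": tr.acute_temp,
                    "rate_mol_O2_per_s": rate,
                    "dry_mass_mg": float(rec["dry_mass_mg"]),
                    "flagged": verdict.flagged,
                }
            )
    rates = pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "taxon",
            "site",
            "acute_temp_C",
            "rate_mol_O2_per_s",
            "dry_mass_mg",
            "flagged",
        ],
    )
    rejects_df = pd.DataFrame(rejects, columns=["trial_id", "vial_id", "reason"])
    return rates, rejects_df
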