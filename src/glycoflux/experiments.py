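"""In-silico experiments: one-at-a-time sensitivity sweeps and dose sweeps.

The OAT protocol scales one parameter through multiplicative factors
0.50, 0.60, ..., 1.50 — five 10% decrements, the baseline, and five 10%
increments, eleven runs in all — holding everything else fixed.  Dose sweeps
run one modulator through integer doses 0..10 with the other held at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModulatorDose, ParameterSet
from .simulate import SummaryMetrics, TimeGrid, Trajectory, simulate, summarize

__all__ = [
    "DoseResponseResult",
    "OATSweepResult",
    "dose_sweep",
    "oat_sweep",
    "sensitivity_report",
    "sweep_to_frame",
]

#: Parameters a sweep may scale (rate constants, capacities, initial glucose).
SWEEPABLE = (
    "k_in", "kf_1", "kr_1", "kf_2", "kr_2", "kf_3", "kr_3", "kf_4", "kr_4",
    "kf_5", "kf_6", "i1", "i2", "Capacity_G", "Capacity_M", "glu_ex0",
)

OAT_STEP = 0.10
OAT_HALF_RUNS = 5


@dataclass(frozen=True)
class OATSweepResult:
    parameter: str
    factors: np.ndarray
    trajectories: tuple[Trajectory, ...]
    metrics: tuple[SummaryMetrics, ...]

    @property
    def baseline_index(self) -> int:
        return int(np.argmin(np.abs(self.factors - 1.0)))


@dataclass(frozen=True)
class DoseResponseResult:
    modulator: str
    doses: np.ndarray
    trajectories: tuple[Trajectory, ...]
    metrics: tuple[SummaryMetrics, ...]


def oat_sweep(
    params: ParameterSet,
    name: str,
    dose: ModulatorDose | None = None,
    grid: TimeGrid | None = None,
    step: float = OAT_STEP,
) -> OATSweepResult:
    """Eleven simulations scaling ``name`` by 1 + step*(-5..5), baseline included."""
    if name not in SWEEPABLE:
        raise KeyError(f"unknown sweepable parameter {name!r}; choose from {SWEEPABLE}")
    factors = 1.0 + step * np.arange(-OAT_HALF_RUNS, OAT_HALF_RUNS + 1)
    base_value = getattr(params, name)
    trajs, mets = [], []
    for f in factors:
        p = params.replace(**{name: base_value * f})
        traj = simulate(p, dose, grid)
        trajs.append(traj)
        mets.append(summarize(traj))
    return OATSweepResult(name, factors, tuple(trajs), tuple(mets))


def dose_sweep(
    params: ParameterSet,
    modulator: str,
    doses=None,
    grid: TimeGrid | None = None,
) -> DoseResponseResult:
    """One simulation per dose of ``modulator`` ("oligo" or "dg2"), other at 0."""
    if modulator not in ("oligo", "dg2"):
        raise KeyError(f"modulator must be 'oligo' or 'dg2', got {modulator!r}")
    doses = np.arange(11.0) if doses is None else np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be nonnegative")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    trajs, mets = [], []
    for d in doses:
        md = ModulatorDose(oligo=d) if modulator == "oligo" else ModulatorDose(dg2=d)
        traj = simulate(params, md, grid)
        trajs.append(traj)
        mets.append(summarize(traj))
    return DoseResponseResult(modulator, doses, tuple(trajs), tuple(mets))


def _max_rel_change(values: np.ndarray, baseline: float) -> float:
    if baseline == 0:
        return 0.0 if np.all(values == 0) else np.inf
    if not np.isfinite(baseline):
        return 0.0 if np.all(~np.isfinite(values)) else np.inf
    finite = values[np.isfinite(values)]
    worst = np.abs(finite - baseline).max() if finite.size else 0.0
    if finite.size < values.size:
        return np.inf
    return float(worst / abs(baseline))


def sensitivity_report(results: list[OATSweepResult]) -> pd.DataFrame:
    """Ranked sensitivity table: one row per swept parameter.

    Columns are the maximum relative change, across the factor grid, of the
    lactate peak, its time, and the glucose-exhaustion time versus the
    baseline run.  Rows are sorted by peak sensitivity descending; ties break
    alphabetically.
    """
    if not results:
        raise ValueError("need at least one sweep result")
    rows = []
    for res in results:
        ib = res.baseline_index
        peak = np.array([m.lac_ex_peak for m in res.metrics])
        ptime = np.array([m.lac_ex_peak_time for m in res.metrics])
        exh = np.array([m.glucose_exhaustion_time for m in res.metrics])
        rows.append({
            "parameter": res.parameter,
            "max_rel_change_lac_ex_peak": _max_rel_change(peak, peak[ib]),
            "max_rel_change_lac_ex_peak_time": _max_rel_change(ptime, ptime[ib]),
            "max_rel_change_glucose_exhaustion_time": _max_rel_change(exh, exh[ib]),
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["max_rel_change_lac_ex_peak", "parameter"], ascending=[False, True]
    ).reset_index(drop=True)
    return df


def sweep_to_frame(result: OATSweepResult | DoseResponseResult) -> pd.DataFrame:
    """Tidy per-run metrics table (one row per run per metric)."""
    if isinstance(result, OATSweepResult):
        run_col, run_vals, label = "factor", result.factors, result.parameter
    else:
        run_col, run_vals, label = "dose", result.doses, result.modulator
    rows = []
    for v, m in zip(run_vals, result.metrics):
        for metric_name, metric_value in vars(m).items():
            rows.append({"sweep": label, run_col: v, "metric": metric_name,
                         "value": metric_value})
    return pd.DataFrame(rows)
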