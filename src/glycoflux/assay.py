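"""Plate-reader ECA kinetic series: containers, normalization, rate estimation.

A kinetic dataset is a long-format CSV with columns::

    well, cell_line, condition, replicate, is_cell_free, time_min, rfu

one row per well per cycle.  Wells carrying only sensor and buffer (cell-free
controls) share the instrument drift of the sample wells; dividing each
sample well by the cell-free signal cancels multiplicative drift exactly,
which is why division (not subtraction) is the default normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentError",
    "ECACurve",
    "NormalizedCurve",
    "average_replicates",
    "ecar",
    "normalize_by_cell_free",
    "normalize_dataset",
    "phase_metrics",
    "read_kinetic_csv",
    "write_kinetic_csv",
]

KINETIC_COLUMNS = ["well", "cell_line", "condition", "replicate", "is_cell_free", "time_min", "rfu"]

CONDITIONS = ("control", "oligo", "dg2")


class AlignmentError(ValueError):
    """Curves do not share a common time grid."""


@dataclass(frozen=True)
class ECACurve:
    """One well's kinetic series in relative fluorescence units."""

    times: np.ndarray
    rfu: np.ndarray
    cell_line: str = ""
    condition: str = "control"
    replicate: int = 1
    is_cell_free: bool = False
    well: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.rfu, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "rfu", r)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("times and rfu must be 1-d arrays of equal length")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("rfu values must be finite")


@dataclass(frozen=True)
class NormalizedCurve:
    """Dimensionless normalized ECA series with provenance of its inputs."""

    times: np.ndarray
    value: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "value", np.asarray(self.value, dtype=float))

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


def _check_common_grid(times_a: np.ndarray, times_b: np.ndarray) -> None:
    if times_a.shape != times_b.shape or not np.array_equal(times_a, times_b):
        raise AlignmentError("curves are not on a common time grid")


def normalize_by_cell_free(
    sample: ECACurve, cell_free: ECACurve, method: str = "ratio"
) -> NormalizedCurve:
    """Normalize a sample well by its matched cell-free control well.

    ``method="ratio"`` (default) divides pointwise, cancelling any
    multiplicative drift shared by the two wells exactly.  ``"difference"``
    subtracts instead and is provided as an alternative only.
    """
    _check_common_grid(sample.times, cell_free.times)
    if not cell_free.is_cell_free:
        raise ValueError("control curve is not flagged is_cell_free")
    if method == "ratio":
        if np.any(cell_free.rfu <= 0):
            raise ZeroDivisionError("cell-free control has nonpositive RFU values")
        value = sample.rfu / cell_free.rfu
    elif method == "difference":
        value = sample.rfu - cell_free.rfu
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    prov = {
        "method": method,
        "sample": sample.well or f"{sample.condition}-{sample.replicate}",
        "cell_free": cell_free.well or "cell-free",
        "cell_line": sample.cell_line,
        "condition": sample.condition,
        "replicate": sample.replicate,
    }
    return NormalizedCurve(sample.times, value, prov)


def average_replicates(curves: list[NormalizedCurve]) -> NormalizedCurve:
    """Pointwise arithmetic mean of replicate curves on a common grid."""
    if not curves:
        raise ValueError("need at least one curve to average")
    for c in curves[1:]:
        _check_common_grid(curves[0].times, c.times)
    value = np.mean([c.value for c in curves], axis=0)
    prov = {
        "method": "mean",
        "n_replicates": len(curves),
        "inputs": [c.provenance for c in curves],
    }
    if curves[0].provenance:
        prov.setdefault("condition", curves[0].provenance.get("condition"))
        prov.setdefault("cell_line", curves[0].provenance.get("cell_line"))
    return NormalizedCurve(curves[0].times, value, prov)


#: Default ECAR sliding window, minutes (~7 samples on the 0.35-min grid).
DEFAULT_ECAR_WINDOW_MIN = 2.45


def ecar(curve: NormalizedCurve, window: float = DEFAULT_ECAR_WINDOW_MIN) -> np.ndarray:
    """Extracellular acidification rate: sliding-window least-squares slope.

    A centered window of ``window`` minutes (rounded to an odd number of
    samples, at least 3) is regressed against time at each grid point; edge
    windows are truncated one-sided.  Linear in the curve: ``ecar(a*c + b) ==
    a * ecar(c)``.
    """
    t, y = curve.times, curve.value
    dt = float(np.median(np.diff(t)))
    if window < 2 * dt:
        raise ValueError(f"window {window} min is below two grid spacings ({2 * dt:g} min)")
    n_win = int(round(window / dt))
    if n_win % 2 == 0:
        n_win += 1
    half = n_win // 2
    n = t.size
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        tw = t[lo:hi] - t[i]
        yw = y[lo:hi]
        # least-squares slope of yw on tw
        tc = tw - tw.mean()
        out[i] = float(tc @ (yw - yw.mean()) / (tc @ tc))
    return out


def _moving_average(y: np.ndarray, n: int = 5) -> np.ndarray:
    """Centered moving average with one-sided truncation at the edges."""
    half = n // 2
    out = np.empty_like(y, dtype=float)
    for i in range(y.size):
        lo, hi = max(0, i - half), min(y.size, i + half + 1)
        out[i] = y[lo:hi].mean()
    return out


#: Phase boundaries, minutes: phase 1 is [0, 70), phase 2 is (90, end].
PHASE1_END_MIN = 70.0
PHASE2_START_MIN = 90.0


def phase_metrics(
    curve: NormalizedCurve, window: float = DEFAULT_ECAR_WINDOW_MIN
) -> dict[str, float]:
    """Peak time and per-phase mean ECAR of a two-phase response curve.

    The peak is located on a 5-point moving-average smoothing of the signal
    (earliest time on ties).  Phase 1 covers [0, 70) min of rising
    acidification; phase 2 covers (90, end] min where lactate re-import pulls
    the signal down.  Requires a curve spanning at least 90 min.
    """
    if curve.span < PHASE2_START_MIN:
        raise ValueError(
            f"curve spans {curve.span:g} min; phase metrics need >= {PHASE2_START_MIN:g}"
        )
    smooth = _moving_average(curve.value, 5)
    peak_time = float(curve.times[int(np.argmax(smooth))])
    rates = ecar(curve, window)
    t = curve.times
    phase1 = rates[(t >= 0) & (t < PHASE1_END_MIN)]
    phase2 = rates[t > PHASE2_START_MIN]
    return {
        "peak_time": peak_time,
        "phase1_mean_ecar": float(phase1.mean()),
        "phase2_mean_ecar": float(phase2.mean()),
    }


# -- kinetic CSV interchange ------------------------------------------------

def write_kinetic_csv(curves: list[ECACurve] | pd.DataFrame, path) -> None:
    """Write the long-format kinetic CSV dialect (UTF-8, header required)."""
    if isinstance(curves, pd.DataFrame):
        df = curves[KINETIC_COLUMNS]
    else:
        frames = [
            pd.DataFrame({
                "well": c.well,
                "cell_line": c.cell_line,
                "condition": c.condition,
                "replicate": c.replicate,
                "is_cell_free": c.is_cell_free,
                "time_min": c.times,
                "rfu": c.rfu,
            })
            for c in curves
        ]
        df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_kinetic_csv(path) -> list[ECACurve]:
    """Read a kinetic CSV back into per-well curves (input order preserved)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(KINETIC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"kinetic CSV missing columns: {sorted(missing)}")
    curves = []
    for well, g in df.groupby("well", sort=False):
        g = g.sort_values("time_min")
        curves.append(ECACurve(
            times=g["time_min"].to_numpy(float),
            rfu=g["rfu"].to_numpy(float),
            cell_line=str(g["cell_line"].iloc[0]),
            condition=str(g["condition"].iloc[0]),
            replicate=int(g["replicate"].iloc[0]),
            is_cell_free=bool(g["is_cell_free"].iloc[0]),
            well=str(well),
        ))
    return curves


def normalize_dataset(curves: list[ECACurve]) -> dict[tuple[str, str], NormalizedCurve]:
    """Full preprocessing of one plate: drift removal, then replicate averaging.

    The cell-free wells are averaged pointwise into one control signal; each
    sample well is divided by it; replicates are then averaged per
    (cell_line, condition).  Division-before-averaging is this package's
    declared convention.
    """
    cell_free = [c for c in curves if c.is_cell_free]
    samples = [c for c in curves if not c.is_cell_free]
    if not cell_free:
        raise ValueError("dataset contains no cell-free control wells")
    for c in cell_free[1:]:
        _check_common_grid(cell_free[0].times, c.times)
    control = ECACurve(
        times=cell_free[0].times,
        rfu=np.mean([c.rfu for c in cell_free], axis=0),
        cell_line=cell_free[0].cell_line,
        condition="control",
        is_cell_free=True,
        well="cell-free-mean",
    )
    out: dict[tuple[str, str], NormalizedCurve] = {}
    keys = sorted({(c.cell_line, c.condition) for c in samples})
    for key in keys:
        group = [c for c in samples if (c.cell_line, c.condition) == key]
        normalized = [normalize_by_cell_free(c, control) for c in group]
        out[key] = average_replicates(normalized)
    return out
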