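"""Model calibration against normalized ECA curves.

The measured (normalized) signal is an affine image of the simulated
extracellular lactate, ``y(t) ~ a * Lac_ex(t) + b``.  The calibration
objective therefore profiles the affine map out analytically (ordinary least
squares per curve) and minimizes the residual sum of squares over a declared
subset of kinetic parameters, with bounded local least squares started from
multiple log-uniform draws.  By default the free subset is exactly the set
of parameters that differs between the characterized cell lines:
{k_in, Capacity_G, Capacity_M, kr_3, i2}.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .assay import NormalizedCurve
from .model import ModulatorDose, ParameterSet
from .simulate import IntegrationError, TimeGrid, Trajectory, simulate

__all__ = [
    "AffineMap",
    "CalibrationError",
    "CalibrationProblem",
    "CalibrationResult",
    "CalibrationTarget",
    "DegenerateRegressorError",
    "DEFAULT_FREE",
    "fit",
    "fit_affine_map",
    "objective",
]

logger = logging.getLogger(__name__)

DEFAULT_FREE: tuple[str, ...] = ("k_in", "Capacity_G", "Capacity_M", "kr_3", "i2")

#: Default bounds: each free parameter within a factor of 10 of its base value.
DEFAULT_BOUND_FACTOR = 10.0

#: Smallest admissible affine scale when the unconstrained OLS slope is <= 0.
A_FLOOR = 1e-12

#: Objective value returned when a simulation fails at a trial point.
PENALTY = 1e12


class CalibrationError(RuntimeError):
    """All optimization starts failed."""


class DegenerateRegressorError(ValueError):
    """Simulated Lac_ex is constant; the affine map is unidentifiable."""


@dataclass(frozen=True)
class AffineMap:
    """Signal = a * Lac_ex + b, with a > 0 (``degenerate`` flags a clamped a)."""

    a: float
    b: float
    degenerate: bool = False


def _ols_affine(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise DegenerateRegressorError("simulated Lac_ex is constant over the curve grid")
    a = float(xc @ (y - y.mean()) / denom)
    b = float(y.mean() - a * x.mean())
    return a, b


def fit_affine_map(traj: Trajectory, curve: NormalizedCurve) -> tuple[AffineMap, float]:
    """OLS affine map from simulated Lac_ex to the measured curve, plus RSS.

    The trajectory is interpolated linearly to the curve's times, which must
    lie inside the simulated span.  If the unconstrained slope is
    nonpositive, it is clamped to a tiny positive floor and flagged.
    """
    if curve.times[0] < traj.times[0] or curve.times[-1] > traj.times[-1]:
        raise ValueError("curve grid extends beyond the simulated time span")
    x = np.interp(curve.times, traj.times, traj.lac_ex)
    a, b = _ols_affine(x, curve.value)
    degenerate = a <= 0
    if degenerate:
        a = A_FLOOR
        b = float(np.mean(curve.value - a * x))
    resid = curve.value - (a * x + b)
    return AffineMap(a, b, degenerate), float(resid @ resid)


@dataclass(frozen=True)
class CalibrationTarget:
    """One normalized curve and the dose it was acquired under."""

    curve: NormalizedCurve
    dose: ModulatorDose = ModulatorDose()


@dataclass(frozen=True)
class CalibrationProblem:
    """Targets, base parameters, free subset, bounds and multistart policy."""

    targets: tuple[CalibrationTarget, ...]
    base: ParameterSet
    free: tuple[str, ...] = DEFAULT_FREE
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_starts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        known = set(self.base.to_dict())
        for name in self.free:
            if name not in known:
                raise KeyError(f"free parameter {name!r} is not a ParameterSet field")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi < np.inf):
                raise ValueError(f"bounds for {name!r} must be positive, finite, lo < hi")

    def bound(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        v = self.base.to_dict()[name]
        if v <= 0:
            raise ValueError(
                f"cannot derive default bounds for {name!r} from base value {v}; "
                "supply explicit bounds"
            )
        return (v / DEFAULT_BOUND_FACTOR, v * DEFAULT_BOUND_FACTOR)


def _apply(problem: CalibrationProblem, theta: np.ndarray) -> ParameterSet:
    changes = {}
    for name, v in zip(problem.free, theta):
        changes["glu_ex0" if name == "Glu_ex" else name] = float(v)
    return problem.base.replace(**changes)


def _residuals(problem: CalibrationProblem, theta: np.ndarray) -> np.ndarray:
    """Concatenated per-point residuals with the affine maps profiled out."""
    params = _apply(problem, theta)
    pieces = []
    for target in problem.targets:
        curve = target.curve
        try:
            traj = simulate(params, target.dose, TimeGrid(curve.times))
            x = traj.lac_ex
            a, b = _ols_affine(x, curve.value)
            pieces.append(curve.value - (a * x + b))
        except (IntegrationError, DegenerateRegressorError) as exc:
            logger.warning("simulation failed at theta=%s: %s", theta, exc)
            n = curve.times.size
            pieces.append(np.full(n, np.sqrt(PENALTY / n)))
    return np.concatenate(pieces)


def objective(problem: CalibrationProblem, theta: np.ndarray | list[float]) -> float:
    """Sum over curves of the profiled-affine residual sum of squares."""
    r = _residuals(problem, np.asarray(theta, dtype=float))
    return float(r @ r)


@dataclass(frozen=True)
class CalibrationResult:
    """Best-start fit, per-curve affine maps and per-start diagnostics."""

    params: ParameterSet
    affine_maps: tuple[AffineMap, ...]
    rss: float
    free: tuple[str, ...]
    theta: tuple[float, ...]
    per_start: tuple[dict, ...]
    best_start: int
    seed: int

    def to_json(self, **dump_kwargs) -> str:
        payload = {
            "free": list(self.free),
            "theta": list(self.theta),
            "params": self.params.to_dict(),
            "affine_maps": [
                {"a": m.a, "b": m.b, "degenerate": m.degenerate} for m in self.affine_maps
            ],
            "rss": self.rss,
            "best_start": self.best_start,
            "seed": self.seed,
            "per_start": list(self.per_start),
        }
        return json.dumps(payload, indent=2, **dump_kwargs)


def _final_maps(
    problem: CalibrationProblem, params: ParameterSet
) -> tuple[tuple[AffineMap, ...], float]:
    maps, rss = [], 0.0
    for target in problem.targets:
        traj = simulate(params, target.dose, TimeGrid(target.curve.times))
        m, r = fit_affine_map(traj, target.curve)
        maps.append(m)
        rss += r
    return tuple(maps), rss


def fit(problem: CalibrationProblem) -> CalibrationResult:
    """Bounded multistart local least squares over the free parameters.

    Starts are drawn log-uniformly inside the bounds with the problem's seed
    and optimized in log-parameter space (trust-region reflective).  The
    result is deterministic given identical problems and seeds.  With an
    empty free set the base parameters are returned with affine maps only.
    """
    if not problem.free:
        maps, rss = _final_maps(problem, problem.base)
        return CalibrationResult(
            problem.base, maps, rss, (), (), ({"note": "no free parameters"},), 0,
            problem.seed,
        )

    lo = np.array([problem.bound(n)[0] for n in problem.free])
    hi = np.array([problem.bound(n)[1] for n in problem.free])
    log_lo, log_hi = np.log(lo), np.log(hi)
    rng = np.random.default_rng(problem.seed)
    starts = np.exp(rng.uniform(log_lo, log_hi, size=(problem.n_starts, len(problem.free))))

    def fun(u: np.ndarray) -> np.ndarray:
        return _residuals(problem, np.exp(u))

    per_start: list[dict] = []
    best = None
    for k, x0 in enumerate(starts):
        try:
            # finite-difference step well above the ODE solver's noise floor
            sol = least_squares(
                fun, np.log(x0), bounds=(log_lo, log_hi), method="trf",
                diff_step=1e-4,
            )
            cost = float(2 * sol.cost)  # residual sum of squares
            per_start.append({
                "start": k,
                "x0": x0.tolist(),
                "theta": np.exp(sol.x).tolist(),
                "rss": cost,
                "success": bool(sol.success),
                "message": sol.message,
            })
            if sol.success and (best is None or cost < best[0]):
                best = (cost, np.exp(sol.x))
        except Exception as exc:  # noqa: BLE001 - per-start diagnostics
            logger.warning("start %d failed: %s", k, exc)
            per_start.append({"start": k, "x0": x0.tolist(), "error": str(exc)})
    if best is None:
        raise CalibrationError(f"all {problem.n_starts} starts failed: {per_start}")

    theta = best[1]
    fitted = _apply(problem, theta)
    maps, rss = _final_maps(problem, fitted)
    best_idx = min(
        (s for s in per_start if s.get("success")), key=lambda s: s["rss"]
    )["start"]
    return CalibrationResult(
        fitted, maps, rss, problem.free, tuple(float(v) for v in theta),
        tuple(per_start), best_idx, problem.seed,
    )
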