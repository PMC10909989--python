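"""Synthetic plate-reader datasets with the statistical structure of the assay.

The generator simulates the latent extracellular lactate Lac_ex(t) for each
condition of a plate and converts it to instrument counts via an affine map
plus plate-wide multiplicative drift and per-observation multiplicative
Gaussian noise::

    RFU(t) = drift(t) * (a * Lac_ex(t) + b) * (1 + eps),   eps ~ N(0, sigma^2)

Cell-free wells carry ``drift(t) * b * (1 + eps)``.  Because the drift is
shared by every well of the plate, dividing by the cell-free control removes
it exactly — the same rationale the assay protocol uses.  The pre-starvation
initial ECA spike seen in unstarved cells is deliberately not generated: the
model targets the starved regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import KINETIC_COLUMNS
from .model import ModulatorDose, ParameterSet, preset
from .simulate import TimeGrid, default_grid, simulate

__all__ = ["GeneratorConfig", "generate", "generate_recovery_bundle"]


def _default_doses() -> dict[str, ModulatorDose]:
    # mid-range model doses for the two drug conditions
    return {
        "control": ModulatorDose(0.0, 0.0),
        "oligo": ModulatorDose(5.0, 0.0),
        "dg2": ModulatorDose(0.0, 5.0),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that defines one synthetic plate.

    Attributes
    ----------
    seed : int
        Mandatory RNG seed; the generated CSV is a pure function of it.
    cell_line : str
        Preset used for the latent kinetics ("A549", "LLCMK2" or "HepG2").
    doses : dict
        ModulatorDose per condition; defaults to control plus mid-range
        (5-unit) oligomycin and 2DG conditions.
    rfu_per_um, rfu_offset : float
        Affine map (a, b) from latent Lac_ex (uM) to instrument RFU.
    sigma : float
        Multiplicative noise, as a fraction of the instantaneous signal.
    drift_slope, drift_intercept : float
        Linear plate-wide drift profile drift(t) = intercept + slope * t,
        applied multiplicatively to all wells including cell-free controls.
    replicates : int
        Wells per condition (and cell-free control wells), default 3.
    grid : TimeGrid
        Acquisition grid, default 400 cycles at 0.35 min.
    """

    seed: int
    cell_line: str = "A549"
    doses: dict[str, ModulatorDose] = field(default_factory=_default_doses)
    rfu_per_um: float = 0.004
    rfu_offset: float = 10.0
    sigma: float = 0.01
    drift_slope: float = 0.001
    drift_intercept: float = 1.0
    replicates: int = 3
    grid: TimeGrid = field(default_factory=default_grid)
    params: ParameterSet | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.rfu_per_um <= 0:
            raise ValueError("rfu_per_um (affine scale a) must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def parameter_set(self) -> ParameterSet:
        return self.params if self.params is not None else preset(self.cell_line)


def generate(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one plate as a long-format kinetic table (see assay module).

    Deterministic given the seed: two calls with the same config produce
    byte-identical CSV output.
    """
    rng = np.random.default_rng(config.seed)
    p = config.parameter_set()
    t = config.grid.points
    drift = config.drift_intercept + config.drift_slope * t
    a, b = config.rfu_per_um, config.rfu_offset

    rows = []

    def emit(well, condition, rep, is_cf, clean):
        eps = rng.normal(0.0, config.sigma, size=t.size) if config.sigma > 0 else 0.0
        rows.append(pd.DataFrame({
            "well": well,
            "cell_line": config.cell_line,
            "condition": condition,
            "replicate": rep,
            "is_cell_free": is_cf,
            "time_min": t,
            "rfu": drift * clean * (1.0 + eps),
        }))

    for condition in sorted(config.doses):
        lac_ex = simulate(p, config.doses[condition], config.grid).lac_ex
        clean = a * lac_ex + b
        for rep in range(1, config.replicates + 1):
            emit(f"{condition}-{rep}", condition, rep, False, clean)
    for rep in range(1, config.replicates + 1):
        emit(f"cellfree-{rep}", "control", rep, True, b)

    return pd.concat(rows, ignore_index=True)[KINETIC_COLUMNS]


def generate_recovery_bundle(
    cell_line: str,
    free_names: tuple[str, ...],
    sigma: float,
    seed: int,
    **config_overrides,
) -> tuple[pd.DataFrame, dict]:
    """Dataset plus the sealed ground truth for a parameter-recovery test.

    The dataset is generated from the named preset; the truth record holds
    the generating values of the declared free parameters along with the
    affine map and per-condition doses, for post-fit comparison.
    """
    config = GeneratorConfig(seed=seed, cell_line=cell_line, sigma=sigma, **config_overrides)
    p = config.parameter_set()
    truth = {
        "cell_line": cell_line,
        "free": {name: p.to_dict()[name] for name in free_names},
        "affine": {"a": config.rfu_per_um, "b": config.rfu_offset},
        "doses": {k: (d.oligo, d.dg2) for k, d in config.doses.items()},
        "sigma": sigma,
        "seed": seed,
    }
    return generate(config), truth
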