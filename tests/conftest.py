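import io

import numpy as np
import pytest

import glycoflux as gf

CELL_LINES = ("A549", "LLCMK2", "HepG2")


@pytest.fixture(scope="session")
def a549():
    return gf.preset("A549")


@pytest.fixture(scope="session")
def control_trajectories():
    """Control (no-dose) trajectories for all presets on the assay grid."""
    return {name: gf.simulate(gf.preset(name)) for name in CELL_LINES}


@pytest.fixture(scope="session")
def noiseless_curves():
    """Drift-free, noise-free normalized curves per cell line (control dose)."""
    out = {}
    for name in CELL_LINES:
        cfg = gf.GeneratorConfig(seed=0, cell_line=name, sigma=0.0, drift_slope=0.0)
        df = gf.generate(cfg)
        curves = _roundtrip_curves(df)
        out[name] = gf.normalize_dataset(curves)[(name, "control")]
    return out


def _roundtrip_curves(df):
    buf = io.StringIO()
    gf.write_kinetic_csv(df, buf)
    buf.seek(0)
    return gf.read_kinetic_csv(buf)


@pytest.fixture()
def curves_from_frame():
    """Callable: kinetic DataFrame -> per-well ECACurve list (via the CSV dialect)."""
    return _roundtrip_curves


def make_calibration_targets(df, oligo_dose=5.0, dg2_dose=5.0):
    """Preprocess a generated plate into calibration targets with known doses."""
    normalized = gf.normalize_dataset(_roundtrip_curves(df))
    dose_map = {
        "control": gf.ModulatorDose(),
        "oligo": gf.ModulatorDose(oligo=oligo_dose),
        "dg2": gf.ModulatorDose(dg2=dg2_dose),
    }
    return tuple(
        gf.CalibrationTarget(curve, dose_map[cond])
        for (_line, cond), curve in sorted(normalized.items())
    )


@pytest.fixture()
def calibration_targets():
    return make_calibration_targets


def assert_close(actual, expected, rtol, floor=0.0):
    actual = np.asarray(actual, dtype=float)
    expected = np.asarray(expected, dtype=float)
    denom = np.maximum(np.abs(expected), floor) if floor else np.abs(expected)
    assert np.all(np.abs(actual - expected) <= rtol * denom), (
        f"max relative error {np.max(np.abs(actual - expected) / denom):g} > {rtol}"
    )
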