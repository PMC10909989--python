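import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glycoflux as gf
from glycoflux.assay import AlignmentError, _moving_average

T = np.arange(0, 140, 0.35)


def curve(rfu, is_cell_free=False, **kw):
    return gf.ECACurve(times=T, rfu=np.asarray(rfu, dtype=float),
                       is_cell_free=is_cell_free, **kw)


def norm(value):
    return gf.NormalizedCurve(times=T, value=np.asarray(value, dtype=float))


class TestNormalization:
    def test_sample_equal_to_control_gives_unit_curve(self):
        c = curve(np.full(T.size, 7.0), is_cell_free=True)
        out = gf.normalize_by_cell_free(curve(np.full(T.size, 7.0)), c)
        np.testing.assert_array_equal(out.value, np.ones(T.size))

    def test_multiplicative_drift_cancels_exactly(self):
        latent = 1.0 + np.sin(T / 20)
        drift = 1.0 + 0.002 * T
        out = gf.normalize_by_cell_free(
            curve(latent * drift), curve(drift, is_cell_free=True)
        )
        np.testing.assert_allclose(out.value, latent, rtol=1e-14)

    def test_grid_mismatch_raises_alignment_error(self):
        other = gf.ECACurve(times=T + 0.1, rfu=np.ones(T.size), is_cell_free=True)
        with pytest.raises(AlignmentError):
            gf.normalize_by_cell_free(curve(np.ones(T.size)), other)

    def test_control_must_be_flagged_cell_free(self):
        with pytest.raises(ValueError, match="cell_free"):
            gf.normalize_by_cell_free(curve(np.ones(T.size)), curve(np.ones(T.size)))

    def test_nonpositive_control_raises_division_error(self):
        bad = np.ones(T.size)
        bad[10] = 0.0
        with pytest.raises(ZeroDivisionError):
            gf.normalize_by_cell_free(curve(np.ones(T.size)),
                                      curve(bad, is_cell_free=True))

    def test_subtraction_is_available_as_alternative(self):
        out = gf.normalize_by_cell_free(
            curve(np.full(T.size, 3.0)), curve(np.ones(T.size), is_cell_free=True),
            method="difference",
        )
        np.testing.assert_array_equal(out.value, np.full(T.size, 2.0))
        assert out.provenance["method"] == "difference"

    def test_generator_drift_round_trip(self, noiseless_curves):
        """Generated plates with and without drift normalize to the same curve."""
        with_drift = gf.generate(
            gf.GeneratorConfig(seed=0, sigma=0.0, drift_slope=0.002)
        )
        import io

        buf = io.StringIO()
        gf.write_kinetic_csv(with_drift, buf)
        buf.seek(0)
        got = gf.normalize_dataset(gf.read_kinetic_csv(buf))[("A549", "control")]
        np.testing.assert_allclose(got.value, noiseless_curves["A549"].value,
                                   rtol=1e-12)


class TestAveraging:
    def test_single_curve_is_returned_unchanged(self):
        c = norm(np.sin(T))
        np.testing.assert_array_equal(gf.average_replicates([c]).value, c.value)

    def test_identical_replicates_average_to_themselves(self):
        c = norm(np.cos(T))
        out = gf.average_replicates([c, c, c])
        np.testing.assert_allclose(out.value, c.value, rtol=1e-15)

    def test_opposite_curves_cancel(self):
        c = np.sin(T)
        out = gf.average_replicates([norm(c), norm(-c)])
        np.testing.assert_allclose(out.value, np.zeros(T.size), atol=1e-15)

    def test_mixed_grids_rejected(self):
        other = gf.NormalizedCurve(times=T[:-1], value=np.ones(T.size - 1))
        with pytest.raises(AlignmentError):
            gf.average_replicates([norm(np.ones(T.size)), other])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            gf.average_replicates([])


class TestEcar:
    def test_linear_curve_gives_constant_slope(self):
        rates = gf.ecar(norm(0.3 * T + 2.0))
        np.testing.assert_allclose(rates, 0.3, rtol=1e-10)

    def test_constant_curve_gives_zero(self):
        np.testing.assert_allclose(gf.ecar(norm(np.full(T.size, 5.0))), 0.0,
                                   atol=1e-12)

    def test_window_below_two_spacings_rejected(self):
        with pytest.raises(ValueError):
            gf.ecar(norm(np.ones(T.size)), window=0.3)

    def test_two_phase_curve_changes_sign_at_peak(self, noiseless_curves):
        c = noiseless_curves["A549"]
        rates = gf.ecar(c)
        i_peak = int(np.argmax(c.value))
        assert np.all(rates[5:i_peak - 5] > 0)
        assert np.mean(rates[i_peak + 5:]) < 0

    @settings(derandomize=True, max_examples=30)
    @given(a=st.floats(-5, 5, allow_nan=False), b=st.floats(-10, 10, allow_nan=False))
    def test_ecar_is_linear_in_the_signal(self, a, b):
        base = np.sin(T / 15) + 0.01 * T
        np.testing.assert_allclose(
            gf.ecar(gf.NormalizedCurve(T, a * base + b)),
            a * gf.ecar(gf.NormalizedCurve(T, base)),
            rtol=1e-9, atol=1e-12,
        )


class TestPhaseMetrics:
    def test_monotone_curve_peaks_at_the_end(self):
        m = gf.phase_metrics(norm(T**1.5))
        assert m["peak_time"] == T[-1]
        assert m["phase2_mean_ecar"] > 0

    def test_short_span_rejected(self):
        short = gf.NormalizedCurve(times=T[T < 80], value=np.ones((T < 80).sum()))
        with pytest.raises(ValueError):
            gf.phase_metrics(short)

    def test_two_phase_signs_on_synthetic_control(self, noiseless_curves):
        m = gf.phase_metrics(noiseless_curves["A549"])
        assert m["phase1_mean_ecar"] > 0
        assert m["phase2_mean_ecar"] < 0

    def test_hepg2_peaks_later_than_a549(self, noiseless_curves):
        assert (gf.phase_metrics(noiseless_curves["HepG2"])["peak_time"]
                > gf.phase_metrics(noiseless_curves["A549"])["peak_time"])

    def test_affine_rescaling_moves_rates_not_peak_time(self, noiseless_curves):
        c = noiseless_curves["A549"]
        scaled = gf.NormalizedCurve(c.times, 3.0 * c.value + 1.0)
        m, ms = gf.phase_metrics(c), gf.phase_metrics(scaled)
        assert ms["peak_time"] == m["peak_time"]
        assert ms["phase1_mean_ecar"] == pytest.approx(3 * m["phase1_mean_ecar"])
        assert ms["phase2_mean_ecar"] == pytest.approx(3 * m["phase2_mean_ecar"])


def test_moving_average_truncates_edges_one_sided():
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    out = _moving_average(y, 5)
    assert out[0] == pytest.approx(np.mean(y[:3]))
    assert out[2] == pytest.approx(np.mean(y[:5]))
    assert out[-1] == pytest.approx(np.mean(y[3:]))


def test_kinetic_csv_round_trip(tmp_path):
    df = gf.generate(gf.GeneratorConfig(seed=5, replicates=2))
    path = tmp_path / "kinetic.csv"
    gf.write_kinetic_csv(df, path)
    curves = gf.read_kinetic_csv(path)
    assert len(curves) == 2 * 3 + 2  # sample wells + cell-free wells
    sample = [c for c in curves if c.well == "control-1"][0]
    original = df[df.well == "control-1"]
    np.testing.assert_array_equal(sample.rfu, original["rfu"].to_numpy())
    assert sample.cell_line == "A549" and not sample.is_cell_free


def test_normalize_dataset_requires_cell_free_wells(curves_from_frame):
    df = gf.generate(gf.GeneratorConfig(seed=5))
    curves = [c for c in curves_from_frame(df) if not c.is_cell_free]
    with pytest.raises(ValueError, match="cell-free"):
        gf.normalize_dataset(curves)
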