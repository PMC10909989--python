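import numpy as np
import pytest

import glycoflux as gf
from glycoflux.experiments import dose_sweep, oat_sweep, sensitivity_report, sweep_to_frame


@pytest.fixture(scope="module")
def a549():
    return gf.preset("A549")


@pytest.fixture(scope="module")
def sweeps(a549):
    """Cached OAT sweeps used across several assertions."""
    names = ["Capacity_G", "Capacity_M", "kf_2", "kf_3", "kf_4", "kf_5", "kf_6",
             "kr_1", "kr_2", "kr_3", "kr_4", "glu_ex0"]
    return {name: oat_sweep(a549, name) for name in names}


def peaks(res):
    return np.array([m.lac_ex_peak for m in res.metrics])


class TestOATProtocol:
    def test_eleven_runs_with_symmetric_factor_grid(self, sweeps):
        res = sweeps["Capacity_G"]
        assert len(res.trajectories) == len(res.metrics) == 11
        np.testing.assert_allclose(res.factors, 1.0 + 0.1 * np.arange(-5, 6))
        assert res.factors[res.baseline_index] == pytest.approx(1.0)

    def test_zero_step_reproduces_baseline_eleven_times(self, a549):
        res = oat_sweep(a549, "kf_2", step=0.0)
        base = res.trajectories[5].states
        for traj in res.trajectories:
            np.testing.assert_array_equal(traj.states, base)

    def test_unknown_parameter_rejected(self, a549):
        with pytest.raises(KeyError):
            oat_sweep(a549, "k_out")

    def test_each_run_conserves_mass(self, sweeps):
        for res in sweeps.values():
            for traj in res.trajectories:
                totals = traj.states.sum(axis=1)
                assert np.abs(totals - traj.params.glu_ex0).max() <= \
                    1e-6 * traj.params.glu_ex0


class TestSupplementaryNarratives:
    """Directional effects of each parameter on the lactate kinetics."""

    def test_reverse_glycolysis_rate_has_essentially_no_effect(self, sweeps):
        p = peaks(sweeps["kr_1"])
        base = p[sweeps["kr_1"].baseline_index]
        # inert at +-10%; still far below every controlling parameter at +-50%
        assert np.abs(p[[4, 6]] - base).max() / base < 1e-3
        assert np.abs(p - base).max() / base < 1.5e-3

    def test_more_glucose_raises_the_terminal_lactate_plateau(self, sweeps):
        terminal = np.array([m.terminal_lac_ex for m in sweeps["glu_ex0"].metrics])
        assert np.all(np.diff(terminal) > 0)

    def test_glycolytic_capacity_accelerates_phase_one(self, a549, sweeps):
        # glucose remaining mid-phase-1 drops as Capacity_G rises
        res = sweeps["Capacity_G"]
        i50 = int(np.searchsorted(res.trajectories[0].times, 50.0))
        remaining = [traj.species("Glu_ex")[i50] for traj in res.trajectories]
        assert np.all(np.diff(remaining) < 0)
        # and glucose exhaustion never gets later (inf-aware comparison)
        exh = [m.glucose_exhaustion_time for m in res.metrics]
        assert all(a >= b for a, b in zip(exh, exh[1:]))

    def test_mitochondrial_capacity_suppresses_the_lactate_peak(self, sweeps):
        assert np.all(np.diff(peaks(sweeps["Capacity_M"])) < 0)

    def test_forward_lactate_path_raises_peak_reverse_lowers_it(self, sweeps):
        for forward in ("kf_2", "kf_3"):
            assert np.all(np.diff(peaks(sweeps[forward])) > 0)
        for reverse in ("kr_2", "kr_3"):
            assert np.all(np.diff(peaks(sweeps[reverse])) < 0)

    def test_mitochondrial_uptake_lowers_peak_and_dwarfs_its_reverse(self, sweeps):
        assert np.all(np.diff(peaks(sweeps["kf_4"])) < 0)
        report = sensitivity_report([sweeps["kf_4"], sweeps["kr_4"]])
        by_param = report.set_index("parameter")["max_rel_change_lac_ex_peak"]
        assert by_param["kr_4"] < by_param["kf_4"] / 3

    def test_the_two_terminal_drains_are_interchangeable(self, sweeps):
        """kf_5 and kf_6 start equal, so their sweeps move Lac_ex identically."""
        for t5, t6 in zip(sweeps["kf_5"].trajectories, sweeps["kf_6"].trajectories):
            assert np.abs(t5.lac_ex - t6.lac_ex).max() <= 1e-9 * t5.params.glu_ex0
        rows = sensitivity_report([sweeps["kf_5"], sweeps["kf_6"]])
        assert np.allclose(rows.iloc[0, 1:].astype(float),
                           rows.iloc[1, 1:].astype(float), atol=1e-9)

    def test_capacities_control_the_model_more_than_reverse_glycolysis(self, sweeps):
        report = sensitivity_report([sweeps["kr_1"], sweeps["Capacity_G"],
                                     sweeps["Capacity_M"]])
        assert report.iloc[-1]["parameter"] == "kr_1"


@pytest.fixture(scope="module")
def oligo_sweep(a549):
    return dose_sweep(a549, "oligo")


@pytest.fixture(scope="module")
def dg2_sweep(a549):
    return dose_sweep(a549, "dg2")


class TestDoseSweeps:
    def test_default_grid_is_integer_doses(self, oligo_sweep):
        np.testing.assert_array_equal(oligo_sweep.doses, np.arange(11.0))

    def test_oligomycin_stimulates_lactate_monotonically(self, oligo_sweep):
        assert np.all(np.diff(peaks(oligo_sweep)) >= 0)

    def test_dg2_inhibits_lactate_and_phase_one_oxpp_formation(self, dg2_sweep):
        assert np.all(np.diff(peaks(dg2_sweep)) <= 0)
        # formation rate: OxPP accumulated by mid-phase-1 falls with dose
        i50 = int(np.searchsorted(dg2_sweep.trajectories[0].times, 50.0))
        oxpp_mid = [t.species("OxPP")[i50] for t in dg2_sweep.trajectories]
        assert np.all(np.diff(oxpp_mid) <= 0)

    def test_zero_dose_run_is_bit_identical_to_control(self, a549, oligo_sweep):
        control = gf.simulate(a549)
        np.testing.assert_array_equal(oligo_sweep.trajectories[0].states,
                                      control.states)

    def test_negative_or_unordered_doses_rejected(self, a549):
        with pytest.raises(ValueError):
            dose_sweep(a549, "oligo", doses=[-1.0, 0.0])
        with pytest.raises(ValueError):
            dose_sweep(a549, "dg2", doses=[0.0, 2.0, 1.0])
        with pytest.raises(KeyError):
            dose_sweep(a549, "caffeine")


class TestReporting:
    def test_empty_result_list_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_report([])

    def test_report_sorted_by_peak_sensitivity_with_alphabetical_ties(self, sweeps):
        report = sensitivity_report([sweeps["kf_5"], sweeps["kf_6"],
                                     sweeps["Capacity_M"]])
        assert report.iloc[0]["parameter"] == "Capacity_M"
        assert list(report["parameter"][1:]) == ["kf_5", "kf_6"]

    def test_tidy_frame_has_one_row_per_run_per_metric(self, sweeps):
        df = sweep_to_frame(sweeps["Capacity_G"])
        assert len(df) == 11 * 6
        assert set(df.columns) == {"sweep", "factor", "metric", "value"}
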