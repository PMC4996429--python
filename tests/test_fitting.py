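"""Unit tests for the least-squares calibration engine."""

import numpy as np
import pytest

from snarfcal import (
    CalibrationParameters,
    FitResult,
    FitSpec,
    NoEndpointError,
    RatioSeries,
    SyntheticConfig,
    TitrationCalibrator,
    TitrationDataset,
    ValidationError,
    aggregate_replicates,
    apparent_pka_shift,
    compare_hill,
    estimate_plateaus,
    eval_ratio_full,
    fit_calibration,
    plot_fit,
)
from snarfcal.synth import simulate_ratio_series, simulation_truth

TRUE_LIMITS = ("i1a", "i1b", "i2a", "i2b")


def _fixed_limits(cal: CalibrationParameters) -> dict:
    return {k: getattr(cal, k) for k in TRUE_LIMITS}


@pytest.fixture
def mito_truth():
    """Effective (bleed-corrected) generating calibration."""
    return simulation_truth(SyntheticConfig(noise_sd=0.0)).calibration


@pytest.fixture
def noiseless_dataset(noiseless_mito):
    return noiseless_mito[0]


class TestEstimatePlateaus:
    def test_flat_plateaus_recovered_exactly(self):
        i1 = np.array([100.0] * 3 + [80.0, 50.0, 25.0] + [20.0] * 3)
        i2 = np.array([30.0] * 3 + [50.0, 80.0, 110.0] + [120.0] * 3)
        ds = TitrationDataset(ph=np.linspace(4.0, 11.0, 9), i1=i1, i2=i2)
        est = estimate_plateaus(ds, edge_fraction=1 / 3)
        assert (est.i1a, est.i1b, est.i2a, est.i2b) == (100.0, 20.0, 30.0, 120.0)

    def test_wide_unit_hill_titration_within_half_percent(self):
        """With a pKa +/- 4 range the edge windows sit on real plateaus."""
        cfg = SyntheticConfig(
            pka_true=7.5, n_true=1.0, noise_sd=0.0,
            ph_grid=tuple(np.linspace(3.5, 11.5, 25)),
        )
        ds, _, truth = simulate_ratio_series(cfg)
        est = estimate_plateaus(ds, edge_fraction=0.15)
        for name in TRUE_LIMITS:
            assert getattr(est, name) == pytest.approx(
                getattr(truth.calibration, name), rel=5e-3
            )

    def test_narrow_range_flagged(self):
        ph = np.linspace(6.5, 8.5, 9)
        ds = TitrationDataset(ph=ph, i1=100 - 8 * (ph - 6.5), i2=30 + 8 * (ph - 6.5))
        with pytest.raises(ValidationError, match="pH units"):
            estimate_plateaus(ds)

    def test_tiny_edge_window_rejected(self):
        ph = np.linspace(4.0, 11.0, 9)
        ds = TitrationDataset(ph=ph, i1=np.linspace(100, 20, 9), i2=np.linspace(30, 120, 9))
        with pytest.raises(ValidationError, match="widen"):
            estimate_plateaus(ds, edge_fraction=0.1)


class TestZeroNoiseIdentifiability:
    def test_full_ratio_fit_recovers_truth(self, noiseless_dataset, mito_truth):
        res = fit_calibration(
            noiseless_dataset, model_id="eq9", fixed_params=_fixed_limits(mito_truth)
        )
        assert res.converged
        assert res.estimates["pka"] == pytest.approx(8.5, abs=1e-8)
        assert res.estimates["n"] == pytest.approx(0.54, abs=1e-8)

    def test_one_site_plateau_fixing_is_also_exact(self, noiseless_dataset):
        """Limiting intensities fixed from per-channel one-site fits are
        exact on noiseless data, so the ratio fit recovers truth too."""
        res = fit_calibration(noiseless_dataset, model_id="eq9")
        assert res.estimates["pka"] == pytest.approx(8.5, abs=1e-7)
        assert res.estimates["n"] == pytest.approx(0.54, abs=1e-7)
        assert res.rss < 1e-14

    def test_single_wavelength_fit(self, noiseless_dataset, mito_truth):
        res = fit_calibration(noiseless_dataset, model_id="eq7", channel=2)
        assert res.estimates["pka"] == pytest.approx(8.5, abs=1e-7)
        assert res.estimates["ia"] == pytest.approx(mito_truth.i2a, rel=1e-6)
        assert res.estimates["ib"] == pytest.approx(mito_truth.i2b, rel=1e-6)

    def test_hh_ratio_fit_lands_on_apparent_pka(self, mito_truth):
        """Fitting the ratio-blend model to exact full-model data recovers
        the closed-form apparent pKa, not the true one."""
        ph = np.linspace(3.0, 13.0, 60)
        series = RatioSeries(ph=ph, ratio=eval_ratio_full(ph, mito_truth), orientation="R12")
        res = fit_calibration(series, model_id="eq8", fixed_params={"n": mito_truth.n})
        assert res.estimates["pka"] == pytest.approx(
            apparent_pka_shift(mito_truth, "R12"), abs=1e-6
        )


class TestFitBehaviour:
    def test_estimates_invariant_to_intensity_rescaling(self, noiseless_dataset):
        res = fit_calibration(noiseless_dataset, model_id="eq9")
        scaled = TitrationDataset(
            ph=noiseless_dataset.ph,
            i1=noiseless_dataset.i1 * 37.0,
            i2=noiseless_dataset.i2 * 37.0,
        )
        res2 = fit_calibration(scaled, model_id="eq9")
        assert res2.estimates["pka"] == pytest.approx(res.estimates["pka"], abs=1e-8)
        assert res2.estimates["n"] == pytest.approx(res.estimates["n"], abs=1e-8)

    def test_estimates_invariant_to_point_order(self, mito_truth):
        ph = np.linspace(4.8, 11.0, 25)
        r = eval_ratio_full(ph, mito_truth)
        rng = np.random.default_rng(7)
        perm = rng.permutation(ph.size)
        kw = dict(model_id="eq9", fixed_params=_fixed_limits(mito_truth))
        a = fit_calibration(RatioSeries(ph=ph, ratio=r, orientation="R12"), **kw)
        b = fit_calibration(RatioSeries(ph=ph[perm], ratio=r[perm], orientation="R12"), **kw)
        assert a.estimates["pka"] == pytest.approx(b.estimates["pka"], abs=1e-10)

    def test_deterministic_given_identical_inputs(self, noiseless_dataset):
        a = fit_calibration(noiseless_dataset, model_id="eq9")
        b = fit_calibration(noiseless_dataset, model_id="eq9")
        assert a.estimates == b.estimates and a.rss == b.rss

    def test_noisy_estimates_with_standard_errors(self):
        ds, _, _ = simulate_ratio_series(SyntheticConfig(noise_sd=0.01, seed=42))
        res = fit_calibration(ds, model_id="eq9")
        assert res.converged and res.stderr is not None
        assert set(res.stderr) == {"pka", "n"}
        assert abs(res.estimates["pka"] - 8.5) < 3 * 3 * res.stderr["pka"] + 0.1

    def test_too_few_points_rejected(self, mito_truth):
        ph = np.linspace(6.0, 9.0, 4)
        series = RatioSeries(ph=ph, ratio=eval_ratio_full(ph, mito_truth), orientation="R12")
        with pytest.raises(ValidationError, match="5"):
            fit_calibration(series, model_id="eq9", fixed_params=_fixed_limits(mito_truth))

    def test_sklearn_estimator_interface(self, noiseless_dataset):
        calib = TitrationCalibrator(model_id="eq9")
        assert calib.get_params()["model_id"] == "eq9"
        calib.set_params(edge_fraction=0.2)
        calib.fit(noiseless_dataset)
        assert calib.converged_ and hasattr(calib, "pka_")
        pred = calib.predict(noiseless_dataset.ph)
        ratio = noiseless_dataset.i1 / noiseless_dataset.i2
        assert np.allclose(pred, ratio, rtol=1e-6)

    def test_bare_ratio_series_needs_fixed_limits(self, mito_truth):
        ph = np.linspace(4.8, 11.0, 25)
        series = RatioSeries(ph=ph, ratio=eval_ratio_full(ph, mito_truth), orientation="R12")
        with pytest.raises(ValidationError, match="fixed_params"):
            fit_calibration(series, model_id="eq9")


class TestEndpointRefusal:
    def test_r21_without_basic_plateau_is_refused(self, noiseless_dataset):
        """Anticooperative in-organello-style data read as R21 diverges at
        the basic end; the fixed-plateau fit is refused."""
        with pytest.raises(NoEndpointError, match="no titration end-point"):
            fit_calibration(noiseless_dataset, model_id="eq10")

    def test_r12_same_data_is_accepted(self, noiseless_dataset):
        assert fit_calibration(noiseless_dataset, model_id="eq9").converged

    def test_check_can_be_disabled(self, noiseless_dataset):
        res = fit_calibration(noiseless_dataset, model_id="eq10", endpoint_check=False)
        assert res.converged


class TestHillComparison:
    def test_unit_hill_truth_gives_no_gain(self):
        cfg = SyntheticConfig(pka_true=7.46, n_true=1.0, noise_sd=0.01, seed=3,
                              ph_grid=tuple(np.linspace(3.5, 11.5, 25)))
        ds, _, _ = simulate_ratio_series(cfg)
        cmp = compare_hill(ds, base_model="eq12", hill_model="eq9")
        assert cmp.n == pytest.approx(1.0, abs=3 * cmp.n_stderr)
        assert cmp.rss_ratio < 2.0

    def test_anticooperative_truth_needs_hill_term(self):
        ds, _, _ = simulate_ratio_series(SyntheticConfig(noise_sd=0.01, seed=4))
        cmp = compare_hill(ds, base_model="eq12", hill_model="eq9")
        assert cmp.n == pytest.approx(0.54, abs=0.05)
        assert cmp.rss_ratio > 5.0

    def test_no_hill_model_leaves_structured_residuals(self, noiseless_dataset):
        """On noiseless anticooperative data the no-n model's residuals are
        large and change sign in long runs rather than scattering."""
        cmp = compare_hill(noiseless_dataset, base_model="eq12", hill_model="eq9")
        assert cmp.base.rss > 1e3 * cmp.hill.rss
        signs = np.sign(cmp.base.residuals)
        runs = 1 + int(np.sum(np.diff(signs[signs != 0]) != 0))
        assert runs <= 6  # few long runs = systematic misfit

    def test_rejects_misordered_models(self, noiseless_dataset):
        with pytest.raises(ValidationError):
            compare_hill(noiseless_dataset, base_model="eq9", hill_model="eq12")


class TestReplicateAggregation:
    @staticmethod
    def _result(pka, n):
        return FitResult(
            model_id="eq9", estimates={"pka": pka, "n": n},
            stderr={"pka": 0.02, "n": 0.01}, residuals=np.zeros(5),
            rss=0.0, converged=True, n_iterations=10,
        )

    def test_replicate_means_match_reported_averages(self):
        """Three replicate calibrations averaging to pKa 8.51 and n 0.54."""
        summary = aggregate_replicates(
            [self._result(8.47, 0.56), self._result(8.57, 0.56), self._result(8.50, 0.51)]
        )
        assert round(summary.mean["pka"], 2) == 8.51
        assert round(summary.mean["n"], 2) == 0.54

    def test_identical_replicates_have_zero_sd(self):
        summary = aggregate_replicates([self._result(8.5, 0.5)] * 3)
        assert summary.sd["pka"] == 0.0

    def test_mixed_model_ids_rejected(self):
        other = FitResult(model_id="eq12", estimates={"pka": 8.3}, stderr={"pka": 0.1},
                          residuals=np.zeros(5), rss=0.0, converged=True, n_iterations=5)
        with pytest.raises(ValidationError, match="mixed"):
            aggregate_replicates([self._result(8.5, 0.5), other])


class TestNarrowRangeArtifact:
    def test_no_hill_narrow_window_biases_ph_high(self, mito_truth):
        """Calibrating over one pH unit around neutrality with the no-n
        model inflates the reported pH by > 0.3 units, mimicking the
        consensus alkaline values obtained from narrow calibrations."""
        true_ph = 7.1
        r_star = eval_ratio_full(true_ph, mito_truth)
        ph = np.linspace(7.55, 8.6, 9)
        narrow = RatioSeries(ph=ph, ratio=eval_ratio_full(ph, mito_truth), orientation="R12")
        res = fit_calibration(
            narrow, model_id="eq12",
            fixed_params=_fixed_limits(mito_truth), endpoint_check=False,
        )
        from snarfcal import invert_manufacturer

        biased_cal = mito_truth.with_(pka=res.estimates["pka"], n=1.0)
        ph_reported = invert_manufacturer(r_star, biased_cal)
        assert ph_reported - true_ph > 0.3


def test_plot_fit_writes_image(tmp_path, noiseless_mito):
    res = fit_calibration(noiseless_mito[0], model_id="eq9")
    out = tmp_path / "fit.png"
    plot_fit(res, out)
    assert out.stat().st_size > 0
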