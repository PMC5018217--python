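"""Three-parameter logarithmic calibration: recovery, prediction, diagnostics."""

import numpy as np
import pytest

from anitax.calibrate import (bootstrap_intervals, correlation_report,
                              fit_calibration, predict_ani)
from anitax.seqio import SymMatrix

TRUE = dict(a=40.0, b=12.0, c=60.0)


def model_points(sims, noise_sd=0.0, seed=None):
    sims = np.asarray(sims, dtype=float)
    anis = TRUE["a"] + TRUE["b"] * np.log(sims - TRUE["c"])
    if noise_sd:
        anis = anis + np.random.default_rng(seed).normal(0, noise_sd, sims.size)
    return list(zip(sims, anis))


class TestFit:
    def test_noiseless_recovery_to_optimizer_tolerance(self):
        m = fit_calibration(model_points([70, 75, 80, 85, 90, 99]))
        assert m.a == pytest.approx(TRUE["a"], abs=1e-6)
        assert m.b == pytest.approx(TRUE["b"], abs=1e-6)
        assert m.c == pytest.approx(TRUE["c"], abs=1e-6)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_fit_keeps_high_r_squared(self):
        pts = model_points(np.linspace(70, 99, 20), noise_sd=0.5, seed=1)
        m = fit_calibration(pts)
        assert m.r_squared > 0.95

    def test_degenerate_equal_sims_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            fit_calibration([(80, 70), (80, 71), (80, 72), (80, 73)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4"):
            fit_calibration(model_points([70, 80, 90]))

    def test_r_squared_invariant_to_point_order(self):
        pts = model_points(np.linspace(70, 99, 12), noise_sd=0.5, seed=2)
        m1 = fit_calibration(pts)
        m2 = fit_calibration(pts[::-1])
        assert m1.r_squared == pytest.approx(m2.r_squared, abs=1e-9)

    def test_fitted_curve_increasing_when_b_positive(self):
        m = fit_calibration(model_points(np.linspace(70, 99, 10)))
        assert m.b > 0
        grid = np.linspace(70, 99, 50)
        assert np.all(np.diff(m.predict(grid)) > 0)


class TestPredict:
    def test_interpolation_identity_on_noiseless_model(self):
        sims = [70, 75, 80, 85, 90, 99]
        pts = model_points(sims)
        m = fit_calibration(pts)
        p = predict_ani(m, 85.0)
        assert p.predicted_ani == pytest.approx(dict(pts)[85.0], abs=1e-6)
        assert p.lower <= p.predicted_ani <= p.upper

    def test_extrapolation_below_offset_rejected(self):
        m = fit_calibration(model_points([70, 80, 90, 99]))
        with pytest.raises(ValueError, match="offset|domain|below"):
            predict_ani(m, m.c - 1.0)

    def test_below_species_threshold_flag(self):
        pts = model_points(np.linspace(70, 99, 20), noise_sd=0.3, seed=3)
        m = fit_calibration(pts)
        low = predict_ani(m, 72.0)   # predicted ANI ~ 70 %
        assert low.below_species_threshold
        # a similarity predicting ANI ~95+ must not be called a new species
        hi_sims = np.linspace(90, 110, 20)
        hi_pts = [(s, 60 + 12 * np.log(s - 85)) for s in hi_sims]
        mh = fit_calibration(hi_pts)
        hi = predict_ani(mh, 109.0)
        assert not hi.below_species_threshold

    def test_synthetic_truth_inside_interval(self):
        pts = model_points(np.linspace(70, 99, 20), noise_sd=0.5, seed=4)
        m = fit_calibration(pts)
        true_ani = TRUE["a"] + TRUE["b"] * np.log(85.0 - TRUE["c"])
        p = predict_ani(m, 85.0)
        assert p.lower <= true_ani <= p.upper


class TestBootstrap:
    def test_intervals_cover_point_estimates(self):
        pts = model_points(np.linspace(70, 99, 20), noise_sd=0.5, seed=5)
        m = fit_calibration(pts)
        ci = bootstrap_intervals(pts, n_boot=99, seed=6)
        for name in ("a", "b", "c"):
            lo, hi = ci[name]
            assert lo < hi
            assert lo - 5 < getattr(m, name) < hi + 5


class TestCorrelationReport:
    @staticmethod
    def _matrices(seed=0, shuffle=False):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(6)]
        sim = SymMatrix.identity(labels, kind="similarity")
        ani = SymMatrix.identity(labels, kind="ani")
        for i in range(6):
            for j in range(i + 1, 6):
                s = rng.uniform(75, 99)
                sim.set_value(labels[i], labels[j], s)
                ani.set_value(labels[i], labels[j],
                              TRUE["a"] + TRUE["b"] * np.log(s - TRUE["c"])
                              + rng.normal(0, 0.3))
        if shuffle:
            perm = rng.permutation(6)
            ani = SymMatrix(labels, ani.values[np.ix_(perm, perm)], kind="ani")
        return sim, ani

    def test_identity_pairing_reaches_r2_one(self):
        labels = ["a", "b", "c", "d"]
        vals = np.full((4, 4), 100.0)
        for (i, j), v in zip([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
                             [80.0, 85.0, 90.0, 77.0, 95.0, 88.0]):
            vals[i, j] = vals[j, i] = v
        sim = SymMatrix(labels, vals, kind="similarity")
        ani = SymMatrix(labels, vals.copy(), kind="ani")
        # a straight line is only the c -> -inf limit of the log family, so
        # within the bounded c search window the fit is near- but not
        # machine-perfect
        rep = correlation_report(sim, ani)
        assert rep["r_squared"] > 0.99
        assert rep["model"].b > 0

    def test_matched_pairing_beats_shuffled(self):
        sim, ani = self._matrices(seed=7)
        matched = correlation_report(sim, ani)["r_squared"]
        sim2, ani2 = self._matrices(seed=7, shuffle=True)
        shuffled = correlation_report(sim2, ani2)["r_squared"]
        assert matched > 0.95
        assert shuffled < matched - 0.2

    def test_p_value_small_for_tight_correlation(self):
        sim, ani = self._matrices(seed=8)
        rep = correlation_report(sim, ani)
        assert rep["p_value"] < 1e-4

    def test_plot_written(self, tmp_path):
        sim, ani = self._matrices(seed=9)
        out = tmp_path / "cal.svg"
        correlation_report(sim, ani, plot_path=str(out))
        assert out.stat().st_size > 0

    def test_too_few_shared_taxa_rejected(self):
        sim, ani = self._matrices(seed=10)
        small = sim.submatrix(sim.labels[:2])
        with pytest.raises(ValueError, match="taxa"):
            correlation_report(small, ani.submatrix(ani.labels[:2]))
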