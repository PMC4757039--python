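import numpy as np
import pytest

from tdrcapture import (
    BloodRecord,
    McmcConfig,
    fit_additive_regression,
    predict_mean,
    extrapolate_mean,
    read_blood_table,
    significance,
    two_group_difference,
    write_blood_table,
)
from tdrcapture.bayes import _gibbs_linear, quadratic_term_check


def make_records(dur, sst, y, response="glucose", alive=None):
    """Records with one meaningful response column; others filled neutrally."""
    n = len(dur)
    alive = [True] * n if alive is None else alive
    out = []
    for i in range(n):
        fields = dict(
            ph=7.4, lactate=3.0, glucose=5.0, potassium=3.4,
            osmolality=1.1, haematocrit=25.0,
        )
        fields[response] = float(y[i])
        out.append(
            BloodRecord(
                animal_id=f"a{i}",
                capture_duration_min=float(dur[i]),
                sst_c=float(sst[i]),
                alive=alive[i],
                **fields,
            )
        )
    return out


class TestSignificance:
    def test_wide_interval_not_significant(self):
        # hook-timer vs depth-logger duration comparison scale
        assert not significance(-52.285, 52.725)

    def test_negative_interval_significant(self):
        assert significance(-1.528, -0.550)

    def test_zero_boundary_not_significant(self):
        assert not significance(0.0, 1.0)

    def test_bad_order_rejected(self):
        with pytest.raises(ValueError):
            significance(1.0, -1.0)


class TestGibbsSampler:
    def test_conjugate_closed_form_with_fixed_variance(self, rng):
        n, s2 = 50, 0.49
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n), rng.normal(0, 1, n)])
        beta_true = np.array([1.0, 2.0, -0.5])
        y = X @ beta_true + rng.normal(0, np.sqrt(s2), n)
        cfg = McmcConfig(iterations=30_000, burn_in=2_000, thinning=5)
        betas, _ = _gibbs_linear(X, y, cfg, np.random.default_rng(8), fixed_sigma2=s2)
        prec = X.T @ X / s2 + cfg.prior_precision * np.eye(3)
        cov = np.linalg.inv(prec)
        mu = cov @ (X.T @ y / s2)
        sd_exact = np.sqrt(np.diag(cov))
        n_draws = betas.shape[0]
        mc_se = sd_exact / np.sqrt(n_draws)
        # draws are thinned but still mildly autocorrelated: allow 5x
        np.testing.assert_array_less(np.abs(betas.mean(0) - mu), 5 * mc_se)
        np.testing.assert_allclose(betas.std(0, ddof=1), sd_exact, rtol=0.1)

    def test_zero_noise_plane_recovered_exactly(self):
        rng = np.random.default_rng(3)
        n = 20
        dur = rng.uniform(30, 240, n)
        sst = rng.uniform(12, 20, n)
        y = 2.0 + 0.0 * dur + 0.2 * sst
        records = make_records(dur, sst, y)
        cfg = McmcConfig(
            iterations=20_000, burn_in=2_000, sigma_prior_rate=1e-12, seed=0
        )
        fit = fit_additive_regression(records, "glucose", mcmc=cfg)
        assert fit.coefficients["intercept"].mean == pytest.approx(2.0, rel=1e-6)
        assert fit.coefficients["sst_c"].mean == pytest.approx(0.2, rel=1e-6)
        assert abs(fit.coefficients["capture_duration_min"].mean) < 1e-6

    def test_parameter_recovery_n200(self):
        rng = np.random.default_rng(4)
        n = 200
        dur = rng.uniform(30, 240, n)
        sst = rng.uniform(12, 20, n)
        y = 2.0 + 0.2 * sst + rng.normal(0, 0.5, n)
        fit = fit_additive_regression(
            make_records(dur, sst, y), "glucose",
            mcmc=McmcConfig(iterations=10_000, burn_in=1_000, seed=1),
        )
        cd = fit.coefficients["capture_duration_min"]
        cs = fit.coefficients["sst_c"]
        assert cd.ci_lo <= 0.0 <= cd.ci_hi and not cd.significant
        assert cs.significant and cs.ci_lo > 0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        records = make_records(
            rng.uniform(30, 240, 22), rng.uniform(12, 20, 22), rng.normal(5, 1, 22)
        )
        cfg = McmcConfig(iterations=5_000, burn_in=500, seed=77)
        a = fit_additive_regression(records, "glucose", mcmc=cfg)
        b = fit_additive_regression(records, "glucose", mcmc=cfg)
        assert a.coefficients == b.coefficients

    def test_posterior_contraction_with_n(self):
        sds = []
        for n in (20, 200, 2000):
            rng = np.random.default_rng(6)
            dur = rng.uniform(30, 240, n)
            sst = rng.uniform(12, 20, n)
            y = 10.0 + 0.1 * sst + rng.normal(0, 1.0, n)
            fit = fit_additive_regression(
                make_records(dur, sst, y), "glucose",
                mcmc=McmcConfig(iterations=5_000, burn_in=500, seed=2),
            )
            sds.append(fit.coefficients["sst_c"].sd)
        assert sds[0] > sds[1] > sds[2]

    def test_ess_diagnostics_present(self):
        rng = np.random.default_rng(7)
        records = make_records(
            rng.uniform(30, 240, 30), rng.uniform(12, 20, 30), rng.normal(5, 1, 30)
        )
        fit = fit_additive_regression(
            records, "glucose", mcmc=McmcConfig(iterations=10_000, burn_in=1_000, seed=3)
        )
        assert fit.converged
        assert fit.diagnostics["ess_sst_c"] >= 200


class TestFitValidation:
    def test_dead_animals_excluded(self):
        rng = np.random.default_rng(8)
        n = 22
        dur = rng.uniform(30, 240, n)
        sst = rng.uniform(12, 20, n)
        y = 3.0 + 0.2 * sst + rng.normal(0, 0.3, n)
        alive = [True] * n
        alive[5] = False
        records = make_records(dur, sst, y, alive=alive)
        fit = fit_additive_regression(
            records, "glucose", mcmc=McmcConfig(iterations=3_000, burn_in=500, seed=0)
        )
        assert fit.n == n - 1

    def test_all_dead_rejected(self):
        records = make_records([60, 70, 80, 90], [12, 14, 16, 18], [5] * 4,
                               alive=[False] * 4)
        with pytest.raises(ValueError, match="live"):
            fit_additive_regression(records, "glucose")

    def test_too_few_records(self):
        records = make_records([60, 70, 80], [12, 14, 16], [5, 5, 5])
        with pytest.raises(ValueError, match=">= 4"):
            fit_additive_regression(records, "glucose")

    def test_constant_predictor_rejected(self):
        records = make_records([60] * 10, np.linspace(12, 20, 10), [5] * 10)
        with pytest.raises(ValueError, match="constant"):
            fit_additive_regression(records, "glucose")

    def test_unknown_response_rejected(self):
        records = make_records([60, 70, 80, 90], [12, 14, 16, 18], [5] * 4)
        with pytest.raises(ValueError, match="unknown response"):
            fit_additive_regression(records, "cortisol")


class TestPredictMean:
    def _fit_noiseless(self, transform, intercept, slope_sst, response="glucose"):
        rng = np.random.default_rng(9)
        n = 30
        dur = rng.uniform(30, 240, n)
        sst = rng.uniform(12, 20, n)
        eta = intercept + slope_sst * sst
        y = np.exp(eta) if transform == "log" else eta
        return fit_additive_regression(
            make_records(dur, sst, y, response=response),
            response,
            mcmc=McmcConfig(iterations=10_000, burn_in=1_000,
                            sigma_prior_rate=1e-12, seed=4),
            transform=transform,
        )

    def test_zero_slope_gives_intercept(self):
        fit = self._fit_noiseless("identity", 4.0, 0.0)
        for sst in (12.0, 16.4, 20.0):
            assert predict_mean(fit, sst).mean == pytest.approx(4.0, rel=1e-6)

    def test_log_transform_round_trip(self):
        # noiseless exponential data: predictions reproduce the curve
        # to <= 0.1% across the fitted SST range
        fit = self._fit_noiseless("log", np.log(2.938) - 0.221 * 12.0, 0.221,
                                  response="lactate")
        for sst in np.linspace(12, 20, 9):
            truth = 2.938 * np.exp(0.221 * (sst - 12.0))
            assert predict_mean(fit, sst).mean == pytest.approx(truth, rel=1e-3)

    def test_extrapolation_warns(self):
        fit = self._fit_noiseless("identity", 4.0, 0.1)
        with pytest.warns(UserWarning, match="extrapolating"):
            predict_mean(fit, 30.0)


class TestExtrapolateMean:
    def test_identity(self):
        assert extrapolate_mean(4.986, 0.196, 8.0) == pytest.approx(6.554)

    def test_log_ratio(self):
        out = extrapolate_mean(2.938, 0.221, 8.0, transform="log")
        assert out / 2.938 == pytest.approx(np.exp(0.221 * 8.0))

    def test_unknown_transform(self):
        with pytest.raises(ValueError):
            extrapolate_mean(1.0, 1.0, 1.0, transform="sqrt")


class TestTwoGroupDifference:
    cfg = McmcConfig(iterations=8_000, burn_in=500, seed=11)

    def test_identical_groups_straddle_zero(self):
        x = np.linspace(0, 1, 30)
        d = two_group_difference(x, x, self.cfg)
        assert d.ci_lo < 0 < d.ci_hi
        assert not d.significant

    def test_separated_groups(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        d = two_group_difference(a, b, self.cfg)
        assert d.significant
        mc_se = 3 * np.sqrt(2.0 / 50)
        assert d.mean == pytest.approx(-5.0, abs=mc_se)

    def test_zero_variance_group_warns(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            d = two_group_difference([2.0, 2.0, 2.0], [1.0, 2.0, 3.0], self.cfg)
        assert np.isfinite(d.mean)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            two_group_difference([1.0], [1.0, 2.0], self.cfg)


class TestQuadraticScreen:
    def test_linear_data_flags_no_curvature(self):
        rng = np.random.default_rng(12)
        n = 60
        dur = rng.uniform(30, 240, n)
        sst = rng.uniform(12, 20, n)
        y = 2.0 + 0.2 * sst + rng.normal(0, 0.3, n)
        c = quadratic_term_check(
            make_records(dur, sst, y), "glucose", "sst_c",
            McmcConfig(iterations=8_000, burn_in=1_000, seed=5),
        )
        assert not c.significant


class TestBloodTableIO:
    def test_round_trip(self, tmp_path, rng):
        records = make_records(
            rng.uniform(30, 240, 5), rng.uniform(12, 20, 5), rng.normal(5, 1, 5)
        )
        p = tmp_path / "blood.csv"
        write_blood_table(records, p)
        back = read_blood_table(p)
        assert back == records

    def test_duplicate_animal_id_named(self, tmp_path):
        records = make_records([60, 70, 80], [12, 14, 16], [5, 5, 5])
        records[2] = BloodRecord(**{**records[0].__dict__})
        p = tmp_path / "blood.csv"
        write_blood_table(records, p)
        with pytest.raises(ValueError, match="duplicate animal_id 'a0'"):
            read_blood_table(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "blood.csv"
        p.write_text("animal_id,ph\nx,7.4\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_blood_table(p)

    def test_record_invariants(self):
        with pytest.raises(ValueError, match="SST"):
            BloodRecord("x", 7.4, 3, 5, 3.4, 1.1, 25, 60.0, 50.0)
        with pytest.raises(ValueError, match="duration"):
            BloodRecord("x", 7.4, 3, 5, 3.4, 1.1, 25, -5.0, 15.0)
        with pytest.raises(ValueError, match="lactate"):
            BloodRecord("x", 7.4, -3, 5, 3.4, 1.1, 25, 60.0, 15.0)
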