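import numpy as np
import pandas as pd
import pytest

from spikescale.bayes import (
    ModelSpec,
    build_design,
    compare_elpd,
    fit_model,
    loo_pit,
    summarize_posterior,
)
from spikescale.cohort import CohortConfig, generate_bayes_cohort

# small but informative cohort for fast unit tests
SMALL = dict(n_mice=4, units_per_area=60,
             areas={"V1": 0.0, "LM": 0.264, "AL": 0.509, "AM": 0.798})
FAST_SAMPLER = dict(n_walkers=50, n_burn=4000, n_steps=2000)


def fit_small(cohort, area_term="hierarchy", likelihood="lognormal", seed=0):
    design = build_design(cohort)
    spec = ModelSpec(area_term=area_term, likelihood=likelihood,
                     seed=seed, **FAST_SAMPLER)
    return fit_model(spec, design, cohort.loc[design.index, "measure"])


class TestCohortGenerator:
    def test_null_model_shared_median(self):
        cfg = CohortConfig(**SMALL, mu_slope=0.0, sigma_slope=0.0,
                           sigma_theta0=0.0, theta_lognu=0.0, theta_rf=0.0,
                           epsilon=0.3)
        t = generate_bayes_cohort(cfg, seed=1)
        meds = t.groupby("area")["measure"].median()
        np.testing.assert_allclose(meds, 0.5, rtol=0.15)

    def test_known_slope_lognormal_median(self):
        """Per-area median of the measure ~ theta0 + slope * HS."""
        cfg = CohortConfig(n_mice=8, units_per_area=400,
                           areas=dict(SMALL["areas"]),
                           mu_theta0=0.1, sigma_theta0=0.0,
                           mu_slope=0.3, sigma_slope=0.0,
                           theta_lognu=0.0, theta_rf=0.0, epsilon=0.5)
        t = generate_bayes_cohort(cfg, seed=2)
        for area, hs in SMALL["areas"].items():
            med = t.loc[t["area"] == area, "measure"].median()
            assert med == pytest.approx(0.1 + 0.3 * hs, rel=0.1)

    def test_negative_alpha_negative_skew(self):
        ok = 0
        for seed in range(20):
            cfg = CohortConfig(**SMALL, alpha=-2.0)
            t = generate_bayes_cohort(cfg, seed=seed)
            ly = np.log(t["measure"])
            from scipy.stats import skew
            ok += skew(ly - ly.groupby([t.mouse_id, t.area]).transform("mean")) < 0
        assert ok >= 19

    def test_nonpositive_area_term_raises(self):
        cfg = CohortConfig(**SMALL, mu_theta0=0.05, mu_slope=-0.3,
                           sigma_theta0=0.0, sigma_slope=0.0)
        with pytest.raises(ValueError):
            generate_bayes_cohort(cfg, seed=0)


class TestBuildDesign:
    def _table(self):
        return pd.DataFrame(
            {
                "mouse_id": ["m0"] * 4,
                "area": ["LGN", "V1", "LM", "AM"],
                "group": ["thalamus", "V1", "higher_cortical", "higher_cortical"],
                "hierarchy_score": [-0.5, 0.1, 0.37, 0.9],
                "firing_rate_hz": [1.0, np.e, np.e**3, np.e**2],
                "rf_flag": [0, 1, 0, 1],
            }
        )

    def test_thalamus_excluded_v1_shift(self):
        d = build_design(self._table())
        assert len(d) == 3
        assert d.loc[d["area"] == "V1", "hs"].iloc[0] == 0.0
        assert d.loc[d["area"] == "V1", "hc"].iloc[0] == 0.0

    def test_lognu_two_sd_normalization(self):
        t = self._table().iloc[1:3]  # rates e and e^3 -> log nu 1 and 3
        d = build_design(t)
        np.testing.assert_allclose(sorted(d["lognu_norm"]), [-0.5, 0.5], atol=1e-12)
        assert d["lognu_norm"].std(ddof=0) == pytest.approx(0.5)

    def test_constant_rate_warns(self):
        t = self._table()
        t["firing_rate_hz"] = 2.0
        with pytest.warns(UserWarning):
            d = build_design(t)
        assert (d["lognu_norm"] == 0).all()

    def test_unknown_group_label(self):
        t = self._table()
        t.loc[0, "group"] = "hippocampus"
        with pytest.raises(ValueError):
            build_design(t)


class TestFitModel:
    def test_null_slope_hdi_covers_zero(self):
        cfg = CohortConfig(**SMALL, mu_slope=0.0)
        cohort = generate_bayes_cohort(cfg, seed=10)
        fit = fit_small(cohort, seed=10)
        lo, hi = fit.hdi("mu_theta_hs")
        assert lo <= 0.0 <= hi
        # small cohorts mix more slowly; just reject wild non-convergence
        assert fit.diagnostics["rhat_max"] < 1.2

    def test_positive_slope_recovery(self):
        cfg = CohortConfig(**SMALL, mu_slope=0.3)
        cohort = generate_bayes_cohort(cfg, seed=11)
        fit = fit_small(cohort, seed=11)
        lo, hi = fit.hdi("mu_theta_hs")
        assert lo <= 0.3 <= hi
        assert fit.posterior_median("mu_theta_hs") > 0

    def test_skew_recovery(self):
        cfg = CohortConfig(**SMALL, alpha=-2.0)
        cohort = generate_bayes_cohort(cfg, seed=12)
        fit = fit_small(cohort, likelihood="skew_lognormal", seed=12)
        assert fit.posterior_median("alpha") < 0

    def test_nonpositive_measure_rejected(self):
        cohort = generate_bayes_cohort(CohortConfig(**SMALL), seed=0)
        design = build_design(cohort)
        y = cohort.loc[design.index, "measure"].copy()
        y.iloc[0] = 0.0
        with pytest.raises(ValueError):
            fit_model(ModelSpec(**FAST_SAMPLER), design, y)


class TestSummaries:
    def test_quantile_oracle(self):
        cohort = generate_bayes_cohort(CohortConfig(**SMALL), seed=13)
        fit = fit_small(cohort, seed=13)
        rows = summarize_posterior(fit, ["mu_theta0", "mu_theta_hs", "epsilon"])
        for _, r in rows.iterrows():
            d = fit.draws[r["param"]]
            assert r["median"] == pytest.approx(np.median(d), rel=1e-9)
            assert r["hdi_2.5"] < r["median"] < r["hdi_97.5"]

    def test_empty_param_set(self):
        cohort = generate_bayes_cohort(CohortConfig(**SMALL), seed=13)
        fit = fit_small(cohort, seed=13)
        assert len(summarize_posterior(fit, [])) == 0


class TestElpdAndPit:
    @pytest.fixture(scope="class")
    def fits(self):
        cfg = CohortConfig(**SMALL, mu_slope=0.3)
        cohort = generate_bayes_cohort(cfg, seed=20)
        return (
            fit_small(cohort, area_term="groups", seed=20),
            fit_small(cohort, area_term="hierarchy", seed=20),
        )

    def test_hierarchy_generated_prefers_hierarchy(self, fits):
        fg, fh = fits
        comp = compare_elpd(fg, fh)
        assert comp["elpd_diff"] > 0
        assert comp["reliable"]

    def test_groups_generated_prefers_groups(self):
        cfg = CohortConfig(**SMALL, area_term="groups", mu_slope=0.4)
        cohort = generate_bayes_cohort(cfg, seed=21)
        fg = fit_small(cohort, area_term="groups", seed=21)
        fh = fit_small(cohort, area_term="hierarchy", seed=21)
        comp = compare_elpd(fg, fh)
        assert comp["elpd_diff"] < 0

    def test_loo_pit_calibrated_under_truth(self, fits):
        _, fh = fits
        res = loo_pit(fh, seed=0)
        assert res["inside"]
        assert np.all((res["pit"] >= 0) & (res["pit"] <= 1))

    def test_loo_pit_detects_shift(self, fits):
        """Shifting the data after fitting piles PIT mass at one end."""
        _, fh = fits
        import copy

        shifted = copy.copy(fh)
        shifted.log_y = fh.log_y + 1.0
        shifted.model = copy.copy(fh.model)
        shifted.model.ly = fh.model.ly + 1.0
        res = loo_pit(shifted, seed=0)
        assert np.mean(res["pit"] > 0.9) > 0.5

    def test_two_area_unit_scores_make_models_coincide(self):
        """With two areas at HS in {0, 1} the hierarchy slope equals the
        higher-cortical offset, so neither model predicts better."""
        cfg = CohortConfig(n_mice=4, units_per_area=100,
                           areas={"V1": 0.0, "HC": 1.0}, mu_slope=0.25)
        cohort = generate_bayes_cohort(cfg, seed=30)
        fg = fit_small(cohort, area_term="groups", seed=30)
        fh = fit_small(cohort, area_term="hierarchy", seed=30)
        comp = compare_elpd(fg, fh)
        assert abs(comp["elpd_diff"]) <= 2 * max(comp["se_diff"], 1.0)

    def test_mismatched_data_rejected(self, fits):
        fg, fh = fits
        import copy

        other = copy.copy(fh)
        other.log_y = fh.log_y + 0.5
        with pytest.raises(ValueError):
            compare_elpd(fg, other)
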