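import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lakescape import DomainError, ModelError
from lakescape import velocity as vel

from _oracles import fit_reml_oracle
from conftest import make_panel


class TestTransforms:
    def test_ln_gdd_plus1_values(self):
        assert vel.transform_response(0.0) == 0.0
        assert vel.transform_response(np.e - 1) == pytest.approx(1.0)
        assert vel.inverse_transform(1.0) == pytest.approx(np.e - 1)

    def test_log_temp_plus10_domain(self):
        assert vel.transform_response(-9.999, "log_temp_plus10") < -6
        with pytest.raises(DomainError):
            vel.transform_response(-10.0, "log_temp_plus10")
        with pytest.raises(DomainError):
            vel.transform_response(-0.5, "ln_gdd_plus1")

    def test_base10_is_constant_rescaling(self):
        x = np.array([0.0, 5.0, 100.0, 2000.0])
        assert np.allclose(
            vel.transform_response(x, base="10") * np.log(10.0),
            vel.transform_response(x, base="e"),
        )


def _two_group_linear():
    years = np.arange(2000, 2010, dtype=float)
    rows = []
    for wid, (a, b) in [("w1", (1.0, 0.5)), ("w2", (2.0, 1.0))]:
        for t, yr in enumerate(years):
            rows.append((wid, yr, np.expm1(a + b * t)))
    return pd.DataFrame(rows, columns=["watershed_id", "year", "gdd"])


def test_exact_linear_two_groups_recovers_slopes():
    fit = vel.fit_random_slope_model(_two_group_linear())
    w = pd.DataFrame(
        {"watershed_id": ["w1", "w2"], "region": "r", "elevation_m": [1.0, 2.0]}
    )
    v = vel.extract_velocities(fit, w).set_index("watershed_id")["velocity"]
    assert v["w1"] == pytest.approx(0.5, abs=1e-3)
    assert v["w2"] == pytest.approx(1.0, abs=1e-3)
    assert fit.boundary  # zero-residual limit


def test_identical_groups_collapse_to_pooled_ols():
    rng = np.random.default_rng(0)
    y0 = 5 + 0.02 * np.arange(40) + rng.normal(0, 0.1, 40)
    rows = [
        (wid, 1980 + t, np.expm1(y0[t])) for wid in "abc" for t in range(40)
    ]
    dd = pd.DataFrame(rows, columns=["watershed_id", "year", "gdd"])
    fit = vel.fit_random_slope_model(dd)
    yc = np.arange(40) - np.arange(40).mean()
    pooled = np.polyfit(yc, y0, 1)[0]
    assert fit.fixed_slope_per_yr == pytest.approx(pooled, abs=1e-6)
    assert fit.var_b1 <= 1e-8


def test_too_few_groups_or_years_rejected():
    dd = _two_group_linear()
    with pytest.raises(ModelError):
        vel.fit_random_slope_model(dd[dd["watershed_id"] == "w1"])
    with pytest.raises(ModelError):
        vel.fit_random_slope_model(dd[dd["year"] <= 2001])


def test_reml_matches_direct_optimization_oracle():
    dd, y, yc, gidx, _ = make_panel(seed=42)
    fit = vel.fit_random_slope_model(dd)
    oracle = fit_reml_oracle(y, yc, gidx)
    assert fit.fixed_slope_per_yr == pytest.approx(oracle["fixed_slope"], rel=1e-4)
    for key, got in [
        ("var_b0", fit.var_b0),
        ("var_b1", fit.var_b1),
        ("sigma2", fit.sigma2),
    ]:
        assert got == pytest.approx(oracle[key], rel=1e-4)
    # neither route found a higher REML objective than the other
    assert fit.criterion_value == pytest.approx(oracle["loglike"], abs=1e-4)


def test_velocities_are_fixed_plus_deviation():
    dd, *_ = make_panel(seed=3, n_groups=8, n_years=20)
    fit = vel.fit_random_slope_model(dd)
    w = pd.DataFrame(
        {
            "watershed_id": fit.random_effects["watershed_id"],
            "region": "r",
            "elevation_m": 1.0,
        }
    )
    total = vel.extract_velocities(fit, w, mode="total")["velocity"]
    devs = vel.extract_velocities(fit, w, mode="deviation")["velocity"]
    assert np.allclose(total, devs + fit.fixed_slope_per_yr)
    assert devs.mean() == pytest.approx(0.0, abs=1e-3)  # BLUPs average ~ 0
    assert total.mean() == pytest.approx(fit.fixed_slope_per_yr, abs=1e-3)


class TestPseudoR2:
    def test_collapses_without_random_variance(self):
        dd, *_ = make_panel(seed=5, n_groups=6, n_years=15)
        fit = vel.fit_random_slope_model(dd)
        fit.var_b0 = fit.var_b1 = fit.cov_b0b1 = 0.0
        r2m, r2c = vel.pseudo_r2(fit)
        assert r2m == pytest.approx(r2c)

    def test_tends_to_one_as_residual_vanishes(self):
        dd, *_ = make_panel(seed=6, n_groups=6, n_years=15)
        fit = vel.fit_random_slope_model(dd)
        fit.sigma2 = 0.0
        _, r2c = vel.pseudo_r2(fit)
        assert r2c == pytest.approx(1.0)

    def test_matches_known_variance_decomposition(self):
        # plug the simulation's latent draws into the same decomposition
        dd, y, yc, gidx, truth = make_panel(seed=42)
        fit = vel.fit_random_slope_model(dd)
        r2m, r2c = vel.pseudo_r2(fit)
        m_yc2 = np.mean(np.unique(yc) ** 2)
        var_f = truth["beta1"] ** 2 * np.var(np.unique(yc))
        var_r = truth["b0"].var() + truth["b1"].var() * m_yc2
        total = var_f + var_r + truth["eps"].var()
        assert r2m == pytest.approx(var_f / total, abs=0.05)
        assert r2c == pytest.approx((var_f + var_r) / total, abs=0.05)
        assert 0 <= r2m <= r2c <= 1


class TestCorrelationAndAnova:
    def test_perfect_anticorrelation(self):
        v = pd.DataFrame(
            {"velocity": [3.0, 2.0, 1.0], "elevation_m": [100.0, 200.0, 300.0]}
        )
        r, p = vel.velocity_elevation_correlation(v)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        v = pd.DataFrame({"velocity": [1.0, 1.0, 1.0], "elevation_m": [1.0, 2.0, 3.0]})
        with pytest.raises(DomainError):
            vel.velocity_elevation_correlation(v)

    def test_anova_hand_checked(self):
        v = pd.DataFrame(
            {
                "region": ["a"] * 3 + ["b"] * 3,
                "velocity": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )
        f, p = vel.compare_ranges_anova(v)
        assert f == pytest.approx(13.5, abs=1e-9)
        assert p == pytest.approx(stats.f.sf(13.5, 1, 4), abs=1e-12)
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_anova_identical_groups_give_zero_f(self):
        v = pd.DataFrame(
            {"region": ["a"] * 3 + ["b"] * 3, "velocity": [1.0, 2.0, 3.0] * 2}
        )
        f, _ = vel.compare_ranges_anova(v)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_anova_degenerate_rejected(self):
        v = pd.DataFrame({"region": ["a", "a", "b", "b"], "velocity": [1.0] * 4})
        with pytest.raises(DomainError):
            vel.compare_ranges_anova(v)


def test_log_base_leaves_correlation_and_anova_invariant(recovery_landscape):
    w, params, temps, truth, dd_tab = recovery_landscape
    half = {"r1a": dd_tab.iloc[: len(dd_tab) // 2], "r1b": dd_tab.iloc[len(dd_tab) // 2:]}
    results = {}
    for base in ("e", "10"):
        frames = []
        for region, part in half.items():
            fit = vel.fit_random_slope_model(part, region=region, log_base=base)
            v = vel.extract_velocities(fit, w)
            v["region"] = region
            frames.append(v)
        allv = pd.concat(frames, ignore_index=True)
        results[base] = (
            vel.velocity_elevation_correlation(allv)[0],
            vel.compare_ranges_anova(allv)[0],
        )
    assert results["e"][0] == pytest.approx(results["10"][0], rel=1e-4)
    assert results["e"][1] == pytest.approx(results["10"][1], rel=1e-3)


def test_gdd_and_temperature_velocities_rank_agree(recovery_landscape):
    w, params, temps, truth, dd_tab = recovery_landscape
    fit_g = vel.fit_random_slope_model(dd_tab)
    annual_t = (
        temps.groupby(["watershed_id", "year"])["tas_c"].mean().reset_index(name="mean_tas")
    )
    fit_t = vel.fit_random_slope_model(
        annual_t, transform="log_temp_plus10", response="mean_tas"
    )
    vg = vel.extract_velocities(fit_g, w).set_index("watershed_id")["velocity"]
    vt = vel.extract_velocities(fit_t, w).set_index("watershed_id")["velocity"]
    rho = stats.spearmanr(vg, vt.loc[vg.index]).statistic
    assert rho > 0.5
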