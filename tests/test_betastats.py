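import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marshcover.betastats import (
    fit_beta_glmm,
    fit_factor_model,
    method_comparison_report,
    pearson_r,
    simulate_beta_glmm,
    sv_inverse,
    sv_transform,
)


class TestSVTransform:
    def test_forced_boundary_values(self):
        assert sv_transform(0.0, 100) == pytest.approx(0.005)
        assert sv_transform(1.0, 100) == pytest.approx(0.995)

    def test_half_is_fixed_point(self):
        for n in (1, 2, 142, 10_000):
            assert sv_transform(0.5, n) == 0.5

    @settings(deadline=None, max_examples=200)
    @given(
        y=st.floats(min_value=0.0, max_value=1.0),
        n=st.integers(min_value=2, max_value=10**6),
    )
    def test_roundtrip_and_interior(self, y, n):
        yp = sv_transform(y, n)
        assert 0.0 < yp < 1.0
        assert sv_inverse(yp, n) == pytest.approx(y, abs=1e-12)

    def test_strictly_monotone_in_y(self):
        ys = np.linspace(0, 1, 101)
        yp = sv_transform(ys, 142)
        assert np.all(np.diff(yp) > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sv_transform(0.5, 0)
        with pytest.raises(ValueError):
            sv_transform(1.5, 10)


class TestFitBetaGLMM:
    def test_zero_variance_data_matches_plain_beta_regression(self):
        """With no cell effect in the data the fixed effects agree with a
        direct-ML beta regression (statsmodels BetaModel) to 1e-4."""
        from statsmodels.othermod.betareg import BetaModel

        y, X, cell = simulate_beta_glmm([0.3, 0.5, -0.6], sigma2=0.0, phi=30.0, n_cells=92, seed=8)
        fit = fit_beta_glmm(y, X, cell)
        sm_fit = BetaModel(y, X, exog_precision=np.ones((len(y), 1))).fit(disp=0)
        np.testing.assert_allclose(fit.beta, sm_fit.params[:3], atol=1e-4)
        assert fit.sigma2_cell < 1e-3

    def test_recovers_known_parameters(self):
        y, X, cell = simulate_beta_glmm([0.5, 0.3, -0.4], sigma2=0.7, phi=40.0, n_cells=92, seed=3)
        fit = fit_beta_glmm(y, X, cell)
        for est, se, truth in zip(fit.beta, fit.beta_se, [0.5, 0.3, -0.4]):
            assert abs(est - truth) < 3 * se
        assert 0.3 < fit.sigma2_cell < 1.5
        assert 20 < fit.phi < 80

    def test_likelihood_improves_from_start(self):
        y, X, cell = simulate_beta_glmm([0.2, 0.1, -0.1], sigma2=0.4, phi=25.0, n_cells=40, seed=5)
        fit = fit_beta_glmm(y, X, cell)
        assert fit.loglik >= fit.loglik_start

    def test_quadrature_refinement_stable(self):
        y, X, cell = simulate_beta_glmm([0.5, 0.3, -0.4], sigma2=0.7, phi=40.0, n_cells=92, seed=4)
        f15 = fit_beta_glmm(y, X, cell, quadrature_nodes=15)
        f30 = fit_beta_glmm(y, X, cell, quadrature_nodes=30)
        np.testing.assert_allclose(f15.beta, f30.beta, atol=1e-4)

    def test_denominator_df_matches_containment_rule(self):
        y, X, cell = simulate_beta_glmm([0.0, 0.0, 0.0], sigma2=0.5, phi=20.0, n_cells=92, seed=6)
        fit = fit_beta_glmm(y, X, cell)
        # 276 obs - 92 cells - 2 non-intercept effects = 182
        assert fit.wald_df == (2, 182)

    def test_boundary_responses_rejected(self):
        y = np.array([0.0, 0.5, 0.7])
        with pytest.raises(ValueError, match="sv_transform"):
            fit_beta_glmm(y, np.ones((3, 1)), np.array([0, 1, 2]))

    def test_agrees_with_glmmTMB(self, tmp_path):
        """Cross-engine check: an independent TMB-based beta GLMM fit on the
        same data gives the same fixed effects (to ~2-3 decimals), random
        variance and precision."""
        y, X, cell = simulate_beta_glmm([0.5, 0.3, -0.4], sigma2=0.7, phi=40.0, n_cells=92, seed=12)
        fit = fit_beta_glmm(y, X, cell)
        df = pd.DataFrame({"y": y, "level": X[:, 1] + 2 * X[:, 2], "cell": cell})
        csv = tmp_path / "dat.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv("{csv}")
            d$level <- factor(d$level)
            d$cell <- factor(d$cell)
            m <- glmmTMB(y ~ level + (1 | cell), family = beta_family(link="logit"), data = d)
            fe <- fixef(m)$cond
            vc <- VarCorr(m)$cond$cell[1,1]
            cat(fe[1], fe[2], fe[3], vc, sigma(m), sep=",")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.strip().split(",")]
        np.testing.assert_allclose(fit.beta, vals[:3], atol=5e-3)
        assert fit.sigma2_cell == pytest.approx(vals[3], rel=0.05)
        assert fit.phi == pytest.approx(vals[4], rel=0.05)


class TestPearson:
    def test_perfect_positive_and_negative(self, rng):
        x = rng.random(92)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x + 2) == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_r(np.ones(10), np.arange(10.0))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


def _cover_table_from_props(props_by_method, n_cells=30, n_by_method=None, altitudes=(75.0, 100.0, 120.0)):
    """Build a CellCoverTable where each method/altitude shares base per-cell
    proportions plus seeded noise."""
    rng = np.random.default_rng(0)
    rows = []
    base = rng.dirichlet([7.55, 0.35, 2.10], size=n_cells)
    for method, shift in props_by_method.items():
        alts = altitudes if method != "ground" else (np.nan,)
        for alt in alts:
            for cid in range(1, n_cells + 1):
                p = np.clip(base[cid - 1] + shift, 1e-4, None)
                p = p / p.sum()
                n = (n_by_method or {}).get(method, 142)
                for c in range(3):
                    rows.append(
                        {"plot_id": 1, "cell_id": cid, "method": method, "altitude_m": alt,
                         "class": c, "proportion": p[c], "n": n}
                    )
    return pd.DataFrame(rows)


class TestMethodComparison:
    def test_null_case_has_small_effects(self):
        table = _cover_table_from_props(
            {"ground": 0.0, "drone_pixels": 0.0, "drone_transects": 0.0}
        )
        report = method_comparison_report(table, altitudes=(75.0, 100.0, 120.0))
        method_tests = report["tests"][report["tests"]["family"] == "method"]
        # identical data for every method: F statistics are essentially zero
        assert (method_tests["F"] < 0.5).all()

    def test_report_row_counts(self):
        table = _cover_table_from_props(
            {"ground": 0.0, "drone_pixels": 0.01, "drone_transects": -0.01}
        )
        report = method_comparison_report(table)
        assert len(report["tests"]) == 3 * 3  # 3 model families x 3 cover types
        # each model: intercept + 2 effects + var(cell) = 4 coefficient rows
        assert len(report["coefficients"]) == 9 * 4
        assert len(report["estimates"]) == 9 * 3

    def test_missing_method_errors(self):
        table = _cover_table_from_props({"ground": 0.0, "drone_pixels": 0.0})
        with pytest.raises(ValueError, match="drone_transects"):
            method_comparison_report(table)

    def test_injected_nonshrub_deficit_gives_negative_drone_coefficients(self):
        """Drone methods that miss non-shrub cover show negative method
        coefficients for the non-shrub model (underestimation signature)."""
        deficit = np.array([0.03, -0.03, 0.0])
        table = _cover_table_from_props(
            {"ground": np.zeros(3), "drone_pixels": deficit, "drone_transects": deficit}
        )
        report = method_comparison_report(table)
        coefs = report["coefficients"]
        ns = coefs[(coefs["family"] == "method") & (coefs["class"] == "non-shrub")]
        for term in ("method=drone_pixels", "method=drone_transects"):
            assert ns[ns["term"] == term]["estimate"].iloc[0] < 0
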