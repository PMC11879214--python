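import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from espmod import (
    ESPMatrix,
    WindowCover,
    WindowEffectProfiler,
    build_esp_matrix,
    fit_window_effect,
    standardize_esp,
)
from espmod._glm import linear_slopes, logistic_fit, logistic_profile
from espmod.cover import CoverGeometry, Window, WindowGeometry
from conftest import make_table


def whole_data_cover(table):
    """A cover with a single window holding every observation."""
    cols = table.roles.continuous_covariates
    Z = table.data[list(cols)].to_numpy()
    span = Z.max(axis=0) - Z.min(axis=0)
    geom = WindowGeometry(
        sides=tuple(2 * s + 1.0 for s in span),
        steps=tuple(s + 1.0 for s in span),
        n_target=1,
    )
    center = tuple(Z.min(axis=0))
    w = Window(stratum=(), center=center, member_idx=np.arange(len(Z)))
    return CoverGeometry(
        geometry=geom, windows=[w], n_candidate=1,
        continuous_cols=cols, discrete_cols=(),
        z_min=tuple(Z.min(axis=0)), z_max=tuple(Z.max(axis=0)),
    )


class TestLinearEffects:
    def test_noiseless_linear_recovered_exactly(self):
        x = np.linspace(-1, 2, 12)
        y = 0.5 + 2.25 * x
        table = make_table(np.linspace(0, 1, 12), y=y, exposures=x[:, None])
        cover = whole_data_cover(table)
        es = fit_window_effect(table, cover, 0, "E1")
        assert es.raw == pytest.approx(2.25, abs=1e-12)

    def test_six_point_toy_slope(self):
        x = np.array([0.0, 1, 2, 3, 4, 5])
        y = np.array([0.0, 1, 1, 2, 3, 3])
        table = make_table(np.linspace(0, 1, 6), y=y, exposures=x[:, None])
        es = fit_window_effect(table, whole_data_cover(table), 0, "E1")
        # closed form: (n*Sxy - Sx*Sy) / (n*Sxx - Sx^2) = 66/105
        assert es.raw == pytest.approx(66.0 / 105.0)

    def test_ols_matches_statsmodels_with_confounders(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            n = rng.integers(15, 40)
            z = rng.uniform(0, 1, size=(n, 2))
            x = rng.normal(size=(n, 1))
            y = rng.normal(size=n)
            table = make_table(z, y=y, exposures=x)
            cover = whole_data_cover(table)
            es = fit_window_effect(table, cover, 0, "E1", confounders="covariates")
            D = sm.add_constant(np.column_stack([x, z]))
            ref = sm.OLS(y, D).fit().params[1]
            assert es.raw == pytest.approx(ref, abs=1e-8)

    def test_vectorised_slopes_match_per_column_fits(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        slopes = linear_slopes(y, X)
        for m in range(6):
            ref = sm.OLS(y, sm.add_constant(X[:, m])).fit().params[1]
            assert slopes[m] == pytest.approx(ref, abs=1e-10)


class TestLogisticEffects:
    def test_null_odds_ratio_near_one(self):
        rng = np.random.default_rng(8)
        n = 4000
        y = np.repeat([0.0, 1.0], n // 2)
        x = rng.normal(size=(n, 1))
        table = make_table(rng.uniform(0, 1, n), y=y, exposures=x, outcome_family="binary")
        es = fit_window_effect(table, whole_data_cover(table), 0, "E1")
        assert es.raw == pytest.approx(1.0, abs=0.15)

    def test_matches_statsmodels_mle_when_unpenalized(self):
        rng = np.random.default_rng(3)
        n = 60
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
        b0, b1, ok = logistic_profile(y, x[:, None], ridge=0.0)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0).params
        assert ok[0]
        assert b0[0] == pytest.approx(ref[0], abs=1e-6)
        assert b1[0] == pytest.approx(ref[1], abs=1e-6)

    def test_general_fit_matches_statsmodels_with_confounder(self):
        rng = np.random.default_rng(4)
        n = 80
        x = rng.normal(size=n)
        z = rng.uniform(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * x + z - 0.5)))).astype(float)
        D = np.column_stack([np.ones(n), x, z])
        beta, ok = logistic_fit(y, D, ridge=0.0)
        ref = sm.Logit(y, D).fit(disp=0).params
        assert ok
        np.testing.assert_allclose(beta, ref, atol=1e-6)

    def test_separation_is_tamed(self):
        # perfectly separating exposure: penalized slope must stay finite
        y = np.repeat([0.0, 1.0], 10)
        x = np.concatenate([np.linspace(-2, -1, 10), np.linspace(1, 2, 10)])
        b0, b1, ok = logistic_profile(y, x[:, None], ridge=1.0)
        assert np.isfinite(b1[0]) and abs(b1[0]) < 10

    def test_log_odds_null_calibration(self):
        """Without exposure-outcome association the log odds ratios over many
        windows are centred at zero."""
        rng = np.random.default_rng(77)
        vals = []
        for _ in range(400):
            n = 30
            y = np.repeat([0.0, 1.0], n // 2)
            x = rng.normal(size=(n, 1))
            _, b1, _ = logistic_profile(y, x, ridge=1.0)
            vals.append(b1[0])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se


class TestESPMatrix:
    def _binary_table(self, n=200, m=4, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.uniform(0, 1, size=(n, 2))
        y = np.repeat([0.0, 1.0], n // 2)
        x = rng.normal(2.0, 0.5, size=(n, m))
        return make_table(z, y=y, exposures=x, outcome_family="binary")

    def test_single_window_equals_global_profile(self):
        table = self._binary_table()
        cover = whole_data_cover(table)
        esp = build_esp_matrix(cover, table)
        assert esp.raw.shape == (1, 4)
        es = fit_window_effect(table, cover, 0, "E2")
        assert esp.raw.iloc[0]["E2"] == pytest.approx(es.raw)

    def test_rows_align_with_windows(self):
        table = self._binary_table()
        cover = WindowCover(n_target=30, min_class_count=5).fit(table).cover_
        esp = build_esp_matrix(cover, table)
        assert esp.raw.shape == (cover.n_retained, 4)

    def test_exposure_permutation_permutes_columns_only(self):
        table = self._binary_table()
        cover = WindowCover(n_target=30, min_class_count=5).fit(table).cover_
        esp = build_esp_matrix(cover, table)
        perm_roles = table.roles.to_dict()
        perm_roles["exposure_cols"] = ["E3", "E1", "E4", "E2"]
        from espmod import ColumnRoles, ObservationTable
        table2 = ObservationTable(table.data, ColumnRoles.from_dict(perm_roles))
        esp2 = build_esp_matrix(cover, table2)
        pd.testing.assert_frame_equal(esp2.raw, esp.raw[["E3", "E1", "E4", "E2"]])

    def test_standardize_column_contract(self):
        table = self._binary_table(seed=2)
        cover = WindowCover(n_target=30, min_class_count=5).fit(table).cover_
        esp = standardize_esp(build_esp_matrix(cover, table))
        X = esp.values()
        assert np.abs(X.mean(axis=0)).max() < 1e-10
        assert np.abs(X.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_standardize_simple_column_and_idempotence(self):
        raw = pd.DataFrame({"E1": [1.0, 2.0, 3.0], "E2": [5.0, 5.0, 5.0]})
        esp = standardize_esp(ESPMatrix(raw=raw))
        np.testing.assert_allclose(esp.standardized["E1"], [-1.0, 0.0, 1.0])
        assert esp.dropped_exposures == ["E2"]
        again = standardize_esp(ESPMatrix(raw=esp.standardized))
        np.testing.assert_allclose(again.standardized.to_numpy(),
                                   esp.standardized.to_numpy(), atol=1e-12)

    def test_profiler_log_odds_scale(self):
        table = self._binary_table(seed=3)
        cover = WindowCover(n_target=40, min_class_count=5).fit(table).cover_
        prof_or = WindowEffectProfiler(log_odds=False).fit(table, cover)
        prof_log = WindowEffectProfiler(log_odds=True).fit(table, cover)
        np.testing.assert_allclose(
            np.log(prof_or.esp_.raw.to_numpy()),
            prof_log.esp_.raw.to_numpy(),
            atol=1e-12,
        )
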