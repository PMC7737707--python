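"""Robust control-ellipsoid fitting, Mahalanobis scoring, contribution
ranking, outlier flagging and well/plate aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenoscreen.plates import (
    PlateLayout,
    ScreenAnnotation,
    WellAddress,
    WellAssignment,
    build_screen_layout,
)
from phenoscreen.scoring import (
    ControlModel,
    ControlModelResults,
    fit_control_model,
    score_plate,
    score_well,
)
from phenoscreen.simulate import (
    ATTRIBUTE_NAMES,
    simulate_dose_response_plate,
)
from conftest import random_correlated_instance


def unit_model(p: int, sigmas=None) -> ControlModelResults:
    """A hand-built diagonal control model with known center/variances."""
    sigmas = np.ones(p) if sigmas is None else np.asarray(sigmas, float)
    return ControlModelResults(
        model=None,
        attribute_names=[f"a{i}" for i in range(p)],
        center=np.zeros(p),
        axes=np.eye(p),
        variances=sigmas**2,
        retained=p,
        trim_quantile=0.975,
        trim_iterations=0,
        trim_history=[],
        n_used=0,
        n_trimmed=0,
    )


class TestRobustFit:
    def test_clean_normal_trims_at_most_twice_the_tail(self):
        rng = np.random.default_rng(0)
        X, _, _ = random_correlated_instance(rng, 2000, 2)
        res = fit_control_model(X, trim_quantile=0.975)
        assert res.n_trimmed / 2000 <= 2 * (1 - 0.975)

    def test_gross_outliers_trimmed_and_center_recovered(self):
        rng = np.random.default_rng(1)
        p, n = 4, 2000
        X, mean, cov = random_correlated_instance(rng, n, p)
        sd = np.sqrt(np.diag(cov))
        n_out = int(0.05 * n)
        outliers = mean + 20 * sd * np.sign(rng.standard_normal((n_out, p)))
        data = np.vstack([X, outliers])
        res = fit_control_model(data)
        d2 = res.squared_mahalanobis(outliers)
        assert np.all(d2 > stats.chi2.ppf(0.975, res.retained))  # all planted trimmed
        assert res.n_trimmed >= n_out
        assert np.all(np.abs(res.center - mean) < 0.1 * sd)

    def test_rank_deficiency_reduces_retained(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((500, 3))
        X = np.column_stack([X, 2.0 * X[:, 0]])  # perfectly correlated pair
        res = fit_control_model(X)
        assert res.retained == 3

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError, match="more control cells"):
            fit_control_model(np.random.default_rng(0).standard_normal((5, 8)))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_control_model(np.ones((50, 3)))

    def test_trim_history_recorded(self, control_model):
        assert control_model.trim_iterations == len(control_model.trim_history)
        assert control_model.n_used + control_model.n_trimmed == 3000


class TestMahalanobisDistance:
    def test_center_scores_zero(self, control_model):
        assert control_model.mahalanobis(control_model.center) == pytest.approx(0.0)

    def test_one_attribute_two_sigma(self):
        m = unit_model(1, sigmas=[3.0])
        assert m.mahalanobis([6.0]) == pytest.approx(2.0)

    def test_pca_route_equals_direct_inverse_covariance(self):
        """Oracle equivalence on 100 random full-rank 8-attribute instances."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            X, _, _ = random_correlated_instance(rng, 400, 8)
            res = ControlModel(X, max_iter=1).fit()  # untrimmed moments
            mu, cov = X.mean(0), np.cov(X, rowvar=False, ddof=1)
            Y = rng.standard_normal((20, 8)) * 3
            direct = np.sqrt(np.einsum("ij,jk,ik->i", Y - mu, np.linalg.inv(cov), Y - mu))
            rel = np.max(np.abs(res.mahalanobis(Y) - direct) / direct)
            worst = max(worst, rel)
        assert worst < 1e-8

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        X, _, _ = random_correlated_instance(rng, 1000, 5)
        Y = rng.standard_normal((50, 5)) * 2
        res = fit_control_model(X)
        scale = np.array([1000.0, 1.0, 1.0, 0.001, 1.0])
        res_scaled = fit_control_model(X * scale)
        if res.retained == 5 and res_scaled.retained == 5:
            d1, d2 = res.mahalanobis(Y), res_scaled.mahalanobis(Y * scale)
            assert np.max(np.abs(d1 - d2) / d1) < 1e-8

    def test_attribute_mismatch_rejected(self, control_model):
        bad = pd.DataFrame({"not_an_attribute": [1.0]})
        with pytest.raises(ValueError, match="lack"):
            control_model.mahalanobis(bad)

    def test_null_squared_distances_follow_chi_square(self, feature_spec, control_model):
        from phenoscreen.simulate import simulate_control_population

        fresh = simulate_control_population(feature_spec, 5000, seed=77)
        d2 = control_model.squared_mahalanobis(fresh)
        ks = stats.kstest(d2, "chi2", args=(control_model.retained,))
        assert ks.pvalue > 0.01


class TestContributions:
    def test_diagonal_model_gives_z_square_shares(self):
        m = unit_model(4, sigmas=[1.0, 2.0, 0.5, 1.0])
        x = np.array([1.0, 4.0, -1.0, 0.0])
        z = x / np.array([1.0, 2.0, 0.5, 1.0])
        expected = z**2 / np.sum(z**2)
        assert m.contributions(x).to_numpy() == pytest.approx(expected)

    def test_contributions_sum_to_one(self, control_model):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = control_model.center * (1 + 0.1 * rng.standard_normal(16))
            c = control_model.contributions(x)
            assert c.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_distance_rejected(self, control_model):
        with pytest.raises(ValueError, match="zero distance"):
            control_model.contributions(control_model.center)

    def test_planted_four_sigma_attribute_ranks_first(self):
        """A 4-sigma shift on one attribute of an uncorrelated model should
        top the contribution ranking in >= 95% of noisy trials."""
        rng = np.random.default_rng(123)
        p, n_trials = 8, 200
        X = rng.standard_normal((3000, p))
        res = fit_control_model(X)
        hits = 0
        for _ in range(n_trials):
            x = rng.standard_normal(p)
            x[3] += 4.0
            top = res.rank_contributions(x).loc[0, "attribute"]
            if top == res.attribute_names[3]:
                hits += 1
        assert hits / n_trials >= 0.95


class TestOutlierFlags:
    def test_null_flag_rate_near_tail_mass(self, feature_spec, control_model):
        from phenoscreen.simulate import simulate_control_population

        fresh = simulate_control_population(feature_spec, 5000, seed=88)
        rate = control_model.flag_outliers(fresh, quantile=0.999).mean()
        assert abs(rate - 0.001) < 0.002

    def test_center_never_flagged(self, control_model):
        assert not control_model.flag_outliers([control_model.center])[0]

    def test_far_artifact_flagged(self, control_model):
        artifact = control_model.center + 50 * np.sqrt(
            np.diag(control_model.axes @ np.diag(control_model.variances) @ control_model.axes.T)
        )
        assert control_model.flag_outliers([artifact])[0]


class TestWellAggregation:
    def test_median_of_distances(self):
        m = unit_model(1)
        ws = score_well(np.array([[1.0], [2.0], [3.0]]), m)
        assert ws.score == pytest.approx(2.0)
        assert ws.n_cells == 3

    def test_outlier_excluded_from_median(self):
        m = unit_model(1)
        ws = score_well(np.array([[1.0], [2.0], [3.0], [100.0]]), m)
        assert ws.score == pytest.approx(2.0)
        assert ws.n_outliers == 1

    def test_empty_well_flagged(self):
        m = unit_model(1)
        ws = score_well(np.empty((0, 1)), m)
        assert ws.empty and np.isnan(ws.score)

    def test_null_well_score_near_chi_median(self, feature_spec, control_model):
        from phenoscreen.simulate import simulate_control_population

        fresh = simulate_control_population(feature_spec, 2000, seed=99)
        ws = score_well(fresh, control_model)
        expected = np.sqrt(stats.chi2.ppf(0.5, control_model.retained))
        assert ws.score == pytest.approx(expected, rel=0.1)


def _control_only_layout(n_wells: int) -> PlateLayout:
    layout = PlateLayout("nullplate")
    for i in range(n_wells):
        layout.assign(
            WellAddress("ABCDEFGHIJKLMNOP"[i // 24], i % 24 + 1),
            WellAssignment("control", replicate_group="control"),
        )
    return layout


class TestPlateScoring:
    def test_all_control_plate_specificity(self, feature_spec):
        """No well of a pure-control plate should clear the 0.999 null
        quantile of the well-score distribution (checked over 12 plates)."""
        n_wells, cells = 12, 120
        layout = _control_only_layout(n_wells)
        # null quantile of a median of `cells` chi draws, via simulation
        rng = np.random.default_rng(2024)
        exceedances = 0
        total = 0
        for rep in range(12):
            records, _ = simulate_dose_response_plate(
                feature_spec, layout, cells_per_well=cells, seed=3000 + rep
            )
            well_scores, model = score_plate(records, layout)
            d = model.retained
            null_medians = np.median(
                np.sqrt(rng.chisquare(d, size=(2000, cells))), axis=1
            )
            threshold = np.quantile(null_medians, 0.999)
            exceedances += int((well_scores["score"] > threshold).sum() > 0)
            total += 1
        assert exceedances / total <= 0.05 or exceedances <= 1

    def test_planted_saturating_row_tops_the_plate(self, feature_spec):
        layout = PlateLayout("planted")
        saturating = 300 * feature_spec.dm_true
        for col in range(1, 11):
            layout.assign(
                WellAddress("A", col),
                WellAssignment("treated", ("hit",), (saturating,), f"hit|{col}"),
            )
        for col in range(1, 9):
            layout.assign(
                WellAddress("P", col), WellAssignment("control", replicate_group="control")
            )
        records, _ = simulate_dose_response_plate(
            feature_spec, layout, cells_per_well=150, seed=55
        )
        well_scores, _ = score_plate(records, layout)
        treated = well_scores[well_scores["role"] == "treated"]
        controls = well_scores[well_scores["role"] == "control"]
        top = well_scores.nlargest(len(treated), "score")
        assert set(top["well"]) == set(treated["well"])
        assert treated["score"].min() > controls["score"].max()

    def test_duplicate_wells_score_alike(self, feature_spec):
        layout = build_screen_layout(
            [ScreenAnnotation("d", gi50=feature_spec.dm_true / 10.0)],
            n_levels=3, duplicates=2,
            control_wells=[WellAddress("P", c) for c in range(1, 7)],
        )
        records, _ = simulate_dose_response_plate(
            feature_spec, layout, cells_per_well=400, seed=66
        )
        well_scores, _ = score_plate(records, layout)
        for _, grp in well_scores[well_scores["role"] == "treated"].groupby(
            "replicate_group"
        ):
            a, b = grp["score"].to_numpy()
            assert abs(a - b) / max(a, b) < 0.25  # within simulation noise

    def test_missing_controls_rejected(self, feature_spec):
        layout = PlateLayout("p")
        layout.assign(
            WellAddress("A", 1), WellAssignment("treated", ("d",), (1e-6,), "g")
        )
        with pytest.raises(ValueError, match="control"):
            score_plate(pd.DataFrame({"well": ["A01"], "x": [1.0]}), layout)

    def test_model_json_round_trip(self, control_model, tmp_path):
        path = tmp_path / "model.json"
        control_model.to_json(path)
        back = ControlModelResults.from_json(path)
        x = control_model.center + np.sqrt(
            np.diag(control_model.axes @ np.diag(control_model.variances)
                    @ control_model.axes.T)
        )
        assert back.mahalanobis(x) == pytest.approx(control_model.mahalanobis(x))
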