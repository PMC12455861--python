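import logging

import numpy as np
import pandas as pd
import pytest

from cordlesion.phantoms import CohortSpec, PhantomConfig, make_cohort
from cordlesion.stats_models import (
    StatsError,
    build_lateralized_table,
    compare_groups,
    fit_cross_sectional,
    fit_lateralized_prediction,
    fit_longitudinal,
)

logging.disable(logging.WARNING)


def _simple_longitudinal(n_patients=8, slope=-2.0, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        a = rng.normal(100, 10)
        for tp, t in (("baseline", 0.65), ("month1", 1.78), ("month6", 6.32)):
            rows.append(
                dict(
                    patient_id=f"P{i}",
                    timepoint=tp,
                    months_post_injury=t,
                    y=a + slope * t + rng.normal(0, noise_sd),
                    age=rng.normal(45, 10),
                    sex=rng.choice(["M", "F"]),
                    center=rng.choice(["A", "B"]),
                )
            )
    return pd.DataFrame(rows)


class TestLongitudinal:
    def test_noiseless_slope_recovered_exactly(self):
        table = _simple_longitudinal(slope=-2.0, noise_sd=0.0)
        res = fit_longitudinal(table, "y")
        assert res.coef == pytest.approx(-2.0, abs=1e-6)
        lo, hi = res.ci95_raw
        assert lo <= -2.0 <= hi
        assert res.r2_conditional == pytest.approx(1.0, abs=1e-6)

    def test_time_constant_outcome_slope_zero(self):
        table = _simple_longitudinal(slope=0.0, noise_sd=0.0)
        res = fit_longitudinal(table, "y")
        assert res.coef == pytest.approx(0.0, abs=1e-6)
        lo, hi = res.ci95_raw
        assert lo <= 0.0 <= hi

    def test_conditional_at_least_marginal(self):
        for seed in range(5):
            cohort, _ = make_cohort(PhantomConfig(seed=seed))
            res = fit_longitudinal(cohort, "lesion_volume_mm3")
            assert res.r2_conditional >= res.r2_marginal - 1e-12
            assert 0.0 <= res.r2_marginal <= 1.0

    def test_standardization_invariance(self):
        """Rescaling predictor and outcome leaves the standardized
        coefficient unchanged (refit on rescaled data)."""
        table = _simple_longitudinal(slope=-2.0, noise_sd=3.0, seed=4)
        res = fit_longitudinal(table, "y")
        rescaled = table.copy()
        rescaled["y"] = 10.0 * rescaled["y"] + 5.0
        rescaled["months_post_injury"] = rescaled["months_post_injury"] * 4.0
        # months appear in both the model and as data; refit on the rescaled frame
        res2 = fit_longitudinal(rescaled, "y")
        assert res2.coef_standardized == pytest.approx(res.coef_standardized, rel=1e-6)

    def test_too_few_patients(self):
        table = _simple_longitudinal(n_patients=2)
        with pytest.raises(StatsError):
            fit_longitudinal(table, "y")


class TestLateralized:
    def test_noiseless_linear_relation(self):
        spec = CohortSpec(
            delta_noise_scale=0.0,
            delta_patient_var=0.0,
            score_noise_sd=0.0,
            score_baseline_sd=0.0,  # keep scores clear of the 0/50 bounds
            damage_noise_sd=0.0,
            round_scores=False,
        )
        cohort, truth = make_cohort(PhantomConfig(seed=5, cohort=spec))
        lat = build_lateralized_table(cohort, "motor_damage", "motor")
        res = fit_lateralized_prediction(lat)
        # delta is an exact linear function of damage: the fitted raw slope
        # equals the generator's, and conditional R^2 is 1
        sd_dmg = np.sqrt(spec.motor_damage_sd**2 + spec.side_asymmetry_sd**2 + spec.damage_noise_sd**2)
        expected_raw = spec.beta_motor * spec.delta_sd_motor / sd_dmg
        assert res.coef == pytest.approx(expected_raw, abs=1e-8)
        assert res.coef_standardized == pytest.approx(-1.0, abs=1e-8)
        assert res.r2_conditional == pytest.approx(1.0, abs=1e-6)

    def test_sign_recovered_under_noise(self):
        negatives = 0
        for seed in range(20):
            cohort, _ = make_cohort(PhantomConfig(seed=900 + seed))
            lat = build_lateralized_table(cohort, "motor_damage", "motor")
            res = fit_lateralized_prediction(lat)
            negatives += res.coef_standardized < 0
        assert negatives >= 18

    def test_too_few_complete_patients(self):
        lat = pd.DataFrame(
            dict(
                patient_id=["P1", "P1", "P2"],
                side=["left", "right", "left"],
                damage=[50.0, 60.0, 70.0],
                delta=[5.0, 3.0, 1.0],
                age=[40.0] * 3,
                sex=["M"] * 3,
                center=["A"] * 3,
            )
        )
        with pytest.raises(StatsError):
            fit_lateralized_prediction(lat)


class TestCrossSectional:
    def _table(self, n=30, beta=-0.5, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(60, 15, n)
        y = 40 + beta * x + rng.normal(0, noise_sd, n)
        return pd.DataFrame(
            dict(
                patient_id=[f"P{i}" for i in range(n)],
                x=x,
                y=y,
                age=rng.normal(45, 12, n),
                sex=rng.choice(["M", "F"], n),
                center=rng.choice(["A", "B", "C"], n),
            )
        )

    def test_noiseless_relation(self):
        table = self._table(noise_sd=0.0)
        res = fit_cross_sectional(table, "x", "y")
        assert res.coef == pytest.approx(-0.5, abs=1e-9)
        assert res.coef_standardized == pytest.approx(-1.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_permuted_predictor_ci_covers_zero(self):
        rng = np.random.default_rng(77)
        covers = 0
        table = self._table(noise_sd=5.0, seed=1)
        for _ in range(100):
            perm = table.copy()
            perm["x"] = rng.permutation(perm["x"].to_numpy())
            res = fit_cross_sectional(perm, "x", "y")
            lo, hi = res.ci95_raw
            covers += lo <= 0.0 <= hi
        assert covers >= 90

    def test_duplicate_patient_row_rejected(self):
        table = self._table(n=10)
        dup = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(StatsError, match="duplicate"):
            fit_cross_sectional(dup, "x", "y")


class TestCompareGroups:
    def test_identical_large_groups_p_near_one(self):
        a = np.concatenate([np.linspace(-3, 3, 500)])
        res = compare_groups(a, a.copy())
        assert res.p_value > 0.99

    def test_separated_groups(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 40)
        b = rng.normal(10, 1, 40)
        assert compare_groups(a, b).p_value < 1e-6

    def test_type1_error_calibration(self):
        rng = np.random.default_rng(12)
        rejections = 0
        for _ in range(1000):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 1.5, 25)
            if compare_groups(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_tiny_group_rejected(self):
        with pytest.raises(StatsError):
            compare_groups([1.0], [2.0, 3.0])
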