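import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from czbkit import biochem, synthetic
from czbkit.biochem import (
    FitError,
    fit_hill,
    fit_linear_inhibition,
    fit_two_state,
    half_maximal_ligand,
    hill_response,
    paired_t,
    relative_biofilm,
    tight_binding_y,
)


def equilibrium_oracle(L0, K_D, y_min, y_max):
    """Independent bisection solve of the underlying binding equilibrium."""
    B = y_max - y_min
    if B == 0 or L0 == 0:
        return y_min
    f = lambda b: (B - b) * (L0 - b) - K_D * b
    bound = brentq(f, 0.0, min(B, L0), xtol=1e-15, rtol=1e-15)
    return y_min + bound


class TestHillResponse:
    def test_half_maximal_at_k(self):
        assert hill_response(122.0, 122.0, 2, 1.0) == pytest.approx(0.5)

    def test_zero_dose(self):
        assert hill_response(0.0, 122.0, 2, 1.0) == 0.0

    def test_saturation(self):
        assert hill_response(1e9, 122.0, 2, 3.0) == pytest.approx(3.0, rel=1e-6)

    def test_sigmoid_single_inflection(self):
        # with n=2 the second derivative changes sign exactly once on (0, inf)
        L = np.linspace(1e-3, 1000, 20000)
        y = hill_response(L, 122.0, 2, 1.0)
        d2 = np.diff(y, 2)
        signs = np.sign(d2[np.abs(d2) > 1e-15])
        changes = np.count_nonzero(np.diff(signs))
        assert changes == 1

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            hill_response(1.0, 0.0)


class TestFitHill:
    DOSES = [0, 25, 50, 100, 150, 250, 400, 500]

    def test_noiseless_round_trip(self):
        ds = synthetic.gen_dose_response(
            "hill", dict(K_half=122.0, n=2.0, A=1.0), self.DOSES,
            reps=3, noise_sd=0.0, seed=0,
        )
        fit = fit_hill(ds)
        assert fit.K_half == pytest.approx(122.0, abs=1e-6)
        assert fit.A == pytest.approx(1.0, abs=1e-8)
        assert fit.n == 2.0

    def test_monte_carlo_recovery(self):
        errors = []
        for i in range(100):
            ds = synthetic.gen_dose_response(
                "hill", dict(K_half=122.0, n=2.0, A=1.0), self.DOSES,
                reps=3, noise_sd=0.05, seed=1000 + i,
            )
            fit = fit_hill(ds)
            errors.append(abs(fit.K_half - 122.0) / 122.0)
        assert np.median(errors) < 0.05

    def test_rising_limb_cutoff_applied(self):
        # doses above max_dose (overoxidation regime) are excluded
        doses = [0, 50, 100, 200, 400, 500, 750, 1000]
        ds = synthetic.gen_dose_response(
            "hill", dict(K_half=122.0, n=2.0, A=1.0), doses,
            reps=1, noise_sd=0.0, seed=0,
        )
        # corrupt the above-cutoff responses downward (overoxidation)
        ds.response[-2:] = 0.05
        fit = fit_hill(ds, max_dose=500.0)
        assert fit.K_half == pytest.approx(122.0, abs=1e-6)

    def test_unit_rescaling_invariance(self):
        ds = synthetic.gen_dose_response(
            "hill", dict(K_half=122.0, n=2.0, A=1.0), self.DOSES,
            reps=2, noise_sd=0.05, seed=9,
        )
        fit_uM = fit_hill(ds)
        ds_mM = synthetic.DoseResponseDataset(
            ds.dose / 1000.0, ds.response, label="mM"
        )
        fit_mM = fit_hill(ds_mM, max_dose=0.5)
        assert fit_mM.K_half * 1000.0 == pytest.approx(fit_uM.K_half, rel=1e-4)

    def test_too_few_doses(self):
        ds = synthetic.gen_dose_response(
            "hill", dict(K_half=10.0), [0, 5, 600, 700], reps=1,
            noise_sd=0.0, seed=0,
        )
        with pytest.raises(FitError):
            fit_hill(ds, max_dose=500.0)


class TestTightBinding:
    def test_zero_ligand_gives_ymin(self):
        assert tight_binding_y(0.0, 1.0, 2.0, 8.0) == pytest.approx(2.0)

    def test_saturation_to_ymax(self):
        K_D = 0.5
        y = tight_binding_y(1e6 * K_D, K_D, 0.0, 1e-2)
        assert abs(y - 1e-2) < 1e-3 * 1e-2

    def test_equilibrium_oracle_grid(self):
        for K_D in np.logspace(-2, 2, 10):
            for L0 in np.logspace(-2, 3, 10):
                for dy_max in np.logspace(-2, 2, 10):
                    got = tight_binding_y(L0, K_D, 1.0, 1.0 + dy_max)
                    want = equilibrium_oracle(L0, K_D, 1.0, 1.0 + dy_max)
                    assert abs(got - want) < 1e-9

    def test_monotone_in_L0_and_parameters(self):
        L = np.linspace(0, 100, 200)
        y = tight_binding_y(L, 5.0, 0.0, 10.0)
        assert np.all(np.diff(y) > 0)
        # decreasing in K_D
        y_lo = tight_binding_y(10.0, 1.0, 0.0, 10.0)
        y_hi = tight_binding_y(10.0, 10.0, 0.0, 10.0)
        assert y_lo > y_hi
        # increasing in dy_max
        assert tight_binding_y(10.0, 5.0, 0.0, 20.0) > tight_binding_y(
            10.0, 5.0, 0.0, 10.0
        )

    def test_bounds(self):
        y = tight_binding_y(50.0, 2.0, 1.0, 9.0)
        assert 1.0 <= y <= 9.0

    @given(
        st.floats(0.01, 1e3), st.floats(0.01, 1e2),
        st.floats(0.0, 10.0), st.floats(0.0, 100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_property_oracle_agreement(self, L0, K_D, y_min, dy):
        got = tight_binding_y(L0, K_D, y_min, y_min + dy)
        want = equilibrium_oracle(L0, K_D, y_min, y_min + dy)
        assert abs(got - want) < 1e-8 * max(1.0, dy)


class TestFitTwoState:
    DOSES = [0, 0.5, 1, 2, 4, 8, 16, 32]

    def test_noiseless_round_trip(self):
        ds = synthetic.gen_dose_response(
            "twostate", dict(K_D=3.0, y_min=1.0, y_max=9.0), self.DOSES,
            reps=2, noise_sd=0.0, seed=0,
        )
        fit = fit_two_state(ds)
        assert fit.K_D == pytest.approx(3.0, rel=1e-6)
        assert fit.y_min == pytest.approx(1.0, rel=1e-6)
        assert fit.y_max == pytest.approx(9.0, rel=1e-6)

    def test_half_max_matches_numeric_inversion(self):
        fitted = half_maximal_ligand(3.0, 1.0, 9.0)
        y = tight_binding_y(fitted, 3.0, 1.0, 9.0)
        assert y == pytest.approx(5.0, abs=1e-9)

    def test_kd_ratio_monte_carlo(self):
        ratios = []
        for i in range(30):
            wt = synthetic.gen_dose_response(
                "twostate", dict(K_D=2.0, y_min=0.5, y_max=10.0),
                [0, 0.5, 1, 2, 4, 8, 20, 50], reps=3, noise_sd=0.05,
                seed=2000 + i,
            )
            mut = synthetic.gen_dose_response(
                "twostate", dict(K_D=20.0, y_min=0.5, y_max=10.0),
                [0, 2, 5, 10, 20, 40, 100, 250], reps=3, noise_sd=0.05,
                seed=3000 + i,
            )
            f_wt, f_mut = fit_two_state(wt), fit_two_state(mut)
            ratios.append(f_mut.half_max_L / f_wt.half_max_L)
        truth = half_maximal_ligand(20.0, 0.5, 10.0) / half_maximal_ligand(
            2.0, 0.5, 10.0
        )
        assert np.median(ratios) == pytest.approx(truth, rel=0.05)

    def test_monte_carlo_kd_recovery(self):
        errors = []
        for i in range(100):
            ds = synthetic.gen_dose_response(
                "twostate", dict(K_D=5.0, y_min=1.0, y_max=9.0),
                [0, 1, 2, 4, 8, 16, 40, 100], reps=12, noise_sd=0.05,
                seed=4000 + i,
            )
            errors.append(abs(fit_two_state(ds).K_D - 5.0) / 5.0)
        assert np.median(errors) < 0.05


class TestLinearInhibition:
    def test_exact_line(self):
        ds = synthetic.gen_dose_response(
            "linear", dict(intercept=10.0, slope=-2.0), [0, 1, 2, 3, 4],
            reps=1, noise_sd=0.0, seed=0,
        )
        fit = fit_linear_inhibition(ds)
        assert fit.intercept == pytest.approx(10.0)
        assert fit.slope == pytest.approx(-2.0)
        assert fit.x_zero == pytest.approx(5.0)

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(43)
        dose = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        resp = 7.0 - 0.5 * dose + rng.normal(0, 0.1, size=5)
        ds = synthetic.DoseResponseDataset(dose, resp[:, None], label="x")
        fit = fit_linear_inhibition(ds)
        # closed-form least squares
        X = np.column_stack([np.ones(5), dose])
        beta = np.linalg.solve(X.T @ X, X.T @ resp)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-9)
        assert fit.slope == pytest.approx(beta[1], rel=1e-9)

    def test_constant_data_warns(self):
        ds = synthetic.DoseResponseDataset(
            [0.0, 1.0, 2.0], np.array([[5.0], [5.0], [5.0]])
        )
        with pytest.warns(UserWarning):
            fit = fit_linear_inhibition(ds)
        assert fit.slope == pytest.approx(0.0)
        assert np.isnan(fit.x_zero)

    def test_truncation_beyond_x_zero(self):
        # points past depletion stay at ~0 instead of going negative
        dose = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        resp = np.maximum(10.0 - 2.0 * dose, 0.0)
        ds = synthetic.DoseResponseDataset(dose, resp[:, None])
        fit = fit_linear_inhibition(ds)
        assert fit.slope == pytest.approx(-2.0)
        assert fit.x_zero == pytest.approx(5.0)


class TestRelativeBiofilm:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["experiment", "strain", "treatment", "dose", "a562"]
        )

    def test_untreated_wt_averages_to_one(self):
        t = self._table([
            ("e1", "WT", "untreated", 0.0, 0.9),
            ("e1", "WT", "untreated", 0.0, 1.1),
        ])
        out = relative_biofilm(t)
        np.testing.assert_allclose(out["relative_biofilm"], [0.9, 1.1])
        assert out["relative_biofilm"].mean() == pytest.approx(1.0)

    def test_sample_ratio(self):
        t = self._table([
            ("e1", "WT", "untreated", 0.0, 0.5),
            ("e1", "WT", "HOCl", 250.0, 0.8),
        ])
        out = relative_biofilm(t)
        assert out.loc[1, "relative_biofilm"] == pytest.approx(1.6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(47)
        rows = [("e1", "WT", "untreated", 0.0, v) for v in rng.uniform(0.5, 1.5, 4)]
        rows += [("e1", "WT", "HOCl", d, v)
                 for d, v in zip([5, 50, 250], rng.uniform(0.5, 2.0, 3))]
        t = self._table(rows)
        base = relative_biofilm(t)["relative_biofilm"]
        t2 = t.copy()
        t2["a562"] *= 7.3
        scaled = relative_biofilm(t2)["relative_biofilm"]
        np.testing.assert_allclose(base, scaled)

    def test_per_experiment_reference(self):
        t = self._table([
            ("e1", "WT", "untreated", 0.0, 1.0),
            ("e1", "dgcZ", "HOCl", 250.0, 2.0),
            ("e2", "WT", "untreated", 0.0, 4.0),
            ("e2", "dgcZ", "HOCl", 250.0, 2.0),
        ])
        out = relative_biofilm(t)
        assert out.loc[1, "relative_biofilm"] == pytest.approx(2.0)
        assert out.loc[3, "relative_biofilm"] == pytest.approx(0.5)

    def test_missing_reference_names_experiment(self):
        t = self._table([("e9", "dgcZ", "HOCl", 250.0, 2.0)])
        with pytest.raises(ValueError, match="e9"):
            relative_biofilm(t)


class TestPairedT:
    def test_identical_vectors(self):
        t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference(self):
        t, p = paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isinf(t) and t > 0
        assert p == 0.0

    def test_hand_computed_four_pairs(self):
        # diffs (0.2, 0.3, 0.2, 0.2): mean 0.225, sd 0.05 -> t = 9.0, df = 3
        t, p = paired_t([1.2, 1.4, 1.1, 1.5], [1.0, 1.1, 0.9, 1.3])
        assert t == pytest.approx(9.0, rel=1e-12)
        assert p == pytest.approx(0.002895812161864147, rel=1e-9)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [1.0])
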