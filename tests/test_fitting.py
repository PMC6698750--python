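"""Dose-response fits, fold-change and CV-curve comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litersim import compare_cv_curves, fit_hill, fit_linear, fold_change, hill
from litersim.fitting import FitError

DOSES = np.array([0, 25, 50, 100, 150, 225, 300, 500, 750, 1000, 2000, 4095], float)


def hill_table(y0=100.0, ymax=900.0, K=300.0, n=2.0, doses=DOSES, noise=0.0, seed=0):
    y = hill(doses, y0, ymax, K, n)
    if noise:
        y = y * (1 + noise * np.random.default_rng(seed).standard_normal(len(doses)))
    return pd.DataFrame({"dose": doses, "value": y})


class TestLinear:
    def test_exact_line_recovered_to_machine_precision(self):
        t = pd.DataFrame({"dose": [0.0, 50.0, 100.0], "value": [1.0, 101.0, 201.0]})
        fit = fit_linear(t)
        assert fit["slope"] == pytest.approx(2.0, abs=1e-12)
        assert fit["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        t = pd.DataFrame({"dose": [0.0, 500.0, 1000.0], "value": [0.0, 1.0, 2.0]})
        with pytest.raises(FitError):
            fit_linear(t, dose_max=600.0)

    def test_hill_curve_linear_below_K_not_above(self):
        """The sub-K range is well fit by a line; the full range is not."""
        t = hill_table()
        restricted = fit_linear(t, dose_max=225.0)
        full = fit_linear(t)
        assert restricted.r2 >= 0.95
        assert full.r2 < restricted.r2


class TestHill:
    def test_noiseless_recovery_under_one_percent(self):
        fit = fit_hill(hill_table(), n_boot=0)
        for name, truth in [("y0", 100.0), ("ymax", 900.0), ("K", 300.0), ("n", 2.0)]:
            assert abs(fit[name] - truth) / truth < 0.01

    def test_ci_brackets_estimate(self):
        fit = fit_hill(hill_table(noise=0.05, seed=4), n_boot=200, seed=1)
        for name in ("y0", "ymax", "K", "n"):
            lo, hi = fit.ci[name]
            assert lo <= fit[name] <= hi or fit[name] == pytest.approx(lo, rel=0.05)

    def test_flat_data_rejected(self):
        flat = pd.DataFrame({"dose": DOSES, "value": np.full(len(DOSES), 7.0)})
        with pytest.raises(FitError):
            fit_hill(flat)

    def test_too_few_distinct_doses_rejected(self):
        t = pd.DataFrame({"dose": [0, 0, 100, 100], "value": [1.0, 1.1, 5.0, 5.2]})
        with pytest.raises(FitError):
            fit_hill(t)

    def test_bootstrap_reproducible_under_seed(self):
        t = hill_table(noise=0.05, seed=2)
        a = fit_hill(t, n_boot=100, seed=7)
        b = fit_hill(t, n_boot=100, seed=7)
        assert a.ci == b.ci

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(scale=st.floats(0.1, 50.0))
    def test_scale_equivariance(self, scale):
        """y -> c*y scales y0/ymax by c and leaves K, n, R^2 unchanged."""
        base = hill_table(noise=0.03, seed=5)
        scaled = base.assign(value=base["value"] * scale)
        f0 = fit_hill(base, n_boot=0)
        f1 = fit_hill(scaled, n_boot=0)
        assert f1["y0"] == pytest.approx(scale * f0["y0"], rel=1e-6, abs=1e-9)
        assert f1["ymax"] == pytest.approx(scale * f0["ymax"], rel=1e-6)
        assert f1["K"] == pytest.approx(f0["K"], rel=1e-6)
        assert f1["n"] == pytest.approx(f0["n"], rel=1e-6)
        assert f1.r2 == pytest.approx(f0.r2, abs=1e-6)


class TestFoldChange:
    def test_clear_separation(self):
        t = pd.DataFrame({"dose": [0, 0, 0, 1000, 1000, 1000],
                          "value": [10.0, 10.0, 10.0, 30.0, 30.0, 30.0]})
        fc = fold_change(t)
        assert fc.fold == pytest.approx(3.0)
        assert fc.p_value < 1e-6  # zero within-group variance -> certain difference

    def test_identical_groups(self):
        t = pd.DataFrame({"dose": [0, 0, 1000, 1000], "value": [5.0, 7.0, 7.0, 5.0]})
        fc = fold_change(t)
        assert fc.fold == pytest.approx(1.0)
        assert fc.p_value == pytest.approx(1.0, abs=1e-9)

    def test_known_triplicate_means(self):
        rng = np.random.default_rng(10)
        rows = []
        for dose, mu in [(0.0, 100.0), (1000.0, 380.0)]:
            for _ in range(3):
                rows.append((dose, mu * (1 + 0.05 * rng.standard_normal())))
        fc = fold_change(pd.DataFrame(rows, columns=["dose", "value"]))
        assert fc.fold == pytest.approx(3.8, rel=0.15)

    def test_zero_minimum_flagged(self):
        t = pd.DataFrame({"dose": [0, 0, 1, 1], "value": [0.0, 0.0, 5.0, 6.0]})
        fc = fold_change(t)
        assert not fc.defined and np.isnan(fc.fold)

    def test_single_condition_rejected(self):
        t = pd.DataFrame({"dose": [0, 0], "value": [1.0, 2.0]})
        with pytest.raises(FitError):
            fold_change(t)


class TestCompareCV:
    def test_identical_tables(self):
        a = pd.DataFrame({"dose": [0, 0, 1, 1], "cv": [0.2, 0.2, 0.3, 0.3]})
        r = compare_cv_curves(a, a.copy())
        assert r.statistic == pytest.approx(0.0, abs=1e-9)
        assert r.p_value == pytest.approx(1.0)
        assert r.max_fold_difference == pytest.approx(1.0)

    def test_five_fold_scaling_detected(self):
        rng = np.random.default_rng(3)
        doses = np.repeat([0, 100, 500, 1000], 3)
        a = pd.DataFrame({"dose": doses, "cv": 0.2 * (1 + 0.02 * rng.standard_normal(len(doses)))})
        b = a.assign(cv=a["cv"] * 5.0)
        r = compare_cv_curves(a, b)
        assert r.max_fold_difference == pytest.approx(5.0, rel=1e-9)
        assert r.p_value < 0.01

    def test_mismatched_grids_rejected(self):
        a = pd.DataFrame({"dose": [0, 1], "cv": [0.1, 0.2]})
        b = pd.DataFrame({"dose": [0, 2], "cv": [0.1, 0.2]})
        with pytest.raises(FitError):
            compare_cv_curves(a, b)
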