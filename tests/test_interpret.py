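"""ICE / PDP curves and the threshold-region summary."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from sklearn.inspection import partial_dependence
from sklearn.linear_model import LogisticRegression

from fhrisk.interpret import (ICEBundle, PDPCurve, default_grid, ice, pdp,
                              stratified_pdp, threshold_summary)


def logistic_predict(beta, intercept=0.0):
    def predict(mat):
        return expit(np.asarray(mat) @ np.asarray(beta) + intercept)
    return predict


@pytest.fixture
def frame(rng):
    return pd.DataFrame({"x": rng.normal(3, 1, 40), "z": rng.normal(0, 1, 40)})


class TestIce:
    def test_brute_force_oracle_small(self, frame):
        predict = logistic_predict([1.2, -0.5])
        grid = np.array([1.0, 2.0, 3.0, 4.0])
        bundle = ice(predict, frame.head(3), "x", grid=grid)
        assert bundle.curves.shape == (3, 4)
        for i in range(3):
            for j, v in enumerate(grid):
                row = frame.head(3).iloc[i].copy()
                row["x"] = v
                assert bundle.curves[i, j] == pytest.approx(
                    predict(row.to_numpy()[None, :])[0])

    def test_logistic_curves_are_parallel_on_link_scale(self, frame):
        predict = logistic_predict([0.8, 1.5])
        bundle = ice(predict, frame, "x", n_points=10)
        link = logit(np.clip(bundle.curves, 1e-12, 1 - 1e-12))
        # within-curve increments are identical across patients
        increments = np.diff(link, axis=1)
        assert np.allclose(increments, increments[0], atol=1e-8)

    def test_constant_model_gives_flat_curves(self, frame):
        bundle = ice(lambda m: np.full(len(m), 0.37), frame, "x", n_points=7)
        assert np.allclose(bundle.curves, 0.37)

    def test_unknown_variable_rejected(self, frame):
        with pytest.raises(KeyError):
            ice(logistic_predict([1, 0]), frame, "nope")

    def test_grid_outside_support_warns_but_computes(self, frame):
        grid = np.array([-100.0, 0.0, 100.0])
        with pytest.warns(UserWarning, match="outside"):
            bundle = ice(logistic_predict([1, 0]), frame, "x", grid=grid)
        assert bundle.curves.shape == (len(frame), 3)

    def test_subsampling_is_seeded(self, frame):
        predict = logistic_predict([1, 0])
        a = ice(predict, frame, "x", n_points=5, max_patients=10, seed=4)
        b = ice(predict, frame, "x", n_points=5, max_patients=10, seed=4)
        assert np.array_equal(a.curves, b.curves)


class TestPdp:
    def test_hand_built_two_curve_mean(self):
        bundle = ICEBundle(variable="x", grid=np.array([0.0, 1.0]),
                           curves=np.array([[0.2, 0.4], [0.6, 0.8]]))
        curve = pdp(bundle)
        assert np.allclose(curve.values, [0.4, 0.6])

    def test_single_patient_pdp_is_the_ice_curve(self, frame):
        predict = logistic_predict([1.0, 0.3])
        grid = default_grid(frame["x"], 6)
        bundle = ice(predict, frame.head(1), "x", grid=grid)
        assert np.allclose(pdp(bundle).values, bundle.curves[0])

    def test_pdp_is_mean_of_ice_everywhere(self, frame):
        bundle = ice(logistic_predict([0.9, -0.2]), frame, "x", n_points=12)
        assert np.allclose(pdp(bundle).values, bundle.curves.mean(axis=0))

    def test_matches_sklearn_partial_dependence(self, rng):
        X = rng.normal(size=(120, 3))
        y = (rng.random(120) < expit(X @ [1.5, -0.7, 0.2])).astype(int)
        est = LogisticRegression().fit(X, y)
        frame = pd.DataFrame(X, columns=["a", "b", "c"])
        sk = partial_dependence(est, X, features=[0], kind="average",
                                grid_resolution=20)
        ours = pdp(ice(lambda m: est.predict_proba(m)[:, 1], frame, "a",
                       grid=sk["grid_values"][0]))
        assert np.allclose(ours.values, sk["average"][0], atol=1e-10)

    def test_empty_bundle_rejected(self):
        bundle = ICEBundle(variable="x", grid=np.array([0.0, 1.0]),
                           curves=np.empty((0, 2)))
        with pytest.raises(ValueError):
            pdp(bundle)


class TestStratifiedPdp:
    def test_constant_stratifier_equals_plain_pdp(self, frame):
        predict = logistic_predict([1.1, 0.4])
        grid = default_grid(frame["x"], 8)
        curves = stratified_pdp(predict, frame, "x", ["all"] * len(frame),
                                grid=grid)
        assert list(curves) == ["all"]
        direct = pdp(ice(predict, frame, "x", grid=grid))
        assert np.allclose(curves["all"].values, direct.values)

    def test_risk_independent_strata_agree(self, rng):
        n = 4000
        frame = pd.DataFrame({"x": rng.normal(3, 1, n)})
        strata = rng.choice(["a", "b"], n)
        predict = logistic_predict([1.0], intercept=-3.0)
        curves = stratified_pdp(predict, frame, "x", strata, n_points=10)
        assert np.allclose(curves["a"].values, curves["b"].values, atol=0.02)

    def test_empty_stratum_warning_path(self, frame):
        strata = np.array(["a"] * len(frame))
        curves = stratified_pdp(logistic_predict([1, 0]), frame, "x",
                                strata, n_points=5)
        assert set(curves) == {"a"}


class TestThresholdSummary:
    def curve(self, values, grid=None):
        values = np.asarray(values, dtype=float)
        grid = np.arange(len(values), dtype=float) if grid is None else grid
        return PDPCurve(variable="ldl", grid=np.asarray(grid, float),
                        values=values, stratum="s")

    def test_crossing_reported_at_first_grid_point_above(self):
        c = self.curve([0.1, 0.3, 0.6, 0.9], grid=[3.5, 4.0, 4.5, 5.0])
        region = threshold_summary({"s": c}, 0.5)["s"]
        assert region.first_above == 4.5 and not region.empty

    def test_flat_curve_below_cutoff_is_empty(self):
        region = threshold_summary({"s": self.curve([0.1, 0.1, 0.1])}, 0.5)["s"]
        assert region.empty and region.first_above is None

    def test_zero_cutoff_covers_whole_range(self):
        c = self.curve([0.2, 0.4, 0.6], grid=[1.0, 2.0, 3.0])
        region = threshold_summary({"s": c}, 0.0)["s"]
        assert region.first_above == 1.0 and region.last_above == 3.0
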