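"""SVR clock: grid search, training, prediction, metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tissueclock.clock import (
    ClockError,
    ClockModel,
    default_grid,
    evaluate,
    grid_search_svr,
    predict_age,
    train_clock,
)
from tissueclock.containers import BetaMatrix
from tissueclock.simulate import SimConfig, generate_panel


class TestMetrics:
    def test_perfect_fit_all_zero(self):
        m = evaluate([30, 40, 50], [30, 40, 50])
        assert (m.rmse, m.mad, m.mape, m.theil_u) == (0.0, 0.0, 0.0, 0.0)

    def test_worked_example_direct_arithmetic(self):
        m = evaluate([30, 40, 50], [20, 40, 60])
        assert m.rmse == pytest.approx(math.sqrt(200 / 3))
        assert m.mad == pytest.approx(20 / 3)
        assert m.pearson_r == pytest.approx(1.0)
        assert m.mape == pytest.approx(100 * (0.5 + 0 + 1 / 6) / 3)
        # naive mean predictor (40) has rmse sqrt(800/3) -> U = 0.5
        assert m.theil_u == pytest.approx(0.5)

    def test_constant_shift(self):
        m = evaluate([25, 35, 45], [20, 30, 40])
        assert m.mad == pytest.approx(5.0)
        assert m.pearson_r == pytest.approx(1.0)

    def test_constant_vector_gives_undefined_r(self):
        m = evaluate([30, 30, 30], [20, 40, 60])
        assert math.isnan(m.pearson_r)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ClockError, match="mismatch"):
            evaluate([1.0, 2.0], [1.0])

    @given(
        st.lists(st.floats(min_value=1.0, max_value=100.0), min_size=2, max_size=30),
        st.data(),
    )
    @settings(deadline=None, max_examples=60)
    def test_rmse_dominates_mad(self, y, data):
        yhat = [
            data.draw(st.floats(min_value=1.0, max_value=100.0)) for _ in y
        ]
        m = evaluate(yhat, y)
        assert m.rmse >= m.mad - 1e-12


def _linear_panel(n=60, m=5, noise=0.0, seed=0):
    """Betas whose first marker is a noise-free linear function of age."""
    rng = np.random.default_rng(seed)
    ages = np.linspace(20, 80, n) + rng.normal(0, 0.01, n)
    X = rng.uniform(0.2, 0.8, size=(m, n))
    X[0] = (ages - 10) / 100.0  # invertible linear map into (0, 1)
    X = X + rng.normal(0, noise, size=X.shape)
    probes = [f"cg{i}" for i in range(m)]
    samples = [f"s{i}" for i in range(n)]
    mat = BetaMatrix(pd.DataFrame(np.clip(X, 0, 1), index=probes, columns=samples))
    tab = pd.DataFrame({"sample_id": samples, "age": ages, "tissue": "lin"})
    return mat, tab, ages


class TestGridSearch:
    def test_noise_free_linear_target_prefers_linear_kernel(self):
        mat, tab, ages = _linear_panel()
        X = mat.values.to_numpy().T
        best, table = grid_search_svr(X, ages, k=5, seed=0)
        assert best["kernel"] == "linear"
        assert table["cv_mad"].min() < 0.5

    def test_single_point_grid_returned(self):
        mat, tab, ages = _linear_panel(n=20)
        grid = [{"kernel": "linear", "C": 1.0, "epsilon": 0.5, "gamma": None}]
        best, table = grid_search_svr(mat.values.to_numpy().T, ages, k=4, grid=grid)
        assert best == grid[0]
        assert len(table) == 1

    def test_fixed_seed_is_deterministic(self):
        mat, tab, ages = _linear_panel(n=40, noise=0.02, seed=3)
        X = mat.values.to_numpy().T
        b1, t1 = grid_search_svr(X, ages, k=5, seed=7)
        b2, t2 = grid_search_svr(X, ages, k=5, seed=7)
        assert b1 == b2
        pd.testing.assert_frame_equal(t1, t2)

    def test_chosen_point_minimizes_cv_mad(self):
        mat, tab, ages = _linear_panel(n=40, noise=0.02, seed=4)
        best, table = grid_search_svr(mat.values.to_numpy().T, ages, k=5, seed=1)
        chosen = table[
            (table["kernel"] == best["kernel"])
            & (table["C"] == best["C"])
            & (table["epsilon"] == best["epsilon"])
        ]["cv_mad"].min()
        assert chosen <= table["cv_mad"].min() + 1e-12

    def test_too_few_samples_rejected(self):
        mat, tab, ages = _linear_panel(n=5)
        with pytest.raises(ClockError):
            grid_search_svr(mat.values.to_numpy().T, ages, k=10)


class TestTrainPredict:
    def test_interpolation_limit_on_noise_free_data(self):
        mat, tab, ages = _linear_panel()
        params = {"kernel": "linear", "C": 1e4, "epsilon": 0.0, "gamma": None}
        model = train_clock(mat, tab, list(mat.probe_ids), params)
        pred = predict_age(model, mat)
        assert np.max(np.abs(pred.to_numpy() - ages)) < 0.1

    def test_serialization_round_trip(self, tmp_path):
        mat, tab, _ = _linear_panel(n=30, noise=0.01, seed=5)
        params = {"kernel": "rbf", "C": 10.0, "epsilon": 0.5, "gamma": "scale"}
        model = train_clock(mat, tab, list(mat.probe_ids), params)
        path = tmp_path / "clock.joblib"
        model.save(path)
        loaded = ClockModel.load(path)
        np.testing.assert_array_equal(
            predict_age(model, mat).to_numpy(), predict_age(loaded, mat).to_numpy()
        )

    def test_missing_marker_listed_in_error(self):
        mat, tab, _ = _linear_panel(n=20)
        with pytest.raises(ClockError, match="cg_missing"):
            train_clock(mat, tab, ["cg0", "cg_missing"], {"kernel": "linear", "C": 1, "epsilon": 0.1})

    def test_sample_permutation_permutes_predictions(self):
        mat, tab, _ = _linear_panel(n=25)
        params = {"kernel": "linear", "C": 1.0, "epsilon": 0.5, "gamma": None}
        model = train_clock(mat, tab, list(mat.probe_ids), params)
        perm = list(mat.sample_ids)[::-1]
        permuted = BetaMatrix(mat.values[perm])
        p1 = predict_age(model, mat)
        p2 = predict_age(model, permuted)
        np.testing.assert_allclose(p1.loc[perm].to_numpy(), p2.to_numpy())

    def test_empty_sample_set_gives_empty_output(self):
        mat, tab, _ = _linear_panel(n=20)
        params = {"kernel": "linear", "C": 1.0, "epsilon": 0.5, "gamma": None}
        model = train_clock(mat, tab, list(mat.probe_ids), params)
        empty = BetaMatrix(mat.values.iloc[:, :0])
        assert len(predict_age(model, empty)) == 0


def test_synthetic_recovery_held_out_r_above_09():
    """Clock trained on 200 samples, tested on 50: r >= 0.9, beats baseline."""
    cfg = SimConfig(
        n_tissues=1,
        n_samples_per_tissue=250,
        n_probes=100,
        n_common_markers=20,
        n_specific_markers_per_tissue=0,
        noise_sd=0.02,
        missing_rate=0.0,
        seed=31,
    )
    mats, tables, _, truth = generate_panel(cfg)
    mat, tab = mats[0], tables[0]
    markers = list(truth.markers())
    train_tab, test_tab = tab.iloc[:200], tab.iloc[200:]
    train_mat = BetaMatrix(mat.values[train_tab["sample_id"]])
    test_mat = BetaMatrix(mat.values[test_tab["sample_id"]])
    X = train_mat.values.loc[markers].to_numpy().T
    best, _ = grid_search_svr(X, train_tab["age"].to_numpy(), k=10, seed=1)
    model = train_clock(train_mat, train_tab, markers, best)
    pred = predict_age(model, test_mat)
    m = evaluate(pred.to_numpy(), test_tab["age"].to_numpy())
    baseline_mad = np.mean(np.abs(test_tab["age"] - train_tab["age"].mean()))
    assert m.pearson_r >= 0.9
    assert m.mad <= baseline_mad
    assert m.theil_u < 1.0


def test_default_grid_order_encodes_tie_breaks():
    grid = default_grid(10)
    kernels = [g["kernel"] for g in grid]
    assert kernels.index("rbf") == kernels.count("linear")  # all linear first
    linear = [g for g in grid if g["kernel"] == "linear"]
    assert linear == sorted(linear, key=lambda g: (g["C"], g["epsilon"]))
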