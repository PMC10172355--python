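import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from picong.neural_gas import (
    NGConfig,
    assign_bmu,
    load_model,
    quantization_error,
    save_model,
    train_ng,
)


def frame(arr, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"S{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


def online_kmeans_oracle(data, init, epochs, eps0, epsf):
    """Winner-take-all online k-means with the exponential step schedule and
    fixed presentation order (the lambda -> 0 limit of the rank update)."""
    W = init.copy()
    n = len(data)
    t_max = epochs * n
    t = 0
    for _ in range(epochs):
        for i in range(n):
            eps = eps0 * (epsf / eps0) ** (t / t_max)
            d2 = ((W - data[i]) ** 2).sum(axis=1)
            w = int(d2.argmin())
            W[w] += eps * (data[i] - W[w])
            t += 1
    return W


class TestTrainNg:
    def test_single_unit_converges_to_data_mean(self):
        rng = np.random.default_rng(0)
        data = rng.normal(5.0, 2.0, size=(200, 3))
        # a small final step size makes the endgame a long running average,
        # pinning the prototype to the stochastic-approximation limit
        model = train_ng(
            frame(data), NGConfig(n_units=1, epochs=300, eps_final=1e-4, seed=1)
        )
        scale = data.std(axis=0)
        rel_err = np.abs(model.codebook.to_numpy()[0] - data.mean(axis=0)) / scale
        assert (rel_err < 1e-2).all()

    def test_repeated_point_is_a_fixed_point(self):
        data = np.tile([2.0, -1.0, 0.5], (30, 1))
        model = train_ng(frame(data), NGConfig(n_units=3, epochs=100, seed=0))
        assert np.allclose(model.codebook.to_numpy(), data[0], atol=1e-6)

    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(4)
        blob_a = rng.normal(0.0, 1.0, size=(60, 2))
        blob_b = rng.normal(10.0, 1.0, size=(60, 2))  # 10 SDs apart
        data = np.vstack([blob_a, blob_b])
        model = train_ng(frame(data), NGConfig(n_units=2, epochs=300, seed=2))
        means = np.vstack([blob_a.mean(axis=0), blob_b.mean(axis=0)])
        cost = np.linalg.norm(
            model.codebook.to_numpy()[:, None] - means[None, :], axis=2
        )
        rows, cols = linear_sum_assignment(cost)
        assert (cost[rows, cols] < 0.1).all()

    def test_nan_and_undersized_data_rejected(self):
        bad = frame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="NaN"):
            train_ng(bad, NGConfig(n_units=1, epochs=1))
        with pytest.raises(ValueError, match="n_units"):
            train_ng(frame([[1.0, 2.0]]), NGConfig(n_units=2, epochs=1))

    def test_determinism_bit_identical(self):
        rng = np.random.default_rng(5)
        X = frame(rng.uniform(size=(40, 4)))
        cfg = NGConfig(n_units=5, epochs=50, seed=9)
        a, b = train_ng(X, cfg), train_ng(X, cfg)
        assert (a.codebook.to_numpy() == b.codebook.to_numpy()).all()
        assert (assign_bmu(a, X).labels == assign_bmu(b, X).labels).all()

    def test_codebook_stays_in_convex_hull_bounds(self):
        rng = np.random.default_rng(6)
        X = frame(rng.uniform(-3, 7, size=(50, 3)))
        model = train_ng(X, NGConfig(n_units=6, epochs=200, seed=3))
        W = model.codebook.to_numpy()
        lo, hi = X.to_numpy().min(axis=0), X.to_numpy().max(axis=0)
        assert (W >= lo - 1e-12).all() and (W <= hi + 1e-12).all()

    def test_feature_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        data = rng.uniform(size=(30, 4))
        perm = [2, 0, 3, 1]
        cfg = NGConfig(n_units=3, epochs=60, seed=11)
        base = train_ng(frame(data), cfg)
        permuted = train_ng(
            pd.DataFrame(
                data[:, perm],
                index=[f"S{i}" for i in range(30)],
                columns=[f"f{j}" for j in perm],
            ),
            cfg,
        )
        assert np.allclose(
            base.codebook.to_numpy()[:, perm], permuted.codebook.to_numpy()
        )
        a = assign_bmu(base, frame(data))
        b = assign_bmu(permuted, frame(data[:, perm], prefix="g").set_axis(
            [f"f{j}" for j in perm], axis=1))
        assert (a.labels == b.labels).all()

    def test_lambda_to_zero_limit_is_online_kmeans(self):
        rng = np.random.default_rng(8)
        data = rng.uniform(size=(40, 3))
        init = data[:4].copy()
        cfg = NGConfig(
            n_units=4, epochs=150, lambda_init=1e-6, lambda_final=1e-6,
            seed=0, shuffle=False,
        )
        model = train_ng(frame(data), cfg, init_codebook=init)
        oracle = online_kmeans_oracle(data, init, 150, cfg.eps_init, cfg.eps_final)
        assert np.allclose(model.codebook.to_numpy(), oracle, atol=1e-6)

    def test_qe_history_recorded_per_epoch_and_decreases(self):
        rng = np.random.default_rng(9)
        X = frame(rng.normal(size=(60, 3)))
        model = train_ng(X, NGConfig(n_units=4, epochs=80, seed=1))
        assert len(model.qe_history) == 80
        assert model.qe_history[-1] < model.qe_history[0]


class TestAssignBmu:
    def test_sample_equal_to_prototype(self):
        rng = np.random.default_rng(10)
        X = frame(rng.uniform(size=(20, 3)))
        model = train_ng(X, NGConfig(n_units=5, epochs=30, seed=4))
        w3 = model.codebook.iloc[3].to_numpy()
        probe = pd.DataFrame([w3], index=["probe"], columns=model.feature_names)
        out = assign_bmu(model, probe)
        assert out.labels["probe"] == 3
        assert out.distances["probe"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_nearest_centroid(self):
        rng = np.random.default_rng(11)
        X = frame(rng.uniform(size=(50, 4)))
        model = train_ng(X, NGConfig(n_units=6, epochs=40, seed=5))
        queries = frame(rng.uniform(size=(200, 4)))
        out = assign_bmu(model, queries)
        W = model.codebook.to_numpy()
        for i, sid in enumerate(queries.index):
            d = np.linalg.norm(W - queries.to_numpy()[i], axis=1)
            assert out.labels[sid] == int(d.argmin())

    def test_equidistant_tie_goes_to_lowest_unit(self):
        codebook = pd.DataFrame(
            [[0.0], [-1.0], [0.0], [2.0], [0.0]], columns=["f0"],
            index=pd.RangeIndex(5, name="unit"),
        )
        model = train_ng(
            frame(np.linspace(-2, 2, 10)[:, None]),
            NGConfig(n_units=5, epochs=1, seed=0),
        )
        model.codebook = codebook
        out = assign_bmu(model, pd.DataFrame([[0.0]], index=["q"], columns=["f0"]))
        assert out.labels["q"] == 0

    def test_feature_mismatch_rejected(self):
        X = frame(np.ones((5, 2)))
        model = train_ng(X, NGConfig(n_units=2, epochs=1, seed=0))
        bad = pd.DataFrame(np.ones((2, 2)), columns=["x", "y"])
        with pytest.raises(ValueError, match="feature mismatch"):
            assign_bmu(model, bad)


class TestQuantizationError:
    def test_zero_when_codebook_covers_data(self):
        data = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        X = frame(data)
        model = train_ng(X, NGConfig(n_units=3, epochs=1, seed=0))
        model.codebook = pd.DataFrame(data, columns=model.feature_names,
                                      index=pd.RangeIndex(3, name="unit"))
        assert quantization_error(model, X) == pytest.approx(0.0, abs=1e-12)

    def test_single_unit_at_mean_matches_mean_absolute_deviation(self):
        rng = np.random.default_rng(12)
        data = rng.normal(size=(500, 1))
        X = frame(data)
        model = train_ng(X, NGConfig(n_units=1, epochs=1, seed=0))
        model.codebook = pd.DataFrame(
            [[data.mean()]], columns=model.feature_names, index=pd.RangeIndex(1, name="unit")
        )
        oracle = np.abs(data - data.mean()).mean()
        assert quantization_error(model, X) == pytest.approx(oracle)

    def test_training_improves_over_random_initialization(self):
        rng = np.random.default_rng(13)
        data = rng.normal(size=(80, 3)) * np.array([1.0, 2.0, 0.5])
        X = frame(data)
        deltas = []
        for seed in range(20):
            trained = train_ng(X, NGConfig(n_units=5, epochs=60, seed=seed))
            local = np.random.default_rng(seed)
            init = data[local.choice(80, 5, replace=False)]
            random_model = train_ng(X, NGConfig(n_units=5, epochs=1, seed=seed),
                                    init_codebook=init)
            random_model.codebook = pd.DataFrame(
                init, columns=X.columns, index=pd.RangeIndex(5, name="unit")
            )
            deltas.append(
                quantization_error(trained, X) - quantization_error(random_model, X)
            )
        assert np.median(deltas) < 0


class TestSerialization:
    def test_model_round_trip(self, tmp_path):
        rng = np.random.default_rng(14)
        X = frame(rng.uniform(size=(20, 3)))
        model = train_ng(X, NGConfig(n_units=3, epochs=10, seed=2))
        save_model(model, tmp_path / "cb.tsv", tmp_path / "cfg.json")
        loaded = load_model(tmp_path / "cb.tsv", tmp_path / "cfg.json")
        assert np.allclose(loaded.codebook.to_numpy(), model.codebook.to_numpy())
        assert loaded.config == model.config
        assert (assign_bmu(loaded, X).labels == assign_bmu(model, X).labels).all()
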