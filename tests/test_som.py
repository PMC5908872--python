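"""Hexagonal SOM: geometry, training behavior, brute-force assignment oracle."""

import numpy as np
import pandas as pd
import pytest

from lymphomap import som
from lymphomap.types import ConfigError


def df(X, columns=None):
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(
        X,
        index=[f"p{i}" for i in range(X.shape[0])],
        columns=columns or [f"f{j}" for j in range(X.shape[1])],
    )


class TestHexGrid:
    def test_same_row_neighbors_distance_one(self):
        c = som.hex_grid(4, 4)
        assert np.linalg.norm(c[0] - c[1]) == pytest.approx(1.0)

    def test_row_offset_geometry(self):
        c = som.hex_grid(4, 4)
        # units (0,0) and (1,0): dx=0.5, dy=sqrt(3)/2 -> distance 1
        assert np.linalg.norm(c[0] - c[4]) == pytest.approx(1.0)

    def test_across_row_distance(self):
        c = som.hex_grid(4, 4)
        assert np.linalg.norm(c[0] - c[3]) == pytest.approx(3.0)

    def test_all_nearest_neighbors_at_unit_distance(self):
        c = som.hex_grid(4, 4)
        d = np.linalg.norm(c[:, None] - c[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert np.allclose(d.min(axis=1), 1.0)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ConfigError):
            som.hex_grid(0, 4)


class TestTraining:
    def test_identical_rows_collapse_codebook(self):
        v = np.array([0.3, -0.2, 0.1])
        data = df(np.tile(v, (20, 1)))
        model = som.train_som(data, epochs=100, seed=0)
        assert np.abs(model.codebook - v).max() < 1e-6

    def test_determinism(self):
        rng = np.random.default_rng(5)
        data = df(rng.normal(size=(30, 5)))
        m1 = som.train_som(data, epochs=20, seed=9)
        m2 = som.train_som(data, epochs=20, seed=9)
        assert np.array_equal(m1.codebook, m2.codebook)

    def test_seed_changes_model(self):
        rng = np.random.default_rng(5)
        data = df(rng.normal(size=(30, 5)))
        m1 = som.train_som(data, epochs=20, seed=1)
        m2 = som.train_som(data, epochs=20, seed=2)
        assert not np.array_equal(m1.codebook, m2.codebook)

    def test_separated_clusters_get_disjoint_units(self):
        """Two clusters at +/-0.5 in all coordinates map to disjoint unit sets."""
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = 0.5 + rng.normal(0, 0.01, size=(15, 4))
            b = -0.5 + rng.normal(0, 0.01, size=(15, 4))
            data = df(np.vstack([a, b]))
            model = som.train_som(data, epochs=50, seed=seed)
            assignment = som.assign_bmu(model, data)
            units_a = set(assignment.units.iloc[:15])
            units_b = set(assignment.units.iloc[15:])
            if not units_a & units_b:
                ok += 1
        assert ok == 10

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigError):
            som.train_som(df(np.empty((0, 4))), seed=0)

    def test_qe_trace_decreases_from_start(self):
        rng = np.random.default_rng(3)
        data = df(rng.normal(size=(60, 7)))
        model = som.train_som(data, epochs=100, seed=3)
        assert model.qe_per_epoch[-1] <= model.qe_per_epoch[0]

    def test_model_json_round_trip(self):
        rng = np.random.default_rng(4)
        data = df(rng.normal(size=(20, 3)))
        model = som.train_som(data, epochs=5, seed=4)
        back = som.SOMModel.from_dict(model.to_dict())
        assert np.array_equal(back.codebook, model.codebook)
        assert back.feature_names == model.feature_names


class TestAssignment:
    def _model(self, rng, n_features=4):
        codebook = rng.normal(size=(16, n_features))
        return som.SOMModel(
            centers=som.hex_grid(4, 4),
            codebook=codebook,
            feature_names=[f"f{j}" for j in range(n_features)],
        )

    def test_exact_codebook_row_maps_to_its_unit(self, rng):
        model = self._model(rng)
        data = df(model.codebook[[5]], columns=model.feature_names)
        assignment = som.assign_bmu(model, data)
        assert assignment.units.iloc[0] == 6  # 1-based

    def test_tie_broken_by_lowest_unit(self, rng):
        codebook = np.zeros((16, 2))
        codebook[3] = [1.0, 0.0]
        codebook[10] = [-1.0, 0.0]
        model = som.SOMModel(
            centers=som.hex_grid(4, 4), codebook=codebook, feature_names=["a", "b"]
        )
        assignment = som.assign_bmu(model, df([[0.0, 0.5]], columns=["a", "b"]))
        assert assignment.units.iloc[0] == 1  # many zero units tie; unit 1 wins

    def test_matches_brute_force_distance_matrix(self, rng):
        for _ in range(200):
            model = self._model(rng)
            X = rng.normal(size=(50, 4))
            data = df(X, columns=model.feature_names)
            assignment = som.assign_bmu(model, data)
            d = np.linalg.norm(X[:, None, :] - model.codebook[None], axis=2)
            assert np.array_equal(assignment.units.to_numpy(), d.argmin(axis=1) + 1)

    def test_counts_sum_to_input_rows(self, rng):
        model = self._model(rng)
        data = df(rng.normal(size=(37, 4)), columns=model.feature_names)
        assignment = som.assign_bmu(model, data)
        assert assignment.summary["n_pathways"].sum() == 37

    def test_dimension_mismatch_rejected(self, rng):
        model = self._model(rng)
        with pytest.raises(ConfigError):
            som.assign_bmu(model, df(rng.normal(size=(3, 5))))


class TestQuantizationError:
    def test_zero_when_rows_equal_codebook(self, rng):
        codebook = rng.normal(size=(16, 3))
        model = som.SOMModel(
            centers=som.hex_grid(4, 4), codebook=codebook, feature_names=list("abc")
        )
        data = df(codebook[[0, 5, 11]], columns=list("abc"))
        assert som.quantization_error(model, data) == 0.0

    def test_single_row_at_known_distance(self):
        codebook = np.zeros((16, 2))
        model = som.SOMModel(
            centers=som.hex_grid(4, 4), codebook=codebook, feature_names=["a", "b"]
        )
        data = df([[0.0, 2.0]], columns=["a", "b"])
        assert som.quantization_error(model, data) == pytest.approx(2.0)

    def test_matches_brute_force_row_minima(self, rng):
        for _ in range(200):
            codebook = rng.normal(size=(16, 4))
            model = som.SOMModel(
                centers=som.hex_grid(4, 4),
                codebook=codebook,
                feature_names=list("abcd"),
            )
            X = rng.normal(size=(20, 4))
            expected = np.mean(
                [
                    min(np.linalg.norm(x - w) for w in codebook)
                    for x in X
                ]
            )
            got = som.quantization_error(model, df(X, columns=list("abcd")))
            assert got == pytest.approx(expected, abs=1e-10)
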