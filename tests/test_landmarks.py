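"""Landmark I/O, reflection, Procrustes alignment and the composite shape."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gnathomech import (GeneralizedProcrustes, LandmarkConfiguration,
                        composite_representation, generalized_procrustes,
                        procrustes_distance, read_landmarks_csv, read_tps,
                        reflect_to_reference, write_landmarks_csv, write_tps)
from gnathomech.landmarks import TPSParseError, _normalize

from conftest import random_configuration, random_rotation


# ---------------------------------------------------------------------------
# TPS and CSV I/O
# ---------------------------------------------------------------------------

class TestTPS:
    def test_minimal_2d_record(self, tmp_path):
        path = tmp_path / "a.tps"
        path.write_text("LM=3\n0 0\n1 0\n0 1\nID=spec1\n")
        (cfg,) = read_tps(path)
        assert cfg.specimen_id == "spec1"
        assert cfg.k == 3 and cfg.ndim == 2
        np.testing.assert_allclose(cfg.coords, [[0, 0], [1, 0], [0, 1]])

    def test_3d_dialect(self, tmp_path):
        path = tmp_path / "a.tps"
        path.write_text("LM3=3\n0 0 0\n1 2 3\n1 1 1\n")
        (cfg,) = read_tps(path)
        assert cfg.ndim == 3

    def test_scale_applied(self, tmp_path):
        path = tmp_path / "a.tps"
        path.write_text("LM=3\n0 0\n2 0\n0 2\nSCALE=0.5\n")
        (cfg,) = read_tps(path)
        np.testing.assert_allclose(cfg.coords, [[0, 0], [1, 0], [0, 1]])

    def test_short_record_raises(self, tmp_path):
        path = tmp_path / "a.tps"
        path.write_text("LM=4\n0 0\n1 0\n0 1\nID=x\n")
        with pytest.raises(TPSParseError):
            read_tps(path)

    def test_malformed_count_raises(self, tmp_path):
        path = tmp_path / "a.tps"
        path.write_text("LM=three\n")
        with pytest.raises(TPSParseError, match="line 1"):
            read_tps(path)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(3, 9), st.sampled_from([2, 3]), st.integers(0, 10**6))
    def test_roundtrip(self, tmp_path_factory, k, d, seed):
        rng = np.random.default_rng(seed)
        configs = [random_configuration(rng, k=k, d=d, specimen_id=f"s{i}")
                   for i in range(3)]
        path = tmp_path_factory.mktemp("tps") / "round.tps"
        write_tps(configs, path)
        back = read_tps(path)
        assert [c.specimen_id for c in back] == ["s0", "s1", "s2"]
        for a, b in zip(configs, back):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-9)


def test_landmarks_csv_roundtrip(tmp_path, rng):
    cfg = random_configuration(rng, k=5, specimen_id="sp1")
    cfg = cfg.with_coords(cfg.coords, side="left",
                          role_labels={"p0": "condyle_anterior",
                                       "p1": "adductor_attachment"})
    path = tmp_path / "lm.csv"
    write_landmarks_csv([cfg], path)
    (back,) = read_landmarks_csv(path)
    np.testing.assert_allclose(back.coords, cfg.coords)
    assert back.role_labels == cfg.role_labels
    assert back.side == "left"


# ---------------------------------------------------------------------------
# Configuration invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bad", [
    dict(labels=["a", "b"], coords=[[0, 0], [1, 1]]),            # k < 3
    dict(labels=["a", "a", "b"], coords=[[0, 0], [1, 1], [2, 0]]),  # dup label
    dict(labels=["a", "b", "c"],
         coords=[[0, 0], [np.nan, 1], [2, 0]]),                  # non-finite
])
def test_invalid_configuration_rejected(bad):
    with pytest.raises(ValueError):
        LandmarkConfiguration("x", bad["labels"], np.asarray(bad["coords"], float))


# ---------------------------------------------------------------------------
# Reflection
# ---------------------------------------------------------------------------

class TestReflect:
    def test_identity_on_reference_side(self, triangle):
        assert reflect_to_reference(triangle, "left") is triangle

    def test_negates_first_axis(self, triangle):
        right = reflect_to_reference(triangle, "right")
        np.testing.assert_allclose(right.coords[:, 0], -triangle.coords[:, 0])
        np.testing.assert_allclose(right.coords[:, 1], triangle.coords[:, 1])
        assert right.side == "right"

    def test_involution(self, triangle):
        back = reflect_to_reference(
            reflect_to_reference(triangle, "right"), "left")
        np.testing.assert_allclose(back.coords, triangle.coords)

    def test_unknown_side_errors(self, triangle):
        with pytest.raises(ValueError):
            reflect_to_reference(triangle.with_coords(triangle.coords, side=None),
                                 "left")
        with pytest.raises(ValueError):
            reflect_to_reference(triangle, "dorsal")


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

def _rigid_copy(cfg, rng, specimen_id):
    rot = random_rotation(rng, cfg.ndim)
    coords = cfg.coords @ rot.T + rng.uniform(-10, 10, cfg.ndim)
    return cfg.with_coords(coords, specimen_id=specimen_id)


class TestGPA:
    def test_rigid_motion_invariance(self, triangle, rng):
        """Two rigid copies of one shape align exactly (distance ~ 0)."""
        moved = _rigid_copy(triangle, rng, "moved")
        res = generalized_procrustes([triangle, moved])
        np.testing.assert_allclose(res.configurations[0].coords,
                                   res.configurations[1].coords, atol=1e-9)
        assert res.procrustes_distances["moved"] < 1e-9

    def test_identical_configs_mean_is_input(self, triangle):
        res = generalized_procrustes([triangle] * 4)
        expected, _ = _normalize(triangle.coords, "tri")
        np.testing.assert_allclose(res.mean_shape.coords, expected, atol=1e-9)

    def test_aligned_configs_normalized(self, triangle, rng):
        configs = [_rigid_copy(random_configuration(rng, k=5), rng, f"s{i}")
                   for i in range(4)]
        res = generalized_procrustes(configs)
        for cfg in res.configurations:
            np.testing.assert_allclose(cfg.centroid, 0.0, atol=1e-9)
            assert abs(cfg.centroid_size - 1.0) < 1e-9
        assert abs(res.mean_shape.centroid_size - 1.0) < 1e-9

    def test_input_similarity_invariance(self, rng):
        """Alignment result is unchanged when any input is translated,
        rotated or rescaled."""
        configs = [random_configuration(rng, k=6, specimen_id=f"s{i}")
                   for i in range(3)]
        res1 = generalized_procrustes(configs)
        rot = random_rotation(rng, 2)
        configs2 = list(configs)
        configs2[1] = configs2[1].with_coords(
            3.7 * configs2[1].coords @ rot.T + [5.0, -2.0])
        res2 = generalized_procrustes(configs2)
        for a, b in zip(res1.configurations, res2.configurations):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-8)

    def test_monotone_convergence(self, rng):
        """Summed squared distance to the mean never increases."""
        configs = [random_configuration(rng, k=8, specimen_id=f"s{i}")
                   for i in range(6)]
        res = generalized_procrustes(configs)
        diffs = np.diff(res.ss_history)
        assert np.all(diffs <= 1e-12)

    def test_idempotence(self, rng):
        configs = [random_configuration(rng, k=6, specimen_id=f"s{i}")
                   for i in range(4)]
        res1 = generalized_procrustes(configs)
        res2 = generalized_procrustes(res1.configurations)
        # convergence stops at delta-SS < tol, so coordinates are pinned
        # down to about sqrt(tol)
        for a, b in zip(res1.configurations, res2.configurations):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-5)

    def test_degenerate_configuration_errors(self, triangle):
        flat = LandmarkConfiguration(
            "flat", ["a", "b", "c"], np.ones((3, 2)))
        with pytest.raises(ValueError, match="flat"):
            generalized_procrustes([triangle, flat])

    def test_mismatched_labels_error(self, triangle):
        other = LandmarkConfiguration(
            "oth", ["a", "b", "z"], np.array([[0, 0], [2, 0], [0, 2.0]]))
        with pytest.raises(ValueError, match="label"):
            generalized_procrustes([triangle, other])

    def test_estimator_transform_aligns_new_configs(self, triangle, rng):
        configs = [_rigid_copy(triangle, rng, f"s{i}") for i in range(3)]
        est = GeneralizedProcrustes().fit(configs)
        new = _rigid_copy(triangle, rng, "new")
        (aligned,) = est.transform([new])
        assert np.linalg.norm(aligned.coords - est.mean_shape_.coords) < 1e-9

    def test_estimator_get_params(self):
        est = GeneralizedProcrustes(tol=1e-8)
        assert est.get_params()["tol"] == 1e-8
        est.set_params(max_iter=50)
        assert est.max_iter == 50


def test_two_shape_distance_matches_svd_oracle(rng):
    """Pairwise Procrustes distance equals the closed-form two-shape
    orthogonal-Procrustes solution: d^2 = 2 - 2 sum of (sign-corrected)
    singular values of the cross-covariance of the normalized shapes."""
    for _ in range(25):
        k = int(rng.integers(3, 9))
        a = random_configuration(rng, k=k, specimen_id="a")
        b = random_configuration(rng, k=k, specimen_id="b")
        x, _ = _normalize(a.coords, "a")
        y, _ = _normalize(b.coords, "b")
        u, s, vt = np.linalg.svd(x.T @ y)
        if np.linalg.det(u @ vt) < 0:
            s[-1] = -s[-1]
        oracle = np.sqrt(max(2.0 - 2.0 * s.sum(), 0.0))
        assert abs(procrustes_distance(a, b) - oracle) < 1e-10


# ---------------------------------------------------------------------------
# Composite fossil representation
# ---------------------------------------------------------------------------

class TestComposite:
    def test_two_identical_equals_normalized_input(self, triangle):
        cfg = triangle.with_coords(triangle.coords,
                                   role_labels={"a": "condyle_anterior"})
        comp = composite_representation([cfg, cfg])
        expected, _ = _normalize(cfg.coords, "tri")
        np.testing.assert_allclose(comp.coords, expected, atol=1e-9)
        assert comp.specimen_id == "CFMR"
        assert comp.role_labels == {"a": "condyle_anterior"}

    def test_label_mismatch_lists_difference(self, triangle):
        other = LandmarkConfiguration(
            "oth", ["a", "b", "z"], np.array([[0, 0], [2, 0], [0, 2.0]]))
        with pytest.raises(ValueError, match="'c'.*'z'|'z'.*'c'"):
            composite_representation([triangle, other])

    def test_noisy_copies_average_toward_truth(self, rng):
        """The composite of 4 noisy copies lies within O(sigma/sqrt(4)) of
        the generating shape."""
        truth = random_configuration(rng, k=20, specimen_id="truth")
        sigma = 0.02
        copies = [truth.with_coords(truth.coords + rng.normal(0, sigma, (20, 2)),
                                    specimen_id=f"c{i}") for i in range(4)]
        comp = composite_representation(copies)
        # distances live on the unit-size preshape sphere
        scale = np.linalg.norm(truth.coords - truth.coords.mean(0))
        err = procrustes_distance(comp, truth)
        assert err < 4 * sigma * np.sqrt(2 * 20) / np.sqrt(4) / scale
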