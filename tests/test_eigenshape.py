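import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from furcula.eigenshape import (
    PhiVector,
    combine_views,
    curve_sensitivity,
    eigenshape_fit,
    extended_eigenshape_fit,
    load_model,
    phi_transform,
    phi_transform_segmented,
    reconstruct_outline,
    reconstruct_phi,
    save_model,
)
from furcula.shapes_io import OutlineCurve, PseudolandmarkSet, orient_standard, resample_equal_arclength
from furcula.synthetic import FurculaParams, make_furcula_outline, measure_interclavicular_angle


def phis_from_matrix(X):
    return [PhiVector(str(i), row) for i, row in enumerate(X)]


class TestPhiTransform:
    def test_collinear_is_zero(self):
        pts = np.column_stack([np.linspace(0, 5, 10), np.linspace(0, 2.5, 10)])
        assert np.allclose(phi_transform(pts).phi, 0.0)

    def test_left_turn_positive_right_angle(self):
        v = phi_transform(np.array([[0.0, 0], [1, 0], [1, 1]]))
        assert np.allclose(v.phi, [np.pi / 2])

    def test_semicircle_total_turning(self):
        t = np.linspace(0, np.pi, 100)
        arc = np.column_stack([np.cos(t), np.sin(t)])
        total = phi_transform(arc).phi.sum()
        # n-2 turning angles cover (n-2)/(n-1) of the semicircle's pi
        assert total == pytest.approx(np.pi * 98 / 99, rel=1e-6)

    def test_zero_length_segment_named(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 0], [2, 1]])
        with pytest.raises(ValueError, match="index 1"):
            phi_transform(pts)

    def test_invariance_to_similarity_transform(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.standard_normal((30, 2)), axis=0)
        th = 0.83
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = 3.7 * pts @ R.T + [5.0, -2.0]
        assert np.allclose(phi_transform(pts).phi, phi_transform(moved).phi, atol=1e-10)


class TestEigenshapeFit:
    def test_two_specimens_single_axis(self):
        X = np.array([[0.1, 0.2, 0.3], [0.3, 0.1, 0.2]])
        m = eigenshape_fit(phis_from_matrix(X), use_correlation=False)
        assert m.axes.shape[1] == 1
        assert np.allclose(m.variance_fraction, [1.0])

    def test_duplication_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 20))
        m1 = eigenshape_fit(phis_from_matrix(X), use_correlation=True)
        m2 = eigenshape_fit(phis_from_matrix(np.vstack([X, X])), use_correlation=True)
        assert np.allclose(m1.variance_fraction, m2.variance_fraction, atol=1e-10)
        assert np.allclose(np.abs(m1.axes), np.abs(m2.axes), atol=1e-8)

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 98)) * 0.1
        m = eigenshape_fit(phis_from_matrix(X), use_correlation=True)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        w, U = np.linalg.eigh(Xs.T @ Xs)
        order = np.argsort(w)[::-1]
        w, U = w[order], U[:, order]
        k = m.axes.shape[1]
        for j in range(k):
            gap = min(
                np.abs(m.axes[:, j] - U[:, j]).max(),
                np.abs(m.axes[:, j] + U[:, j]).max(),
            )
            assert gap < 1e-6
        assert np.allclose(m.variance_fraction, w[:k] / w[:k].sum(), atol=1e-10)

    def test_requires_two_specimens(self):
        with pytest.raises(ValueError):
            eigenshape_fit(phis_from_matrix(np.zeros((1, 5))))

    def test_identical_specimens_degenerate(self):
        X = np.tile([0.1, 0.2, 0.3], (4, 1))
        with pytest.raises(ValueError, match="degenerate"):
            eigenshape_fit(phis_from_matrix(X))

    def test_axes_orthonormal_and_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        m = eigenshape_fit(phis_from_matrix(rng.standard_normal((8, 30))))
        G = m.axes.T @ m.axes
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-8)
        assert m.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(m.variance_fraction) <= 1e-12)

    def test_scores_invariant_to_global_similarity_of_outlines(self):
        rng = np.random.default_rng(4)
        curves = [np.cumsum(rng.standard_normal((40, 2)), axis=0) for _ in range(6)]
        th = -0.61
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        phis_a = [PhiVector(str(i), phi_transform(c).phi) for i, c in enumerate(curves)]
        phis_b = [
            PhiVector(str(i), phi_transform(0.37 * c @ R.T + [1, 2]).phi)
            for i, c in enumerate(curves)
        ]
        ma = eigenshape_fit(phis_a)
        mb = eigenshape_fit(phis_b)
        assert np.allclose(ma.scores, mb.scores, atol=1e-8)


class TestReconstruction:
    def test_zero_scores_give_mean_shape(self):
        rng = np.random.default_rng(5)
        m = eigenshape_fit(phis_from_matrix(rng.standard_normal((5, 12)) * 0.1))
        assert np.allclose(reconstruct_phi(m, {}), m.mean_phi)

    def test_full_scores_round_trip(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((5, 12)) * 0.1
        m = eigenshape_fit(phis_from_matrix(X), use_correlation=True)
        for k in range(5):
            assert np.allclose(reconstruct_phi(m, m.scores[k]), X[k], atol=1e-8)

    def test_score_index_beyond_axes_rejected(self):
        rng = np.random.default_rng(7)
        m = eigenshape_fit(phis_from_matrix(rng.standard_normal((3, 10))))
        with pytest.raises(IndexError):
            reconstruct_phi(m, {10: 1.0})

    def test_outline_coordinates_start_at_origin_heading_x(self):
        rng = np.random.default_rng(8)
        m = eigenshape_fit(phis_from_matrix(rng.standard_normal((4, 10)) * 0.2))
        out = reconstruct_outline(m, {}, segment_length=0.5)
        assert np.allclose(out.points[0], [0, 0])
        assert np.allclose(out.points[1], [0.5, 0])

    def test_axis1_sweep_moves_interclavicular_angle_monotonically(self):
        angles = np.linspace(40, 130, 20)
        phis = []
        for i, a in enumerate(angles):
            c = make_furcula_outline(
                FurculaParams(a, 0.4, 0.0, 0.0, 0.4), "profile", specimen_id=str(i)
            )
            phis.append(phi_transform(resample_equal_arclength(orient_standard(c), 100)))
        m = eigenshape_fit(phis, use_correlation=True)
        sd = m.scores[:, 0].std()
        measured = []
        for s in (-2 * sd, -sd, 0.0, sd, 2 * sd):
            rec = reconstruct_outline(m, {0: s}, segment_length=0.02)
            measured.append(measure_interclavicular_angle(
                OutlineCurve("r", "profile", rec.points)
            ))
        diffs = np.diff(measured)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_model_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        m = eigenshape_fit(phis_from_matrix(rng.standard_normal((5, 15))))
        save_model(m, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        assert np.allclose(back.axes, m.axes)
        assert np.allclose(back.scores, m.scores)
        assert back.specimen_ids == m.specimen_ids


class TestExtended:
    def make_pls(self, pts, lms=()):
        return PseudolandmarkSet("s", "lateral", np.asarray(pts, float), len(pts), lms)

    def test_no_landmarks_reduces_to_standard(self):
        rng = np.random.default_rng(10)
        curves = [np.cumsum(rng.standard_normal((20, 2)), axis=0) for _ in range(5)]
        pls = [PseudolandmarkSet(str(i), "profile", c, 20) for i, c in enumerate(curves)]
        phis = [phi_transform(p) for p in pls]
        m1 = eigenshape_fit(phis)
        m2 = extended_eigenshape_fit(pls)
        assert np.allclose(m1.scores, m2.scores)

    def test_straight_segments_give_zero_phi(self):
        pts = np.column_stack([np.linspace(0, 2, 9), np.r_[np.zeros(5), np.arange(1, 5) * 0.5]])
        v = phi_transform_segmented(self.make_pls(pts, (4,)))
        assert np.allclose(v.phi, 0.0, atol=1e-12)
        assert v.segment_lengths == (3, 3)

    def test_mismatched_landmark_counts_rejected(self):
        a = self.make_pls(np.random.default_rng(0).standard_normal((10, 2)).cumsum(0), (4,))
        b = self.make_pls(np.random.default_rng(1).standard_normal((10, 2)).cumsum(0))
        with pytest.raises(ValueError, match="landmark count"):
            extended_eigenshape_fit([a, b])

    def test_epicleideum_curl_separates_classes(self):
        """Lateral curves differing only in the epicleideum segment separate
        on the leading axes."""
        pls = []
        labels = []
        for i in range(20):
            flare = -0.2 if i < 10 else 0.2
            c = make_furcula_outline(
                FurculaParams(80, 0.5, 0.1, flare, 0.4),
                "lateral",
                noise_sd=0.002,
                seed=40 + i,
                specimen_id=str(i),
            )
            pls.append(resample_equal_arclength(orient_standard(c), 100))
            labels.append(flare > 0)
        m = extended_eigenshape_fit(pls)
        s1 = m.scores[:10, 0]
        s2 = m.scores[10:, 0]
        gap = abs(s1.mean() - s2.mean()) / np.sqrt(0.5 * (s1.var() + s2.var()))
        assert gap > 3.0


class TestCombineViews:
    def test_same_input_preserves_subspace(self):
        rng = np.random.default_rng(11)
        A = rng.standard_normal((10, 3))
        fused, _ = combine_views(A, A)
        # principal angles between span(fused) and span(A) are ~0
        Qa, _ = np.linalg.qr(A - A.mean(0))
        Qf, _ = np.linalg.qr(fused)
        s = np.linalg.svd(Qa.T @ Qf, compute_uv=False)
        assert np.allclose(s[: A.shape[1]], 1.0, atol=1e-8)

    def test_orthogonal_equal_variance_splits_evenly(self):
        a = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        b = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        _, vf = combine_views(a, b)
        assert np.allclose(vf, [0.5, 0.5])

    def test_matches_pca_oracle(self):
        rng = np.random.default_rng(12)
        A, B = rng.standard_normal((12, 3)), rng.standard_normal((12, 2))
        fused, _ = combine_views(A, B)
        X = np.hstack([A, B])
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        U, s, _ = np.linalg.svd(Xs, full_matrices=False)
        ref = U * s
        for j in range(fused.shape[1]):
            gap = min(
                np.abs(fused[:, j] - ref[:, j]).max(),
                np.abs(fused[:, j] + ref[:, j]).max(),
            )
            assert gap < 1e-8

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError, match="row mismatch"):
            combine_views(np.zeros((3, 2)), np.zeros((4, 2)))


class TestCurveSensitivity:
    @staticmethod
    def _datasets(signal_in="outside", n=16, seed=0):
        """Two curve definitions; only one carries class-correlated shape."""
        from furcula.synthetic import simulate_tree

        rng = np.random.default_rng(seed)
        tree = simulate_tree(n, seed=seed + 1)
        groups = ["g1"] * (n // 2) + ["g2"] * (n - n // 2)
        datasets = {"outside": [], "inside": []}
        for i, tip in enumerate(tree.tip_labels):
            ang_sig = 60.0 if groups[i] == "g1" else 110.0
            for name in datasets:
                ang = ang_sig if name == signal_in else 85.0
                c = make_furcula_outline(
                    FurculaParams(ang + rng.normal(0, 3), 0.4, 0.1, 0.0, 0.4),
                    "profile",
                    noise_sd=0.002,
                    seed=int(rng.integers(2**31 - 1)),
                    specimen_id=tip,
                )
                datasets[name].append(resample_equal_arclength(orient_standard(c), 100))
        return datasets, groups, tree

    def test_signal_bearing_definition_ranked_first(self):
        datasets, groups, tree = self._datasets(signal_in="outside")
        table = curve_sensitivity(datasets, groups, tree, n_sim=99, seed=0)
        assert table["curve_definition"].iloc[0] == "outside"

    def test_single_definition_single_row(self):
        datasets, groups, tree = self._datasets()
        table = curve_sensitivity({"only": datasets["inside"]}, groups, tree, n_sim=99, seed=0)
        assert len(table) == 1

    def test_tied_identical_data_name_order(self):
        datasets, groups, tree = self._datasets()
        same = {"a_name": datasets["inside"], "b_name": datasets["inside"]}
        table = curve_sensitivity(same, groups, tree, n_sim=99, seed=0)
        assert list(table["curve_definition"]) == ["a_name", "b_name"]
        assert table["separation_F"].iloc[0] == pytest.approx(table["separation_F"].iloc[1])

    def test_missing_specimens_rejected(self):
        datasets, groups, tree = self._datasets()
        short = {"inside": datasets["inside"], "outside": datasets["outside"][:-1]}
        with pytest.raises(ValueError, match="mismatch"):
            curve_sensitivity(short, groups, tree, n_sim=99, seed=0)
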