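"""Eigenshape morphometrics: semi-landmarks, phi functions, SVD, CVA."""

import numpy as np
import pandas as pd
import pytest

from floralsignals.eigenshape import (
    CanonicalVariates,
    GeometryError,
    Outline,
    cva_two_group,
    eigenshape_decompose,
    group_distance_test,
    interpolate_semilandmarks,
    nearest_group_distance,
    outlines_to_phi_matrix,
    read_outlines_csv,
    read_outlines_tps,
    retain_axes,
    to_phi,
)
from floralsignals.synthetic_data import gen_outlines


def similarity(pts, angle=0.0, scale=1.0, shift=(0.0, 0.0)):
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return scale * pts @ R.T + np.asarray(shift)


class TestSemilandmarks:
    def test_straight_segment_equal_spacing(self):
        o = Outline(points=[[0, 0], [0.3, 0], [1, 0]])
        out = interpolate_semilandmarks(o, m=5)
        np.testing.assert_allclose(out.points[:, 0], [0, 0.25, 0.5, 0.75, 1.0], atol=1e-12)
        np.testing.assert_allclose(out.points[:, 1], 0, atol=1e-12)

    def test_idempotent_on_equally_spaced_points(self):
        t = np.linspace(0, 1, 40)
        o = Outline(points=np.column_stack([t, np.zeros_like(t)]))
        out = interpolate_semilandmarks(o, m=40)
        np.testing.assert_allclose(out.points, o.points, atol=1e-12)

    def test_quarter_circle_equal_chords(self):
        th = np.linspace(0, np.pi / 2, 2000)
        o = Outline(points=np.column_stack([np.cos(th), np.sin(th)]))
        out = interpolate_semilandmarks(o, m=91)
        chords = np.linalg.norm(np.diff(out.points, axis=0), axis=1)
        assert chords.max() - chords.min() < 1e-6

    def test_anchors_preserved_exactly(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.uniform(0.1, 1, (20, 2)), axis=0)
        out = interpolate_semilandmarks(Outline(points=pts), m=33)
        np.testing.assert_array_equal(out.points[0], pts[0])
        np.testing.assert_array_equal(out.points[-1], pts[-1])


class TestPhi:
    def test_straight_segment_is_zero(self):
        t = np.linspace(0, 1, 20)
        o = Outline(points=np.column_stack([t, 2 * t]))
        np.testing.assert_allclose(to_phi(o), 0.0, atol=1e-12)

    def test_similarity_invariance(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 1, 50)
        pts = np.column_stack([t, 0.2 * np.sin(2 * np.pi * t) + 0.05 * rng.standard_normal(50)])
        a = to_phi(Outline(points=pts))
        b = to_phi(Outline(points=similarity(pts, angle=np.deg2rad(37), scale=3.0, shift=(5, -2))))
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_semicircle_linear_tangent_angles(self):
        th = np.linspace(np.pi, 0, 181)  # upper unit semicircle, left to right
        o = Outline(points=np.column_stack([np.cos(th), np.sin(th)]))
        phi = to_phi(o)
        # tangent angle sweeps linearly from ~ +pi/2 to ~ -pi/2 around the chord
        assert phi[0] == pytest.approx(np.pi / 2, abs=0.02)
        assert phi[-1] == pytest.approx(-np.pi / 2, abs=0.02)
        np.testing.assert_allclose(np.diff(phi), np.diff(phi).mean(), atol=1e-6)

    def test_coincident_points_rejected(self):
        with pytest.raises(GeometryError):
            Outline(points=[[0, 0], [0, 0], [1, 0]])


class TestDecomposition:
    def test_identical_specimens_zero_variance(self):
        phi = np.tile(np.linspace(0, 1, 30), (5, 1))
        r = eigenshape_decompose(phi)
        assert r.n_axes == 0 or np.all(r.eigenvalues < 1e-20)
        np.testing.assert_allclose(r.scores, 0.0, atol=1e-10)

    def test_two_specimens_rank_one(self):
        rng = np.random.default_rng(2)
        phi = rng.standard_normal((2, 40))
        r = eigenshape_decompose(phi)
        assert r.n_axes == 1
        np.testing.assert_allclose(r.scores[0], -r.scores[1], atol=1e-10)

    def test_matches_independent_covariance_eigendecomposition(self):
        rng = np.random.default_rng(3)
        phi = rng.standard_normal((20, 50))
        r = eigenshape_decompose(phi)
        # oracle: dense eigendecomposition of the explicit covariance matrix
        C = np.cov(phi, rowvar=False, ddof=1)
        w = np.linalg.eigvalsh(C)[::-1]
        np.testing.assert_allclose(r.eigenvalues, w[: r.n_axes], atol=1e-8)
        assert r.eigenvalues.sum() == pytest.approx(np.trace(C), rel=1e-8)

    def test_full_reconstruction_and_orthogonality(self):
        rng = np.random.default_rng(4)
        phi = rng.standard_normal((20, 50))
        r = eigenshape_decompose(phi)
        recon = r.scores @ r.axes + r.mean_phi
        np.testing.assert_allclose(recon, phi, atol=1e-8)
        gram = r.axes @ r.axes.T
        np.testing.assert_allclose(gram, np.eye(r.n_axes), atol=1e-8)
        score_gram = r.scores.T @ r.scores
        np.testing.assert_allclose(score_gram, np.diag(np.diag(score_gram)), atol=1e-8)

    def test_retention_rule(self):
        rng = np.random.default_rng(5)
        phi = rng.standard_normal((10, 20))
        r = eigenshape_decompose(phi)
        # synthetic variance fractions: cumulative-sum rule
        r.variance_fraction = np.array([0.8, 0.15, 0.05] + [0.0] * (r.n_axes - 3))
        assert retain_axes(r, 0.90).n_axes == 2
        assert retain_axes(r, 1.0).n_axes == r.n_axes

    def test_pipeline_similarity_invariance(self):
        outlines = gen_outlines(n_per_group=5, seed=6)
        moved = [
            Outline(
                points=similarity(o.points, angle=0.9, scale=2.5, shift=(3, 1)),
                species=o.species,
                group=o.group,
                family=o.family,
                specimen_id=o.specimen_id,
            )
            for o in outlines
        ]
        phi_a, _ = outlines_to_phi_matrix(outlines, m=80)
        phi_b, _ = outlines_to_phi_matrix(moved, m=80)
        ra, rb = eigenshape_decompose(phi_a), eigenshape_decompose(phi_b)
        np.testing.assert_allclose(ra.eigenvalues, rb.eigenvalues, atol=1e-8)
        np.testing.assert_allclose(np.abs(ra.scores), np.abs(rb.scores), atol=1e-8)


class TestNearestDistances:
    def test_trivial_cases(self):
        scores = np.array([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0]])
        fam = ["Malpighiaceae", "Orchidaceae", "Orchidaceae"]
        d = nearest_group_distance(scores, fam)
        assert np.isnan(d[0])
        assert d[1] == pytest.approx(5.0)
        assert d[2] == pytest.approx(0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        scores = rng.standard_normal((30, 6))
        fam = np.array(["Malpighiaceae"] * 6 + ["A"] * 12 + ["B"] * 12)
        d = nearest_group_distance(scores, fam)
        for i in range(6, 30):
            brute = min(np.linalg.norm(scores[i] - scores[j]) for j in range(6))
            assert d[i] == pytest.approx(brute, abs=1e-12)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            nearest_group_distance(np.zeros((3, 2)), ["A", "A", "B"], "Malpighiaceae")


class TestGroupDistanceTest:
    def test_identical_groups_uninformative(self):
        rng = np.random.default_rng(8)
        d = np.concatenate([rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)])
        g = ["yellow-Oncidiinae"] * 10 + ["other-angiosperms"] * 10
        res = group_distance_test(d, g)
        assert 0.1 < res.p < 0.9

    def test_zero_vs_one_separation(self):
        d = np.array([0.0, 0.001, 0.002, 1.0, 1.01, 0.99])
        g = ["yellow-Oncidiinae"] * 3 + ["other-angiosperms"] * 3
        res = group_distance_test(d, g)
        assert res.p < 1e-4

    def test_exclusion_list_applied(self):
        d = np.array([0.0, 0.0, 5.0, 1.0, 1.0, 1.0])
        g = ["yellow-Oncidiinae"] * 3 + ["other-angiosperms"] * 3
        labels = ["a", "b", "outlier", "c", "d", "e"]
        with_out = group_distance_test(d, g)
        without = group_distance_test(d, g, exclude=["outlier"], labels=labels)
        assert without.p < with_out.p
        assert without.n_a == 2

    def test_welch_arithmetic(self):
        from scipy import stats

        a = np.array([0.1, 0.2, 0.15, 0.12])
        b = np.array([0.5, 0.45, 0.6])
        res = group_distance_test(
            np.concatenate([a, b]),
            ["yellow-Oncidiinae"] * 4 + ["other-angiosperms"] * 3,
        )
        sa2, sb2 = a.var(ddof=1) / 4, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / np.sqrt(sa2 + sb2)
        df = (sa2 + sb2) ** 2 / (sa2**2 / 3 + sb2**2 / 2)
        assert res.t == pytest.approx(t)
        assert res.df == pytest.approx(df)
        assert res.p == pytest.approx(stats.t.cdf(t, df))


class TestCVA:
    def test_two_groups_give_single_axis(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 1, (10, 4)), rng.normal(3, 1, (10, 4))])
        y = np.array(["a"] * 10 + ["b"] * 10)
        est = CanonicalVariates().fit(X, y)
        assert est.coef_.shape == (4,)

    def test_perfect_separation(self):
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(0, 0.1, (8, 3)), rng.normal(5, 0.1, (8, 3))])
        y = np.array(["a"] * 8 + ["b"] * 8)
        for validation in ("resubstitution", "leave-one-out"):
            res = cva_two_group(X, y, validation=validation)
            assert res.classification_rate == 1.0
            assert res.confusion.sum() == 16

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((24, 3))
        rates = []
        for _ in range(40):
            y = np.array(["a"] * 12 + ["b"] * 12)
            rng.shuffle(y)
            rates.append(cva_two_group(X, y, validation="leave-one-out").classification_rate)
        assert 0.35 < np.mean(rates) < 0.65

    def test_one_dimensional_reduces_to_threshold(self):
        # brute-force best threshold rule on 1-D scores
        X = np.array([[0.1], [0.2], [0.3], [0.9], [1.0], [1.1]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        res = cva_two_group(X, y)
        assert res.classification_rate == 1.0
        est = CanonicalVariates().fit(X, y)
        # midpoint threshold sits between the group means
        cut = est.threshold_ / est.coef_[0]
        assert 0.3 < cut < 0.9

    def test_regularization_flagged_when_underdetermined(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((6, 10))  # more axes than specimens
        y = np.array(["a"] * 3 + ["b"] * 3)
        est = CanonicalVariates().fit(X, y)
        assert est.regularized_
        assert np.isfinite(est.coef_).all()

    def test_sklearn_param_interface(self):
        est = CanonicalVariates(ridge=1e-6)
        assert est.get_params() == {"ridge": 1e-6}
        est.set_params(ridge=1e-3)
        assert est.ridge == 1e-3


class TestOutlineIO:
    def test_csv_roundtrip(self, tmp_path):
        outlines = gen_outlines(n_per_group=2, m=20, seed=13)
        rows, meta = [], []
        for o in outlines:
            for i, (x, y) in enumerate(o.points):
                rows.append({"specimen_id": o.specimen_id, "point_index": i, "x": x, "y": y})
            meta.append(
                {
                    "specimen_id": o.specimen_id,
                    "species": o.species,
                    "group": o.group,
                    "family": o.family,
                }
            )
        cp, mp = tmp_path / "c.csv", tmp_path / "m.csv"
        pd.DataFrame(rows).to_csv(cp, index=False)
        pd.DataFrame(meta).to_csv(mp, index=False)
        back = read_outlines_csv(cp, mp)
        assert len(back) == len(outlines)
        by_id = {o.specimen_id: o for o in outlines}
        for o in back:
            np.testing.assert_allclose(o.points, by_id[o.specimen_id].points)
            assert o.group == by_id[o.specimen_id].group

    def test_tps_reader(self, tmp_path):
        tps = tmp_path / "o.tps"
        tps.write_text("LM=3\n0.0 0.0\n0.5 0.2\n1.0 0.0\nID=spec1\nLM=3\n0 0\n0.4 -0.1\n1 0\nID=spec2\n")
        outlines = read_outlines_tps(tps)
        assert [o.specimen_id for o in outlines] == ["spec1", "spec2"]
        np.testing.assert_allclose(outlines[0].points[1], [0.5, 0.2])
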