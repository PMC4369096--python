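"""QDA/CVA biplot layouts: Phi, PCA scores, back-projection, regions, axes."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

import qdabiplot as q
import qdabiplot.biplot as bp
from qdabiplot.discriminant import phi_squared_matrix, qda_classify_matrix


class TestBuildPhiMatrix:
    def test_columns_standardized(self, three_group_model):
        Phi = three_group_model.Phi
        assert np.all(np.abs(Phi.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(Phi.std(axis=0, ddof=1) - 1.0) < 1e-10)

    def test_duplicate_classes_give_identical_raw_columns(self):
        rng = np.random.default_rng(8)
        block = rng.normal(size=(30, 3))
        d = q.centre_and_index(np.vstack([block, block]), ["a"] * 30 + ["b"] * 30)
        m = q.fit_quadratic(d)
        raw = phi_squared_matrix(d.X, m)
        assert_allclose(raw[:, 0], raw[:, 1], atol=1e-10)

    def test_raw_columns_match_per_sample_oracle(self, three_group_data, three_group_model):
        raw = (
            three_group_model.Phi * three_group_model.phi_sds
            + three_group_model.phi_means
        )
        for i in range(0, three_group_data.n, 7):
            for j in range(3):
                assert_allclose(
                    raw[i, j],
                    q.phi_squared(three_group_data.X[i], three_group_model, j),
                    atol=1e-10,
                )


class TestQdaScores:
    def test_two_group_representation_is_lossless(self, two_group_data):
        m = q.build_phi_matrix(two_group_data, q.fit_quadratic(two_group_data))
        lay = q.qda_scores(m, r=2)
        recon = lay.scores @ lay.loadings.T
        assert np.sum((recon - m.Phi) ** 2) < 1e-10

    def test_score_orthogonality(self, three_group_layout):
        gram = three_group_layout.scores.T @ three_group_layout.scores
        assert abs(gram[0, 1]) < 1e-8

    def test_component_variance_ordering(self, three_group_layout):
        v = three_group_layout.scores.var(axis=0)
        assert v[0] >= v[1]

    def test_loadings_orthonormal(self, three_group_layout):
        L = three_group_layout.loadings
        assert_allclose(L.T @ L, np.eye(2), atol=1e-10)

    def test_r_exceeding_class_count_rejected(self, three_group_model):
        with pytest.raises(ValueError, match="r=4"):
            q.qda_scores(three_group_model, r=4)

    def test_requires_phi(self, three_group_data):
        m = q.fit_quadratic(three_group_data)
        with pytest.raises(ValueError, match="Phi not built"):
            q.qda_scores(m)


class TestBackProject:
    def test_lossless_for_two_groups(self, two_group_data):
        m = q.build_phi_matrix(two_group_data, q.fit_quadratic(two_group_data))
        lay = q.qda_scores(m, r=2)
        raw = phi_squared_matrix(two_group_data.X, m)
        for i in range(0, 200, 13):
            assert_allclose(q.back_project(lay.scores[i], lay), raw[i], atol=1e-8)

    def test_origin_maps_to_column_means(self, three_group_layout, three_group_model):
        assert_allclose(
            q.back_project(np.zeros(2), three_group_layout),
            three_group_model.phi_means,
            atol=1e-12,
        )

    def test_matches_truncated_reconstruction_oracle(self, three_group_model, three_group_layout):
        # rank-2 truncated SVD reconstruction of Phi, un-standardized
        Phi = three_group_model.Phi
        U, s, Vt = np.linalg.svd(Phi, full_matrices=False)
        recon = (U[:, :2] * s[:2]) @ Vt[:2]
        raw_recon = recon * three_group_model.phi_sds + three_group_model.phi_means
        for i in range(0, 150, 11):
            assert_allclose(
                q.back_project(three_group_layout.scores[i], three_group_layout),
                raw_recon[i],
                atol=1e-8,
            )

    def test_undefined_for_cva(self, three_group_data):
        canon = q.canonical_transform(
            q.scatter_decomposition(three_group_data), three_group_data, r=2
        )
        lay = q.cva_layout(canon, three_group_data)
        with pytest.raises(ValueError, match="cva"):
            q.back_project(np.zeros(2), lay)


class TestClassifyDisplayPoint:
    def test_smaller_phi_wins_equal_priors(self, two_group_data):
        m = q.build_phi_matrix(
            two_group_data, q.fit_quadratic(two_group_data, priors="equal")
        )
        lay = q.two_group_plot(two_group_data, m, scaled=False)
        # display coordinates ARE raw (phi_1^2, phi_2^2): (3, 5) favours class 1
        assert q.classify_display_point(np.array([3.0, 5.0]), lay) == 0
        assert q.classify_display_point(np.array([5.0, 3.0]), lay) == 1

    def test_prior_decides_at_equal_phi(self, two_group_data):
        m = q.build_phi_matrix(
            two_group_data, q.fit_quadratic(two_group_data, priors=[0.99, 0.01])
        )
        lay = q.two_group_plot(two_group_data, m, scaled=False)
        assert q.classify_display_point(np.array([4.0, 4.0]), lay) == 0

    def test_training_scores_match_direct_qda(self, two_group_data):
        m = q.build_phi_matrix(
            two_group_data, q.fit_quadratic(two_group_data, priors="equal")
        )
        lay = q.qda_scores(m, r=2)
        display = bp.classify_display_points(lay.scores, lay)
        direct = qda_classify_matrix(two_group_data.X, m)
        assert np.array_equal(display, direct)


class TestRegionGrid:
    def test_resolution_two_gives_four_points(self, three_group_layout):
        g = q.build_region_grid(three_group_layout, resolution=2)
        assert g.labels.shape == (2, 2) and g.labels.size == 4

    def test_every_point_matches_oracle(self, three_group_layout):
        g = q.build_region_grid(three_group_layout, resolution=9)
        for iy, y in enumerate(g.y):
            for ix, x in enumerate(g.x):
                assert g.labels[iy, ix] == q.classify_display_point(
                    np.array([x, y]), three_group_layout
                )

    def test_refinement_preserves_existing_labels(self, three_group_layout):
        coarse = q.build_region_grid(three_group_layout, resolution=5)
        fine = q.build_region_grid(three_group_layout, resolution=9)  # nested: 2k-1
        assert_allclose(fine.x[::2], coarse.x, atol=1e-12)
        assert np.array_equal(fine.labels[::2, ::2], coarse.labels)

    def test_two_group_boundary_is_identity_line(self, two_group_data):
        """Equal priors, unscaled display: labels flip exactly at y = x."""
        m = q.build_phi_matrix(
            two_group_data, q.fit_quadratic(two_group_data, priors="equal")
        )
        lay = q.two_group_plot(two_group_data, m, scaled=False)
        g = q.build_region_grid(lay, resolution=60)
        XX, YY = np.meshgrid(g.x, g.y)
        assert np.array_equal(g.labels == 0, XX <= YY)

    def test_min_resolution(self, three_group_layout):
        with pytest.raises(ValueError, match="resolution"):
            q.build_region_grid(three_group_layout, resolution=1)


class TestTwoGroupPlot:
    def test_scaled_is_unscaled_over_sds(self, two_group_data):
        m = q.build_phi_matrix(two_group_data, q.fit_quadratic(two_group_data))
        unscaled = q.two_group_plot(two_group_data, m, scaled=False)
        scaled = q.two_group_plot(two_group_data, m, scaled=True)
        raw = phi_squared_matrix(two_group_data.X, m)
        sds = raw.std(axis=0, ddof=1)
        assert_allclose(scaled.scores, unscaled.scores / sds, atol=1e-12)

    def test_samples_above_identity_line_are_class_one(self, two_group_data):
        m = q.build_phi_matrix(
            two_group_data, q.fit_quadratic(two_group_data, priors="equal")
        )
        lay = q.two_group_plot(two_group_data, m, scaled=False)
        labels = bp.classify_display_points(lay.scores, lay)
        above = lay.scores[:, 1] > lay.scores[:, 0]
        assert np.array_equal(labels == 0, above | (lay.scores[:, 1] == lay.scores[:, 0]))

    def test_three_groups_rejected(self, three_group_data, three_group_model):
        with pytest.raises(ValueError, match="qda_scores"):
            q.two_group_plot(three_group_data, three_group_model)


@pytest.fixture(scope="module")
def cva(three_group_data):
    canon = q.canonical_transform(
        q.scatter_decomposition(three_group_data), three_group_data, r=2
    )
    return q.cva_layout(canon, three_group_data, priors="proportional")


class TestCvaLayout:
    def test_grid_matches_lda_oracle(self, cva, three_group_data):
        g = q.build_region_grid(cva, resolution=7)
        scale = three_group_data.n - three_group_data.J
        for iy, y in enumerate(g.y):
            for ix, x in enumerate(g.x):
                expect = q.lda_classify(
                    [x, y], cva.class_means_display, cva.priors, scale
                )
                assert g.labels[iy, ix] == expect

    def test_boundaries_are_perpendicular_bisectors(self):
        """Equal priors and symmetric canonical means: points equidistant from
        two means lie on the boundary; closer points classify to the closer mean."""
        rng = np.random.default_rng(19)
        # three symmetric clusters with shared covariance
        means = np.array([[0.0, 0.0], [4.0, 0.0], [2.0, 3.0]])
        raw = np.vstack([rng.normal(size=(40, 2)) + mu for mu in means])
        d = q.centre_and_index(raw, sum([[f"g{j}"] * 40 for j in range(3)], []))
        canon = q.canonical_transform(q.scatter_decomposition(d), d, r=2)
        lay = q.cva_layout(canon, d, priors="equal")
        cm = lay.class_means_display
        for a in range(3):
            for b in range(a + 1, 3):
                mid = (cm[a] + cm[b]) / 2
                d_all = np.sum((cm - mid) ** 2, axis=1)
                # the midpoint is equidistant from a and b; if no third mean is
                # closer the tie-break assigns the lower index
                if d_all.min() >= d_all[a] - 1e-12:
                    assert q.classify_display_point(mid, lay) == a

    def test_class_score_means_equal_plotted_means(self, cva, three_group_data):
        for j in range(3):
            avg = cva.scores[three_group_data.groups == j].mean(axis=0)
            assert_allclose(avg, cva.class_means_display[j], atol=1e-10)

    def test_two_class_layout_is_rank_one(self, two_group_data):
        with pytest.warns(UserWarning):
            canon = q.canonical_transform(
                q.scatter_decomposition(two_group_data), two_group_data, r=2
            )
            lay = q.cva_layout(canon, two_group_data)
        assert_allclose(lay.scores[:, 1], 0.0)


class TestRegressionAxes:
    def test_calibration_reproduces_least_squares_fit(self, three_group_data, three_group_layout):
        axes = q.regression_axes(three_group_layout, three_group_data)
        Z = three_group_layout.scores
        for k, ax in enumerate(axes):
            b = ax.direction
            fitted = Z @ b + ax.centre_value
            # read-off: project each score onto the axis, read the calibrated value
            read = (Z @ b) / (b @ b) * (b @ b) + ax.centre_value
            assert_allclose(read, fitted, atol=1e-12)
            # markers are placed so position (v - centre)/(b'b) * b projects to v
            for v, pos in ax.markers:
                t = (pos @ b) / (b @ b)
                assert_allclose(t * (b @ b) + ax.centre_value, v, atol=1e-9)

    def test_variable_equal_to_pc1_gives_horizontal_axis(self, three_group_data, three_group_model):
        lay = q.qda_scores(three_group_model, r=2)
        fake = q.centre_and_index(
            np.column_stack([lay.scores[:, 0] + 5.0, three_group_data.X[:, 0]]),
            [three_group_data.class_labels[g] for g in three_group_data.groups],
        )
        axes = q.regression_axes(lay, fake, which_variables=[0])
        b = axes[0].direction
        assert abs(b[1]) < 1e-8 * abs(b[0])

    def test_direction_matches_normal_equations_oracle(self, three_group_data, three_group_layout):
        axes = q.regression_axes(three_group_layout, three_group_data)
        Z = three_group_layout.scores
        ZtZ = Z.T @ Z
        det = ZtZ[0, 0] * ZtZ[1, 1] - ZtZ[0, 1] * ZtZ[1, 0]
        inv = np.array([[ZtZ[1, 1], -ZtZ[0, 1]], [-ZtZ[1, 0], ZtZ[0, 0]]]) / det
        for k, ax in enumerate(axes):
            oracle = inv @ (Z.T @ three_group_data.X[:, k])
            assert_allclose(ax.direction, oracle, atol=1e-10)

    def test_binary_variable_markers_at_zero_and_one(self, two_group_binary_data):
        m = q.build_phi_matrix(
            two_group_binary_data, q.fit_quadratic(two_group_binary_data)
        )
        lay = q.qda_scores(m, r=2)
        axes = q.regression_axes(lay, two_group_binary_data)
        for ax in axes:
            assert [v for v, _ in ax.markers] == [0.0, 1.0]

    def test_markers_collinear_along_direction(self, three_group_data, three_group_layout):
        axes = q.regression_axes(three_group_layout, three_group_data)
        for ax in axes:
            d = ax.direction / np.linalg.norm(ax.direction)
            normal = np.array([-d[1], d[0]])
            for _, pos in ax.markers:
                assert abs((pos - ax.offset) @ normal) < 1e-10


class TestTranslateAxes:
    def test_offset_orthogonal_to_direction(self, three_group_data, three_group_layout):
        axes = q.regression_axes(three_group_layout, three_group_data)
        q.translate_axes(axes, three_group_layout, strategy="hull-clear")
        for ax in axes:
            assert abs(ax.offset @ ax.direction) < 1e-10 * np.linalg.norm(
                ax.direction
            ) * max(1.0, np.linalg.norm(ax.offset))

    def test_none_strategy_zero_offsets(self, three_group_data, three_group_layout):
        axes = q.regression_axes(three_group_layout, three_group_data)
        q.translate_axes(axes, three_group_layout, strategy="hull-clear")
        q.translate_axes(axes, three_group_layout, strategy="none")
        for ax in axes:
            assert_allclose(ax.offset, 0.0, atol=1e-15)

    def test_translated_segments_clear_sample_hull(self, three_group_data, three_group_layout):
        from scipy.spatial import ConvexHull, Delaunay

        axes = q.regression_axes(three_group_layout, three_group_data)
        q.translate_axes(axes, three_group_layout, strategy="hull-clear")
        hull = Delaunay(
            three_group_layout.scores[
                ConvexHull(three_group_layout.scores).vertices
            ]
        )
        for ax in axes:
            positions = np.array([p for _, p in ax.markers])
            # sample densely along the drawn segment
            t = np.linspace(0, 1, 200)[:, None]
            seg = positions[0] + t * (positions[-1] - positions[0])
            assert np.all(hull.find_simplex(seg) < 0)

    def test_read_off_invariant_under_translation(self, three_group_data, three_group_layout):
        axes = q.regression_axes(three_group_layout, three_group_data)
        before = [[(v, pos.copy()) for v, pos in ax.markers] for ax in axes]
        q.translate_axes(axes, three_group_layout, strategy="hull-clear")
        Z = three_group_layout.scores
        for ax, orig_markers in zip(axes, before):
            b = ax.direction
            for (v0, p0), (v1, p1) in zip(orig_markers, ax.markers):
                assert v0 == v1
                # projection of any score difference onto the axis is unchanged
                assert_allclose((p1 - p0) @ b, 0.0, atol=1e-9)


class TestCollapsePatterns:
    def test_at_most_16_patterns_for_4_binary_variables(self, two_group_binary_data):
        table = q.collapse_patterns(two_group_binary_data)
        assert 1 <= len(table) <= 16
        assert table["multiplicity"].sum() == two_group_binary_data.n

    def test_majority_vote(self):
        raw = np.array([[0, 1]] * 4 + [[1, 0]] * 2, dtype=float)
        labels = ["a", "a", "a", "b", "b", "b"]
        d = q.centre_and_index(raw, labels)
        table = q.collapse_patterns(d).sort_values("V1").reset_index(drop=True)
        # pattern (0,1): 3 x a, 1 x b -> majority a; pattern (1,0): 2 x b -> b
        assert table.loc[0, "display_class"] == "a"
        assert table.loc[1, "display_class"] == "b"

    def test_tie_goes_to_lowest_class_index(self):
        raw = np.array([[0.0, 1.0]] * 4, dtype=float)
        d = q.centre_and_index(
            np.vstack([raw, [[1, 0], [1, 0]]]), ["a", "a", "b", "b", "a", "b"]
        )
        table = q.collapse_patterns(d)
        row = table[table["V1"] == 0].iloc[0]
        assert row["count_a"] == 2 and row["count_b"] == 2
        assert row["display_class"] == "a"

    def test_rejects_non_binary(self, three_group_data):
        with pytest.raises(ValueError, match="binary"):
            q.collapse_patterns(three_group_data)
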