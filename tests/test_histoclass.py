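import numpy as np
import pandas as pd
import pytest

import mmmp
from mmmp.extract import MMMPMatrix
from mmmp.histoclass import (AnnotationSet, ablate_channels,
                             annotate_from_phantom, apply_model_cross_sample,
                             checkerboard_partition, cross_predict,
                             feature_profiles, he_channels, train_lda)

from conftest import small_panel_spec


def synthetic_matrix(means, ns, seed=0, sd=1.0, canvas=(60, 60)):
    """Labeled pixels drawn from Gaussian class profiles; returns
    (matrix, annotation) on a compact canvas."""
    rng = np.random.default_rng(seed)
    means = np.asarray(means, dtype=float)
    d = means.shape[1]
    rows, labels = [], []
    for cid, (mu, n) in enumerate(zip(means, ns), start=1):
        rows.append(rng.normal(mu, sd, size=(n, d)))
        labels += [cid] * n
    data = np.vstack(rows)
    labels = np.array(labels)
    total = len(labels)
    assert total <= canvas[0] * canvas[1]
    order = rng.permutation(total)      # scatter classes over the canvas
    flat = np.arange(total)
    coords = np.stack([flat // canvas[1], flat % canvas[1]], axis=1)
    data, labels = data[order], labels[order]
    mat = MMMPMatrix(data=data, coords=coords,
                     channel_names=[f"ch{j}" for j in range(d)],
                     canvas_shape=canvas)
    lab_img = np.zeros(canvas, dtype=np.int64)
    lab_img[coords[:, 0], coords[:, 1]] = labels
    ann = AnnotationSet(label_image=lab_img,
                        names={i + 1: f"f{i + 1}"
                               for i in range(len(means))})
    return mat, ann


class TestFeatureProfiles:
    def test_disjoint_signatures_all_specific(self):
        mat, ann = synthetic_matrix([[0, 0], [100, 100]], [300, 300],
                                    sd=1.0)
        fp = feature_profiles(mat, ann, k=5, seed=0)
        assert fp.fraction_specific == 1.0
        assert len(fp.centroids) == 10

    def test_identical_distributions_mostly_nonspecific(self):
        # two features drawn from the same distribution: their centroid
        # sets interleave, and because centroids within one set repel each
        # other (quantizer spacing) while the other set's positions are
        # uncorrelated, the nearest neighbor is usually from the other
        # feature -- specificity collapses
        mat, ann = synthetic_matrix([[50, 50], [50, 50]], [600, 600],
                                    sd=10.0, seed=3)
        fp = feature_profiles(mat, ann, k=40, seed=0)
        assert fp.fraction_specific < 0.3

    def test_single_category_trivially_specific(self):
        mat, ann = synthetic_matrix([[10, 10]], [200], sd=5.0)
        fp = feature_profiles(mat, ann, k=8, seed=0)
        assert fp.fraction_specific == 1.0

    def test_absent_category_rejected(self):
        mat, ann = synthetic_matrix([[0, 0]], [100])
        ann.label_image = ann.label_image.copy()
        ann.names[9] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            feature_profiles(mat, ann, k=4, seed=0)


class TestCheckerboardPartition:
    def test_parity_rule_holds_everywhere(self):
        mat, ann = synthetic_matrix([[0, 0], [5, 5]], [1000, 1000],
                                    canvas=(60, 60))
        grid = checkerboard_partition(ann, candidates=(16, 8))
        g = grid.grid_size
        rr, cc = np.indices(ann.label_image.shape)
        expect = ((rr // g + cc // g) % 2 + 1)
        np.testing.assert_array_equal(grid.region_image, expect)

    def test_single_category_selects_largest_candidate(self):
        lab = np.zeros((220, 220), dtype=int)
        lab[:150, :150] = 1
        ann = AnnotationSet(label_image=lab, names={1: "only"})
        grid = checkerboard_partition(ann)
        assert grid.grid_size == 100
        assert grid.candidates_tried == [100]

    def test_rare_category_forces_smaller_grid(self):
        # rare category confined to one 100-px square, but spanning two
        # 50-px squares of opposite parity -> 50 must be selected
        lab = np.zeros((200, 200), dtype=int)
        lab[:, :] = 1
        lab[10, 45:55] = 2      # crosses the col=50 boundary, rows < 100
        ann = AnnotationSet(label_image=lab, names={1: "common", 2: "rare"})
        grid = checkerboard_partition(ann, candidates=(100, 50, 20))
        assert grid.grid_size == 50
        assert grid.candidates_tried == [100, 50]

    def test_infeasible_candidates_raise(self):
        lab = np.zeros((200, 200), dtype=int)
        lab[0, 0] = 1           # a single annotated pixel per category
        lab[0, 1] = 2
        ann = AnnotationSet(label_image=lab, names={1: "a", 2: "b"})
        with pytest.raises(ValueError, match="smaller"):
            checkerboard_partition(ann, candidates=(100, 50, 20))

    def test_candidate_order_irrelevant(self):
        mat, ann = synthetic_matrix([[0, 0], [5, 5]], [1200, 1200],
                                    canvas=(60, 60))
        a = checkerboard_partition(ann, candidates=(20, 8, 12))
        b = checkerboard_partition(ann, candidates=(8, 12, 20))
        assert a.grid_size == b.grid_size


class TestLDA:
    def test_two_gaussian_boundary_at_midpoint(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 4000),
                            rng.normal(10, 1, 4000)])[:, None]
        y = np.repeat([1, 2], 4000)
        model = train_lda(x, y)
        grid = np.linspace(0, 10, 2001)[:, None]
        pred = model.predict(grid)
        boundary = grid[np.argmax(pred == 2), 0]
        assert boundary == pytest.approx(5.0, abs=0.2)

    def test_interior_point_classified_to_its_class(self):
        x = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 10.0], [11.0, 10.0]])
        y = np.array([1, 1, 2, 2])
        model = train_lda(x, y)
        assert model.predict(np.array([[0.4, 0.1]]))[0] == 1
        assert model.predict(np.array([[10.5, 9.9]]))[0] == 2

    def test_predictions_match_bruteforce_discriminant_scores(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(300, 4)) + rng.integers(0, 3, 300)[:, None] * 3
        y = rng.integers(0, 3, 300) + 1
        x += y[:, None]
        model = train_lda(x, y)
        query = rng.normal(5, 3, size=(500, 4))
        inv = np.linalg.inv(model.covariance)
        scores = np.stack([
            q @ inv @ model.means.T
            - 0.5 * np.einsum("cd,de,ce->c", model.means, inv, model.means)
            + np.log(model.priors)
            for q in query])
        np.testing.assert_array_equal(model.predict(query),
                                      model.classes[scores.argmax(1)])

    def test_agreement_with_sklearn_reference(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(2)
        means = np.array([[0, 0, 0], [6, 0, 0], [0, 6, 0]])
        x = np.vstack([rng.normal(m, 1.5, size=(200, 3)) for m in means])
        y = np.repeat([1, 2, 3], 200)
        ours = train_lda(x, y, ridge=0.0)
        ref = LinearDiscriminantAnalysis().fit(x, y)
        agree = (ours.predict(x) == ref.predict(x)).mean()
        assert agree > 0.999

    def test_small_class_rejected(self):
        x = np.zeros((3, 2))
        y = np.array([1, 1, 2])
        with pytest.raises(ValueError, match="fewer than 2"):
            train_lda(x, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            train_lda(np.zeros((4, 2)), np.ones(4))


class TestCrossPredict:
    def test_separable_classes_fully_recovered(self):
        mat, ann = synthetic_matrix([[0, 0], [60, 0], [0, 60]],
                                    [800, 800, 800], sd=2.0, canvas=(60, 60))
        grid = checkerboard_partition(ann, candidates=(16, 8))
        _, cm = cross_predict(mat, ann, grid)
        assert (cm.per_feature_accuracy == 100.0).all()

    def test_shuffled_labels_fall_to_chance(self):
        rng = np.random.default_rng(4)
        mat, ann = synthetic_matrix([[10, 10]] * 4, [600] * 4, sd=5.0,
                                    seed=4, canvas=(60, 60))
        grid = checkerboard_partition(ann, candidates=(8,))
        _, cm = cross_predict(mat, ann, grid)
        assert cm.mean_accuracy == pytest.approx(25.0, abs=6.0)

    def test_confusion_rows_sum_to_annotated_counts(self):
        mat, ann = synthetic_matrix([[0, 0], [30, 0]], [500, 700], sd=3.0,
                                    canvas=(60, 60))
        grid = checkerboard_partition(ann, candidates=(16, 8))
        _, cm = cross_predict(mat, ann, grid)
        assert cm.counts.loc["f1"].sum() == 500
        assert cm.counts.loc["f2"].sum() == 700

    def test_folds_are_pixel_disjoint(self):
        mat, ann = synthetic_matrix([[0, 0], [30, 0]], [500, 500],
                                    canvas=(60, 60))
        grid = checkerboard_partition(ann, candidates=(16, 8))
        r = grid.region_at(mat.coords)
        assert set(np.unique(r)) == {1, 2}
        assert ((r == 1) & (r == 2)).sum() == 0

    def test_every_foreground_pixel_predicted(self):
        mat, ann = synthetic_matrix([[0, 0], [30, 0]], [500, 500],
                                    canvas=(60, 60))
        grid = checkerboard_partition(ann, candidates=(16, 8))
        pred, _ = cross_predict(mat, ann, grid)
        assert (pred[mat.coords[:, 0], mat.coords[:, 1]] > 0).all()


class TestAblation:
    def test_full_subset_is_noop(self):
        mat, ann = synthetic_matrix([[0, 0], [30, 0]], [400, 400], sd=3.0,
                                    canvas=(60, 60))
        grid = checkerboard_partition(ann, candidates=(16, 8))
        res = ablate_channels(mat, ann, grid, list(mat.channel_names))
        pd.testing.assert_frame_equal(res.full.counts, res.subset.counts)

    def test_removing_only_discriminative_channel_drops_to_chance(self):
        # two classes identical except in channel 0
        mat, ann = synthetic_matrix([[0, 20], [40, 20]], [600, 600],
                                    sd=2.0, canvas=(60, 60))
        grid = checkerboard_partition(ann, candidates=(16, 8))
        res = ablate_channels(mat, ann, grid, ["ch1"])
        assert (res.full.per_feature_accuracy > 99).all()
        assert res.subset.mean_accuracy == pytest.approx(50.0, abs=8.0)

    def test_he_preset_selects_rgb_columns(self, small_matrix):
        subset = he_channels(small_matrix.channel_names)
        assert subset == ["HE_R", "HE_G", "HE_B"]

    def test_unknown_channel_rejected(self):
        mat, ann = synthetic_matrix([[0, 0], [30, 0]], [300, 300],
                                    canvas=(60, 60))
        grid = checkerboard_partition(ann, candidates=(8,))
        with pytest.raises(ValueError, match="unknown"):
            ablate_channels(mat, ann, grid, ["bogus"])


class TestCrossSample:
    def test_same_matrix_reproduces_predictions(self):
        mat, ann = synthetic_matrix([[0, 0], [30, 0]], [400, 400], sd=3.0,
                                    canvas=(60, 60))
        labels = ann.labels_at(mat.coords)
        model = train_lda(mat.data, labels,
                          channel_names=mat.channel_names)
        img = apply_model_cross_sample(model, mat)
        direct = model.predict(mat.data)
        np.testing.assert_array_equal(
            img[mat.coords[:, 0], mat.coords[:, 1]], direct)

    def test_permuted_channel_order_rejected(self):
        mat, ann = synthetic_matrix([[0, 0], [30, 0]], [400, 400],
                                    canvas=(60, 60))
        labels = ann.labels_at(mat.coords)
        model = train_lda(mat.data, labels,
                          channel_names=mat.channel_names)
        permuted = mat.subset_channels(mat.channel_names[::-1])
        with pytest.raises(ValueError, match="mismatch"):
            apply_model_cross_sample(model, permuted)

    def test_generalizes_across_same_distribution_samples(self):
        mat1, ann1 = synthetic_matrix([[0, 0], [25, 0], [0, 25]],
                                      [500, 500, 500], sd=4.0, seed=7,
                                      canvas=(60, 60))
        mat2, ann2 = synthetic_matrix([[0, 0], [25, 0], [0, 25]],
                                      [500, 500, 500], sd=4.0, seed=8,
                                      canvas=(60, 60))
        labels1 = ann1.labels_at(mat1.coords)
        model = train_lda(mat1.data, labels1,
                          channel_names=mat1.channel_names)
        intra = (model.predict(mat1.data) == labels1).mean() * 100
        labels2 = ann2.labels_at(mat2.coords)
        cross = (model.predict(mat2.data) == labels2).mean() * 100
        assert cross >= intra - 5.0


class TestAnnotationIO:
    def test_png_round_trip(self, tmp_path):
        _, ann = synthetic_matrix([[0, 0], [30, 0]], [200, 200],
                                  canvas=(60, 60))
        ann.to_png(tmp_path / "ann.png", tmp_path / "legend.json")
        back = AnnotationSet.from_png(tmp_path / "ann.png",
                                      tmp_path / "legend.json")
        np.testing.assert_array_equal(back.label_image, ann.label_image)
        assert back.names == ann.names
        assert back.colors == ann.colors

    def test_unnamed_label_rejected(self):
        lab = np.zeros((4, 4), dtype=int)
        lab[0, 0] = 3
        with pytest.raises(ValueError, match="without a name"):
            AnnotationSet(label_image=lab, names={1: "a"})

    def test_phantom_annotation_covers_features(self):
        spec = small_panel_spec(seed=42)
        truth = mmmp.make_phantom_core(spec)
        ann = annotate_from_phantom(truth)
        assert set(ann.names.values()) == {"ecm", "muscle", "epithelium",
                                           "vessels", "nuclei"}
        np.testing.assert_array_equal(ann.label_image, truth.label_image)
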