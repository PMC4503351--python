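"""Supervised automated histology.

Annotated histological features (epithelium, muscle, vessels, ...) are
related to the per-pixel channel matrix three ways: per-feature k-means
finds feature-specific molecular profiles (a centroid is feature-specific
when its nearest neighbor among all centroids shares its feature); a
spatially interleaved checkerboard partition splits the annotated area into
two reciprocal train/test folds; and linear discriminant analysis (LDA)
trained on each fold predicts the other, with a confusion matrix and
per-feature accuracies summarizing the merged predictions.  Ablating
channel subsets (e.g. H&E only) quantifies how much the multiplexed panel
adds over conventional staining.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .extract import MMMPMatrix
from .profile import kmeans_profiles

DEFAULT_GRID_CANDIDATES = (100, 50, 20)
DEFAULT_RIDGE = 1e-4


# --------------------------------------------------------------------------
# annotations
# --------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """Per-pixel categorical feature labels (0 = unannotated) plus legend."""

    label_image: np.ndarray
    names: dict[int, str]
    colors: dict[int, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = set(np.unique(self.label_image)) - {0}
        unnamed = present - set(self.names)
        if unnamed:
            raise ValueError(f"labels without a name: {sorted(unnamed)}")
        if not self.colors:
            # arbitrary distinct display colors, stable per label id
            rng = np.random.default_rng(12345)
            self.colors = {i: tuple(int(v) for v in rng.integers(40, 255, 3))
                           for i in self.names}

    @property
    def category_ids(self) -> list[int]:
        return sorted(self.names)

    def labels_at(self, coords: np.ndarray) -> np.ndarray:
        return self.label_image[coords[:, 0], coords[:, 1]]

    def render(self, labels: np.ndarray | None = None) -> np.ndarray:
        """Color image of an annotation (or prediction) label map."""
        lab = self.label_image if labels is None else labels
        img = np.zeros(lab.shape + (3,), dtype=np.uint8)
        for i, rgb in self.colors.items():
            img[lab == i] = rgb
        return img

    # ---- indexed-PNG + JSON-legend round trip ----------------------------
    def to_png(self, png_path: str | Path, legend_path: str | Path) -> None:
        from PIL import Image

        if self.label_image.max() > 255:
            raise ValueError("more than 255 categories; cannot index PNG")
        im = Image.fromarray(self.label_image.astype(np.uint8), mode="P")
        palette = np.zeros((256, 3), dtype=np.uint8)
        for i, rgb in self.colors.items():
            palette[i] = rgb
        im.putpalette(palette.flatten().tolist())
        im.save(png_path)
        legend = {str(i): {"name": self.names[i],
                           "color": list(self.colors[i])}
                  for i in self.names}
        Path(legend_path).write_text(json.dumps(legend, indent=2))

    @classmethod
    def from_png(cls, png_path: str | Path,
                 legend_path: str | Path) -> "AnnotationSet":
        from PIL import Image

        lab = np.asarray(Image.open(png_path)).astype(np.int32)
        legend = json.loads(Path(legend_path).read_text())
        names = {int(i): v["name"] for i, v in legend.items()}
        colors = {int(i): tuple(v["color"]) for i, v in legend.items()}
        return cls(label_image=lab, names=names, colors=colors)


def annotate_from_phantom(truth, categories: list[str] | None = None
                          ) -> AnnotationSet:
    """Turn a phantom's ground-truth labels into an annotation set
    (every labeled feature, or a chosen subset, becomes a category)."""
    if categories is None:
        categories = [n for n, i in truth.feature_ids.items() if i != 0]
    lab = np.zeros_like(truth.label_image)
    names = {}
    for name in categories:
        fid = truth.feature_ids[name]
        if fid == 0:
            continue
        lab[truth.label_image == fid] = fid
        names[fid] = name
    return AnnotationSet(label_image=lab, names=names)


# --------------------------------------------------------------------------
# feature-specific profiles
# --------------------------------------------------------------------------

@dataclass
class FeatureProfileSet:
    centroids: pd.DataFrame     # columns = channels; index (feature, cluster)
    specific: pd.Series         # bool per centroid

    @property
    def fraction_specific(self) -> float:
        return float(self.specific.mean())


def feature_profiles(matrix: MMMPMatrix, ann: AnnotationSet, k: int = 100,
                     seed: int | None = 0) -> FeatureProfileSet:
    """k-means separately within each annotated category, then flag each
    centroid as feature-specific iff its nearest neighbor among all other
    centroids (Euclidean) belongs to the same category."""
    labels = ann.labels_at(matrix.coords)
    frames = []
    for cid in ann.category_ids:
        rows = matrix.data[labels == cid]
        if len(rows) == 0:
            raise ValueError(f"category {ann.names[cid]!r} absent from the "
                             "matrix")
        kk = min(k, len(np.unique(rows, axis=0)))
        if kk < k:
            warnings.warn(f"category {ann.names[cid]!r}: k reduced to {kk}",
                          stacklevel=2)
        model = kmeans_profiles(rows, k=kk, seed=seed)
        idx = pd.MultiIndex.from_product([[ann.names[cid]], range(model.k)],
                                         names=["feature", "cluster"])
        frames.append(pd.DataFrame(model.centroids, index=idx,
                                   columns=matrix.channel_names))
    cent = pd.concat(frames)
    x = cent.to_numpy()
    d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    feats = cent.index.get_level_values("feature").to_numpy()
    specific = pd.Series(feats[nn] == feats, index=cent.index)
    return FeatureProfileSet(centroids=cent, specific=specific)


# --------------------------------------------------------------------------
# checkerboard partition
# --------------------------------------------------------------------------

@dataclass
class PartitionGrid:
    grid_size: int
    region_image: np.ndarray        # 1 or 2 everywhere
    candidates_tried: list[int]

    def region_at(self, coords: np.ndarray) -> np.ndarray:
        return self.region_image[coords[:, 0], coords[:, 1]]


def checkerboard_partition(ann: AnnotationSet,
                           candidates=DEFAULT_GRID_CANDIDATES
                           ) -> PartitionGrid:
    """Alternating square grid splitting the image into two interleaved
    regions; the selected edge length is the largest candidate for which
    both regions contain at least one pixel of every annotated category."""
    lab = ann.label_image
    if (lab != 0).sum() < 2:
        raise ValueError("need at least 2 annotated pixels")
    cats = ann.category_ids
    tried = []
    for g in sorted(candidates, reverse=True):
        tried.append(g)
        rr, cc = np.indices(lab.shape)
        region = ((rr // g + cc // g) % 2 + 1).astype(np.uint8)
        ok = all((lab[region == r] == cid).any()
                 for cid in cats for r in (1, 2))
        if ok:
            return PartitionGrid(grid_size=g, region_image=region,
                                 candidates_tried=tried)
    raise ValueError(
        f"no candidate grid size in {sorted(candidates, reverse=True)} puts "
        "every category in both regions; try smaller sizes")


# --------------------------------------------------------------------------
# LDA
# --------------------------------------------------------------------------

@dataclass
class LDAModel:
    classes: np.ndarray
    means: np.ndarray               # (n_classes, d)
    covariance: np.ndarray          # pooled within-class, regularized
    priors: np.ndarray
    channel_names: list[str] | None = None

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        """Linear discriminant score per class (shared covariance)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        inv = np.linalg.inv(self.covariance)
        w = self.means @ inv                          # (C, d)
        b = (-0.5 * np.einsum("cd,cd->c", w, self.means)
             + np.log(self.priors))
        return x @ w.T + b

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes[self.decision_scores(x).argmax(axis=1)]


def train_lda(x: np.ndarray, y: np.ndarray,
              ridge: float = DEFAULT_RIDGE,
              uniform_priors: bool = False,
              channel_names: list[str] | None = None) -> LDAModel:
    """LDA: class means, pooled within-class covariance with a relative
    ridge (``ridge * trace/d`` added to the diagonal), empirical priors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    small = classes[counts < 2]
    if len(small):
        raise ValueError(f"classes with fewer than 2 training pixels: "
                         f"{small.tolist()}")
    d = x.shape[1]
    means = np.stack([x[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((d, d))
    for c, mu in zip(classes, means):
        xc = x[y == c] - mu
        pooled += xc.T @ xc
    pooled /= (len(x) - len(classes))
    tr = np.trace(pooled)
    pooled += ridge * (tr / d if tr > 0 else 1.0) * np.eye(d)
    priors = (np.full(len(classes), 1.0 / len(classes)) if uniform_priors
              else counts / counts.sum())
    return LDAModel(classes=classes, means=means, covariance=pooled,
                    priors=priors, channel_names=channel_names)


# --------------------------------------------------------------------------
# reciprocal checkerboard classification
# --------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    counts: pd.DataFrame            # rows = true feature, cols = predicted

    def __post_init__(self) -> None:
        acc = 100.0 * np.diag(self.counts.to_numpy()) \
            / self.counts.sum(axis=1).to_numpy()
        self.per_feature_accuracy = pd.Series(acc, index=self.counts.index)

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_feature_accuracy.mean())

    @property
    def median_accuracy(self) -> float:
        return float(self.per_feature_accuracy.median())


def _confusion(true_lab, pred_lab, ann: AnnotationSet) -> ConfusionMatrix:
    cats = ann.category_ids
    names = [ann.names[c] for c in cats]
    m = np.zeros((len(cats), len(cats)), dtype=int)
    cat_arr = np.asarray(cats)
    ti = np.searchsorted(cat_arr, true_lab)
    pi = np.searchsorted(cat_arr, pred_lab)
    np.add.at(m, (ti, pi), 1)
    return ConfusionMatrix(counts=pd.DataFrame(m, index=names,
                                               columns=names))


def cross_predict(matrix: MMMPMatrix, ann: AnnotationSet,
                  grid: PartitionGrid,
                  channel_subset: list[str] | None = None,
                  ridge: float = DEFAULT_RIDGE,
                  uniform_priors: bool = False
                  ) -> tuple[np.ndarray, ConfusionMatrix]:
    """Reciprocal checkerboard LDA classification.

    Train on region 1 / predict region 2, then the reverse; the two
    disjoint prediction sets are merged into one label image covering every
    foreground pixel.  The confusion matrix counts annotated pixels only;
    per-feature accuracy is the percentage of that feature's annotated
    pixels predicted correctly.
    """
    work = (matrix.subset_channels(channel_subset)
            if channel_subset is not None else matrix)
    labels = ann.labels_at(work.coords)
    regions = grid.region_at(work.coords)
    annotated = labels != 0

    pred = np.zeros(len(labels), dtype=np.int64)
    for train_r, test_r in ((1, 2), (2, 1)):
        tr = annotated & (regions == train_r)
        model = train_lda(work.data[tr], labels[tr], ridge=ridge,
                          uniform_priors=uniform_priors,
                          channel_names=work.channel_names)
        te = regions == test_r
        pred[te] = model.predict(work.data[te])

    pred_image = np.zeros(ann.label_image.shape, dtype=np.int64)
    pred_image[work.coords[:, 0], work.coords[:, 1]] = pred
    cm = _confusion(labels[annotated], pred[annotated], ann)
    counts_per_cat = pd.Series(labels[annotated]).value_counts()
    assert all(cm.counts.sum(axis=1)[ann.names[c]] == counts_per_cat[c]
               for c in counts_per_cat.index)
    return pred_image, cm


@dataclass
class AblationResult:
    full: ConfusionMatrix
    subset: ConfusionMatrix
    channel_subset: list[str]

    @property
    def paired_accuracy(self) -> pd.DataFrame:
        return pd.DataFrame({
            "full": self.full.per_feature_accuracy,
            "subset": self.subset.per_feature_accuracy})


def he_channels(channel_names: list[str], stain: str = "HE") -> list[str]:
    """The RGB columns of the H&E brightfield cycle."""
    subset = [n for n in channel_names
              if n in (f"{stain}_R", f"{stain}_G", f"{stain}_B")]
    if not subset:
        raise ValueError(f"no {stain} channels in {channel_names}")
    return subset


def ablate_channels(matrix: MMMPMatrix, ann: AnnotationSet,
                    grid: PartitionGrid, subset: list[str],
                    **kwargs) -> AblationResult:
    """Rerun the reciprocal classification restricted to ``subset`` and pair
    its per-feature accuracies with the full-panel result."""
    if not subset:
        raise ValueError("channel subset is empty")
    missing = [s for s in subset if s not in matrix.channel_names]
    if missing:
        raise ValueError(f"unknown channels: {missing}")
    _, full = cross_predict(matrix, ann, grid, **kwargs)
    _, sub = cross_predict(matrix, ann, grid, channel_subset=subset,
                           **kwargs)
    return AblationResult(full=full, subset=sub, channel_subset=list(subset))


def apply_model_cross_sample(model: LDAModel,
                             other_matrix: MMMPMatrix) -> np.ndarray:
    """Predict every foreground pixel of an unannotated sample with a model
    trained elsewhere; returns the predicted label image (no accuracy — the
    other sample has no truth)."""
    if model.channel_names is not None and \
            list(other_matrix.channel_names) != list(model.channel_names):
        raise ValueError(
            f"channel layout mismatch: model has {model.channel_names}, "
            f"matrix has {other_matrix.channel_names}")
    pred = model.predict(other_matrix.data)
    img = np.zeros(other_matrix.canvas_shape, dtype=np.int64)
    img[other_matrix.coords[:, 0], other_matrix.coords[:, 1]] = pred
    return img
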