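"""Unsupervised per-pixel profiling.

PCA summarises the standardized channel matrix; k-means (Hartigan-Wong
transfer algorithm, k = 100 by default) partitions pixels into recurrent
molecular profiles; Kruskal's nonmetric MDS embeds the cluster centroids in
3-D and the axes become RGB so that molecularly similar clusters get similar
colors; imputation r-squared quantifies how faithfully the centroids
reproduce the original intensities; and centroids from many samples can be
pooled into one global matrix with a universal color palette.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.manifold import MDS

from .extract import MMMPMatrix


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, MMMPMatrix):
        return np.asarray(matrix.data, dtype=float)
    return np.asarray(matrix, dtype=float)


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PCASummary:
    loadings: np.ndarray            # (n_components, n_channels)
    variance_fraction: np.ndarray
    cumulative_variance: np.ndarray
    scores: np.ndarray              # (n_pixels, n_components)
    channel_names: list[str]
    dropped_channels: list[str] = field(default_factory=list)

    def score_image(self, component: int, matrix: MMMPMatrix) -> np.ndarray:
        """Per-pixel component-score image, min-max scaled to 0-255."""
        s = self.scores[:, component]
        lo, hi = s.min(), s.max()
        scaled = np.zeros_like(s) if hi - lo < 1e-12 else \
            (s - lo) / (hi - lo) * 255.0
        img = np.zeros(matrix.canvas_shape, dtype=np.uint8)
        img[matrix.coords[:, 0], matrix.coords[:, 1]] = \
            np.rint(scaled).astype(np.uint8)
        return img


def pca_summary(matrix) -> PCASummary:
    """PCA of the channel-standardized matrix (zero mean, unit variance).

    Zero-variance channels are dropped with a warning; components are
    ordered by decreasing explained variance.
    """
    x = _as_array(matrix)
    names = (matrix.channel_names if isinstance(matrix, MMMPMatrix)
             else [f"ch{j}" for j in range(x.shape[1])])
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    sd = x.std(axis=0)
    keep = sd > 1e-12
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance channels: {dropped}",
                      stacklevel=2)
    x = x[:, keep]
    if x.shape[0] < x.shape[1]:
        warnings.warn("fewer pixels than channels; PCA rank-limited",
                      stacklevel=2)
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    pca = PCA(n_components=min(z.shape))
    scores = pca.fit_transform(z)
    frac = pca.explained_variance_ratio_
    return PCASummary(loadings=pca.components_,
                      variance_fraction=frac,
                      cumulative_variance=np.cumsum(frac),
                      scores=scores,
                      channel_names=[n for n, k in zip(names, keep) if k],
                      dropped_channels=dropped)


# --------------------------------------------------------------------------
# Hartigan-Wong k-means
# --------------------------------------------------------------------------

@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray           # (k, n_channels)
    assignments: np.ndarray         # (n_pixels,) int
    wss: float
    channel_names: list[str] | None = None
    n_iter: int = 0


@njit(cache=True)
def _nearest(x, centroids, out):
    n, d = x.shape
    k = centroids.shape[0]
    for i in range(n):
        best, bj = 1e300, 0
        for j in range(k):
            s = 0.0
            for c in range(d):
                diff = x[i, c] - centroids[j, c]
                s += diff * diff
            if s < best:
                best, bj = s, j
        out[i] = bj
    return out


@njit(cache=True)
def _hartigan_passes(x, sums, counts, assign, max_iter):
    """In-place Hartigan-Wong transfer passes; returns passes used."""
    n, d = x.shape
    k = sums.shape[0]
    it = 0
    for it in range(max_iter):
        moved = 0
        for i in range(n):
            a = assign[i]
            na = counts[a]
            if na <= 1:
                continue
            # squared distance to own centroid
            da = 0.0
            for c in range(d):
                diff = x[i, c] - sums[a, c] / na
                da += diff * diff
            remove_gain = na / (na - 1.0) * da
            best_cost, best_b = 1e300, -1
            for b in range(k):
                if b == a:
                    continue
                nb = counts[b]
                db = 0.0
                for c in range(d):
                    diff = x[i, c] - sums[b, c] / nb
                    db += diff * diff
                cost = nb / (nb + 1.0) * db
                if cost < best_cost:
                    best_cost, best_b = cost, b
            if best_b >= 0 and best_cost < remove_gain - 1e-12:
                for c in range(d):
                    sums[a, c] -= x[i, c]
                    sums[best_b, c] += x[i, c]
                counts[a] -= 1
                counts[best_b] += 1
                assign[i] = best_b
                moved += 1
        if moved == 0:
            break
    return it + 1


def _lloyd_polish(x, centroids, assign, cap=2000):
    """Reassign-to-nearest / recompute until a fixed point, so the final
    model satisfies the nearest-centroid invariant exactly."""
    k = centroids.shape[0]
    for _ in range(cap):
        new = np.empty(len(x), dtype=np.int64)
        _nearest(x, centroids, new)
        if np.array_equal(new, assign):
            break
        assign = new
        for j in range(k):
            sel = assign == j
            if sel.any():
                centroids[j] = x[sel].mean(axis=0)
    return centroids, assign


def kmeans_profiles(matrix, k: int = 100, max_iter: int = 20,
                    restarts: int = 1, seed: int | None = None,
                    init: np.ndarray | None = None) -> ClusterModel:
    """Hartigan-Wong k-means on raw (unscaled) matrix rows.

    ``init`` may give explicit starting centroids; otherwise ``k`` distinct
    rows are drawn at random per restart and the lowest-WSS restart wins.
    If fewer than ``k`` distinct rows exist, ``k`` is reduced with a
    warning.  A short Lloyd polish after the transfer passes guarantees the
    final assignments are nearest-centroid.
    """
    x = np.ascontiguousarray(_as_array(matrix))
    names = matrix.channel_names if isinstance(matrix, MMMPMatrix) else None
    if k < 1:
        raise ValueError("k must be >= 1")
    distinct = np.unique(x, axis=0)
    if len(distinct) < k:
        warnings.warn(f"only {len(distinct)} distinct rows; reducing k from "
                      f"{k}", stacklevel=2)
        k = len(distinct)
    if len(x) < k:
        raise ValueError("need at least k rows")

    rng = np.random.default_rng(seed)
    best: ClusterModel | None = None
    n_starts = 1 if init is not None else max(1, restarts)
    for _ in range(n_starts):
        if init is not None:
            centroids = np.ascontiguousarray(np.asarray(init, dtype=float))
            if centroids.shape != (k, x.shape[1]):
                raise ValueError("init centroids have wrong shape")
        else:
            pick = rng.choice(len(distinct), size=k, replace=False)
            centroids = np.ascontiguousarray(distinct[pick])
        assign = np.empty(len(x), dtype=np.int64)
        _nearest(x, centroids, assign)
        sums = np.zeros_like(centroids)
        counts = np.zeros(k, dtype=np.float64)
        np.add.at(sums, assign, x)
        np.add.at(counts, assign, 1.0)
        for j in np.nonzero(counts == 0)[0]:
            # move one point out of a multi-member cluster into the empty one
            donors = np.nonzero(counts[assign] > 1)[0]
            i = int(rng.choice(donors))
            a = assign[i]
            sums[a] -= x[i]
            counts[a] -= 1.0
            sums[j] += x[i]
            counts[j] += 1.0
            assign[i] = j
        n_pass = _hartigan_passes(x, sums, counts, assign, max_iter)
        centroids = sums / counts[:, None]
        centroids, assign = _lloyd_polish(x, centroids, assign)
        wss = float(((x - centroids[assign]) ** 2).sum())
        model = ClusterModel(k=k, centroids=centroids, assignments=assign,
                             wss=wss, channel_names=names, n_iter=n_pass)
        if best is None or model.wss < best.wss:
            best = model
    return best


# --------------------------------------------------------------------------
# similarity-based color mapping
# --------------------------------------------------------------------------

@dataclass
class ColorMap:
    colors: np.ndarray              # (k, 3) float RGB in [0, 255]
    stress: float
    embedding: np.ndarray           # (k, 3) float, pre-scaling

    def __getitem__(self, cluster: int) -> np.ndarray:
        return self.colors[cluster]

    def to_dict(self) -> dict:
        return {"stress": self.stress,
                "colors": self.colors.tolist()}


def _classical_mds(dist: np.ndarray, ndim: int = 3) -> np.ndarray:
    """Torgerson scaling: eigendecomposition of the double-centered squared
    distance matrix (the classical-MDS initialisation of isoMDS)."""
    n = dist.shape[0]
    d2 = dist ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:ndim]
    vals = np.clip(vals[order], 0, None)
    out = vecs[:, order] * np.sqrt(vals)
    if out.shape[1] < ndim:
        out = np.hstack([out, np.zeros((n, ndim - out.shape[1]))])
    return out


def mds_colormap(centroids: np.ndarray, seed: int = 0) -> ColorMap:
    """Embed cluster centroids in 3-D by Kruskal's nonmetric MDS and read
    the axes as RGB.

    The embedding is initialized from classical MDS; axes are ordered by
    decreasing variance, reflections fixed by forcing positive skew, and
    the coordinates mapped into the RGB cube with a single shared scale
    (longest axis spanning 0-255), which preserves the rank order of
    pairwise distances.  The reported stress is Kruskal's normalized
    stress-1.  Duplicate centroids are collapsed before the
    embedding and share a single point, so identical profiles always get
    identical colors.
    """
    c = np.asarray(centroids, dtype=float)
    if c.ndim != 2 or len(c) < 2:
        raise ValueError("need at least 2 centroids")
    uniq, inverse = np.unique(c, axis=0, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("all centroids identical; no similarity structure")
    if len(uniq) < len(c):
        warnings.warn("duplicate centroids collapsed for MDS", stacklevel=2)
    dist = squareform(pdist(uniq))

    init = _classical_mds(dist, 3)
    mds = MDS(n_components=3, metric=False, dissimilarity="precomputed",
              n_init=1, random_state=seed, normalized_stress=True,
              eps=1e-9, max_iter=500)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = mds.fit_transform(dist, init=init)
    stress = float(mds.stress_)
    emb = emb[inverse]          # duplicates share their unique row's point

    # deterministic orientation: axes by variance, positive skew
    order = np.argsort(emb.var(axis=0))[::-1]
    emb = emb[:, order]
    for ax in range(3):
        v = emb[:, ax] - emb[:, ax].mean()
        if (v ** 3).sum() < 0:
            emb[:, ax] = -emb[:, ax]
    # one global scale factor (not per-axis) so color distances keep the
    # same rank order as centroid distances; the longest axis spans 0-255
    ranges = emb.max(axis=0) - emb.min(axis=0)
    scale = 255.0 / ranges.max() if ranges.max() > 1e-12 else 0.0
    colors = (emb - emb.min(axis=0)) * scale
    return ColorMap(colors=colors, stress=stress, embedding=emb)


def render_cluster_image(model: ClusterModel, cmap: ColorMap,
                         coords: np.ndarray,
                         canvas_shape: tuple[int, int],
                         background: tuple[int, int, int] = (0, 0, 0)
                         ) -> np.ndarray:
    """RGB image: each pixel takes its cluster's similarity-based color."""
    if model.assignments.max() >= len(cmap.colors):
        raise ValueError("colormap missing colors for some clusters")
    if len(coords) != len(model.assignments):
        raise ValueError("coords must match assignments one-to-one")
    img = np.zeros(canvas_shape + (3,), dtype=np.uint8)
    img[...] = np.asarray(background, dtype=np.uint8)
    img[coords[:, 0], coords[:, 1]] = np.clip(
        np.rint(cmap.colors[model.assignments]), 0, 255).astype(np.uint8)
    return img


# --------------------------------------------------------------------------
# imputation fidelity
# --------------------------------------------------------------------------

@dataclass
class FidelityReport:
    per_channel_r2: pd.Series
    mean_r2: float
    excluded_channels: list[str]


def imputation_r2(matrix, model: ClusterModel) -> FidelityReport:
    """Squared Pearson correlation, per channel, between the original
    intensities and the centroid-imputed ones (each pixel replaced by its
    cluster centroid).  Channels with zero variance in either vector are
    excluded from the mean and reported."""
    x = _as_array(matrix)
    if len(x) != len(model.assignments):
        raise ValueError("assignments do not match matrix rows")
    names = (matrix.channel_names if isinstance(matrix, MMMPMatrix)
             else [f"ch{j}" for j in range(x.shape[1])])
    imputed = model.centroids[model.assignments]
    r2, excluded = {}, []
    for j, name in enumerate(names):
        a, b = x[:, j], imputed[:, j]
        if a.std() < 1e-12 or b.std() < 1e-12:
            r2[name] = np.nan
            excluded.append(name)
            continue
        r = np.corrcoef(a, b)[0, 1]
        r2[name] = float(r * r)
    series = pd.Series(r2)
    return FidelityReport(per_channel_r2=series,
                         mean_r2=float(series.dropna().mean()),
                         excluded_channels=excluded)


# --------------------------------------------------------------------------
# cross-sample compilation
# --------------------------------------------------------------------------

@dataclass
class GlobalProfile:
    centroids: pd.DataFrame         # MultiIndex (sample, cluster) x channels
    linkage: np.ndarray | None
    colormap: ColorMap | None

    def sample_colormap(self, sample) -> ColorMap:
        """The universal palette restricted to one sample's clusters."""
        if self.colormap is None:
            raise ValueError("compiled without a universal colormap")
        pos = self.centroids.index.get_locs([sample])
        return ColorMap(colors=self.colormap.colors[pos],
                        stress=self.colormap.stress,
                        embedding=self.colormap.embedding[pos])


def compile_global(models: list[ClusterModel],
                   samples: list | None = None,
                   seed: int = 0, cluster_rows: bool = True,
                   fit_colormap: bool = True) -> GlobalProfile:
    """Pool every sample's cluster centroids into one matrix (rows indexed
    by (sample, cluster)), hierarchically cluster them (average linkage,
    Euclidean), and fit one universal MDS color palette on the pooled set.

    Both post-processing steps are quadratic in the pooled row count (the
    nonmetric MDS much worse); ``cluster_rows=False`` / ``fit_colormap=
    False`` skip them when only the pooled matrix is needed.
    """
    if not models:
        raise ValueError("no models to compile")
    layouts = {tuple(m.channel_names or ()) for m in models}
    widths = {m.centroids.shape[1] for m in models}
    if len(layouts) > 1 or len(widths) > 1:
        raise ValueError("models have mismatched channel layouts")
    if samples is None:
        samples = list(range(len(models)))
    names = models[0].channel_names or \
        [f"ch{j}" for j in range(models[0].centroids.shape[1])]
    frames = []
    for sid, m in zip(samples, models):
        idx = pd.MultiIndex.from_product([[sid], range(m.k)],
                                         names=["sample", "cluster"])
        frames.append(pd.DataFrame(m.centroids, index=idx, columns=names))
    pooled = pd.concat(frames)
    link = (linkage(pooled.to_numpy(), method="average", metric="euclidean")
            if cluster_rows else None)
    cmap = mds_colormap(pooled.to_numpy(), seed=seed) if fit_colormap \
        else None
    return GlobalProfile(centroids=pooled, linkage=link, colormap=cmap)
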