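"""Tile stitching with three-run consensus overlap selection.

Each imaging cycle is acquired as a grid of overlapping stage-scan tiles.
Pairwise translations between grid-adjacent tiles are estimated by phase
correlation inside a search window centered on the overlap implied by an
``overlap`` prior (in percent of the tile edge), the per-tile canvas offsets
are reconciled globally by least squares over the grid graph, and overlapping
pixels are fused with linear feather blending.

Because the true overlap is not known in advance, stitching is run with
several overlap priors (5, 8 and 10 percent by default); the run whose
per-tile offsets agree best with the coordinate-wise median consensus (summed
Euclidean distance) is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import match_template

DEFAULT_OVERLAP_PRIORS = (5.0, 8.0, 10.0)


@dataclass
class TileSet:
    """One cycle's acquisition tiles plus their nominal grid layout.

    ``tiles[i]`` is ``(h, w)`` or ``(h, w, n_channels)``; ``layout`` has one
    row per tile with columns ``tile_id, row, col, nominal_y, nominal_x``
    (grid indices and nominal top-left canvas position in pixels).
    """

    tiles: list[np.ndarray]
    layout: pd.DataFrame
    cycle_id: int = 0
    sample_id: str = ""
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        shapes = {t.shape for t in self.tiles}
        if len(shapes) > 1:
            raise ValueError(f"tiles differ in shape: {shapes}")
        pos = list(zip(self.layout["row"], self.layout["col"]))
        if len(set(pos)) != len(pos):
            raise ValueError("duplicate (row, col) grid positions in layout")

    @property
    def tile_shape(self) -> tuple[int, int]:
        return self.tiles[0].shape[:2]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (int(self.layout["row"].max()) + 1,
                int(self.layout["col"].max()) + 1)


@dataclass
class StitchResult:
    canvas: np.ndarray
    offsets: pd.DataFrame          # tile_id, y, x (inferred top-left, px)
    chosen_overlap: float
    candidate_offsets: dict[float, pd.DataFrame] = field(default_factory=dict)
    flagged_pairs: list[tuple[int, int]] = field(default_factory=list)


def _registration_image(tile: np.ndarray, channel: int | None) -> np.ndarray:
    if tile.ndim == 2:
        return tile.astype(float)
    if channel is not None:
        return tile[..., channel].astype(float)
    return tile.astype(float).mean(axis=-1)


def _pair_shift(a: np.ndarray, b: np.ndarray, axis: int, step_prior: int,
                window: int) -> tuple[np.ndarray | None, float]:
    """Estimated (dy, dx) of tile ``b`` relative to tile ``a`` for a pair
    adjacent along ``axis`` (0 = b below a, 1 = b right of a).

    The leading block of ``b`` is matched against ``a`` by normalized
    cross-correlation, with the along-axis offset restricted to
    ``step_prior +- window`` and the cross-axis offset to ``+- window``.
    Returns ``(None, 0.0)`` when the block has no texture.
    """
    size = a.shape[axis]
    cross = a.shape[1 - axis]
    length = max(4, size - step_prior - window)   # overlap depth that always
    #                                               fits a for every candidate
    if axis == 0:
        tpl = b[:length, window:cross - window]
    else:
        tpl = b[window:cross - window, :length]
    if tpl.std() < 1e-9 or a.std() < 1e-9:
        return None, 0.0
    ncc = match_template(a, tpl, pad_input=False)
    lo = int(np.clip(step_prior - window, 0, ncc.shape[axis] - 1))
    hi = int(np.clip(step_prior + window, 0, ncc.shape[axis] - 1))
    if axis == 0:
        sub = ncc[lo:hi + 1, :]
    else:
        sub = ncc[:, lo:hi + 1]
    ij = np.unravel_index(np.argmax(sub), sub.shape)
    score = float(sub[ij])
    rel = np.array([0.0, 0.0])
    rel[axis] = lo + ij[axis]
    rel[1 - axis] = ij[1 - axis] - window
    return rel, score


def stitch_tiles(tiles: TileSet, overlap_prior: float = 10.0,
                 channel: int | None = None, window: int = 12,
                 min_score: float = 0.5) -> StitchResult:
    """Assemble one cycle's tiles into a single canvas.

    Parameters
    ----------
    overlap_prior : float
        Expected tile overlap in percent of the tile edge, in ``(0, 50)``.
    channel : int, optional
        Channel used for offset estimation on multi-channel tiles
        (default: mean across channels).
    window : int
        Extra strip width (px) added around the overlap implied by the
        prior when searching for the pairwise shift.
    """
    if len(tiles.tiles) < 1:
        raise ValueError("need at least one tile")
    if not 0 < overlap_prior < 50:
        raise ValueError("overlap_prior must be in (0, 50) percent")

    th, tw = tiles.tile_shape
    lay = tiles.layout.reset_index(drop=True)
    n = len(lay)
    idx_of = {(int(r), int(c)): i
              for i, (r, c) in enumerate(zip(lay["row"], lay["col"]))}
    reg = [_registration_image(t, channel) for t in tiles.tiles]

    nominal = lay[["nominal_y", "nominal_x"]].to_numpy(float)
    if n == 1:
        offsets = pd.DataFrame({"tile_id": lay["tile_id"],
                                "y": [0.0], "x": [0.0]})
        return StitchResult(canvas=np.asarray(tiles.tiles[0], dtype=float),
                            offsets=offsets, chosen_overlap=overlap_prior)

    # --- pairwise shifts between grid-adjacent tiles -----------------------
    # an unreliable match (no texture, or the jittered overlap shrank to
    # almost nothing so the correlation peak is weak) falls back to the
    # nominal grid step with near-zero weight in the reconciliation
    pairs: list[tuple[int, int, np.ndarray, float]] = []
    flagged: list[tuple[int, int]] = []
    for (r, c), i in idx_of.items():
        for axis, (rr, cc) in enumerate([(r + 1, c), (r, c + 1)]):
            j = idx_of.get((rr, cc))
            if j is None:
                continue
            size = (th, tw)[axis]
            step_prior = int(round(size * (1 - overlap_prior / 100.0)))
            rel, score = _pair_shift(reg[i], reg[j], axis, step_prior, window)
            if rel is None or score < min_score:
                rel = nominal[j] - nominal[i]
                weight = 0.01
                flagged.append((int(lay["tile_id"][i]), int(lay["tile_id"][j])))
            else:
                weight = 1.0
            pairs.append((i, j, rel, weight))

    # --- global least squares on the grid graph ----------------------------
    # unknown per-tile positions p_i; equations p_j - p_i = rel_ij, anchored
    # at the first tile.  Axes are separable.
    a_mat = np.zeros((len(pairs) + 1, n))
    rhs = np.zeros((len(pairs) + 1, 2))
    for k, (i, j, rel, weight) in enumerate(pairs):
        a_mat[k, i], a_mat[k, j] = -weight, weight
        rhs[k] = np.asarray(rel) * weight
    a_mat[-1, 0] = 1.0   # anchor tile 0 at the origin
    pos, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    pos -= pos.min(axis=0)

    offsets = pd.DataFrame({"tile_id": lay["tile_id"],
                            "y": pos[:, 0], "x": pos[:, 1]})
    canvas = _blend(tiles.tiles, pos)
    return StitchResult(canvas=canvas, offsets=offsets,
                        chosen_overlap=overlap_prior, flagged_pairs=flagged)


def _blend(tiles: list[np.ndarray], pos: np.ndarray) -> np.ndarray:
    """Feathered linear blending at integer tile placements."""
    th, tw = tiles[0].shape[:2]
    ipos = np.rint(pos).astype(int)
    big_h = int(ipos[:, 0].max()) + th
    big_w = int(ipos[:, 1].max()) + tw
    nchan = 1 if tiles[0].ndim == 2 else tiles[0].shape[2]
    num = np.zeros((big_h, big_w, nchan))
    den = np.zeros((big_h, big_w, 1))
    wy = np.minimum(np.arange(th) + 1, th - np.arange(th)).astype(float)
    wx = np.minimum(np.arange(tw) + 1, tw - np.arange(tw)).astype(float)
    weight = np.outer(wy, wx)[..., None]
    for t, (y, x) in zip(tiles, ipos):
        data = t[..., None] if t.ndim == 2 else t
        num[y:y + th, x:x + tw] += data * weight
        den[y:y + th, x:x + tw] += weight
    with np.errstate(invalid="ignore"):
        canvas = num / np.where(den > 0, den, np.nan)
    canvas = np.nan_to_num(canvas)
    return canvas[..., 0] if nchan == 1 else canvas


def select_consensus(offsets_by_prior: dict[float, np.ndarray]
                     ) -> tuple[float, dict[float, float]]:
    """Pick the run agreeing best with the median consensus.

    The consensus offset of each tile is the coordinate-wise median across
    runs (each run anchored at tile 0); the winner minimizes the summed
    Euclidean distance of its per-tile offsets to that consensus, ties
    going to the smallest prior.  Returns (best prior, distances per run).
    """
    anchored = {p: np.asarray(off, float) - np.asarray(off, float)[0]
                for p, off in offsets_by_prior.items()}
    consensus = np.median(np.stack(list(anchored.values())), axis=0)
    dist = {p: float(np.linalg.norm(a - consensus, axis=1).sum())
            for p, a in anchored.items()}
    best = min(sorted(dist), key=lambda p: dist[p])
    return best, dist


def consensus_stitch(tiles: TileSet,
                     overlap_priors: tuple[float, ...] = DEFAULT_OVERLAP_PRIORS,
                     channel: int | None = None) -> StitchResult:
    """Stitch once per overlap prior and keep the run closest to the
    coordinate-wise median consensus (see :func:`select_consensus`)."""
    if len(overlap_priors) < 2:
        raise ValueError("need at least two overlap priors")
    runs: dict[float, StitchResult] = {}
    offsets: dict[float, np.ndarray] = {}
    for p in overlap_priors:
        res = stitch_tiles(tiles, overlap_prior=p, channel=channel)
        runs[p] = res
        offsets[p] = res.offsets[["y", "x"]].to_numpy(float)
    best, _ = select_consensus(offsets)
    result = runs[best]
    result.candidate_offsets = {p: runs[p].offsets for p in overlap_priors}
    result.chosen_overlap = best
    return result


def crop_canvas(canvas_or_result, size: int = 2300,
                background: float = 0.0) -> np.ndarray:
    """Centered crop (or symmetric pad) to ``size``x``size`` pixels."""
    canvas = (canvas_or_result.canvas
              if isinstance(canvas_or_result, StitchResult)
              else np.asarray(canvas_or_result))
    h, w = canvas.shape[:2]
    out_shape = (size, size) + canvas.shape[2:]
    out = np.full(out_shape, background, dtype=canvas.dtype)
    # source window (crop) and destination window (pad) per axis
    sy, dy = max(0, (h - size) // 2), max(0, (size - h) // 2)
    sx, dx = max(0, (w - size) // 2), max(0, (size - w) // 2)
    hh, ww = min(h, size), min(w, size)
    out[dy:dy + hh, dx:dx + ww] = canvas[sy:sy + hh, sx:sx + ww]
    return out


def align_core_grid(centroids: pd.DataFrame,
                    reference_cycle: int | None = None) -> dict:
    """Track tissue-microarray cores across cycles from their centroids.

    ``centroids`` has columns ``cycle, core_id, y, x`` (core_id is the
    per-cycle detection label, not assumed consistent across cycles).  For
    each cycle one global translation to the reference cycle is estimated
    (difference of point-set means, refined once from nearest-neighbor
    matches), then every core is matched to its nearest reference-cycle
    centroid.  Cores farther than half the minimum inter-core spacing are
    reported as dropped.

    Returns a dict with ``shifts`` (cycle -> (dy, dx)), ``matches``
    (DataFrame cycle, core_id, ref_core_id) and ``dropped``.
    """
    cycles = sorted(centroids["cycle"].unique())
    if reference_cycle is None:
        reference_cycle = cycles[0]
    ref = centroids[centroids["cycle"] == reference_cycle]
    ref_pts = ref[["y", "x"]].to_numpy(float)
    ref_ids = ref["core_id"].to_numpy()
    if len(ref_pts) < 1:
        raise ValueError("reference cycle has no cores")
    if len(ref_pts) > 1:
        d = np.linalg.norm(ref_pts[:, None] - ref_pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        max_dist = d.min() / 2.0
    else:
        max_dist = np.inf

    shifts: dict[int, tuple[float, float]] = {}
    rows, dropped = [], []
    for cyc in cycles:
        sub = centroids[centroids["cycle"] == cyc]
        pts = sub[["y", "x"]].to_numpy(float)
        shift = ref_pts.mean(axis=0) - pts.mean(axis=0)
        for _ in range(2):      # refine from trimmed nearest-neighbor matches
            moved = pts + shift
            d = np.linalg.norm(moved[:, None] - ref_pts[None, :], axis=-1)
            nearest = d.argmin(axis=1)
            ok = d[np.arange(len(pts)), nearest] <= max_dist
            if ok.sum() >= 1:
                shift = (ref_pts[nearest[ok]] - pts[ok]).mean(axis=0)
        moved = pts + shift
        d = np.linalg.norm(moved[:, None] - ref_pts[None, :], axis=-1)
        nearest = d.argmin(axis=1)
        mind = d[np.arange(len(pts)), nearest]
        shifts[cyc] = (float(shift[0]), float(shift[1]))
        matched_refs: dict[int, int] = {}
        for i, cid in enumerate(sub["core_id"]):
            if mind[i] > max_dist:
                dropped.append({"cycle": cyc, "core_id": cid,
                                "distance": float(mind[i])})
                continue
            tgt = int(nearest[i])
            if tgt in matched_refs:
                raise ValueError(
                    f"ambiguous core matching in cycle {cyc}: cores "
                    f"{matched_refs[tgt]} and {cid} both map to reference "
                    f"core {ref_ids[tgt]}")
            matched_refs[tgt] = cid
            rows.append({"cycle": cyc, "core_id": cid,
                         "ref_core_id": ref_ids[tgt]})
        # reference cores with no counterpart in this cycle are lost too
        for tgt in set(range(len(ref_pts))) - set(matched_refs):
            dropped.append({"cycle": cyc, "core_id": int(ref_ids[tgt]),
                            "distance": float("nan")})
    if dropped:
        warnings.warn(f"{len(dropped)} core(s) dropped during grid alignment",
                      stacklevel=2)
    return {"shifts": shifts,
            "matches": pd.DataFrame(rows),
            "dropped": pd.DataFrame(dropped)}
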