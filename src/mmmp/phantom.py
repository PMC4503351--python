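"""Synthetic multiplexed-imaging phantoms with full ground truth.

A phantom emulates one tissue section imaged over repeated
immunofluorescence (IF) and brightfield histochemistry cycles: a labeled
map of spatially coherent histological features (nuclei, epithelium,
vessels, muscle, extracellular matrix, lumen/background) is drawn from
parametric geometry primitives, and every imaging channel is rendered as
``signature[feature, channel] + Gaussian noise``.  DAPI is imaged in every
IF cycle; brightfield stains are rendered with their stain signal bright
("negated" orientation) internally and converted to conventional
bright-background RGB in the acquired stack, so downstream negation is
genuinely exercised.

All randomness flows through the single ``seed``: identical specs produce
bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .stitch import TileSet
from .transforms import RigidTransform, center_of

# Default panel mirroring a 15-antibody / 4-histochemical-stain design.
DEFAULT_ANTIBODIES = (
    "Lyve1", "Sparc", "Cd34", "Ace", "Mmp11", "Fzd7", "Cd105", "Col4a2",
    "Ctgf", "Bcat", "Dkk3", "Cd44", "Desmin", "Col1", "Sma",
)
DEFAULT_BF_STAINS = ("HE", "AB", "PAS", "VVG")


@dataclass(frozen=True)
class CycleDef:
    """One imaging cycle: IF (Cy5 stain + optional DAPI) or brightfield RGB."""

    index: int
    modality: str                  # "IF" or "BF"
    stain: str
    has_dapi: bool = True          # only meaningful for IF cycles

    @property
    def channel_names(self) -> tuple[str, ...]:
        if self.modality == "IF":
            names = ("DAPI",) if self.has_dapi else ()
            return names + (self.stain,)
        return tuple(f"{self.stain}_{c}" for c in "RGB")


@dataclass(frozen=True)
class FeatureDef:
    """A histological feature drawn from a geometry primitive.

    kinds: ``empty`` (lumen/background), ``field`` (space-filling matrix),
    ``bands`` (muscle layers), ``blobs`` (epithelium), ``rings`` (vessel
    walls, lumen interior reset to background), ``disks`` (nuclei).
    """

    name: str
    kind: str
    params: dict = field(default_factory=dict)


@dataclass
class PhantomSpec:
    canvas_size: tuple[int, int] = (240, 240)
    feature_set: tuple[FeatureDef, ...] = ()
    signatures: pd.DataFrame | None = None   # feature x channel, 0-255
    noise_sd: float = 5.0
    cycles: tuple[CycleDef, ...] = ()
    drift_max: tuple[float, float] = (6.0, 1.5)   # (px, deg)
    tile_shape: tuple[int, int] = (100, 100)
    overlap_frac: float = 0.1
    jitter_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [f.name for f in self.feature_set]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if not 0 < self.overlap_frac < 0.5:
            raise ValueError("overlap_frac must be in (0, 0.5)")
        if self.drift_max[0] < 0 or self.drift_max[1] < 0:
            raise ValueError("drift_max components must be >= 0")
        if self.signatures is not None:
            sig = self.signatures.to_numpy(float)
            if sig.min() < 0 or sig.max() > 255:
                raise ValueError("signature means must lie in [0, 255]")

    @property
    def n_if_cycles(self) -> int:
        return sum(c.modality == "IF" for c in self.cycles)

    @property
    def n_bf_cycles(self) -> int:
        return sum(c.modality == "BF" for c in self.cycles)


@dataclass
class PhantomTruth:
    """A generated phantom with its ground truth."""

    spec: PhantomSpec
    label_image: np.ndarray                     # feature id per pixel, 0 = bg
    feature_ids: dict[str, int]                 # name -> id (background = 0)
    channel_stack: list[dict[str, np.ndarray]]  # per cycle, as acquired
    cycle_transforms: list[RigidTransform]
    tile_offsets: dict[int, pd.DataFrame] = field(default_factory=dict)
    _pristine: list[dict[str, np.ndarray]] = field(default_factory=list,
                                                   repr=False)

    def feature_mask(self, name: str) -> np.ndarray:
        return self.label_image == self.feature_ids[name]


# --------------------------------------------------------------------------
# default study design
# --------------------------------------------------------------------------

def default_feature_set() -> tuple[FeatureDef, ...]:
    return (
        FeatureDef("background", "empty"),
        FeatureDef("ecm", "field"),
        FeatureDef("muscle", "bands",
                   {"centers": (0.62, 0.80), "thickness": 0.07}),
        FeatureDef("epithelium", "blobs", {"n": 5, "radius": 0.09}),
        FeatureDef("vessels", "rings",
                   {"n": 4, "outer": 0.05, "inner": 0.03}),
        FeatureDef("nuclei", "disks", {"n": 120, "radius": (2, 4)}),
    )


def default_signatures(features: tuple[str, ...] | None = None,
                       antibodies: tuple[str, ...] = DEFAULT_ANTIBODIES,
                       bf_stains: tuple[str, ...] = DEFAULT_BF_STAINS,
                       ) -> pd.DataFrame:
    """Feature x channel mean-intensity table on the 0-255 scale.

    Brightfield columns are in negated orientation (stain signal bright).
    Values are hand-set so every feature has a distinctive multi-channel
    profile well separated from the others.
    """
    if features is None:
        features = tuple(f.name for f in default_feature_set())
    channels = (("DAPI",) + tuple(antibodies)
                + tuple(f"{s}_{c}" for s in bf_stains for c in "RGB"))
    sig = pd.DataFrame(10.0, index=list(features), columns=list(channels))
    # histochemical stains absorb throughout the section, with absorbance
    # tracking local tissue density: every brightfield channel shares this
    # morphology (as consecutive stains of one section do), and the
    # stain-specific highlights below modulate it
    density = {"ecm": 60.0, "muscle": 90.0, "epithelium": 75.0,
               "vessels": 85.0, "nuclei": 110.0}
    bf_cols = [c for c in channels if c.rsplit("_", 1)[0] in bf_stains]
    for feat in features:
        sig.loc[feat, bf_cols] = density.get(feat, 60.0)
    if "background" in sig.index:
        sig.loc["background"] = 0.0
    high = {
        "nuclei": {"DAPI": 220, "Bcat": 60, "HE_R": 180, "HE_G": 150,
                   "HE_B": 60, "PAS_R": 60},
        "epithelium": {"Cd44": 180, "Bcat": 170, "Fzd7": 120, "Dkk3": 100,
                       "PAS_R": 140, "PAS_G": 120, "AB_B": 90, "HE_G": 60},
        "ecm": {"Col1": 200, "Sparc": 160, "Col4a2": 130, "Ctgf": 90,
                "HE_B": 120, "HE_G": 80, "VVG_G": 60},
        "muscle": {"Sma": 210, "Desmin": 190, "Mmp11": 70, "Col1": 50,
                   "HE_B": 150, "VVG_R": 110, "VVG_B": 80},
        "vessels": {"Cd34": 200, "Cd105": 170, "Ace": 130, "Lyve1": 90,
                    "Col4a2": 90, "VVG_R": 160, "VVG_G": 130, "HE_B": 70},
    }
    for feat, vals in high.items():
        if feat in sig.index:
            for ch, v in vals.items():
                if ch in sig.columns:
                    sig.loc[feat, ch] = float(v)
    return sig


def default_cycles(antibodies: tuple[str, ...] = DEFAULT_ANTIBODIES,
                   bf_stains: tuple[str, ...] = DEFAULT_BF_STAINS,
                   ) -> tuple[CycleDef, ...]:
    cycles = [CycleDef(i, "IF", ab) for i, ab in enumerate(antibodies)]
    cycles += [CycleDef(len(antibodies) + j, "BF", s)
               for j, s in enumerate(bf_stains)]
    return tuple(cycles)


def default_spec(canvas_size: tuple[int, int] = (240, 240),
                 noise_sd: float = 5.0, seed: int = 0,
                 **overrides) -> PhantomSpec:
    """The full-panel study design: 15 IF cycles plus 4 brightfield cycles."""
    return PhantomSpec(canvas_size=canvas_size,
                       feature_set=default_feature_set(),
                       signatures=default_signatures(),
                       noise_sd=noise_sd,
                       cycles=default_cycles(),
                       seed=seed, **overrides)


# --------------------------------------------------------------------------
# geometry painting
# --------------------------------------------------------------------------

def _disk_mask(shape, cy, cx, r):
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def _paint_labels(spec: PhantomSpec, rng: np.random.Generator
                  ) -> tuple[np.ndarray, dict[str, int]]:
    h, w = spec.canvas_size
    label = np.zeros((h, w), dtype=np.int32)
    # tissue = central ellipse; everything outside stays background
    yy, xx = np.ogrid[:h, :w]
    tissue = (((yy - (h - 1) / 2) / (0.48 * h)) ** 2
              + ((xx - (w - 1) / 2) / (0.48 * w)) ** 2) <= 1.0

    ids: dict[str, int] = {}
    next_id = 1
    order = {"empty": 0, "field": 1, "bands": 2, "blobs": 3,
             "rings": 4, "disks": 5}
    feats = sorted(spec.feature_set, key=lambda f: order.get(f.kind, 9))
    for feat in feats:
        if feat.kind == "empty":
            ids[feat.name] = 0
            continue
        fid = next_id
        next_id += 1
        ids[feat.name] = fid
        p = feat.params
        if feat.kind == "field":
            label[tissue] = fid
        elif feat.kind == "bands":
            for cfrac in p.get("centers", (0.6, 0.8)):
                t = p.get("thickness", 0.06)
                lo, hi = int((cfrac - t / 2) * h), int((cfrac + t / 2) * h)
                band = np.zeros_like(tissue)
                band[lo:hi, :] = True
                label[band & tissue] = fid
        elif feat.kind == "blobs":
            r0 = p.get("radius", 0.09) * min(h, w)
            for _ in range(p.get("n", 5)):
                cy = rng.uniform(0.18 * h, 0.55 * h)
                cx = rng.uniform(0.15 * w, 0.85 * w)
                # a blob = union of a few jittered overlapping disks
                for _ in range(4):
                    dy, dx = rng.normal(0, r0 / 2, size=2)
                    r = rng.uniform(0.6 * r0, r0)
                    m = _disk_mask((h, w), cy + dy, cx + dx, r)
                    label[m & tissue] = fid
        elif feat.kind == "rings":
            ro = p.get("outer", 0.05) * min(h, w)
            ri = p.get("inner", 0.03) * min(h, w)
            for _ in range(p.get("n", 4)):
                cy = rng.uniform(0.2 * h, 0.8 * h)
                cx = rng.uniform(0.2 * w, 0.8 * w)
                outer = _disk_mask((h, w), cy, cx, ro)
                inner = _disk_mask((h, w), cy, cx, ri)
                label[outer & ~inner & tissue] = fid
                label[inner & tissue] = 0       # vessel lumen
        elif feat.kind == "disks":
            rlo, rhi = p.get("radius", (2, 4))
            placed = 0
            for _ in range(20 * p.get("n", 100)):
                if placed >= p.get("n", 100):
                    break
                cy = rng.uniform(0, h)
                cx = rng.uniform(0, w)
                if not tissue[int(cy) % h, int(cx) % w]:
                    continue
                m = _disk_mask((h, w), cy, cx, rng.uniform(rlo, rhi))
                label[m & tissue] = fid
                placed += 1
        else:
            raise ValueError(f"unknown geometry kind {feat.kind!r}")
    return label, ids


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _render_channel(label: np.ndarray, lut: np.ndarray, noise_sd: float,
                    rng: np.random.Generator) -> np.ndarray:
    img = lut[label]
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_phantom_core(spec: PhantomSpec) -> PhantomTruth:
    """Generate the labeled canvas and the per-cycle acquired channel stack."""
    if not spec.feature_set:
        raise ValueError("feature_set is empty")
    if spec.signatures is None:
        raise ValueError("spec.signatures is required")
    if not spec.cycles:
        raise ValueError("spec.cycles is empty")

    needed = {ch for c in spec.cycles for ch in c.channel_names}
    missing_ch = needed - set(spec.signatures.columns)
    missing_ft = ({f.name for f in spec.feature_set}
                  - set(spec.signatures.index))
    if missing_ch or missing_ft:
        raise ValueError(
            f"signature table is missing channels {sorted(missing_ch)} / "
            f"features {sorted(missing_ft)}")

    rng = np.random.default_rng(spec.seed)
    label, ids = _paint_labels(spec, rng)

    # signature lookup tables indexed by feature id (id 0 = background)
    max_id = max(ids.values())
    name_of = {v: k for k, v in ids.items()}
    luts = {}
    for ch in needed:
        lut = np.zeros(max_id + 1)
        for fid in range(max_id + 1):
            if fid in name_of:
                lut[fid] = float(spec.signatures.loc[name_of[fid], ch])
        luts[ch] = lut

    stack: list[dict[str, np.ndarray]] = []
    for cyc in spec.cycles:
        chans: dict[str, np.ndarray] = {}
        for ch in cyc.channel_names:
            img = _render_channel(label, luts[ch], spec.noise_sd, rng)
            if cyc.modality == "BF":
                img = 255 - img     # acquired brightfield: bright background
            chans[ch] = img
        stack.append(chans)

    truth = PhantomTruth(
        spec=spec, label_image=label, feature_ids=ids, channel_stack=stack,
        cycle_transforms=[RigidTransform.identity(frame="cycle0")
                          for _ in spec.cycles],
        _pristine=[{k: v.copy() for k, v in c.items()} for c in stack])
    return truth


# --------------------------------------------------------------------------
# inter-cycle drift
# --------------------------------------------------------------------------

def perturb_cycle(truth: PhantomTruth, cycle: int,
                  shift: tuple[float, float] = (0.0, 0.0),
                  angle: float = 0.0) -> dict[str, np.ndarray]:
    """Apply an additional rigid drift (``shift`` = (dx, dy) px, ``angle``
    in degrees, about the canvas center) to one cycle's acquired images.

    The drift composes with any previously applied drift; images are always
    re-rendered from the pristine stack so repeated perturbations do not
    accumulate interpolation error.  Returns the perturbed channel dict.
    """
    max_shift, max_rot = truth.spec.drift_max
    if np.hypot(*shift) > max_shift + 1e-9 or abs(angle) > max_rot + 1e-9:
        raise ValueError("requested drift exceeds spec.drift_max")
    h, w = truth.spec.canvas_size
    new = RigidTransform(rotation_deg=angle, translation=tuple(shift),
                         center=center_of((h, w)))
    composed = new.compose(truth.cycle_transforms[cycle])
    truth.cycle_transforms[cycle] = composed
    bg = {ch: (255.0 if truth.spec.cycles[cycle].modality == "BF" else 0.0)
          for ch in truth.channel_stack[cycle]}
    truth.channel_stack[cycle] = {
        ch: composed.warp_image(img, order=1, cval=bg[ch])
        for ch, img in truth._pristine[cycle].items()}
    return truth.channel_stack[cycle]


def apply_random_drifts(truth: PhantomTruth,
                        rng: np.random.Generator | int | None = None) -> None:
    """Draw one drift per cycle (cycle 0 stays at identity), uniform within
    ``spec.drift_max``."""
    rng = np.random.default_rng(rng)
    mx, mr = truth.spec.drift_max
    for c in range(1, len(truth.spec.cycles)):
        dx, dy = rng.uniform(-mx / np.sqrt(2), mx / np.sqrt(2), size=2)
        ang = rng.uniform(-mr, mr)
        perturb_cycle(truth, c, (dx, dy), ang)


# --------------------------------------------------------------------------
# tiling
# --------------------------------------------------------------------------

def _pad_slice(img: np.ndarray, y: int, x: int, th: int, tw: int,
               cval: float) -> np.ndarray:
    """Read a (th, tw) window at (y, x), padding with ``cval`` off-canvas."""
    h, w = img.shape[:2]
    out = np.full((th, tw) + img.shape[2:], cval, dtype=img.dtype)
    ys, xs = max(0, y), max(0, x)
    ye, xe = min(h, y + th), min(w, x + tw)
    if ye > ys and xe > xs:
        out[ys - y:ye - y, xs - x:xe - x] = img[ys:ye, xs:xe]
    return out


def tile_phantom(truth: PhantomTruth, cycle: int) -> TileSet:
    """Cut one cycle's canvas into a grid of overlapping tiles.

    Nominal positions sit on a grid with step ``tile * (1 - overlap_frac)``;
    the acquired (true) position of each tile is jittered by
    ``N(0, jitter_sd)`` rounded to whole pixels and recorded in
    ``truth.tile_offsets[cycle]``.  Tiles protruding past the canvas are
    padded with the background value, so the union always covers the canvas.
    """
    spec = truth.spec
    h, w = spec.canvas_size
    th, tw = spec.tile_shape
    if th > h or tw > w:
        raise ValueError("tile_shape larger than canvas")
    if cycle < 0 or cycle >= len(spec.cycles):
        raise IndexError(f"no cycle {cycle}")

    step_y = int(round(th * (1 - spec.overlap_frac)))
    step_x = int(round(tw * (1 - spec.overlap_frac)))
    n_r = max(1, int(np.ceil((h - th) / step_y)) + 1)
    n_c = max(1, int(np.ceil((w - tw) / step_x)) + 1)

    chans = truth.channel_stack[cycle]
    names = tuple(chans)
    cube = np.stack([chans[n].astype(float) for n in names], axis=-1)
    bg = 255.0 if spec.cycles[cycle].modality == "BF" else 0.0

    rng = np.random.default_rng((spec.seed, 7919, cycle))
    tiles, rows = [], []
    tid = 0
    for r in range(n_r):
        for c in range(n_c):
            ny, nx = r * step_y, c * step_x
            jy, jx = ((0, 0) if spec.jitter_sd == 0 else
                      np.rint(rng.normal(0, spec.jitter_sd, 2)).astype(int))
            ty, tx = ny + int(jy), nx + int(jx)
            tiles.append(_pad_slice(cube, ty, tx, th, tw, bg))
            rows.append({"tile_id": tid, "row": r, "col": c,
                         "nominal_y": ny, "nominal_x": nx,
                         "true_y": ty, "true_x": tx})
            tid += 1
    layout = pd.DataFrame(rows)
    truth.tile_offsets[cycle] = layout.copy()
    return TileSet(tiles=tiles,
                   layout=layout[["tile_id", "row", "col",
                                  "nominal_y", "nominal_x"]],
                   cycle_id=cycle, channel_names=names)


# --------------------------------------------------------------------------
# disk output
# --------------------------------------------------------------------------

def write_phantom(truth: PhantomTruth, outdir: str | Path,
                  write_tiles: bool = False) -> None:
    """Write per-cycle TIFFs, the tile-layout CSV and a ground-truth JSON.

    With ``write_tiles`` the acquisition tiles of every cycle are written
    too (one multi-channel TIFF per tile plus a per-cycle layout CSV with
    a ``filename`` column), ready for the stitching stage.
    """
    import tifffile

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if write_tiles:
        tiledir = out / "tiles"
        tiledir.mkdir(exist_ok=True)
        for cyc in truth.spec.cycles:
            ts = tile_phantom(truth, cyc.index)
            names = []
            for tid, tile in enumerate(ts.tiles):
                name = f"cycle{cyc.index:02d}_tile{tid:03d}.tif"
                tifffile.imwrite(tiledir / name,
                                 np.clip(tile, 0, 255).astype(np.uint8))
                names.append(name)
            lay = ts.layout.copy()
            lay["filename"] = names
            lay.to_csv(tiledir / f"layout_cycle{cyc.index:02d}.csv",
                       index=False)
    for cyc in truth.spec.cycles:
        chans = truth.channel_stack[cyc.index]
        if cyc.modality == "BF":
            rgb = np.stack([chans[f"{cyc.stain}_{c}"] for c in "RGB"],
                           axis=-1).astype(np.uint8)
            tifffile.imwrite(
                out / f"cycle{cyc.index:02d}_BF_{cyc.stain}.tif", rgb)
        else:
            for ch, img in chans.items():
                tifffile.imwrite(
                    out / f"cycle{cyc.index:02d}_IF_{cyc.stain}_{ch}.tif",
                    img.astype(np.uint8))
    if truth.tile_offsets:
        pd.concat([df.assign(cycle=c)
                   for c, df in truth.tile_offsets.items()]
                  ).to_csv(out / "tile_layout.csv", index=False)
    tifffile.imwrite(out / "label_image.tif",
                     truth.label_image.astype(np.uint16))
    meta = {
        "feature_ids": truth.feature_ids,
        "cycles": [{"index": c.index, "modality": c.modality,
                    "stain": c.stain, "has_dapi": c.has_dapi}
                   for c in truth.spec.cycles],
        "cycle_transforms": [t.to_dict() for t in truth.cycle_transforms],
        "canvas_size": list(truth.spec.canvas_size),
        "noise_sd": truth.spec.noise_sd,
        "seed": truth.spec.seed,
    }
    (out / "truth.json").write_text(json.dumps(meta, indent=2))


def spec_from_yaml(path: str | Path) -> PhantomSpec:
    """Load a PhantomSpec from a YAML config (defaults fill what is absent)."""
    import yaml

    cfg = yaml.safe_load(Path(path).read_text()) or {}
    spec = default_spec()
    simple = {k: cfg[k] for k in
              ("noise_sd", "overlap_frac", "jitter_sd", "seed") if k in cfg}
    if "canvas_size" in cfg:
        simple["canvas_size"] = tuple(cfg["canvas_size"])
    if "tile_shape" in cfg:
        simple["tile_shape"] = tuple(cfg["tile_shape"])
    if "drift_max" in cfg:
        simple["drift_max"] = tuple(cfg["drift_max"])
    return replace(spec, **simple)
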