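"""Cross-cycle rigid registration on fiducial channels.

Every IF cycle carries a DAPI counterstain and every histochemistry cycle a
bright-background RGB image; after negating the brightfield, both yield a
grayscale fiducial with tissue bright on dark.  IF cycles are chained
sequentially on DAPI into the first-IF frame, brightfield cycles are chained
among themselves on negated-RGB luminance, the first brightfield cycle is
rigidly bridged to the last IF cycle, and the composed transforms are applied
to every channel of every cycle.  Pixels whose value would come from outside
the source canvas are marked invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .phantom import CycleDef
from .transforms import RigidTransform, center_of


def negate_brightfield(image: np.ndarray) -> np.ndarray:
    """Photometric negation of an 8-bit image: v -> 255 - v (an involution)."""
    img = np.asarray(image)
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError("expected 8-bit intensities in [0, 255]")
        return 255.0 - img
    return (255 - img).astype(np.uint8)


def extract_fiducial(image: np.ndarray, modality: str) -> np.ndarray:
    """Grayscale registration fiducial in [0, 1].

    IF: the DAPI channel, min-max rescaled.  Brightfield: the luminance
    (channel mean) of the negated RGB, min-max rescaled.
    """
    img = np.asarray(image, dtype=float)
    if modality == "IF":
        gray = img
    elif modality in ("BF", "brightfield"):
        gray = negate_brightfield(img).astype(float)
        if gray.ndim == 3:
            gray = gray.mean(axis=-1)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    lo, hi = gray.min(), gray.max()
    if hi - lo < 1e-12:
        raise ValueError("constant image has no registration signal")
    return (gray - lo) / (hi - lo)


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None
         ) -> float:
    """Normalized cross-correlation (Pearson) over optionally masked pixels."""
    if mask is not None:
        a, b = a[mask], b[mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom < 1e-12:
        return 0.0
    return float((a * b).sum() / denom)


def rigid_register_pair(fixed: np.ndarray, moving: np.ndarray,
                        max_rotation: float = 3.0,
                        coarse_step: float = 0.5, fine_step: float = 0.02,
                        upsample: int = 20,
                        min_similarity: float = 0.2) -> RigidTransform:
    """Rigid transform aligning ``moving`` onto ``fixed``.

    Searches rotation on a coarse-to-fine grid (about the image center); at
    each candidate angle the translation is taken from subpixel phase
    correlation and the candidate is scored by normalized cross-correlation
    over valid pixels.  ``transform.warp_image(moving)`` best matches
    ``fixed``.  A similarity below ``min_similarity`` sets
    ``transform.warning`` rather than failing.
    """
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must have the same shape")
    center = center_of(fixed.shape)

    def evaluate(angle: float) -> tuple[float, RigidTransform]:
        rot = RigidTransform(rotation_deg=angle, center=center)
        rotated = rot.warp_image(moving.astype(float))
        shift, _, _ = phase_cross_correlation(fixed.astype(float), rotated,
                                              upsample_factor=upsample,
                                              normalization=None)
        t = RigidTransform(rotation_deg=angle,
                           translation=(float(shift[1]), float(shift[0])),
                           center=center)
        aligned = t.warp_image(moving.astype(float))
        valid = t.validity_mask(fixed.shape)
        score = _ncc(fixed.astype(float), aligned, valid)
        return score, t

    if max_rotation <= 0:
        best_score, best_t = evaluate(0.0)
    else:
        coarse = np.arange(-max_rotation, max_rotation + coarse_step / 2,
                           coarse_step)
        scored = [evaluate(a) for a in coarse]
        best_score, best_t = max(scored, key=lambda st: st[0])
        step = coarse_step
        while step > fine_step / 2:     # successive 5x grid refinements
            a0 = best_t.rotation_deg
            next_step = max(step / 5.0, fine_step)
            for a in np.arange(a0 - step, a0 + step + next_step / 2,
                               next_step):
                s, t = evaluate(float(a))
                if s > best_score:
                    best_score, best_t = s, t
            step = next_step if next_step > fine_step else 0.0
    best_t.similarity = best_score  # extra diagnostic attribute
    if best_score < min_similarity:
        best_t.warning = (f"similarity {best_score:.3f} below "
                          f"{min_similarity}")
    return best_t


@dataclass
class RegisteredStack:
    """All cycles of one sample resampled into the first-IF frame."""

    images: list[dict[str, np.ndarray]]
    cycles: list[CycleDef]
    transforms: list[RigidTransform]
    validity_masks: list[np.ndarray]
    reference: str = "IF0"

    def channel(self, cycle: int, name: str) -> np.ndarray:
        return self.images[cycle][name]

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.images[0].values()))
        return first.shape[:2]


def _cycle_fiducial(channels: dict[str, np.ndarray], cyc: CycleDef
                    ) -> np.ndarray:
    if cyc.modality == "IF":
        if "DAPI" not in channels:
            raise ValueError(f"IF cycle {cyc.index} has no DAPI channel")
        return extract_fiducial(channels["DAPI"], "IF")
    rgb = np.stack([channels[f"{cyc.stain}_{c}"] for c in "RGB"], axis=-1)
    return extract_fiducial(rgb, "BF")


def register_series(stack: list[dict[str, np.ndarray]],
                    cycles: list[CycleDef],
                    max_rotation: float = 3.0,
                    min_similarity: float = 0.3,
                    **pair_kwargs) -> RegisteredStack:
    """Align a whole multi-cycle series into the first-IF frame.

    IF cycles must come first and brightfield cycles form a contiguous block
    after them.  Raises if any pairwise registration scores below
    ``min_similarity`` (naming the offending cycle pair).
    """
    modal = [c.modality for c in cycles]
    if "IF" not in modal:
        raise ValueError("need at least one IF cycle")
    n_if = modal.index("BF") if "BF" in modal else len(modal)
    if any(m != "IF" for m in modal[:n_if]) or \
       any(m != "BF" for m in modal[n_if:]):
        raise ValueError("cycles must be all IF then all brightfield")

    fids = [_cycle_fiducial(chs, cyc) for chs, cyc in zip(stack, cycles)]

    def pair(fixed_i: int, moving_i: int) -> RigidTransform:
        t = rigid_register_pair(fids[fixed_i], fids[moving_i],
                                max_rotation=max_rotation,
                                min_similarity=min_similarity, **pair_kwargs)
        if t.warning is not None:
            raise ValueError(
                f"registration of cycle {cycles[moving_i].index} onto cycle "
                f"{cycles[fixed_i].index} failed: {t.warning}")
        return t

    transforms: list[RigidTransform] = [RigidTransform.identity("IF0")]
    for i in range(1, n_if):                      # IF chain
        transforms.append(transforms[i - 1].compose(pair(i - 1, i)))
    if n_if < len(cycles):                        # brightfield bridge + chain
        bridge = pair(n_if - 1, n_if)
        transforms.append(transforms[n_if - 1].compose(bridge))
        for j in range(n_if + 1, len(cycles)):
            transforms.append(transforms[j - 1].compose(pair(j - 1, j)))

    shape = fids[0].shape
    images, masks = [], []
    for chs, cyc, t in zip(stack, cycles, transforms):
        cval = 255.0 if cyc.modality == "BF" else 0.0
        images.append({name: t.warp_image(img, order=1, cval=cval)
                       for name, img in chs.items()})
        masks.append(t.validity_mask(shape))
    return RegisteredStack(images=images, cycles=list(cycles),
                           transforms=transforms, validity_masks=masks)
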