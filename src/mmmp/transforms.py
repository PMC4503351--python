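"""Rigid (rotation + translation) plane transforms.

All image coordinates in this package are 0-based ``(row, col)`` with the
origin at the top-left.  Internally transforms are stored as 3x3 homogeneous
matrices acting on ``(x, y) = (col, row)`` points, matching the convention of
:mod:`skimage.transform`, so they can be handed to ``skimage.transform.warp``
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import warp


def _rigid_matrix(rotation_deg: float, translation_xy: tuple[float, float],
                  center_xy: tuple[float, float]) -> np.ndarray:
    """Matrix for rotation about ``center_xy`` followed by translation."""
    theta = np.deg2rad(rotation_deg)
    c, s = np.cos(theta), np.sin(theta)
    cx, cy = center_xy
    tx, ty = translation_xy
    m = np.eye(3)
    m[0, 0], m[0, 1] = c, -s
    m[1, 0], m[1, 1] = s, c
    # T(center) . R . T(-center) . T(translation)
    m[0, 2] = cx - c * cx + s * cy + tx
    m[1, 2] = cy - s * cx - c * cy + ty
    return m


@dataclass
class RigidTransform:
    """A rigid map from a moving frame into a reference frame.

    Parameters
    ----------
    rotation_deg : float
        Counter-clockwise rotation in degrees (in the (x, y) plane with y
        pointing down, this appears clockwise on screen).
    translation : (dx, dy)
        Translation in pixels, applied after the rotation.
    center : (cx, cy) or None
        Rotation center in (x, y) pixels.  ``None`` means the origin.
    frame : str
        Identifier of the reference frame this transform maps into.
    warning : str or None
        Set by registration when the similarity score is suspiciously low.
    """

    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] | None = None
    frame: str = ""
    warning: str | None = field(default=None, compare=False)

    @property
    def matrix(self) -> np.ndarray:
        center = (0.0, 0.0) if self.center is None else self.center
        return _rigid_matrix(self.rotation_deg, tuple(self.translation), center)

    @classmethod
    def identity(cls, frame: str = "") -> "RigidTransform":
        return cls(frame=frame)

    @classmethod
    def from_matrix(cls, m: np.ndarray, frame: str = "") -> "RigidTransform":
        """Build from a homogeneous rigid matrix (rotation about the origin)."""
        rot = np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))
        return cls(rotation_deg=float(rot),
                   translation=(float(m[0, 2]), float(m[1, 2])),
                   center=None, frame=frame)

    # ------------------------------------------------------------------ algebra
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply ``other`` first, then ``self``)."""
        return RigidTransform.from_matrix(self.matrix @ other.matrix,
                                          frame=self.frame)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix))

    def apply_points(self, pts_xy: np.ndarray) -> np.ndarray:
        """Map an ``(n, 2)`` array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(pts_xy, dtype=float))
        h = np.hstack([pts, np.ones((len(pts), 1))])
        out = (self.matrix @ h.T).T
        return out[:, :2]

    def shift_at(self, point_xy: tuple[float, float]) -> np.ndarray:
        """Effective displacement ``T(p) - p`` at a point (useful for
        comparing transforms with different rotation centers)."""
        p = np.asarray(point_xy, dtype=float)
        return self.apply_points(p)[0] - p

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, np.eye(3), atol=tol))

    # ------------------------------------------------------------------ images
    def warp_image(self, image: np.ndarray, order: int = 1,
                   cval: float = 0.0) -> np.ndarray:
        """Resample ``image`` (the moving frame) into the reference frame.

        Bilinear interpolation by default; pass ``order=0`` for label images.
        Output has the same shape and dtype scale as the input.
        """
        inv = np.linalg.inv(self.matrix)
        out = warp(image.astype(float), inverse_map=inv, order=order,
                   cval=cval, preserve_range=True)
        if np.issubdtype(image.dtype, np.integer):
            info = np.iinfo(image.dtype)
            out = np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
        return out

    def validity_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean map of output pixels whose value came from inside the
        source canvas (no extrapolation)."""
        ones = np.ones(shape, dtype=float)
        inv = np.linalg.inv(self.matrix)
        filled = warp(ones, inverse_map=inv, order=1, cval=0.0,
                      preserve_range=True)
        return filled > 1.0 - 1e-6

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return {"rotation_deg": float(self.rotation_deg),
                "translation": [float(t) for t in self.translation],
                "center": None if self.center is None
                else [float(c) for c in self.center],
                "frame": self.frame}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(rotation_deg=d["rotation_deg"],
                   translation=tuple(d["translation"]),
                   center=None if d.get("center") is None
                   else tuple(d["center"]),
                   frame=d.get("frame", ""))


def center_of(shape: tuple[int, int]) -> tuple[float, float]:
    """Geometric center of an image in (x, y) pixels."""
    h, w = shape[:2]
    return ((w - 1) / 2.0, (h - 1) / 2.0)
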