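"""Per-pixel data-matrix extraction from a registered cycle stack.

Each foreground pixel — present (non-extrapolated) in every aligned cycle —
becomes one row of the profiling matrix; the ordered panel of image channels
defines the columns.  The default panel (15 Cy5 antibody channels, DAPI from
the first and last IF cycles, and R/G/B from each of 4 histochemical stains)
yields 29 columns.  Brightfield intensities are stored in negated
orientation (stain signal bright), on the native 8-bit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import CycleDef
from .register import RegisteredStack, negate_brightfield


@dataclass(frozen=True)
class ChannelDescriptor:
    cycle: int
    modality: str          # "IF" or "BF"
    stain: str
    role: str              # "DAPI", "Cy5", "R", "G" or "B"

    @property
    def column_name(self) -> str:
        if self.role == "DAPI":
            return f"DAPI_c{self.cycle:02d}"
        if self.role == "Cy5":
            return self.stain
        return f"{self.stain}_{self.role}"

    @property
    def stack_key(self) -> str:
        """Key of this channel inside the cycle's channel dict."""
        if self.role == "DAPI":
            return "DAPI"
        if self.role == "Cy5":
            return self.stain
        return f"{self.stain}_{self.role}"


@dataclass
class PanelConfig:
    """Ordered channel layout defining the matrix columns."""

    channels: tuple[ChannelDescriptor, ...]

    def __post_init__(self) -> None:
        names = self.column_names
        if len(set(names)) != len(names):
            raise ValueError("panel column names must be unique")

    @property
    def column_names(self) -> list[str]:
        return [c.column_name for c in self.channels]

    def __len__(self) -> int:
        return len(self.channels)

    @classmethod
    def from_cycles(cls, cycles: list[CycleDef],
                    include_dapi_cycles: tuple[int, ...] | None = None
                    ) -> "PanelConfig":
        """Panel for a cycle series: DAPI from the first and last IF cycles
        (by default), one Cy5 column per IF cycle, R/G/B per brightfield."""
        if_cycles = [c for c in cycles if c.modality == "IF"]
        bf_cycles = [c for c in cycles if c.modality == "BF"]
        if include_dapi_cycles is None:
            include_dapi_cycles = ((if_cycles[0].index, if_cycles[-1].index)
                                   if if_cycles else ())
        desc = [ChannelDescriptor(i, "IF", "DAPI", "DAPI")
                for i in include_dapi_cycles]
        desc += [ChannelDescriptor(c.index, "IF", c.stain, "Cy5")
                 for c in if_cycles]
        desc += [ChannelDescriptor(c.index, "BF", c.stain, role)
                 for c in bf_cycles for role in "RGB"]
        return cls(channels=tuple(desc))


def default_panel() -> PanelConfig:
    """The 29-column default panel: 2 DAPI + 15 Cy5 + 4x3 brightfield."""
    from .phantom import default_cycles

    return PanelConfig.from_cycles(list(default_cycles()))


@dataclass
class ForegroundMask:
    mask: np.ndarray

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class MMMPMatrix:
    """Per-foreground-pixel channel intensities with pixel coordinates."""

    data: np.ndarray               # (n_pixels, n_channels) float
    coords: np.ndarray             # (n_pixels, 2) int (row, col)
    channel_names: list[str]
    canvas_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.coords), len(self.channel_names)):
            raise ValueError("data shape inconsistent with coords/channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("matrix intensities must be finite")

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self.channel_names.index(name)]

    def scatter_channel(self, name_or_index: str | int,
                        background: float = np.nan) -> np.ndarray:
        """Paint one column back onto the canvas at its pixel coordinates."""
        j = (self.channel_names.index(name_or_index)
             if isinstance(name_or_index, str) else name_or_index)
        img = np.full(self.canvas_shape, background, dtype=float)
        img[self.coords[:, 0], self.coords[:, 1]] = self.data[:, j]
        return img

    def subset_channels(self, names: list[str]) -> "MMMPMatrix":
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise ValueError(f"unknown channels: {missing}")
        idx = [self.channel_names.index(n) for n in names]
        return MMMPMatrix(data=self.data[:, idx], coords=self.coords,
                          channel_names=list(names),
                          canvas_shape=self.canvas_shape)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=self.channel_names)
        df.insert(0, "col", self.coords[:, 1])
        df.insert(0, "row", self.coords[:, 0])
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 canvas_shape: tuple[int, int] | None = None) -> "MMMPMatrix":
        df = pd.read_csv(path)
        coords = df[["row", "col"]].to_numpy(int)
        data = df.drop(columns=["row", "col"])
        if canvas_shape is None:
            canvas_shape = (int(coords[:, 0].max()) + 1,
                            int(coords[:, 1].max()) + 1)
        return cls(data=data.to_numpy(float), coords=coords,
                   channel_names=list(data.columns),
                   canvas_shape=canvas_shape)


def compute_foreground(stack: RegisteredStack,
                       tissue_threshold: float = 0.0) -> ForegroundMask:
    """Pixels with defined values in every aligned cycle.

    With ``tissue_threshold > 0`` (on the normalized 0-1 scale) the mask is
    additionally restricted to pixels where at least one channel exceeds the
    threshold, excluding signal-free glass/lumen regions.  Brightfield
    channels are negated before thresholding so "no tissue" is dark in every
    channel.
    """
    mask = np.logical_and.reduce(stack.validity_masks)
    if tissue_threshold > 0:
        tissue = np.zeros(stack.shape, dtype=bool)
        for chs, cyc in zip(stack.images, stack.cycles):
            for img in chs.values():
                v = (negate_brightfield(img) if cyc.modality == "BF"
                     else np.asarray(img, dtype=float))
                tissue |= (v / 255.0) > tissue_threshold
        mask &= tissue
    if not mask.any():
        raise ValueError("foreground mask is empty")
    return ForegroundMask(mask=mask)


def build_matrix(stack: RegisteredStack, mask: ForegroundMask,
                 panel: PanelConfig) -> MMMPMatrix:
    """Assemble the per-pixel matrix in raster (row-major) pixel order."""
    rr, cc = np.nonzero(mask.mask)              # nonzero is raster-ordered
    coords = np.stack([rr, cc], axis=1)
    cols = []
    for desc in panel.channels:
        if desc.cycle >= len(stack.images) or \
           desc.stack_key not in stack.images[desc.cycle]:
            raise ValueError(f"channel {desc.column_name!r} (cycle "
                             f"{desc.cycle}) missing from the stack")
        img = np.asarray(stack.images[desc.cycle][desc.stack_key],
                         dtype=float)
        if desc.modality == "BF":
            img = 255.0 - img
        cols.append(img[rr, cc])
    data = (np.stack(cols, axis=1) if cols
            else np.empty((len(coords), 0)))
    return MMMPMatrix(data=data, coords=coords,
                      channel_names=panel.column_names,
                      canvas_shape=stack.shape)
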