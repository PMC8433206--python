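"""Contrast conditioning of reconstructed volumes.

Mesoscopic OPT scans of immunolabelled tissue have a weak signal-to-noise
ratio for the labelled objects against the tissue background.  Three
operators improve it before segmentation:

1. min–max rescaling to the displayable range,
2. slice-wise contrast-limited adaptive histogram equalization (CLAHE),
   with a 32×32 tile grid for the labelled (near-infrared) channel and a
   16×16 grid for the anatomy/autofluorescence channel by default,
3. for the labelled channel, fusion of low-, middle- and high-range
   stretched copies of the same image.

All operators act per channel and per z-slice on reconstructed volumes;
none mixes channels, and all preserve the grid's shape and voxel-size
metadata.  The fusion combiner is the pixelwise arithmetic mean of the
three stretched copies — the simplest strictly monotone choice — with the
windows configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import exposure

from .core import VoxelGrid

__all__ = ["EnhanceConfig", "rescale_minmax", "clahe_slicewise", "fuse_ranges"]


@dataclass
class EnhanceConfig:
    """Parameters of the enhancement stage.

    ``fusion_ranges`` are three ``(low, high)`` intensity windows on the
    [0, 1] rescaled image; defaults split the range into overlapping low,
    middle and high thirds.  ``clahe_clip_limit`` is the clipping fraction
    of the per-tile histogram (0.01 keeps equalization gentle).
    """

    clahe_tile_signal: int = 32
    clahe_tile_anatomy: int = 16
    clahe_clip_limit: float = 0.01
    fusion_ranges: tuple[tuple[float, float], ...] = (
        (0.0, 0.4),
        (0.2, 0.8),
        (0.6, 1.0),
    )

    def __post_init__(self) -> None:
        if self.clahe_tile_signal < 2 or self.clahe_tile_anatomy < 2:
            raise ValueError("CLAHE tiles must be >= 2")
        if len(self.fusion_ranges) != 3:
            raise ValueError("exactly three fusion windows required")
        for lo, hi in self.fusion_ranges:
            if not lo < hi:
                raise ValueError(f"degenerate fusion window ({lo}, {hi})")


def rescale_minmax(grid: VoxelGrid) -> VoxelGrid:
    """Affine rescale of the whole volume to span [0, 1].

    A constant input maps to all zeros (there is no contrast to stretch);
    this is deliberate and mirrors display-range adjustment.
    """
    data = np.asarray(grid.data, dtype=np.float32)
    lo = float(data.min())
    hi = float(data.max())
    if hi == lo:
        return grid.with_data(np.zeros_like(data))
    return grid.with_data((data - lo) / (hi - lo))


def clahe_slicewise(grid: VoxelGrid, tile: int, clip: float = 0.01) -> VoxelGrid:
    """CLAHE applied independently to every z-slice.

    ``tile`` is the number of contextual regions per image axis (a 32-tile
    grid divides each slice into 32×32 regions).  Output is in [0, 1].
    Constant slices are passed through rescaled (equalization of a flat
    histogram is undefined).
    """
    nz, ny, nx = grid.shape
    if tile < 2:
        raise ValueError("tile must be >= 2")
    if ny < tile or nx < tile:
        raise ValueError(
            f"tile count {tile} exceeds slice dimensions {(ny, nx)}; "
            "use global histogram equalization for such small slices"
        )
    data = np.asarray(grid.data, dtype=np.float32)
    lo, hi = float(data.min()), float(data.max())
    span = hi - lo
    out = np.zeros_like(data, dtype=np.float32)
    kernel = (max(ny // tile, 1), max(nx // tile, 1))
    for z in range(nz):
        sl = data[z]
        if span == 0 or sl.max() == sl.min():
            out[z] = 0.0 if span == 0 else (sl - lo) / span
            continue
        norm = (sl - lo) / span  # volume-wide normalization keeps slices comparable
        out[z] = exposure.equalize_adapthist(norm, kernel_size=kernel, clip_limit=clip)
    return grid.with_data(out)


def fuse_ranges(grid: VoxelGrid, ranges=None) -> VoxelGrid:
    """Fuse low-, middle- and high-range stretched copies of the volume.

    Each copy is the input clipped and stretched to one ``(low, high)``
    window (windows are in units of the [0, 1] min–max rescaled input);
    the fused result is the pixelwise mean of the three copies, rescaled
    back to [0, 1].  The map is monotone non-decreasing in the input, so
    rank order is preserved.
    """
    if ranges is None:
        ranges = EnhanceConfig().fusion_ranges
    if len(ranges) != 3:
        raise ValueError("exactly three fusion windows required")
    for lo, hi in ranges:
        if not lo < hi:
            raise ValueError(f"degenerate fusion window ({lo}, {hi})")
    base = rescale_minmax(grid).data
    copies = [np.clip((base - lo) / (hi - lo), 0.0, 1.0) for lo, hi in ranges]
    fused = np.mean(copies, axis=0, dtype=np.float32)
    lo_f, hi_f = float(fused.min()), float(fused.max())
    if hi_f > lo_f:
        fused = (fused - lo_f) / (hi_f - lo_f)
    return grid.with_data(fused)
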