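"""Patch decomposition of large sections and seam-free stitching.

Whole sections (up to ~10,000 px per side at full scale) are far too
large for a segmenter, so they are processed as patches.  Training uses
a plain non-overlapping grid.  Prediction uses *patch-wise
interpolation*: overlapping windows slid by half the window size, of
which only the central block is kept — the surrounding trim gives every
kept pixel full spatial context and removes the grid pattern that
plain tiling leaves at patch borders.

Coordinates are 0-based, half-open row/col intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import SectionImage

__all__ = ["PatchGrid", "grid_patches", "sliding_windows", "stitch_centers", "Window"]


@dataclass(frozen=True)
class PatchGrid:
    """Sliding-window geometry: ``window = stride + 2 * trim``.

    Full-scale defaults are 512/256/128; desk-scale runs typically use
    64/32/16.  ``pad_mode`` controls how edge windows obtain their trim
    of context (reflection preserves local intensity statistics better
    than zero fill).
    """

    window: int = 512
    stride: int = 256
    trim: int = 128
    pad_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.window != self.stride + 2 * self.trim:
            raise ValueError(
                f"window ({self.window}) must equal stride ({self.stride}) "
                f"+ 2*trim ({self.trim})"
            )
        if self.window <= 2 * self.trim:
            raise ValueError("window must exceed 2*trim")
        if self.pad_mode not in ("reflect", "zero"):
            raise ValueError(f"pad_mode must be 'reflect' or 'zero', got {self.pad_mode!r}")


@dataclass(frozen=True)
class Window:
    """One overlapping prediction window.

    ``pos`` is the (row, col) grid index; ``center`` the 0-based
    half-open bounds (r0, r1, c0, c1) of its stride-sized center block
    in original-section coordinates (clipped at the section edge).
    """

    pixels: np.ndarray
    pos: tuple[int, int]
    center: tuple[int, int, int, int]


def _pixels(section: SectionImage | np.ndarray) -> np.ndarray:
    return section.pixels if isinstance(section, SectionImage) else np.asarray(section)


def grid_patches(
    section: SectionImage | np.ndarray, window: int = 512
) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Non-overlapping window-sized tiling (training-time patches).

    The section is zero-padded on the right/bottom to a window multiple;
    returns ``(patch, (r0, c0))`` pairs where (r0, c0) is the patch
    origin in original coordinates.
    """
    x = _pixels(section)
    h, w = x.shape[:2]
    nh, nw = -(-h // window), -(-w // window)
    pad = [(0, nh * window - h), (0, nw * window - w)] + [(0, 0)] * (x.ndim - 2)
    xp = np.pad(x, pad, mode="constant")
    out = []
    for i in range(nh):
        for j in range(nw):
            r0, c0 = i * window, j * window
            out.append((xp[r0 : r0 + window, c0 : c0 + window], (r0, c0)))
    return out


def sliding_windows(
    section: SectionImage | np.ndarray, grid: PatchGrid
) -> list[Window]:
    """Overlapping windows whose stride-sized centers tile the section.

    The section is first zero-padded on the right/bottom to a stride
    multiple, then padded by ``trim`` on all four sides (``pad_mode``),
    and a window is cut at every stride step.  Every original pixel
    falls in exactly one window center.
    """
    x = _pixels(section)
    h, w = x.shape[:2]
    s, t = grid.stride, grid.trim
    nh, nw = -(-h // s), -(-w // s)
    pad_sm = [(0, nh * s - h), (0, nw * s - w)] + [(0, 0)] * (x.ndim - 2)
    xp = np.pad(x, pad_sm, mode="constant")
    mode = "reflect" if grid.pad_mode == "reflect" else "constant"
    pad_tr = [(t, t), (t, t)] + [(0, 0)] * (x.ndim - 2)
    xp = np.pad(xp, pad_tr, mode=mode)
    windows = []
    for i in range(nh):
        for j in range(nw):
            r0, c0 = i * s, j * s  # center origin in padded-to-multiple coords
            win = xp[r0 : r0 + grid.window, c0 : c0 + grid.window]
            center = (r0, min(r0 + s, h), c0, min(c0 + s, w))
            windows.append(Window(pixels=win, pos=(i, j), center=center))
    return windows


def stitch_centers(
    outputs: Mapping[tuple[int, int], np.ndarray] | Sequence[np.ndarray],
    grid: PatchGrid,
    original_shape: tuple[int, int],
) -> np.ndarray:
    """Reassemble per-window outputs into a full-section map.

    Places the central stride-sized block of each window output at its
    center coordinates and crops the right/bottom padding.  ``outputs``
    maps grid position (i, j) to a window-sized array (2-D, or 3-D with
    leading channel axis); a plain sequence is interpreted in the
    row-major order produced by :func:`sliding_windows`.
    """
    h, w = original_shape
    s, t = grid.stride, grid.trim
    nh, nw = -(-h // s), -(-w // s)
    if not isinstance(outputs, Mapping):
        seq = list(outputs)
        outputs = {
            (i, j): seq[i * nw + j]
            for i in range(nh)
            for j in range(nw)
            if i * nw + j < len(seq)
        }
    missing = [(i, j) for i in range(nh) for j in range(nw) if (i, j) not in outputs]
    if missing:
        raise ValueError(f"missing window outputs at grid positions {missing}")

    sample = np.asarray(outputs[(0, 0)])
    channel_first = sample.ndim == 3
    full_shape = (
        (sample.shape[0], nh * s, nw * s) if channel_first else (nh * s, nw * s)
    )
    full = np.zeros(full_shape, dtype=sample.dtype)
    for i in range(nh):
        for j in range(nw):
            out = np.asarray(outputs[(i, j)])
            if out.shape[-2:] != (grid.window, grid.window):
                raise ValueError(
                    f"window output at {(i, j)} has shape {out.shape}, "
                    f"expected trailing dims ({grid.window}, {grid.window})"
                )
            block = out[..., t : t + s, t : t + s]
            full[..., i * s : (i + 1) * s, j * s : (j + 1) * s] = block
    return full[..., :h, :w]
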