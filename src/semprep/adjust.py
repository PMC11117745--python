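"""Pixel-intensity transforms and benchmark histogram preprocessors.

The first group (gamma / brightness / contrast and chain rendering) is
the action set of the semantic-preprocessing searches.  Chains are
always re-rendered from the raw image in floating point with a single
8-bit quantization at the end, so repeated search steps never
accumulate rounding error.

The second group wraps the four histogram-based preprocessors used as
benchmarks: difference of Gaussians, global histogram equalization,
contrast-limited adaptive histogram equalization, and histogram
matching.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import exposure

from .core import Adjustment, AdjustmentChain, SectionImage

__all__ = [
    "apply_gamma",
    "apply_brightness",
    "apply_contrast",
    "render_chain",
    "render_chain_float",
    "difference_of_gaussians",
    "hist_equalize",
    "adaptive_hist_equalize",
    "hist_match",
]

_MID = 127.5  # contrast pivot: mid-scale of the 8-bit range


def _as_float(img: SectionImage | np.ndarray) -> np.ndarray:
    if isinstance(img, SectionImage):
        return img.pixels.astype(np.float64)
    return np.asarray(img, dtype=np.float64)


def _like(img: SectionImage | np.ndarray, pixels: np.ndarray):
    out = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    if isinstance(img, SectionImage):
        return dataclasses.replace(img, pixels=out)
    return out


def _gamma_f(x: np.ndarray, gamma: float) -> np.ndarray:
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    return 255.0 * (x / 255.0) ** gamma


def _brightness_f(x: np.ndarray, amount: float) -> np.ndarray:
    if abs(amount) > 1:
        raise ValueError(f"|brightness amount| must be <= 1, got {amount}")
    return x + amount * 255.0


def _contrast_f(x: np.ndarray, amount: float) -> np.ndarray:
    if amount <= -1:
        raise ValueError(f"contrast amount must be > -1, got {amount}")
    return _MID + (1.0 + amount) * (x - _MID)


def apply_gamma(img: SectionImage | np.ndarray, gamma: float):
    """Power-law transform ``255 * (in/255)**gamma``, clipped to [0, 255]."""
    return _like(img, _gamma_f(_as_float(img), gamma))


def apply_brightness(img: SectionImage | np.ndarray, amount: float):
    """Additive offset of ``amount * 255`` gray levels, clipped."""
    return _like(img, _brightness_f(_as_float(img), amount))


def apply_contrast(img: SectionImage | np.ndarray, amount: float):
    """Linear stretch about mid-scale: ``127.5 + (1+amount)*(in-127.5)``."""
    return _like(img, _contrast_f(_as_float(img), amount))


def render_chain_float(
    raw: SectionImage | np.ndarray, chain: AdjustmentChain
) -> np.ndarray:
    """Apply a chain to the raw image entirely in floating point.

    Every transform is defined on the 8-bit range, so values are
    clipped to [0, 255] after each step (this makes chain composition
    associative) but never quantized.
    """
    x = np.clip(_as_float(raw), 0.0, 255.0)
    for step in chain:
        if step.op == "gamma":
            x = _gamma_f(x, step.amount)
        elif step.op == "brightness":
            x = _brightness_f(x, step.amount)
        elif step.op == "contrast":
            x = _contrast_f(x, step.amount)
        else:  # pragma: no cover - Adjustment validates op names
            raise ValueError(f"unknown adjustment op {step.op!r}")
        x = np.clip(x, 0.0, 255.0)
    return x


def render_chain(raw: SectionImage | np.ndarray, chain: AdjustmentChain):
    """Render a chain from the raw image; quantize to 8-bit once at the end."""
    return _like(raw, render_chain_float(raw, chain))


def difference_of_gaussians(
    img: SectionImage | np.ndarray, sigma_low: float = 1.0, sigma_high: float = 10.0
):
    """Band-pass filter: blur(sigma_low) − blur(sigma_high), rescaled to [0, 255].

    A constant image (zero band-pass response everywhere) maps to a
    constant mid-level output.
    """
    if not (sigma_high > sigma_low > 0):
        raise ValueError(
            f"need sigma_high > sigma_low > 0, got low={sigma_low}, high={sigma_high}"
        )
    x = _as_float(img)
    band = ndimage.gaussian_filter(x, sigma_low) - ndimage.gaussian_filter(
        x, sigma_high
    )
    lo, hi = band.min(), band.max()
    if hi - lo < 1e-12:
        out = np.full_like(band, _MID)
    else:
        out = (band - lo) / (hi - lo) * 255.0
    return _like(img, out)


def hist_equalize(img: SectionImage | np.ndarray):
    """Global histogram equalization via the empirical CDF."""
    x = _as_float(img).astype(np.uint8)
    out = exposure.equalize_hist(x) * 255.0
    return _like(img, out)


def adaptive_hist_equalize(
    img: SectionImage | np.ndarray,
    window: int | None = None,
    clip_limit: float = 0.01,
):
    """Contrast-limited adaptive histogram equalization (CLAHE).

    ``window`` defaults to 1/8 of the smaller image dimension.
    """
    x = _as_float(img).astype(np.uint8)
    if window is None:
        window = max(8, min(x.shape) // 8)
    if window < 8:
        raise ValueError(f"window must be >= 8, got {window}")
    if not (0 < clip_limit <= 1):
        raise ValueError(f"clip_limit must be in (0, 1], got {clip_limit}")
    out = exposure.equalize_adapthist(x, kernel_size=window, clip_limit=clip_limit)
    return _like(img, out * 255.0)


def hist_match(img: SectionImage | np.ndarray, target: SectionImage | np.ndarray):
    """Monotone remapping so the output's empirical CDF matches the target's."""
    x = _as_float(img).astype(np.uint8)
    t = _as_float(target).astype(np.uint8)
    out = exposure.match_histograms(x, t)
    return _like(img, out)
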