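"""Semantic preprocessing: metric extraction and target-seeking searches.

Semantic preprocessing (SP) adjusts an image so that the intensity
statistics of its *class areas* — background and foreground as defined
by a segmentation — match those of an expert-designated reference
section.  The statistics form a coordinate ("semantic metric"): the two
region means for plain SP, means plus population standard deviations
(4-D) for the gradient-descent variant.  Searches always re-render
candidate adjustments from the raw image so no information is destroyed
by intermediate quantization.

The bootstrap loop (:func:`bsp_iterate`) alternates adjustment with
model re-prediction: the first masks come from Otsu thresholding, later
masks from the segmenter's own prediction of the adjusted images, which
converges jointly toward a stable adjustment and label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from skimage.filters import threshold_otsu

from .adjust import render_chain, render_chain_float
from .core import (
    AdjustmentChain,
    Channel,
    ClassLabel,
    ClassMap,
    SectionImage,
    SemanticMetric,
    metric_distance,
)

__all__ = [
    "SPConfig",
    "otsu_binary",
    "extract_metric",
    "sp_gamma_search",
    "gd_search",
    "compose_class_map",
    "bsp_iterate",
    "BootstrapResult",
]

logger = logging.getLogger(__name__)

_MAX_STEPS = 1000  # hard cap; the strict-improvement rule terminates far sooner


@dataclass
class SPConfig:
    """Search hyperparameters.

    gamma_step
        Multiplicative gamma step of the plain SP search (0.05 = 5%).
    gd_initial_step, gd_step_decrement
        Annealing schedule of the gradient-descent search: start at 10%
        moves, shrink by 1% whenever no move improves, stop below 1%.
    bootstrap_iters
        Number of adjust/predict rounds in the bootstrap loop.
    use_std
        If set, searches navigate the 4-D mean+std metric space with
        the full contrast/brightness/gamma action set (GDBSP);
        otherwise the 2-D mean space with gamma only (SP/BSP).
    """

    gamma_step: float = 0.05
    gd_initial_step: float = 0.10
    gd_step_decrement: float = 0.01
    bootstrap_iters: int = 5
    use_std: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.gd_step_decrement <= self.gd_initial_step <= 1):
            raise ValueError("need 0 < gd_step_decrement <= gd_initial_step <= 1")
        if self.bootstrap_iters < 1:
            raise ValueError("bootstrap_iters must be >= 1")
        if self.gamma_step <= 0:
            raise ValueError("gamma_step must be > 0")


def otsu_binary(img: SectionImage | np.ndarray) -> np.ndarray:
    """Binary foreground mask by Otsu's between-class-variance threshold.

    Pixels strictly above the threshold are foreground.  Raises on a
    constant image ("degenerate histogram"); callers fall back to no
    adjustment in that case.
    """
    pixels = img.pixels if isinstance(img, SectionImage) else np.asarray(img)
    if np.unique(pixels).size < 2:
        raise ValueError("degenerate histogram: image has fewer than 2 distinct values")
    thresh = threshold_otsu(pixels)
    return pixels > thresh


def extract_metric(
    img: SectionImage | np.ndarray,
    mask: np.ndarray,
    use_std: bool = False,
) -> SemanticMetric:
    """Class-area intensity statistics of an image under a binary mask.

    Returns means (and population stds if ``use_std``) of the
    background (mask False) and foreground (mask True) regions on the
    0-255 scale.  If either region is empty the metric is flagged
    degenerate and the searches skip adjustment.
    """
    pixels = img.pixels if isinstance(img, SectionImage) else np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pixels.shape:
        raise ValueError(f"shape mismatch: image {pixels.shape} vs mask {mask.shape}")
    fg = pixels[mask].astype(float)
    bg = pixels[~mask].astype(float)
    if fg.size == 0 or bg.size == 0:
        logger.warning("degenerate metric: empty %s region", "fg" if fg.size == 0 else "bg")
        return SemanticMetric(
            bg_mean=float("nan"),
            fg_mean=float("nan"),
            bg_std=float("nan") if use_std else None,
            fg_std=float("nan") if use_std else None,
            degenerate=True,
        )
    return SemanticMetric(
        bg_mean=float(bg.mean()),
        fg_mean=float(fg.mean()),
        bg_std=float(bg.std()) if use_std else None,
        fg_std=float(fg.std()) if use_std else None,
    )


def _chain_distance(
    raw: SectionImage | np.ndarray,
    chain: AdjustmentChain,
    mask: np.ndarray,
    target: SemanticMetric,
    use_std: bool,
) -> float:
    rendered = render_chain_float(raw, chain)
    return metric_distance(extract_metric(rendered, mask, use_std), target)


def sp_gamma_search(
    raw: SectionImage | np.ndarray,
    mask: np.ndarray,
    target: SemanticMetric,
    cfg: SPConfig | None = None,
    trace: list[float] | None = None,
) -> AdjustmentChain:
    """Greedy gamma search toward a 2-D (mean/mean) target metric.

    Starting at gamma 1, each step evaluates the current gamma scaled
    up and down by ``cfg.gamma_step`` and moves to whichever strictly
    reduces the Euclidean distance of the rendered image's metric to
    the target; the search stops as soon as neither direction improves.
    """
    cfg = cfg or SPConfig()
    if target.degenerate:
        logger.warning("sp_gamma_search: degenerate target; skipping adjustment")
        return AdjustmentChain()
    if not np.any(mask) or np.all(mask):
        logger.warning("sp_gamma_search: degenerate mask; skipping adjustment")
        return AdjustmentChain()
    if target.has_std:
        raise ValueError("SP target must have means only (2-D)")

    def dist(g: float) -> float:
        return _chain_distance(
            raw, AdjustmentChain([]).extended("gamma", g), mask, target, use_std=False
        )

    g = 1.0
    d = dist(g)
    if trace is not None:
        trace.append(d)
    for _ in range(_MAX_STEPS):
        up, dn = g * (1 + cfg.gamma_step), g * (1 - cfg.gamma_step)
        d_up, d_dn = dist(up), dist(dn)
        best_d, best_g = d, g
        # tie broken toward the upward step
        if d_up < best_d:
            best_d, best_g = d_up, up
        if d_dn < best_d:
            best_d, best_g = d_dn, dn
        if best_g == g:
            break
        g, d = best_g, best_d
        if trace is not None:
            trace.append(d)
    return AdjustmentChain([]).extended("gamma", g)


#: fixed candidate priority: contrast > brightness > gamma, + before −
_GD_OPS = ("contrast", "brightness", "gamma")


def gd_search(
    raw: SectionImage | np.ndarray,
    mask: np.ndarray,
    target: SemanticMetric,
    cfg: SPConfig | None = None,
    trace: list[float] | None = None,
) -> AdjustmentChain:
    """Annealed greedy descent in the 4-D mean+std metric space.

    At step size *s* (start ``gd_initial_step``) the six candidate
    moves {contrast, brightness, gamma} x {+s, −s} are appended to the
    current chain, rendered from the raw image, and the one with the
    greatest strict distance reduction is taken.  When no move
    improves, *s* shrinks by ``gd_step_decrement``; the search stops
    when *s* would fall below the decrement.  Ties break by the fixed
    priority contrast > brightness > gamma, + before −.
    """
    cfg = cfg or SPConfig(use_std=True)
    if target.degenerate:
        logger.warning("gd_search: degenerate target; skipping adjustment")
        return AdjustmentChain()
    if not np.any(mask) or np.all(mask):
        logger.warning("gd_search: degenerate mask; skipping adjustment")
        return AdjustmentChain()
    if not target.has_std:
        raise ValueError("GD target must have means and stds (4-D)")

    chain = AdjustmentChain()
    d = _chain_distance(raw, chain, mask, target, use_std=True)
    if trace is not None:
        trace.append(d)
    s = cfg.gd_initial_step
    for _ in range(_MAX_STEPS):
        if s < cfg.gd_step_decrement - 1e-12:
            break
        best_d, best_chain = d, None
        for op in _GD_OPS:
            for sign in (+1, -1):
                amount = 1 + sign * s if op == "gamma" else sign * s
                if op == "gamma" and amount <= 0:
                    continue
                cand = chain.extended(op, amount)
                d_c = _chain_distance(raw, cand, mask, target, use_std=True)
                if d_c < best_d:
                    best_d, best_chain = d_c, cand
        if best_chain is None:
            s = round(s - cfg.gd_step_decrement, 12)
            continue
        chain, d = best_chain, best_d
        if trace is not None:
            trace.append(d)
    return chain


def compose_class_map(
    nuclear_mask: np.ndarray, lectin_mask: np.ndarray, section_id: str = ""
) -> ClassMap:
    """Combine the two binary problems into one 3-class map.

    ``normal`` where the lectin channel has signal, ``risk`` where
    there is tissue (nuclear foreground) but no lectin signal, ``none``
    elsewhere.
    """
    nuclear_mask = np.asarray(nuclear_mask, dtype=bool)
    lectin_mask = np.asarray(lectin_mask, dtype=bool)
    if nuclear_mask.shape != lectin_mask.shape:
        raise ValueError(
            f"shape mismatch: nuclear {nuclear_mask.shape} vs lectin {lectin_mask.shape}"
        )
    labels = np.zeros(nuclear_mask.shape, dtype=np.uint8)
    labels[nuclear_mask & ~lectin_mask] = int(ClassLabel.RISK)
    labels[lectin_mask] = int(ClassLabel.NORMAL)
    return ClassMap(labels, section_id=section_id)


@dataclass
class BootstrapResult:
    """Outcome of one bootstrapped-semantic-preprocessing run."""

    chains: dict[Channel, AdjustmentChain]
    class_map: ClassMap
    adjusted: dict[Channel, SectionImage]
    trace: list[dict] = field(default_factory=list)


def _safe_otsu(img: SectionImage) -> np.ndarray | None:
    try:
        return otsu_binary(img)
    except ValueError:
        logger.warning("otsu fallback: degenerate histogram in %s channel", img.channel)
        return None


def bsp_iterate(
    nuclear: SectionImage,
    lectin: SectionImage,
    predict_fn: Callable[[SectionImage, SectionImage], ClassMap],
    targets: Mapping[Channel, SemanticMetric],
    cfg: SPConfig | None = None,
) -> BootstrapResult:
    """Bootstrapped semantic preprocessing of one two-channel section.

    Iteration 0 derives per-channel masks from Otsu thresholding; every
    iteration runs the configured search (gamma-only SP, or GD if
    ``cfg.use_std``) per channel from the *raw* images, renders the
    chains, asks ``predict_fn`` for a 3-class map of the adjusted
    section, and takes next-iteration masks from that prediction
    (nuclear: not-none; lectin: normal).  Channels are adjusted fully
    independently.
    """
    cfg = cfg or SPConfig()
    if nuclear.shape != lectin.shape:
        raise ValueError(f"shape mismatch: {nuclear.shape} vs {lectin.shape}")
    search = gd_search if cfg.use_std else sp_gamma_search
    raws = {Channel.NUCLEAR: nuclear, Channel.LECTIN: lectin}
    masks: dict[Channel, np.ndarray | None] = {
        ch: _safe_otsu(img) for ch, img in raws.items()
    }

    chains = {ch: AdjustmentChain() for ch in raws}
    adjusted = dict(raws)
    class_map = None
    trace: list[dict] = []
    for it in range(cfg.bootstrap_iters):
        distances: dict[str, float] = {}
        for ch, raw in raws.items():
            mask = masks[ch]
            if mask is None:
                chains[ch] = AdjustmentChain()
            else:
                chains[ch] = search(raw, mask, targets[ch], cfg)
            adjusted[ch] = render_chain(raw, chains[ch])
            if mask is not None:
                m = extract_metric(adjusted[ch], mask, use_std=cfg.use_std)
                if not m.degenerate:
                    distances[ch.value] = metric_distance(m, targets[ch])
        try:
            class_map = predict_fn(adjusted[Channel.NUCLEAR], adjusted[Channel.LECTIN])
        except Exception as exc:
            raise RuntimeError(f"segmenter failed at bootstrap iteration {it}") from exc
        nuc_mask = class_map.labels != int(ClassLabel.NONE)
        lec_mask = class_map.labels == int(ClassLabel.NORMAL)
        masks = {
            Channel.NUCLEAR: nuc_mask if nuc_mask.any() and not nuc_mask.all() else masks[Channel.NUCLEAR],
            Channel.LECTIN: lec_mask if lec_mask.any() and not lec_mask.all() else masks[Channel.LECTIN],
        }
        trace.append(
            {
                "iteration": it,
                "distances": distances,
                "chains": {
                    ch.value: [(st.op, st.amount) for st in chains[ch]] for ch in raws
                },
            }
        )
    assert class_map is not None
    return BootstrapResult(chains=chains, class_map=class_map, adjusted=adjusted, trace=trace)
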