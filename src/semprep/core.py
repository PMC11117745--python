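"""Shared domain types for two-channel fluorescence section analysis.

A *section* is one physical tissue slice imaged in two co-registered
8-bit grayscale channels: a nuclear stain that delimits tissue against
the slide background, and a lectin-488 vascular label that marks
perfused ("normal") myocardium.  Segmentations assign each pixel one of
three classes: ``none`` (slide background), ``risk`` (ischemic
area-at-risk: tissue without lectin signal) and ``normal`` (perfused
tissue).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Channel",
    "ClassLabel",
    "SectionImage",
    "ClassMap",
    "ConfidenceMap",
    "SemanticMetric",
    "Adjustment",
    "AdjustmentChain",
    "dice",
    "dice_scores",
    "metric_distance",
]

#: native pixel pitch of the downscaled whole-slide scans, in nm/pixel
DEFAULT_RESOLUTION_NM_PER_PX = 541.67


class Channel(str, enum.Enum):
    """Fluorescence channel role."""

    NUCLEAR = "nuclear"
    LECTIN = "lectin"


class ClassLabel(enum.IntEnum):
    """Per-pixel tissue class.

    Small-integer codes are used everywhere in memory; the conventional
    false colors (black / yellow / green) are applied only at I/O time.
    """

    NONE = 0
    RISK = 1
    NORMAL = 2


@dataclass
class SectionImage:
    """One 8-bit grayscale channel of a section.

    Parameters
    ----------
    pixels
        2-D array of intensities; stored as ``uint8`` (values 0-255).
    channel
        Which stain this image carries.
    section_id
        Opaque identifier shared by both channels of a section.
    resolution_nm_per_px
        Physical pixel pitch.
    """

    pixels: np.ndarray
    channel: Channel
    section_id: str = ""
    resolution_nm_per_px: float = DEFAULT_RESOLUTION_NM_PER_PX

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"section image must be 2-D, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("pixel values outside [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr
        self.channel = Channel(self.channel)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ClassMap:
    """Per-pixel 3-class segmentation of a section."""

    labels: np.ndarray
    section_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError(f"class map must be 2-D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("class map labels must be integers")
        if arr.size and (arr.min() < 0 or arr.max() > 2):
            raise ValueError("class labels must be in {0, 1, 2}")
        self.labels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, label: ClassLabel) -> np.ndarray:
        """Boolean mask of one class."""
        return self.labels == int(label)


@dataclass
class ConfidenceMap:
    """Per-pixel winning-vote proportion of a snapshot ensemble.

    ``mean_confidence`` (the acquisition score *f*) is the arithmetic
    mean of the per-pixel proportions over the whole section.
    """

    proportions: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.proportions, dtype=float)
        if arr.ndim != 2:
            raise ValueError("confidence map must be 2-D")
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0 + 1e-12):
            raise ValueError("vote proportions must lie in [0, 1]")
        self.proportions = arr

    @property
    def mean_confidence(self) -> float:
        return float(self.proportions.mean())


@dataclass(frozen=True)
class SemanticMetric:
    """Class-area intensity statistics used as the preprocessing coordinate.

    Means (and, in mean+std mode, population standard deviations) of the
    pixel values inside the background and foreground regions, on the
    0-255 scale.  Two populated fields give the 2-D coordinate used by
    the gamma-only search; four give the 4-D coordinate used by the
    annealed gradient descent.
    """

    bg_mean: float
    fg_mean: float
    bg_std: float | None = None
    fg_std: float | None = None
    degenerate: bool = False

    @property
    def has_std(self) -> bool:
        return self.bg_std is not None and self.fg_std is not None

    def as_vector(self) -> np.ndarray:
        if self.has_std:
            return np.array(
                [self.bg_mean, self.fg_mean, self.bg_std, self.fg_std], dtype=float
            )
        return np.array([self.bg_mean, self.fg_mean], dtype=float)


@dataclass(frozen=True)
class Adjustment:
    """One intensity transform in a chain.

    ``gamma`` amounts are the exponent itself (identity at 1.0);
    ``brightness`` and ``contrast`` amounts are signed fractions of the
    full scale (identity at 0.0).
    """

    op: str
    amount: float

    VALID_OPS = ("gamma", "brightness", "contrast")

    def __post_init__(self) -> None:
        if self.op not in self.VALID_OPS:
            raise ValueError(f"unknown adjustment op {self.op!r}")


@dataclass
class AdjustmentChain:
    """Ordered intensity transforms, always re-rendered from the raw image.

    The empty chain is the identity.  Rendering is deterministic and is
    done in floating point with a single 8-bit quantization at the end
    (see :func:`semprep.adjust.render_chain`).
    """

    steps: list[Adjustment] = field(default_factory=list)

    def __iter__(self):
        return iter(self.steps)

    def __len__(self) -> int:
        return len(self.steps)

    def append(self, op: str, amount: float) -> None:
        self.steps.append(Adjustment(op, amount))

    def extended(self, op: str, amount: float) -> "AdjustmentChain":
        """A copy of the chain with one more step appended."""
        return AdjustmentChain(self.steps + [Adjustment(op, amount)])

    @property
    def is_identity(self) -> bool:
        for step in self.steps:
            if step.op == "gamma" and step.amount != 1.0:
                return False
            if step.op in ("brightness", "contrast") and step.amount != 0.0:
                return False
        return True


def _binary_dice(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        # agreement on absence
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks.

    Defined as 1.0 when both masks are empty.  Raises on shape mismatch.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return _binary_dice(a.astype(bool), b.astype(bool))


def dice_scores(
    a: "ClassMap | np.ndarray",
    b: "ClassMap | np.ndarray",
    classes: Sequence[ClassLabel] = tuple(ClassLabel),
) -> tuple[dict[ClassLabel, float], float]:
    """Per-class Dice scores and their macro mean for 3-class maps.

    Each class is scored as a binary mask (empty-vs-empty counts 1.0);
    the macro score is the unweighted mean over ``classes``.
    """
    la = a.labels if isinstance(a, ClassMap) else np.asarray(a)
    lb = b.labels if isinstance(b, ClassMap) else np.asarray(b)
    if la.shape != lb.shape:
        raise ValueError(f"shape mismatch: {la.shape} vs {lb.shape}")
    per_class = {
        c: _binary_dice(la == int(c), lb == int(c)) for c in classes
    }
    macro = float(np.mean(list(per_class.values())))
    return per_class, macro


def metric_distance(m1: SemanticMetric, m2: SemanticMetric) -> float:
    """Euclidean distance between two semantic-metric coordinates.

    2-D (means only) or 4-D (means + stds); both metrics must populate
    the same fields.
    """
    if m1.has_std != m2.has_std:
        raise ValueError(
            "metrics populate different fields: "
            f"m1 has_std={m1.has_std}, m2 has_std={m2.has_std}"
        )
    return float(np.linalg.norm(m1.as_vector() - m2.as_vector()))
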