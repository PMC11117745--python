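"""Compact encoder-decoder segmenter, snapshot training and ensemble voting.

The segmenter is a U-Net-style encoder-decoder with skip connections,
implemented directly in numpy (see ``_nn``): it maps a two-channel
fluorescence window normalized to [0, 1] to a per-pixel three-class
confidence triple.  At the default width the model carries roughly two
million trainable parameters; width and depth are configurable, and
desk-scale tests use far smaller instances.

Training follows a fixed recipe: categorical cross-entropy, Adadelta
(decay 0.9, eps 1e-6), global gradient-norm clipping at 1.0, snapshots
of the weights saved at a few late epochs (90/100/110 at full scale).
The snapshots vote per pixel; the winning-vote proportion forms the
confidence map whose section mean *f* is the active-learning
acquisition score.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import _nn
from .core import ClassLabel, ClassMap, ConfidenceMap, SectionImage, dice_scores
from .patchwork import PatchGrid, sliding_windows, stitch_centers

__all__ = [
    "UNet",
    "build_model",
    "TrainConfig",
    "SnapshotEnsemble",
    "FoldPlan",
    "Fold",
    "train_snapshots",
    "predict_section",
    "ensemble_vote",
    "section_confidence",
    "choose_threshold",
    "least_overfit_fold",
]


def _unet_param_count(in_ch: int, n_classes: int, width: int, levels: int) -> int:
    """Analytic parameter count of the architecture below."""
    count, c_prev = 0, in_ch
    for l in range(levels):
        c = width * 2**l
        count += 9 * c_prev * c + c + 9 * c * c + c + 4 * c  # convs + norm affine
        c_prev = c
    cb = width * 2**levels
    count += 9 * c_prev * cb + cb + 9 * cb * cb + cb + 4 * cb
    c_prev = cb
    for l in reversed(range(levels)):
        c = width * 2**l
        count += 9 * (c + c_prev) * c + c + 9 * c * c + c + 4 * c
        c_prev = c
    count += c_prev * n_classes + n_classes
    return count


class UNet:
    """Encoder-decoder segmenter with skip connections (numpy).

    ``levels`` pooling steps halve resolution each; the decoder mirrors
    them with nearest-neighbour upsampling and concatenation of the
    matching encoder feature map.  Channel widths double per level from
    ``base_width``.  Inputs must have spatial dims divisible by
    ``2**levels``.  Prediction is deterministic given fixed weights.
    """

    def __init__(
        self,
        base_width: int = 16,
        levels: int = 4,
        in_channels: int = 2,
        n_classes: int = 3,
        seed: int = 0,
    ):
        self.base_width = base_width
        self.levels = levels
        self.in_channels = in_channels
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        self.stats: dict[str, dict[str, np.ndarray]] = {}

        def add_conv(name: str, c_in: int, c_out: int, k: int = 3,
                     norm: bool = False) -> None:
            std = np.sqrt(2.0 / (c_in * k * k))
            self.params[f"{name}.W"] = rng.normal(
                0.0, std, (c_out, c_in, k, k)
            ).astype(np.float32)
            self.params[f"{name}.b"] = np.zeros(c_out, dtype=np.float32)
            if norm:
                self.params[f"{name}.g"] = np.ones(c_out, dtype=np.float32)
                self.params[f"{name}.nb"] = np.zeros(c_out, dtype=np.float32)
                self.stats[name] = {
                    "mean": np.zeros(c_out, dtype=np.float32),
                    "var": np.ones(c_out, dtype=np.float32),
                }

        c_prev = in_channels
        for l in range(levels):
            c = base_width * 2**l
            add_conv(f"enc{l}.0", c_prev, c, norm=True)
            add_conv(f"enc{l}.1", c, c, norm=True)
            c_prev = c
        cb = base_width * 2**levels
        add_conv("bott.0", c_prev, cb, norm=True)
        add_conv("bott.1", cb, cb, norm=True)
        c_prev = cb
        for l in reversed(range(levels)):
            c = base_width * 2**l
            add_conv(f"dec{l}.0", c + c_prev, c, norm=True)
            add_conv(f"dec{l}.1", c, c, norm=True)
            c_prev = c
        add_conv("head", c_prev, n_classes, k=1)

    # -- bookkeeping ---------------------------------------------------
    @property
    def param_count(self) -> int:
        return sum(p.size for p in self.params.values())

    def clone(self) -> "UNet":
        dup = copy.copy(self)
        dup.params = {k: v.copy() for k, v in self.params.items()}
        dup.stats = {
            k: {kk: vv.copy() for kk, vv in v.items()}
            for k, v in self.stats.items()
        }
        return dup

    def _check_dims(self, h: int, w: int) -> None:
        f = 2**self.levels
        if h % f or w % f:
            raise ValueError(
                f"input dims {(h, w)} must be divisible by the downsampling "
                f"factor {f}"
            )

    # -- forward / backward --------------------------------------------
    def _double_conv(self, x, name, caches, training):
        p = self.params
        z, c0 = _nn.conv_forward(x, p[f"{name}.0.W"], p[f"{name}.0.b"])
        z, n0 = _nn.batchnorm_forward(z, p[f"{name}.0.g"], p[f"{name}.0.nb"],
                                      self.stats[f"{name}.0"], training)
        a, m0 = _nn.relu_forward(z)
        z, c1 = _nn.conv_forward(a, p[f"{name}.1.W"], p[f"{name}.1.b"])
        z, n1 = _nn.batchnorm_forward(z, p[f"{name}.1.g"], p[f"{name}.1.nb"],
                                      self.stats[f"{name}.1"], training)
        a, m1 = _nn.relu_forward(z)
        caches[name] = (c0, n0, m0, c1, n1, m1)
        return a

    def _double_conv_back(self, dout, name, caches, grads):
        p = self.params
        c0, n0, m0, c1, n1, m1 = caches[name]
        d = _nn.relu_backward(dout, m1)
        d, dg, dnb = _nn.batchnorm_backward(d, n1)
        grads[f"{name}.1.g"], grads[f"{name}.1.nb"] = dg, dnb
        d, dW, db = _nn.conv_backward(d, p[f"{name}.1.W"], c1)
        grads[f"{name}.1.W"], grads[f"{name}.1.b"] = dW, db
        d = _nn.relu_backward(d, m0)
        d, dg, dnb = _nn.batchnorm_backward(d, n0)
        grads[f"{name}.0.g"], grads[f"{name}.0.nb"] = dg, dnb
        d, dW, db = _nn.conv_backward(d, p[f"{name}.0.W"], c0)
        grads[f"{name}.0.W"], grads[f"{name}.0.b"] = dW, db
        return d

    def forward(self, x: np.ndarray, training: bool = True):
        """Logits for a batch (N, in_channels, H, W) of [0, 1] inputs."""
        x = np.asarray(x, dtype=np.float32)
        self._check_dims(*x.shape[2:])
        caches: dict = {}
        skips = []
        for l in range(self.levels):
            x = self._double_conv(x, f"enc{l}", caches, training)
            skips.append(x)
            x, pc = _nn.maxpool2_forward(x)
            caches[f"pool{l}"] = pc
        x = self._double_conv(x, "bott", caches, training)
        for l in reversed(range(self.levels)):
            up = _nn.upsample2_forward(x)
            x = np.concatenate([skips[l], up], axis=1)
            caches[f"cat{l}"] = skips[l].shape[1]
            x = self._double_conv(x, f"dec{l}", caches, training)
        p = self.params
        logits, hc = _nn.conv_forward(x, p["head.W"], p["head.b"])
        caches["head"] = hc
        self._caches = caches
        return logits

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        caches = self._caches
        grads: dict[str, np.ndarray] = {}
        d, dW, db = _nn.conv_backward(dlogits, self.params["head.W"], caches["head"])
        grads["head.W"], grads["head.b"] = dW, db
        dskips = {}
        for l in range(self.levels):
            d = self._double_conv_back(d, f"dec{l}", caches, grads)
            n_skip = caches[f"cat{l}"]
            dskips[l] = d[:, :n_skip]
            d = _nn.upsample2_backward(d[:, n_skip:])
        d = self._double_conv_back(d, "bott", caches, grads)
        for l in reversed(range(self.levels)):
            d = _nn.maxpool2_backward(d, caches[f"pool{l}"])
            d = d + dskips[l]
            d = self._double_conv_back(d, f"enc{l}", caches, grads)
        self._caches = None
        return grads

    # -- inference ------------------------------------------------------
    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (3, H, W) for one (2, H, W) window."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[0] != self.in_channels:
            raise ValueError(
                f"expected ({self.in_channels}, H, W) input, got {x.shape}"
            )
        logits = self.forward(x[None], training=False)
        self._caches = None
        return _nn.softmax(logits, axis=1)[0]


def build_model(
    params_budget: float = 2e6,
    levels: int = 4,
    in_channels: int = 2,
    n_classes: int = 3,
    seed: int = 0,
) -> UNet:
    """Instantiate a segmenter whose parameter count lands near a budget.

    The channel width is chosen so the total trainable parameter count
    falls within +/-25% of ``params_budget``; an unreachable budget
    raises.
    """
    if params_budget <= 0:
        raise ValueError("params_budget must be > 0")
    best_w, best_dev = None, np.inf
    for w in range(1, 257):
        count = _unet_param_count(in_channels, n_classes, w, levels)
        dev = abs(count - params_budget) / params_budget
        if dev < best_dev:
            best_w, best_dev = w, dev
    if best_dev > 0.25:
        raise ValueError(
            f"no width reaches within 25% of a {params_budget:.0f}-parameter budget"
        )
    return UNet(base_width=best_w, levels=levels, in_channels=in_channels,
                n_classes=n_classes, seed=seed)


@dataclass
class TrainConfig:
    """Training recipe.

    Full-scale defaults: 110 epochs with snapshots at 90/100/110,
    Adadelta (decay 0.9, eps 1e-6), gradient-norm clip 1.0, inputs
    scaled to [0, 1].  Desk-scale runs shorten the schedule (e.g., 10
    epochs, snapshots 8/9/10) without changing anything else.
    """

    epochs: int = 110
    snapshot_epochs: tuple[int, ...] = (90, 100, 110)
    rho: float = 0.9
    eps: float = 1e-6
    lr: float = 1.0
    grad_clip_norm: float = 1.0
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(e < 1 or e > self.epochs for e in self.snapshot_epochs):
            raise ValueError("snapshot_epochs must lie within [1, epochs]")


@dataclass
class SnapshotEnsemble:
    """Segmenters saved at several late training epochs, used as voters."""

    members: dict[int, object]  # epoch tag -> Segmenter

    def __post_init__(self) -> None:
        if len(self.members) % 2 == 0:
            raise ValueError("snapshot ensemble needs an odd member count")

    @property
    def final(self):
        """The most-trained snapshot (highest epoch tag)."""
        return self.members[max(self.members)]

    @property
    def epochs(self) -> tuple[int, ...]:
        return tuple(sorted(self.members))


@dataclass(frozen=True)
class Fold:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        all_ids = self.train_ids + self.val_ids + self.test_ids
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("train/val/test sets within a fold must be disjoint")


@dataclass
class FoldPlan:
    """Cross-validation splits over section ids.

    Every section appears in exactly one fold's test set, so the fold
    ensemble evaluated on it never saw it in training.
    """

    folds: list[Fold]
    seed: int = 0

    def __post_init__(self) -> None:
        tests = [sid for f in self.folds for sid in f.test_ids]
        if len(set(tests)) != len(tests):
            raise ValueError("a section appears in more than one test set")

    @classmethod
    def leave_one_out(cls, ids: Sequence[str], n_val: int = 1, seed: int = 0) -> "FoldPlan":
        """One fold per section: that section tests, ``n_val`` rotate to validation."""
        ids = list(ids)
        n = len(ids)
        folds = []
        for i in range(n):
            test = (ids[i],)
            val = tuple(ids[(i + 1 + j) % n] for j in range(n_val))
            train = tuple(s for s in ids if s not in test + val)
            folds.append(Fold(train, val, test))
        return cls(folds, seed=seed)

    @classmethod
    def partition(cls, ids: Sequence[str], n_folds: int, n_val: int = 1,
                  seed: int = 0) -> "FoldPlan":
        """Shuffle ids and partition them into ``n_folds`` test groups."""
        rng = np.random.default_rng(seed)
        ids = list(ids)
        order = [ids[i] for i in rng.permutation(len(ids))]
        groups = [list(order[i::n_folds]) for i in range(n_folds)]
        folds = []
        for i, test in enumerate(groups):
            rest = [s for s in order if s not in test]
            val = tuple(rest[:n_val])
            train = tuple(rest[n_val:])
            folds.append(Fold(train, val, tuple(test)))
        return cls(folds, seed=seed)


def train_snapshots(
    train: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    model: UNet | None = None,
    val: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
):
    """Train a segmenter and capture weight snapshots at the tagged epochs.

    ``train``/``val`` are sequences of ``(x, y)`` pairs where ``x`` is a
    (2, H, W) window scaled to [0, 1] and ``y`` an integer (H, W) class
    map.  Loss is categorical cross-entropy; validation macro Dice is
    monitored (never used for early stopping).  Returns the
    :class:`SnapshotEnsemble` and a per-epoch metric list.
    """
    if not train:
        raise ValueError("empty training set")
    model = model or build_model()
    names = sorted(model.params)
    opt = _nn.Adadelta([model.params[n] for n in names],
                       rho=cfg.rho, eps=cfg.eps, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    xs = np.stack([np.asarray(x, dtype=np.float32) for x, _ in train])
    ys = np.stack([np.asarray(y) for _, y in train]).astype(np.int64)

    snapshots: dict[int, UNet] = {}
    metrics: list[dict] = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(xs[idx])
            loss, dlogits = _nn.softmax_ce(logits, ys[idx])
            grads = model.backward(dlogits)
            glist = [grads[n] for n in names]
            _nn.clip_grad_norm(glist, cfg.grad_clip_norm)
            opt.step(glist)
            losses.append(loss)
        row = {"epoch": epoch, "loss": float(np.mean(losses))}
        if val:
            dices = []
            for x, y in val:
                pred = model.predict(np.asarray(x, dtype=np.float32)).argmax(axis=0)
                _, macro = dice_scores(pred, np.asarray(y))
                dices.append(macro)
            row["val_dice"] = float(np.mean(dices))
        metrics.append(row)
        if epoch in cfg.snapshot_epochs:
            snapshots[epoch] = model.clone()
    return SnapshotEnsemble(members=snapshots), metrics


#: argmax tie priority when stitching confidences: normal > risk > none
_CLASS_PRIORITY = (int(ClassLabel.NORMAL), int(ClassLabel.RISK), int(ClassLabel.NONE))


def predict_section(
    model,
    nuclear: SectionImage,
    lectin: SectionImage,
    grid: PatchGrid,
) -> tuple[ClassMap, np.ndarray]:
    """Predict a whole section by patch-wise interpolation.

    Overlapping windows are predicted independently and only their
    centers stitched.  Returns the argmax class map (exact probability
    ties resolved normal > risk > none) and the stitched (3, H, W)
    confidence array.
    """
    if nuclear.shape != lectin.shape:
        raise ValueError(f"shape mismatch: {nuclear.shape} vs {lectin.shape}")
    wins_n = sliding_windows(nuclear, grid)
    wins_l = sliding_windows(lectin, grid)
    outputs = {}
    for wn, wl in zip(wins_n, wins_l):
        x = np.stack([wn.pixels, wl.pixels]).astype(np.float32) / 255.0
        outputs[wn.pos] = model.predict(x)
    conf = stitch_centers(outputs, grid, nuclear.shape)
    ordered = conf[list(_CLASS_PRIORITY)]
    labels = np.asarray(_CLASS_PRIORITY)[ordered.argmax(axis=0)]
    return ClassMap(labels.astype(np.uint8), section_id=nuclear.section_id), conf


def ensemble_vote(
    maps: Sequence[ClassMap], final: ClassMap | None = None
) -> tuple[ClassMap, ConfidenceMap]:
    """Per-pixel plurality vote of snapshot predictions.

    The winner's vote proportion forms the confidence map.  With three
    voters and three classes a 1/1/1 three-way tie is possible; it is
    resolved to the final (most-trained) snapshot's class with
    proportion 1/3.  ``final`` defaults to the last map.
    """
    if len(maps) % 2 == 0:
        raise ValueError(f"need an odd number of voters, got {len(maps)}")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"voter maps disagree on shape: {shapes}")
    final = final if final is not None else maps[-1]
    stack = np.stack([m.labels for m in maps])
    counts = np.stack([(stack == c).sum(axis=0) for c in range(3)])
    maxc = counts.max(axis=0)
    winner = counts.argmax(axis=0)
    final_count = np.take_along_axis(counts, final.labels[None].astype(np.int64), axis=0)[0]
    winner = np.where(final_count == maxc, final.labels, winner)
    proportions = maxc / len(maps)
    return (
        ClassMap(winner.astype(np.uint8), section_id=maps[0].section_id),
        ConfidenceMap(proportions),
    )


def section_confidence(z_conf: ConfidenceMap | np.ndarray) -> float:
    """Section confidence *f*: mean winning-vote proportion over all pixels."""
    if isinstance(z_conf, ConfidenceMap):
        return z_conf.mean_confidence
    return float(np.asarray(z_conf, dtype=float).mean())


def choose_threshold(
    f_values: Sequence[float], capacity: int = 12, floor: float = 0.90
) -> float:
    """Confidence threshold targeting the expert's per-iteration capacity.

    Picks the k-th largest confidence (k = min(capacity, n)) but never
    below the minimum floor that filters unstable low-confidence
    ensembles; if fewer than ``capacity`` sections clear the floor the
    threshold is the floor itself.
    """
    if len(f_values) == 0:
        raise ValueError("empty confidence list")
    k = min(capacity, len(f_values))
    kth = sorted(f_values, reverse=True)[k - 1]
    return max(floor, kth)


def least_overfit_fold(fold_metrics) -> object:
    """Fold id with the lowest test Dice (ties broken by fold order)."""
    if isinstance(fold_metrics, Mapping):
        items = list(fold_metrics.items())
    else:
        items = list(fold_metrics)
    if not items:
        raise ValueError("no fold metrics")
    best_id, best = items[0]
    for fid, d in items[1:]:
        if d < best:
            best_id, best = fid, d
    return best_id
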