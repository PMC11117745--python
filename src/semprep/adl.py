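"""Active-deep-learning orchestration, expert protocol and run accounting.

One ADL iteration trains a snapshot ensemble per cross-validation fold
on the current training data, picks the *least overfit* fold (lowest
test Dice — the ensemble least likely to be confidently wrong), lets
its most-trained snapshot preprocess and predict the unlabeled active
set, has the two earlier snapshots vote on the adjusted inputs, and
presents the sections whose section confidence *f* clears a threshold
to an expert for a quick accept/reject.  Accepted sections — adjusted
images plus the ensemble's voted segmentation as the label — join
every fold's training set for the next iteration.

The expert time model prices an accept (evaluation plus quick edits)
at 5 minutes and a reject at 1 minute; manual ground-truth painting of
a whole section is priced at 2 hours.  Rejected sections remain in the
active set and may be re-presented (each presentation costs time).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .adjust import (
    adaptive_hist_equalize,
    difference_of_gaussians,
    hist_equalize,
    hist_match,
)
from .core import (
    Channel,
    ClassLabel,
    ClassMap,
    SectionImage,
    dice_scores,
)
from .patchwork import PatchGrid, grid_patches
from .segnet import (
    FoldPlan,
    TrainConfig,
    UNet,
    choose_threshold,
    ensemble_vote,
    least_overfit_fold,
    predict_section,
    train_snapshots,
)
from .semantic import SPConfig, bsp_iterate, extract_metric
from .synthdata import Section

__all__ = [
    "METHODS",
    "ExpertDecision",
    "ActiveSet",
    "RunLedger",
    "ADLConfig",
    "ADLRun",
    "simulated_expert",
    "make_simulated_expert",
    "dataset_size_pct",
    "acceptance_pct",
    "expert_time_hours",
    "time_saved_pct",
]

METHODS = ("raw", "dog", "he", "ahe", "hm", "sp", "bsp", "gdbsp")
_SEMANTIC = ("sp", "bsp", "gdbsp")


# ---------------------------------------------------------------------------
# accounting (the bookkeeping behind the run tables)
# ---------------------------------------------------------------------------

def _round_pct(x: float) -> int:
    return int(np.floor(x + 0.5))


def dataset_size_pct(base_samples: int, accepted_samples: int) -> int:
    """Dataset size after acceptance, as % of the base sample count."""
    if base_samples <= 0:
        raise ValueError("base_samples must be > 0")
    return _round_pct(100.0 * (base_samples + accepted_samples) / base_samples)


def acceptance_pct(accepted_sections: int, total_sections: int) -> int:
    """Share of the active set accepted, in percent."""
    if total_sections <= 0:
        raise ValueError("total_sections must be > 0")
    return _round_pct(100.0 * accepted_sections / total_sections)


def expert_time_hours(
    accept_decisions: int,
    reject_decisions: int,
    accept_minutes: float = 5.0,
    reject_minutes: float = 1.0,
) -> float:
    """Expert hours under the 5-min-accept / 1-min-reject time model."""
    return (accept_minutes * accept_decisions + reject_minutes * reject_decisions) / 60.0


def time_saved_pct(expert_hours: float, manual_hours: float) -> int:
    """Expert time saved relative to fully manual labeling, in percent."""
    if manual_hours <= 0:
        raise ValueError("manual_hours must be > 0")
    return _round_pct(100.0 * (1.0 - expert_hours / manual_hours))


# ---------------------------------------------------------------------------
# expert protocol
# ---------------------------------------------------------------------------

@dataclass
class ExpertDecision:
    section_id: str
    verdict: str  # "accept" | "reject"
    minutes: float
    edits: list[str] | None = None


def simulated_expert(
    candidate: ClassMap,
    truth: ClassMap,
    accept_dice: float = 0.90,
    accept_minutes: float = 5.0,
    reject_minutes: float = 1.0,
) -> ExpertDecision:
    """Stand-in for the human accept/reject decision on synthetic data.

    Accepts iff the candidate's macro Dice against the hidden truth
    reaches ``accept_dice`` (boundary inclusive); minutes follow the
    5/1 time model.
    """
    _, macro = dice_scores(candidate, truth)
    accept = macro >= accept_dice
    return ExpertDecision(
        section_id=candidate.section_id,
        verdict="accept" if accept else "reject",
        minutes=accept_minutes if accept else reject_minutes,
    )


def make_simulated_expert(
    truth_lookup: Callable[[str], ClassMap],
    accept_dice: float = 0.90,
    accept_minutes: float = 5.0,
    reject_minutes: float = 1.0,
) -> Callable[[str, ClassMap], ExpertDecision]:
    """Bind :func:`simulated_expert` to a hidden-truth oracle."""

    def expert(section_id: str, candidate: ClassMap) -> ExpertDecision:
        return simulated_expert(
            candidate,
            truth_lookup(section_id),
            accept_dice=accept_dice,
            accept_minutes=accept_minutes,
            reject_minutes=reject_minutes,
        )

    return expert


# ---------------------------------------------------------------------------
# run state
# ---------------------------------------------------------------------------

@dataclass
class ActiveSet:
    """Unlabeled sections awaiting automatic labeling and expert review."""

    sections: dict[str, Section]
    status: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid in self.sections:
            self.status.setdefault(sid, "pending")

    @property
    def pending(self) -> list[str]:
        return [sid for sid, st in self.status.items() if st != "accepted"]

    @property
    def accepted(self) -> list[str]:
        return [sid for sid, st in self.status.items() if st == "accepted"]


@dataclass
class RunLedger:
    """Per-iteration accounting mirroring the run tables."""

    base_sections: int
    base_samples: int
    rows: list[dict] = field(default_factory=list)

    def append(self, row: dict) -> None:
        if self.rows:
            prev = self.rows[-1]
            if row["cum_accepted_samples"] < prev["cum_accepted_samples"]:
                raise ValueError("cumulative accepted samples decreased")
            if row["cum_expert_minutes"] < prev["cum_expert_minutes"]:
                raise ValueError("cumulative expert minutes decreased")
        self.rows.append(row)

    def to_dataframe(self) -> pd.DataFrame:
        columns = [
            "iteration", "method", "mean_active_confidence", "f_thresh",
            "presented", "accepted_sections", "rejected_sections",
            "accepted_samples", "cum_accepted_sections", "cum_accepted_samples",
            "pct_active_accepted_cum", "pct_remaining_accepted",
            "cum_expert_minutes", "cum_manual_hours", "dataset_size_pct",
        ]
        return pd.DataFrame(self.rows, columns=columns)


@dataclass
class ADLConfig:
    """Configuration of an ADL run.

    Thresholds follow the study protocol: a 0.90 confidence floor, an
    expert capacity of 12 sections per iteration (~1 h of review), and
    an optional stricter 0.97 floor preset for verification runs on
    labeled data.  ``model_width``/``model_levels`` size the segmenter;
    desk-scale runs use small values.
    """

    method: str = "gdbsp"
    sp: SPConfig = field(default_factory=SPConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    grid: PatchGrid = field(default_factory=PatchGrid)
    floor: float = 0.90
    capacity: int = 12
    accept_dice: float = 0.90
    accept_minutes: float = 5.0
    reject_minutes: float = 1.0
    manual_hours_per_section: float = 2.0
    model_width: int = 16
    model_levels: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")


class ADLRun:
    """Stateful active-deep-learning run over a fold plan and an active set.

    Parameters
    ----------
    base_sections
        Labeled sections (ground truth present) forming the core
        training data.
    fold_plan
        Cross-validation splits over the base section ids.
    active
        The unlabeled active set.
    reference
        Expert-designated high-quality section providing the semantic
        target metrics (and the histogram-matching target).
    expert
        Callable ``(section_id, candidate map) -> ExpertDecision``.
    """

    def __init__(
        self,
        base_sections: Sequence[Section],
        fold_plan: FoldPlan,
        active: ActiveSet,
        reference: Section,
        expert: Callable[[str, ClassMap], ExpertDecision],
        cfg: ADLConfig,
    ):
        self.base = {s.section_id: s for s in base_sections}
        for s in self.base.values():
            if s.truth is None:
                raise ValueError(f"base section {s.section_id} lacks ground truth")
        self.fold_plan = fold_plan
        self.active = active
        self.reference = reference
        self.expert = expert
        self.cfg = cfg
        self.extras: list[tuple[SectionImage, SectionImage, ClassMap]] = []
        self.ledger = RunLedger(
            base_sections=len(self.base),
            base_samples=sum(
                self._n_samples(s.nuclear) for s in self.base.values()
            ),
        )
        self.iteration = 0
        self._targets = self._reference_targets()
        self.initial_active_size = len(active.sections)

    # -- helpers --------------------------------------------------------
    def _n_samples(self, img: SectionImage) -> int:
        return len(grid_patches(img, self.cfg.grid.window))

    def _reference_targets(self) -> dict[bool, dict[Channel, object]]:
        """Target metrics (2-D and 4-D) from the reference section's truth."""
        ref = self.reference
        if ref.truth is not None:
            nuc_mask = ref.truth.labels != int(ClassLabel.NONE)
            lec_mask = ref.truth.labels == int(ClassLabel.NORMAL)
        else:  # fall back to Otsu if the reference is unlabeled
            from .semantic import otsu_binary

            nuc_mask = otsu_binary(ref.nuclear)
            lec_mask = otsu_binary(ref.lectin)
        out = {}
        for use_std in (False, True):
            out[use_std] = {
                Channel.NUCLEAR: extract_metric(ref.nuclear, nuc_mask, use_std),
                Channel.LECTIN: extract_metric(ref.lectin, lec_mask, use_std),
            }
        return out

    def _benchmark_prep(
        self, nuclear: SectionImage, lectin: SectionImage
    ) -> tuple[SectionImage, SectionImage]:
        method = self.cfg.method
        if method == "raw" or method in _SEMANTIC:
            return nuclear, lectin
        if method == "dog":
            return difference_of_gaussians(nuclear), difference_of_gaussians(lectin)
        if method == "he":
            return hist_equalize(nuclear), hist_equalize(lectin)
        if method == "ahe":
            return adaptive_hist_equalize(nuclear), adaptive_hist_equalize(lectin)
        if method == "hm":
            return (
                hist_match(nuclear, self.reference.nuclear),
                hist_match(lectin, self.reference.lectin),
            )
        raise AssertionError(method)

    def _patches(
        self, nuclear: SectionImage, lectin: SectionImage, labels: ClassMap
    ) -> list[tuple[np.ndarray, np.ndarray]]:
        w = self.cfg.grid.window
        pn = grid_patches(nuclear, w)
        pl = grid_patches(lectin, w)
        py = grid_patches(labels.labels, w)
        return [
            (np.stack([a, b]).astype(np.float32) / 255.0, y.astype(np.int64))
            for (a, _), (b, _), (y, _) in zip(pn, pl, py)
        ]

    def _fold_training_data(self, fold) -> list[tuple[np.ndarray, np.ndarray]]:
        data = []
        for sid in fold.train_ids:
            s = self.base[sid]
            n, l = self._benchmark_prep(s.nuclear, s.lectin)
            data.extend(self._patches(n, l, s.truth))
        for n, l, labels in self.extras:
            data.extend(self._patches(n, l, labels))
        return data

    def _ensemble_predict(self, ensemble, nuclear, lectin):
        maps = []
        for epoch in ensemble.epochs:
            m, _ = predict_section(ensemble.members[epoch], nuclear, lectin, self.cfg.grid)
            maps.append(m)
        return ensemble_vote(maps, final=maps[-1])

    def _sp_config(self) -> SPConfig:
        cfg = self.cfg.sp
        if self.cfg.method == "sp":
            return dataclasses.replace(cfg, bootstrap_iters=1, use_std=False)
        if self.cfg.method == "bsp":
            return dataclasses.replace(cfg, use_std=False)
        return dataclasses.replace(cfg, use_std=True)  # gdbsp

    # -- one iteration --------------------------------------------------
    def run_iteration(self) -> dict:
        """Execute one full ADL iteration; returns the ledger row."""
        cfg = self.cfg
        self.iteration += 1

        # 1-2: train all fold ensembles, cross-validate
        ensembles, fold_dice = {}, {}
        for k, fold in enumerate(self.fold_plan.folds):
            train_cfg = dataclasses.replace(
                cfg.train, seed=(cfg.seed * 9973 + self.iteration * 101 + k) % (2**31)
            )
            model = UNet(
                base_width=cfg.model_width,
                levels=cfg.model_levels,
                seed=(cfg.seed * 7919 + k) % (2**31),
            )
            ensemble, _ = train_snapshots(
                self._fold_training_data(fold), train_cfg, model=model
            )
            ensembles[k] = ensemble
            dices = []
            for sid in fold.test_ids:
                s = self.base[sid]
                n, l = self._benchmark_prep(s.nuclear, s.lectin)
                z, _ = self._ensemble_predict(ensemble, n, l)
                _, macro = dice_scores(z, s.truth)
                dices.append(macro)
            fold_dice[k] = float(np.mean(dices)) if dices else 1.0

        # 3: the least overfit fold's ensemble works the active set
        working = ensembles[least_overfit_fold(fold_dice)]
        m_final = working.final

        # 3-5: preprocess + predict + vote every pending section
        results = {}
        for sid in self.active.pending:
            s = self.active.sections[sid]
            if cfg.method in _SEMANTIC:
                sp_cfg = self._sp_config()
                boot = bsp_iterate(
                    s.nuclear,
                    s.lectin,
                    lambda n, l: predict_section(m_final, n, l, cfg.grid)[0],
                    self._targets[sp_cfg.use_std],
                    sp_cfg,
                )
                adj_n = boot.adjusted[Channel.NUCLEAR]
                adj_l = boot.adjusted[Channel.LECTIN]
                map_final = boot.class_map
            else:
                adj_n, adj_l = self._benchmark_prep(s.nuclear, s.lectin)
                map_final, _ = predict_section(m_final, adj_n, adj_l, cfg.grid)
            earlier = [
                predict_section(working.members[e], adj_n, adj_l, cfg.grid)[0]
                for e in working.epochs[:-1]
            ]
            z_ens, z_conf = ensemble_vote(earlier + [map_final], final=map_final)
            results[sid] = (adj_n, adj_l, z_ens, z_conf.mean_confidence)

        f_values = {sid: r[3] for sid, r in results.items()}
        mean_conf = float(np.mean(list(f_values.values()))) if f_values else float("nan")
        f_thresh = (
            choose_threshold(list(f_values.values()), cfg.capacity, cfg.floor)
            if f_values
            else cfg.floor
        )

        # 6-8: expert review; accepted sections join every training set
        accepted, rejected, minutes = [], [], 0.0
        for sid, (adj_n, adj_l, z_ens, f) in results.items():
            if f < f_thresh:
                continue
            decision = self.expert(sid, z_ens)
            minutes += decision.minutes
            if decision.verdict == "accept":
                accepted.append(sid)
                self.active.status[sid] = "accepted"
                self.extras.append((adj_n, adj_l, z_ens))
            else:
                rejected.append(sid)
                self.active.status[sid] = "rejected"

        accepted_samples = sum(
            self._n_samples(self.active.sections[sid].nuclear) for sid in accepted
        )
        prev = self.ledger.rows[-1] if self.ledger.rows else None
        cum_sections = (prev["cum_accepted_sections"] if prev else 0) + len(accepted)
        cum_samples = (prev["cum_accepted_samples"] if prev else 0) + accepted_samples
        cum_minutes = (prev["cum_expert_minutes"] if prev else 0.0) + minutes
        n_remaining_before = len(results)
        row = {
            "iteration": self.iteration,
            "method": cfg.method,
            "mean_active_confidence": mean_conf,
            "f_thresh": f_thresh,
            "presented": len(accepted) + len(rejected),
            "accepted_sections": len(accepted),
            "rejected_sections": len(rejected),
            "accepted_samples": accepted_samples,
            "cum_accepted_sections": cum_sections,
            "cum_accepted_samples": cum_samples,
            # both normalizations of "% accepted": vs the original active
            # set and vs the sections still pending this iteration
            "pct_active_accepted_cum": acceptance_pct(
                cum_sections, self.initial_active_size
            ),
            "pct_remaining_accepted": (
                acceptance_pct(len(accepted), n_remaining_before)
                if n_remaining_before
                else 0
            ),
            "cum_expert_minutes": cum_minutes,
            "cum_manual_hours": cfg.manual_hours_per_section * cum_sections,
            "dataset_size_pct": dataset_size_pct(self.ledger.base_samples, cum_samples),
        }
        self.ledger.append(row)
        # conservation: accepted + still-pending == initial active set
        assert len(self.active.accepted) + len(self.active.pending) == (
            self.initial_active_size
        )
        return row

    def run(self, n_iterations: int) -> RunLedger:
        for _ in range(n_iterations):
            if not self.active.pending:
                break
            self.run_iteration()
        return self.ledger
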