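"""Cohort splitting, patient-grouped cross-validation, training and ablation.

The protocol mirrors a follow-up-heavy clinical cohort: the test set is drawn
only from non-follow-up lesion cases (so no patient can appear on both sides
of the split), normal brains always stay in training, and k-fold
cross-validation partitions *patients*, never scans. Model selection picks
the epoch minimizing the fold-averaged validation Dice-based loss, then
retrains on the full training set for that many epochs.

The ablation ladder reproduces the five training strategies of the study
design at phantom scale:

  A  pre-training domain only (no fine-tuning)
  B  target domain from scratch
  C  pre-train, then fine-tune on the target domain
  D  C plus lesion-free brains, soft Dice loss
  E  C plus lesion-free brains, balanced Dice loss

All five are evaluated on the identical fixed test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import preprocess_case, read_case
from .losses import (
    LossConfig,
    balanced_dice_loss,
    balanced_dice_loss_grad,
    soft_dice_loss,
    soft_dice_loss_grad,
)
from .metrics import CaseMetrics, aggregate_metrics, evaluate_case
from .network import NetworkConfig, build_model, predict_case
from .nn import Adam, UNet3D

__all__ = [
    "TrainConfig",
    "StrategyResult",
    "split_cohort",
    "make_folds",
    "learning_rate",
    "train_model",
    "cross_validate",
    "select_final_model",
    "load_cases",
    "run_ablation",
    "STRATEGY_LABELS",
]

STRATEGY_LABELS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Adam with an initial learning rate of 1e-4, halved every 30 epochs
    (``lr(e) = initial_lr * 0.5 ** (e // lr_halving_period)``). The loss is
    summed over the images of each mini-batch. ``loss_mode`` selects the
    plain soft Dice loss or the balanced Dice loss with weight ``beta``.
    """

    initial_lr: float = 1e-4
    lr_halving_period: int = 30
    max_epochs: int = 300
    batch_size: int = 4
    loss_mode: str = "soft-dice"
    beta: float = 100.0
    epsilon: float = 1e-5
    seed: int = 0
    init_weights: dict[str, np.ndarray] | None = field(
        default=None, repr=False, hash=False, compare=False
    )

    def __post_init__(self) -> None:
        if not self.initial_lr > 0:
            raise ValueError("initial_lr must be > 0")
        if self.lr_halving_period < 1:
            raise ValueError("lr_halving_period must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss_mode not in ("soft-dice", "bdl"):
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")

    @property
    def loss_config(self) -> LossConfig:
        return LossConfig(epsilon=self.epsilon, beta=self.beta)


def learning_rate(cfg: TrainConfig, epoch: int) -> float:
    """Closed-form step schedule: ``initial_lr * 0.5 ** floor(e / period)``."""
    return cfg.initial_lr * 0.5 ** (epoch // cfg.lr_halving_period)


# ---------------------------------------------------------------------------
# cohort splitting
# ---------------------------------------------------------------------------

def split_cohort(
    manifest: pd.DataFrame, n_test: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reserve a test set of ``n_test`` scans from non-follow-up lesion cases.

    Follow-up patients contribute several scans each, so drawing the test set
    only from single-scan (non-follow-up) lesion patients guarantees no
    patient straddles the train/test boundary. Normal brains always stay in
    training — they are augmentation data, and evaluation is on lesions.
    """
    eligible = manifest[(~manifest.followup) & manifest.has_lesion]
    if n_test > len(eligible):
        raise ValueError(
            f"cannot reserve {n_test} test scans: only {len(eligible)} "
            "non-follow-up lesion cases available"
        )
    rng = np.random.default_rng(seed)
    test_idx = rng.choice(eligible.index.to_numpy(), size=n_test, replace=False)
    test = manifest.loc[np.sort(test_idx)].reset_index(drop=True)
    train = manifest.drop(index=test_idx).reset_index(drop=True)
    return train, test


def make_folds(
    manifest: pd.DataFrame, k: int = 5, seed: int = 0
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Patient-grouped k-fold splits of a training manifest.

    Lesion patients are shuffled and partitioned into ``k`` folds whose
    patient counts differ by at most one; all scans of a patient share a
    fold. Normal brains are excluded from every validation side and included
    in every training side (they only ever augment training).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    lesion = manifest[manifest.has_lesion]
    normal = manifest[~manifest.has_lesion]
    patients = lesion.patient_id.unique()
    if len(patients) < k:
        raise ValueError(f"{len(patients)} patients cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    patients = rng.permutation(patients)
    chunks = np.array_split(patients, k)
    folds = []
    for chunk in chunks:
        val = lesion[lesion.patient_id.isin(chunk)].reset_index(drop=True)
        tr = pd.concat(
            [lesion[~lesion.patient_id.isin(chunk)], normal]
        ).reset_index(drop=True)
        folds.append((tr, val))
    return folds


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

Case = tuple[np.ndarray, np.ndarray]  # (4,S,S,S) volume, (S,S,S) mask


def _case_loss_and_grad(
    model: UNet3D, vol: np.ndarray, mask: np.ndarray, cfg: TrainConfig
) -> float:
    """Forward + backward for one case; gradients accumulate in the model."""
    p = model.forward(vol)
    lcfg = cfg.loss_config
    if cfg.loss_mode == "bdl":
        loss = balanced_dice_loss(p, mask, lcfg)
        g = balanced_dice_loss_grad(p, mask, lcfg)
    else:
        loss = soft_dice_loss(p, mask, lcfg)
        g = soft_dice_loss_grad(p, mask, lcfg)
    model.backward(g.astype(model.dtype))
    return loss


def _validation_loss(
    model: UNet3D, val_cases: Sequence[Case], cfg: TrainConfig
) -> float:
    """Mean soft Dice loss over lesion validation cases.

    Model selection compares strategies that do or do not train on
    lesion-free brains, so the validation score is computed on lesion cases
    only (and with the unweighted loss) to stay comparable across them.
    """
    lcfg = cfg.loss_config
    losses = [
        soft_dice_loss(model.forward(v), m, lcfg)
        for v, m in val_cases
        if m.max() > 0
    ]
    return float(np.mean(losses)) if losses else float("nan")


def train_model(
    train_cases: Sequence[Case],
    val_cases: Sequence[Case],
    net_cfg: NetworkConfig,
    cfg: TrainConfig,
) -> tuple[UNet3D, dict]:
    """Train a U-Net, returning the model and its per-epoch history.

    History records the training loss (sum over images, averaged over
    batches), the validation Dice-based loss, and the learning rate at each
    epoch, plus the validation loss of the initial (untrained) weights —
    useful for judging what a pre-trained initialization buys.
    """
    if not train_cases:
        raise ValueError("train_model requires a nonempty training set")
    model = build_model(net_cfg)
    if cfg.init_weights is not None:
        model.load_state_dict(cfg.init_weights)
    opt = Adam(model, lr=cfg.initial_lr)
    rng = np.random.default_rng(cfg.seed)
    history: dict = {
        "train_loss": [],
        "val_loss": [],
        "lr": [],
        "initial_val_loss": _validation_loss(model, val_cases, cfg)
        if val_cases
        else float("nan"),
    }
    n = len(train_cases)
    for epoch in range(cfg.max_epochs):
        opt.lr = learning_rate(cfg, epoch)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            opt.zero_grad()
            batch_total = 0.0
            for i in batch:
                vol, mask = train_cases[i]
                batch_total += _case_loss_and_grad(model, vol, mask, cfg)
            opt.step()
            epoch_losses.append(batch_total)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(
            _validation_loss(model, val_cases, cfg) if val_cases else float("nan")
        )
        history["lr"].append(opt.lr)
    return model, history


def cross_validate(
    folds: Sequence[tuple[Sequence[Case], Sequence[Case]]],
    net_cfg: NetworkConfig,
    cfg: TrainConfig,
) -> list[dict]:
    """Train one model per fold, returning the fold histories."""
    return [
        train_model(tr, val, net_cfg, cfg)[1] for tr, val in folds
    ]


def optimize_beta(
    folds: Sequence[tuple[Sequence[Case], Sequence[Case]]],
    net_cfg: NetworkConfig,
    cfg: TrainConfig,
    grid: Sequence[float] = (1.0, 10.0, 100.0, 1000.0),
) -> tuple[float, dict[float, float]]:
    """Select the BDL weight by k-fold cross-validation over a grid.

    For each candidate beta the folds are trained with the balanced Dice
    loss and scored by the best (minimum over epochs) fold-averaged
    validation loss; the validation loss is the unweighted soft Dice loss
    over lesion cases, so scores are comparable across betas. Returns the
    winning beta and the per-beta scores (ties break toward the smallest
    beta).
    """
    if not grid:
        raise ValueError("beta grid must be nonempty")
    scores: dict[float, float] = {}
    for beta in grid:
        beta_cfg = TrainConfig(
            **{
                **{f: getattr(cfg, f) for f in (
                    "initial_lr", "lr_halving_period", "max_epochs",
                    "batch_size", "epsilon", "seed",
                )},
                "loss_mode": "bdl",
                "beta": float(beta),
                "init_weights": cfg.init_weights,
            }
        )
        histories = cross_validate(folds, net_cfg, beta_cfg)
        curve = np.array([h["val_loss"] for h in histories]).mean(axis=0)
        scores[float(beta)] = float(curve.min())
    best = min(scores, key=lambda b: (scores[b], b))
    return best, scores


def select_final_model(
    fold_histories: Sequence[dict],
    train_cases: Sequence[Case],
    net_cfg: NetworkConfig,
    cfg: TrainConfig,
) -> tuple[UNet3D, int]:
    """Pick epoch* = argmin of the fold-averaged validation loss and retrain.

    Ties break toward the earliest epoch (smallest training budget). The
    final model is retrained from the same initialization on the full
    training set for ``epoch* + 1`` epochs, i.e. through the selected epoch.
    """
    lengths = {len(h["val_loss"]) for h in fold_histories}
    if len(lengths) != 1:
        raise ValueError("fold histories have unequal lengths")
    curves = np.array([h["val_loss"] for h in fold_histories], dtype=np.float64)
    mean_curve = curves.mean(axis=0)
    epoch_star = int(np.argmin(mean_curve))  # argmin takes the first minimum
    final_cfg = TrainConfig(
        **{
            **{f: getattr(cfg, f) for f in (
                "initial_lr", "lr_halving_period", "batch_size", "loss_mode",
                "beta", "epsilon", "seed",
            )},
            "max_epochs": epoch_star + 1,
            "init_weights": cfg.init_weights,
        }
    )
    model, _ = train_model(train_cases, [], net_cfg, final_cfg)
    return model, epoch_star


# ---------------------------------------------------------------------------
# ablation ladder
# ---------------------------------------------------------------------------

@dataclass
class StrategyResult:
    """One row of the ablation table: a strategy scored on the fixed test set."""

    label: str
    n_patients: int
    n_scans: int
    case_metrics: list[CaseMetrics]
    aggregate: dict[str, dict[str, float]]
    initial_val_loss: float = float("nan")
    history: dict | None = None

    @property
    def mean_dice(self) -> float:
        return self.aggregate["dice"]["mean"]


def load_cases(
    manifest: pd.DataFrame, cohort_dir: str | Path, input_size: int
) -> list[Case]:
    """Read and preprocess every scan of a manifest to the network grid."""
    cohort_dir = Path(cohort_dir)
    cases = []
    for row in manifest.itertuples():
        vol, mask, _ = read_case(cohort_dir / row.path)
        vol, mask = preprocess_case(vol, mask, input_size)
        cases.append((vol, mask))
    return cases


def _evaluate_on(
    model: UNet3D, test_cases: Sequence[Case], threshold: float = 0.5
) -> tuple[list[CaseMetrics], dict]:
    ms = [evaluate_case(predict_case(model, v), m, threshold) for v, m in test_cases]
    return ms, aggregate_metrics(ms)


def run_ablation(
    manifest: pd.DataFrame,
    cohort_dir: str | Path,
    pretrain_cases: Sequence[Case],
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    n_test: int,
    strategies: Sequence[str] = STRATEGY_LABELS,
    pretrain_epochs: int | None = None,
    seed: int = 0,
) -> list[StrategyResult]:
    """Run the five-strategy ablation ladder on one fixed train/test split.

    All strategies share the identical test split (drawn once from
    non-follow-up lesion cases with ``seed``) and, for B-E, the identical
    target training scans. A validation fold (one patient-grouped fold of
    the training set) supplies the per-epoch validation curve; strategies
    train on the remaining folds. Returns one :class:`StrategyResult` per
    requested strategy, in ladder order.
    """
    for s in strategies:
        if s not in STRATEGY_LABELS:
            raise ValueError(f"unknown strategy {s!r}")
    train_man, test_man = split_cohort(manifest, n_test, seed)
    test_cases = load_cases(test_man, cohort_dir, net_cfg.input_size)

    n_lesion_patients = train_man[train_man.has_lesion].patient_id.nunique()
    folds = make_folds(train_man, k=min(5, n_lesion_patients), seed=seed)
    fit_man, val_man = folds[0][0], folds[0][1]
    val_cases = load_cases(val_man, cohort_dir, net_cfg.input_size)
    fit_lesion = fit_man[fit_man.has_lesion]
    fit_normal = fit_man[~fit_man.has_lesion]
    lesion_cases = load_cases(fit_lesion, cohort_dir, net_cfg.input_size)
    normal_cases = load_cases(fit_normal, cohort_dir, net_cfg.input_size)

    needs_pretrain = any(s in strategies for s in ("A", "C", "D", "E"))
    pretrain_state = None
    if needs_pretrain:
        if not pretrain_cases:
            raise ValueError("strategies A/C/D/E require pretrain_cases")
        pt_cfg = TrainConfig(
            **{
                **{f: getattr(train_cfg, f) for f in (
                    "initial_lr", "lr_halving_period", "batch_size",
                    "epsilon", "seed",
                )},
                "loss_mode": "soft-dice",
                "max_epochs": pretrain_epochs or train_cfg.max_epochs,
            }
        )
        pretrain_model, _ = train_model(pretrain_cases, [], net_cfg, pt_cfg)
        pretrain_state = pretrain_model.state_dict()

    def _cfg(loss_mode: str, init: dict | None) -> TrainConfig:
        return TrainConfig(
            **{
                **{f: getattr(train_cfg, f) for f in (
                    "initial_lr", "lr_halving_period", "max_epochs",
                    "batch_size", "beta", "epsilon", "seed",
                )},
                "loss_mode": loss_mode,
                "init_weights": init,
            }
        )

    recipes = {
        # label -> (training cases, loss mode, init state or None)
        "B": (lesion_cases, "soft-dice", None),
        "C": (lesion_cases, "soft-dice", pretrain_state),
        "D": (lesion_cases + normal_cases, "soft-dice", pretrain_state),
        "E": (lesion_cases + normal_cases, "bdl", pretrain_state),
    }
    results = []
    for label in STRATEGY_LABELS:
        if label not in strategies:
            continue
        if label == "A":
            model, _ = load_checkpoint_state(pretrain_state, net_cfg)
            history = None
            init_val = float("nan")
            n_pat = len(pretrain_cases)
            n_scan = len(pretrain_cases)
        else:
            cases, loss_mode, init = recipes[label]
            model, history = train_model(
                cases, val_cases, net_cfg, _cfg(loss_mode, init)
            )
            init_val = history["initial_val_loss"]
            man = fit_man if label in ("D", "E") else fit_lesion
            n_pat = man.patient_id.nunique()
            n_scan = len(cases)
        case_ms, agg = _evaluate_on(model, test_cases)
        results.append(
            StrategyResult(
                label=label,
                n_patients=n_pat,
                n_scans=n_scan,
                case_metrics=case_ms,
                aggregate=agg,
                initial_val_loss=init_val,
                history=history,
            )
        )
    return results


def load_checkpoint_state(
    state: dict[str, np.ndarray], net_cfg: NetworkConfig
) -> tuple[UNet3D, NetworkConfig]:
    """Build a model from a config and load an in-memory state dict."""
    model = build_model(net_cfg)
    model.load_state_dict(state)
    return model, net_cfg


def ablation_table(results: Sequence[StrategyResult]) -> pd.DataFrame:
    """Summarize strategy results in the shape of the study's results table."""
    rows = []
    for r in results:
        a = r.aggregate
        rows.append(
            {
                "strategy": r.label,
                "patients": r.n_patients,
                "total_mris": r.n_scans,
                "dice_mean": a["dice"]["mean"],
                "dice_sd": a["dice"]["sd"],
                "recall_mean": a["recall"]["mean"],
                "recall_sd": a["recall"]["sd"],
                "precision_mean": a["precision"]["mean"],
                "precision_sd": a["precision"]["sd"],
                "dice_min": a["dice"]["min"],
                "dice_max": a["dice"]["max"],
            }
        )
    return pd.DataFrame(rows)
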