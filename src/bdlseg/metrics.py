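"""Segmentation evaluation: per-case Dice / recall / precision and aggregates.

Predictions are binarized at a threshold (default 0.5) before scoring. The
empty-set conventions: when nothing is annotated and nothing is predicted,
all three metrics are 1 (agreement on emptiness); a degenerate denominator
with disagreement scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .losses import dsc

__all__ = ["CaseMetrics", "evaluate_case", "aggregate_metrics", "write_metrics_table"]


@dataclass(frozen=True)
class CaseMetrics:
    """Dice, recall (sensitivity) and precision (PPV) for one scan, all in [0, 1]."""

    dice: float
    recall: float
    precision: float


def evaluate_case(
    p: np.ndarray, t: np.ndarray, threshold: float = 0.5
) -> CaseMetrics:
    """Binarize ``p`` at ``threshold`` and score it against the binary mask ``t``.

    recall = TP/(TP+FN); precision = TP/(TP+FP); Dice on the binarized map.
    Empty denominators: recall is 1 if there is nothing to find (sum(T)=0)
    and nothing was predicted, else 0 for a miss; precision is 1 if nothing
    was predicted and nothing was annotated, else 0 for pure false positives.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    p = np.asarray(p, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"prediction and truth shapes differ: {p.shape} vs {t.shape}")
    pb = (p >= threshold).astype(np.float64)
    tp = float((pb * t).sum())
    fp = float((pb * (1.0 - t)).sum())
    fn = float(((1.0 - pb) * t).sum())

    recall = tp / (tp + fn) if (tp + fn) > 0 else (1.0 if fp == 0 else 0.0)
    precision = tp / (tp + fp) if (tp + fp) > 0 else (1.0 if fn == 0 else 0.0)
    return CaseMetrics(dice=dsc(pb, t), recall=recall, precision=precision)


def aggregate_metrics(
    cases: list[CaseMetrics], ddof: int = 1
) -> dict[str, dict[str, float]]:
    """Mean, sd (sample sd by default; ``ddof=0`` for population), min, max.

    The sd flavor matters at small n: over the five cross-validation fold
    scores only the population sd reproduces the conventionally printed
    two-decimal value, while the sample sd is the safer default for
    test-set summaries.
    """
    if not cases:
        raise ValueError("aggregate_metrics requires at least one case")
    out: dict[str, dict[str, float]] = {}
    for name in ("dice", "recall", "precision"):
        vals = np.array([getattr(c, name) for c in cases], dtype=np.float64)
        sd = float(vals.std(ddof=ddof)) if len(vals) > 1 else 0.0
        out[name] = {
            "mean": float(vals.mean()),
            "sd": sd,
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return out


def write_metrics_table(
    cases: list[CaseMetrics],
    path: str | Path,
    case_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Write per-case rows plus an aggregate footer (mean, sd, min, max) as CSV."""
    if case_ids is None:
        case_ids = [f"case_{i:03d}" for i in range(len(cases))]
    if len(case_ids) != len(cases):
        raise ValueError("case_ids length must match cases")
    rows = [{"case": cid, **asdict(c)} for cid, c in zip(case_ids, cases)]
    agg = aggregate_metrics(cases)
    for stat in ("mean", "sd", "min", "max"):
        rows.append({"case": stat, **{m: agg[m][stat] for m in agg}})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
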