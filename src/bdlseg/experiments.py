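"""Preset desk-scale experiments: the scaled-down ablation study.

The full ablation ladder on clinical volumes needs GPU-scale training; this
module defines the phantom-scale analog used for directional checks: a
19-scan target cohort (4 follow-up patients with 8 scans, 8 single-scan
patients, 3 normal brains) on a 16-voxel grid, a 4-filter depth-3 U-Net and
an 8-case pretrain-like phantom set, trained for 30 epochs per strategy.
The quantities of interest are the sign of the Dice gap between strategy E
(transfer + normals + balanced Dice loss) and strategy B (scratch), and
whether transfer (C) starts from a lower validation loss than scratch (B).
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import preprocess_case
from .network import NetworkConfig
from .phantoms import CohortSpec, PhantomConfig, generate_brain, generate_cohort
from .training import StrategyResult, TrainConfig, run_ablation

__all__ = ["toy_ablation", "TOY_NET", "TOY_COHORT", "TOY_PHANTOM"]

TOY_NET = NetworkConfig(base_filters=4, depth=3, input_size=16, seed=0)
TOY_COHORT = dict(
    n_followup_patients=4,
    n_followup_scans=8,
    n_single_scan_patients=8,
    n_normal_subjects=3,
)
TOY_PHANTOM = PhantomConfig(
    grid_size=16, domain="target-like", lesion_volume_fraction=0.03
)
TOY_EPOCHS = 30
TOY_N_TEST = 4
TOY_N_PRETRAIN = 8


def toy_ablation(
    seed: int,
    strategies: Sequence[str] = ("B", "C", "E"),
    cohort_dir: str | Path | None = None,
) -> list[StrategyResult]:
    """Run one seeded replicate of the scaled-down ablation ladder.

    Generates the toy phantom cohort and pretrain set from ``seed``, then
    runs the requested strategies on one fixed split. Returns the strategy
    results in ladder order.
    """
    if cohort_dir is None:
        cohort_dir = tempfile.mkdtemp(prefix="bdlseg_toy_")
    cohort_dir = Path(cohort_dir)
    rng = np.random.default_rng(seed)
    cohort_seed, pretrain_seed, split_seed, train_seed = rng.integers(
        0, 2**31 - 1, 4
    )
    spec = CohortSpec(**TOY_COHORT, seed=int(cohort_seed))
    manifest = generate_cohort(spec, TOY_PHANTOM, cohort_dir)

    pretrain_cases = []
    for i in range(TOY_N_PRETRAIN):
        cfg = PhantomConfig(
            grid_size=TOY_NET.input_size,
            domain="pretrain-like",
            lesion_volume_fraction=0.05,
            seed=int(pretrain_seed) + i,
        )
        vol, mask = generate_brain(cfg)
        pretrain_cases.append(preprocess_case(vol, mask, TOY_NET.input_size))

    train_cfg = TrainConfig(
        initial_lr=1e-3,
        lr_halving_period=30,
        max_epochs=TOY_EPOCHS,
        batch_size=4,
        beta=100.0,
        seed=int(train_seed),
    )
    return run_ablation(
        manifest,
        cohort_dir,
        pretrain_cases,
        TOY_NET,
        train_cfg,
        n_test=TOY_N_TEST,
        strategies=strategies,
        pretrain_epochs=TOY_EPOCHS,
        seed=int(split_seed),
    )
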