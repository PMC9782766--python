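"""Synthetic multi-modal brain phantoms and cohort generation.

The phantoms stand in for clinical MRI so the whole training pipeline runs at
desk scale: each case is an ellipsoidal "brain" with smooth per-channel
texture in four modalities (T1, contrast-enhanced T1, T2, FLAIR), optionally
carrying a single lesion with one of four radiological appearance classes:

* ``solid`` — uniformly enhancing on the contrast channel;
* ``cystic`` — fluid-bright core on T2 with an enhancing rim;
* ``calcified`` — hypointense in every channel;
* ``heterogeneous`` — enhancing rim around a necrotic low-intensity core.

Two lesion domains mimic the two training data sources: ``target-like``
lesions are blob-shaped and sit at the brain border (where dural-based
meningiomas live), while ``pretrain-like`` lesions are interior masses with a
FLAIR-bright edema halo (a glioma-like phenotype used for pre-training).
``normal`` brains carry an all-zero mask. Lesion size is controlled as a
fraction of brain volume via bisection on the blob radius.

No claim of radiological realism is made: the phantoms exist to exercise the
loss, network and training machinery with controllable, reproducible data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import write_case

__all__ = [
    "PhantomConfig",
    "CohortSpec",
    "generate_brain",
    "generate_manifest",
    "generate_cohort",
    "APPEARANCES",
    "DOMAINS",
]

APPEARANCES = ("solid", "cystic", "calcified", "heterogeneous")
DOMAINS = ("pretrain-like", "target-like", "normal")

# per-channel baseline tissue intensity, channel order (t1, t1ce, t2, flair)
_TISSUE_BASE = np.array([1.0, 1.0, 1.2, 1.1])

# additive lesion contrast per appearance: (rim/solid deltas, core deltas)
_LESION_CONTRAST = {
    "solid": (np.array([0.3, 1.5, 0.4, 0.5]), None),
    "cystic": (np.array([0.2, 1.5, 0.3, 0.2]), np.array([-0.5, -0.2, 1.5, -0.3])),
    "calcified": (np.array([-0.8, -0.8, -0.8, -0.8]), None),
    "heterogeneous": (np.array([0.3, 2.0, 0.6, 0.4]), np.array([-0.3, -0.5, 0.2, 0.0])),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Recipe for one synthetic case; identical config + seed is bit-reproducible."""

    grid_size: int = 32
    domain: str = "target-like"
    lesion_volume_fraction: float = 0.02
    appearance: str = "solid"
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError(f"grid_size must be >= 16, got {self.grid_size}")
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.appearance not in APPEARANCES:
            raise ValueError(f"unknown appearance {self.appearance!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.domain == "normal":
            if self.lesion_volume_fraction != 0:
                raise ValueError(
                    "normal domain requires lesion_volume_fraction == 0"
                )
        else:
            if not 0 < self.lesion_volume_fraction <= 0.3:
                raise ValueError(
                    "lesion_volume_fraction must be in (0, 0.3] for lesion "
                    f"domains, got {self.lesion_volume_fraction}"
                )


def _smooth_field(rng: np.random.Generator, s: int, sigma: float) -> np.ndarray:
    """Unit-variance smoothed Gaussian random field on an s^3 grid."""
    f = ndimage.gaussian_filter(rng.standard_normal((s, s, s)), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _fit_lesion_radius(
    dist: np.ndarray, brain: np.ndarray, target_voxels: float
) -> np.ndarray:
    """Bisect the blob radius so the lesion voxel count hits the target.

    ``dist`` is a perturbed distance-to-center field; the lesion at radius r
    is ``(dist < r) & brain``, whose voxel count grows monotonically with r.
    """
    lo, hi = 0.0, float(dist.max()) + 1.0
    best = None
    for _ in range(60):
        r = 0.5 * (lo + hi)
        lesion = (dist < r) & brain
        n = int(lesion.sum())
        if best is None or abs(n - target_voxels) < abs(best[1] - target_voxels):
            best = (lesion, n)
        if n < target_voxels:
            lo = r
        else:
            hi = r
    return best[0]


def generate_brain(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate one case: a (4, S, S, S) float32 volume and an (S, S, S) uint8 mask.

    The brain is an ellipsoid with seeded semi-axis jitter; outside-brain
    voxels are exactly zero in every channel. Lesion voxels are labeled 1 in
    the mask; the edema halo of pretrain-like lesions alters FLAIR intensity
    but is *not* part of the mask (edema is not lesion).
    """
    s = config.grid_size
    rng = np.random.default_rng(config.seed)

    center = (s - 1) / 2.0
    semi = 0.42 * s * (1.0 + 0.04 * rng.uniform(-1, 1, size=3))
    zz, yy, xx = np.meshgrid(*(np.arange(s),) * 3, indexing="ij")
    coords = np.stack([zz, yy, xx]).astype(np.float64) - center
    brain = (coords[0] / semi[0]) ** 2 + (coords[1] / semi[1]) ** 2 + (
        coords[2] / semi[2]
    ) ** 2 < 1.0

    vol = np.zeros((4, s, s, s), dtype=np.float64)
    for c in range(4):
        texture = 0.15 * _smooth_field(rng, s, sigma=s / 8)
        vol[c] = (_TISSUE_BASE[c] + texture) * brain

    mask = np.zeros((s, s, s), dtype=np.uint8)
    if config.domain != "normal":
        # lesion center: border-adjacent for target-like, interior otherwise
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r_boundary = 1.0 / np.sqrt(((u / semi) ** 2).sum())
        if config.domain == "target-like":
            # within 15% of grid_size from the brain boundary
            offset = rng.uniform(0.04, 0.12) * s
        else:
            offset = rng.uniform(0.5, 0.8) * r_boundary
        lesion_center = center + u * (r_boundary - offset)

        d = np.sqrt(((coords - (lesion_center - center)[:, None, None, None]) ** 2).sum(0))
        pert = 1.5 * _smooth_field(rng, s, sigma=s / 10)
        target = config.lesion_volume_fraction * brain.sum()
        lesion = _fit_lesion_radius(d + pert, brain, target)
        mask[lesion] = 1

        rim_delta, core_delta = _LESION_CONTRAST[config.appearance]
        if core_delta is None:
            rim, core = lesion, np.zeros_like(lesion)
        else:
            # core = inner portion of the lesion by distance quantile
            dl = d[lesion]
            cut = np.quantile(dl, 0.35) if dl.size else 0.0
            core = lesion & (d <= cut)
            rim = lesion & ~core
        for c in range(4):
            vol[c][rim] += rim_delta[c]
            if core_delta is not None:
                vol[c][core] += core_delta[c]

        if config.domain == "pretrain-like":
            halo = ndimage.binary_dilation(lesion, iterations=max(2, s // 16))
            halo = halo & brain & ~lesion
            vol[3][halo] += 0.8  # FLAIR-bright edema

    if config.noise_sd > 0:
        vol += config.noise_sd * rng.standard_normal(vol.shape) * brain

    return vol.astype(np.float32), mask


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a generated cohort, mirroring a follow-up-heavy clinical registry.

    ``n_followup_scans`` scans are spread over ``n_followup_patients``
    patients with at least two scans each; ``n_single_scan_patients`` each
    contribute one scan; ``n_normal_subjects`` contribute one lesion-free
    brain each.
    """

    n_followup_patients: int = 35
    n_followup_scans: int = 115
    n_single_scan_patients: int = 56
    n_normal_subjects: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (
            "n_followup_patients",
            "n_followup_scans",
            "n_single_scan_patients",
            "n_normal_subjects",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.n_followup_scans < 2 * self.n_followup_patients:
            raise ValueError(
                "n_followup_scans must be >= 2 * n_followup_patients "
                f"({self.n_followup_scans} < {2 * self.n_followup_patients})"
            )
        if self.n_followup_patients == 0 and self.n_followup_scans > 0:
            raise ValueError("follow-up scans require follow-up patients")

    @property
    def total_scans(self) -> int:
        return (
            self.n_followup_scans
            + self.n_single_scan_patients
            + self.n_normal_subjects
        )


def _partition_scans(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Seeded partition of follow-up scans: >= 2 per patient, summing exactly."""
    n_pat = spec.n_followup_patients
    counts = np.full(n_pat, 2, dtype=int)
    extra = spec.n_followup_scans - 2 * n_pat
    if extra > 0:
        counts += np.bincount(rng.integers(0, n_pat, size=extra), minlength=n_pat)
    return counts


def generate_manifest(spec: CohortSpec) -> pd.DataFrame:
    """Build the cohort manifest (no volumes) for the given spec.

    Columns: scan_id, patient_id, followup, has_lesion, path. Paths are
    prefixes relative to the cohort directory; they are only meaningful once
    :func:`generate_cohort` has written the volumes.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _partition_scans(spec, rng)
    rows = []
    for p, c in enumerate(counts):
        pid = f"fu{p:03d}"
        for s_i in range(c):
            sid = f"{pid}_s{s_i}"
            rows.append((sid, pid, True, True, sid))
    for p in range(spec.n_single_scan_patients):
        pid = f"sg{p:03d}"
        rows.append((f"{pid}_s0", pid, False, True, f"{pid}_s0"))
    for p in range(spec.n_normal_subjects):
        pid = f"nm{p:03d}"
        rows.append((f"{pid}_s0", pid, False, False, f"{pid}_s0"))
    return pd.DataFrame(
        rows, columns=["scan_id", "patient_id", "followup", "has_lesion", "path"]
    )


def generate_cohort(
    spec: CohortSpec,
    phantom_defaults: PhantomConfig,
    out_dir: str | Path,
    write_volumes: bool = True,
) -> pd.DataFrame:
    """Generate a full phantom cohort on disk and return its manifest.

    Each lesion scan gets a seeded per-scan phantom: appearance classes
    cycle through the four phenotypes and the lesion volume fraction is
    jittered by a factor in [0.5, 1.5] around the default, so cohorts span a
    range of lesion sizes and appearances. Volumes are written as NIfTI
    (one file per channel, ``_t1/_t1ce/_t2/_flair`` suffixes, plus ``_seg``
    for the mask); the manifest is written as ``manifest.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = generate_manifest(spec)
    rng = np.random.default_rng(spec.seed + 1)
    scan_seeds = rng.integers(0, 2**31 - 1, size=len(manifest))
    fractions = phantom_defaults.lesion_volume_fraction * rng.uniform(
        0.5, 1.5, size=len(manifest)
    )
    if write_volumes:
        for i, row in manifest.iterrows():
            if row.has_lesion:
                cfg = replace(
                    phantom_defaults,
                    appearance=APPEARANCES[i % len(APPEARANCES)],
                    lesion_volume_fraction=float(
                        np.clip(fractions[i], 1e-3, 0.3)
                    ),
                    seed=int(scan_seeds[i]),
                )
            else:
                cfg = replace(
                    phantom_defaults,
                    domain="normal",
                    lesion_volume_fraction=0.0,
                    seed=int(scan_seeds[i]),
                )
            vol, mask = generate_brain(cfg)
            write_case(out_dir / row.path, vol, mask)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
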