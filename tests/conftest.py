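import numpy as np
import pytest

from bdlseg.io import preprocess_case
from bdlseg.phantoms import CohortSpec, PhantomConfig, generate_brain, generate_manifest


@pytest.fixture(scope="session")
def lesion_phantom():
    """One target-like solid-lesion phantom on a 32-voxel grid."""
    cfg = PhantomConfig(
        grid_size=32, domain="target-like", lesion_volume_fraction=0.02,
        appearance="solid", seed=7,
    )
    return generate_brain(cfg)


@pytest.fixture(scope="session")
def tiny_cases():
    """Two preprocessed 16-voxel lesion cases plus one normal brain."""
    cases = []
    for seed in (1, 2):
        cfg = PhantomConfig(
            grid_size=16, domain="target-like", lesion_volume_fraction=0.03,
            seed=seed,
        )
        cases.append(preprocess_case(*generate_brain(cfg), 16))
    normal_cfg = PhantomConfig(
        grid_size=16, domain="normal", lesion_volume_fraction=0.0, seed=3
    )
    normal = preprocess_case(*generate_brain(normal_cfg), 16)
    return cases, normal


@pytest.fixture(scope="session")
def registry_manifest():
    """Manifest mirroring the clinical registry: 35 fu patients / 115 scans,
    56 single-scan patients, 10 normal subjects (181 scans, 101 subjects)."""
    spec = CohortSpec(
        n_followup_patients=35,
        n_followup_scans=115,
        n_single_scan_patients=56,
        n_normal_subjects=10,
        seed=0,
    )
    return generate_manifest(spec)
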