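"""Shared fixtures: ancestral reference objects and synthetic data."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import minihelix as mx

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ancestral_segmented() -> mx.SegmentedTRNA:
    return mx.segment_trna(mx.ANCESTRAL_CORE, source_id="ancestral")


@pytest.fixture(scope="session")
def synthetic_500() -> tuple[mx.SyntheticTRNASet, list, list]:
    """The archaeal-survey-like condition: 500 records, 80% D-deleted."""
    cfg = mx.SyntheticConfig(n_sequences=500, d_deletion_probability=0.8, seed=1)
    synth = mx.generate_trna_set(cfg)
    segmented, failures = mx.core_model.segment_set(list(synth.records))
    return synth, segmented, failures


@pytest.fixture(scope="session")
def clean_hairpin_pdb(tmp_path_factory) -> str:
    path = tmp_path_factory.mktemp("pdb") / "hairpin17.pdb"
    path.write_text(mx.generate_hairpin_coords(17, noise=0.0, seed=0))
    return str(path)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation from QR decomposition."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
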