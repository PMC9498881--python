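import numpy as np
import pytest

from snpnets import AssociationMap, SimilarityNetwork, normalize_rows
from snpnets.simulate import SimulationConfig, generate_cohort


def random_network(rng: np.random.Generator, size: int, measure: str = "cosine") -> SimilarityNetwork:
    """Random symmetric similarity matrix in [0,1] with unit diagonal."""
    w = rng.uniform(0, 1, size=(size, size))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 1.0)
    return SimilarityNetwork([f"rs{i}" for i in range(size)], measure, w)


def planted_network(
    sizes: list[int],
    within: float = 1.0,
    between: float = 0.0,
    measure: str = "cosine",
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[SimilarityNetwork, np.ndarray]:
    """Block network with planted clusters; returns (network, true labels)."""
    labels = np.concatenate([[k] * s for k, s in enumerate(sizes)])
    n = len(labels)
    w = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if jitter and rng is not None:
        noise = rng.uniform(-jitter, jitter, size=(n, n))
        w = np.clip(w + (noise + noise.T) / 2, 0, 1)
    np.fill_diagonal(w, 1.0)
    return SimilarityNetwork([f"rs{i}" for i in range(n)], measure, w), labels


def normalized_map(rng: np.random.Generator, n_snps: int, n_rois: int) -> AssociationMap:
    """Random nonnegative association map, row-normalized."""
    values = np.abs(rng.normal(1.0, 1.0, size=(n_snps, n_rois)))
    assoc = AssociationMap(
        [f"rs{i}" for i in range(n_snps)], [f"ROI_{j}" for j in range(n_rois)], values
    )
    return normalize_rows(assoc)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort reused across association/pipeline tests."""
    cfg = SimulationConfig(
        n_subjects=200,
        n_snps=12,
        n_rois=20,
        n_planted_clusters=2,
        effect_size=2.0,
        maf_range=(0.2, 0.5),
        seed=11,
    )
    return generate_cohort(cfg)
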