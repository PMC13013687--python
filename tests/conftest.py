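import numpy as np
import pytest

from nbsconn import (
    Atlas,
    Connectome,
    build_backbone,
    build_design,
    generate_dataset,
    stack_edges,
)
from nbsconn.simulate import GeneratorConfig


@pytest.fixture
def toy_atlas():
    """Six regions spanning all five lobes, both hemispheres."""
    return Atlas(
        region_names=tuple(f"r{i}" for i in range(6)),
        lobe=("frontal", "frontal", "temporal", "parietal", "occipital", "insula"),
        hemisphere=("L", "R", "L", "R", "L", "R"),
    )


def make_connectome(n, rng, density=0.5, subject_id="sub", with_lengths=True):
    """Random symmetric integer-count connectome for unit tests."""
    upper = rng.integers(0, 20, size=(n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(upper * mask, k=1).astype(float)
    w = w + w.T
    lengths = None
    if with_lengths:
        lengths = np.triu(rng.uniform(10, 120, size=(n, n)), k=1)
        lengths = lengths + lengths.T
        lengths[w == 0] = 0.0
    return Connectome(subject_id=subject_id, weights=w, lengths=lengths)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def scaled_config(**overrides) -> GeneratorConfig:
    """Small-cohort generator configuration for fast tests."""
    base = dict(
        n_hc=60, n_mdd=40, n_mdd_anx=40, n_nodes=30, planted_size=15,
        delta_hypo=-0.8, delta_hyper=0.8, anxiety_size=20, seed=7,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def planted_dataset():
    """One scaled dataset with strong planted effects, shared across tests."""
    cfg = GeneratorConfig(
        n_hc=80, n_mdd=60, n_mdd_anx=60, n_nodes=30, planted_size=15,
        delta_hypo=-0.8, delta_hyper=0.8, anxiety_size=20,
        anxiety_coupling=0.25, seed=11,
    )
    atlas, cohort, conns, truth = generate_dataset(cfg)
    backbone = build_backbone(conns, prevalence=0.05)
    Y = stack_edges(conns, backbone)
    design = build_design(cohort)
    return dict(config=cfg, atlas=atlas, cohort=cohort, connectomes=conns,
                truth=truth, backbone=backbone, Y=Y, design=design)
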