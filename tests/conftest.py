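import numpy as np
import pytest

from somgrn.som import HexLattice, SOMModel, TrainingConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_model(weights: np.ndarray, rows: int, cols: int) -> SOMModel:
    """Wrap a raw weight array into a SOMModel without training."""
    weights = np.asarray(weights, dtype=float)
    assert weights.shape[0] == rows * cols
    return SOMModel(
        lattice=HexLattice(rows, cols),
        weights=weights,
        config=TrainingConfig(rows=rows, cols=cols, trials=1),
        final_score=0.0,
    )


@pytest.fixture
def small_bundle():
    """A reduced synthetic bundle shared by slower tests (module scope)."""
    from somgrn.synthetic import SyntheticConfig, generate_bundle

    cfg = SyntheticConfig(
        seed=7,
        n_chromosomes=1,
        chromosome_length=2_000_000,
        n_genes=30,
        n_tfs=2,
        targets_per_tf=5,
        n_distractor_regions=30,
    )
    return generate_bundle(cfg)
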