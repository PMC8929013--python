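import numpy as np
import pytest

from pseusite import (
    EnsembleConfig,
    FixtureSpec,
    RnaSequence,
    generate_dataset,
    train_ensemble,
)
from pseusite.bpso import BpsoConfig

NUCLEOTIDES = "AUCG"


def random_rna(rng: np.random.Generator, length: int, seq_id: str = "r") -> RnaSequence:
    return RnaSequence(seq_id, "".join(rng.choice(list(NUCLEOTIDES), size=length)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """60-window planted-signal dataset, cheap enough for unit tests."""
    dataset, truth = generate_dataset(FixtureSpec(n_pos=30, n_neg=30, seed=11))
    return dataset, truth


@pytest.fixture(scope="session")
def tiny_ensemble(small_dataset):
    """A six-descriptor ensemble trained with a minimal BPSO budget.

    Small enough for scanner/ensemble unit tests; quality is not the
    point here, wiring is.
    """
    dataset, _ = small_dataset
    config = EnsembleConfig(
        bpso=BpsoConfig(
            n_particles=5, n_iterations=4, phase_switch_iteration=3, cv_folds=5
        ),
        random_seed=11,
    )
    ensemble, selections = train_ensemble(dataset, config)
    return ensemble, selections, dataset
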