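"""Shared fixtures: a small synthetic corpus and a trained predictor.

All randomness is seed-fixed; the session-scoped model is trained once on a
small corpus so unit tests of prediction, serialization and the CLI do not
retrain repeatedly.
"""

from __future__ import annotations

import numpy as np
import pytest

from barreltm import BarrelSpec, generate_corpus
from barreltm.dataset import NTM, TM
from barreltm.pipeline import TrainingResult, train_pipeline

#: reduced grid used wherever a test needs a real (but quick) grid search
FAST_GRID = dict(
    folds=3,
    c_exponents=(1.0, 3.0, 5.0),
    gamma_exponents=(-7.0, -5.0, -3.0),
    refine_radius=0.25,
)


@pytest.fixture(scope="session")
def corpus():
    """24 training + 6 held-out synthetic barrel proteins, default signal."""
    return generate_corpus(BarrelSpec(), 30, seed=7)


@pytest.fixture(scope="session")
def train_proteins(corpus):
    return corpus[:24]


@pytest.fixture(scope="session")
def heldout_proteins(corpus):
    return corpus[24:]


@pytest.fixture(scope="session")
def trained(train_proteins) -> TrainingResult:
    return train_pipeline(train_proteins, seed=7, **FAST_GRID)


@pytest.fixture()
def worked_labels():
    """162-window label vector with seven runs of consecutive tm windows."""
    labels = [NTM] * 162
    for first, last in [
        (4, 11),
        (31, 53),
        (70, 80),
        (89, 96),
        (117, 124),
        (132, 140),
        (156, 162),
    ]:
        for win in range(first, last + 1):
            labels[win - 1] = TM
    return labels


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
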