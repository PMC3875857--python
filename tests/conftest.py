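"""Shared fixtures: small genomes, motif libraries, and trained models.

Session-scoped fixtures cache the expensive artifacts (trained classifier
ensembles, decoded posteriors) so the end-to-end objects are built once
and shared across test modules.
"""

import numpy as np
import pytest

from txdefine import classifiers as cl
from txdefine import evaluation as ev
from txdefine import features as ft
from txdefine import motifs as mo
from txdefine import pipeline as pl
from txdefine import synthetic_data as sd
from txdefine.sequence_io import Genome


@pytest.fixture(scope="session")
def motif_library():
    return mo.builtin_motifs()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_genome():
    return Genome({"c1": "ACGTACGTACGTACGTNACGT", "c2": "TTTTAAAACCCCGGGG"})


@pytest.fixture(scope="session")
def small_synthetic():
    """A small annotated random genome (2 chromosomes, ~15 genes each)."""
    spec = sd.SyntheticGenomeSpec(
        length=30_000, n_chromosomes=2, n_genes=15, seed=7
    )
    genome, annotations, state_map = sd.generate_random_genome(spec)
    return genome, annotations, state_map


@pytest.fixture(scope="session")
def trained_model(small_synthetic):
    """Classifiers + HMM trained on the small synthetic genome."""
    genome, annotations, _ = small_synthetic
    return pl.train_transcript_model(
        genome,
        annotations,
        config=cl.EnsembleConfig(replicates_per_fold=2, trees_per_forest=25, seed=0),
    )


@pytest.fixture(scope="session")
def eval_synthetic():
    """An independently seeded genome from the same recipe, for held-out
    evaluation of models trained on ``small_synthetic``."""
    spec = sd.SyntheticGenomeSpec(
        length=30_000, n_chromosomes=2, n_genes=15, seed=8
    )
    return sd.generate_random_genome(spec)
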