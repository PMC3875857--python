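"""End-to-end glue: train classifiers, score genomes, fit and run the
transcript model.

Convenience wrappers over the module APIs for the common workflow:
annotated genome in, per-base score tracks and transcript predictions
out.  Defaults are sized for simulation-scale genomes (hundreds of
kilobases); the reference ensemble configuration (8 x 4 x 50 trees) and
stride 1 are available through the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classifiers as cl
from . import features as ft
from . import motifs as mo
from . import unified_model as um
from .sequence_io import Genome, TranscriptAnnotation, build_state_map

__all__ = ["TranscriptModel", "train_transcript_model", "HMM_TSS_STATE_WIDTH",
           "HMM_CPA_STATE_WIDTH", "DEFAULT_EMISSION_WEIGHT"]

# HMM state-map widths for the TSS/CPA site states.  The TSS width matches
# the initiation classifier's intrinsic resolution (~70 bp, set by its bin
# sizes).  The CPA width spans the cleavage signal on both strands: the
# palindromic efficiency elements fire the termination classifier in both
# orientations with a ~90-bp strand offset, so a 100-bp state absorbs the
# whole bidirectional peak rather than leaving its shoulders to contaminate
# the Gene/IG emission statistics.
HMM_TSS_STATE_WIDTH = 70
HMM_CPA_STATE_WIDTH = 100

# One effective independent observation per ~50 bp (the classifiers'
# positional resolution): the scoring windows make neighbouring per-base
# scores strongly correlated, so emission log-likelihoods are down-weighted
# accordingly when decoding.
DEFAULT_EMISSION_WEIGHT = 1.0 / 50.0


@dataclass
class TranscriptModel:
    """Trained classifiers plus fitted unified-model parameters."""

    initiation: cl.TrainedEnsemble
    termination: cl.TrainedEnsemble
    params: um.UMParameters
    motif_library: dict = field(default_factory=dict)
    initiation_scheme: ft.BinScheme = field(default_factory=ft.default_initiation_scheme)
    termination_scheme: ft.BinScheme = field(default_factory=ft.default_termination_scheme)
    stride: int = 5
    emission_weight: float = DEFAULT_EMISSION_WEIGHT

    def score_tracks(self, genome: Genome) -> tuple[cl.ScoreTrack, cl.ScoreTrack]:
        """Initiation and termination score tracks on both strands."""
        ti = cl.score_genome(
            self.initiation, genome, self.initiation_scheme,
            self.initiation.specs, self.motif_library, stride=self.stride,
            name="initiation",
        )
        tt = cl.score_genome(
            self.termination, genome, self.termination_scheme,
            self.termination.specs, self.motif_library, stride=self.stride,
            name="termination",
        )
        return ti, tt

    def observations(self, genome: Genome) -> dict[str, np.ndarray]:
        ti, tt = self.score_tracks(genome)
        return um.stack_tracks(ti, tt)

    def decode(self, genome: Genome) -> um.PosteriorTrack:
        return um.posterior_decode(
            self.params, self.observations(genome),
            emission_weight=self.emission_weight,
        )

    def predict(
        self,
        genome: Genome,
        threshold: float = 0.5,
        min_length: int = 250,
        min_confidence: float = 0.85,
    ) -> list[TranscriptAnnotation]:
        return um.predict_transcripts(
            self.decode(genome),
            threshold=threshold,
            min_length=min_length,
            min_confidence=min_confidence,
        )


def train_transcript_model(
    genome: Genome,
    annotations: list[TranscriptAnnotation],
    config: cl.EnsembleConfig | None = None,
    motif_library: dict | None = None,
    stride: int = 5,
    initiation_specs: list[ft.FeatureSpec] | None = None,
    termination_specs: list[ft.FeatureSpec] | None = None,
) -> TranscriptModel:
    """Train both classifiers and estimate the HMM on one annotated genome.

    The classifiers are trained on TSS/CPA-anchored positives and tiled
    negatives; the genome is then scored and the unified model's
    parameters estimated from a state map whose TSS/CPA states are widened
    to the classifiers' intrinsic resolution.
    """
    lib = motif_library or mo.builtin_motifs(background=genome.composition())
    cfg = config or cl.EnsembleConfig(replicates_per_fold=2, trees_per_forest=25)
    ischeme = ft.default_initiation_scheme()
    tscheme = ft.default_termination_scheme()
    ispecs = initiation_specs or ft.default_initiation_specs()
    tspecs = termination_specs or ft.default_termination_specs()

    ip, ineg, tp, tneg = ft.make_training_sets(genome, annotations, ischeme, tscheme)
    dfi = ft.feature_matrix(genome, [ip, ineg], ischeme, ispecs, lib)
    dft = ft.feature_matrix(genome, [tp, tneg], tscheme, tspecs, lib)
    ei = cl.train_ensemble(cl.ExampleSet.from_frame(dfi, ispecs), cfg)
    et = cl.train_ensemble(cl.ExampleSet.from_frame(dft, tspecs), cfg)

    model = TranscriptModel(
        initiation=ei,
        termination=et,
        params=None,  # filled below
        motif_library=lib,
        initiation_scheme=ischeme,
        termination_scheme=tscheme,
        stride=stride,
    )
    hmm_map = build_state_map(
        annotations,
        genome,
        tss_width=HMM_TSS_STATE_WIDTH,
        cpa_width=HMM_CPA_STATE_WIDTH,
    )
    params = um.estimate_parameters(hmm_map, model.observations(genome))
    model.params = um.tie_gene_to_intergenic(params)
    return model
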