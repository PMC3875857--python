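"""Initiation and termination classifiers.

Random-Forest ensembles with leave-one-chromosome-out structure: for each
held-out chromosome a group of replicate forests is trained on the
remaining chromosomes, and the ensemble score is the mean of the per-forest
class probabilities.  The reference configuration (8 folds x 4 replicates
x 50 trees = 1600 trees per classifier) is the default; smaller
configurations are used for simulation-scale work.

Also provides a regularized logistic-regression alternative with the same
predict contract, importance-ordered feature reduction, per-base genome
scoring on both strands, and leave-one-feature-out dependence calls.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .features import BinScheme, FeatureSpec, GenomeFeaturizer
from .motifs import MotifModel
from .sequence_io import Genome

__all__ = [
    "EnsembleConfig",
    "ExampleSet",
    "TrainedEnsemble",
    "LogisticModel",
    "ScoreTrack",
    "train_ensemble",
    "train_logistic",
    "reduce_features",
    "score_genome",
    "feature_dependence",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Fold/replicate/tree structure of the ensemble."""

    held_out_chromosomes: tuple[str, ...] | None = None  # None = all present
    replicates_per_fold: int = 4
    trees_per_forest: int = 50
    seed: int = 0
    balanced_bootstrap: bool = True

    def __post_init__(self):
        if self.replicates_per_fold < 1 or self.trees_per_forest < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class ExampleSet:
    """Labeled feature vectors grouped by chromosome."""

    X: np.ndarray
    y: np.ndarray  # 1 = positive, 0 = negative
    chroms: np.ndarray
    specs: list[FeatureSpec]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.chroms = np.asarray(self.chroms)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.specs):
            raise ValueError("X width must match the feature spec list")
        if len(self.y) != len(self.X) or len(self.chroms) != len(self.X):
            raise ValueError("inconsistent example counts")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, specs: list[FeatureSpec]) -> "ExampleSet":
        """Build from a :func:`txdefine.features.feature_matrix` table."""
        X = df[[s.name for s in specs]].to_numpy(float)
        y = (df["label"] == "positive").to_numpy(int)
        return cls(X=X, y=y, chroms=df["chrom"].to_numpy(), specs=list(specs))

    def subset_features(self, keep: list[int]) -> "ExampleSet":
        return ExampleSet(
            X=self.X[:, keep],
            y=self.y,
            chroms=self.chroms,
            specs=[self.specs[i] for i in keep],
        )

    def restrict_chroms(self, chroms) -> "ExampleSet":
        m = np.isin(self.chroms, list(chroms))
        return ExampleSet(self.X[m], self.y[m], self.chroms[m], self.specs)


@dataclass
class TrainedEnsemble:
    """Per-fold forest groups plus training metadata.

    The ensemble prediction is the mean of all per-forest positive-class
    probabilities; held-out prediction for a chromosome uses only the fold
    that withheld it.
    """

    forests: dict[str, list[RandomForestClassifier]]  # held-out chrom -> forests
    specs: list[FeatureSpec]
    config: EnsembleConfig
    negative_medians: np.ndarray
    metadata: dict = field(default_factory=dict)
    _examples: ExampleSet | None = None

    @property
    def n_trees(self) -> int:
        return sum(f.n_estimators for group in self.forests.values() for f in group)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.specs):
            raise ValueError("feature-spec mismatch")
        probs = [f.predict_proba(X)[:, 1] for group in self.forests.values() for f in group]
        return np.mean(probs, axis=0)

    def predict(self, x) -> float:
        values = x.values if hasattr(x, "values") else np.asarray(x, dtype=float)
        return float(self.predict_matrix(values.reshape(1, -1))[0])

    def predict_heldout(self, chrom: str, X: np.ndarray) -> np.ndarray:
        """Predictions for examples on ``chrom`` using only the fold that
        withheld that chromosome (never a forest trained on it)."""
        if chrom not in self.forests:
            raise KeyError(f"no fold withheld chromosome {chrom!r}")
        X = np.asarray(X, dtype=float)
        probs = [f.predict_proba(X)[:, 1] for f in self.forests[chrom]]
        return np.mean(probs, axis=0)

    def feature_importances(self) -> np.ndarray:
        """Impurity-based importances averaged over all forests."""
        imps = [f.feature_importances_ for g in self.forests.values() for f in g]
        return np.mean(imps, axis=0)


def _balanced_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Balanced bootstrap: sample n_pos positives and n_pos negatives with
    replacement (downsampling the majority class per forest)."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n = len(pos)
    return np.concatenate(
        [rng.choice(pos, size=n, replace=True), rng.choice(neg, size=n, replace=True)]
    )


def train_ensemble(examples: ExampleSet, config: EnsembleConfig) -> TrainedEnsemble:
    """Train the leave-one-chromosome-out Random-Forest ensemble."""
    if len(examples.X) == 0:
        raise ValueError("empty example set")
    chroms = (
        list(config.held_out_chromosomes)
        if config.held_out_chromosomes is not None
        else sorted(set(examples.chroms))
    )
    if len(chroms) < 2:
        raise ValueError("need >= 2 chromosomes for leave-one-out folds")
    rng = np.random.default_rng(config.seed)
    forests: dict[str, list[RandomForestClassifier]] = {}
    for held in chroms:
        train = examples.restrict_chroms([c for c in chroms if c != held])
        if len(np.unique(train.y)) < 2:
            raise ValueError(f"fold withholding {held!r} has a single class")
        group = []
        for _ in range(config.replicates_per_fold):
            seed = int(rng.integers(0, 2**31 - 1))
            if config.balanced_bootstrap:
                idx = _balanced_indices(train.y, np.random.default_rng(seed))
                Xf, yf = train.X[idx], train.y[idx]
                forest = RandomForestClassifier(
                    n_estimators=config.trees_per_forest,
                    bootstrap=True,
                    random_state=seed,
                )
            else:
                Xf, yf = train.X, train.y
                forest = RandomForestClassifier(
                    n_estimators=config.trees_per_forest, random_state=seed
                )
            forest.fit(Xf, yf)
            group.append(forest)
        forests[held] = group
    neg = examples.X[examples.y == 0]
    neg_median = (
        np.median(neg, axis=0) if len(neg) else np.zeros(examples.X.shape[1])
    )
    return TrainedEnsemble(
        forests=forests,
        specs=list(examples.specs),
        config=config,
        negative_medians=neg_median,
        metadata={
            "chromosome_folds": chroms,
            "seed": config.seed,
            "n_examples": int(len(examples.X)),
            "forest_hyperparameters": "scikit-learn defaults beyond tree count",
        },
        _examples=examples,
    )


@dataclass
class LogisticModel:
    """Regularized logistic regression with the ensemble's predict contract."""

    model: LogisticRegression
    specs: list[FeatureSpec]
    mean_: np.ndarray
    scale_: np.ndarray
    kept_: np.ndarray  # indices of non-constant features

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.specs):
            raise ValueError("feature-spec mismatch")
        Z = (X[:, self.kept_] - self.mean_) / self.scale_
        return self.model.predict_proba(Z)[:, 1]

    def predict(self, x) -> float:
        values = x.values if hasattr(x, "values") else np.asarray(x, dtype=float)
        return float(self.predict_matrix(values.reshape(1, -1))[0])


def train_logistic(examples: ExampleSet, C: float = 1.0, seed: int = 0) -> LogisticModel:
    """Standardized, L2-regularized logistic fit on the same examples.

    Constant features are dropped with a warning; scores are probabilities
    in [0, 1].
    """
    X, y = examples.X, examples.y
    std = X.std(axis=0)
    # tolerance: a column of identical values can carry ~1e-14 float noise
    kept = np.flatnonzero(std > 1e-12 * np.maximum(np.abs(X).max(axis=0), 1.0))
    if len(kept) < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - len(kept)} constant feature(s)", stacklevel=2
        )
    if len(kept) == 0:
        raise ValueError("all features are constant")
    mean, scale = X[:, kept].mean(axis=0), std[kept]
    Z = (X[:, kept] - mean) / scale
    model = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    model.fit(Z, y)
    return LogisticModel(
        model=model, specs=list(examples.specs), mean_=mean, scale_=scale, kept_=kept
    )


def reduce_features(
    ensemble: TrainedEnsemble,
    refinement_examples: ExampleSet,
    improvement_threshold: float = 0.002,
    retrain_config: EnsembleConfig | None = None,
) -> list[FeatureSpec]:
    """Importance-ordered greedy feature reduction.

    Features are considered in decreasing forest importance; one is retained
    iff adding it improves the AUROC measured on the refinement examples by
    at least ``improvement_threshold``.  Returns the retained ordered spec
    subset.
    """
    from .evaluation import auroc

    if len(refinement_examples.X) == 0:
        raise ValueError("empty refinement set")
    if len(np.unique(refinement_examples.y)) < 2:
        raise ValueError("refinement set needs both classes")
    train = ensemble._examples
    if train is None:
        raise ValueError("ensemble does not retain its training examples")
    cfg = retrain_config or EnsembleConfig(
        replicates_per_fold=1,
        trees_per_forest=min(ensemble.config.trees_per_forest, 50),
        seed=ensemble.config.seed,
    )
    order = np.argsort(ensemble.feature_importances())[::-1]
    selected: list[int] = []
    current_auc = 0.5  # chance performance with no features
    for idx in order:
        candidate = selected + [int(idx)]
        sub_train = train.subset_features(candidate)
        sub_ref = refinement_examples.subset_features(candidate)
        model = train_ensemble(sub_train, cfg)
        scores = model.predict_matrix(sub_ref.X)
        auc = auroc(scores[sub_ref.y == 1], scores[sub_ref.y == 0])
        if auc - current_auc >= improvement_threshold:
            selected = candidate
            current_auc = auc
    return [ensemble.specs[i] for i in selected]


# ---------------------------------------------------------------------------
# Genome scoring


@dataclass
class ScoreTrack:
    """Per-base classifier scores in [0, 1] per chromosome and strand."""

    name: str
    data: dict[str, dict[str, np.ndarray]]  # chrom -> strand -> array

    def __post_init__(self):
        for chrom, strands in self.data.items():
            for strand, arr in strands.items():
                if np.any((arr < 0) | (arr > 1)):
                    raise ValueError("scores must lie in [0, 1]")

    def chroms(self):
        return list(self.data)

    def to_bedgraph(self, path, strand: str) -> None:
        """Write one strand's track as bedGraph (runs of equal value)."""
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{self.name}{strand}"\n')
            for chrom, strands in self.data.items():
                arr = strands[strand]
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(arr)]])
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.6g}\n")


def score_genome(
    model,
    genome: Genome,
    scheme: BinScheme,
    specs: list[FeatureSpec],
    motif_library: dict[str, MotifModel],
    stride: int = 10,
    name: str = "score",
    featurizers: dict | None = None,
) -> ScoreTrack:
    """Score every base of the genome on both strands.

    Anchors step by ``stride``; intermediate bases carry the last anchored
    score forward.  Edge bases whose window does not fit are masked to the
    minimum of the scored values.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    data: dict[str, dict[str, np.ndarray]] = {}
    for chrom in genome:
        fz = (featurizers or {}).get(chrom)
        if fz is None:
            fz = GenomeFeaturizer(genome, scheme, specs, motif_library)
        L = genome.length(chrom)
        data[chrom] = {}
        for strand in "+-":
            lo, hi = fz.valid_anchor_range(chrom, strand)
            if hi <= lo:
                raise ValueError(f"chromosome {chrom!r} shorter than the window")
            anchors = np.arange(lo, hi, stride, dtype=np.int64)
            X = fz.features_for_anchors(chrom, anchors, strand)
            scores = model.predict_matrix(X)
            track = np.full(L, float(scores.min()))
            # carry each anchor's score forward to the next anchor
            bounds = np.append(anchors, hi)
            track[lo:hi] = np.repeat(scores, np.diff(bounds))
            data[chrom][strand] = track
    return ScoreTrack(name=name, data=data)


def feature_dependence(
    ensemble: TrainedEnsemble,
    x,
    group: list[str],
    threshold: float = 0.1,
) -> tuple[bool, float]:
    """Leave-out dependence call for one example.

    The features in ``group`` are neutralized to the negative-class median
    and the score drop Delta = score(x) - score(neutralized) is compared to
    ``threshold`` (default 0.1): the promoter depends on the group iff
    Delta >= threshold.  Returns (dependent, Delta).
    """
    names = [s.name for s in ensemble.specs]
    missing = [g for g in group if g not in names]
    if missing:
        raise KeyError(f"unknown feature(s) in group: {missing}")
    values = x.values if hasattr(x, "values") else np.asarray(x, dtype=float)
    values = values.astype(float).copy()
    neutral = values.copy()
    for g in group:
        i = names.index(g)
        neutral[i] = ensemble.negative_medians[i]
    delta = float(
        ensemble.predict_matrix(values.reshape(1, -1))[0]
        - ensemble.predict_matrix(neutral.reshape(1, -1))[0]
    )
    return delta >= threshold, delta


def save_model(model, path) -> None:
    """Persist a trained model (binary container with the spec embedded)."""
    with open(path, "wb") as fh:
        pickle.dump({"format_version": 1, "model": model}, fh)


def load_model(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != 1:
        raise ValueError("unsupported model container version")
    return payload["model"]
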