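"""Random-Forest ensembles, logistic alternative, feature reduction,
genome scoring, and feature-dependence calls."""

import numpy as np
import pytest

from txdefine.classifiers import (
    EnsembleConfig,
    ExampleSet,
    feature_dependence,
    load_model,
    reduce_features,
    save_model,
    score_genome,
    train_ensemble,
    train_logistic,
)
from txdefine.evaluation import auroc
from txdefine.features import (
    FeatureSpec,
    GenomeFeaturizer,
    default_initiation_scheme,
    default_initiation_specs,
)
from txdefine.motifs import builtin_motifs
from txdefine.sequence_io import Genome


def toy_specs(n):
    return [FeatureSpec(f"f{i}", "base_fraction", 0, ("GC",)) for i in range(n)]


def separable_examples(n_per_chrom=40, n_chroms=4, noise_features=3, seed=0):
    """Linearly separable synthetic examples spread over chromosomes."""
    rng = np.random.default_rng(seed)
    X, y, chroms = [], [], []
    for c in range(n_chroms):
        for _ in range(n_per_chrom):
            label = rng.integers(2)
            informative = label + 0.1 * rng.standard_normal()
            row = [informative] + list(rng.standard_normal(noise_features))
            X.append(row)
            y.append(label)
            chroms.append(f"chr{c + 1}")
    return ExampleSet(
        X=np.array(X), y=np.array(y), chroms=np.array(chroms),
        specs=toy_specs(1 + noise_features),
    )


class TestTrainEnsemble:
    def test_total_tree_count_contract(self):
        ex = separable_examples(n_chroms=8)
        cfg = EnsembleConfig(replicates_per_fold=4, trees_per_forest=50, seed=0)
        ens = train_ensemble(ex, cfg)
        assert ens.n_trees == 8 * 4 * 50 == 1600  # the reference configuration

    def test_small_config_tree_count(self):
        ex = separable_examples(n_chroms=2)
        ens = train_ensemble(ex, EnsembleConfig(replicates_per_fold=1,
                                                trees_per_forest=10, seed=0))
        assert ens.n_trees == 20

    def test_separable_data_heldout_auroc_one(self):
        """Held-out predictions on linearly separable data achieve AUROC 1,
        verified with the pair-counting estimator."""
        ex = separable_examples()
        ens = train_ensemble(ex, EnsembleConfig(replicates_per_fold=2,
                                                trees_per_forest=25, seed=0))
        for chrom in ["chr1", "chr2"]:
            mask = ex.chroms == chrom
            s = ens.predict_heldout(chrom, ex.X[mask])
            assert auroc(s[ex.y[mask] == 1], s[ex.y[mask] == 0]) == 1.0

    def test_single_class_fold_rejected(self):
        ex = separable_examples(n_chroms=2)
        ex.y[ex.chroms == "chr2"] = 1  # chr1-training fold sees... still both
        ex.y[ex.chroms == "chr1"] = 1  # now all positive
        with pytest.raises(ValueError):
            train_ensemble(ex, EnsembleConfig(seed=0))

    def test_single_chromosome_rejected(self):
        ex = separable_examples(n_chroms=1)
        with pytest.raises(ValueError, match="chromosomes"):
            train_ensemble(ex, EnsembleConfig(seed=0))

    def test_heldout_never_uses_own_chromosome(self):
        ex = separable_examples(n_chroms=3)
        ens = train_ensemble(ex, EnsembleConfig(replicates_per_fold=1,
                                                trees_per_forest=5, seed=0))
        assert set(ens.forests) == {"chr1", "chr2", "chr3"}
        with pytest.raises(KeyError):
            ens.predict_heldout("chr9", ex.X[:2])


class TestPredict:
    def test_prediction_is_mean_of_fold_probabilities(self):
        """Ensemble score equals externally recomputed per-forest mean."""
        ex = separable_examples()
        ens = train_ensemble(ex, EnsembleConfig(replicates_per_fold=2,
                                                trees_per_forest=10, seed=1))
        X = ex.X[:7]
        manual = np.mean(
            [f.predict_proba(X)[:, 1] for g in ens.forests.values() for f in g],
            axis=0,
        )
        np.testing.assert_allclose(ens.predict_matrix(X), manual, atol=1e-12)

    def test_scores_in_unit_interval(self):
        ex = separable_examples()
        ens = train_ensemble(ex, EnsembleConfig(replicates_per_fold=1,
                                                trees_per_forest=5, seed=2))
        s = ens.predict_matrix(ex.X)
        assert np.all((s >= 0) & (s <= 1))

    def test_spec_mismatch_rejected(self):
        ex = separable_examples()
        ens = train_ensemble(ex, EnsembleConfig(replicates_per_fold=1,
                                                trees_per_forest=5, seed=3))
        with pytest.raises(ValueError):
            ens.predict_matrix(np.zeros((2, 9)))


class TestLogistic:
    def test_separating_feature_auroc_one(self):
        ex = separable_examples()
        model = train_logistic(ex)
        s = model.predict_matrix(ex.X)
        assert auroc(s[ex.y == 1], s[ex.y == 0]) == 1.0

    def test_noise_features_auroc_near_half(self):
        """Pure-noise features: held-out AUROC ~ 0.5."""
        rng = np.random.default_rng(8)
        n = 3000
        X = rng.standard_normal((n, 4))
        y = rng.integers(2, size=n)
        ex = ExampleSet(X=X[: n // 2], y=y[: n // 2],
                        chroms=np.array(["c1"] * (n // 2)), specs=toy_specs(4))
        model = train_logistic(ex)
        s = model.predict_matrix(X[n // 2 :])
        assert auroc(s[y[n // 2 :] == 1], s[y[n // 2 :] == 0]) == pytest.approx(
            0.5, abs=0.05
        )

    def test_constant_features_dropped_with_warning(self):
        ex = separable_examples()
        ex.X[:, 2] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            model = train_logistic(ex)
        assert len(model.kept_) == ex.X.shape[1] - 1

    def test_deterministic_given_seed_and_data(self):
        ex = separable_examples()
        a = train_logistic(ex, seed=0).predict_matrix(ex.X)
        b = train_logistic(ex, seed=0).predict_matrix(ex.X)
        np.testing.assert_array_equal(a, b)

    def test_logistic_close_to_forest_on_synthetic_promoters(
        self, small_synthetic, trained_model, eval_synthetic
    ):
        """On implanted-promoter data the linear model performs only
        marginally worse than the forest (within 0.05 AUROC)."""
        from txdefine.features import feature_matrix, make_training_sets

        genome, anns, _ = small_synthetic
        g2, anns2, _ = eval_synthetic
        ischeme = trained_model.initiation_scheme
        specs = trained_model.initiation.specs
        lib = trained_model.motif_library
        ip, ineg, _, _ = make_training_sets(genome, anns)
        train = ExampleSet.from_frame(
            feature_matrix(genome, [ip, ineg], ischeme, specs, lib), specs
        )
        logi = train_logistic(train)
        ip2, ineg2, _, _ = make_training_sets(g2, anns2)
        test = ExampleSet.from_frame(
            feature_matrix(g2, [ip2, ineg2], ischeme, specs, lib), specs
        )
        s_rf = trained_model.initiation.predict_matrix(test.X)
        s_lg = logi.predict_matrix(test.X)
        auc_rf = auroc(s_rf[test.y == 1], s_rf[test.y == 0])
        auc_lg = auroc(s_lg[test.y == 1], s_lg[test.y == 0])
        assert auc_rf >= 0.9
        assert abs(auc_rf - auc_lg) < 0.05


class TestReduceFeatures:
    def _examples_with_duplicate(self, seed=0):
        """One informative feature, an exact duplicate, and noise."""
        rng = np.random.default_rng(seed)
        n = 120
        X, y, chroms = [], [], []
        for c in range(3):
            for _ in range(n):
                label = rng.integers(2)
                info = label + 0.05 * rng.standard_normal()
                noise = rng.standard_normal(2)
                X.append([info, info, *noise])
                y.append(label)
                chroms.append(f"chr{c + 1}")
        specs = [FeatureSpec(nm, "base_fraction", 0, ("GC",))
                 for nm in ("info", "info_copy", "noise1", "noise2")]
        return ExampleSet(X=np.array(X), y=np.array(y),
                          chroms=np.array(chroms), specs=specs)

    def test_duplicate_removed_and_separator_retained(self):
        ex = self._examples_with_duplicate()
        train = ex.restrict_chroms(["chr1", "chr2"])
        refine = ex.restrict_chroms(["chr3"])
        ens = train_ensemble(train, EnsembleConfig(replicates_per_fold=1,
                                                   trees_per_forest=25, seed=0))
        kept = reduce_features(ens, refine, improvement_threshold=0.002)
        names = [s.name for s in kept]
        assert names[0] in ("info", "info_copy")
        # the duplicate adds zero AUROC and is dropped
        assert not {"info", "info_copy"} <= set(names)

    def test_threshold_monotonicity(self):
        """Raising the threshold never enlarges the retained set."""
        ex = self._examples_with_duplicate(seed=1)
        train = ex.restrict_chroms(["chr1", "chr2"])
        refine = ex.restrict_chroms(["chr3"])
        ens = train_ensemble(train, EnsembleConfig(replicates_per_fold=1,
                                                   trees_per_forest=25, seed=0))
        small = reduce_features(ens, refine, improvement_threshold=0.0)
        large = reduce_features(ens, refine, improvement_threshold=0.05)
        assert len(large) <= len(small)

    def test_empty_refinement_rejected(self):
        ex = self._examples_with_duplicate()
        ens = train_ensemble(ex, EnsembleConfig(replicates_per_fold=1,
                                                trees_per_forest=5, seed=0))
        empty = ex.restrict_chroms(["nope"])
        with pytest.raises(ValueError):
            reduce_features(ens, empty)


class TestScoreGenome:
    def test_constant_sequence_constant_interior(self, trained_model):
        g = Genome({"c": "ACGT" * 500})  # periodic, effectively constant bins
        track = score_genome(
            trained_model.initiation, g, trained_model.initiation_scheme,
            trained_model.initiation.specs, trained_model.motif_library,
            stride=10,
        )
        arr = track.data["c"]["+"]
        interior = arr[500:1400]
        assert np.allclose(interior, interior[0])

    def test_scores_at_sampled_anchors_agree_across_strides(
        self, trained_model, eval_synthetic
    ):
        genome, _, _ = eval_synthetic
        kw = dict(
            scheme=trained_model.termination_scheme,
            specs=trained_model.termination.specs,
            motif_library=trained_model.motif_library,
        )
        t1 = score_genome(trained_model.termination, genome, stride=1,
                          scheme=kw["scheme"], specs=kw["specs"],
                          motif_library=kw["motif_library"])
        t10 = score_genome(trained_model.termination, genome, stride=10,
                           scheme=kw["scheme"], specs=kw["specs"],
                           motif_library=kw["motif_library"])
        fz = GenomeFeaturizer(genome, kw["scheme"], kw["specs"],
                              kw["motif_library"])
        lo, hi = fz.valid_anchor_range("chr1", "+")
        anchors = np.arange(lo, hi, 10)[:50]
        np.testing.assert_allclose(
            t1.data["chr1"]["+"][anchors], t10.data["chr1"]["+"][anchors],
            atol=1e-12,
        )

    def test_reverse_complement_swaps_and_reverses_tracks(
        self, trained_model, eval_synthetic
    ):
        genome, _, _ = eval_synthetic
        rc = genome.reverse_complemented()
        kw = dict(
            scheme=trained_model.termination_scheme,
            specs=trained_model.termination.specs,
            motif_library=trained_model.motif_library,
        )
        fwd = score_genome(trained_model.termination, genome, stride=1, **kw)
        rev = score_genome(trained_model.termination, rc, stride=1, **kw)
        L = genome.length("chr1")
        # interior comparison (edge masking differs at the boundaries)
        sl = slice(200, L - 200)
        np.testing.assert_allclose(
            rev.data["chr1"]["-"][::-1][sl], fwd.data["chr1"]["+"][sl], atol=1e-12
        )

    def test_chromosome_shorter_than_window_rejected(self, trained_model):
        g = Genome({"tiny": "ACGT" * 20})
        with pytest.raises(ValueError, match="shorter"):
            score_genome(
                trained_model.initiation, g, trained_model.initiation_scheme,
                trained_model.initiation.specs, trained_model.motif_library,
            )

    def test_reproducible_given_seed(self, small_synthetic):
        """Identical seeds give bit-identical score tracks."""
        from txdefine import pipeline as pl
        from txdefine.classifiers import EnsembleConfig

        genome, anns, _ = small_synthetic
        cfg = EnsembleConfig(replicates_per_fold=1, trees_per_forest=10, seed=5)
        m1 = pl.train_transcript_model(genome, anns, config=cfg)
        m2 = pl.train_transcript_model(genome, anns, config=cfg)
        t1, _ = m1.score_tracks(genome)
        t2, _ = m2.score_tracks(genome)
        np.testing.assert_array_equal(t1.data["chr1"]["+"], t2.data["chr1"]["+"])


class TestFeatureDependence:
    def test_unused_feature_independent(self):
        ex = separable_examples()
        ens = train_ensemble(ex, EnsembleConfig(replicates_per_fold=1,
                                                trees_per_forest=25, seed=0))
        x = ex.X[ex.y == 1][0]
        dep, delta = feature_dependence(ens, x, ["f3"], threshold=0.1)
        assert not dep
        assert abs(delta) < 0.05

    def test_driving_feature_dependent(self):
        ex = separable_examples()
        ens = train_ensemble(ex, EnsembleConfig(replicates_per_fold=2,
                                                trees_per_forest=25, seed=0))
        x = ex.X[ex.y == 1][0]
        dep, delta = feature_dependence(ens, x, ["f0"], threshold=0.1)
        assert dep and delta >= 0.1

    def test_threshold_monotone(self):
        ex = separable_examples()
        ens = train_ensemble(ex, EnsembleConfig(replicates_per_fold=1,
                                                trees_per_forest=25, seed=0))
        x = ex.X[ex.y == 1][0]
        dep_02, _ = feature_dependence(ens, x, ["f0"], threshold=0.2)
        dep_01, _ = feature_dependence(ens, x, ["f0"], threshold=0.1)
        if dep_02:
            assert dep_01

    def test_unknown_feature_rejected(self):
        ex = separable_examples()
        ens = train_ensemble(ex, EnsembleConfig(replicates_per_fold=1,
                                                trees_per_forest=5, seed=0))
        with pytest.raises(KeyError):
            feature_dependence(ens, ex.X[0], ["nope"])


class TestPersistence:
    def test_model_container_roundtrip(self, tmp_path):
        ex = separable_examples()
        ens = train_ensemble(ex, EnsembleConfig(replicates_per_fold=1,
                                                trees_per_forest=5, seed=0))
        path = tmp_path / "model.bin"
        save_model(ens, path)
        back = load_model(path)
        np.testing.assert_allclose(
            back.predict_matrix(ex.X[:5]), ens.predict_matrix(ex.X[:5])
        )
        assert [s.name for s in back.specs] == [s.name for s in ens.specs]
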