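"""Grid enumeration, splitting, selection and the repeated evaluation
protocol."""

import numpy as np
import pandas as pd
import pytest

from tlradiomics import (PipelineConfig, SimulationDesign, downsample_split,
                         enumerate_grid, evaluate_config, prepare_inputs,
                         results_to_frame, run_grid, select_features,
                         simulate_cohort, with_clinical)

from conftest import make_table

#: shrunken ensemble sizes so repeated protocols stay desk-scale; every
#: other hyperparameter remains the library default
SMALL_MODELS = {"RF": {"n_estimators": 40}, "ET": {"n_estimators": 40},
                "XGB": {"n_estimators": 40}}


class TestEnumeration:
    def test_full_factorial_cardinality_and_marginals(self):
        grid = enumerate_grid()
        assert len(grid) == 630
        frame = pd.DataFrame([vars(c) for c in grid])
        assert frame["feature_type"].value_counts().eq(315).all()
        assert frame["batch_method"].value_counts().eq(210).all()
        assert frame["discretization"].value_counts().eq(126).all()
        assert frame["selector"].value_counts().eq(210).all()
        assert frame["classifier"].value_counts().eq(90).all()
        assert len(set(grid)) == 630          # all distinct, hashable

    def test_order_deterministic(self):
        assert enumerate_grid() == enumerate_grid()
        first = enumerate_grid()[0]
        assert (first.feature_type, first.batch_method) == ("OR", "none")

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="classifier"):
            PipelineConfig("OR", "none", "none", "DT", "MLP")


class TestDownsampleSplit:
    @pytest.fixture()
    def imbalanced(self):
        rng = np.random.default_rng(0)
        n1, n0 = 52, 95
        return make_table(rng.normal(size=(n1 + n0, 4)),
                          batch=["b"] * (n1 + n0),
                          outcome=[1] * n1 + [0] * n0)

    def test_paper_counts_95_52(self, imbalanced):
        train, val = downsample_split(imbalanced, 0.8, rng_seed=1)
        # 95 non-pCR down-sampled to 52, floor(0.8*52)=41 per class
        assert train.outcome.value_counts().tolist() == [41, 41]
        assert val.outcome.value_counts().tolist() == [11, 11]
        assert set(train.sample_ids).isdisjoint(val.sample_ids)

    def test_balanced_classes_lose_no_sample(self):
        t = make_table(np.random.default_rng(1).normal(size=(40, 3)),
                       batch=["b"] * 40, outcome=[0, 1] * 20)
        train, val = downsample_split(t, 0.8, rng_seed=2)
        assert train.n_samples + val.n_samples == 40

    def test_same_seed_same_split(self, imbalanced):
        a = downsample_split(imbalanced, 0.8, rng_seed=7)
        b = downsample_split(imbalanced, 0.8, rng_seed=7)
        assert list(a[0].sample_ids) == list(b[0].sample_ids)
        assert list(a[1].sample_ids) == list(b[1].sample_ids)

    def test_tiny_class_rejected(self):
        t = make_table(np.ones((3, 2)) + np.eye(3, 2), batch=["b"] * 3,
                       outcome=[1, 0, 0])
        with pytest.raises(ValueError, match=">= 2"):
            downsample_split(t, 0.8, rng_seed=0)


class TestSelectFeatures:
    def test_returns_exactly_k(self):
        rng = np.random.default_rng(2)
        t = make_table(rng.normal(size=(60, 25)), batch=["b"] * 60,
                       outcome=rng.integers(0, 2, 60))
        for sel in ("DT", "RF", "XGB"):
            out = select_features(t, sel, k=10, rng_seed=0,
                                  selector_params=SMALL_MODELS.get(sel))
            assert len(out) == 10
            assert len(set(out.features)) == 10
            assert list(out.weights.index) == out.features

    def test_single_feature_table(self):
        t = make_table(np.random.default_rng(3).normal(size=(30, 1)),
                       batch=["b"] * 30,
                       outcome=[0, 1] * 15)
        out = select_features(t, "DT", k=1)
        assert out.features == ["0"]

    def test_unknown_selector_lists_valid_names(self):
        t = make_table(np.ones((4, 2)) + np.eye(4, 2), batch=["b"] * 4,
                       outcome=[0, 1, 0, 1])
        with pytest.raises(ValueError, match="DT.*RF.*XGB"):
            select_features(t, "LASSO")

    def test_informative_features_enriched(self, default_cohort):
        c = default_cohort
        table = c.tumor_table
        info = set(c.truth["informative_features"])
        n_rep = 20
        counts = []
        for rep in range(n_rep):
            train, _ = downsample_split(table, 0.8, rng_seed=rep)
            out = select_features(train, "RF", k=10, rng_seed=rep,
                                  selector_params=SMALL_MODELS["RF"])
            counts.append(sum(1 for f in out.features if f in info))
        # pooled count against the sum of hypergeometric nulls
        # (10 draws from n_features with len(info) informative, per repeat)
        N, K, n = table.n_features, len(info), 10
        mean = n_rep * n * K / N
        var = n_rep * n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
        z = (sum(counts) - mean) / np.sqrt(var)
        from scipy.stats import norm
        assert norm.sf(z) < 0.01


@pytest.fixture(scope="module")
def small_tables():
    """A compact cohort + assembled tables for protocol tests."""
    design = SimulationDesign(
        n_per_batch={"scanner1": 40, "scanner2": 40, "scanner3": 40},
        n_features_ct=30, n_features_pet=30, n_informative=8, seed=17)
    cohort = simulate_cohort(design)
    return cohort, prepare_inputs(cohort)


class TestEvaluateConfig:
    def test_separable_feature_gives_perfect_validation_auc(self):
        rng = np.random.default_rng(4)
        outcome = rng.integers(0, 2, 80)
        x = rng.normal(size=(80, 5))
        x[:, 2] = outcome * 10.0              # one perfectly separating feature
        t = make_table(x, batch=["b1"] * 40 + ["b2"] * 40, outcome=outcome,
                       modality=["CT", "CT", "CT", "PET", "PET"])
        tables = {"OR": t}
        cfg = PipelineConfig("OR", "none", "none", "DT", "DT")
        res = evaluate_config(cfg, tables, ["b1"], "b2", repeats=5, seed=0)
        assert res.auc_validation == 1.0
        assert res.auc_test == 1.0

    def test_no_signal_aucs_near_half(self):
        design = SimulationDesign(
            n_per_batch={"scanner1": 40, "scanner2": 40, "scanner3": 40},
            n_features_ct=30, n_features_pet=30, n_informative=0, seed=23)
        cohort = simulate_cohort(design)
        tables = prepare_inputs(cohort)
        cfg = PipelineConfig("OR", "none", "none", "DT", "SGD")
        res = evaluate_config(cfg, tables, ["scanner1", "scanner2"],
                              "scanner3", repeats=200, seed=3)
        assert 0.45 <= res.auc_mean <= 0.55

    def test_deterministic_given_seed(self, small_tables):
        _, tables = small_tables
        cfg = PipelineConfig("TLR", "limma", "FBW32", "DT", "KNN")
        a = evaluate_config(cfg, tables, ["scanner1", "scanner2"], "scanner3",
                            repeats=5, seed=11)
        b = evaluate_config(cfg, tables, ["scanner1", "scanner2"], "scanner3",
                            repeats=5, seed=11)
        np.testing.assert_array_equal(a.auc_validation_per_repeat,
                                      b.auc_validation_per_repeat)
        assert a.auc_mean == b.auc_mean

    def test_mean_auc_consistent_with_components(self, small_tables):
        _, tables = small_tables
        cfg = PipelineConfig("OR", "combat", "FBN32", "DT", "DT")
        res = evaluate_config(cfg, tables, ["scanner1", "scanner2"],
                              "scanner3", repeats=4, seed=5)
        assert res.auc_mean == pytest.approx(
            (res.auc_validation + res.auc_test) / 2.0, abs=1e-12)

    def test_test_batch_never_in_training(self, small_tables, monkeypatch):
        _, tables = small_tables
        seen = []
        import tlradiomics.grid as grid_mod
        orig = grid_mod.downsample_split

        def spy(table, frac=0.8, rng_seed=0):
            train, val = orig(table, frac, rng_seed)
            seen.append((set(train.batch), set(val.batch)))
            return train, val

        monkeypatch.setattr(grid_mod, "downsample_split", spy)
        cfg = PipelineConfig("OR", "none", "none", "DT", "DT")
        evaluate_config(cfg, tables, ["scanner1", "scanner2"], "scanner3",
                        repeats=6, seed=0)
        assert seen
        for train_b, val_b in seen:
            assert "scanner3" not in train_b | val_b

    def test_leakage_safe_mode_runs_and_differs_from_default(self,
                                                             small_tables):
        """With leakage-safe preprocessing the held-out scanner never
        enters the harmonization or discretizer fits, so the binned
        values (and generally the AUCs) differ from the default
        fit-on-everything mode."""
        _, tables = small_tables
        cfg = PipelineConfig("TLR", "limma", "FBN32", "DT", "KNN")
        default = evaluate_config(cfg, tables, ["scanner1", "scanner2"],
                                  "scanner3", repeats=5, seed=4)
        safe = evaluate_config(cfg, tables, ["scanner1", "scanner2"],
                               "scanner3", repeats=5, seed=4,
                               leakage_safe=True)
        assert 0.0 <= safe.auc_mean <= 1.0
        assert not np.allclose(safe.auc_test_per_repeat,
                               default.auc_test_per_repeat)

    def test_overlapping_test_batch_rejected(self, small_tables):
        _, tables = small_tables
        cfg = PipelineConfig("OR", "none", "none", "DT", "DT")
        with pytest.raises(ValueError, match="disjoint"):
            evaluate_config(cfg, tables, ["scanner1", "scanner3"], "scanner3")


class TestRunGrid:
    def test_subset_ranked_by_mean_auc(self, small_tables):
        _, tables = small_tables
        configs = [PipelineConfig("OR", "none", "none", "DT", "DT"),
                   PipelineConfig("TLR", "limma", "none", "DT", "KNN")]
        results = run_grid(tables, ["scanner1", "scanner2"], "scanner3",
                           configs=configs, repeats=4, seed=2)
        assert len(results) == 2
        aucs = [r.auc_mean for r in results]
        assert aucs == sorted(aucs, reverse=True)
        frame = results_to_frame(results)
        assert set(frame.columns) >= {"feature_type", "batch_method",
                                      "discretization", "selector",
                                      "classifier", "auc_validation",
                                      "auc_test", "auc_mean", "n_repeats"}

    def test_identical_seed_identical_ranking(self, small_tables):
        _, tables = small_tables
        configs = [PipelineConfig("OR", "none", "none", "DT", c)
                   for c in ("DT", "KNN", "SGD")]
        a = run_grid(tables, ["scanner1", "scanner2"], "scanner3",
                     configs=configs, repeats=4, seed=9)
        b = run_grid(tables, ["scanner1", "scanner2"], "scanner3",
                     configs=configs, repeats=4, seed=9)
        assert [r.config for r in a] == [r.config for r in b]
        assert [r.auc_mean for r in a] == [r.auc_mean for r in b]

    def test_one_failure_does_not_abort(self, small_tables, monkeypatch):
        _, tables = small_tables
        import tlradiomics.grid as grid_mod
        orig = grid_mod.select_features

        def sometimes_broken(train, selector, **kw):
            if selector == "XGB":
                raise RuntimeError("synthetic failure")
            return orig(train, selector, **kw)

        monkeypatch.setattr(grid_mod, "select_features", sometimes_broken)
        configs = [PipelineConfig("OR", "none", "none", "XGB", "DT"),
                   PipelineConfig("OR", "none", "none", "DT", "DT")]
        results = run_grid(tables, ["scanner1", "scanner2"], "scanner3",
                           configs=configs, repeats=3, seed=0)
        by_sel = {r.config.selector: r for r in results}
        assert by_sel["XGB"].error is not None
        assert by_sel["DT"].error is None


def test_with_clinical_appends_covariate_columns(small_tables):
    cohort, tables = small_tables
    combined = with_clinical(tables["OR"])
    assert combined.n_features == tables["OR"].n_features + 3
    assert set(combined.feature_meta["modality"]) >= {"CLIN"}
    np.testing.assert_array_equal(
        combined.values["CLIN_ER"].to_numpy(),
        cohort.tumor_table.sample_meta["ER"].reindex(
            combined.sample_ids).to_numpy().astype(float))
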