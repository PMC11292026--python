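"""Cross-validation, threshold transfer, VUS scoring and contamination runs."""

import numpy as np
import pandas as pd
import pytest

import genecalib as gc
from genecalib.validation import ValidationError

from conftest import brute_force_sweep


class TestKFoldSplit:
    def test_equal_sizes(self):
        folds = gc.kfold_split(np.arange(10), 5, seed=0)
        assert sorted(len(f) for f in folds) == [2] * 5

    def test_primary_sizes(self):
        folds = gc.kfold_split(np.arange(241), 5, seed=0)
        assert sorted(len(f) for f in folds) == [48, 48, 48, 48, 49]

    def test_disjoint_union(self):
        ids = np.array([f"v{i}" for i in range(37)])
        folds = gc.kfold_split(ids, 5, seed=1)
        all_ids = np.concatenate(folds)
        assert len(all_ids) == len(set(all_ids)) == 37

    def test_determinism(self):
        a = gc.kfold_split(np.arange(50), 5, seed=3)
        b = gc.kfold_split(np.arange(50), 5, seed=3)
        c = gc.kfold_split(np.arange(50), 5, seed=4)
        assert all((x == y).all() for x, y in zip(a, b))
        assert any((x != y).any() for x, y in zip(a, c) if len(x) == len(y))

    def test_class_presence_guard(self):
        # 5 disease among 50: an unguarded split often strands a fold
        labels = np.array(["disease"] * 5 + ["neutral"] * 45, dtype=object)
        for seed in range(5):
            folds = gc.kfold_split(np.arange(50), 5, seed=seed, labels=labels)
            for f in folds:
                assert set(labels[f]) == {"disease", "neutral"}

    def test_stratified(self):
        labels = np.array(["disease"] * 10 + ["neutral"] * 40, dtype=object)
        folds = gc.kfold_split(np.arange(50), 5, seed=0, labels=labels, stratified=True)
        for f in folds:
            assert (labels[f] == "disease").sum() == 2

    def test_too_few_variants(self):
        with pytest.raises(ValidationError):
            gc.kfold_split(np.arange(3), 5, seed=0)

    def test_retry_exhaustion(self):
        labels = np.array(["disease"] + ["neutral"] * 9, dtype=object)
        with pytest.raises(ValidationError, match="could not draw"):
            gc.kfold_split(np.arange(10), 5, seed=0, labels=labels, max_retries=3)


class TestCrossValidate:
    def test_separable_data_perfect_folds(self, ascending_spec):
        # repeated boundary scores so every training fold sees the class edge
        n = 51
        scores = np.concatenate([np.tile([0.7, 0.8, 0.9], n // 3), np.tile([0.1, 0.2, 0.3], n // 3)])
        labels = np.array(["disease"] * n + ["neutral"] * n, dtype=object)
        report = gc.cross_validate(scores, labels, ascending_spec, k=5, seed=0)
        assert len(report.folds) == 5
        assert all(f.metrics.mcc == 1.0 for f in report.folds)
        assert report.sd["mcc"] == 0.0

    def test_summary_recomputes_from_folds(self, registry, synthetic_world):
        variants, scores = synthetic_world
        keep = variants["label"].isin(["disease", "neutral"]).to_numpy()
        report = gc.cross_validate(
            scores.loc[keep, "AlphaMissense"].to_numpy(),
            variants.loc[keep, "label"].to_numpy(),
            registry["AlphaMissense"], k=5, seed=1,
        )
        mccs = [f.metrics.mcc for f in report.folds]
        assert report.mean["mcc"] == pytest.approx(np.mean(mccs), abs=1e-12)
        assert report.sd["mcc"] == pytest.approx(np.std(mccs, ddof=1), abs=1e-12)

    def test_thresholds_learned_on_training_folds_only(self, ascending_spec):
        """Re-deriving each fold's threshold from the complement partition
        reproduces the report: learning never saw the held-out fold."""
        rng = np.random.default_rng(12)
        n = 80
        scores = np.concatenate([rng.normal(0.7, 0.15, n), rng.normal(0.3, 0.15, n)]).clip(0, 1)
        labels = np.array(["disease"] * n + ["neutral"] * n, dtype=object)
        seed = 5
        report = gc.cross_validate(scores, labels, ascending_spec, k=5, seed=seed)
        folds = gc.kfold_split(np.arange(len(scores)), 5, seed, labels=labels)
        for fold_res, test_ids in zip(report.folds, folds):
            train = np.setdiff1d(np.arange(len(scores)), test_ids)
            assert len(np.intersect1d(train, test_ids)) == 0
            res = gc.optimize_threshold(scores[train], labels[train], ascending_spec)
            assert fold_res.threshold == res.best_threshold


class TestEvaluateTransfer:
    def test_train_equals_test(self, registry, synthetic_world):
        variants, scores = synthetic_world
        keep = variants["label"].isin(["disease", "neutral"]).to_numpy()
        sub = scores.loc[keep]
        labels = variants.loc[keep, "label"].to_numpy()
        out = gc.evaluate_transfer(sub, labels, sub, labels, registry, tools=["AlphaMissense"])
        opt_row = out[(out["thresholds"] == "optimized") & (out["tool"] == "AlphaMissense")].iloc[0]
        train_res = gc.optimize_threshold(sub["AlphaMissense"], labels, registry["AlphaMissense"])
        assert opt_row["mcc"] == pytest.approx(train_res.best_mcc)
        assert opt_row["threshold"] == train_res.best_threshold

    def test_panel_row_appended(self, registry, synthetic_world):
        variants, scores = synthetic_world
        keep = variants["label"].isin(["disease", "neutral"]).to_numpy()
        sub, labels = scores.loc[keep], variants.loc[keep, "label"].to_numpy()
        out = gc.evaluate_transfer(sub, labels, sub, labels, registry)
        assert out["tool"].str.contains(r"\+").sum() == 1
        assert len(out) == 2 * 10 + 1

    def test_same_distribution_transfer_close_to_cv(self, registry):
        cfg_a = gc.SyntheticConfig(n_disease=120, n_neutral=60, seed=31, missing_rate=0.0)
        cfg_b = gc.SyntheticConfig(n_disease=120, n_neutral=60, seed=32, missing_rate=0.0)
        va, sa = gc.generate_dataset(cfg_a, registry)
        vb, sb = gc.generate_dataset(cfg_b, registry)
        tool = "REVEL"
        out = gc.evaluate_transfer(
            sa, va["label"].to_numpy(), sb, vb["label"].to_numpy(), registry, tools=[tool]
        )
        cv = gc.cross_validate(
            sa[tool].to_numpy(), va["label"].to_numpy(), registry[tool], k=5, seed=0
        )
        transferred = out[out["thresholds"] == "optimized"]["mcc"].iloc[0]
        assert abs(transferred - cv.mean["mcc"]) < max(3 * cv.sd["mcc"], 0.1)

    def test_no_shared_tools(self, registry, synthetic_world):
        variants, scores = synthetic_world
        labels = variants["label"].to_numpy()
        with pytest.raises(ValidationError):
            gc.evaluate_transfer(
                scores[["REVEL"]], labels, scores[["CADD"]], labels, registry, tools=None
            )


class TestScoreVus:
    def test_discordant_variant(self, registry):
        scores = pd.DataFrame(
            {"AlphaMissense": [0.1654], "SIFT4G": [0.16]}, index=["11:31806584:T:G"]
        )
        thresholds = {"AlphaMissense": 0.967, "SIFT4G": 0.025}
        votes, summary = gc.score_vus(scores, registry, thresholds)
        assert (votes.loc["11:31806584:T:G"] == "benign").all()
        assert summary.loc["11:31806584:T:G", "n_pathogenic_votes"] == 0
        assert bool(summary.loc["11:31806584:T:G", "all_benign"])

    def test_fully_concordant_pathogenic(self, registry):
        # maximal pathogenicity in every tool: high everywhere, minimal SIFT4G
        row = {t: (0.0 if t == "SIFT4G" else registry[t].score_max or 10.0) for t in registry}
        scores = pd.DataFrame(row, index=["v1"])
        thresholds = {t: registry[t].default_threshold for t in registry}
        votes, summary = gc.score_vus(scores, registry, thresholds)
        assert summary.loc["v1", "n_pathogenic_votes"] == 10
        assert bool(summary.loc["v1", "all_pathogenic"])

    def test_empty_vus_set(self, registry):
        scores = pd.DataFrame(columns=["REVEL"], dtype=float)
        votes, summary = gc.score_vus(scores, registry, {"REVEL": 0.5})
        assert votes.empty and summary.empty


class TestContaminationExperiment:
    @pytest.fixture()
    def world(self, registry):
        cfg = gc.SyntheticConfig(n_disease=100, n_neutral=60, seed=13, missing_rate=0.0)
        variants, scores = gc.generate_dataset(cfg, registry)
        return variants, scores["REVEL"], registry["REVEL"]

    def test_zero_fraction_matches_clean_run(self, world):
        variants, scores, spec = world
        out = gc.contamination_experiment(
            variants, scores, spec, fractions=[0.0], seeds=[0]
        )
        clean = gc.optimize_threshold(scores, variants["label"].to_numpy(), spec)
        assert out.loc[0, "best_threshold"] == clean.best_threshold
        assert out.loc[0, "mcc"] == pytest.approx(clean.best_mcc)
        assert out.loc[0, "n_flipped"] == 0

    def test_oracle_replay(self, world):
        """One contaminated cell agrees with an independent replay: flip the
        same labels and sweep thresholds by brute force."""
        variants, scores, spec = world
        out = gc.contamination_experiment(
            variants, scores, spec, fractions=[0.2], seeds=[7]
        )
        flipped_tbl, _ = gc.contaminate(variants, 0.2, seed=7)
        oracle_mcc, _ = brute_force_sweep(
            scores.to_numpy(), flipped_tbl["label"].to_numpy(), spec
        )
        assert out.loc[0, "mcc"] == pytest.approx(oracle_mcc, abs=1e-12)

    def test_mcc_degrades_with_contamination(self, world):
        variants, scores, spec = world
        out = gc.contamination_experiment(
            variants, scores, spec, fractions=[0.0, 0.2], seeds=range(3)
        )
        clean = out[out["fraction"] == 0.0]["mcc"].mean()
        dirty = out[out["fraction"] == 0.2]["mcc"].mean()
        assert dirty < clean

    def test_grid_shape(self, world):
        variants, scores, spec = world
        out = gc.contamination_experiment(
            variants, scores, spec, fractions=[0.05, 0.1], seeds=range(4)
        )
        assert len(out) == 8
        assert set(out["n_flipped"]) == {5, 10}
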