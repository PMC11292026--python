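"""The synthetic benchmark generator: class structure, score distributions,
correlation direction, missingness, determinism and contamination."""

import numpy as np
import pandas as pd
import pytest

import genecalib as gc
from genecalib.synthetic import ConfigurationError, Dist


class TestGenerateDataset:
    def test_degenerate_single_class(self, registry):
        cfg = gc.SyntheticConfig(n_disease=0, n_neutral=10, n_vus=0, missing_rate=0.0, seed=0)
        variants, scores = gc.generate_dataset(cfg, registry)
        assert len(variants) == 10
        assert (variants["label"] == "neutral").all()
        assert not scores.isna().any().any()

    def test_primary_class_sizes(self, registry):
        cfg = gc.SyntheticConfig(n_disease=167, n_neutral=74, n_vus=0, seed=0)
        variants, scores = gc.generate_dataset(cfg, registry)
        assert len(variants) == 241
        assert (variants["label"] == "disease").sum() == 167
        assert variants["variant_id"].is_unique
        assert list(scores.index) == list(variants["variant_id"])

    def test_beta_class_mean_difference(self, registry):
        # disease ~ Beta(8,2) (mean .8), neutral ~ Beta(2,8) (mean .2)
        cfg = gc.SyntheticConfig(
            n_disease=2000, n_neutral=2000, seed=1, missing_rate=0.0,
            tools=("REVEL",),
        )
        variants, scores = gc.generate_dataset(cfg, registry)
        dis = scores.loc[variants["label"].to_numpy() == "disease", "REVEL"]
        neu = scores.loc[variants["label"].to_numpy() == "neutral", "REVEL"]
        var_beta = 8 * 2 / ((10) ** 2 * 11)  # Var Beta(8,2) = Var Beta(2,8)
        se = np.sqrt(2 * var_beta / 2000)
        assert abs((dis.mean() - neu.mean()) - 0.6) < 3 * se

    def test_determinism_and_seed_sensitivity(self, registry):
        cfg = gc.SyntheticConfig(n_disease=30, n_neutral=30, seed=5)
        v1, s1 = gc.generate_dataset(cfg, registry)
        v2, s2 = gc.generate_dataset(cfg, registry)
        pd.testing.assert_frame_equal(v1, v2)
        pd.testing.assert_frame_equal(s1, s2)
        v3, s3 = gc.generate_dataset(gc.SyntheticConfig(n_disease=30, n_neutral=30, seed=6), registry)
        assert not s1.equals(s3)

    def test_descending_tool_ordering_reversed(self, registry, synthetic_world):
        variants, scores = synthetic_world
        dis = variants["label"].to_numpy() == "disease"
        neu = variants["label"].to_numpy() == "neutral"
        # SIFT4G: disease variants score LOW; ascending tools the opposite
        assert scores.loc[dis, "SIFT4G"].mean() < scores.loc[neu, "SIFT4G"].mean()
        assert scores.loc[dis, "REVEL"].mean() > scores.loc[neu, "REVEL"].mean()

    def test_scores_within_declared_bounds(self, registry, synthetic_world):
        _, scores = synthetic_world
        for tool in scores.columns:
            spec = registry[tool]
            if spec.bounded:
                col = scores[tool].dropna()
                assert col.between(spec.score_min, spec.score_max).all()

    def test_missingness_rate(self, registry):
        cfg = gc.SyntheticConfig(n_disease=1000, n_neutral=1000, missing_rate=0.1, seed=2)
        _, scores = gc.generate_dataset(cfg, registry)
        n_cells = scores.size
        frac = scores.isna().to_numpy().mean()
        se = np.sqrt(0.1 * 0.9 / n_cells)
        assert abs(frac - 0.1) < 3 * se

    def test_inter_tool_correlation_positive(self, registry):
        cfg = gc.SyntheticConfig(
            n_disease=0, n_neutral=3000, missing_rate=0.0, seed=4,
            tools=("REVEL", "VEST4"), inter_tool_correlation=0.8,
        )
        _, scores = gc.generate_dataset(cfg, registry)
        r = np.corrcoef(scores["REVEL"], scores["VEST4"])[0, 1]
        assert r > 0.5
        cfg0 = gc.SyntheticConfig(
            n_disease=0, n_neutral=3000, missing_rate=0.0, seed=4,
            tools=("REVEL", "VEST4"), inter_tool_correlation=0.0,
        )
        _, s0 = gc.generate_dataset(cfg0, registry)
        assert abs(np.corrcoef(s0["REVEL"], s0["VEST4"])[0, 1]) < 0.1

    def test_domain_enrichment(self, registry):
        cfg = gc.SyntheticConfig(n_disease=2000, n_neutral=0, seed=9, domain_enrichment=0.9)
        variants, _ = gc.generate_dataset(cfg, registry)
        inside = variants["protein_pos"].map(
            lambda p: any(lo <= p <= hi for lo, hi in cfg.domain_intervals)
        )
        se = np.sqrt(0.9 * 0.1 / 2000)
        assert abs(inside.mean() - 0.9) < 3 * se

    def test_vus_scored_but_labeled_vus(self, registry):
        cfg = gc.SyntheticConfig(n_disease=5, n_neutral=5, n_vus=7, seed=0, missing_rate=0.0)
        variants, scores = gc.generate_dataset(cfg, registry)
        assert (variants["label"] == "vus").sum() == 7
        assert len(scores) == 17

    def test_invalid_distribution_names_tool(self, registry):
        cfg = gc.SyntheticConfig(
            tools=("REVEL",),
            disease_score_dist={"REVEL": Dist("beta", a=-1, b=2)},
        )
        with pytest.raises(ConfigurationError, match="REVEL"):
            gc.generate_dataset(cfg, registry)

    def test_config_from_yaml_and_json(self, registry, tmp_path):
        yaml_path = tmp_path / "cfg.yaml"
        yaml_path.write_text(
            "n_disease: 12\nn_neutral: 6\nseed: 3\nmissing_rate: 0.0\n"
            "tools: [REVEL]\n"
            "disease_score_dist: {REVEL: {kind: beta, a: 5, b: 2}}\n"
        )
        cfg = gc.SyntheticConfig.from_file(yaml_path)
        assert cfg.n_disease == 12
        assert cfg.disease_score_dist["REVEL"].a == 5
        json_path = tmp_path / "cfg.json"
        json_path.write_text('{"n_disease": 12, "n_neutral": 6, "seed": 3, "tools": ["REVEL"]}')
        cfg_json = gc.SyntheticConfig.from_file(json_path)
        v1, _ = gc.generate_dataset(cfg_json, registry)
        assert len(v1) == 18

    def test_invalid_probability(self, registry):
        with pytest.raises(ConfigurationError, match="missing_rate"):
            gc.generate_dataset(gc.SyntheticConfig(missing_rate=1.5), registry)


class TestContaminate:
    @pytest.fixture()
    def small_world(self, registry):
        cfg = gc.SyntheticConfig(n_disease=167, n_neutral=74, seed=0)
        variants, _ = gc.generate_dataset(cfg, registry)
        return variants

    def test_zero_fraction_identity(self, small_world):
        out, flipped = gc.contaminate(small_world, 0.0, seed=1)
        assert flipped == []
        pd.testing.assert_frame_equal(out, small_world)

    def test_exact_flip_count(self, small_world):
        out, flipped = gc.contaminate(small_world, 0.1, seed=1)
        assert len(flipped) == 17  # round(0.1 * 167)
        assert (out["label"] == "disease").sum() == 150
        assert len(out) == len(small_world)
        assert (out.loc[out["variant_id"].isin(flipped), "label"] == "neutral").all()

    def test_only_label_changes(self, small_world):
        out, flipped = gc.contaminate(small_world, 0.2, seed=3)
        pd.testing.assert_frame_equal(
            out.drop(columns="label"), small_world.drop(columns="label")
        )

    def test_total_flip(self, registry):
        cfg = gc.SyntheticConfig(n_disease=5, n_neutral=5, seed=0)
        variants, _ = gc.generate_dataset(cfg, registry)
        out, flipped = gc.contaminate(variants, 1.0, seed=0)
        assert (out["label"] == "neutral").sum() == 10
        assert len(flipped) == 5

    def test_reverse_direction(self, small_world):
        out, flipped = gc.contaminate(
            small_world, 0.5, seed=2, direction="neutral_to_disease"
        )
        assert len(flipped) == 37  # round(0.5 * 74)
        assert (out["label"] == "disease").sum() == 167 + 37

    def test_seeded_reproducibility(self, small_world):
        _, f1 = gc.contaminate(small_world, 0.1, seed=4)
        _, f2 = gc.contaminate(small_world, 0.1, seed=4)
        _, f3 = gc.contaminate(small_world, 0.1, seed=5)
        assert f1 == f2
        assert f1 != f3

    def test_fraction_out_of_range(self, small_world):
        with pytest.raises(ConfigurationError):
            gc.contaminate(small_world, 1.2, seed=0)
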