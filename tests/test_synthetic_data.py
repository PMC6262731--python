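import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import raterpanel as rp
from raterpanel.synthetic_data import (
    DEFAULT_DIFFICULTY_EFFECTS,
    category_difficulty,
    features_token,
)


def flat_config(**kw):
    """A difficulty-free single-category config for limiting-case tests."""
    design = (
        rp.CategorySpec("flat", kw.pop("n_images", 60), 1, "winter", "forest",
                        frozenset({"face", "legs"}), "day"),
    )
    defaults = dict(
        n_raters=9,
        category_design=design,
        difficulty_effects={},
        image_difficulty_sd=0.0,
        rater_skill_sd=0.0,
        unknown_propensity=0.0,
    )
    defaults.update(kw)
    return rp.PanelConfig(**defaults)


class TestGeneratePanel:
    def test_noiseless_limit_is_unanimous_with_kappa_one(self):
        panel, truth = rp.generate_panel(flat_config(base_accuracy=1.0), seed=0)
        table = rp.tabulate_agreement(panel)
        assert table.n_unanimous == panel.n_images
        assert rp.fleiss_kappa(panel).kappa == 1.0
        # every classification equals the true species
        wide = panel.response_matrix()
        for img in panel.images:
            assert set(wide.loc[img]) == {truth.images.loc[img, "true_species"]}

    def test_coin_flip_limit_has_chance_agreement(self):
        cfg = flat_config(base_accuracy=0.5, n_images=400, n_raters=27)
        panel, _ = rp.generate_panel(cfg, seed=1)
        assert abs(rp.fleiss_kappa(panel).kappa) < 0.02

    def test_default_design_matches_study_shape(self, default_synthetic):
        panel, truth = default_synthetic
        assert panel.n_images == 299
        assert panel.n_raters == 27
        assert len(panel.category_labels) == 3
        meta = panel.image_metadata
        assert meta["category"].nunique() == 15
        assert (meta.groupby("category").size().sort_values().unique() == [19, 20]).all()
        assert sorted(panel.rater_info["region"].value_counts().values) == [8, 9, 10]

    def test_northern_images_are_always_lynx(self, default_synthetic):
        panel, truth = default_synthetic
        northern = panel.image_metadata.query("region == 'northern_BC'").index
        assert set(truth.images.loc[northern, "true_species"]) == {"lynx"}

    def test_seed_determinism(self):
        cfg = rp.PanelConfig()
        a, _ = rp.generate_panel(cfg, seed=9)
        b, _ = rp.generate_panel(cfg, seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)
        c, _ = rp.generate_panel(cfg, seed=10)
        assert not a.records.equals(c.records)

    def test_unknown_fraction_converges_to_configured_expectation(self):
        from scipy.special import expit, logit

        u0, slope, d = 0.08, 0.7, 0.5
        cfg = flat_config(
            n_images=1200,
            base_accuracy=0.9,
            unknown_propensity=u0,
            unknown_difficulty_slope=slope,
            difficulty_effects={"winter": d},
        )
        panel, _ = rp.generate_panel(cfg, seed=3)
        expected = float(expit(logit(u0) + slope * d))
        observed = (panel.records["response"] == "unknown").mean()
        n = len(panel.records)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * se

    def test_harder_category_gets_lower_kappa_and_more_unknowns(self):
        design = (
            rp.CategorySpec("easy", 30, 1, "winter", "forest", frozenset({"face", "legs"}), "day"),
            rp.CategorySpec("hard", 30, 1, "summer", "forest", frozenset({"face", "legs"}), "day"),
        )
        cfg = rp.PanelConfig(
            n_raters=27,
            category_design=design,
            difficulty_effects={"summer": 1.8},
            image_difficulty_sd=0.0,
            rater_skill_sd=0.0,
            base_accuracy=0.95,
            unknown_propensity=0.05,
            unknown_difficulty_slope=0.8,
        )
        wins = 0
        for seed in range(20):
            panel, _ = rp.generate_panel(cfg, seed=seed)
            easy = rp.filter_panel(panel, image_selector={"category": "easy"})
            hard = rp.filter_panel(panel, image_selector={"category": "hard"})
            if rp.fleiss_kappa(easy).kappa > rp.fleiss_kappa(hard).kappa:
                wins += 1
        assert wins >= 18

    def test_invalid_configs_rejected_before_sampling(self):
        with pytest.raises(rp.PanelValidationError):
            rp.generate_panel(rp.PanelConfig(base_accuracy=0.3))
        with pytest.raises(rp.PanelValidationError):
            rp.generate_panel(rp.PanelConfig(unknown_propensity=1.0))
        with pytest.raises(rp.PanelValidationError):
            rp.generate_panel(rp.PanelConfig(n_raters=1))
        with pytest.raises(rp.PanelValidationError):
            rp.generate_panel(rp.PanelConfig(consistency=1.5))


class TestRepeatPass:
    def test_full_consistency_reproduces_every_response(self, small_config):
        panel, truth = rp.generate_panel(small_config, seed=4)
        retest = rp.generate_repeat_pass(panel, truth, small_config, consistency=1.0, seed=5)
        report = rp.rater_consistency(panel, retest)
        assert all(r.n_changed == 0 for r in report.per_rater)
        assert all(r.kappa_self == 1.0 or np.isnan(r.kappa_self) for r in report.per_rater)

    def test_zero_consistency_with_degenerate_distribution_still_repeats(self):
        cfg = flat_config(base_accuracy=1.0, n_images=20)
        panel, truth = rp.generate_panel(cfg, seed=6)
        retest = rp.generate_repeat_pass(panel, truth, cfg, consistency=0.0, seed=7)
        report = rp.rater_consistency(panel, retest)
        assert all(r.n_changed == 0 for r in report.per_rater)

    def test_mean_self_kappa_increases_with_consistency(self):
        cfg = rp.PanelConfig()
        panel, truth = rp.generate_panel(cfg, seed=8)
        first = rp.filter_panel(panel, image_selector=lambda m: m["trial"] == 1)
        means = []
        for c in (0.5, 0.7, 0.9):
            retests = [
                rp.generate_repeat_pass(first, truth, cfg, consistency=c, seed=100 + i)
                for i in range(3)
            ]
            means.append(
                np.mean([rp.rater_consistency(first, r).mean_kappa for r in retests])
            )
        assert means[0] < means[1] < means[2]


class TestTruthSeparation:
    def test_truth_never_leaks_into_panel_files(self, tmp_path, small_config):
        panel, truth = rp.generate_panel(small_config, seed=11)
        cls, meta, raters, tr = (
            tmp_path / n for n in ("c.csv", "m.csv", "r.csv", "t.csv")
        )
        rp.write_panel(panel, cls, meta, raters)
        rp.write_truth(truth, tr)
        for path in (cls, meta, raters):
            header = path.read_text().splitlines()[0]
            assert "true_species" not in header
            assert "difficulty" not in header
            assert "skill" not in header
        assert tr.read_text().splitlines()[0] == "image_id,true_species"

    def test_expected_kappa_is_finite_and_plausible(self):
        cfg = dataclasses.replace(rp.PanelConfig(), rater_skill_sd=0.0)
        k = rp.expected_kappa(cfg, n_design_reps=5, seed=12)
        assert 0.3 < k < 0.9


def test_features_token_and_category_difficulty():
    assert features_token("face+legs+tail") == "full_body"
    assert features_token(frozenset({"face"})) == "face_only"
    spec = rp.CategorySpec(
        "x", 1, 1, "summer", "forest", frozenset({"legs", "tail"}), "day"
    )
    d = category_difficulty(spec, DEFAULT_DIFFICULTY_EFFECTS)
    assert d == pytest.approx(
        DEFAULT_DIFFICULTY_EFFECTS["summer"]
        + DEFAULT_DIFFICULTY_EFFECTS["forest"]
        + DEFAULT_DIFFICULTY_EFFECTS["legs_tail"]
        + DEFAULT_DIFFICULTY_EFFECTS["day"]
    )
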