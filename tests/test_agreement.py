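import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import raterpanel as rp
from conftest import panel_from_votes, records_from_pairs


class TestFleissKappa:
    def test_hand_worked_two_image_panel(self):
        # 3 raters, votes (2,1,0) and (1,2,0): P_i = 1/3 each, chance 1/2
        panel = panel_from_votes([(2, 1, 0), (1, 2, 0)])
        res = rp.fleiss_kappa(panel)
        assert res.p_bar == pytest.approx(1 / 3, abs=1e-12)
        assert res.p_bar_e == pytest.approx(1 / 2, abs=1e-12)
        assert res.kappa == pytest.approx(-1 / 3, abs=1e-12)
        assert res.category_proportions["bobcat"] == pytest.approx(0.5)

    def test_unanimous_multicategory_panel_is_exactly_one(self):
        panel = rp.unanimous_panel(n_raters=27, n_images=40)
        assert rp.fleiss_kappa(panel).kappa == 1.0

    def test_uniform_random_panel_is_near_zero(self):
        panel = rp.uniform_random_panel(n_raters=27, n_images=500, seed=20240901)
        assert abs(rp.fleiss_kappa(panel).kappa) < 0.02

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_statsmodels_reference(self, seed):
        """Independent cross-check against the reference implementation."""
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        panel, _ = rp.generate_panel(rp.PanelConfig(), seed=seed)
        ours = rp.fleiss_kappa(panel).kappa
        assert ours == pytest.approx(sm_fleiss(panel.counts), abs=1e-10)

    def test_degenerate_single_category_is_flagged_not_silent(self):
        panel = panel_from_votes([(5, 0, 0), (5, 0, 0)])
        res = rp.fleiss_kappa(panel)
        assert res.degenerate
        assert np.isnan(res.kappa)
        assert res.p_bar_e == pytest.approx(1.0)

    def test_unused_category_still_counts_toward_chance(self):
        """k is fixed by the declared category set, not the used set."""
        two_cat = panel_from_votes([(2, 1), (1, 2)], labels=("bobcat", "lynx"))
        three_cat = panel_from_votes([(2, 1, 0), (1, 2, 0)])
        assert rp.fleiss_kappa(two_cat).kappa == pytest.approx(
            rp.fleiss_kappa(three_cat).kappa
        )
        assert len(rp.fleiss_kappa(three_cat).category_proportions) == 3


class TestProportionOfAgreement:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((9, 9, 9), 216 / 702),      # perfect three-way disagreement
            ((27, 0, 0), 1.0),           # unanimity
            ((26, 0, 1), 650 / 702),     # one dissenting abstention
        ],
    )
    def test_formula_values(self, counts, expected):
        assert rp.proportion_of_agreement(rp.VoteCount(counts)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_bounds_round_as_printed(self):
        assert rp.round_half_up(
            rp.proportion_of_agreement(rp.VoteCount((9, 9, 9))), 2
        ) == 0.31
        assert rp.round_half_up(
            rp.proportion_of_agreement(rp.VoteCount((27, 0, 0))), 2
        ) == 1.00

    @given(
        st.lists(st.integers(min_value=0, max_value=30), min_size=3, max_size=3).filter(
            lambda c: sum(c) >= 2
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_invariant_under_count_permutation(self, counts):
        base = rp.proportion_of_agreement(rp.VoteCount(tuple(counts)))
        for perm in itertools.permutations(counts):
            assert rp.proportion_of_agreement(rp.VoteCount(perm)) == pytest.approx(
                base, abs=1e-15
            )

    @pytest.mark.parametrize("n", range(2, 31))
    def test_extremes_over_all_compositions(self, n):
        """Exhaustively: minimized at the most even split, maximized at unanimity."""
        poas = {
            (a, b, n - a - b): rp.proportion_of_agreement(rp.VoteCount((a, b, n - a - b)))
            for a in range(n + 1)
            for b in range(n - a + 1)
        }
        q, r = divmod(n, 3)
        even_split = tuple(sorted([q + (1 if i < r else 0) for i in range(3)], reverse=True))
        assert min(poas, key=poas.get) in set(itertools.permutations(even_split))
        assert poas[(n, 0, 0)] == max(poas.values()) == 1.0

    def test_mean_equals_kappa_p_bar(self, default_synthetic):
        """Per-image agreement and the kappa numerator share one intermediate."""
        panel, _ = default_synthetic
        mean_poa = np.mean(
            [rp.proportion_of_agreement(v) for _, v in panel.iter_vote_counts()]
        )
        assert mean_poa == pytest.approx(rp.fleiss_kappa(panel).p_bar, abs=1e-12)

    def test_single_rater_rejected(self):
        with pytest.raises(rp.PanelValidationError):
            rp.VoteCount((1, 0, 0))


class TestMajorityClassification:
    @pytest.mark.parametrize(
        "counts,majority,margin,unanimous",
        [
            ((26, 0, 1), "bobcat", 25, False),
            ((13, 13, 1), None, 0, False),
            ((27, 0, 0), "bobcat", 27, True),
            ((1, 25, 1), "lynx", 24, False),
        ],
    )
    def test_examples(self, counts, majority, margin, unanimous):
        res = rp.majority_classification(rp.VoteCount(counts))
        assert (res.majority, res.margin, res.unanimous) == (majority, margin, unanimous)


class TestTabulateAgreement:
    def test_panel_level_counts(self):
        panel = panel_from_votes([(27, 0, 0), (0, 27, 0), (20, 6, 1), (9, 9, 9)])
        table = rp.tabulate_agreement(panel)
        assert table.n_unanimous == 2
        assert table.n_any_unknown == 2
        assert table.n_both_species == 2
        assert table.n_majority_none == 1
        assert table.n_majority_unknown == 0
        assert table.mean_agreement == pytest.approx(
            (1.0 + 1.0 + rp.proportion_of_agreement(rp.VoteCount((20, 6, 1)))
             + 216 / 702) / 4
        )

    def test_mean_agreement_of_extreme_pair(self):
        panel = panel_from_votes([(27, 0, 0), (9, 9, 9)])
        table = rp.tabulate_agreement(panel)
        assert table.mean_agreement == pytest.approx((1.0 + 216 / 702) / 2, abs=1e-12)

    def test_identical_images_have_zero_sd(self):
        panel = panel_from_votes([(20, 6, 1)] * 5)
        assert rp.tabulate_agreement(panel).sd_agreement == 0.0

    def test_histogram_counts_images(self):
        panel = panel_from_votes([(27, 0, 0), (0, 27, 0), (20, 6, 1)])
        assert rp.tabulate_agreement(panel).majority_size_histogram == {20: 1, 27: 2}


class TestBootstrap:
    def test_unanimous_panel_zero_width_interval(self):
        panel = rp.unanimous_panel(n_raters=5, n_images=12)
        res = rp.bootstrap_kappa_ci(panel, n_boot=200, seed=0)
        assert res.ci_low == res.ci_high == 1.0

    def test_seed_reproducibility(self, default_synthetic):
        panel, _ = default_synthetic
        a = rp.bootstrap_kappa_ci(panel, n_boot=200, seed=7)
        b = rp.bootstrap_kappa_ci(panel, n_boot=200, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        c = rp.bootstrap_kappa_ci(panel, n_boot=200, seed=8)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_interval_brackets_point_estimate_and_stays_bounded(self, default_synthetic):
        panel, _ = default_synthetic
        res = rp.bootstrap_kappa_ci(panel, n_boot=300, seed=3)
        assert -1.0 <= res.ci_low <= res.kappa <= res.ci_high <= 1.0

    def test_degenerate_panel_refused(self):
        panel = panel_from_votes([(5, 0, 0), (5, 0, 0)])
        with pytest.raises(rp.DegenerateAgreementError):
            rp.bootstrap_kappa_ci(panel, n_boot=50, seed=0)


class TestRaterConsistency:
    def test_identical_passes_give_kappa_one(self):
        pairs = [("bobcat", "bobcat")] * 20 + [("lynx", "lynx")] * 20
        pa, pb = records_from_pairs(pairs)
        report = rp.rater_consistency(pa, pb)
        (res,) = report.per_rater
        assert res.n_changed == 0
        assert res.kappa_self == 1.0

    def test_symmetric_confusion_table_hand_value(self):
        # 2x2 confusion [[15, 5], [5, 15]]: observed 0.75, chance 0.5
        pairs = (
            [("bobcat", "bobcat")] * 15 + [("bobcat", "lynx")] * 5
            + [("lynx", "bobcat")] * 5 + [("lynx", "lynx")] * 15
        )
        pa, pb = records_from_pairs(pairs)
        report = rp.rater_consistency(pa, pb)
        (res,) = report.per_rater
        assert res.n_changed == 10
        assert res.kappa_self == pytest.approx(0.5, abs=1e-12)

    def test_independent_passes_give_near_zero(self):
        rng = np.random.default_rng(11)
        labels = np.array(rp.DEFAULT_CATEGORIES)
        pairs = list(zip(labels[rng.integers(0, 3, 3000)], labels[rng.integers(0, 3, 3000)]))
        pa, pb = records_from_pairs(pairs)
        (res,) = rp.rater_consistency(pa, pb).per_rater
        assert abs(res.kappa_self) < 0.05

    def test_degenerate_single_category_rater_is_nan(self):
        pairs = [("lynx", "lynx")] * 10
        pa, pb = records_from_pairs(pairs)
        (res,) = rp.rater_consistency(pa, pb).per_rater
        assert res.n_changed == 0
        assert np.isnan(res.kappa_self)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_cohen_matches_sklearn(self, seed):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(seed)
        labels = np.array(rp.DEFAULT_CATEGORIES)
        a = labels[rng.integers(0, 3, 200)]
        b = np.where(rng.random(200) < 0.6, a, labels[rng.integers(0, 3, 200)])
        ours = rp.cohen_kappa(a, b, rp.DEFAULT_CATEGORIES)
        assert ours == pytest.approx(
            cohen_kappa_score(a, b, labels=list(rp.DEFAULT_CATEGORIES)), abs=1e-12
        )

    def test_pooled_variant_equals_two_rater_fleiss(self):
        """A rater's two passes, stacked as a 2-rater panel, give the pooled kappa."""
        rng = np.random.default_rng(4)
        labels = np.array(rp.DEFAULT_CATEGORIES)
        a = labels[rng.integers(0, 3, 60)]
        b = np.where(rng.random(60) < 0.7, a, labels[rng.integers(0, 3, 60)])
        pa, pb = records_from_pairs(list(zip(a, b)))
        (res,) = rp.rater_consistency(pa, pb).per_rater

        rows = []
        for i, (x, y) in enumerate(zip(a, b)):
            rows.append({"image_id": f"i{i:04d}", "rater_id": "p1", "trial": 1, "response": x})
            rows.append({"image_id": f"i{i:04d}", "rater_id": "p2", "trial": 1, "response": y})
        two_rater = rp.ClassificationPanel.from_records(pd.DataFrame(rows))
        assert res.kappa_self_pooled == pytest.approx(
            rp.fleiss_kappa(two_rater).kappa, abs=1e-12
        )

    def test_mismatched_image_sets_rejected(self):
        pa, _ = records_from_pairs([("bobcat", "bobcat")] * 5)
        _, pb = records_from_pairs([("bobcat", "bobcat")] * 6)
        with pytest.raises(rp.PanelValidationError, match="image sets differ"):
            rp.rater_consistency(pa, pb)

    def test_panel_level_kappas_reported(self, small_config):
        panel, truth = rp.generate_panel(small_config, seed=2)
        retest = rp.generate_repeat_pass(panel, truth, small_config, seed=3)
        report = rp.rater_consistency(panel, retest)
        assert report.fleiss_first.kappa == pytest.approx(rp.fleiss_kappa(panel).kappa)
        assert -1 <= report.mean_kappa <= 1
        assert report.min_changed <= report.mean_changed <= report.max_changed


class TestSingleRaterMatchRate:
    def test_always_with_unanimous_panel(self):
        panel = rp.unanimous_panel(n_raters=5, n_images=8)
        report = rp.single_rater_match_rate(panel)
        assert set(report.per_rater.values()) == {1.0}
        assert report.mean == report.median == 1.0

    def test_half_matching_rater(self):
        # 3 raters; rater r1 votes bobcat on both images; majorities split
        rows = []
        for img, votes in [("a", ["bobcat", "bobcat", "lynx"]),
                           ("b", ["bobcat", "lynx", "lynx"])]:
            for j, v in enumerate(votes):
                rows.append({"image_id": img, "rater_id": f"r{j}", "trial": 1, "response": v})
        panel = rp.ClassificationPanel.from_records(pd.DataFrame(rows))
        report = rp.single_rater_match_rate(panel)
        assert report.per_rater["r0"] == 0.5

    def test_majority_none_images_excluded_from_both_sides(self):
        # image c is tied and must not dilute the rate
        rows = []
        for img, votes in [
            ("a", ["bobcat", "bobcat", "bobcat", "lynx"]),
            ("b", ["lynx", "lynx", "lynx", "bobcat"]),
            ("c", ["bobcat", "bobcat", "lynx", "lynx"]),
        ]:
            for j, v in enumerate(votes):
                rows.append({"image_id": img, "rater_id": f"r{j}", "trial": 1, "response": v})
        panel = rp.ClassificationPanel.from_records(pd.DataFrame(rows))
        report = rp.single_rater_match_rate(panel)
        assert report.n_images_used == 2
        assert report.n_excluded_no_majority == 1
        assert report.per_rater["r0"] == 1.0  # matched a and b; c excluded

    def test_all_tied_panel_rejected(self):
        panel = panel_from_votes([(13, 13, 1), (13, 13, 1)])
        with pytest.raises(rp.EmptyPanelError):
            rp.single_rater_match_rate(panel)
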