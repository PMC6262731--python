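import pandas as pd
import pytest

import raterpanel as rp


def panel_from_votes(vote_rows, labels=rp.DEFAULT_CATEGORIES, trial=1):
    """Build a complete panel whose per-image tallies are the given rows.

    Rater identities are assigned in label order, so all images share the
    same rater set and the panel is complete.
    """
    rows = []
    for i, counts in enumerate(vote_rows):
        rater = 0
        for label, c in zip(labels, counts):
            for _ in range(c):
                rater += 1
                rows.append(
                    {
                        "image_id": f"i{i + 1:03d}",
                        "rater_id": f"r{rater:02d}",
                        "trial": trial,
                        "response": label,
                    }
                )
    return rp.ClassificationPanel.from_records(
        pd.DataFrame(rows), category_labels=labels
    )


def records_from_pairs(pairs, labels=rp.DEFAULT_CATEGORIES):
    """Two single-rater panels from (pass1, pass2) response pairs."""
    rows_a, rows_b = [], []
    for i, (a, b) in enumerate(pairs):
        rows_a.append(
            {"image_id": f"i{i:04d}", "rater_id": "r01", "trial": 1, "response": a}
        )
        rows_b.append(
            {"image_id": f"i{i:04d}", "rater_id": "r01", "trial": 6, "response": b}
        )
    pa = rp.ClassificationPanel.from_records(pd.DataFrame(rows_a), category_labels=labels)
    pb = rp.ClassificationPanel.from_records(pd.DataFrame(rows_b), category_labels=labels)
    return pa, pb


@pytest.fixture(scope="session")
def default_synthetic():
    """One default-configuration synthetic panel, shared across tests."""
    return rp.generate_panel(rp.PanelConfig(), seed=42)


@pytest.fixture()
def small_config():
    """A reduced design for fast pipeline tests: 3 categories, 9 raters."""
    design = (
        rp.CategorySpec("easy", 8, 1, "winter", "forest", frozenset({"face", "legs"}), "day"),
        rp.CategorySpec("hard", 8, 1, "summer", "forest", frozenset({"face"}), "day"),
        rp.CategorySpec("mid", 8, 2, "winter", "grassland", frozenset({"face", "legs", "tail"}), "day"),
    )
    return rp.PanelConfig(n_raters=9, category_design=design, repeat_trial=True)
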