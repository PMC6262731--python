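"""Synthetic classification panels with known generative structure.

The study's raw expert-response matrix is not released, so every pipeline
stage is exercised against synthetic panels that emulate its design: 27
raters drawn from three regions, 15 image categories across five trials
(259 images — one category holds 19 images rather than 20 because a
mistakenly repeated stimulus was discarded), three response options
(two similar species plus "unknown"), category-dependent difficulty, and
an optional repeated pass of the first trial's images for test-retest
consistency.

Response model.  Each image has a true species (drawn by prevalence, with
northern-region images forced to lynx, where bobcats are absent) and a
difficulty d_i = category penalty + N(0, image_difficulty_sd).  Each rater
has a skill offset s_r ~ N(0, rater_skill_sd).  A rater's response is a
three-outcome draw:

    p_unknown = expit(logit(u0) + slope * d_i)            (0 if u0 = 0)
    p_correct = (1 - p_unknown) * expit(logit(a0) + s_r - d_i)
    p_wrong   = (1 - p_unknown) * (1 - expit(...))

with a0 the base accuracy on a difficulty-0 image and u0 the baseline
"unknown" propensity.  Difficulty enters both the correct-vs-wrong log-odds
and the abstention probability — the simplest model that reproduces the
qualitative findings (harder categories get more "unknown" responses and
lower agreement).

The hidden truth table (true species, difficulties, rater skills) is
returned separately from the panel and is never written into any panel
output file, so downstream pipeline stages cannot accidentally see it.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core_data import (
    DEFAULT_CATEGORIES,
    ClassificationPanel,
    PanelValidationError,
    format_features,
    parse_features,
)

SPECIES = ("bobcat", "lynx")
UNKNOWN = "unknown"


@dataclasses.dataclass(frozen=True)
class CategorySpec:
    """One image category: its covariates and image count."""

    name: str
    n_images: int
    trial: int
    season: str
    habitat: str
    visible_features: frozenset[str]
    time_of_day: str
    region: str = "other"
    location_provided: bool = False


def _cat(name, n, trial, season, habitat, features, time, region="other", loc=False):
    return CategorySpec(
        name, n, trial, season, habitat, frozenset(features), time, region, loc
    )


#: The study design: 15 categories over five trials, 259 images.  Categories
#: vary exactly one covariate per trial; "partial" features means two of
#: face/legs/tail (represented here as face+legs).
DEFAULT_CATEGORY_DESIGN: tuple[CategorySpec, ...] = (
    _cat("summer", 20, 1, "summer", "forest", ("face", "legs"), "day"),
    _cat("winter", 20, 1, "winter", "forest", ("face", "legs"), "day"),
    _cat("forest", 20, 2, "summer", "forest", ("face", "legs"), "day"),
    _cat("grassland", 20, 2, "summer", "grassland", ("face", "legs"), "day"),
    _cat("developed", 20, 2, "summer", "developed", ("face", "legs"), "day"),
    _cat("full_body", 20, 3, "winter", "forest", ("face", "legs", "tail"), "day"),
    _cat("face_only", 20, 3, "winter", "forest", ("face",), "day"),
    _cat("face_and_legs", 20, 3, "winter", "forest", ("face", "legs"), "day"),
    _cat("legs_and_tail", 19, 3, "winter", "forest", ("legs", "tail"), "day"),
    _cat("day", 20, 4, "winter", "forest", ("face", "legs"), "day"),
    _cat("night", 20, 4, "winter", "forest", ("face", "legs"), "night"),
    _cat("north_loc", 20, 5, "summer", "forest", ("face", "legs"), "day", "northern_BC", True),
    _cat("south_loc", 20, 5, "summer", "forest", ("face", "legs"), "day", "southern_BC", True),
    _cat("north_noloc", 20, 5, "summer", "forest", ("face", "legs"), "day", "northern_BC", False),
    _cat("south_noloc", 20, 5, "summer", "forest", ("face", "legs"), "day", "southern_BC", False),
)

#: Additive log-odds difficulty penalties per covariate level.  Signs and
#: orderings follow the study's qualitative findings: summer pelage and
#: forest backgrounds are harder, face-and-legs views easiest, knowing the
#: image location helps.
DEFAULT_DIFFICULTY_EFFECTS: Mapping[str, float] = {
    "summer": 1.15,
    "winter": 0.0,
    "forest": 0.4,
    "grassland": 0.0,
    "developed": -0.1,
    "full_body": 0.2,
    "face_only": 0.9,
    "face_legs": 0.0,
    "legs_tail": 0.9,
    "day": 0.15,
    "night": 0.0,
    "location_provided": -0.5,
}

#: Rater regions in the study's 9:8:10 split.
DEFAULT_RATER_REGIONS: Mapping[str, int] = {
    "northern_BC_yukon": 9,
    "southern_BC": 8,
    "northwestern_US": 10,
}


@dataclasses.dataclass
class PanelConfig:
    """Generative parameters for synthetic classification panels.

    Defaults emulate the study conditions: 27 raters, the 15-category /
    259-image design, roughly one "unknown" response in ten, and moderate
    overall agreement.  ``species_prevalence`` is the probability an
    image's true species is bobcat (default the study's 92/259 image mix);
    northern-region images are always lynx.
    """

    n_raters: int = 27
    category_design: Sequence[CategorySpec] = DEFAULT_CATEGORY_DESIGN
    base_accuracy: float = 0.998
    difficulty_effects: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_DIFFICULTY_EFFECTS)
    )
    unknown_propensity: float = 0.055
    unknown_difficulty_slope: float = 0.5
    image_difficulty_sd: float = 0.8
    rater_skill_sd: float = 0.4
    species_prevalence: float = 92 / 259
    repeat_trial: bool = False
    consistency: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        if not 0.5 <= self.base_accuracy <= 1.0:
            # 0.5 is the coin-flip floor: raters at chance between the species
            raise PanelValidationError(
                f"base_accuracy must be in [0.5, 1], got {self.base_accuracy}"
            )
        if not 0.0 <= self.unknown_propensity < 1.0:
            raise PanelValidationError(
                f"unknown_propensity must be in [0, 1), got {self.unknown_propensity}"
            )
        if not 0.0 <= self.species_prevalence <= 1.0:
            raise PanelValidationError("species_prevalence must be in [0, 1]")
        if self.rater_skill_sd < 0 or self.image_difficulty_sd < 0:
            raise PanelValidationError("spread parameters must be non-negative")
        if not 0.0 <= self.consistency <= 1.0:
            raise PanelValidationError("consistency must be in [0, 1]")
        if self.n_raters < 2:
            raise PanelValidationError("need at least 2 raters")
        if not self.category_design:
            raise PanelValidationError("empty category design")


@dataclasses.dataclass
class SyntheticTruth:
    """Hidden generative state: per-image truth and per-rater skills.

    Kept separate from the panel so that analysis stages never see it.
    """

    images: pd.DataFrame  # index image_id: true_species, difficulty
    rater_skills: pd.Series  # index rater_id


def features_token(features) -> str:
    """Canonical token for a visible-features set (difficulty-effect key)."""
    fs = parse_features(features)
    named = {
        frozenset({"face", "legs", "tail"}): "full_body",
        frozenset({"face"}): "face_only",
        frozenset({"face", "legs"}): "face_legs",
        frozenset({"legs", "tail"}): "legs_tail",
    }
    return named.get(fs, "_".join(sorted(fs)) or "none")


def category_difficulty(spec: CategorySpec, effects: Mapping[str, float]) -> float:
    """Sum of covariate difficulty penalties for one category."""
    d = 0.0
    d += effects.get(spec.season, 0.0)
    d += effects.get(spec.habitat, 0.0)
    d += effects.get(features_token(spec.visible_features), 0.0)
    d += effects.get(spec.time_of_day, 0.0)
    if spec.location_provided:
        d += effects.get("location_provided", 0.0)
    return d


def response_probabilities(
    config: PanelConfig, difficulty: np.ndarray, skill: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(p_correct, p_wrong, p_unknown) arrays, broadcasting images x raters."""
    d = np.asarray(difficulty, dtype=float)[..., None]
    s = np.asarray(skill, dtype=float)[None, ...]
    with np.errstate(divide="ignore", over="ignore"):
        if config.unknown_propensity == 0.0:
            p_unknown = np.zeros(np.broadcast_shapes(d.shape, s.shape))
        else:
            p_unknown = expit(
                logit(config.unknown_propensity)
                + config.unknown_difficulty_slope * d
            ) * np.ones_like(s)
        p_corr_species = expit(logit(config.base_accuracy) + s - d)
    p_correct = (1.0 - p_unknown) * p_corr_species
    p_wrong = (1.0 - p_unknown) * (1.0 - p_corr_species)
    return p_correct, p_wrong, p_unknown


def _rater_ids(n_raters: int) -> list[str]:
    return [f"r{j:02d}" for j in range(1, n_raters + 1)]


def _rater_regions(n_raters: int) -> list[str]:
    """Assign regions in the study's 9:8:10 proportions (largest remainder)."""
    total = sum(DEFAULT_RATER_REGIONS.values())
    quotas = {r: n_raters * c / total for r, c in DEFAULT_RATER_REGIONS.items()}
    counts = {r: int(q) for r, q in quotas.items()}
    short = n_raters - sum(counts.values())
    for r in sorted(quotas, key=lambda r: quotas[r] - counts[r], reverse=True)[:short]:
        counts[r] += 1
    out: list[str] = []
    for region, c in counts.items():
        out.extend([region] * c)
    return out


def _draw_responses(
    rng: np.random.Generator,
    true_idx: np.ndarray,
    p_correct: np.ndarray,
    p_wrong: np.ndarray,
) -> np.ndarray:
    """Response index array (images x raters): 0/1 species, 2 unknown."""
    u = rng.random(p_correct.shape)
    wrong_idx = 1 - true_idx  # two species
    resp = np.full(p_correct.shape, 2, dtype=np.int64)
    correct_mask = u < p_correct
    wrong_mask = (~correct_mask) & (u < p_correct + p_wrong)
    resp[correct_mask] = np.broadcast_to(true_idx[:, None], resp.shape)[correct_mask]
    resp[wrong_mask] = np.broadcast_to(wrong_idx[:, None], resp.shape)[wrong_mask]
    return resp


def generate_panel(
    config: PanelConfig, seed: int | np.random.Generator | None = None
) -> tuple[ClassificationPanel, SyntheticTruth]:
    """Generate a synthetic classification panel plus its hidden truth.

    Seed-deterministic; ``seed`` overrides ``config.seed`` when given.
    The returned panel carries image metadata and rater info; the truth
    table (true species, image difficulties, rater skills) is separate.
    """
    config.validate()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )

    meta_rows = []
    difficulties = []
    i = 0
    for spec in config.category_design:
        d_cat = category_difficulty(spec, config.difficulty_effects)
        for _ in range(spec.n_images):
            i += 1
            image_id = f"img{i:04d}"
            meta_rows.append(
                {
                    "image_id": image_id,
                    "trial": spec.trial,
                    "category": spec.name,
                    "season": spec.season,
                    "habitat": spec.habitat,
                    "visible_features": format_features(spec.visible_features),
                    "time_of_day": spec.time_of_day,
                    "region": spec.region,
                    "location_provided": spec.location_provided,
                }
            )
            difficulties.append(d_cat)
    metadata = pd.DataFrame(meta_rows)
    n_images = len(metadata)

    d = np.asarray(difficulties) + rng.normal(
        0.0, config.image_difficulty_sd, size=n_images
    )
    # true species: bobcat with prob species_prevalence, lynx otherwise;
    # northern-region images are always lynx (bobcats absent there)
    true_idx = (rng.random(n_images) >= config.species_prevalence).astype(np.int64)
    northern = (metadata["region"] == "northern_BC").to_numpy()
    true_idx[northern] = SPECIES.index("lynx")

    raters = _rater_ids(config.n_raters)
    skills = rng.normal(0.0, config.rater_skill_sd, size=config.n_raters)

    p_correct, p_wrong, _ = response_probabilities(config, d, skills)
    resp_idx = _draw_responses(rng, true_idx, p_correct, p_wrong)

    labels = SPECIES + (UNKNOWN,)
    records = pd.DataFrame(
        {
            "image_id": np.repeat(metadata["image_id"].to_numpy(), config.n_raters),
            "rater_id": np.tile(np.array(raters), n_images),
            "trial": np.repeat(metadata["trial"].to_numpy(), config.n_raters),
            "response": np.array(labels)[resp_idx.ravel()],
        }
    )
    rater_info = pd.DataFrame(
        {"rater_id": raters, "region": _rater_regions(config.n_raters)}
    )

    panel = ClassificationPanel.from_records(
        records,
        category_labels=DEFAULT_CATEGORIES,
        image_metadata=metadata,
        rater_info=rater_info,
    )
    truth = SyntheticTruth(
        images=pd.DataFrame(
            {
                "true_species": np.array(SPECIES)[true_idx],
                "difficulty": d,
            },
            index=pd.Index(metadata["image_id"], name="image_id"),
        ),
        rater_skills=pd.Series(skills, index=pd.Index(raters, name="rater_id")),
    )
    return panel, truth


def generate_repeat_pass(
    panel: ClassificationPanel,
    truth: SyntheticTruth,
    config: PanelConfig,
    consistency: float | None = None,
    seed: int | np.random.Generator | None = None,
    trial: int = 6,
) -> ClassificationPanel:
    """Second classification pass of the same images by the same raters.

    Each rater repeats their first-pass response with probability
    ``consistency`` and otherwise redraws from their response distribution
    for that image (so a redraw can coincide with the original answer).
    Emitted with the given trial number and image order permuted, mirroring
    a retest trial where the same images reappear randomly reordered.
    """
    if consistency is None:
        consistency = config.consistency
    if not 0.0 <= consistency <= 1.0:
        raise PanelValidationError("consistency must be in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed + 1 if seed is None else seed)
    )

    wide = panel.response_matrix()  # images x raters, panel order
    images = list(wide.index)
    raters = list(wide.columns)
    labels = SPECIES + (UNKNOWN,)
    lab_idx = {c: j for j, c in enumerate(labels)}
    first = np.vectorize(lab_idx.get)(wide.to_numpy())

    d = truth.images.loc[images, "difficulty"].to_numpy()
    skills = truth.rater_skills.loc[raters].to_numpy()
    true_idx = np.array(
        [SPECIES.index(s) for s in truth.images.loc[images, "true_species"]]
    )
    p_correct, p_wrong, _ = response_probabilities(config, d, skills)
    redraw = _draw_responses(rng, true_idx, p_correct, p_wrong)
    keep = rng.random(first.shape) < consistency
    second = np.where(keep, first, redraw)

    order = rng.permutation(len(images))
    rows = []
    for i in order:
        for j, rater in enumerate(raters):
            rows.append(
                {
                    "image_id": images[i],
                    "rater_id": rater,
                    "trial": trial,
                    "response": labels[second[i, j]],
                }
            )
    meta = (
        panel.image_metadata.reset_index() if panel.image_metadata is not None else None
    )
    rinfo = panel.rater_info.reset_index() if panel.rater_info is not None else None
    return ClassificationPanel.from_records(
        pd.DataFrame(rows),
        category_labels=panel.category_labels,
        image_metadata=meta,
        rater_info=rinfo,
    )


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write the truth table (image_id, true_species only) to CSV.

    Difficulties and rater skills are generator internals and stay out of
    the file, as does everything else that could leak into panel outputs.
    """
    truth.images[["true_species"]].reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reference panels for exact limiting cases


def unanimous_panel(
    n_raters: int = 27,
    n_images: int = 40,
    category_labels: Sequence[str] = DEFAULT_CATEGORIES,
) -> ClassificationPanel:
    """Panel where every image is unanimous, alternating between two labels.

    The perfect-agreement limit: Fleiss' kappa is exactly 1 as long as at
    least two categories are used across images.
    """
    rows = []
    for i in range(n_images):
        label = category_labels[i % 2]
        for j in range(n_raters):
            rows.append(
                {
                    "image_id": f"img{i + 1:04d}",
                    "rater_id": f"r{j + 1:02d}",
                    "trial": 1,
                    "response": label,
                }
            )
    return ClassificationPanel.from_records(
        pd.DataFrame(rows), category_labels=category_labels
    )


def uniform_random_panel(
    n_raters: int = 27,
    n_images: int = 500,
    category_labels: Sequence[str] = DEFAULT_CATEGORIES,
    seed: int | np.random.Generator | None = 0,
) -> ClassificationPanel:
    """Panel of responses independent of the images, uniform over categories.

    The chance-agreement limit: Fleiss' kappa is ~0 within Monte-Carlo
    error.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(category_labels)
    resp = rng.integers(0, k, size=(n_images, n_raters))
    rows = {
        "image_id": np.repeat([f"img{i + 1:04d}" for i in range(n_images)], n_raters),
        "rater_id": np.tile([f"r{j + 1:02d}" for j in range(n_raters)], n_images),
        "trial": 1,
        "response": np.array(list(category_labels))[resp.ravel()],
    }
    return ClassificationPanel.from_records(
        pd.DataFrame(rows), category_labels=category_labels
    )


def expected_kappa(
    config: PanelConfig,
    n_design_reps: int = 40,
    seed: int | np.random.Generator | None = 12345,
) -> float:
    """Long-run Fleiss' kappa of a generator configuration, by large-N simulation.

    Replicates the category design ``n_design_reps`` times (so the image
    population proportions are those of the design) and computes kappa on
    the resulting panel.  With ``rater_skill_sd > 0`` the value is
    conditional on the simulated rater panel; use skill SD 0 when a single
    population value is needed (e.g. as a coverage target).
    """
    from .agreement import fleiss_kappa

    design = tuple(
        dataclasses.replace(spec, name=f"{spec.name}_rep{r}")
        for r in range(n_design_reps)
        for spec in config.category_design
    )
    big = dataclasses.replace(config, category_design=design)
    panel, _ = generate_panel(big, seed=seed)
    return fleiss_kappa(panel).kappa
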