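"""Agreement statistics for multi-rater categorical classification panels.

Implements chance-corrected agreement among a fixed panel of raters
(Fleiss' kappa) with percentile-bootstrap confidence intervals, the
per-image proportion-of-agreement statistic, majority/unanimity
tabulation, intra-rater (test-retest) consistency, and per-rater
majority-match rates.

Notation, for a complete panel of N images, n raters and k categories with
``n_ij`` raters assigning image i to category j:

    p_j   = (sum_i n_ij) / (N n)               category proportions
    P_i   = (sum_j n_ij^2 - n) / (n (n - 1))   per-image agreement
    P_bar = mean_i P_i                          observed agreement
    P_e   = sum_j p_j^2                         chance agreement
    kappa = (P_bar - P_e) / (1 - P_e)

kappa is bounded in [-1, 1]; 1 is perfect agreement, 0 agreement expected
by chance alone.  The category set k is fixed by the panel's declared
labels even when a label is never chosen in a sub-panel: the option set,
not the used set, defines chance agreement.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .core_data import (
    ClassificationPanel,
    EmptyPanelError,
    PanelValidationError,
    VoteCount,
)

MAJORITY_NONE = None  # sentinel: maximum vote count shared by >= 2 categories


class DegenerateAgreementError(ValueError):
    """Chance agreement is 1 (all classifications in one category)."""


@dataclasses.dataclass(frozen=True)
class KappaResult:
    """Fleiss' kappa point estimate with optional bootstrap CI.

    ``degenerate`` is True when chance agreement P_e = 1 (every
    classification in a single category), in which case ``kappa`` is NaN —
    a flagged undefined value, never a silent number.
    """

    kappa: float
    n_images: int
    n_raters: int
    p_bar: float
    p_bar_e: float
    category_proportions: dict[str, float]
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float | None = None
    n_boot: int | None = None
    n_degenerate_replicates: int = 0
    degenerate: bool = False


@dataclasses.dataclass(frozen=True)
class MajorityResult:
    """Majority classification of one image.

    ``majority`` is None iff the maximum vote count is shared by two or
    more categories (a tied image has no majority classification).
    """

    image_id: str | None
    majority: str | None
    margin: int
    unanimous: bool


@dataclasses.dataclass(frozen=True)
class ConsistencyResult:
    """One rater's agreement with themselves across two passes.

    ``kappa_self`` is Cohen's kappa over the k x k confusion table of the
    rater's two passes; ``kappa_self_pooled`` is the two-rating Fleiss'
    kappa, which pools the marginals of the two passes and therefore can
    differ from Cohen's when the passes have different marginals.  Both are
    NaN when the rater used a single category identically in both passes
    (chance agreement 1: undefined, not perfect).
    """

    rater_id: str
    n_changed: int
    n_images: int
    kappa_self: float
    kappa_self_pooled: float


@dataclasses.dataclass(frozen=True)
class ConsistencyReport:
    per_rater: tuple[ConsistencyResult, ...]
    mean_kappa: float
    sd_kappa: float
    min_kappa: float
    max_kappa: float
    mean_changed: float
    sd_changed: float
    min_changed: int
    max_changed: int
    #: Panel-level Fleiss' kappa of each pass; None for single-rater panels.
    fleiss_first: KappaResult | None
    fleiss_second: KappaResult | None


@dataclasses.dataclass(frozen=True)
class MatchRateReport:
    """Per-rater fraction of images matching the full-panel majority."""

    per_rater: dict[str, float]
    mean: float
    median: float
    min: float
    max: float
    n_images_used: int
    n_excluded_no_majority: int


# ---------------------------------------------------------------------------
# Fleiss' kappa


def _kappa_components(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (P_bar, P_e, p_j) for stacked count tables.

    ``counts`` has shape (..., N, k) with constant row sums n.
    """
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.sum(axis=-1)
    n0 = n[..., 0] if counts.ndim > 1 else n
    p_i = (np.square(counts).sum(axis=-1) - n) / (n * (n - 1.0))
    p_bar = p_i.mean(axis=-1)
    n_images = counts.shape[-2]
    p_j = counts.sum(axis=-2) / (n_images * n0[..., None])
    p_e = np.square(p_j).sum(axis=-1)
    return p_bar, p_e, p_j


def fleiss_kappa(panel: ClassificationPanel) -> KappaResult:
    """Fleiss' kappa point estimate for a complete panel.

    Requires n >= 2 raters and N >= 1 images, each image classified by all
    raters.  When chance agreement equals 1 the result is flagged
    ``degenerate`` with ``kappa`` NaN.
    """
    panel.require_complete("fleiss_kappa")
    if panel.n_raters < 2:
        raise PanelValidationError("Fleiss' kappa requires at least 2 raters")
    if panel.n_images < 1:
        raise EmptyPanelError("Fleiss' kappa requires at least 1 image")

    p_bar, p_e, p_j = _kappa_components(panel.counts)
    p_bar, p_e = float(p_bar), float(p_e)
    props = dict(zip(panel.category_labels, map(float, np.atleast_1d(p_j))))
    if p_e >= 1.0 - 1e-15:
        return KappaResult(
            kappa=float("nan"),
            n_images=panel.n_images,
            n_raters=panel.n_raters,
            p_bar=p_bar,
            p_bar_e=p_e,
            category_proportions=props,
            degenerate=True,
        )
    kappa = (p_bar - p_e) / (1.0 - p_e)
    return KappaResult(
        kappa=float(kappa),
        n_images=panel.n_images,
        n_raters=panel.n_raters,
        p_bar=p_bar,
        p_bar_e=p_e,
        category_proportions=props,
    )


def bootstrap_kappa_ci(
    panel: ClassificationPanel,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> KappaResult:
    """Fleiss' kappa with a percentile bootstrap confidence interval.

    Images (the study's sampling unit) are resampled with replacement;
    the rater set stays fixed.  Replicates whose resample is degenerate
    (chance agreement 1) are dropped and counted; if more than half the
    replicates are degenerate the panel is too uniform to bootstrap and an
    error is raised.  Deterministic for a fixed integer seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    point = fleiss_kappa(panel)
    if point.degenerate:
        raise DegenerateAgreementError(
            "kappa undefined on the full panel (all classifications in one "
            "category); bootstrap CI not meaningful"
        )
    rng = np.random.default_rng(seed)
    N = panel.n_images
    idx = rng.integers(0, N, size=(n_boot, N))
    boot_counts = panel.counts[idx]  # (n_boot, N, k)
    p_bar, p_e, _ = _kappa_components(boot_counts)
    ok = p_e < 1.0 - 1e-15
    n_degenerate = int(n_boot - ok.sum())
    if n_degenerate > n_boot / 2:
        raise DegenerateAgreementError(
            f"{n_degenerate}/{n_boot} bootstrap replicates were degenerate; "
            "use a larger or more varied panel"
        )
    kappas = (p_bar[ok] - p_e[ok]) / (1.0 - p_e[ok])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(kappas, [alpha, 1.0 - alpha])
    return dataclasses.replace(
        point,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=level,
        n_boot=n_boot,
        n_degenerate_replicates=n_degenerate,
    )


# ---------------------------------------------------------------------------
# Per-image statistics


def proportion_of_agreement(votes: VoteCount) -> float:
    """Per-image proportion of agreement among the n raters.

    For counts ``(c_1, ..., c_k)`` summing to n, returns
    ``(sum_j c_j^2 - n) / (n (n - 1))`` — the fraction of rater pairs in
    agreement.  With 3 categories and n = 27 the statistic ranges from
    0.3077 (perfect three-way disagreement, a 9/9/9 split) to 1.00
    (unanimity).
    """
    n = votes.n
    if n < 2:
        raise PanelValidationError("proportion of agreement requires n >= 2 raters")
    return (sum(c * c for c in votes.counts) - n) / (n * (n - 1))


def majority_classification(votes: VoteCount, image_id: str | None = None) -> MajorityResult:
    """Majority classification: unique argmax category, or None on ties.

    ``margin`` is votes for the majority minus the runner-up; a unanimous
    image has margin n.  Tied images return ``majority=None`` with margin 0
    — ties are first-class and never broken randomly or alphabetically.
    """
    counts = votes.counts
    order = sorted(range(len(counts)), key=lambda j: counts[j], reverse=True)
    top, runner = counts[order[0]], counts[order[1]]
    if top == runner:
        return MajorityResult(image_id, MAJORITY_NONE, 0, False)
    return MajorityResult(
        image_id,
        votes.labels[order[0]],
        top - runner,
        unanimous=(top == votes.n),
    )


@dataclasses.dataclass(frozen=True)
class AgreementTable:
    """Per-image and panel-level agreement tabulation.

    ``per_image`` has one row per image: vote counts per category,
    majority, margin, unanimity flag and proportion of agreement.
    ``majority_size_histogram`` maps (number of raters voting with the
    majority) -> image count, the input to the majority-size distribution
    plot; tied images are binned at their maximum vote count.
    """

    per_image: pd.DataFrame
    n_images: int
    n_raters: int
    n_unanimous: int
    n_any_unknown: int
    n_both_species: int
    n_majority_unknown: int
    n_majority_none: int
    mean_agreement: float
    sd_agreement: float
    majority_size_histogram: dict[int, int]


def tabulate_agreement(
    panel: ClassificationPanel, unknown_label: str = "unknown"
) -> AgreementTable:
    """Tabulate per-image votes, majorities and agreement for a panel.

    Panel-level counts follow the headline summary conventions: images with
    at least one "unknown" response, unanimously classified images, images
    receiving votes for both species (i.e. at least two distinct
    non-unknown categories), and images whose majority is "unknown".
    """
    panel.require_complete("tabulate_agreement")
    labels = panel.category_labels
    species = [c for c in labels if c != unknown_label]
    rows = []
    hist: dict[int, int] = {}
    for image_id, votes in panel.iter_vote_counts():
        maj = majority_classification(votes, image_id)
        poa = proportion_of_agreement(votes)
        top = max(votes.counts)
        hist[top] = hist.get(top, 0) + 1
        row = {"image_id": image_id}
        row.update({f"n_{c}": v for c, v in votes.as_dict().items()})
        row.update(
            majority=maj.majority,
            margin=maj.margin,
            unanimous=maj.unanimous,
            proportion_agreement=poa,
        )
        rows.append(row)
    table = pd.DataFrame(rows)

    vd = {c: table[f"n_{c}"] for c in labels}
    any_unknown = (
        int((vd[unknown_label] > 0).sum()) if unknown_label in labels else 0
    )
    both_species = int(
        (sum((vd[c] > 0).astype(int) for c in species) >= 2).sum()
    )
    return AgreementTable(
        per_image=table,
        n_images=panel.n_images,
        n_raters=panel.n_raters,
        n_unanimous=int(table["unanimous"].sum()),
        n_any_unknown=any_unknown,
        n_both_species=both_species,
        n_majority_unknown=int((table["majority"] == unknown_label).sum()),
        n_majority_none=int(table["majority"].isna().sum()),
        mean_agreement=float(table["proportion_agreement"].mean()),
        sd_agreement=float(table["proportion_agreement"].std(ddof=1))
        if len(table) > 1
        else 0.0,
        majority_size_histogram=dict(sorted(hist.items())),
    )


# ---------------------------------------------------------------------------
# Intra-rater consistency


def cohen_kappa(
    first: "pd.Series | np.ndarray",
    second: "pd.Series | np.ndarray",
    labels: tuple[str, ...],
) -> float:
    """Cohen's kappa between two ratings of the same items, fixed label set.

    Returns NaN when chance agreement is 1 (both ratings constant on the
    same single category): agreement is then undefined, not perfect.
    """
    first = np.asarray(first)
    second = np.asarray(second)
    if first.shape != second.shape:
        raise PanelValidationError("ratings must have equal length")
    n = len(first)
    k = len(labels)
    idx = {c: j for j, c in enumerate(labels)}
    table = np.zeros((k, k))
    for a, b in zip(first, second):
        table[idx[a], idx[b]] += 1
    po = np.trace(table) / n
    pe = float(table.sum(axis=1) @ table.sum(axis=0)) / (n * n)
    if pe >= 1.0 - 1e-15:
        return float("nan")
    return float((po - pe) / (1.0 - pe))


def _two_pass_fleiss(
    first: np.ndarray, second: np.ndarray, labels: tuple[str, ...]
) -> float:
    """Two-rating Fleiss' kappa (marginals pooled across the two passes)."""
    idx = {c: j for j, c in enumerate(labels)}
    counts = np.zeros((len(first), len(labels)), dtype=np.int64)
    for i, (a, b) in enumerate(zip(first, second)):
        counts[i, idx[a]] += 1
        counts[i, idx[b]] += 1
    p_bar, p_e, _ = _kappa_components(counts)
    if float(p_e) >= 1.0 - 1e-15:
        return float("nan")
    return float((p_bar - p_e) / (1.0 - p_e))


def rater_consistency(
    panel_first: ClassificationPanel, panel_second: ClassificationPanel
) -> ConsistencyReport:
    """Test-retest consistency of each rater across two classification passes.

    Both panels must cover identical image and rater sets (matched by id).
    Per rater, reports the count of images whose classification changed and
    Cohen's kappa over the k x k confusion table of pass 1 vs pass 2
    (plus the pooled-marginal two-rating Fleiss variant).  Also returns the
    two panel-level Fleiss' kappas, pass 1 vs pass 2.
    """
    if set(panel_first.images) != set(panel_second.images):
        unmatched = sorted(
            set(panel_first.images) ^ set(panel_second.images)
        )
        raise PanelValidationError(f"image sets differ: {unmatched[:10]}")
    if set(panel_first.raters) != set(panel_second.raters):
        unmatched = sorted(set(panel_first.raters) ^ set(panel_second.raters))
        raise PanelValidationError(f"rater sets differ: {unmatched[:10]}")
    if panel_first.category_labels != panel_second.category_labels:
        raise PanelValidationError("category sets differ between passes")

    wide_a = panel_first.response_matrix()
    wide_b = panel_second.response_matrix().reindex(
        index=wide_a.index, columns=wide_a.columns
    )
    labels = panel_first.category_labels

    results = []
    for rater in panel_first.raters:
        a = wide_a[rater].to_numpy()
        b = wide_b[rater].to_numpy()
        n_changed = int((a != b).sum())
        results.append(
            ConsistencyResult(
                rater_id=rater,
                n_changed=n_changed,
                n_images=len(a),
                kappa_self=cohen_kappa(a, b, labels),
                kappa_self_pooled=_two_pass_fleiss(a, b, labels),
            )
        )

    kappas = np.array([r.kappa_self for r in results])
    changed = np.array([r.n_changed for r in results])
    defined = kappas[~np.isnan(kappas)]
    if len(defined) == 0:
        defined = np.array([np.nan])
    return ConsistencyReport(
        per_rater=tuple(results),
        mean_kappa=float(defined.mean()),
        sd_kappa=float(defined.std(ddof=1)) if len(defined) > 1 else 0.0,
        min_kappa=float(defined.min()),
        max_kappa=float(defined.max()),
        mean_changed=float(changed.mean()),
        sd_changed=float(changed.std(ddof=1)) if len(changed) > 1 else 0.0,
        min_changed=int(changed.min()),
        max_changed=int(changed.max()),
        fleiss_first=fleiss_kappa(panel_first) if panel_first.n_raters >= 2 else None,
        fleiss_second=fleiss_kappa(panel_second) if panel_second.n_raters >= 2 else None,
    )


# ---------------------------------------------------------------------------
# Single-rater majority match


def single_rater_match_rate(panel: ClassificationPanel) -> MatchRateReport:
    """Fraction of images where each single rater matches the panel majority.

    Images with no defined majority (tied maximum) are excluded from both
    numerator and denominator.  Raises if every image lacks a majority.
    """
    panel.require_complete("single_rater_match_rate")
    if panel.records is None:
        raise PanelValidationError("single_rater_match_rate requires long records")

    majorities = {
        image_id: majority_classification(votes, image_id).majority
        for image_id, votes in panel.iter_vote_counts()
    }
    used = [img for img, m in majorities.items() if m is not MAJORITY_NONE]
    n_excluded = panel.n_images - len(used)
    if not used:
        raise EmptyPanelError("no image has a defined majority classification")

    wide = panel.response_matrix().loc[used]
    maj = pd.Series({img: majorities[img] for img in used})
    per_rater = {
        rater: float((wide[rater] == maj).mean()) for rater in panel.raters
    }
    rates = np.array(list(per_rater.values()))
    return MatchRateReport(
        per_rater=per_rater,
        mean=float(rates.mean()),
        median=float(np.median(rates)),
        min=float(rates.min()),
        max=float(rates.max()),
        n_images_used=len(used),
        n_excluded_no_majority=n_excluded,
    )
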