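"""Probability that a rater subset's majority matches the full-panel majority.

For an image classified with votes ``(n_1, ..., n_k)`` by n raters, a
random subset of size s drawn without replacement has category counts
distributed multivariate-hypergeometrically.  The match probability is the
total probability of all count compositions whose unique argmax equals the
full panel's majority category.  Subset ties count as non-matches (no
half-credit, no random tie-break): this single rule — centralized in
:func:`_composition_matches` and shared by the exact and Monte-Carlo paths —
is what makes the mean curve dip at even subset sizes, where split votes are
possible, relative to the neighboring odd sizes.

The exact path enumerates compositions with exact integer binomial
coefficients (no overflow at C(27, 13), no floating-point accumulation
error); Monte-Carlo is retained as an independent oracle only.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np

from .core_data import ClassificationPanel, EmptyPanelError, VoteCount
from .agreement import MAJORITY_NONE, majority_classification


class MajorityUndefinedError(ValueError):
    """The full panel has no unique majority for this image."""


@dataclasses.dataclass(frozen=True)
class SubsetCurve:
    """Mean subset-majority match probability per subset size.

    Means are taken over images with a defined full-panel majority;
    ``n_excluded_no_majority`` counts the images dropped for lacking one.
    Confidence bounds are percentile-bootstrap over images.
    """

    subset_sizes: np.ndarray
    mean_match_prob: np.ndarray
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    n_images_used: int
    n_excluded_no_majority: int
    ci_level: float | None = None

    def as_dict(self) -> dict[int, float]:
        return dict(zip(map(int, self.subset_sizes), map(float, self.mean_match_prob)))


def _composition_matches(composition: tuple[int, ...], majority_index: int) -> bool:
    """True iff the composition's argmax is unique and equals the majority.

    The single tie predicate shared by the exact and Monte-Carlo paths:
    a tied subset is a non-match.
    """
    top = max(composition)
    return (
        composition[majority_index] == top
        and sum(1 for c in composition if c == top) == 1
    )


def _majority_index(votes: VoteCount) -> int:
    maj = majority_classification(votes)
    if maj.majority is MAJORITY_NONE:
        raise MajorityUndefinedError(
            f"votes {votes.counts} have no unique majority; exclude such images"
        )
    return votes.labels.index(maj.majority)


def _check_size(votes: VoteCount, subset_size: int) -> None:
    if not 1 <= subset_size <= votes.n:
        raise ValueError(
            f"subset_size must be in [1, {votes.n}], got {subset_size}"
        )


@lru_cache(maxsize=200_000)
def _exact_match_probability(
    counts: tuple[int, ...], majority_index: int, subset_size: int
) -> Fraction:
    """Exact match probability by composition enumeration, exact arithmetic."""
    n = sum(counts)
    k = len(counts)
    numerator = 0

    def recurse(j: int, remaining: int, weight: int, composition: tuple[int, ...]) -> None:
        nonlocal numerator
        if j == k - 1:
            if remaining <= counts[j]:
                comp = composition + (remaining,)
                if _composition_matches(comp, majority_index):
                    numerator += weight * comb(counts[j], remaining)
            return
        # prune: remaining draws must fit in the remaining categories
        tail_capacity = sum(counts[j + 1 :])
        lo = max(0, remaining - tail_capacity)
        hi = min(counts[j], remaining)
        for c in range(lo, hi + 1):
            recurse(j + 1, remaining - c, weight * comb(counts[j], c), composition + (c,))

    recurse(0, subset_size, 1, ())
    return Fraction(numerator, comb(n, subset_size))


def exact_match_probability(votes: VoteCount, subset_size: int) -> float:
    """P(majority of a random size-s rater subset equals the panel majority).

    Sums, over all category-count compositions of the subset, the
    multivariate hypergeometric probability
    ``prod_j C(n_j, c_j) / C(n, s)`` restricted to compositions whose
    unique argmax is the full-panel majority category; tied compositions
    contribute zero.  Raises :class:`MajorityUndefinedError` when the full
    panel itself has no unique majority.
    """
    _check_size(votes, subset_size)
    maj_idx = _majority_index(votes)
    return float(_exact_match_probability(votes.counts, maj_idx, subset_size))


def monte_carlo_match_probability(
    votes: VoteCount,
    subset_size: int,
    n_draws: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo estimate of the subset-majority match probability.

    Draws subsets without replacement (multivariate hypergeometric counts)
    and applies the same unique-argmax / tie-is-non-match rule as the exact
    path.  Seed-deterministic; serves as an independent oracle for
    :func:`exact_match_probability`.
    """
    _check_size(votes, subset_size)
    maj_idx = _majority_index(votes)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(
        np.asarray(votes.counts), subset_size, size=n_draws
    )
    top = draws.max(axis=1)
    is_match = (draws[:, maj_idx] == top) & (
        (draws == top[:, None]).sum(axis=1) == 1
    )
    return float(is_match.mean())


def per_image_match_probabilities(
    panel: ClassificationPanel,
) -> tuple[np.ndarray, list[str], int]:
    """Exact match-probability matrix for all images with a defined majority.

    Returns ``(probs, image_ids, n_excluded)`` where ``probs[i, s-1]`` is
    the exact probability for image i at subset size s, s = 1..n_raters.
    """
    panel.require_complete("subset-majority analysis")
    n = panel.n_raters
    used_ids: list[str] = []
    rows: list[list[float]] = []
    n_excluded = 0
    for image_id, votes in panel.iter_vote_counts():
        maj = majority_classification(votes)
        if maj.majority is MAJORITY_NONE:
            n_excluded += 1
            continue
        maj_idx = votes.labels.index(maj.majority)
        rows.append(
            [
                float(_exact_match_probability(votes.counts, maj_idx, s))
                for s in range(1, n + 1)
            ]
        )
        used_ids.append(image_id)
    if not rows:
        raise EmptyPanelError("no image has a defined majority classification")
    return np.array(rows), used_ids, n_excluded


def mean_subset_curve(
    panel: ClassificationPanel,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> SubsetCurve:
    """Mean exact match probability per subset size, with bootstrap CIs.

    Per subset size, the mean of the exact per-image probabilities over
    images with a defined full-panel majority; percentile CIs by bootstrap
    over images.  At size n the probability is identically 1 — the subset
    is the whole panel.
    """
    probs, used_ids, n_excluded = per_image_match_probabilities(panel)
    n = panel.n_raters
    mean = probs.mean(axis=0)

    ci_low = ci_high = None
    if n_boot >= 1 and len(used_ids) > 1:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(used_ids), size=(n_boot, len(used_ids)))
        boot_means = probs[idx].mean(axis=1)  # (n_boot, n)
        alpha = (1.0 - level) / 2.0
        ci_low, ci_high = np.quantile(boot_means, [alpha, 1.0 - alpha], axis=0)

    return SubsetCurve(
        subset_sizes=np.arange(1, n + 1),
        mean_match_prob=mean,
        ci_low=ci_low,
        ci_high=ci_high,
        n_images_used=len(used_ids),
        n_excluded_no_majority=n_excluded,
        ci_level=level if ci_low is not None else None,
    )


def experts_needed(curve: SubsetCurve, threshold: float) -> int | None:
    """Smallest subset size meeting the threshold at that size and all larger.

    Returns the smallest s such that the mean match probability is at least
    ``threshold`` for every size >= s, or None if the threshold is never
    sustained.  The "and all larger sizes" clause matters because the curve
    is not monotone: even sizes dip below neighboring odd sizes.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    probs = curve.mean_match_prob
    answer: int | None = None
    # scan from the largest size, tracking the suffix minimum
    for s in range(len(probs), 0, -1):
        if probs[s - 1] >= threshold:
            answer = int(curve.subset_sizes[s - 1])
        else:
            break
    return answer
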