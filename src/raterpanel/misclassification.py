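"""Misclassification-rate bounds when ground truth is unavailable.

When the true species in each image cannot be independently verified, the
panel's misclassification rate can only be bounded.  If the majority
classification is correct for every image, the rate is the fraction of
species classifications (i.e. excluding "unknown" responses) that disagree
with the majority — a lower bound.  If the majority were instead wrong for
every image, species classifications *agreeing* with the majority would be
the errors — the default upper-bound rule here, always labeled in the
output, since rules for the majority-incorrect scenario are a modeling
choice rather than an observable.

"Unknown" responses are excluded from both numerator and denominator
throughout: an abstention is not a misclassification.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np

from .core_data import ClassificationPanel, EmptyPanelError, PanelValidationError
from .agreement import MAJORITY_NONE, majority_classification


@dataclasses.dataclass(frozen=True)
class MisclassificationBounds:
    """Bounds on the rate of incorrect species classifications.

    ``lower_bound_rate`` assumes the reference (by default the majority)
    classification is correct for every image; ``upper_bound_rate`` assumes
    it is incorrect for every image, under the rule named in ``rule_used``.
    Images with no defined reference are excluded and counted.
    """

    n_species_classifications: int
    n_disagree_reference: int
    lower_bound_rate: float
    upper_bound_rate: float
    rule_used: str
    n_images_used: int
    n_excluded_no_reference: int


@dataclasses.dataclass(frozen=True)
class ConstrainedSubsetRate:
    """Misclassification rate on images with externally known species."""

    rate: float
    n_wrong: int
    n_species_classifications: int
    n_images: int


def misclassification_bounds(
    panel: ClassificationPanel,
    reference: Mapping[str, str] | None = None,
    unknown_label: str = "unknown",
    upper_rule: str = "majority_incorrect_complement",
) -> MisclassificationBounds:
    """Bound the misclassification rate against a per-image reference.

    Parameters
    ----------
    reference : mapping image_id -> reference label; when None, the
        majority classification is used and images whose maximum vote is
        tied are excluded (and counted).
    upper_rule : rule for the majority-incorrect scenario.  The default,
        ``majority_incorrect_complement``, counts species classifications
        that *agree* with the reference as errors.  The rule name is always
        carried in the output.
    """
    panel.require_complete("misclassification_bounds")
    labels = panel.category_labels
    if unknown_label not in labels:
        raise PanelValidationError(
            f"unknown_label {unknown_label!r} not in category set {labels}"
        )
    if upper_rule != "majority_incorrect_complement":
        raise ValueError(f"unsupported upper-bound rule: {upper_rule!r}")

    unk_j = labels.index(unknown_label)
    n_species_total = 0
    n_disagree = 0
    n_used = 0
    n_excluded = 0
    for i, image_id in enumerate(panel.images):
        if reference is None:
            maj = majority_classification(panel.vote_count(image_id))
            ref = maj.majority
            if ref is MAJORITY_NONE:
                n_excluded += 1
                continue
        elif image_id in reference:
            ref = reference[image_id]
            if ref not in labels:
                raise PanelValidationError(
                    f"reference label {ref!r} for {image_id!r} not in {labels}"
                )
        else:
            n_excluded += 1
            continue
        n_used += 1
        row = panel.counts[i]
        species_votes = int(row.sum() - row[unk_j])
        agree = int(row[labels.index(ref)]) if ref != unknown_label else 0
        n_species_total += species_votes
        n_disagree += species_votes - agree

    if n_used == 0:
        raise EmptyPanelError("no image has a defined reference classification")
    if n_species_total == 0:
        raise EmptyPanelError(
            "no species classifications (all responses were 'unknown')"
        )

    return MisclassificationBounds(
        n_species_classifications=n_species_total,
        n_disagree_reference=n_disagree,
        lower_bound_rate=n_disagree / n_species_total,
        upper_bound_rate=(n_species_total - n_disagree) / n_species_total,
        rule_used=upper_rule,
        n_images_used=n_used,
        n_excluded_no_reference=n_excluded,
    )


def constrained_subset_rate(
    panel: ClassificationPanel,
    truth: Mapping[str, str],
    unknown_label: str = "unknown",
) -> ConstrainedSubsetRate:
    """Misclassification rate on images whose species is externally known.

    ``truth`` maps image ids to known species labels — e.g. images from
    locations where only one of two similar species occurs.  Returns the
    fraction of species classifications contradicting the supplied truth,
    with "unknown" responses excluded from numerator and denominator.
    """
    panel.require_complete("constrained_subset_rate")
    if not truth:
        raise PanelValidationError("empty truth mapping")
    unknown_ids = sorted(set(truth) - set(panel.images))
    if unknown_ids:
        raise PanelValidationError(
            f"truth references image ids not in the panel: {unknown_ids[:10]}"
        )
    labels = panel.category_labels
    unk_j = labels.index(unknown_label) if unknown_label in labels else None

    n_species_total = 0
    n_wrong = 0
    for image_id, true_label in truth.items():
        if true_label not in labels or true_label == unknown_label:
            raise PanelValidationError(
                f"truth label {true_label!r} for {image_id!r} is not a species label"
            )
        row = panel.counts[panel.images.index(image_id)]
        species_votes = int(row.sum() - (row[unk_j] if unk_j is not None else 0))
        n_species_total += species_votes
        n_wrong += species_votes - int(row[labels.index(true_label)])

    if n_species_total == 0:
        raise EmptyPanelError("no species classifications in the truth subset")
    return ConstrainedSubsetRate(
        rate=n_wrong / n_species_total,
        n_wrong=n_wrong,
        n_species_classifications=n_species_total,
        n_images=len(truth),
    )
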