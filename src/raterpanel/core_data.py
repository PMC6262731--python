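"""Domain types, validation, and readers/writers for classification panels.

The canonical on-disk form is long format: one row per individual
classification (``image_id, rater_id, trial, response``).  Count matrices
(images x categories) are always derived from long records, never authored,
so that per-rater analyses (consistency, single-rater match rates) remain
possible.

Responses are canonicalized by trimming whitespace and lowercasing before
validation: classification tables assembled from survey exports are messy,
and the normalization contract must be explicit rather than implicit.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable, Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

#: Default response options, in canonical order.
DEFAULT_CATEGORIES: tuple[str, ...] = ("bobcat", "lynx", "unknown")

#: Columns of the long-format classifications CSV.
CLASSIFICATION_COLUMNS = ("image_id", "rater_id", "trial", "response")

#: Columns of the image-metadata CSV.
METADATA_COLUMNS = (
    "image_id",
    "trial",
    "category",
    "season",
    "habitat",
    "visible_features",
    "time_of_day",
    "region",
    "location_provided",
)

#: Columns of the rater-info CSV.
RATER_COLUMNS = ("rater_id", "region")

RATER_REGIONS = ("northern_BC_yukon", "southern_BC", "northwestern_US")


class PanelValidationError(ValueError):
    """A classification table violates the panel data contract."""


class EmptyPanelError(PanelValidationError):
    """A filter or selection produced a panel with no images or raters."""


class IncompletePanelError(PanelValidationError):
    """An operation requiring a complete panel received a ragged one."""


def canonicalize_response(response: str) -> str:
    """Trim whitespace and lowercase a raw response string."""
    return str(response).strip().lower()


@dataclasses.dataclass(frozen=True)
class ClassificationRecord:
    """A single rater's classification of a single image in one trial."""

    image_id: str
    rater_id: str
    trial: int
    response: str


@dataclasses.dataclass(frozen=True)
class RaterInfo:
    """Rater identity and home region."""

    rater_id: str
    region: str

    def __post_init__(self) -> None:
        if self.region not in RATER_REGIONS:
            raise PanelValidationError(
                f"rater {self.rater_id!r}: region {self.region!r} is not one of "
                f"{RATER_REGIONS}"
            )


@dataclasses.dataclass(frozen=True)
class VoteCount:
    """Per-image tally of classifications over the panel's category set.

    The tally is the unit for the proportion-of-agreement statistic,
    majority classification, and subset-majority probabilities.
    """

    counts: tuple[int, ...]
    labels: tuple[str, ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.labels):
            raise PanelValidationError(
                f"{len(self.counts)} counts for {len(self.labels)} labels"
            )
        if any(int(c) != c or c < 0 for c in self.counts):
            raise PanelValidationError(f"counts must be non-negative integers: {self.counts}")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if self.n < 2:
            raise PanelValidationError(
                f"a vote count needs at least 2 raters, got n={self.n}"
            )

    @property
    def n(self) -> int:
        """Total number of raters who classified the image."""
        return sum(self.counts)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.labels, self.counts))


@dataclasses.dataclass
class ClassificationPanel:
    """A raters x images response matrix in long and count form.

    Attributes
    ----------
    category_labels : ordered category set; fixes k for all chance-corrected
        statistics even when a label is never chosen in a sub-panel.
    raters, images : deterministic (lexicographic) orderings of ids.
    counts : (N, k) non-negative integer array, ``counts[i, j]`` = number of
        raters classifying image i as category j.
    records : long-form records (one row per classification), retained for
        per-rater analyses.
    image_metadata : optional per-image covariates, indexed by image_id.
    rater_info : optional per-rater covariates, indexed by rater_id.
    """

    category_labels: tuple[str, ...]
    raters: tuple[str, ...]
    images: tuple[str, ...]
    counts: np.ndarray
    records: pd.DataFrame | None = None
    image_metadata: pd.DataFrame | None = None
    rater_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.images), len(self.category_labels)):
            raise PanelValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.images)} images x {len(self.category_labels)} categories"
            )
        if (self.counts < 0).any():
            raise PanelValidationError("negative counts")
        if self.records is not None:
            if len(self.records) != int(self.counts.sum()):
                raise PanelValidationError(
                    "long-form records inconsistent with counts: "
                    f"{len(self.records)} records vs counts total {int(self.counts.sum())}"
                )

    # -- basic structure -------------------------------------------------

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    @property
    def n_categories(self) -> int:
        return len(self.category_labels)

    def is_complete(self) -> bool:
        """True when every image was classified by every rater exactly once."""
        return bool((self.counts.sum(axis=1) == self.n_raters).all())

    def require_complete(self, operation: str = "this operation") -> None:
        if not self.is_complete():
            ragged = [
                img
                for img, total in zip(self.images, self.counts.sum(axis=1))
                if total != self.n_raters
            ]
            raise IncompletePanelError(
                f"{operation} requires a complete panel; images not classified by "
                f"all {self.n_raters} raters: {ragged[:10]}"
            )

    def vote_count(self, image_id: str) -> VoteCount:
        i = self.images.index(image_id)
        return VoteCount(tuple(self.counts[i]), self.category_labels)

    def iter_vote_counts(self) -> Iterable[tuple[str, VoteCount]]:
        for i, image_id in enumerate(self.images):
            yield image_id, VoteCount(tuple(self.counts[i]), self.category_labels)

    def response_matrix(self) -> pd.DataFrame:
        """Images x raters matrix of responses (requires long records)."""
        if self.records is None:
            raise PanelValidationError("panel has no long-form records")
        wide = self.records.pivot(index="image_id", columns="rater_id", values="response")
        return wide.reindex(index=list(self.images), columns=list(self.raters))

    # -- construction ----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        category_labels: Sequence[str] = DEFAULT_CATEGORIES,
        image_metadata: pd.DataFrame | None = None,
        rater_info: pd.DataFrame | None = None,
    ) -> "ClassificationPanel":
        """Build a validated panel from long-form records.

        Raises :class:`PanelValidationError` on duplicate
        (image_id, rater_id, trial) keys, responses outside the category
        set, or images lacking a metadata row when metadata is supplied.
        """
        records = records.copy()
        missing = set(CLASSIFICATION_COLUMNS) - set(records.columns)
        if missing:
            raise PanelValidationError(f"records missing columns: {sorted(missing)}")
        if len(records) == 0:
            raise EmptyPanelError("no classification records")

        category_labels = tuple(canonicalize_response(c) for c in category_labels)
        records["image_id"] = records["image_id"].astype(str)
        records["rater_id"] = records["rater_id"].astype(str)
        records["trial"] = records["trial"].astype(int)
        records["response"] = records["response"].map(canonicalize_response)

        dup_mask = records.duplicated(subset=["image_id", "rater_id", "trial"], keep=False)
        if dup_mask.any():
            dups = (
                records.loc[dup_mask, ["image_id", "rater_id", "trial"]]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise PanelValidationError(
                "duplicate (image_id, rater_id, trial) keys: "
                + ", ".join(map(str, list(dups)[:10]))
            )

        bad = sorted(set(records["response"]) - set(category_labels))
        if bad:
            raise PanelValidationError(
                f"responses outside category set {category_labels}: {bad}"
            )

        images = tuple(sorted(records["image_id"].unique()))
        raters = tuple(sorted(records["rater_id"].unique()))

        if image_metadata is not None:
            image_metadata = _normalize_metadata(image_metadata)
            missing_meta = sorted(set(images) - set(image_metadata.index))
            if missing_meta:
                raise PanelValidationError(
                    f"images without a metadata row: {missing_meta[:10]}"
                )
        if rater_info is not None:
            rater_info = _normalize_rater_info(rater_info)

        cat_idx = {c: j for j, c in enumerate(category_labels)}
        img_idx = {im: i for i, im in enumerate(images)}
        counts = np.zeros((len(images), len(category_labels)), dtype=np.int64)
        np.add.at(
            counts,
            (
                records["image_id"].map(img_idx).to_numpy(),
                records["response"].map(cat_idx).to_numpy(),
            ),
            1,
        )

        return cls(
            category_labels=category_labels,
            raters=raters,
            images=images,
            counts=counts,
            records=records.reset_index(drop=True),
            image_metadata=image_metadata,
            rater_info=rater_info,
        )


def _normalize_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    metadata = metadata.copy()
    if metadata.index.name != "image_id":
        if "image_id" not in metadata.columns:
            raise PanelValidationError("metadata table lacks an image_id column")
        metadata["image_id"] = metadata["image_id"].astype(str)
        dup = metadata["image_id"].duplicated()
        if dup.any():
            raise PanelValidationError(
                f"duplicate metadata rows for images: "
                f"{sorted(metadata.loc[dup, 'image_id'].unique())[:10]}"
            )
        metadata = metadata.set_index("image_id")
    if "visible_features" in metadata.columns:
        metadata["visible_features"] = metadata["visible_features"].map(parse_features)
    if "location_provided" in metadata.columns:
        metadata["location_provided"] = metadata["location_provided"].map(_parse_bool)
    return metadata


def _normalize_rater_info(rater_info: pd.DataFrame) -> pd.DataFrame:
    rater_info = rater_info.copy()
    if rater_info.index.name != "rater_id":
        if "rater_id" not in rater_info.columns:
            raise PanelValidationError("rater table lacks a rater_id column")
        rater_info["rater_id"] = rater_info["rater_id"].astype(str)
        rater_info = rater_info.set_index("rater_id")
    bad = sorted(set(rater_info["region"]) - set(RATER_REGIONS))
    if bad:
        raise PanelValidationError(f"unknown rater regions: {bad}")
    return rater_info


def parse_features(value) -> frozenset[str]:
    """Parse a plus-separated visible-features token (e.g. ``face+legs``)."""
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(str(v).strip().lower() for v in value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    return frozenset(
        tok.strip().lower() for tok in str(value).split("+") if tok.strip()
    )


def format_features(features: frozenset[str]) -> str:
    return "+".join(sorted(features))


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in {"true", "1", "yes", "y"}:
        return True
    if token in {"false", "0", "no", "n"}:
        return False
    raise PanelValidationError(f"cannot parse boolean: {value!r}")


# ---------------------------------------------------------------------------
# Readers / writers


def read_panel(
    classifications_path: str | Path,
    metadata_path: str | Path | None = None,
    raters_path: str | Path | None = None,
    category_labels: Sequence[str] = DEFAULT_CATEGORIES,
    exclude_images: Iterable[str] = (),
) -> ClassificationPanel:
    """Read and validate a classification panel from CSV files.

    Parameters
    ----------
    classifications_path : long-format CSV with columns
        ``image_id,rater_id,trial,response``.
    metadata_path : optional image-metadata CSV (see :data:`METADATA_COLUMNS`);
        every image referenced by a classification must have exactly one row.
    raters_path : optional rater CSV with columns ``rater_id,region``.
    category_labels : allowed response options; responses outside this set
        are rejected after canonical trimming/lowercasing.
    exclude_images : image ids dropped before validation — the supported
        mechanism for discarding, e.g., the second occurrence of a stimulus
        mistakenly shown twice.
    """
    records = pd.read_csv(classifications_path, dtype=str)
    missing = set(CLASSIFICATION_COLUMNS) - set(records.columns)
    if missing:
        raise PanelValidationError(
            f"{classifications_path}: missing columns {sorted(missing)}"
        )
    exclude = {str(e) for e in exclude_images}
    if exclude:
        records = records[~records["image_id"].astype(str).isin(exclude)]

    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, dtype=str)
        miss_meta = set(METADATA_COLUMNS) - set(metadata.columns)
        if miss_meta:
            raise PanelValidationError(
                f"{metadata_path}: missing columns {sorted(miss_meta)}"
            )
        metadata["trial"] = metadata["trial"].astype(int)
        if exclude:
            metadata = metadata[~metadata["image_id"].isin(exclude)]

    rater_info = None
    if raters_path is not None:
        rater_info = pd.read_csv(raters_path, dtype=str)
        miss_r = set(RATER_COLUMNS) - set(rater_info.columns)
        if miss_r:
            raise PanelValidationError(f"{raters_path}: missing columns {sorted(miss_r)}")

    return ClassificationPanel.from_records(
        records,
        category_labels=category_labels,
        image_metadata=metadata,
        rater_info=rater_info,
    )


def write_panel(
    panel: ClassificationPanel,
    classifications_path: str | Path,
    metadata_path: str | Path | None = None,
    raters_path: str | Path | None = None,
) -> None:
    """Write a panel back to long-format CSV (round-trips with read_panel)."""
    if panel.records is None:
        raise PanelValidationError("panel has no long-form records to write")
    panel.records.loc[:, list(CLASSIFICATION_COLUMNS)].to_csv(
        classifications_path, index=False
    )
    if metadata_path is not None and panel.image_metadata is not None:
        meta = panel.image_metadata.copy()
        if "visible_features" in meta.columns:
            meta["visible_features"] = meta["visible_features"].map(
                lambda f: format_features(parse_features(f))
            )
        meta.reset_index().to_csv(metadata_path, index=False)
    if raters_path is not None and panel.rater_info is not None:
        panel.rater_info.reset_index().to_csv(raters_path, index=False)


# ---------------------------------------------------------------------------
# Filtering


def filter_panel(
    panel: ClassificationPanel,
    image_selector: Callable[[pd.Series], bool] | Mapping[str, object] | None = None,
    rater_selector: Callable[[pd.Series], bool] | Mapping[str, object] | None = None,
) -> ClassificationPanel:
    """Restrict a panel to matching images and/or raters.

    Selectors are either callables receiving the metadata row for one image
    (or rater) as a pandas Series, or mappings of ``{field: required value}``
    tested for equality.  Counts are re-derived from the retained long-form
    records.  An empty selection raises :class:`EmptyPanelError` rather than
    returning a silent empty panel.
    """
    if panel.records is None:
        raise PanelValidationError("filter_panel requires long-form records")

    keep_images = set(panel.images)
    if image_selector is not None:
        if panel.image_metadata is None:
            raise PanelValidationError("image selector given but panel has no metadata")
        pred = _as_predicate(image_selector, panel.image_metadata.columns, "image")
        keep_images = {
            img
            for img in panel.images
            if pred(panel.image_metadata.loc[img])
        }

    keep_raters = set(panel.raters)
    if rater_selector is not None:
        if panel.rater_info is None:
            raise PanelValidationError("rater selector given but panel has no rater info")
        pred = _as_predicate(rater_selector, panel.rater_info.columns, "rater")
        keep_raters = {
            r for r in panel.raters if pred(panel.rater_info.loc[r])
        }

    sub = panel.records[
        panel.records["image_id"].isin(keep_images)
        & panel.records["rater_id"].isin(keep_raters)
    ]
    if len(sub) == 0:
        raise EmptyPanelError("selector matched no classifications")

    meta = (
        panel.image_metadata.loc[sorted(keep_images & set(panel.images))]
        if panel.image_metadata is not None
        else None
    )
    rinfo = (
        panel.rater_info.loc[sorted(keep_raters & set(panel.raters))]
        if panel.rater_info is not None
        else None
    )
    return ClassificationPanel.from_records(
        sub,
        category_labels=panel.category_labels,
        image_metadata=meta.reset_index() if meta is not None else None,
        rater_info=rinfo.reset_index() if rinfo is not None else None,
    )


def _as_predicate(selector, known_fields, kind: str) -> Callable[[pd.Series], bool]:
    if callable(selector):
        return selector
    unknown = set(selector) - set(known_fields)
    if unknown:
        raise PanelValidationError(
            f"{kind} selector references undeclared fields: {sorted(unknown)}"
        )

    def pred(row: pd.Series) -> bool:
        return all(row[field] == value for field, value in selector.items())

    return pred
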