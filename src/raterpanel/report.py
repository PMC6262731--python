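"""End-to-end analysis pipeline: panel in, report bundle out.

Wires a classification panel through every analysis stage — overall and
stratified kappa with bootstrap CIs, per-image agreement tables and
histograms, the subset-majority curve with experts-needed thresholds,
test-retest consistency when a repeat trial is present, and
misclassification bounds — and writes CSV tables, PNG figures, and a
machine-readable JSON manifest.

All randomness flows from one top-level seed: per-stage substreams are
derived deterministically with ``numpy.random.SeedSequence.spawn``, so a
rerun with the same seed reproduces every number byte-for-byte.  Rounding
(half-up, 2 decimals by default) is applied only at the presentation layer;
internal values keep full precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_data import (
    ClassificationPanel,
    EmptyPanelError,
    filter_panel,
    read_panel,
    write_panel,
)
from .agreement import (
    bootstrap_kappa_ci,
    fleiss_kappa,
    rater_consistency,
    single_rater_match_rate,
    tabulate_agreement,
)
from .misclassification import misclassification_bounds
from .subset_majority import experts_needed, mean_subset_curve
from .synthetic_data import (
    PanelConfig,
    generate_panel,
    generate_repeat_pass,
    write_truth,
)

logger = logging.getLogger("raterpanel")

#: Metadata fields available for stratified kappa comparisons.
STRATIFIABLE_FIELDS = (
    "category",
    "season",
    "habitat",
    "visible_features",
    "time_of_day",
    "region",
    "location_provided",
)


@dataclasses.dataclass
class RunConfig:
    """Settings for one pipeline run.

    Exactly one of (``classifications_path``, ``panel_config``) must be
    supplied: analyse an on-disk panel, or generate a synthetic one.
    """

    out_dir: str | Path
    classifications_path: str | Path | None = None
    metadata_path: str | Path | None = None
    raters_path: str | Path | None = None
    retest_path: str | Path | None = None
    panel_config: PanelConfig | None = None
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    stratify: tuple[str, ...] = ("category",)
    thresholds: tuple[float, ...] = (0.90, 0.95)
    rounding: int = 2
    make_plots: bool = True

    def validate(self) -> None:
        have_files = self.classifications_path is not None
        have_synth = self.panel_config is not None
        if have_files == have_synth:
            raise ValueError(
                "supply exactly one of classifications_path or panel_config"
            )
        bad = set(self.stratify) - set(STRATIFIABLE_FIELDS)
        if bad:
            raise ValueError(
                f"cannot stratify by undeclared fields {sorted(bad)}; "
                f"choose from {STRATIFIABLE_FIELDS}"
            )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Presentation-layer rounding: half-up, never banker's."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _kappa_row(name: str, panel: ClassificationPanel, n_boot, level, seed) -> dict:
    table = tabulate_agreement(panel)
    if n_boot >= 1 and panel.n_images > 1:
        try:
            res = bootstrap_kappa_ci(panel, n_boot=n_boot, level=level, seed=seed)
        except Exception:
            res = fleiss_kappa(panel)
    else:
        res = fleiss_kappa(panel)
    return {
        "stratum": name,
        "n_images": panel.n_images,
        "n_unanimous": table.n_unanimous,
        "kappa": res.kappa,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "degenerate": res.degenerate,
    }


def _stage(name: str):
    """Decorator tagging stage failures with the stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # re-raise with stage context
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

        return inner

    return wrap


def run_analysis(config: RunConfig) -> dict:
    """Run the full analysis pipeline and write the report bundle.

    Returns the manifest dictionary (also written to ``manifest.json``).
    Outputs: ``kappa_summary.csv`` (one row per stratum, mirroring a
    per-category agreement table with unanimous counts), ``per_image.csv``,
    ``subset_curve.csv``, ``consistency.csv`` when a retest pass exists,
    histogram and curve PNGs, and the JSON manifest with seeds, versions
    and every headline number at full precision plus rounded presentation
    values.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    (
        ss_generate,
        ss_retest,
        ss_boot_overall,
        ss_boot_strata,
        ss_curve,
    ) = ss.spawn(5)

    # -- load or generate the panel --------------------------------------
    retest_panel = None
    if config.panel_config is not None:
        panel, truth = generate_panel(
            config.panel_config, seed=np.random.default_rng(ss_generate)
        )
        write_panel(
            panel,
            out / "classifications.csv",
            out / "image_metadata.csv",
            out / "raters.csv",
        )
        write_truth(truth, out / "truth.csv")
        if config.panel_config.repeat_trial:
            first = filter_panel(panel, image_selector=lambda m: m["trial"] == 1)
            retest_panel = generate_repeat_pass(
                first,
                truth,
                config.panel_config,
                seed=np.random.default_rng(ss_retest),
            )
            write_panel(retest_panel, out / "classifications_retest.csv")
        logger.info("generated synthetic panel: %d images x %d raters",
                    panel.n_images, panel.n_raters)
    else:
        panel = read_panel(
            config.classifications_path,
            config.metadata_path,
            config.raters_path,
        )
        if config.retest_path is not None:
            retest_records = pd.read_csv(config.retest_path, dtype=str)
            retest_panel = ClassificationPanel.from_records(
                retest_records, category_labels=panel.category_labels
            )
        logger.info("read panel: %d images x %d raters", panel.n_images, panel.n_raters)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "ci_level": config.ci_level,
        "n_images": panel.n_images,
        "n_raters": panel.n_raters,
        "category_labels": list(panel.category_labels),
    }

    # -- (a) overall kappa ------------------------------------------------
    overall = _stage("overall_kappa")(bootstrap_kappa_ci)(
        panel,
        n_boot=config.n_boot,
        level=config.ci_level,
        seed=np.random.default_rng(ss_boot_overall),
    )
    manifest["overall"] = {
        "kappa": overall.kappa,
        "ci_low": overall.ci_low,
        "ci_high": overall.ci_high,
        "p_bar": overall.p_bar,
        "p_bar_e": overall.p_bar_e,
        "kappa_rounded": round_half_up(overall.kappa, config.rounding),
    }
    logger.info("overall kappa %.4f (%.4f-%.4f)", overall.kappa,
                overall.ci_low, overall.ci_high)

    # -- (b) stratified kappa table ---------------------------------------
    rows = [
        _kappa_row("overall", panel, config.n_boot, config.ci_level,
                   np.random.default_rng(ss_boot_strata.spawn(1)[0]))
    ]
    strata_streams = iter(ss_boot_strata.spawn(512))
    if panel.image_metadata is not None:
        for field in config.stratify:
            values = panel.image_metadata[field]
            for value in sorted(values.unique(), key=str):
                try:
                    sub = filter_panel(
                        panel, image_selector=lambda m, f=field, v=value: m[f] == v
                    )
                except EmptyPanelError:
                    continue
                rows.append(
                    _kappa_row(
                        f"{field}={value}", sub, config.n_boot, config.ci_level,
                        np.random.default_rng(next(strata_streams)),
                    )
                )
        # pooled covariate combinations (>= 10 images), location-blind images only
        meta = panel.image_metadata
        pool = meta[~meta["location_provided"].astype(bool)].copy()
        pool["features"] = pool["visible_features"].astype(str)
        for key, grp in pool.groupby(["season", "habitat", "features"], sort=True):
            if len(grp) < 10:
                continue
            ids = set(grp.index)
            sub = filter_panel(panel, image_selector=lambda m, s=ids: m.name in s)
            rows.append(
                _kappa_row(
                    "combination=" + "+".join(map(str, key)), sub,
                    config.n_boot, config.ci_level,
                    np.random.default_rng(next(strata_streams)),
                )
            )
    summary = pd.DataFrame(rows)
    for col in ("kappa", "ci_low", "ci_high"):
        summary[col + "_rounded"] = summary[col].map(
            lambda x: round_half_up(x, config.rounding) if pd.notna(x) else x
        )
    summary.to_csv(out / "kappa_summary.csv", index=False)
    manifest["n_strata"] = len(summary)

    # -- (c) per-image table + histograms ---------------------------------
    table = _stage("tabulate")(tabulate_agreement)(panel)
    table.per_image.to_csv(out / "per_image.csv", index=False)
    match = _stage("single_rater_match")(single_rater_match_rate)(panel)
    manifest["agreement"] = {
        "n_unanimous": table.n_unanimous,
        "n_any_unknown": table.n_any_unknown,
        "n_both_species": table.n_both_species,
        "n_majority_unknown": table.n_majority_unknown,
        "n_majority_none": table.n_majority_none,
        "mean_proportion_agreement": table.mean_agreement,
        "sd_proportion_agreement": table.sd_agreement,
        "single_rater_match_mean": match.mean,
        "single_rater_match_median": match.median,
        "single_rater_match_range": [match.min, match.max],
        "majority_size_histogram": {
            str(k): v for k, v in table.majority_size_histogram.items()
        },
    }

    # -- (d) subset-majority curve ----------------------------------------
    curve = _stage("subset_curve")(mean_subset_curve)(
        panel,
        n_boot=config.n_boot,
        level=config.ci_level,
        seed=np.random.default_rng(ss_curve),
    )
    curve_df = pd.DataFrame(
        {
            "subset_size": curve.subset_sizes,
            "mean_match_prob": curve.mean_match_prob,
            "ci_low": curve.ci_low,
            "ci_high": curve.ci_high,
            "n_images_used": curve.n_images_used,
        }
    )
    curve_df.to_csv(out / "subset_curve.csv", index=False)
    manifest["subset_curve"] = {
        "n_images_used": curve.n_images_used,
        "n_excluded_no_majority": curve.n_excluded_no_majority,
        "experts_needed": {
            str(t): experts_needed(curve, t) for t in config.thresholds
        },
    }
    for t in config.thresholds:
        logger.info("experts needed for >=%.2f: %s", t, experts_needed(curve, t))

    # -- (e) consistency ---------------------------------------------------
    if retest_panel is not None:
        first = panel
        if panel.image_metadata is not None and set(retest_panel.images) != set(
            panel.images
        ):
            first = filter_panel(
                panel, image_selector=lambda m: m.name in set(retest_panel.images)
            )
        report = _stage("consistency")(rater_consistency)(first, retest_panel)
        pd.DataFrame(
            [dataclasses.asdict(r) for r in report.per_rater]
        ).to_csv(out / "consistency.csv", index=False)
        manifest["consistency"] = {
            "mean_kappa_self": report.mean_kappa,
            "sd_kappa_self": report.sd_kappa,
            "range_kappa_self": [report.min_kappa, report.max_kappa],
            "mean_changed": report.mean_changed,
            "range_changed": [report.min_changed, report.max_changed],
            "fleiss_first_pass": report.fleiss_first.kappa,
            "fleiss_second_pass": report.fleiss_second.kappa,
        }

    # -- (f) misclassification bounds --------------------------------------
    bounds = _stage("misclassification")(misclassification_bounds)(panel)
    manifest["misclassification"] = {
        "lower_bound_rate": bounds.lower_bound_rate,
        "upper_bound_rate": bounds.upper_bound_rate,
        "rule_used": bounds.rule_used,
        "n_species_classifications": bounds.n_species_classifications,
        "n_disagree_reference": bounds.n_disagree_reference,
        "n_excluded_no_reference": bounds.n_excluded_no_reference,
    }

    # -- plots --------------------------------------------------------------
    if config.make_plots:
        _stage("plots")(_write_plots)(out, table, curve)

    # -- (g) manifest -------------------------------------------------------
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("report bundle written to %s", out)
    return manifest


def _write_plots(out: Path, table, curve) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    sizes = sorted(table.majority_size_histogram)
    axes[0].bar(sizes, [table.majority_size_histogram[s] for s in sizes], color="0.4")
    axes[0].set_xlabel("raters voting with the majority")
    axes[0].set_ylabel("number of images")
    axes[1].hist(
        table.per_image["proportion_agreement"], bins=np.linspace(0.3, 1.0, 15),
        color="0.4",
    )
    axes[1].set_xlabel("proportion of agreement")
    axes[1].set_ylabel("number of images")
    fig.tight_layout()
    fig.savefig(out / "agreement_distributions.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(
        curve.subset_sizes,
        curve.mean_match_prob,
        yerr=None
        if curve.ci_low is None
        else [
            curve.mean_match_prob - curve.ci_low,
            curve.ci_high - curve.mean_match_prob,
        ],
        fmt="o-",
        ms=3,
        color="0.2",
    )
    ax.set_xlabel("number of raters in subset")
    ax.set_ylabel("mean P(subset majority = panel majority)")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(out / "subset_curve.png", dpi=120)
    plt.close(fig)
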