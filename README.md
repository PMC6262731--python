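# raterpanel

Multi-rater agreement analysis for categorical classification panels —
built for the situation where a fixed panel of raters classifies the same
set of items into a small set of options and no ground truth exists.  The
motivating case is wildlife camera images of two similar sympatric felids
(bobcat *Lynx rufus* vs Canada lynx *Lynx canadensis*), where each of 27
experts labels each image "bobcat", "lynx", or "unknown" and the question
is how much the experts agree, how many of them you need to ask, and how
wrong a single classifier could plausibly be.

## What it computes

For a complete panel of *N* items, *n* raters and *k* categories with
*n<sub>ij</sub>* raters assigning item *i* to category *j*:

- **Fleiss' kappa** — chance-corrected panel agreement,
  *K* = (P̄ − P̄<sub>e</sub>) / (1 − P̄<sub>e</sub>), with
  P<sub>i</sub> = (Σ<sub>j</sub> n<sub>ij</sub>² − n) / (n(n−1)),
  P̄ = mean<sub>i</sub> P<sub>i</sub>,
  p<sub>j</sub> = Σ<sub>i</sub> n<sub>ij</sub> / (N·n), and
  P̄<sub>e</sub> = Σ<sub>j</sub> p<sub>j</sub>².
  95% percentile-bootstrap confidence intervals resample items with the
  rater panel fixed.
- **Per-image proportion of agreement** — the P<sub>i</sub> statistic on
  its own; with 3 options and n = 27 it spans 0.31 (a 9/9/9 three-way
  split) to 1.00 (unanimity).
- **Majority classification** — unique argmax of the votes; ties are
  first-class (`majority = None`), never broken arbitrarily.
- **Subset-majority curve** — for each subset size *s* = 1…n, the mean
  probability that the majority of a random size-*s* rater subset matches
  the full-panel majority, computed exactly by multivariate hypergeometric
  enumeration (subset ties count as non-matches, which is why the curve
  dips at even sizes).  `experts_needed` reads off the smallest panel that
  sustains a target probability.
- **Intra-rater consistency** — Cohen's kappa between each rater's two
  passes over the same items, plus the pooled-marginal two-rating variant.
- **Misclassification bounds** — assuming the majority is right for every
  image (lower bound) or wrong for every image (upper bound, rule always
  labeled), with "unknown" responses excluded from both sides.
- **Synthetic panels** — a generator with known structure (true species,
  category-level difficulty, rater skill, abstention propensity,
  test-retest consistency) emulating the 27-expert × 15-category study
  design, so every stage is testable end to end.

## Worked example

```python
import raterpanel as rp

panel, truth = rp.generate_panel(rp.PanelConfig(), seed=42)
study = rp.filter_panel(panel, image_selector=lambda m: not m["location_provided"])

res = rp.bootstrap_kappa_ci(study, n_boot=1000, seed=42)
print(f"kappa = {res.kappa:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), "
      f"N = {res.n_images} images, n = {res.n_raters} raters")

table = rp.tabulate_agreement(study)
print(f"unanimous images: {table.n_unanimous} ({table.n_unanimous/table.n_images:.0%})")
print(f"mean proportion of agreement: {table.mean_agreement:.2f} "
      f"(SD {table.sd_agreement:.2f})")

curve = rp.mean_subset_curve(study, n_boot=1000, seed=42)
for t in (0.90, 0.95):
    print(f"experts needed for mean match probability >= {t}: "
          f"{rp.experts_needed(curve, t)}")
```

prints

```
kappa = 0.65 (95% CI 0.61-0.68), N = 259 images, n = 27 raters
unanimous images: 31 (12%)
mean proportion of agreement: 0.82 (SD 0.12)
experts needed for mean match probability >= 0.9: 3
experts needed for mean match probability >= 0.95: 5
```

The synthetic panel lands in the moderate-agreement regime its defaults
target: the 27 simulated experts disagree enough that a single rater is
unreliable, yet a handful of raters almost always reproduces the
full-panel majority.  The kappa of 0.65 means agreement sits about
two-thirds of the way from chance (P̄<sub>e</sub> ≈ 0.5 here) to perfect.

The same pipeline runs from the command line on CSV panels
(`image_id,rater_id,trial,response` long format):

```bash
raterpanel simulate --seed 1 --out data/
raterpanel analyze --classifications data/classifications.csv \
    --metadata data/image_metadata.csv --raters data/raters.csv \
    --bootstrap 1000 --seed 1 --stratify category,season --out report/
```

which writes stratified kappa tables, the per-image table, the subset
curve (CSV + plot), misclassification bounds, and a JSON manifest of every
setting and result.

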