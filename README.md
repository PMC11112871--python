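# fruitmorph

Multi-view fruit morphometry for breeding programs and germplasm collections.

Describing fruit appearance — shape, size, weight, peel color — for many
accessions with only tens of fruit each is usually done visually by experts:
slow, hard to compare, and subjective. `fruitmorph` implements the image
analysis behind a five-camera imaging chamber that photographs each fruit
from four sides and the top against a uniform background, and turns those
images into quantitative, comparable per-fruit records and per-cultivar
summaries. A bundled synthetic renderer produces chamber-like image sets
with known ground truth, so the entire pipeline is testable without any
real data.

## What it computes

For each fruit (four side views + one top view, with per-camera cm-per-px
calibration and an empty-chamber reference frame per camera):

- **Segmentation** — the fruit mask is the union of two masks:
  `m1 = (S/V > 0.2) ∧ (S > 0.19)` in HSV space, and `m2` = Otsu threshold on
  the magnitude of the image − background difference; post-processed to the
  largest 8-connected component with holes filled.
- **Polar shape profile** — boundary radius `r(θ)` around the mask centroid
  at every integer degree. Side views are first rotated about the centroid
  (grid search ±20° in 0.25° steps) to minimise the mirror **asymmetry
  index** `A = |M △ mirror(M)| / (2|M|)`, which is 0 for a perfectly
  symmetric mask.
- **Dimensions** — calibrated width/height per view and their means;
  **shape index** = mean height / mean width.
- **Top-view circle metrics** — centroid-based circumcircle (max radius),
  incircle (min), mean radius, and the SD of radii normalised to mean 1.
- **Shape class** — Pearson correlation of the mean-1-normalised 360-vector
  against a 13-outline reference library (standard pomological descriptors;
  replaceable by a user library); plus k-means clustering of profiles and
  per-degree average shapes with SDs.
- **Color** — hue and saturation density histograms (64 bins) of all peel
  pixels pooled over the four side views; reporting restricted to hue
  ∈ [0, 0.5] (yellow–red–green, the informative range for apples).
- **Cultivar statistics** — trait summaries, one-way ANOVA with Tukey HSD
  compact-letter displays, one-page factsheets.
- **Sample size** — the relative margin of error of a trait mean at sample
  size *n*: draw 200 random subsets of *n* fruit without replacement, take
  the 2.5%/97.5% quantiles of the subset means; the margin is half that
  range divided by the full-sample mean. Curves over n = 5…50 tell you how
  many fruit you need per accession.

## Worked example

Render a small synthetic study, extract features, and determine sample size:

```bash
fruitmorph simulate --out demo --cultivars 2 --fruit 3 --seed 4 --cm-per-px 0.02
fruitmorph extract --root demo --calibration demo/calibration.txt \
    --field-plan demo/field_plan.tsv --out demo/features
fruitmorph summarize demo/features/CV01_records.tsv demo/features/CV02_records.tsv \
    --out demo/summary
```

`demo/features/CV01_records.tsv` holds one row per fruit with columns such
as `ShapeClass`, `Corr_side`, `weight_g`, `radius_circ_pix`,
`width_mean_cm`, `height_mean_cm`, `asymmetry`, `shape_index` and the
64-bin color histograms. A typical row reads

```
ShapeClass=5  Corr_side=0.938  weight_g=80.84  width_mean_cm=5.72
height_mean_cm=5.865  asymmetry=0.00728  shape_index=1.025
```

i.e. this fruit is closest to the "obovoid" reference outline (class 5,
correlation 0.94), weighs 80.8 g, is 5.72 cm wide and 5.87 cm tall (shape
index 1.03, slightly taller than wide), and has a mirror asymmetry of
0.007 (0.7% of its area does not overlap its own mirror image).
`demo/summary/trait_summary.tsv` then lists per-cultivar n/mean/median/
SD/min/max per trait, and `significance_letters.tsv` the ANOVA p-value and
Tukey letter groups. From Python the same objects are available as
`fruitmorph.run_extract`, `fruitmorph.summarize_cultivar`,
`fruitmorph.moe_curve`, etc.

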