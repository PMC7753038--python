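# marrowmap

Quantitative analysis of micro-vessels in human bone-marrow trephine
sections, for researchers studying the vascular architecture of the
hematopoietic niche from multi-channel confocal micrographs.

Bone-marrow micro-vessels stain for NESTIN (a cytoskeletal intermediate
filament) in their endothelium, and the smallest of them — capillary-like
tubes without a CD146+/αSMA+ perivascular layer — concentrate near the bone
surface together with immature hematopoietic cells (imHCs, rounded CD34+
cells). `marrowmap` implements the three quantitative pillars of that
analysis, plus a seeded synthetic micrograph generator so every stage is
testable without archival tissue:

1. **Co-localization** (`marrowmap.coloc`). Pearson's *R* between a
   cytoskeletal channel (NESTIN, green) and an endothelial surface channel
   (CD34/CD31, red); the Costes automatic dual threshold, found by scanning
   the regression line T_red = a + b·T_green down the distinct green levels
   until the below-threshold pixels are uncorrelated; thresholded Manders
   coefficients M1 = Σᵢ red_i [green_i > T_g] / Σᵢ red_i (and M2
   conversely); and translated negative controls (channel shifted ±100 px,
   full re-analysis on the overlap). Group comparison by Kruskal–Wallis
   with Dunn's post test.
2. **Morphometry** (`marrowmap.morphometry`). Inner caliber (IC) of each
   lumen as the minor axis of its best-fit ellipse; empirical quartile
   cut-offs over the non-zero calibers; classification into {A, EA, cEA,
   NCLT, NC} from IC, perivascular-layer presence and a tubularity flag;
   the 5 caliber-band × complexity contingency table with a Pearson
   chi-square test. Also exposed as a scikit-learn-style
   `VesselClassifier` (fit = learn cut-offs, predict = assign classes).
3. **Spatial statistics** (`marrowmap.spatial`). Distances normalized by
   subtracting half the IC (floored at zero); bone co-occurrence tests;
   and distribution-based clustering inference: a distance series
   compatible with random placement looks normal, while an excess of short
   distances produces a right-skewed series flagged by Shapiro–Wilk
   together with the skewness z-score

   z = g₁ / SE(g₁),  SE(g₁) = √( 6n(n−1) / ((n−2)(n+1)(n+3)) ),

   and localized on a de-trended Q–Q plot (windows: endosteal 40 µm,
   perivascular 20 µm, bone contact 10 µm).

The generator (`marrowmap.fixtures`) renders annular vessel cross-sections
with log-normal calibers per class, a radially offset membrane ring (so the
two markers co-occur without coinciding pixel-by-pixel), pericyte rings,
a bone trabecula entering from one edge, and imHC point patterns that are
uniform or condensed in an exponential shell around a target class — with
full ground-truth tables.

## Worked example

```python
import pandas as pd
import marrowmap as mm

# 1. class percentages at the published category counts
rows = (
    [{"ic_um": 10, "has_pericytes": True, "tubular": True, "assigned_class": "A"}] * 58
    + [{"ic_um": 6, "has_pericytes": True, "tubular": True, "assigned_class": "EA"}] * 58
    + [{"ic_um": 3, "has_pericytes": True, "tubular": True, "assigned_class": "cEA"}] * 39
    + [{"ic_um": 2, "has_pericytes": False, "tubular": True, "assigned_class": "NCLT"}] * 268
    + [{"ic_um": 0, "has_pericytes": False, "tubular": False, "assigned_class": "NC"}] * 64
)
print(mm.class_percentages(pd.DataFrame(rows)))
# {'A': 13.7, 'EA': 13.7, 'cEA': 9.2, 'NCLT': 63.4, 'EA+cEA': 22.9}

# 2. skewness z of the capillary bone-distance series (g1 = 1.734, n = 123)
z, z_int = mm.skewness_z_from_g1(1.734, 123)
print(f"z = {z:.3f} -> reported {z_int}")
# z = 7.946 -> reported 8

# 3. co-occurrence signature on a synthetic capillary field
sets, truth = mm.generate_dataset(mm.nclt_coloc_config(seed=0))
ms = sets[0]
res = mm.coloc_analysis(
    mm.ChannelPair(green=ms.channels["nestin"], red=ms.channels["endothelial"])
)
print(f"R = {res.R:.3f}  M1 = {res.M1:.3f}  M2 = {res.M2:.3f}"
      f"  tR = {res.tR:.3f}  tM1 = {res.tM1:.3f}")
# R = 0.704  M1 = 0.763  M2 = 0.301  tR = -0.039  tM1 = 0.000
```

The percentages are the share of each class among tubular vessels (single
cells excluded): ~63% of NESTIN+ vessels are capillary-like tubes. The
skewness z of 8 marks the bone-distance series as strongly right-skewed —
capillaries pile up near the trabecula. In the co-localization block, M1
close to 1 with M2 much lower and near-zero translated controls is the
signature of a membrane marker riding on cytoskeleton-positive cells:
co-occurrence of the two markers without pixel-level identity.

A full pipeline run (`marrowmap run`, or `marrowmap.run_pipeline`) chains
generator → co-localization → classification → spatial inference and emits
one JSON report with every convention used (threshold rule, percentile
method, multiplicity adjustment, ...) recorded alongside the numbers.

## Command line

```
marrowmap run --config run.yaml --seed 1 --out outdir
marrowmap fixtures --seed 0 --out fixtures/
marrowmap coloc --green a.tif --red b.tif --offset 100 100 --out result.json
marrowmap morpho-classify --table vessels.csv --out classified.csv
marrowmap spatial-analyze --table distances.csv --out spatial.json
```

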