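# Methods

This note records the models, conventions and numerical choices behind
`marrowmap`, and what the synthetic data do and do not establish.

## The analysis model

A bone-marrow trephine micrograph is treated as a set of registered 2-D
channels on a common pixel grid (default 0.5 µm/px, the regime of a 1,000×
confocal field of Φ 0.25 mm digitized at 512 px): a cytoskeletal channel
(NESTIN), an endothelial surface channel (CD34 or CD31), a perivascular
channel (CD146/αSMA) and a nuclear channel, plus label masks for vessel
lumens/walls and a bone-trabecula mask. Three analyses run on top:

### Co-localization

Pearson's R is the product–moment correlation of paired pixel intensities.
The Costes automatic threshold regresses red on green over the ROI and
scans candidate thresholds down the distinct green levels, taking
T_red = intercept + slope·T_green at each step; the below-threshold set is
the pixels below both thresholds. The scan stops at the first level where
the below-threshold pixels are uncorrelated. "Uncorrelated" is implemented
as: correlation ≤ 0 (stop, status `ok`), or positive but negligible —
below `uncorrelated_band` (default 0.02) and below 2/√n — (stop, status
`flagged`). The band exists because on images whose background is genuinely
independent between channels the below-threshold correlation hovers at
statistically-zero positive values; a strict ≤ 0 rule then becomes a random
walk that can descend arbitrarily far, which is also why truly independent
channels are expected to stop at or near the top of the scan, flagged. A
fast prefix-sum search (pixels ordered by max(g, (r−a)/b), exact int64
moments for integer images) is used when the regression slope is positive;
it is exactly equivalent to the naive per-level scan, and the test suite
asserts that equivalence against an independently written exhaustive scan.

Manders coefficients use the thresholds: M1 is the fraction of total red
intensity on green-above-threshold pixels, M2 the converse. The reported R
uses pixels above **either** threshold (config-switchable to "both"); the
either-rule keeps R defined when one channel saturates. Translated negative
controls shift the green channel by (+100, +100) px with no wraparound,
restrict the ROI to the overlap, and re-estimate thresholds on the
translated pair — a control is a full re-analysis, not a re-use of the
original thresholds. Group comparison: Kruskal–Wallis with tie correction
(scipy), then Dunn's pairwise z tests with tie-corrected variance and
Bonferroni adjustment (implemented here; the adjustment is logged in every
report).

### Morphometry

Inner caliber (IC) = minor-axis length of the best-fit ellipse of the
largest connected lumen component, in µm (config alternative:
equivalent-circular diameter was considered and rejected because the minor
axis is robust to the sectioning-compression artifact). An empty lumen mask
gives IC = 0 ("imperceptible lumen"). Quartile cut-offs are empirical
25/50/75th percentiles with linear interpolation, computed over **non-zero**
calibers: zero is a detection floor, not a measurement, and including the
zeros would drag the lower quartile to 0, inconsistent with the micrometre-
scale cut-offs the classification operates with. Classification rules, in
order: not tubular → NC; tubular without pericytes → NCLT; compressed and
IC ≤ q50 → cEA; q50 < IC ≤ q75 → EA; IC > q75 → A; a pericyte-bearing
small-IC vessel without the compressed flag is cEA with a warning flag. The
`compressed` flag is an input (visual morphology); an automatic eccentricity
fallback was deliberately left out of the default path. The contingency
analysis counts 5 caliber bands (no-lumen, ≤q25, q25–q50, q50–q75, >q75)
against complexity columns; the pericytes-but-not-tubular column is excluded
by default before the Pearson chi-square (no continuity correction), and
zero-marginal rows/columns are dropped with df = (r−1)(c−1) on the rest.

### Spatial inference

Raw distances are measured from the structure centroid to the target
boundary via a Euclidean distance transform; for imHC targets the reference
is the point centroid. Normalization subtracts half the IC and floors at
zero — a raw distance smaller than the vessel radius means contact. The
clustering question ("are imHCs condensed around capillaries? are
capillaries condensed at the bone?") is answered from the *shape* of the
distance distribution, because a 3-D point-process analysis is not
available for trephine sections: random placement ↔ symmetric/normal
series; condensation ↔ excess of short distances ↔ right skew. Diagnostics
per series: Shapiro–Wilk W and p; adjusted Fisher–Pearson sample skewness
g₁ with its exact finite-sample standard error
SE(g₁) = √(6n(n−1)/((n−2)(n+1)(n+3))) and z = g₁/SE(g₁), reported raw and
rounded to the nearest integer; de-trended Q–Q ordinates (sorted sample
minus the (mean, SD)-fitted normal line at standard-normal quantiles of the
plotting positions (i−0.5)/n; Blom positions are a config switch). Windowed
re-analyses use the endosteal window (40 µm) and split the series at the
perivascular (20 µm, imHC targets) or bone-contact (10 µm, bone targets)
threshold. Verdicts: "right-skewed" iff p_SW < 0.05 and z ≥ 2; "normal" iff
p_SW ≥ 0.05; otherwise "symmetric non-normal"; "insufficient-n" below n = 5.
These rules are configuration and are printed in every report. Note that a
series with p_SW < 0.05 and z = 2 is called right-skewed here even where a
reader eyeballing a Q–Q plot might call it "potentially normal"; the rule is
deliberately mechanical. 2×2 association tests (bone co-occurrence, marker
vs proximity) use Pearson chi-square without continuity correction,
switching to Fisher's exact test when any expected cell count is below 5.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
histological appearance. Fields are class-homogeneous (one vessel class per
micrograph, mirroring photos centered on a structure type), with ~10
vessels per 512² field placed uniformly at random without overlap; the
placement also avoids the ±(100,100) px translation lattice so that a
translated negative control lands on empty marrow, the sparse-field regime
the control analysis presumes.

Per-class inner calibers are log-normal (µ, σ on the log-µm scale),
calibrated once so the pooled non-zero quartiles at the default class
counts (268 NCLT / 58 EA / 39 cEA / 58 A / 64 NC) land in the published
3.2 / 4.5 / 7.6 µm regime: NCLT ~ logN(ln 3.0, 0.35) right-truncated at
4.1 µm, EA ~ logN(ln 5.9, 0.14), cEA apparent caliber ~ logN(ln 4.1, 0.13)
rendered as an ellipse with compression 0.65, A ~ logN(ln 11, 0.20). The
NCLT zero-lumen fraction defaults to 0.70. That last number deserves a
remark: the source counts (163 zero-lumen capillaries of 268, pooled median
4.5 µm, and *every* no-pericyte tubular vessel below the median) are
mutually inconsistent under any percentile pool we could construct — with
163 zeros excluded, the remaining capillaries plus the compressed
arterioles necessarily overfill the below-median half. The generator
resolves the conflict in favour of the structural regularities (quartile
regime, all-capillaries-below-median, recoverable classes) by raising the
zero-lumen fraction; this is a deliberate design choice of the synthetic
model, not a measurement.

Rendering: the endothelial wall (2 µm) is an annulus filled in the
cytoskeletal channel; the membrane channel is a ring centered mid-wall and
displaced radially outward by `marker_offset_px` (default 1), so the two
markers co-occur on the same cells without coinciding pixel-by-pixel;
pericyte rings (1.5 µm) go only to the perivascular channel; lumenless
structures are filled disks (2.5 µm cell radius). Realism terms that the
co-localization behaviour depends on: per-channel *independent* dim cell
populations (dense NESTIN-dim stroma, sparser CD34-dim cells — these are
what keep the converse Manders coefficient low and anchor the
below-threshold anti-correlation), Gaussian PSF blur (σ 0.5 µm), Poisson
noise then Gaussian read noise (σ 2) on top of an additive background
(0.5), optional channel crosstalk (default 0: spectrally unmixed channels —
any nonzero crosstalk couples the channels at every intensity and shifts
the Costes threshold floorward), 16-bit quantization. Bone trabeculae are
smoothed random regions entering from the top edge covering ~15% of the
field, present with class-specific probabilities set to the published
co-occurrence frequencies (45.7% NCLT, 31.6% EA/cEA, 24.1% A, 43.7% NC).
imHC points are uniform over the marrow (never in bone or lumens) or, in
shell mode, a `clustered_fraction` of them have distance-to-target drawn
from Exponential(`shell_decay_um`) around a uniformly chosen target of the
configured class.

What passing tests on these fixtures show: the measurement operators,
threshold search, classification rules and distribution diagnostics do what
they claim on data with known truth, at realistic noise. What they do not
show: performance on real tissue — real marrow has autofluorescence
gradients, sectioning artifacts, touching structures, imperfect masks and
staining variability that the generator does not model; absolute coefficient
values (R, M1) on archival images are not reproduced here, only their
qualitative signatures.

## Determinism and problem sizes

All randomness flows from `numpy.random.SeedSequence(seed)`, fanned out per
image (generator) and per stage (pipeline, children derived below 2³¹), so
identical (config, seed) gives bit-identical images, tables and report
payloads. The test suite runs the full 487-vessel dataset once (shared
fixture), 20-seed ensembles for the co-occurrence signature, 50-seed nulls
for verdict calibration and 200-seed calibration for Shapiro–Wilk — sizes
chosen to give the binomial margins quoted in the tests.

## Known limitations

- The Costes search assumes an approximately linear red–green relation
  among signal pixels; bright single-channel populations violate it and
  push the stop to the top of the scan (flagged) — real but worth knowing.
- The uncorrelated band (0.02) is a practical-zero convention; series whose
  true below-threshold correlation is positive but smaller than the band
  are treated as uncorrelated.
- IC from a single section underestimates the true caliber of obliquely cut
  vessels; the tubularity flag is an input and is not inferred from 2-D
  morphology.
- Verdicts dichotomize at conventional α = 0.05 and z ≥ 2; borderline
  series (e.g. small-n arterial distances) can flip verdicts across nearby
  samples.
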