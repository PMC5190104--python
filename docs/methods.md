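# Methods

## The analysis chain

The package models one tissue section per patient as 15 fields of view,
each a triplet of co-registered greyscale rasters: DAPI (all nuclei),
pan-cytokeratin (epithelium/tumor) and D2-40 (lymphatic endothelium).
Processing is hierarchical: a four-class ROI partition per pixel, an object
level (detached stromal epithelial objects; vessels), and a nucleus level
in which every nucleus has exactly one parent — the object containing its
centroid, else its centroid's ROI class. Centroid containment was chosen
over pixel-majority assignment because it is unambiguous (no ties) and
cheap; for convex nucleus masks the two rules agree except at object
borders.

Segmentation is rule-based: global intensity thresholds plus morphology,
with every threshold in `SegmentationConfig`. The tumor ROI is the union of
pan-CK-positive connected components larger than `mass_min_area_um2`
(default 10,000 µm²); smaller stromal components become candidate objects.
Pan-CK-negative holes enclosed by the mass are lumen/necrosis. Nuclei are
declumped by a distance-transform watershed seeded at local EDT maxima with
a minimum separation of 1.4× the expected nucleus radius; touching nuclei
whose centres are ≥1.5× radius apart are split (tested at 1.6×). The
downstream contract is only the four-class partition and the object and
nucleus inventories — a trained segmentation model could be substituted
behind the same interface.

Classification thresholds follow the conventional cluster definitions:
tumor bud ≤4 nuclei, PDC ≥5 nuclei, minimal LVI <5 intravascular tumor
cells. An epithelial object is intravascular when ≥50% of its area lies in
a vessel lumen — area overlap rather than any-pixel contact, so a vessel
brushing a gland is not scored as invasion. Objects with zero assigned
nuclei (cytokeratin debris) are excluded as `unresolved` rather than
counted as buds. The LVD denominator is the whole analyzed tissue area.
All of these are configuration, not constants.

## The 123-parameter feature-set

The manifest (123 named entries, versioned as CSV in package data and
constructed programmatically) spans counts, morphometry (areas; roundness
4πA/P²; elongation = major/minor axis), densities, spatial distances from
detached clusters to the tumor ROI, per-region channel intensities, and
grey-level co-occurrence texture. Texture uses 32 grey levels after linear
quantization over the image's own range, distance-1 offsets,
direction-averaged and symmetrized, accumulated only over pixel pairs that
both lie in the (non-rectangular) region mask — hence the in-package GLCM
rather than a rectangular-window library call.

Collation to one patient vector: extensive quantities (counts, summed
areas) are summed over fields, intensive ones (means, ratios, intensities,
texture) averaged over the fields where the source class is present. A
feature missing in every field falls back to 0 with a QC flag, keeping the
table rectangular for the models.

## Distillation

`rf_iterative_reduce` refits the forest at every step (5000 trees by
default; smaller forests are adequate for the package's simulation-scale
problems) and removes one feature per iteration — the lowest Gini
importance. "Predictive value" for the stopping rule is out-of-bag AUC
with tolerance 0.005; the loop stops when OOB AUC falls more than the
tolerance below the best observed, and the reported subset is the surviving
set at the (earliest) best OOB AUC. Returning the earliest best matters
when informative features are mutually redundant: removing one does not
hurt OOB AUC, but a parsimony rule would then discard genuinely informative
parameters.

`cart_fit` grows a Gini tree (minimum leaf 5) and selects cost-complexity
pruning by stratified k-fold cross-validation (default 10 folds, read as
self-test validation on the training data). The pruning strength is the
largest alpha whose CV misclassification risk stays within c·SE of the
minimum. c = 1.5 rather than the classical 1.0: measured on pure-noise data
(n=100, 5 features, 20 seeds), c=1 pruned to a single leaf in only 12/20
seeds while c=1.5 reached 18/20 without ever pruning away a strong planted
split (10/10 kept). Split thresholds are midpoints between adjacent sorted
values (scikit-learn's convention, declared here as the package's). The
root split is exported as the headline parameter + cut-off.

`pca_overview` z-scores features, takes the top two principal components,
2-means clusters the scores, maps clusters to outcome by majority, and
computes AUC from each patient's projection on the inter-centroid axis —
a declared substitute for reading sensitivity/specificity off a scatter
plot, which has no unique definition.

## Survival statistics

The cut-point search scans midpoints of consecutive sorted unique values
restricted to the 10th–90th percentile (degenerate tail splits excluded)
and maximizes the two-group log-rank chi-square (vectorized over
thresholds). The corrected p is a permutation test of the *maximum*
statistic: labels (value vector) permuted `n_sim` times (default 1000),
p = (1 + #{perm max ≥ observed}) / (1 + n_sim), floored at the naive 1-df
p so the corrected value can never undercut it. Under the null the
corrected p rejects at ≤ nominal level (measured 0.015–0.05 at 0.05 over
200 replicates).

Dichotomization: group 2 iff value strictly above the threshold; exact
ties stay in group 1. Defaults are the training-set cut-offs (287 buds,
16 minimal-LVI events, 35 PDCs, 21% tumor:stroma — where the *low* group
carries the risk — and 35,647 µm² AreaPDC).

Cox models use lifelines (Efron tie handling, Wald CIs). Backward
elimination removes, at each step, the covariate whose removal most
decreases the partial-likelihood AIC and stops when no removal decreases
it; the retained set may be empty, using the null model's Efron partial
log-likelihood (computed in-package, since a zero-covariate model cannot
be fitted by the library) as the baseline AIC. Collinear covariates
(|r| > 0.999) are dropped with a warning before fitting.

The composite prognostic index scores three flags — AreaPDC above cut-off,
pT4 stage, poor differentiation — and calls a patient high-risk at ≥2.
"Poor differentiation" is poor vs {well, moderate}; pT4 vs pT3. These
binarizations are the natural reading of "above cut-off" for ordinal
clinical covariates; the alternative (moderate+poor) is a one-line config
change.

## Synthetic data: what it emulates and what it does not

Fields default to 512×512 px at 0.5 µm/px (the acquisition platform's
micron scale is treated as a free parameter; all areas are reported in µm²
via pixel_size²). The intensity model is three-level (slide background ~5,
tissue autofluorescence 12–15, positive marker 200 camera units), blurred
with a σ=1 px Gaussian PSF and overlaid with Gaussian read noise (σ=4 by
default). Nuclei are discs of radius 3 px placed with guaranteed pairwise
separation (hex-lattice layout inside clusters); cluster pan-CK masks are
unions of nucleus-centred discs with a 2 px margin; vessels are elliptical
D2-40 rings with a dark lumen, enlarged as needed to hold planted
intravascular clusters; the tumor mass is a block occupying the requested
tissue fraction with circular lumen holes carved to the requested lumen
fraction. Object placement is rejection-sampled with non-overlap margins
and fails loudly (`FieldTooCrowdedError`) rather than truncating.

Default per-field object counts (0–3 buds, 0–2 PDCs, 0–2 vessels, 40%
chance of one LVI event when a vessel is present; tumor fraction uniform in
0.3–0.5) give section totals of order tens of objects — deliberately modest
field occupancy typical of an invasive-front field rather than a stress
test.

Cohorts follow an exponential proportional-hazards model: per-patient
hazard = baseline × Π HRᶜᵒᵛ with independent Bernoulli covariates and
administrative censoring — the minimal generating model consistent with the
Cox analyses downstream. The study-like default plants HR 4.0 on the
AreaPDC-high group (prevalence 65/134), HR 4.26 on pT4 (prevalence 32/134)
and HR 2.0 on poor differentiation, baseline hazard 0.0025/month, censoring
at 60 months; AreaPDC values are Gaussian around group means 15,000 /
70,000 µm² (σ 9,000).

Passing the recovery suites therefore shows the chain is *correct* on data
obeying its contrast and shape assumptions with exact ground truth; it does
not show robustness to real-slide phenomena the generator deliberately
omits: autofluorescence bleed-through, stain gradients, touching nuclei in
dense sheets, necrotic debris, sectioning artefacts, or non-proportional
hazards.

## Problem sizes and numerical choices

The test and acceptance runs use scaled problem sizes chosen as adequate
for their statistical question: forests of 100–150 trees (OOB AUC is stable
well below the 5000-tree default at n≈150), 20-seed recovery studies,
200-replicate null calibrations with 200 permutations each, and Cox
recovery at n=500–1000. Tolerances asserted in tests (±5% object area, ±10%
relative on planted area fractions, ≥90% seed success rates) are stated in
the corresponding operations' contracts. All randomness flows from explicit
integer seeds through `numpy.random.SeedSequence` spawning; reruns are
bit-identical.

## Known limitations

Rule-based segmentation presumes the synthetic contrast model; real
immunofluorescence would need threshold recalibration or a learned ROI
classifier behind the same interface. The manifest's 123 names are a
declared reconstruction from the stated measurement families, not a
recovered instrument export list. The PCA overview's
sensitivity/specificity depend on the clustering substitute described
above. X-Tile-style cross-validated cut-point correction is implemented as
a pure max-statistic permutation test; both control the scan's optimism but
are not numerically identical procedures.
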