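# invasivefront

Quantitative histopathology of the colorectal-cancer invasive front from
multichannel immunofluorescence, with survival modelling for stage II
disease.

Stage II colorectal cancer sits on a clinical knife edge: most patients are
cured by surgery alone, but a subset dies of recurrence and would have
benefited from adjuvant therapy. Invasive-front features — tumor buds,
poorly differentiated clusters (PDCs), lymphatic vessel invasion (LVI), the
tumor:stroma ratio — carry prognostic information but are tedious and poorly
reproducible to score by eye. This package implements an end-to-end,
seed-reproducible pipeline that quantifies these features objectively from
three-channel immunofluorescence fields (DAPI nuclei, pan-cytokeratin
epithelium, D2-40 lymphatic endothelium), distills a 123-parameter
feature-set down to the informative few, and builds a composite prognostic
index.

## What it computes

**Hierarchical segmentation** of each field of view:
ROI level (tumor / stroma / lumen-necrosis / no-tissue partition), object
level (detached pan-CK⁺ epithelial objects in stroma; D2-40⁺ vessels
reconstructed as ring+lumen), nucleus level (DAPI blobs with
distance-transform watershed declumping). Every nucleus is exclusively
assigned to one parent.

**Feature classification**: a detached object with ≤4 nuclei is a tumor
bud, with ≥5 a PDC; an object lying ≥50% inside a vessel lumen is LVI
(*minimal* LVI when fewer than 5 tumor cells have invaded). Field scalars:
bud/PDC/LVI counts, summed PDC area (AreaPDC, µm²), lymphatic vessel
density (vessels/mm²), tumor:stroma ratio (%).

**Multi-parametric feature-set**: 123 declared parameters per patient
(counts, morphometry, densities, spatial distances, intensities, GLCM
texture), collated over the 15 fields of a section by sum-or-average rules.

**Distillation**: iterative random-forest elimination — fit a forest
(default 5000 trees), drop the lowest-Gini feature, refit, stop when
out-of-bag AUC degrades — followed by a single CART whose
cost-complexity pruning is selected by cross-validation; the root split is
the headline parameter and clinical cut-off.

**Survival statistics**: maximally selected log-rank cut-points with
Monte-Carlo (permutation) correction, dichotomization at the training-set
cut-offs (287 buds, 16 minimal-LVI events, 35 PDCs, 21% tumor:stroma,
35,647 µm² AreaPDC), Kaplan-Meier/log-rank with Benjamini-Hochberg FDR,
univariate Cox, backward elimination with an AIC stopping rule, and the
novel prognostic index (NPI): high risk when ≥2 of {AreaPDC above cut-off,
pT4 stage, poor differentiation}.

Because no patient images or outcomes ship with the package, a first-class
synthetic module generates immunofluorescence fields with exact ground
truth and survival cohorts with planted hazard structure; every stage is
validated against those plants.

## Worked example

```python
import invasivefront as iv

spec = iv.FieldSpec(
    n_buds=3, bud_nucleus_counts=[2, 3, 4],
    n_pdc=2, pdc_nucleus_counts=[6, 8],
    n_vessels=2, lvi_events=[(0, 6), (1, 3)],   # one LVI, one minimal LVI
    tumor_fraction=0.4, seed=7,
)
field, truth = iv.generate_field(spec)
hierarchy = iv.segment_field(field)
cf = iv.classify_objects(hierarchy)
print(cf.n_buds, cf.n_pdc, cf.n_lvi, cf.n_minimal_lvi, cf.n_vessels)
# 3 2 1 1 2          <- planted counts recovered exactly
print(round(truth.area_pdc_um2, 1), round(cf.area_pdc_um2, 1))
# 230.5 233.0        <- planted vs measured summed PDC area (um^2), ~1% apart
```

Survival stage on a planted cohort (hazard ratio 4 on the AreaPDC-high
group):

```python
from invasivefront.synthetic import study_cohort_spec, generate_cohort, cohort_to_frame
df = cohort_to_frame(generate_cohort(study_cohort_spec(seed=2, n_patients=300)))
flag = (df["area_pdc_um2"] > 35_647).astype(int)
res = iv.cox_univariate(flag, df["time_months"], df["event"], "area_pdc_high")
print(res.summary())
#                    hr  ci_low  ci_high    p
# covariate
# area_pdc_high  3.5784  2.4128    5.307  0.0
```

The estimated hazard ratio recovers the planted effect within its
confidence interval. A command line mirrors the library:
`invasivefront simulate|extract|distill|survive|all`.

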