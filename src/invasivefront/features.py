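"""The multi-parametric feature-set: extraction and per-patient collation.

Each field of view yields one value per entry of a declared
:class:`FeatureManifest` spanning the three hierarchy levels (ROI, object,
nucleus) and six measurement families: counts, morphometry (areas, roundness
``4*pi*A/P^2``, elongation = major/minor axis), densities, spatial distances
to the tumor ROI, per-region channel intensities, and grey-level
co-occurrence texture (32 levels, distance 1, direction-averaged).

The default manifest has exactly 123 entries. Per patient, the 15 field
vectors are collated to a single vector: extensive quantities (counts,
summed areas) are summed, intensive ones (means, ratios, intensities,
texture) are averaged, skipping fields where the source class is absent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from invasivefront.classification import ClassifiedField
from invasivefront.segmentation import (
    FieldImage,
    ROI_LUMEN,
    ROI_NO_TISSUE,
    ROI_STROMA,
    ROI_TUMOR,
    SegmentationHierarchy,
)

logger = logging.getLogger(__name__)

OBJECT_CLASSES = ("tumor_bud", "pdc", "lvi", "minimal_lvi")
GLCM_LEVELS = 32


@dataclass(frozen=True)
class FeatureDef:
    name: str
    level: str          # roi | object | nucleus
    source_class: str
    family: str         # count | sum_area | mean_area | sd_area | shape |
                        # density | spatial_distance | intensity | texture
    collation: str      # sum | mean


@dataclass
class FeatureManifest:
    entries: list[FeatureDef]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if any(e.collation not in ("sum", "mean") for e in self.entries):
            raise ValueError("every feature needs a declared collation rule")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def collations(self) -> np.ndarray:
        return np.array([e.collation for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.name, e.level, e.source_class, e.family, e.collation) for e in self.entries],
            columns=["name", "level", "source_class", "family", "collation"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureManifest":
        return cls([FeatureDef(*row) for row in df.itertuples(index=False)])


def build_default_manifest() -> FeatureManifest:
    """Construct the default 123-parameter manifest programmatically."""
    e: list[FeatureDef] = []

    def add(name, level, src, family, collation):
        e.append(FeatureDef(name, level, src, family, collation))

    # headline candidate-feature scalars
    add("n_buds", "object", "tumor_bud", "count", "sum")
    add("n_pdc", "object", "pdc", "count", "sum")
    add("n_lvi", "object", "lvi", "count", "sum")
    add("n_minimal_lvi", "object", "minimal_lvi", "count", "sum")
    add("n_vessels", "object", "vessel", "count", "sum")
    add("lvd_per_mm2", "object", "vessel", "density", "mean")
    add("tumor_stroma_pct", "roi", "tumor", "density", "mean")
    add("area_pdc_um2", "object", "pdc", "sum_area", "sum")

    # object morphometry per epithelial class
    for cls in OBJECT_CLASSES:
        add(f"{cls}_sum_area_um2", "object", cls, "sum_area", "sum")
        add(f"{cls}_mean_area_um2", "object", cls, "mean_area", "mean")
        add(f"{cls}_sd_area_um2", "object", cls, "sd_area", "mean")
        add(f"{cls}_mean_roundness", "object", cls, "shape", "mean")
        add(f"{cls}_mean_elongation", "object", cls, "shape", "mean")
        add(f"{cls}_mean_nuclei", "object", cls, "count", "mean")

    # spatial distances from detached clusters to the tumor ROI
    for cls in ("tumor_bud", "pdc"):
        add(f"{cls}_mean_dist_to_tumor_um", "object", cls, "spatial_distance", "mean")
        add(f"{cls}_min_dist_to_tumor_um", "object", cls, "spatial_distance", "mean")

    # vessel morphometry
    add("vessel_sum_area_um2", "object", "vessel", "sum_area", "sum")
    add("vessel_mean_area_um2", "object", "vessel", "mean_area", "mean")
    add("vessel_sd_area_um2", "object", "vessel", "sd_area", "mean")
    add("vessel_mean_elongation", "object", "vessel", "shape", "mean")

    # ROI areas
    add("tumor_area_um2", "roi", "tumor", "sum_area", "sum")
    add("stroma_area_um2", "roi", "stroma", "sum_area", "sum")
    add("lumen_necrosis_area_um2", "roi", "lumen_necrosis", "sum_area", "sum")
    add("tissue_area_mm2", "roi", "tissue", "sum_area", "sum")

    # nucleus-level tallies
    for src in ("tumor", "stroma", "tumor_bud", "pdc", "intravascular"):
        add(f"n_nuclei_{src}", "nucleus", src, "count", "sum")
    for src in ("tumor", "stroma"):
        add(f"nucleus_mean_area_um2_{src}", "nucleus", src, "mean_area", "mean")
    for src in ("tumor", "stroma"):
        add(f"nucleus_density_per_mm2_{src}", "nucleus", src, "density", "mean")

    # channel intensities per region / class
    for src in ("tumor", "stroma"):
        for chan in ("dapi", "panck", "d240"):
            add(f"{src}_mean_intensity_{chan}", "roi", src, "intensity", "mean")
            add(f"{src}_sd_intensity_{chan}", "roi", src, "intensity", "mean")
    for cls in OBJECT_CLASSES:
        for chan in ("dapi", "panck"):
            add(f"{cls}_mean_intensity_{chan}", "object", cls, "intensity", "mean")
            add(f"{cls}_sd_intensity_{chan}", "object", cls, "intensity", "mean")
    add("vessel_mean_intensity_d240", "object", "vessel", "intensity", "mean")
    add("vessel_sd_intensity_d240", "object", "vessel", "intensity", "mean")

    # grey-level co-occurrence texture
    for src in ("tumor", "stroma"):
        for chan in ("dapi", "panck"):
            for stat in ("contrast", "entropy", "correlation"):
                add(f"{src}_glcm_{stat}_{chan}", "roi", src, "texture", "mean")
    for cls in ("tumor_bud", "pdc"):
        for chan in ("panck", "dapi"):
            for stat in ("contrast", "entropy", "correlation"):
                add(f"{cls}_glcm_{stat}_{chan}", "object", cls, "texture", "mean")
    for stat in ("contrast", "entropy", "correlation"):
        add(f"vessel_glcm_{stat}_d240", "object", "vessel", "texture", "mean")

    # remaining density/shape summaries
    for src in ("tumor", "stroma"):
        add(f"nucleus_mean_roundness_{src}", "nucleus", src, "shape", "mean")
    for cls in OBJECT_CLASSES:
        add(f"{cls}_per_mm2", "object", cls, "density", "mean")
    add("lumen_fraction_pct", "roi", "lumen_necrosis", "density", "mean")
    add("stroma_nucleus_mean_dist_to_tumor_um", "nucleus", "stroma",
        "spatial_distance", "mean")
    add("bud_total_nuclei", "nucleus", "tumor_bud", "count", "sum")
    add("pdc_total_nuclei", "nucleus", "pdc", "count", "sum")
    add("vessel_mean_roundness", "object", "vessel", "shape", "mean")
    add("bud_sum_area_pct_tissue", "object", "tumor_bud", "density", "mean")
    add("pdc_sum_area_pct_tissue", "object", "pdc", "density", "mean")

    manifest = FeatureManifest(e)
    assert len(manifest) == 123, f"default manifest has {len(manifest)} entries"
    return manifest


_DEFAULT_MANIFEST: FeatureManifest | None = None


def manifest_default() -> FeatureManifest:
    """The packaged 123-parameter manifest (stable order across runs)."""
    global _DEFAULT_MANIFEST
    if _DEFAULT_MANIFEST is None:
        _DEFAULT_MANIFEST = build_default_manifest()
    return _DEFAULT_MANIFEST


# ---------------------------------------------------------------------------
# per-field extraction helpers
# ---------------------------------------------------------------------------

def _shape_props(mask: np.ndarray) -> tuple[float, float]:
    """(roundness, elongation) of a single binary object."""
    props = measure.regionprops(mask.astype(np.uint8))
    if not props:
        return np.nan, np.nan
    p = props[0]
    perim = p.perimeter
    roundness = 4.0 * math.pi * p.area / perim**2 if perim > 0 else np.nan
    minor = p.axis_minor_length
    elong = p.axis_major_length / minor if minor > 0 else np.nan
    return float(min(roundness, 1.0)) if np.isfinite(roundness) else np.nan, elong


def masked_glcm_stats(
    img: np.ndarray, mask: np.ndarray, levels: int = GLCM_LEVELS
) -> dict[str, float]:
    """Grey-level co-occurrence statistics over an arbitrary pixel mask.

    The image is linearly quantized to ``levels`` grey levels over its own
    range; co-occurrences are accumulated for the four distance-1 offsets
    where *both* pixels lie in the mask, symmetrized and direction-averaged.
    """
    if mask.sum() < 2:
        return {"contrast": np.nan, "entropy": np.nan, "correlation": np.nan}
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        q = np.zeros(img.shape, dtype=np.int64)
    else:
        q = np.clip(((img - lo) / (hi - lo) * levels).astype(np.int64), 0, levels - 1)

    glcm = np.zeros((levels, levels), dtype=np.float64)
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a_sl = (slice(max(0, -dr), img.shape[0] - max(0, dr)),
                slice(max(0, -dc), img.shape[1] - max(0, dc)))
        b_sl = (slice(max(0, dr), img.shape[0] + min(0, dr) or None),
                slice(max(0, dc), img.shape[1] + min(0, dc) or None))
        valid = mask[a_sl] & mask[b_sl]
        if not valid.any():
            continue
        i = q[a_sl][valid]
        j = q[b_sl][valid]
        np.add.at(glcm, (i, j), 1.0)
        np.add.at(glcm, (j, i), 1.0)

    total = glcm.sum()
    if total == 0:
        return {"contrast": np.nan, "entropy": np.nan, "correlation": np.nan}
    p = glcm / total
    idx = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    contrast = float((p * (ii - jj) ** 2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    var_i = float((p * (ii - mu_i) ** 2).sum())
    var_j = float((p * (jj - mu_j) ** 2).sum())
    if var_i > 0 and var_j > 0:
        corr = float(((p * (ii - mu_i) * (jj - mu_j)).sum()) / math.sqrt(var_i * var_j))
    else:
        corr = 0.0
    return {"contrast": contrast, "entropy": entropy, "correlation": corr}


def extract_field_features(
    field: FieldImage,
    h: SegmentationHierarchy,
    cf: ClassifiedField,
    manifest: FeatureManifest | None = None,
) -> np.ndarray:
    """One value per manifest entry for a single segmented, classified field.

    Counts and summed areas of an absent class are 0; intensive features of
    an absent class are NaN (flagged missing; the collation step skips them).
    """
    manifest = manifest or manifest_default()
    px = field.pixel_size_um
    px_area = px**2
    roi = h.roi_map
    channels = {"dapi": field.dapi, "panck": field.panck, "d240": field.d240}

    tumor_mask = roi == ROI_TUMOR
    stroma_mask = roi == ROI_STROMA
    lumen_mask = roi == ROI_LUMEN
    tissue_px = int((roi != ROI_NO_TISSUE).sum())
    tissue_um2 = tissue_px * px_area
    tissue_mm2 = tissue_um2 / 1e6

    # distance (px) from any pixel to the nearest tumor pixel
    dist_to_tumor = (
        ndi.distance_transform_edt(~tumor_mask) if tumor_mask.any() else None
    )

    class_objs = {cls: cf.objects_of_class(cls) for cls in OBJECT_CLASSES}
    vessels = h.vessels

    # per-object shape, cached
    shape_cache: dict[int, tuple[float, float]] = {}

    def shapes(objs):
        vals = []
        for o in objs:
            if o.id not in shape_cache:
                shape_cache[o.id] = _shape_props(o.mask)
            vals.append(shape_cache[o.id])
        return vals

    def class_mask(objs):
        m = np.zeros(roi.shape, dtype=bool)
        for o in objs:
            m |= o.mask
        return m

    region_masks = {
        "tumor": tumor_mask,
        "stroma": stroma_mask,
        "lumen_necrosis": lumen_mask,
    }
    class_masks = {cls: class_mask(objs) for cls, objs in class_objs.items()}
    vessel_mask = class_mask(vessels)

    # nucleus tallies by compartment
    nuc_groups: dict[str, list] = {k: [] for k in
                                   ("tumor", "stroma", "tumor_bud", "pdc",
                                    "intravascular", "lumen_necrosis", "no_tissue")}
    obj_class = cf.object_classes
    for nuc in h.nuclei:
        parent = nuc.parent
        if isinstance(parent, (int, np.integer)):
            cls = obj_class.get(int(parent), "unresolved")
            if cls in ("tumor_bud", "pdc"):
                nuc_groups[cls].append(nuc)
            elif cls in ("lvi", "minimal_lvi"):
                nuc_groups["intravascular"].append(nuc)
        elif parent in nuc_groups:
            nuc_groups[parent].append(nuc)

    glcm_cache: dict[tuple[str, str], dict[str, float]] = {}

    def glcm(src_key: str, mask: np.ndarray, chan: str) -> dict[str, float]:
        key = (src_key, chan)
        if key not in glcm_cache:
            glcm_cache[key] = masked_glcm_stats(channels[chan], mask)
        return glcm_cache[key]

    def nan_mean(vals):
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else np.nan

    def nan_sd(vals):
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.std(vals, ddof=0)) if len(vals) >= 1 else np.nan

    values: dict[str, float] = {}

    values["n_buds"] = cf.n_buds
    values["n_pdc"] = cf.n_pdc
    values["n_lvi"] = cf.n_lvi
    values["n_minimal_lvi"] = cf.n_minimal_lvi
    values["n_vessels"] = cf.n_vessels
    values["lvd_per_mm2"] = cf.lvd_per_mm2
    values["tumor_stroma_pct"] = cf.tumor_stroma_pct
    values["area_pdc_um2"] = cf.area_pdc_um2

    for cls in OBJECT_CLASSES:
        objs = class_objs[cls]
        areas = [o.area_um2 for o in objs]
        sh = shapes(objs)
        values[f"{cls}_sum_area_um2"] = float(sum(areas))
        values[f"{cls}_mean_area_um2"] = nan_mean(areas) if objs else np.nan
        values[f"{cls}_sd_area_um2"] = nan_sd(areas) if objs else np.nan
        values[f"{cls}_mean_roundness"] = nan_mean([s[0] for s in sh])
        values[f"{cls}_mean_elongation"] = nan_mean([s[1] for s in sh])
        values[f"{cls}_mean_nuclei"] = (
            nan_mean([o.nucleus_count for o in objs]) if objs else np.nan
        )

    for cls in ("tumor_bud", "pdc"):
        objs = class_objs[cls]
        if objs and dist_to_tumor is not None:
            dists = [
                float(dist_to_tumor[int(round(o.centroid[0])), int(round(o.centroid[1]))]) * px
                for o in objs
            ]
            values[f"{cls}_mean_dist_to_tumor_um"] = float(np.mean(dists))
            values[f"{cls}_min_dist_to_tumor_um"] = float(np.min(dists))
        else:
            values[f"{cls}_mean_dist_to_tumor_um"] = np.nan
            values[f"{cls}_min_dist_to_tumor_um"] = np.nan

    v_areas = [v.area_um2 for v in vessels]
    v_sh = shapes(vessels)
    values["vessel_sum_area_um2"] = float(sum(v_areas))
    values["vessel_mean_area_um2"] = nan_mean(v_areas) if vessels else np.nan
    values["vessel_sd_area_um2"] = nan_sd(v_areas) if vessels else np.nan
    values["vessel_mean_elongation"] = nan_mean([s[1] for s in v_sh])

    values["tumor_area_um2"] = float(tumor_mask.sum()) * px_area
    values["stroma_area_um2"] = float(stroma_mask.sum()) * px_area
    values["lumen_necrosis_area_um2"] = float(lumen_mask.sum()) * px_area
    values["tissue_area_mm2"] = tissue_mm2

    for src in ("tumor", "stroma", "tumor_bud", "pdc", "intravascular"):
        values[f"n_nuclei_{src}"] = len(nuc_groups[src])
    for src in ("tumor", "stroma"):
        nucs = nuc_groups[src]
        areas = [float(n.mask.sum()) * px_area for n in nucs]
        values[f"nucleus_mean_area_um2_{src}"] = nan_mean(areas) if nucs else np.nan
        region_mm2 = float(region_masks[src].sum()) * px_area / 1e6
        values[f"nucleus_density_per_mm2_{src}"] = (
            len(nucs) / region_mm2 if region_mm2 > 0 else np.nan
        )

    for src in ("tumor", "stroma"):
        m = region_masks[src]
        for chan, img in channels.items():
            if m.any():
                values[f"{src}_mean_intensity_{chan}"] = float(img[m].mean())
                values[f"{src}_sd_intensity_{chan}"] = float(img[m].std())
            else:
                values[f"{src}_mean_intensity_{chan}"] = np.nan
                values[f"{src}_sd_intensity_{chan}"] = np.nan
    for cls in OBJECT_CLASSES:
        m = class_masks[cls]
        for chan in ("dapi", "panck"):
            if m.any():
                values[f"{cls}_mean_intensity_{chan}"] = float(channels[chan][m].mean())
                values[f"{cls}_sd_intensity_{chan}"] = float(channels[chan][m].std())
            else:
                values[f"{cls}_mean_intensity_{chan}"] = np.nan
                values[f"{cls}_sd_intensity_{chan}"] = np.nan
    if vessel_mask.any():
        values["vessel_mean_intensity_d240"] = float(channels["d240"][vessel_mask].mean())
        values["vessel_sd_intensity_d240"] = float(channels["d240"][vessel_mask].std())
    else:
        values["vessel_mean_intensity_d240"] = np.nan
        values["vessel_sd_intensity_d240"] = np.nan

    for src in ("tumor", "stroma"):
        for chan in ("dapi", "panck"):
            stats = glcm(src, region_masks[src], chan)
            for stat in ("contrast", "entropy", "correlation"):
                values[f"{src}_glcm_{stat}_{chan}"] = stats[stat]
    for cls in ("tumor_bud", "pdc"):
        for chan in ("panck", "dapi"):
            stats = glcm(cls, class_masks[cls], chan)
            for stat in ("contrast", "entropy", "correlation"):
                values[f"{cls}_glcm_{stat}_{chan}"] = stats[stat]
    stats = glcm("vessel", vessel_mask, "d240")
    for stat in ("contrast", "entropy", "correlation"):
        values[f"vessel_glcm_{stat}_d240"] = stats[stat]

    for src in ("tumor", "stroma"):
        nucs = nuc_groups[src]
        rounds = [_shape_props(n.mask)[0] for n in nucs[:200]]
        values[f"nucleus_mean_roundness_{src}"] = nan_mean(rounds)
    for cls in OBJECT_CLASSES:
        values[f"{cls}_per_mm2"] = (
            len(class_objs[cls]) / tissue_mm2 if tissue_mm2 > 0 else np.nan
        )
    values["lumen_fraction_pct"] = (
        100.0 * float(lumen_mask.sum()) / tissue_px if tissue_px else np.nan
    )
    stroma_nucs = nuc_groups["stroma"]
    if stroma_nucs and dist_to_tumor is not None:
        values["stroma_nucleus_mean_dist_to_tumor_um"] = float(np.mean([
            dist_to_tumor[int(round(n.centroid[0])), int(round(n.centroid[1]))] * px
            for n in stroma_nucs
        ]))
    else:
        values["stroma_nucleus_mean_dist_to_tumor_um"] = np.nan
    values["bud_total_nuclei"] = sum(o.nucleus_count for o in class_objs["tumor_bud"])
    values["pdc_total_nuclei"] = sum(o.nucleus_count for o in class_objs["pdc"])
    values["vessel_mean_roundness"] = nan_mean([s[0] for s in v_sh])
    values["bud_sum_area_pct_tissue"] = (
        100.0 * values["tumor_bud_sum_area_um2"] / tissue_um2 if tissue_um2 else np.nan
    )
    values["pdc_sum_area_pct_tissue"] = (
        100.0 * values["pdc_sum_area_um2"] / tissue_um2 if tissue_um2 else np.nan
    )

    out = np.array([values[name] for name in manifest.names], dtype=float)
    return out


@dataclass
class FeatureVector:
    """One patient's collated feature vector, aligned to a manifest."""

    patient_id: str
    values: np.ndarray
    manifest: FeatureManifest
    qc_flags: list[str]

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.manifest.names.index(name)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.manifest.names, name=self.patient_id)


def collate_patient(
    field_vectors: list[np.ndarray],
    manifest: FeatureManifest | None = None,
    patient_id: str = "patient",
) -> FeatureVector:
    """Collapse per-field value lists to one patient vector (sum or mean).

    ``sum`` features treat missing fields as 0; ``mean`` features average
    over the fields where the value is present. A feature missing in every
    field falls back to 0 and is QC-flagged, keeping vectors rectangular.
    """
    manifest = manifest or manifest_default()
    if not field_vectors:
        raise ValueError("need at least one field vector")
    arr = np.asarray(field_vectors, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(manifest):
        raise ValueError(
            f"field vectors must all have length {len(manifest)}, got shape {arr.shape}"
        )

    out = np.empty(len(manifest))
    qc: list[str] = []
    is_sum = manifest.collations() == "sum"
    with np.errstate(invalid="ignore"):
        sums = np.nansum(arr, axis=0)
        counts = np.sum(np.isfinite(arr), axis=0)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out[is_sum] = sums[is_sum]
    out[~is_sum] = means[~is_sum]
    all_missing = counts == 0
    for i in np.flatnonzero(all_missing & ~is_sum):
        qc.append(manifest.names[i])
        out[i] = 0.0
    out[all_missing & is_sum] = 0.0
    if qc:
        logger.info("patient %s: %d all-missing features set to 0", patient_id, len(qc))
    return FeatureVector(patient_id, out, manifest, qc)
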