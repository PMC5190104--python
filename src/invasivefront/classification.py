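"""Sub-classification of segmented objects into candidate histopathologic features.

Detached stromal pan-CK objects are classified by their exclusively-assigned
nucleus count: tumor buds (<=4 nuclei, the established small-cluster
definition) versus poorly differentiated clusters (>=5 nuclei). Objects
lying predominantly inside a lymphatic vessel lumen are intravascular:
lymphatic vessel invasion (LVI), or "minimal LVI" when fewer than 5 tumor
cells have invaded the vessel. Field-level scalars — bud/PDC/LVI counts,
summed PDC area, lymphatic vessel density and tumor:stroma ratio — are the
candidate prognostic parameters consumed downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from invasivefront.segmentation import (
    ROI_LUMEN,
    ROI_NO_TISSUE,
    ROI_STROMA,
    ROI_TUMOR,
    SegmentationHierarchy,
    SegmentedObject,
)

logger = logging.getLogger(__name__)


@dataclass
class FeatureClassConfig:
    """Numeric definitions of the candidate features.

    ``bud_max_nuclei``/``pdc_min_nuclei`` follow the conventional <=4 / >=5
    tumor-cell definitions; ``lvi_min_nuclei_full`` separates minimal LVI
    (fewer than 5 intravascular cells) from full LVI. An epithelial object is
    intravascular when at least ``vessel_overlap_fraction`` of its area lies
    in a vessel lumen, and is main-mass epithelium (``tumor_gland``) when at
    least ``tumor_overlap_fraction`` of its area lies in the tumor ROI.
    """

    bud_max_nuclei: int = 4
    pdc_min_nuclei: int = 5
    lvi_min_nuclei_full: int = 5
    vessel_overlap_fraction: float = 0.5
    tumor_overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.bud_max_nuclei >= self.pdc_min_nuclei:
            raise ValueError("bud_max_nuclei must be < pdc_min_nuclei")
        if min(self.bud_max_nuclei, self.pdc_min_nuclei, self.lvi_min_nuclei_full) < 1:
            raise ValueError("nucleus-count thresholds must be positive")
        if not 0 < self.vessel_overlap_fraction <= 1:
            raise ValueError("vessel_overlap_fraction in (0,1]")


@dataclass
class ClassifiedField:
    """Per-object classes and the field-level candidate-feature scalars."""

    object_classes: dict[int, str]           # object id -> class
    n_buds: int
    n_pdc: int
    n_lvi: int
    n_minimal_lvi: int
    n_vessels: int
    area_pdc_um2: float
    lvd_per_mm2: float
    tumor_stroma_pct: float
    n_unresolved: int = 0
    hierarchy: SegmentationHierarchy | None = dc_field(default=None, repr=False)

    def objects_of_class(self, cls: str) -> list[SegmentedObject]:
        if self.hierarchy is None:
            return []
        return [o for o in self.hierarchy.objects if self.object_classes.get(o.id) == cls]


def tumor_stroma_ratio(roi: np.ndarray) -> float:
    """Tumor area as a percentage of total tissue area (tumor+stroma+lumen)."""
    tissue = int((roi != ROI_NO_TISSUE).sum())
    if tissue == 0:
        raise ValueError("no tissue pixels: tumor:stroma ratio undefined")
    return 100.0 * float((roi == ROI_TUMOR).sum()) / tissue


def compute_lvd(cf_or_count, tissue_area_mm2: float) -> float:
    """Lymphatic vessel density: vessels per mm^2 of analyzed tissue.

    Accepts either a vessel count or a :class:`ClassifiedField`.
    """
    if tissue_area_mm2 <= 0:
        raise ValueError("tissue area must be positive for LVD")
    n = cf_or_count.n_vessels if isinstance(cf_or_count, ClassifiedField) else cf_or_count
    return n / tissue_area_mm2


def area_pdc(cf: ClassifiedField) -> float:
    """Summed cross-sectional area of all PDC-class objects, in um^2."""
    return cf.area_pdc_um2


def classify_objects(
    h: SegmentationHierarchy,
    cfg: FeatureClassConfig | None = None,
) -> ClassifiedField:
    """Assign one class per epithelial object and compute field scalars.

    Objects with zero assigned nuclei (cytokeratin debris) are classed
    ``unresolved`` and excluded from all counts.
    """
    cfg = cfg or FeatureClassConfig()
    px_area = h.pixel_size_um ** 2
    roi = h.roi_map

    lumen_raster = np.zeros(roi.shape, dtype=bool)
    for v in h.vessels:
        if v.lumen_mask is not None:
            lumen_raster |= v.lumen_mask

    classes: dict[int, str] = {}
    n_buds = n_pdc = n_lvi = n_min = n_unres = 0
    area_pdc_um2 = 0.0
    tumor_roi = roi == ROI_TUMOR

    for obj in h.epithelial_objects:
        area = obj.area_px
        if area == 0:
            classes[obj.id] = "unresolved"
            n_unres += 1
            continue
        lumen_frac = float((obj.mask & lumen_raster).sum()) / area
        tumor_frac = float((obj.mask & tumor_roi).sum()) / area
        if lumen_frac >= cfg.vessel_overlap_fraction:
            if obj.nucleus_count == 0:
                classes[obj.id] = "unresolved"
                n_unres += 1
            elif obj.nucleus_count < cfg.lvi_min_nuclei_full:
                classes[obj.id] = "minimal_lvi"
                n_min += 1
            else:
                classes[obj.id] = "lvi"
                n_lvi += 1
        elif tumor_frac >= cfg.tumor_overlap_fraction:
            classes[obj.id] = "tumor_gland"
        elif obj.nucleus_count == 0:
            classes[obj.id] = "unresolved"
            n_unres += 1
            logger.info("object %d has no nuclei: excluded as unresolved", obj.id)
        elif obj.nucleus_count <= cfg.bud_max_nuclei:
            classes[obj.id] = "tumor_bud"
            n_buds += 1
        else:
            classes[obj.id] = "pdc"
            n_pdc += 1
            area_pdc_um2 += obj.area_um2

    n_vessels = len(h.vessels)
    for v in h.vessels:
        classes[v.id] = "vessel"

    tissue_px = int((roi != ROI_NO_TISSUE).sum())
    tissue_mm2 = tissue_px * px_area / 1e6
    lvd = compute_lvd(n_vessels, tissue_mm2) if tissue_mm2 > 0 else 0.0
    ts_pct = tumor_stroma_ratio(roi) if tissue_px else 0.0

    return ClassifiedField(
        object_classes=classes,
        n_buds=n_buds,
        n_pdc=n_pdc,
        n_lvi=n_lvi,
        n_minimal_lvi=n_min,
        n_vessels=n_vessels,
        area_pdc_um2=area_pdc_um2,
        lvd_per_mm2=lvd,
        tumor_stroma_pct=ts_pct,
        n_unresolved=n_unres,
        hierarchy=h,
    )
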