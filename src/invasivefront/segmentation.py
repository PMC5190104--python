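"""Three-level hierarchical segmentation of immunofluorescence fields.

The hierarchy mirrors routine invasive-front image analysis:

* **ROI level** — every pixel is assigned to exactly one of four classes:
  ``tumor`` (the main pan-cytokeratin-dense mass), ``lumen_necrosis``
  (pan-CK-negative holes enclosed by tumor), ``stroma`` (tissue outside the
  tumor mass) and ``no_tissue`` (background).
* **Object level** — connected pan-CK-positive components restricted to the
  stroma ROI (detached epithelial objects: candidate buds/PDCs/intravascular
  clusters) and D2-40-positive lymphatic vessels reconstructed as ring+lumen
  regions.
* **Nucleus level** — DAPI blob segmentation with distance-transform
  watershed declumping; every nucleus is exclusively assigned to exactly one
  parent (a segmented object, else its centroid's ROI class).

Segmentation here is rule-based (global thresholds + morphology) with all
thresholds exposed in :class:`SegmentationConfig`; the downstream contract is
only the four-class partition and the object/nucleus inventories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

# ROI label codes (fixed; RoiMap rasters use these values)
ROI_NO_TISSUE = 0
ROI_TUMOR = 1
ROI_STROMA = 2
ROI_LUMEN = 3

ROI_NAMES = {
    ROI_NO_TISSUE: "no_tissue",
    ROI_TUMOR: "tumor",
    ROI_STROMA: "stroma",
    ROI_LUMEN: "lumen_necrosis",
}


@dataclass(frozen=True)
class FieldImage:
    """One field of view: three co-registered greyscale channel rasters.

    Attributes
    ----------
    dapi, panck, d240 : ndarray
        2-D nonnegative intensity rasters of identical shape (nuclear
        counterstain, pan-cytokeratin, lymphatic endothelium).
    pixel_size_um : float
        Physical pixel edge length in micrometres.
    """

    dapi: np.ndarray
    panck: np.ndarray
    d240: np.ndarray
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        if not (self.dapi.shape == self.panck.shape == self.d240.shape):
            raise ValueError("channel rasters must be co-registered (equal shape)")
        if self.dapi.ndim != 2:
            raise ValueError("channel rasters must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for name in ("dapi", "panck", "d240"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} raster contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dapi.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2


@dataclass
class SegmentationConfig:
    """Tunable thresholds for the rule-based segmentation.

    Intensity thresholds are in raw camera units; defaults suit the contrast
    model of the synthetic generator (bright marker ~200, tissue background
    ~12-15, slide background ~5).
    """

    tissue_smooth_sigma: float = 2.0     # px, smoothing before tissue detection
    tissue_threshold: float = 10.0       # smoothed pan-CK above this = tissue
    panck_threshold: float = 100.0       # pan-CK positive (epithelium)
    dapi_threshold: float = 100.0        # DAPI positive (nucleus)
    d240_threshold: float = 100.0        # D2-40 positive (lymphatic rim)
    mass_min_area_um2: float = 10_000.0  # pan-CK component at least this big = tumor mass
    min_object_px: int = 20              # discard smaller object-level components
    min_vessel_px: int = 30
    nucleus_radius_px: float = 3.0       # expected nucleus radius, drives declumping
    min_nucleus_px: int = 4


@dataclass
class SegmentedObject:
    """One object-level segment (stromal epithelial object or vessel)."""

    id: int
    layer: str                     # "epithelial_object" | "vessel"
    mask: np.ndarray               # boolean, full-frame
    area_um2: float
    centroid: tuple[float, float]  # (row, col)
    parent_roi: str
    nucleus_count: int = 0
    lumen_mask: np.ndarray | None = None  # vessels only: enclosed lumen

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class Nucleus:
    id: int
    mask: np.ndarray
    centroid: tuple[float, float]
    parent: str | int | None = None  # object id or ROI class name


@dataclass
class SegmentationHierarchy:
    """ROI map + objects + nuclei with exclusive parent links."""

    roi_map: np.ndarray
    objects: list[SegmentedObject]
    nuclei: list[Nucleus]
    pixel_size_um: float = 0.5
    qc: dict = field(default_factory=dict)

    @property
    def epithelial_objects(self) -> list[SegmentedObject]:
        return [o for o in self.objects if o.layer == "epithelial_object"]

    @property
    def vessels(self) -> list[SegmentedObject]:
        return [o for o in self.objects if o.layer == "vessel"]

    def nuclei_per_parent(self) -> dict:
        tally: dict = {}
        for nuc in self.nuclei:
            tally[nuc.parent] = tally.get(nuc.parent, 0) + 1
        return tally


def segment_rois(field: FieldImage, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Partition the field into the four ROI classes.

    Tissue is detected from smoothed pan-CK signal (stromal background
    autofluorescence is above slide background); the tumor mass is the union
    of pan-CK components exceeding ``mass_min_area_um2``; pan-CK-negative
    holes enclosed by the mass become ``lumen_necrosis``; remaining tissue is
    ``stroma``.

    Returns a uint8 raster of ROI codes. Every pixel gets exactly one class.
    """
    cfg = cfg or SegmentationConfig()
    px_area = field.pixel_area_um2

    smoothed = ndi.gaussian_filter(field.panck.astype(float), cfg.tissue_smooth_sigma)
    tissue = smoothed > cfg.tissue_threshold
    # lumen/necrosis and vessel lumens are pan-CK-dark but sit inside tissue
    tissue = ndi.binary_fill_holes(tissue)
    tissue = morphology.remove_small_objects(tissue, max_size=cfg.min_object_px - 1)

    if not tissue.any():
        logger.warning("empty field: no tissue detected, ROI map is all no_tissue")
        return np.full(field.shape, ROI_NO_TISSUE, dtype=np.uint8)

    epith = field.panck > cfg.panck_threshold
    labels = measure.label(epith, connectivity=2)
    min_px = int(round(cfg.mass_min_area_um2 / px_area))
    sizes = np.bincount(labels.ravel())
    big = np.flatnonzero(sizes >= min_px)
    big = big[big != 0]
    tumor = np.isin(labels, big)

    tumor_filled = ndi.binary_fill_holes(tumor)
    lumen = tumor_filled & ~tumor & tissue

    roi = np.full(field.shape, ROI_NO_TISSUE, dtype=np.uint8)
    roi[tissue] = ROI_STROMA
    roi[tumor & tissue] = ROI_TUMOR
    roi[lumen] = ROI_LUMEN
    return roi


def detect_objects(
    field: FieldImage,
    roi: np.ndarray,
    cfg: SegmentationConfig | None = None,
) -> list[SegmentedObject]:
    """Object-level segmentation: stromal pan-CK objects and D2-40 vessels.

    Epithelial objects are connected pan-CK-positive components restricted to
    the stroma ROI; components below ``min_object_px`` are discarded. Vessels
    are D2-40-positive rings, each reconstructed with its enclosed lumen.
    """
    cfg = cfg or SegmentationConfig()
    px_area = field.pixel_area_um2
    objects: list[SegmentedObject] = []
    next_id = 1

    epi_mask = (field.panck > cfg.panck_threshold) & (roi == ROI_STROMA)
    labels = measure.label(epi_mask, connectivity=2)
    for region in measure.regionprops(labels):
        if region.area < cfg.min_object_px:
            continue
        mask = labels == region.label
        objects.append(
            SegmentedObject(
                id=next_id,
                layer="epithelial_object",
                mask=mask,
                area_um2=float(region.area) * px_area,
                centroid=tuple(region.centroid),
                parent_roi="stroma",
            )
        )
        next_id += 1

    ring_mask = field.d240 > cfg.d240_threshold
    ring_labels = measure.label(ring_mask, connectivity=2)
    for region in measure.regionprops(ring_labels):
        if region.area < cfg.min_vessel_px:
            continue
        ring = ring_labels == region.label
        filled = ndi.binary_fill_holes(ring)
        lumen = filled & ~ring
        r, c = np.nonzero(filled)
        objects.append(
            SegmentedObject(
                id=next_id,
                layer="vessel",
                mask=filled,
                area_um2=float(filled.sum()) * px_area,
                centroid=(float(r.mean()), float(c.mean())),
                parent_roi=ROI_NAMES[int(np.bincount(roi[filled]).argmax())],
                lumen_mask=lumen,
            )
        )
        next_id += 1

    return objects


def segment_nuclei(field: FieldImage, cfg: SegmentationConfig | None = None) -> list[Nucleus]:
    """DAPI blob segmentation with distance-transform watershed declumping.

    Touching nuclei whose centres are at least ~1.5x the expected nucleus
    radius apart are split; per-nucleus pixel sets are disjoint by
    construction of the watershed.
    """
    cfg = cfg or SegmentationConfig()
    mask = field.dapi > cfg.dapi_threshold
    if not mask.any():
        return []
    mask = morphology.remove_small_objects(mask, max_size=cfg.min_nucleus_px - 1)
    if not mask.any():
        return []

    distance = ndi.distance_transform_edt(mask)
    min_dist = max(2, int(round(1.4 * cfg.nucleus_radius_px)))
    peaks = peak_local_max(distance, min_distance=min_dist, labels=mask, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask)

    nuclei: list[Nucleus] = []
    for region in measure.regionprops(labels):
        if region.area < cfg.min_nucleus_px:
            continue
        nuclei.append(
            Nucleus(
                id=region.label,
                mask=labels == region.label,
                centroid=tuple(region.centroid),
            )
        )
    return nuclei


def assign_hierarchy(
    roi: np.ndarray,
    objects: list[SegmentedObject],
    nuclei: list[Nucleus],
    pixel_size_um: float = 0.5,
) -> SegmentationHierarchy:
    """Exclusively assign every nucleus to one parent and tally counts.

    A nucleus belongs to the unique object containing its centroid pixel
    (epithelial objects take precedence over vessels where they overlap,
    i.e. intravascular tumor clusters), otherwise to its centroid's ROI
    class. Nuclei landing on ``no_tissue`` are counted in a QC tally.
    """
    epi_raster = np.zeros(roi.shape, dtype=np.int32)
    vessel_raster = np.zeros(roi.shape, dtype=np.int32)
    for obj in objects:
        if obj.layer == "epithelial_object":
            epi_raster[obj.mask] = obj.id
        else:
            vessel_raster[obj.mask] = obj.id

    by_id = {obj.id: obj for obj in objects}
    qc_no_tissue = 0
    for nuc in nuclei:
        r = int(round(nuc.centroid[0]))
        c = int(round(nuc.centroid[1]))
        r = min(max(r, 0), roi.shape[0] - 1)
        c = min(max(c, 0), roi.shape[1] - 1)
        if epi_raster[r, c]:
            nuc.parent = int(epi_raster[r, c])
            by_id[nuc.parent].nucleus_count += 1
        elif vessel_raster[r, c]:
            nuc.parent = int(vessel_raster[r, c])
            by_id[nuc.parent].nucleus_count += 1
        else:
            nuc.parent = ROI_NAMES[int(roi[r, c])]
            if nuc.parent == "no_tissue":
                qc_no_tissue += 1
    if qc_no_tissue:
        logger.info("%d nuclei assigned to no_tissue", qc_no_tissue)

    return SegmentationHierarchy(
        roi_map=roi,
        objects=objects,
        nuclei=nuclei,
        pixel_size_um=pixel_size_um,
        qc={"nuclei_on_no_tissue": qc_no_tissue},
    )


def segment_field(field: FieldImage, cfg: SegmentationConfig | None = None) -> SegmentationHierarchy:
    """Run the full three-level segmentation on one field of view."""
    cfg = cfg or SegmentationConfig()
    roi = segment_rois(field, cfg)
    objects = detect_objects(field, roi, cfg)
    nuclei = segment_nuclei(field, cfg)
    return assign_hierarchy(roi, objects, nuclei, pixel_size_um=field.pixel_size_um)
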