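"""Seeded synthetic immunofluorescence fields and survival cohorts.

Every downstream stage of the pipeline is exercised against data produced
here, with exact ground truth:

* :func:`generate_field` renders one field of view in the three-channel
  convention (DAPI / pan-CK / D2-40) with a tumor mass, stroma, enclosed
  lumen holes, detached epithelial clusters of controlled nucleus counts
  (tumor buds <=4 nuclei, PDCs >=5), and elliptical lymphatic vessel rings
  with or without intravascular tumor cells.
* :func:`generate_section` bundles 15 such fields into one "tissue section"
  per patient, the acquisition unit used throughout.
* :func:`generate_cohort` draws survival cohorts from an exponential
  proportional-hazards model with administrative censoring, planting hazard
  ratios on binary covariates and continuous features around group means.

Shapes are deliberately simple (Gaussian-blurred nucleus discs, cluster
masks as unions of nucleus-centred discs, elliptical vessel rings): they
exercise the segmentation contract, not histology realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw

from invasivefront.segmentation import (
    FieldImage,
    ROI_LUMEN,
    ROI_NO_TISSUE,
    ROI_STROMA,
    ROI_TUMOR,
)

# rendered intensity model (camera units)
_BG = 5.0            # slide background
_STROMA_CK = 15.0    # stromal autofluorescence in pan-CK channel
_LUMEN_CK = 6.0
_TISSUE_DAPI = 12.0
_MARKER = 200.0      # bright positive signal in any channel
_BLUR_SIGMA = 1.0

_NUCLEUS_SPACING = None  # derived: 2*r + 2


class FieldTooCrowdedError(RuntimeError):
    """Raised when the requested objects cannot be placed without overlap."""


@dataclass
class FieldSpec:
    """Recipe for one synthetic field of view.

    ``bud_nucleus_counts`` must have length ``n_buds`` with entries in 1..4;
    ``pdc_nucleus_counts`` length ``n_pdc`` with entries >=5. ``lvi_events``
    lists ``(vessel_index, intravascular_nucleus_count)`` pairs; fewer than 5
    intravascular nuclei is a "minimal LVI" event.
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.5
    n_buds: int = 0
    bud_nucleus_counts: list[int] = dc_field(default_factory=list)
    n_pdc: int = 0
    pdc_nucleus_counts: list[int] = dc_field(default_factory=list)
    n_vessels: int = 0
    lvi_events: list[tuple[int, int]] = dc_field(default_factory=list)
    tumor_fraction: float = 0.4
    lumen_fraction: float = 0.05
    noise_sd: float = 4.0
    nucleus_radius_px: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.bud_nucleus_counts) != self.n_buds:
            raise ValueError("bud_nucleus_counts length must equal n_buds")
        if len(self.pdc_nucleus_counts) != self.n_pdc:
            raise ValueError("pdc_nucleus_counts length must equal n_pdc")
        if any(not 1 <= c <= 4 for c in self.bud_nucleus_counts):
            raise ValueError("tumor buds have 1-4 nuclei")
        if any(c < 5 for c in self.pdc_nucleus_counts):
            raise ValueError("PDCs have >=5 nuclei")
        for vi, count in self.lvi_events:
            if not 0 <= vi < self.n_vessels:
                raise ValueError(f"lvi vessel index {vi} out of range")
            if count < 1:
                raise ValueError("lvi events need >=1 intravascular nucleus")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction in [0,1]")
        if not 0.0 <= self.lumen_fraction <= 1.0:
            raise ValueError("lumen_fraction in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class ObjectRecord:
    """Ground-truth record for one planted object."""

    id: int
    cls: str                      # tumor_bud | pdc | lvi | minimal_lvi | vessel
    nucleus_count: int
    area_px: int
    area_um2: float
    centroid: tuple[float, float]


@dataclass
class GroundTruth:
    """Exact per-field ground truth emitted alongside the rendered rasters."""

    roi: np.ndarray                 # uint8 ROI codes
    epithelial_labels: np.ndarray   # int32, planted cluster ids
    vessel_labels: np.ndarray       # int32, ring+lumen footprints
    nucleus_labels: np.ndarray      # int32, all planted nuclei
    objects: list[ObjectRecord]
    pixel_size_um: float

    @property
    def counts(self) -> dict[str, int]:
        tally = {"tumor_bud": 0, "pdc": 0, "lvi": 0, "minimal_lvi": 0, "vessel": 0}
        for rec in self.objects:
            tally[rec.cls] += 1
        return tally

    @property
    def area_pdc_um2(self) -> float:
        return float(sum(r.area_um2 for r in self.objects if r.cls == "pdc"))

    @property
    def n_nuclei(self) -> int:
        return int(self.nucleus_labels.max())

    def tumor_stroma_pct(self) -> float:
        tumor = int((self.roi == ROI_TUMOR).sum())
        tissue = int((self.roi != ROI_NO_TISSUE).sum())
        return 100.0 * tumor / tissue if tissue else 0.0

    def to_json_dict(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size_um,
            "counts": self.counts,
            "area_pdc_um2": self.area_pdc_um2,
            "n_nuclei": self.n_nuclei,
            "tumor_stroma_pct": self.tumor_stroma_pct(),
            "objects": [
                {
                    "id": r.id,
                    "class": r.cls,
                    "nucleus_count": r.nucleus_count,
                    "area_px": r.area_px,
                    "area_um2": r.area_um2,
                    "centroid": list(r.centroid),
                }
                for r in self.objects
            ],
        }


def _hex_lattice_offsets(n: int, spacing: float) -> np.ndarray:
    """First *n* points of a hexagonal lattice sorted by distance to origin.

    Guarantees pairwise separation >= spacing, so nucleus discs of radius
    < spacing/2 never touch within a cluster.
    """
    pts = []
    for j in range(-8, 9):
        for i in range(-8, 9):
            x = i * spacing + (spacing / 2 if j % 2 else 0.0)
            y = j * spacing * np.sqrt(3) / 2
            pts.append((y, x))
    pts = np.array(pts)
    order = np.argsort(np.hypot(pts[:, 0], pts[:, 1]), kind="stable")
    if n > len(pts):
        raise FieldTooCrowdedError(f"cannot lay out {n} nuclei in one cluster")
    return pts[order[:n]]


def _place_centers(
    rng: np.random.Generator,
    footprints: list[float],
    row_range: tuple[float, float],
    col_range: tuple[float, float],
    gap: float = 4.0,
    max_tries: int = 400,
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping circular footprints in a box."""
    placed: list[tuple[float, float, float]] = []
    for radius in footprints:
        lo_r, hi_r = row_range[0] + radius, row_range[1] - radius
        lo_c, hi_c = col_range[0] + radius, col_range[1] - radius
        if hi_r <= lo_r or hi_c <= lo_c:
            raise FieldTooCrowdedError("field too crowded: footprint exceeds placement box")
        for _ in range(max_tries):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if all(np.hypot(r - pr, c - pc) >= radius + prad + gap for pr, pc, prad in placed):
                placed.append((r, c, radius))
                break
        else:
            raise FieldTooCrowdedError(
                f"field too crowded: failed to place object of radius {radius:.0f}px"
            )
    return [(r, c) for r, c, _ in placed]


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = draw.disk(center, radius, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def generate_field(spec: FieldSpec) -> tuple[FieldImage, GroundTruth]:
    """Render one field of view and its exact ground truth.

    Deterministic for a fixed spec (including seed). Raises
    :class:`FieldTooCrowdedError` if the requested objects cannot be placed
    without overlap after bounded retries — never silently truncates.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_size_px
    shape = (H, W)
    r_nuc = spec.nucleus_radius_px
    spacing = 2 * r_nuc + 2
    px_area = spec.pixel_size_um ** 2

    # --- ROI geometry: top no-tissue band, tumor block on the left ----------
    band = int(round(0.08 * H))
    tumor_w = int(round(spec.tumor_fraction * W))
    roi = np.full(shape, ROI_NO_TISSUE, dtype=np.uint8)
    roi[band:, :] = ROI_STROMA
    tumor_mask = np.zeros(shape, dtype=bool)
    tumor_mask[band:, :tumor_w] = True

    # carve enclosed lumen holes inside the tumor mass
    lumen_mask = np.zeros(shape, dtype=bool)
    if spec.lumen_fraction > 0 and tumor_mask.sum() > 0:
        target = spec.lumen_fraction * tumor_mask.sum()
        hole_r = 12.0
        n_holes = max(1, int(round(target / (np.pi * hole_r**2))))
        margin = hole_r + 6
        if tumor_w > 2 * margin and (H - band) > 2 * margin:
            centers = _place_centers(
                rng,
                [hole_r] * n_holes,
                (band + 6, H - 6),
                (6, tumor_w - 6),
                gap=6.0,
            )
            for c in centers:
                lumen_mask |= _disc_mask(shape, c, hole_r)
    tumor_mask &= ~lumen_mask
    roi[tumor_mask] = ROI_TUMOR
    roi[lumen_mask] = ROI_LUMEN

    # --- detached objects & vessels in the stroma ---------------------------
    cluster_counts = list(spec.bud_nucleus_counts) + list(spec.pdc_nucleus_counts)
    cluster_cls = ["tumor_bud"] * spec.n_buds + ["pdc"] * spec.n_pdc
    cluster_offsets = [_hex_lattice_offsets(n, spacing) for n in cluster_counts]
    cluster_R = [
        (np.max(np.hypot(off[:, 0], off[:, 1])) if len(off) > 1 else 0.0) + r_nuc + 3
        for off in cluster_offsets
    ]

    lvi_by_vessel = dict(spec.lvi_events)
    vessel_inner = []
    for vi in range(spec.n_vessels):
        n_in = lvi_by_vessel.get(vi, 0)
        if n_in:
            off = _hex_lattice_offsets(n_in, spacing)
            lumen_r = np.max(np.hypot(off[:, 0], off[:, 1])) + r_nuc + 3
        else:
            off = np.zeros((0, 2))
            lumen_r = 8.0
        vessel_inner.append((max(9.0, lumen_r), max(7.0, 0.75 * max(9.0, lumen_r)), off))
    ring_thick = 4.0
    vessel_R = [a + ring_thick + 1 for a, _, _ in vessel_inner]

    stroma_box_rows = (band + 8.0, H - 8.0)
    stroma_box_cols = (tumor_w + 10.0, W - 8.0)
    centers = _place_centers(
        rng, cluster_R + vessel_R, stroma_box_rows, stroma_box_cols, gap=5.0
    )
    cluster_centers = centers[: len(cluster_R)]
    vessel_centers = centers[len(cluster_R):]

    epi_labels = np.zeros(shape, dtype=np.int32)
    vessel_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    ring_mask_all = np.zeros(shape, dtype=bool)
    records: list[ObjectRecord] = []
    nucleus_centers: list[tuple[float, float]] = []
    next_obj = 1
    next_nuc = 1

    def _add_nucleus(center: tuple[float, float]) -> None:
        nonlocal next_nuc
        m = _disc_mask(shape, center, r_nuc)
        nucleus_labels[m] = next_nuc
        nucleus_centers.append(center)
        next_nuc += 1

    # detached clusters (buds, PDCs)
    for (cy, cx), offsets, cls in zip(cluster_centers, cluster_offsets, cluster_cls):
        jitter = rng.uniform(-0.5, 0.5, size=offsets.shape)
        pts = offsets + jitter + np.array([cy, cx])
        cluster_mask = np.zeros(shape, dtype=bool)
        for p in pts:
            cluster_mask |= _disc_mask(shape, tuple(p), r_nuc + 2)
            _add_nucleus(tuple(p))
        epi_labels[cluster_mask] = next_obj
        area = int(cluster_mask.sum())
        rr, cc = np.nonzero(cluster_mask)
        records.append(
            ObjectRecord(next_obj, cls, len(pts), area, area * px_area,
                         (float(rr.mean()), float(cc.mean())))
        )
        next_obj += 1

    # vessels (elliptical rings) and intravascular clusters
    for vi, ((cy, cx), (ra, rb, offsets)) in enumerate(zip(vessel_centers, vessel_inner)):
        rot = rng.uniform(0, np.pi)
        outer = np.zeros(shape, dtype=bool)
        rr, cc = draw.ellipse(cy, cx, ra + ring_thick, rb + ring_thick,
                              shape=shape, rotation=rot)
        outer[rr, cc] = True
        inner = np.zeros(shape, dtype=bool)
        rr, cc = draw.ellipse(cy, cx, ra, rb, shape=shape, rotation=rot)
        inner[rr, cc] = True
        ring = outer & ~inner
        ring_mask_all |= ring
        vessel_labels[outer] = next_obj
        area = int(outer.sum())
        records.append(
            ObjectRecord(next_obj, "vessel", 0, area, area * px_area, (cy, cx))
        )
        vessel_id = next_obj
        next_obj += 1

        n_in = lvi_by_vessel.get(vi, 0)
        if n_in:
            pts = offsets + np.array([cy, cx])
            cluster_mask = np.zeros(shape, dtype=bool)
            for p in pts:
                cluster_mask |= _disc_mask(shape, tuple(p), r_nuc + 2)
                _add_nucleus(tuple(p))
            cluster_mask &= inner  # intravascular epithelium stays inside the lumen
            epi_labels[cluster_mask] = next_obj
            area = int(cluster_mask.sum())
            rr, cc = np.nonzero(cluster_mask)
            cls = "minimal_lvi" if n_in < 5 else "lvi"
            records.append(
                ObjectRecord(next_obj, cls, n_in, area, area * px_area,
                             (float(rr.mean()), float(cc.mean())))
            )
            next_obj += 1

    # --- background nuclei: tumor mass (dense) and stroma (sparse) ----------
    def _scatter_grid(mask: np.ndarray, step: int, jitter: float) -> None:
        occupied = (epi_labels > 0) | (vessel_labels > 0) | ring_mask_all
        occupied = ndi.binary_dilation(occupied, iterations=int(spacing))
        for gy in np.arange(band + step, H - step, step, dtype=float):
            for gx in np.arange(step, W - step, step, dtype=float):
                y = gy + rng.uniform(-jitter, jitter)
                x = gx + rng.uniform(-jitter, jitter)
                yi, xi = int(round(y)), int(round(x))
                if not (0 <= yi < H and 0 <= xi < W):
                    continue
                if not mask[yi, xi] or occupied[yi, xi]:
                    continue
                if nucleus_labels[
                    max(yi - spacing, 0):yi + spacing, max(xi - spacing, 0):xi + spacing
                ].any():
                    continue
                _add_nucleus((y, x))

    inner_tumor = ndi.binary_erosion(tumor_mask, iterations=r_nuc + 1)
    _scatter_grid(inner_tumor, step=12, jitter=2.0)
    stroma_mask = roi == ROI_STROMA
    inner_stroma = ndi.binary_erosion(stroma_mask, iterations=r_nuc + 1)
    _scatter_grid(inner_stroma, step=28, jitter=3.0)

    # --- render the three channels ------------------------------------------
    panck = np.full(shape, _BG)
    panck[roi != ROI_NO_TISSUE] = _STROMA_CK
    panck[roi == ROI_LUMEN] = _LUMEN_CK
    panck[tumor_mask] = _MARKER
    panck[epi_labels > 0] = _MARKER

    dapi = np.full(shape, _BG * 0.6)
    dapi[roi != ROI_NO_TISSUE] = _TISSUE_DAPI
    dapi[roi == ROI_LUMEN] = _LUMEN_CK
    dapi[nucleus_labels > 0] = _MARKER

    d240 = np.full(shape, _BG * 0.8)
    d240[ring_mask_all] = _MARKER

    channels = []
    for ideal in (dapi, panck, d240):
        img = ndi.gaussian_filter(ideal, _BLUR_SIGMA)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=shape)
        channels.append(np.clip(img, 0.0, None).astype(np.float32))

    field = FieldImage(
        dapi=channels[0], panck=channels[1], d240=channels[2],
        pixel_size_um=spec.pixel_size_um,
    )
    truth = GroundTruth(
        roi=roi,
        epithelial_labels=epi_labels,
        vessel_labels=vessel_labels,
        nucleus_labels=nucleus_labels,
        objects=records,
        pixel_size_um=spec.pixel_size_um,
    )
    return field, truth


def default_field_spec(seed: int, **overrides) -> FieldSpec:
    """A randomized but reproducible field recipe for one field of view.

    Object counts are drawn from modest Poisson-like ranges typical of an
    invasive-front field; all randomness derives from *seed*.
    """
    rng = np.random.default_rng(seed)
    n_buds = int(rng.integers(0, 4))
    n_pdc = int(rng.integers(0, 3))
    n_vessels = int(rng.integers(0, 3))
    lvi_events = []
    if n_vessels and rng.random() < 0.4:
        vi = int(rng.integers(0, n_vessels))
        lvi_events = [(vi, int(rng.integers(2, 8)))]
    defaults = dict(
        n_buds=n_buds,
        bud_nucleus_counts=[int(rng.integers(1, 5)) for _ in range(n_buds)],
        n_pdc=n_pdc,
        pdc_nucleus_counts=[int(rng.integers(5, 10)) for _ in range(n_pdc)],
        n_vessels=n_vessels,
        lvi_events=lvi_events,
        tumor_fraction=float(rng.uniform(0.3, 0.5)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    defaults.update(overrides)
    return FieldSpec(**defaults)


def default_section_specs(seed: int, n_fields: int = 15, **overrides) -> list[FieldSpec]:
    """Field recipes for one tissue section (15 fields by default)."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_fields)]
    return [default_field_spec(s, **overrides) for s in child_seeds]


def generate_section(
    section_spec: list[FieldSpec],
) -> list[tuple[FieldImage, GroundTruth]]:
    """Generate an ordered list of fields forming one tissue section."""
    return [generate_field(spec) for spec in section_spec]


def write_field(
    out_dir: str | Path, patient: str, field_idx: int,
    field: FieldImage, truth: GroundTruth | None = None,
) -> list[Path]:
    """Export a field as three greyscale TIFFs plus a JSON ground-truth sidecar."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for chan, arr in (("dapi", field.dapi), ("cy3", field.panck), ("cy5", field.d240)):
        path = out_dir / f"{patient}_{field_idx:02d}_{chan}.tif"
        tifffile.imwrite(path, np.clip(arr, 0, 65535).astype(np.uint16))
        written.append(path)
    if truth is not None:
        sidecar = out_dir / f"{patient}_{field_idx:02d}_truth.json"
        sidecar.write_text(json.dumps(truth.to_json_dict(), indent=1))
        written.append(sidecar)
    return written


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

@dataclass
class FeatureEffect:
    """Continuous feature drawn around group means set by a binary driver.

    With ``driver=None`` the feature is pure noise around ``low_mean``.
    """

    driver: str | None
    low_mean: float
    high_mean: float
    sd: float


@dataclass
class CohortSpec:
    """Recipe for a synthetic survival cohort.

    Event times are exponential with per-patient hazard
    ``baseline_hazard * prod(hr_map[c] ** covariate_c)`` and administrative
    censoring at ``censor_time_months`` — the minimal generating model
    consistent with the proportional-hazards analyses downstream.
    """

    n_patients: int = 134
    baseline_hazard: float = 0.004          # events per month
    hr_map: dict[str, float] = dc_field(default_factory=dict)
    covariate_prevalence: dict[str, float] = dc_field(default_factory=dict)
    censor_time_months: float = 60.0
    feature_effects: dict[str, FeatureEffect] = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        if self.baseline_hazard <= 0 or self.censor_time_months <= 0:
            raise ValueError("baseline hazard and censor time must be positive")
        if any(hr <= 0 for hr in self.hr_map.values()):
            raise ValueError("hazard ratios must be positive")
        if any(not 0 <= p <= 1 for p in self.covariate_prevalence.values()):
            raise ValueError("prevalences must lie in [0,1]")


def generate_cohort(spec: CohortSpec) -> list["PatientRecord"]:
    """Draw a cohort of :class:`~invasivefront.survival.PatientRecord`.

    Binary covariates are independent Bernoulli draws; the special covariate
    names ``pT4`` and ``poor_differentiation`` additionally populate the
    clinical ``pt_stage`` and ``differentiation`` fields (non-poor patients
    split 30/70 between well and moderate differentiation).
    """
    from invasivefront.survival import PatientRecord

    rng = np.random.default_rng(spec.seed)
    names = sorted(set(spec.hr_map) | set(spec.covariate_prevalence))
    records: list[PatientRecord] = []
    for i in range(spec.n_patients):
        cov = {
            name: int(rng.random() < spec.covariate_prevalence.get(name, 0.5))
            for name in names
        }
        hazard = spec.baseline_hazard
        for name, hr in spec.hr_map.items():
            hazard *= hr ** cov.get(name, 0)
        t_event = rng.exponential(1.0 / hazard)
        time = min(t_event, spec.censor_time_months)
        event = int(t_event <= spec.censor_time_months)

        pt_stage = "pT4" if cov.get("pT4", 0) else "pT3"
        if cov.get("poor_differentiation", 0):
            differentiation = "poor"
        else:
            differentiation = "well" if rng.random() < 0.3 else "moderate"

        feats = {}
        for fname, eff in spec.feature_effects.items():
            group_high = cov.get(eff.driver, 0) if eff.driver else 0
            mean = eff.high_mean if group_high else eff.low_mean
            feats[fname] = float(rng.normal(mean, eff.sd))

        records.append(
            PatientRecord(
                id=f"P{i:04d}",
                time_months=float(time),
                event=event,
                pt_stage=pt_stage,
                differentiation=differentiation,
                covariates={k: v for k, v in cov.items()
                            if k not in ("pT4", "poor_differentiation")},
                features=feats,
            )
        )
    return records


def study_cohort_spec(seed: int = 0, n_patients: int = 134) -> CohortSpec:
    """Default cohort emulating a stage II validation cohort.

    Prevalences follow the published cohort composition (pT4 in roughly a
    quarter of patients, about half above the AreaPDC cut-off); planted
    hazard ratios match the reported univariate effects (AreaPDC ~4, pT4
    ~4.26); baseline hazard and 60-month administrative censoring give an
    event fraction near one quarter.
    """
    return CohortSpec(
        n_patients=n_patients,
        baseline_hazard=0.0025,
        hr_map={"area_pdc_high": 4.0, "pT4": 4.26, "poor_differentiation": 2.0},
        covariate_prevalence={
            "area_pdc_high": 65 / 134,
            "pT4": 32 / 134,
            "poor_differentiation": 0.15,
        },
        censor_time_months=60.0,
        feature_effects={
            "area_pdc_um2": FeatureEffect("area_pdc_high", 15_000.0, 70_000.0, 9_000.0),
        },
        seed=seed,
    )


def cohort_to_frame(records: list) -> pd.DataFrame:
    """Flatten patient records to one row per patient."""
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "time_months": r.time_months,
            "event": r.event,
            "pt_stage": r.pt_stage,
            "differentiation": r.differentiation,
        }
        row.update(r.covariates)
        row.update(r.features)
        rows.append(row)
    return pd.DataFrame(rows)
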