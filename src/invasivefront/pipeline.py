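"""End-to-end orchestration: simulate -> extract -> distill -> survival.

Each stage reads/writes plain files (TIFF fields, CSV tables, JSON reports)
so runs are resumable and auditable; every report embeds the seeds and a
hash of the configuration that produced it. A failure on one patient is
logged and skipped — it never aborts the cohort run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from invasivefront.classification import FeatureClassConfig, classify_objects
from invasivefront.distill import cart_fit, rf_iterative_reduce
from invasivefront.features import collate_patient, extract_field_features, manifest_default
from invasivefront.segmentation import FieldImage, SegmentationConfig, segment_field
from invasivefront.survival import (
    CutoffConfig,
    bh_adjust,
    build_npi,
    cox_backward_aic,
    cox_univariate,
    dichotomize,
    km_logrank,
)
from invasivefront.synthetic import (
    default_section_specs,
    generate_cohort,
    generate_section,
    study_cohort_spec,
    write_field,
    cohort_to_frame,
)

logger = logging.getLogger(__name__)

CHANNEL_SUFFIXES = ("dapi", "cy3", "cy5")


@dataclass
class RunConfig:
    """Flat run configuration; all stage defaults in one place."""

    image_root: str | Path = "fields"
    cohort_csv: str | Path = "cohort.csv"
    output_dir: str | Path = "out"
    fields_per_section: int = 15
    pixel_size_um: float = 0.5
    n_trees: int = 5000
    rf_tolerance: float = 0.005
    cart_folds: int = 10
    n_cutpoint_sim: int = 1000
    seed: int = 0
    field_overrides: dict = dc_field(default_factory=dict)  # forwarded to FieldSpec
    class_config: FeatureClassConfig = dc_field(default_factory=FeatureClassConfig)
    seg_config: SegmentationConfig = dc_field(default_factory=SegmentationConfig)
    cutoffs: CutoffConfig = dc_field(default_factory=CutoffConfig)

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            return obj

        payload = json.dumps(enc(dataclasses.asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_simulate(config: RunConfig, n_patients: int = 2) -> Path:
    """Write synthetic TIFF sections (and ground-truth sidecars) for *n_patients*."""
    root = Path(config.image_root)
    ss = np.random.SeedSequence(config.seed)
    for i, child in enumerate(ss.spawn(n_patients)):
        patient = f"P{i:04d}"
        pseed = int(child.generate_state(1)[0] % (2**31 - 1))
        specs = default_section_specs(pseed, n_fields=config.fields_per_section,
                                      pixel_size_um=config.pixel_size_um,
                                      **config.field_overrides)
        for f_idx, (field, truth) in enumerate(generate_section(specs)):
            write_field(root / patient, patient, f_idx, field, truth)
    return root


def _read_field(paths: dict[str, Path], pixel_size_um: float) -> FieldImage:
    import tifffile

    arrs = {chan: tifffile.imread(paths[chan]).astype(np.float32)
            for chan in CHANNEL_SUFFIXES}
    return FieldImage(dapi=arrs["dapi"], panck=arrs["cy3"], d240=arrs["cy5"],
                      pixel_size_um=pixel_size_um)


def discover_fields(image_root: str | Path) -> dict[str, list[dict[str, Path]]]:
    """Map patient id -> ordered list of channel-triplet path dicts."""
    root = Path(image_root)
    patients: dict[str, dict[str, dict[str, Path]]] = {}
    for tif in sorted(root.rglob("*_*_*.tif")):
        stem = tif.stem
        parts = stem.rsplit("_", 2)
        if len(parts) != 3 or parts[2] not in CHANNEL_SUFFIXES:
            continue
        patient, field_idx, chan = parts
        patients.setdefault(patient, {}).setdefault(field_idx, {})[chan] = tif
    out: dict[str, list[dict[str, Path]]] = {}
    for patient, fields in sorted(patients.items()):
        triplets = []
        for f_idx in sorted(fields):
            if set(fields[f_idx]) == set(CHANNEL_SUFFIXES):
                triplets.append(fields[f_idx])
            else:
                logger.warning("patient %s field %s: incomplete triplet, skipped",
                               patient, f_idx)
        out[patient] = triplets
    return out


def run_extract(config: RunConfig) -> pd.DataFrame:
    """Segment, classify and featurize every patient section under image_root.

    Returns the patient feature table (rows = patients, 123 columns) and
    writes it, a per-field QC table, and a provenance stamp to output_dir.
    """
    manifest = manifest_default()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = {}
    qc_rows = []
    for patient, triplets in discover_fields(config.image_root).items():
        try:
            field_vectors = []
            for f_idx, paths in enumerate(triplets):
                field = _read_field(paths, config.pixel_size_um)
                h = segment_field(field, config.seg_config)
                cf = classify_objects(h, config.class_config)
                field_vectors.append(extract_field_features(field, h, cf, manifest))
                qc_rows.append({
                    "patient": patient, "field": f_idx,
                    "n_objects": len(h.objects), "n_nuclei": len(h.nuclei),
                    "n_unresolved": cf.n_unresolved,
                    "nuclei_on_no_tissue": h.qc.get("nuclei_on_no_tissue", 0),
                })
            vec = collate_patient(field_vectors, manifest, patient_id=patient)
            rows[patient] = vec.values
        except Exception as err:  # noqa: BLE001 — one bad patient never kills the run
            logger.error("patient %s skipped: %s", patient, err)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=manifest.names)
    table.index.name = "id"
    table.to_csv(out_dir / "patient_features.csv")
    pd.DataFrame(qc_rows).to_csv(out_dir / "field_qc.csv", index=False)
    _stamp(out_dir / "extract_meta.json", config)
    return table


def run_distill(
    feature_table: pd.DataFrame,
    outcomes: pd.Series,
    config: RunConfig,
) -> dict:
    """Random-forest elimination then CART on the surviving features."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if feature_table.empty:
        raise ValueError("empty feature table")
    missing = feature_table.index.difference(outcomes.index)
    if len(missing):
        raise ValueError(f"no outcome for patients: {sorted(map(str, missing))}")
    y = outcomes.loc[feature_table.index].to_numpy()

    X = feature_table.loc[:, feature_table.var(axis=0) > 0]
    ranking = rf_iterative_reduce(
        X, y, n_trees=config.n_trees, tolerance=config.rf_tolerance, seed=config.seed
    )
    cart = cart_fit(X[ranking.selected], y, folds=config.cart_folds, seed=config.seed)

    report = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_features_in": int(X.shape[1]),
        "n_features_selected": len(ranking.selected),
        "selected": ranking.selected,
        "best_oob_auc": ranking.best_oob_auc,
        "cart": cart.to_dict(),
    }
    ranking.summary().to_csv(out_dir / "elimination_trace.csv", index=False)
    (out_dir / "cart_model.json").write_text(json.dumps(report, indent=1))
    (out_dir / "cart_tree.txt").write_text(cart.pretty())
    return {"ranking": ranking, "cart": cart, "report": report}


def run_survival(
    feature_table: pd.DataFrame,
    cohort: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Dichotomized KM/log-rank with BH-FDR, univariate Cox, backward
    elimination and the composite prognostic index."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if int(cohort["event"].sum()) < 2:
        raise ValueError("cohort has fewer than 2 events")

    merged = cohort.set_index("id").join(feature_table, how="inner", rsuffix="_img")
    time = merged["time_months"].to_numpy()
    event = merged["event"].to_numpy().astype(int)

    groups = dichotomize(merged, config.cutoffs)
    km_rows = []
    km_results = {}
    for feat in groups.columns:
        g = groups[feat]
        ok = g.notna()
        if g[ok].nunique() < 2:
            logger.info("feature %s: single group after dichotomization", feat)
            continue
        res = km_logrank(g[ok].astype(int).to_numpy(), time[ok.to_numpy()],
                         event[ok.to_numpy()])
        km_results[feat] = res
        km_rows.append({"feature": feat, "chi2": res.chi2, "p": res.p})
    km_table = pd.DataFrame(km_rows)
    if not km_table.empty:
        km_table["p_bh"] = bh_adjust(km_table["p"].to_numpy())

    cox_rows = []
    for feat in groups.columns:
        g = groups[feat]
        ok = g.notna()
        if g[ok].nunique() < 2:
            continue
        flag = (g[ok].astype(int) == 2).astype(int).to_numpy()
        try:
            res = cox_univariate(flag, time[ok.to_numpy()], event[ok.to_numpy()],
                                 name=feat)
            row = res.table.iloc[0]
            cox_rows.append({"feature": feat, "hr": row["hr"], "ci_low": row["ci_low"],
                             "ci_high": row["ci_high"], "p": row["p"]})
        except ValueError as err:
            logger.info("univariate Cox skipped for %s: %s", feat, err)
    cox_table = pd.DataFrame(cox_rows)

    # composite index per patient
    npi_flags = []
    for _, row in merged.iterrows():
        try:
            npi = build_npi(
                {"area_pdc_um2": row.get("area_pdc_um2"),
                 "pt_stage": row.get("pt_stage"),
                 "differentiation": row.get("differentiation")},
                config.cutoffs,
            )
            npi_flags.append(1 if npi.group == "high" else 0)
        except ValueError:
            npi_flags.append(np.nan)
    merged["npi_high"] = npi_flags

    npi_result = None
    ok = merged["npi_high"].notna()
    if ok.any() and merged.loc[ok, "npi_high"].nunique() == 2:
        npi_result = cox_univariate(
            merged.loc[ok, "npi_high"].to_numpy(),
            time[ok.to_numpy()], event[ok.to_numpy()], name="npi_high",
        )

    multivariate = None
    cov_df = pd.DataFrame({
        "area_pdc_high": (groups.get("area_pdc_um2") == 2).astype(float)
        if "area_pdc_um2" in groups else np.nan,
        "pT4": (merged["pt_stage"] == "pT4").astype(float),
        "poor_differentiation": (merged["differentiation"] == "poor").astype(float),
    })
    if cov_df.notna().all().all() and all(cov_df.nunique() > 1):
        multivariate = cox_backward_aic(cov_df.reset_index(drop=True), time, event)

    km_table.to_csv(out_dir / "km_logrank.csv", index=False)
    cox_table.to_csv(out_dir / "cox_univariate.csv", index=False)
    _stamp(out_dir / "survival_meta.json", config)
    return {
        "km": km_results,
        "km_table": km_table,
        "cox_table": cox_table,
        "npi": npi_result,
        "multivariate": multivariate,
        "cohort": merged,
    }


def run_all(config: RunConfig, n_patients: int = 2) -> dict:
    """Simulate a tiny cohort end-to-end (images + outcomes) and analyze it."""
    run_simulate(config, n_patients=n_patients)
    table = run_extract(config)
    cohort = cohort_to_frame(generate_cohort(study_cohort_spec(config.seed,
                                                               n_patients)))
    cohort["id"] = table.index[: len(cohort)]
    out = run_survival(table, cohort, config)
    out["features"] = table
    return out


def _stamp(path: Path, config: RunConfig) -> None:
    path.write_text(json.dumps(
        {"seed": config.seed, "config_hash": config.config_hash()}, indent=1
    ))
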