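"""End-to-end pipeline: simulate -> dmap -> aggregate -> risk -> classify -> report.

Each stage is a function over the library modules; ``run_pipeline`` chains
them, writes every artifact under the output directory, and records a
manifest with the configuration fingerprint and seed. Reruns with the same
config and seed reproduce all outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import io as cio
from . import nuclei as nuc
from . import risk as riskmod
from . import stats as statsmod
from .config import PipelineConfig
from .core import build_calibration, compute_sigma, estimate_d_map, normalize_cube
from .params import ChromatinParams, InstrumentParams, RIModel
from .synthetic import CohortConfig, disk_phantom, generate_cube, generate_cohort

__all__ = ["run_pipeline", "parse_endpoint"]

log = logging.getLogger("chromascan")


def parse_endpoint(endpoint: str) -> tuple[list[str], list[str]]:
    """Parse 'Control+DA vs AA' into (control groups, case groups)."""
    parts = endpoint.split(" vs ")
    if len(parts) != 2:
        raise ValueError(f"endpoint must be '<groups> vs <groups>', got {endpoint!r}")
    neg = [g.strip() for g in parts[0].split("+") if g.strip()]
    pos = [g.strip() for g in parts[1].split("+") if g.strip()]
    if not neg or not pos or set(neg) & set(pos):
        raise ValueError(f"endpoint sides must be non-empty and disjoint: {endpoint!r}")
    return neg, pos


def _instrument(config: PipelineConfig) -> InstrumentParams:
    return InstrumentParams(**config.instrument.model_dump())


def _nucleus_layout(n_cells: int, radius: int, cols: int) -> tuple[tuple[int, int], list[tuple[int, int]]]:
    pitch = 2 * radius + 3
    rows = int(np.ceil(n_cells / cols))
    shape = (rows * pitch, cols * pitch)
    centers = [
        (pitch // 2 + pitch * (i // cols), pitch // 2 + pitch * (i % cols))
        for i in range(n_cells)
    ]
    return shape, centers


def run_pipeline(config: PipelineConfig, out_dir: str | Path, seed: int = 0) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fingerprint = config.fingerprint()
    manifest: dict = {"config_fingerprint": fingerprint, "seed": seed, "stages": {}}
    instrument = _instrument(config)
    try:
        artifacts = _simulate_stage(config, instrument, out, seed)
        manifest["stages"]["simulate"] = artifacts["files"]
        dmaps = _dmap_stage(config, instrument, out, artifacts)
        manifest["stages"]["dmap"] = dmaps["files"]
        agg = _aggregate_stage(config, out, artifacts, dmaps)
        manifest["stages"]["aggregate"] = agg["files"]
        risk = _risk_stage(config, out, agg["patients"])
        manifest["stages"]["risk"] = risk["files"]
        cv = _classify_stage(config, out, artifacts, dmaps, agg["patients"], seed)
        manifest["stages"]["classify"] = cv["files"]
        rep = _report_stage(config, out, agg["patients"])
        manifest["stages"]["report"] = rep["files"]
    except Exception as exc:
        stage = len(manifest["stages"])
        names = ["simulate", "dmap", "aggregate", "risk", "classify", "report"]
        raise RuntimeError(f"pipeline failed at stage '{names[min(stage, 5)]}': {exc}") from exc
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %d stages, fingerprint %s", len(manifest["stages"]), fingerprint)
    return manifest


def load_artifacts(out: Path) -> dict:
    """Reconstruct the simulate/dmap stage state from an output directory,
    so the aggregate/risk/classify/report subcommands can run standalone."""
    out = Path(out)
    patients = pd.read_csv(out / "cohort.csv")
    nuclei_path = out / "nuclei_true.csv"
    nuclei = pd.read_csv(nuclei_path) if nuclei_path.exists() else pd.DataFrame()
    cube_paths: dict[str, Path] = {}
    masks: dict[str, np.ndarray] = {}
    dmaps: dict[str, object] = {}
    for pid in patients["patient_id"]:
        cube_path = out / "cubes" / f"{pid}.h5"
        mask_path = out / "cubes" / f"{pid}_mask.tif"
        if cube_path.exists():
            cube_paths[pid] = cube_path
        if mask_path.exists():
            masks[pid] = cio.read_mask(mask_path)
        dmap_path = out / "dmaps" / f"{pid}_dmap.tif"
        if dmap_path.exists():
            dmaps[pid] = cio.read_dmap(dmap_path)
    return {
        "patients": patients,
        "nuclei": nuclei,
        "cube_paths": cube_paths,
        "masks": masks,
        "dmaps": dmaps,
    }


def _simulate_stage(config: PipelineConfig, instrument: InstrumentParams, out: Path, seed: int) -> dict:
    sim = config.simulate
    cohort_cfg = CohortConfig(
        group_sizes=dict(sim.group_sizes),
        cells_per_patient=sim.cells_per_patient,
        group_d_sd=sim.group_d_sd,
        nucleus_d_sd=sim.nucleus_d_sd,
        age_coeff=sim.age_coeff,
        seed=seed,
    )
    patients, nuclei = generate_cohort(cohort_cfg)
    cube_dir = out / "cubes"
    cube_dir.mkdir(exist_ok=True)
    chromatin = ChromatinParams.from_genomic_size(
        d=2.5, phi=config.dmap.phi, nf=config.dmap.nf
    )
    ri = RIModel()
    shape, centers = _nucleus_layout(
        sim.cells_per_patient, sim.nucleus_radius_px, sim.grid_cols
    )
    files: list[str] = []
    cube_paths: dict[str, Path] = {}
    mask_by_patient: dict[str, np.ndarray] = {}
    for idx, row in patients.iterrows():
        pid = row["patient_id"]
        mask = disk_phantom(shape, centers, sim.nucleus_radius_px)
        d_true = np.full(shape, np.nan)
        nucs = nuclei[nuclei["patient_id"] == pid]
        for label, (_, nrow) in enumerate(nucs.iterrows(), start=1):
            sel = mask == label
            d_true[sel] = nrow["true_d"]
        d_fill = np.where(mask > 0, d_true, 2.5)
        cube = generate_cube(
            d_fill, mask > 0, chromatin, instrument, ri,
            noise_sd=sim.noise_sd, seed=seed + 1000 + idx,
        )
        cube_path = cube_dir / f"{pid}.h5"
        cio.write_cube(cube, cube_path)
        mask_path = cube_dir / f"{pid}_mask.tif"
        cio.write_mask(mask, mask_path)
        cube_paths[pid] = cube_path
        mask_by_patient[pid] = mask
        files += [str(cube_path), str(mask_path)]
    cohort_path = out / "cohort.csv"
    cols = ["patient_id", "group", "age", "sex", "smoker", "drinker", "true_mean_d"]
    patients[cols].to_csv(cohort_path, index=False)
    nuclei_path = out / "nuclei_true.csv"
    nuclei.to_csv(nuclei_path, index=False)
    files += [str(cohort_path), str(nuclei_path)]
    log.info("simulate: %d patients, %d nuclei", len(patients), len(nuclei))
    return {
        "files": files,
        "patients": patients,
        "nuclei": nuclei,
        "cube_paths": cube_paths,
        "masks": mask_by_patient,
    }


def _dmap_stage(config: PipelineConfig, instrument: InstrumentParams, out: Path, artifacts: dict) -> dict:
    dm = config.dmap
    d_grid = np.arange(dm.d_grid_lo, dm.d_grid_hi + dm.d_grid_step / 2, dm.d_grid_step)
    cal = build_calibration(instrument, dm.phi, dm.nf, d_grid)
    dmap_dir = out / "dmaps"
    dmap_dir.mkdir(exist_ok=True)
    files: list[str] = []
    dmaps: dict[str, object] = {}
    n_pixels = 0
    for pid, cube_path in artifacts["cube_paths"].items():
        cube = cio.read_cube(cube_path, expected_wavelengths=instrument.wavelengths)
        mask = artifacts["masks"][pid] > 0
        sigma = compute_sigma(normalize_cube(cube), mask, noise_floor=dm.noise_floor)
        dmap = estimate_d_map(sigma, cal)
        path = dmap_dir / f"{pid}_dmap.tif"
        cio.write_dmap(dmap, path, calibration_fingerprint=cal.fingerprint())
        dmaps[pid] = dmap
        files.append(str(path))
        n_pixels += int(mask.sum())
    log.info("dmap: %d cubes, %d in-mask pixels", len(dmaps), n_pixels)
    return {"files": files, "dmaps": dmaps, "calibration": cal}


def _aggregate_stage(config: PipelineConfig, out: Path, artifacts: dict, dmaps: dict) -> dict:
    rows_nuc = []
    rows_pat = []
    for _, prow in artifacts["patients"].iterrows():
        pid = prow["patient_id"]
        dmap = dmaps["dmaps"][pid]
        mask = artifacts["masks"][pid]
        records = [
            nuc.nucleus_mean_d(dmap, mask, label, patient_id=pid)
            for label in range(1, mask.max() + 1)
        ]
        patient = nuc.aggregate_patient(
            records,
            patient_id=pid,
            group=prow["group"],
            age=prow["age"],
            sex=prow["sex"],
            smoker=prow["smoker"],
            drinker=prow["drinker"],
            delta_ref=config.aggregate.delta_ref,
            ci_level=config.aggregate.ci_level,
        )
        for r in records:
            rows_nuc.append(
                {"patient_id": pid, "nucleus_id": r.nucleus_id, "mean_d": r.mean_d,
                 "pixel_count": r.pixel_count, "clipped_fraction": r.clipped_fraction}
            )
        rows_pat.append(
            {"patient_id": pid, "group": patient.group, "age": patient.age,
             "sex": patient.sex, "smoker": patient.smoker, "drinker": patient.drinker,
             "mean_d": patient.mean_d, "n_nuclei": len(records),
             "qc_pass": patient.qc_pass, "qc_count_pass": patient.qc_count_pass,
             "qc_ci_pass": patient.qc_ci_pass}
        )
    nuclei_df = pd.DataFrame(rows_nuc)
    patients_df = pd.DataFrame(rows_pat)
    p1 = out / "per_nucleus.csv"
    p2 = out / "patients.csv"
    nuclei_df.to_csv(p1, index=False)
    patients_df.to_csv(p2, index=False)
    log.info("aggregate: %d patients, %d nuclei", len(patients_df), len(nuclei_df))
    return {"files": [str(p1), str(p2)], "patients": patients_df, "nuclei": nuclei_df}


def _risk_stage(config: PipelineConfig, out: Path, patients: pd.DataFrame) -> dict:
    rb = config.risk_model
    strata = [
        riskmod.RiskStratum(s.sex, s.age_band, s.annual_aa_to_crc) for s in rb.strata
    ]
    group_rows = []
    for group, sub in patients.groupby("group", sort=False):
        n = len(sub)
        nc = int(round(rb.group_cancer_history_frac.get(group, 0.0) * n))
        na = n - nc
        params = riskmod.RiskModelParams(
            na=na, nc=nc, aar=rb.group_aar.get(group, 0.0), crcm=rb.crcm,
            strata=strata, horizon=rb.horizon,
        )
        sub_na = sub.iloc[:na]
        annual = np.array(
            [
                params.annual_for("female" if s.startswith("F") else "male", a)
                for s, a in zip(sub_na["sex"], sub_na["age"])
            ]
        ) if na else np.zeros(0)
        modeled = riskmod.crc_5yr_risk(params, annual)
        group_rows.append(
            {"group": group, "n": n, "modeled_risk": modeled,
             "mean_d": float(sub["mean_d"].mean()),
             "config_fingerprint": params.fingerprint()}
        )
    table = pd.DataFrame(group_rows)
    if len(table) >= 3:
        reg = riskmod.regress_d_vs_risk(
            table["mean_d"].to_numpy(), table["modeled_risk"].to_numpy()
        )
        regression = {"slope": reg.slope, "intercept": reg.intercept,
                      "r_squared": round(reg.r_squared, 3), "n_points": reg.n_points}
    else:
        regression = {"unavailable": "regression needs at least 3 groups"}
    report = {"groups": table.to_dict(orient="records"), "regression": regression}
    path = out / "risk_report.json"
    path.write_text(json.dumps(report, indent=2))
    log.info("risk: %d groups", len(table))
    return {"files": [str(path)], "report": report}


def _classify_stage(
    config: PipelineConfig, out: Path, artifacts: dict, dmaps: dict,
    patients: pd.DataFrame, seed: int,
) -> dict:
    cb = config.classify
    neg, pos = parse_endpoint(cb.endpoint)
    selected = patients[patients["group"].isin(neg + pos)]
    labels = {
        row["patient_id"]: int(row["group"] in pos) for _, row in selected.iterrows()
    }
    parts = []
    for pid in labels:
        dmap = dmaps["dmaps"][pid]
        mask = artifacts["masks"][pid]
        parts.append(
            clf.nucleus_feature_matrix(
                dmap, mask, list(range(1, int(mask.max()) + 1)), pid, out_side=cb.out_side
            )
        )
    features = clf.FeatureMatrix(
        np.vstack([p.values for p in parts]),
        [rid for p in parts for rid in p.row_ids],
        parts[0].feature_names,
    )
    report = clf.cross_validate(
        features, labels, k=cb.k, repeats=cb.repeats, seed=seed,
        latent_dim=cb.latent_dim, epochs=cb.epochs, grid=cb.grid,
    )
    folds_path = out / "cv_folds.csv"
    report.folds.to_csv(folds_path, index=False)
    json_path = out / "cv_report.json"
    json_path.write_text(
        json.dumps({"endpoint": cb.endpoint, "k": cb.k, "repeats": cb.repeats,
                    "summary": report.summary}, indent=2)
    )
    log.info("classify: %d folds, mean AUC %.3f", len(report.folds),
             report.summary["auc"]["mean"])
    return {"files": [str(folds_path), str(json_path)], "report": report}


def _report_stage(config: PipelineConfig, out: Path, patients: pd.DataFrame) -> dict:
    ref = config.report.reference_group
    groups = {
        g: sub["mean_d"].to_numpy() for g, sub in patients.groupby("group", sort=False)
    }
    comparisons = statsmod.compare_many(groups, reference=ref)
    demo = statsmod.demographic_table(patients)
    order = [g for g in ("Control", "DA", "NDA", "AA", "HNPCC", "CRC") if g in groups]
    if len(order) >= 3:
        trend = statsmod.trend_across_stages(
            order, {g: float(v.mean()) for g, v in groups.items()}
        )
    else:
        trend = {"unavailable": "trend needs at least 3 groups"}
    try:
        ancova = statsmod.ancova_d(patients)
        ancova_out = {
            "n": ancova.n,
            "terms": {t: {"coef": ancova.coef(t), "p": ancova.p(t)}
                      for t in ancova.table.index},
        }
    except ValueError as exc:
        ancova_out = {"error": str(exc)}
    c_path = out / "group_comparisons.csv"
    comparisons.to_csv(c_path, index=False)
    d_path = out / "demographics.csv"
    demo.to_csv(d_path, index=False)
    j_path = out / "stats_report.json"
    j_path.write_text(json.dumps({"trend": trend, "ancova": ancova_out,
                                  "test": "welch_t", "effect_size": "cohens_d_pooled"},
                                 indent=2))
    log.info("report: %d comparisons", len(comparisons))
    return {"files": [str(c_path), str(d_path), str(j_path)]}
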