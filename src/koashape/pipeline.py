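"""End-to-end orchestration: cohort generation -> features -> shape models -> evaluation.

The in-memory entry points (:func:`featurize_cohort`, :func:`run_task_grid`)
power both the command-line interface and the test/acceptance harness; the
``*_to_dir`` variants add on-disk interchange (NIfTI masks, PLY meshes,
CSV tables, JSON manifest).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .evaluation import SplitConfig, TaskSpec, run_task
from .geometry import SurfaceMesh
from .ldse import (CorrespondedShapeSet, ShapeModel, align_shapes, align_to,
                   encode_shape, fit_shape_model)
from .meas_features import MEAS_COLUMNS, compute_meas
from .synthetic_knee import (SHAPE_STRUCTURES, CohortConfig, KneeRecord,
                             sample_cohort, voxelize)

__all__ = ["featurize_cohort", "fit_cohort_shape_models", "encode_cohort",
           "run_task_grid", "default_task_grid", "simulate_to_dir",
           "run_pipeline", "FEATURE_SETS"]

logger = logging.getLogger(__name__)

#: The feature sets evaluated throughout (individual encodings, the
#: combined encoding, morphometrics, and combinations).
FEATURE_SETS = ("MEAS",
                "LDSE-FB", "LDSE-FB + MEAS",
                "LDSE-TB", "LDSE-TB + MEAS",
                "LDSE-mM", "LDSE-mM + MEAS",
                "LDSE-lM", "LDSE-lM + MEAS",
                "LDSE-COMB", "LDSE-COMB + MEAS")


def _canonical_vertices(mesh: SurfaceMesh, side: str) -> np.ndarray:
    """Vertices in the right-knee frame (left knees mirrored back on ML)."""
    v = mesh.vertices
    if side == "left":
        v = v.copy()
        v[:, 0] *= -1.0
    return v


def fit_cohort_shape_models(records: list[KneeRecord],
                            meshes: list[dict[str, SurfaceMesh]],
                            cohort: str = "") -> dict[str, ShapeModel]:
    """Per-structure shape models from one cohort (one visit).

    Left knees are mirrored into the right-knee frame so a single model
    per structure covers both sides; sets are Procrustes-aligned before
    fitting.  Cohorts are modelled independently — no state is shared
    across visits.
    """
    models: dict[str, ShapeModel] = {}
    for s in SHAPE_STRUCTURES:
        stack = np.stack([_canonical_vertices(m[s], r.side)
                          for r, m in zip(records, meshes)])
        sset = CorrespondedShapeSet(s, meshes[0][s].faces, stack, cohort=cohort,
                                    shape_ids=tuple(r.knee_id for r in records))
        models[s] = fit_shape_model(align_shapes(sset))
    return models


def encode_cohort(records: list[KneeRecord],
                  meshes: list[dict[str, SurfaceMesh]],
                  models: dict[str, ShapeModel]) -> pd.DataFrame:
    """LDSE coefficient columns (``ldse_<structure>_000`` ...) per knee."""
    cols: dict[str, np.ndarray] = {}
    for s, model in models.items():
        coeffs = np.empty((len(records), model.n_modes))
        for i, (r, m) in enumerate(zip(records, meshes)):
            v = align_to(model.mean, _canonical_vertices(m[s], r.side))
            coeffs[i] = encode_shape(model, v).coefficients
        for k in range(model.n_modes):
            cols[f"ldse_{s}_{k:03d}"] = coeffs[:, k]
    return pd.DataFrame(cols)


def featurize_cohort(records: list[KneeRecord],
                     meshes: list[dict[str, SurfaceMesh]],
                     spacing: tuple[float, float, float],
                     with_ldse: bool = True) -> pd.DataFrame:
    """Full feature table for a cohort: 14 MEAS columns plus LDSE blocks.

    Each knee's meshes are voxelized at ``spacing`` and the morphometric
    features measured on the label volume; shape models are fitted on the
    meshes of this cohort and every knee encoded against them.
    """
    meas_rows = []
    for r, m in zip(records, meshes):
        vol = voxelize(m, spacing, side=r.side)
        meas_rows.append(compute_meas(vol, r.height_m).as_dict())
    frame = pd.DataFrame(meas_rows)[list(MEAS_COLUMNS)]
    frame.insert(0, "knee_id", [r.knee_id for r in records])
    frame.insert(1, "visit", [r.visit for r in records])
    if with_ldse:
        models = fit_cohort_shape_models(records, meshes,
                                         cohort=records[0].visit if records else "")
        frame = pd.concat([frame, encode_cohort(records, meshes, models)], axis=1)
    return frame


# ---------------------------------------------------------------------------
# task grid
# ---------------------------------------------------------------------------

def default_task_grid(feature_sets=FEATURE_SETS,
                      horizons=(1, 2, 3, 4, 5)) -> list[TaskSpec]:
    """The full evaluation grid: five KLG groupings, medial and lateral JSN,
    and incident-KOA / TKR prediction per horizon, crossed with the
    feature sets."""
    tasks: list[TaskSpec] = []
    klg_groupings = (
        ((0,), (1,), (2,), (3,), (4,)),
        ((0, 1), (2,), (3, 4)),
        ((0, 1), (2, 3, 4)),
        ((0,), (2,)),
        ((0,), (4,)),
    )
    jsn_grouping = ((0,), (1,), (2,), (3,))
    for fs in feature_sets:
        for grp in klg_groupings:
            tasks.append(TaskSpec("classification", "KLG", grp, feature_set=fs))
        for src in ("mJSN", "lJSN"):
            tasks.append(TaskSpec("classification", src, jsn_grouping,
                                  feature_set=fs))
        for h in horizons:
            tasks.append(TaskSpec("prediction", "incident_koa",
                                  horizon_years=h, feature_set=fs))
            tasks.append(TaskSpec("prediction", "tkr",
                                  horizon_years=h, feature_set=fs))
    return tasks


def run_task_grid(features: pd.DataFrame, records: pd.DataFrame,
                  tasks: list[TaskSpec], cfg: SplitConfig,
                  on_infeasible: str = "skip") -> pd.DataFrame:
    """Tidy results: one row per (task, feature set, metric).

    Infeasible tasks (a class empty or below the minimum size after
    filtering) are skipped with a log line by default, or re-raised with
    ``on_infeasible='raise'``.
    """
    from .evaluation import TaskInfeasibleError
    rows = []
    for task in tasks:
        try:
            res = run_task(features, records, task, cfg)
        except TaskInfeasibleError as exc:
            if on_infeasible == "raise":
                raise
            logger.info("skipping %s [%s]: %s", task.name, task.feature_set, exc)
            continue
        summ = res.summary()
        for metric in ("ba", "kappa", "auc"):
            if f"{metric}_mean" in summ:
                rows.append({"task": task.name, "feature_set": task.feature_set,
                             "metric": metric, "mean": summ[f"{metric}_mean"],
                             "sd": summ[f"{metric}_sd"],
                             "n": res.n_included,
                             "n_dropped": res.n_dropped_missing})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk pipeline
# ---------------------------------------------------------------------------

def simulate_to_dir(cfg: CohortConfig, outdir: str | Path) -> Path:
    """Write a complete synthetic cohort: NIfTI masks, PLY meshes, labels CSV,
    config snapshot and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, meshes = sample_cohort(cfg)
    outputs: dict[str, str] = {}
    for r, m in zip(records, meshes):
        kdir = outdir / r.knee_id
        kdir.mkdir(exist_ok=True)
        vol = voxelize(m, cfg.voxel_spacing_mm, side=r.side)
        p = kio.save_label_volume(vol, kdir / f"{r.knee_id}_labels.nii.gz")
        outputs[str(p.relative_to(outdir))] = kio.sha256_of(p)
        for s, mesh in m.items():
            kio.save_mesh(mesh, kdir / f"{r.knee_id}_{s}.ply")
    frame = kio.records_to_frame(records)
    frame.to_csv(outdir / "records.csv", index=False)
    outputs["records.csv"] = kio.sha256_of(outdir / "records.csv")
    kio.dump_cohort_config(cfg, outdir / "config.yaml")
    kio.write_manifest(outdir / "manifest.json",
                       config=dataclasses.asdict(cfg), seed=cfg.seed,
                       outputs=outputs)
    return outdir


def features_from_dir(cohort_dir: str | Path, with_ldse: bool = True
                      ) -> pd.DataFrame:
    """Feature table from an on-disk cohort (masks + meshes + records CSV).

    Unreadable knees are skipped with a logged reason and an exclusion
    summary, mirroring real-cohort quality-assurance bookkeeping.
    """
    cohort_dir = Path(cohort_dir)
    frame = pd.read_csv(cohort_dir / "records.csv")
    records = kio.frame_to_records(frame)
    kept, meshes, meas_rows = [], [], []
    excluded = 0
    for r in records:
        kdir = cohort_dir / r.knee_id
        try:
            vol = kio.load_label_volume(kdir / f"{r.knee_id}_labels.nii.gz",
                                        side=r.side)
            knee_meshes = {s: kio.load_mesh(kdir / f"{r.knee_id}_{s}.ply")
                           for s in SHAPE_STRUCTURES} if with_ldse else {}
        except Exception as exc:  # unreadable input: exclude, keep going
            logger.warning("excluding %s: %s", r.knee_id, exc)
            excluded += 1
            continue
        kept.append(r)
        meshes.append(knee_meshes)
        meas_rows.append(compute_meas(vol, r.height_m).as_dict())
    if excluded:
        logger.warning("%d knee(s) excluded", excluded)
    out = pd.DataFrame(meas_rows)[list(MEAS_COLUMNS)]
    out.insert(0, "knee_id", [r.knee_id for r in kept])
    out.insert(1, "visit", [r.visit for r in kept])
    if with_ldse and kept:
        models = fit_cohort_shape_models(kept, meshes, cohort=kept[0].visit)
        out = pd.concat([out, encode_cohort(kept, meshes, models)], axis=1)
    out.attrs["n_excluded"] = excluded
    return out


def run_pipeline(cfg: CohortConfig, outdir: str | Path,
                 split: SplitConfig | None = None,
                 feature_sets=FEATURE_SETS,
                 horizons=(1,)) -> pd.DataFrame:
    """simulate -> features -> shape models -> evaluate, writing results CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    split = split or SplitConfig(n_repeats=50, seed=cfg.seed)
    records, meshes = sample_cohort(cfg)
    features = featurize_cohort(records, meshes, cfg.voxel_spacing_mm)
    rec_frame = kio.records_to_frame(records)
    tasks = default_task_grid(feature_sets=feature_sets, horizons=horizons)
    results = run_task_grid(features, rec_frame, tasks, split)
    rec_frame.to_csv(outdir / "records.csv", index=False)
    features.to_csv(outdir / "features.csv", index=False)
    results.to_csv(outdir / "results.csv", index=False)
    kio.write_manifest(outdir / "manifest.json",
                       config=dataclasses.asdict(cfg), seed=cfg.seed,
                       outputs={"results.csv": kio.sha256_of(outdir / "results.csv")})
    return results
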