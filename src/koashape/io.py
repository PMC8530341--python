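"""File formats: NIfTI / MetaImage label volumes, PLY meshes, CSV tables, YAML configs.

The NIfTI affine is RAS-style diagonal built from the voxel spacing (world
coordinate = index * spacing, no origin offset); the header description
records the fixed label encoding so every mask file is self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .geometry import LABELS, LabelVolume, SurfaceMesh
from .synthetic_knee import HORIZONS, CohortConfig, KneeRecord, SeverityEffects

__all__ = ["save_label_volume", "load_label_volume", "save_mesh", "load_mesh",
           "records_to_frame", "frame_to_records", "load_cohort_config",
           "dump_cohort_config", "write_manifest", "sha256_of"]

_LABEL_DESCRIP = ",".join(f"{v}={k}" for k, v in LABELS.items())


def save_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    """Write a label volume as NIfTI-1 (.nii or .nii.gz)."""
    path = Path(path)
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    img = nib.Nifti1Image(vol.labels.astype(np.uint8), affine)
    img.header["descrip"] = _LABEL_DESCRIP[:79].encode()
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    return path


def load_label_volume(path: str | Path, side: str = "right") -> LabelVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha) label volume."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".mhd", ".mha")):
        import SimpleITK as sitk
        img = sitk.ReadImage(str(path))
        # SimpleITK arrays come back (z, y, x); restore (x, y, z)
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = tuple(float(s) for s in img.GetSpacing())
    else:
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(arr.astype(np.uint8), spacing, side=side)


def save_mesh(mesh: SurfaceMesh, path: str | Path) -> Path:
    """Write a surface mesh as PLY (or OBJ, by extension)."""
    import trimesh
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))
    return path


def load_mesh(path: str | Path) -> SurfaceMesh:
    import trimesh
    tm = trimesh.load_mesh(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))


# ---------------------------------------------------------------------------
# cohort records
# ---------------------------------------------------------------------------

def records_to_frame(records: list[KneeRecord]) -> pd.DataFrame:
    """One row per knee-visit; outcome columns ``tkr_{h}y`` / ``inc_koa_{h}y``
    (incident KOA is NaN for knees not at risk)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "knee_id": r.knee_id, "visit": r.visit, "side": r.side,
            "height_m": r.height_m, "severity": r.severity,
            "klg": r.klg, "mjsn": r.mjsn, "ljsn": r.ljsn,
        }
        for h in HORIZONS:
            v = r.incident_koa_within.get(h)
            row[f"inc_koa_{h}y"] = np.nan if v is None else v
            row[f"tkr_{h}y"] = r.tkr_within.get(h, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[KneeRecord]:
    records = []
    for _, row in frame.iterrows():
        koa = {h: (None if pd.isna(row.get(f"inc_koa_{h}y")) else
                   int(row[f"inc_koa_{h}y"])) for h in HORIZONS}
        tkr = {h: int(row[f"tkr_{h}y"]) for h in HORIZONS
               if f"tkr_{h}y" in row and pd.notna(row[f"tkr_{h}y"])}
        records.append(KneeRecord(
            knee_id=str(row["knee_id"]), visit=str(row["visit"]),
            side=str(row["side"]), height_m=float(row["height_m"]),
            severity=float(row["severity"]), klg=int(row["klg"]),
            mjsn=int(row["mjsn"]), ljsn=int(row["ljsn"]),
            incident_koa_within=koa, tkr_within=tkr))
    return records


# ---------------------------------------------------------------------------
# configuration & manifests
# ---------------------------------------------------------------------------

def load_cohort_config(path: str | Path) -> CohortConfig:
    """Parse a YAML cohort configuration; validation errors name the field."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return cohort_config_from_dict(data)


def cohort_config_from_dict(data: dict) -> CohortConfig:
    data = dict(data)
    if "severity_effects" in data and isinstance(data["severity_effects"], dict):
        data["severity_effects"] = SeverityEffects(**data["severity_effects"])
    tuple_fields = {"voxel_spacing_mm", "mode_sd_mm", "klg_thresholds",
                    "mjsn_thresholds", "ljsn_thresholds", "tkr_beta0", "koa_beta0"}
    for key in tuple_fields & data.keys():
        data[key] = tuple(data[key])
    valid = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    cfg = CohortConfig(**data)
    cfg.validate()
    return cfg


def dump_cohort_config(cfg: CohortConfig, path: str | Path) -> Path:
    path = Path(path)
    data = dataclasses.asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, *, config: dict, seed: int,
                   outputs: dict[str, str] | None = None) -> Path:
    """JSON run manifest: version, config snapshot, seed, output checksums."""
    from . import __version__
    path = Path(path)
    manifest = {
        "tool": "koashape", "version": __version__,
        "seed": seed, "config": config,
        "outputs_sha256": outputs or {},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
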