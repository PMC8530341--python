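"""MEAS morphometric features from labeled knee segmentation volumes.

Fourteen direct measurements per knee:

* six height-normalized volumes (femoral cartilage, total/medial/lateral
  tibial cartilage, both menisci), mm^3 per m of subject height;
* two meniscal surface areas, mm^2;
* two meniscal surface-area-to-volume ratios, 1/mm (un-normalized volume);
* two medio-lateral meniscal extrusions, mm;
* two tibial coverages, percent of the tibial-cartilage axial footprint
  overlapped by the meniscus footprint.

Volumes come straight from voxel counting; areas from extracted boundary
surfaces; extrusion and coverage from axial (ML x AP) voxel-column
footprints.  Missing inputs (absent structures, missing height) yield NaN
markers rather than exceptions from :func:`compute_meas`, so incomplete
rows can be excluded downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .geometry import (EmptyStructureError, LabelVolume, axial_footprint,
                       extract_surface, mesh_surface_area, voxel_volume)

__all__ = ["MeasVector", "MEAS_COLUMNS", "normalized_volume",
           "area_volume_ratio", "meniscal_extrusion", "tibial_coverage",
           "compute_meas"]

#: Column order of the 14 MEAS features in every table this package writes.
MEAS_COLUMNS = ("V_FC", "V_TC", "V_mTC", "V_lTC", "V_mM", "V_lM",
                "A_mM", "A_lM", "R_AV_mM", "R_AV_lM",
                "E_mM", "E_lM", "TC_mTC", "TC_lTC")


@dataclass
class MeasVector:
    """The 14 MEAS features of one knee; NaN marks a missing value."""

    V_FC: float = math.nan    # mm^3 / m
    V_TC: float = math.nan
    V_mTC: float = math.nan
    V_lTC: float = math.nan
    V_mM: float = math.nan
    V_lM: float = math.nan
    A_mM: float = math.nan    # mm^2
    A_lM: float = math.nan
    R_AV_mM: float = math.nan  # 1/mm
    R_AV_lM: float = math.nan
    E_mM: float = math.nan    # mm
    E_lM: float = math.nan
    TC_mTC: float = math.nan  # percent
    TC_lTC: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in MEAS_COLUMNS], dtype=float)


def normalized_volume(raw_mm3: float, height_m: float | None) -> float:
    """Volume normalized by subject height; NaN if height missing/invalid."""
    if height_m is None or not np.isfinite(height_m) or height_m <= 0:
        return math.nan
    return raw_mm3 / height_m


def area_volume_ratio(area_mm2: float, volume_mm3: float) -> float:
    """Surface-area-to-volume ratio in 1/mm; NaN for non-positive volume."""
    if not np.isfinite(volume_mm3) or volume_mm3 <= 0 or not np.isfinite(area_mm2):
        return math.nan
    return area_mm2 / volume_mm3


def _outer_sign(vol: LabelVolume, compartment: str) -> int:
    """Sign of the outward ML direction (+1 toward increasing axis-0 index).

    Right-knee convention: medial is the negative ML direction; left
    volumes are mirrored, so the signs flip.
    """
    if compartment not in ("medial", "lateral"):
        raise ValueError(f"compartment must be medial|lateral, got {compartment!r}")
    medial_sign = -1 if vol.side == "right" else 1
    return medial_sign if compartment == "medial" else -medial_sign


def meniscal_extrusion(vol: LabelVolume, compartment: str) -> float:
    """Medio-lateral meniscal extrusion past the tibial plateau, mm.

    The meniscus voxels and the tibial-plateau footprint (tibial bone plus
    the compartment's tibial cartilage) are projected onto the axial plane.
    For every AP row containing both, the ML overhang of the outermost
    meniscus column beyond the outermost plateau column on the
    compartment's outer side is measured; the extrusion is the maximum
    overhang over rows, clamped at 0 (no negative "intrusion").
    """
    men = "mM" if compartment == "medial" else "lM"
    tc = "mTC" if compartment == "medial" else "lTC"
    men_fp = axial_footprint(vol, men)
    plateau_fp = axial_footprint(vol, "TB") | axial_footprint(vol, tc)
    if not men_fp.any():
        raise EmptyStructureError(f"meniscus {men!r} absent")
    if not plateau_fp.any():
        raise EmptyStructureError("tibial plateau (TB and compartment TC) absent")
    sign = _outer_sign(vol, compartment)
    nx = men_fp.shape[0]
    idx = np.arange(nx)[:, None]
    # outermost occupied ML index per AP row, in the outward direction
    key = sign * idx
    men_edge = np.where(men_fp, key, np.iinfo(np.int64).min).max(axis=0)
    plat_edge = np.where(plateau_fp, key, np.iinfo(np.int64).min).max(axis=0)
    rows = men_fp.any(axis=0) & plateau_fp.any(axis=0)
    if not rows.any():
        return 0.0
    overhang = (men_edge[rows] - plat_edge[rows]).max()
    return max(0.0, float(overhang) * vol.spacing_mm[0])


def tibial_coverage(vol: LabelVolume, compartment: str) -> float:
    """Percent of the tibial-cartilage axial footprint covered by the meniscus."""
    men = "mM" if compartment == "medial" else "lM"
    tc = "mTC" if compartment == "medial" else "lTC"
    tc_fp = axial_footprint(vol, tc)
    if not tc_fp.any():
        raise EmptyStructureError(f"tibial cartilage {tc!r} absent")
    men_fp = axial_footprint(vol, men)
    return 100.0 * float(np.count_nonzero(tc_fp & men_fp)) / float(np.count_nonzero(tc_fp))


def compute_meas(vol: LabelVolume, height_m: float | None) -> MeasVector:
    """Assemble all 14 MEAS features for one knee.

    Absent structures and missing height produce NaN markers in the
    affected features only; the function itself does not raise for
    incomplete anatomy.
    """
    out = MeasVector()
    raw: dict[str, float] = {}
    for s in ("FC", "mTC", "lTC", "mM", "lM"):
        v = voxel_volume(vol, s)
        raw[s] = v if v > 0 else math.nan
    raw["TC"] = raw["mTC"] + raw["lTC"]  # NaN-propagating by design
    for s in ("FC", "TC", "mTC", "lTC", "mM", "lM"):
        setattr(out, f"V_{s}",
                normalized_volume(raw[s], height_m) if np.isfinite(raw[s])
                else math.nan)
    for men, a_col, r_col in (("mM", "A_mM", "R_AV_mM"), ("lM", "A_lM", "R_AV_lM")):
        try:
            area = mesh_surface_area(extract_surface(vol, men))
        except (EmptyStructureError, ValueError):
            continue
        setattr(out, a_col, area)
        setattr(out, r_col, area_volume_ratio(area, raw[men]))
    for comp, e_col, c_col in (("medial", "E_mM", "TC_mTC"),
                               ("lateral", "E_lM", "TC_lTC")):
        try:
            setattr(out, e_col, meniscal_extrusion(vol, comp))
        except EmptyStructureError:
            pass
        try:
            setattr(out, c_col, tibial_coverage(vol, comp))
        except EmptyStructureError:
            pass
    return out
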