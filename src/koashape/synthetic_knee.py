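"""Synthetic knee cohorts: corresponded meshes, label volumes, grades, outcomes.

Real cohorts of segmented knee MRI (e.g. OAI DESS scans) are access
restricted, so this module generates stand-in cohorts with *known* planted
structure, which is what makes every downstream stage of the pipeline
testable: six closed template meshes (femoral/tibial bone, femoral and
medial/lateral tibial cartilage, both menisci) share one anatomical frame
and one triangulation per structure across the whole cohort.

Disease severity is collapsed to a single latent scalar in [0, 1] per knee.
It drives

* deterministic morphological effects with closed-form magnitudes
  (cartilage thinning, volume-preserving meniscal flattening, medio-lateral
  meniscal extrusion, bone-surface bumps),
* ordinal grades (KLG 0-4, medial/lateral JSN 0-3) by thresholding
  ``severity + noise`` (an ordered-probit style mechanism), and
* binary clinical outcomes (incident knee OA, total knee replacement)
  through a logistic link per horizon year.

Random anatomical variation is planted as orthonormal vertex-displacement
modes with strictly descending standard deviations, so statistical shape
model fitting downstream has an unambiguous ground truth.

All randomness is driven by ``CohortConfig.seed``; identical configs give
identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import LABELS, STRUCTURES, LabelVolume, SurfaceMesh

__all__ = [
    "CohortConfig",
    "KneeRecord",
    "SeverityEffects",
    "build_templates",
    "sample_cohort",
    "voxelize",
    "OverlapError",
]

#: Structures that receive planted shape-variation modes / LDSE encodings.
SHAPE_STRUCTURES = ("FB", "TB", "mM", "lM")

#: Internal seed fixing the planted variation modes (part of the template,
#: deliberately independent of the cohort seed so templates are a constant).
_TEMPLATE_MODE_SEED = 715517

HORIZONS = (1, 2, 3, 4, 5)


class OverlapError(ValueError):
    """Two structure interiors claim the same voxel center."""


# ---------------------------------------------------------------------------
# configuration & records
# ---------------------------------------------------------------------------

@dataclass
class SeverityEffects:
    """Slopes of the deterministic severity-linked deformations.

    All effects are linear in the latent severity ``s`` in [0, 1]:

    cartilage_shrink
        fractional loss of cartilage thickness (and hence volume) at s=1;
        cartilage is scaled along SI about its centroid by ``1 - shrink*s``.
    meniscus_flatten
        fractional loss of meniscal height at s=1; the meniscus is scaled by
        ``f = 1 - flatten*s`` along SI and by ``1/sqrt(f)`` in-plane, which
        preserves its volume exactly.
    extrusion_mm
        medio-lateral outward translation of each meniscus, mm at s=1.
    bone_bump_mm
        radial osteophyte-like bump amplitude on bone surfaces, mm at s=1,
        localized on the antero-posterior aspect.
    """

    cartilage_shrink: float = 0.5
    meniscus_flatten: float = 0.35
    extrusion_mm: float = 6.0
    bone_bump_mm: float = 3.0

    @classmethod
    def none(cls) -> "SeverityEffects":
        """All slopes zero — severity leaves the anatomy untouched."""
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort (one visit)."""

    n_knees: int = 300
    seed: int = 0
    voxel_spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    n_shape_modes: int = 3
    mode_sd_mm: tuple[float, ...] = (2.0, 1.0, 0.5)
    severity_effects: SeverityEffects = field(default_factory=SeverityEffects)
    #: ascending severity cut-points for KLG 0..4
    klg_thresholds: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    #: ascending severity cut-points for mJSN / lJSN 0..3
    mjsn_thresholds: tuple[float, ...] = (0.35, 0.6, 0.85)
    ljsn_thresholds: tuple[float, ...] = (0.45, 0.7, 0.9)
    grade_noise_sd: float = 0.12
    #: SD of the per-structure deviation of disease expression from the
    #: common latent severity.  Osteoarthritis expresses unevenly across
    #: tissues; independent per-structure deviations make multi-structure
    #: feature sets complementary readouts of the latent, as in real
    #: cohorts.  0 makes every structure express the latent exactly.
    expression_noise_sd: float = 0.15
    #: per-horizon intercepts beta0 (ascending) and severity slope beta1
    tkr_beta0: tuple[float, ...] = (-3.5, -3.1, -2.8, -2.6, -2.4)
    tkr_beta1: float = 3.5
    koa_beta0: tuple[float, ...] = (-2.5, -2.2, -2.0, -1.8, -1.6)
    koa_beta1: float = 2.5
    height_mean_m: float = 1.70
    height_sd_m: float = 0.10
    visit: str = "v00"

    def validate(self) -> None:
        if self.n_knees < 1:
            raise ValueError("n_knees must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel_spacing_mm must be positive")
        for name, thr in (("klg_thresholds", self.klg_thresholds),
                          ("mjsn_thresholds", self.mjsn_thresholds),
                          ("ljsn_thresholds", self.ljsn_thresholds)):
            if any(b <= a for a, b in zip(thr, thr[1:])):
                raise ValueError(f"{name} must be strictly ascending: {thr}")
        if len(self.mode_sd_mm) != self.n_shape_modes:
            raise ValueError("mode_sd_mm length must equal n_shape_modes")
        if any(b >= a for a, b in zip(self.mode_sd_mm, self.mode_sd_mm[1:])):
            raise ValueError("mode_sd_mm must be strictly descending")
        if any(sd < 0 for sd in self.mode_sd_mm):
            raise ValueError("mode_sd_mm must be non-negative")
        if len(self.tkr_beta0) != len(HORIZONS) or len(self.koa_beta0) != len(HORIZONS):
            raise ValueError("outcome intercepts must cover horizons 1..5")
        if (self.grade_noise_sd < 0 or self.height_sd_m < 0
                or self.expression_noise_sd < 0):
            raise ValueError("noise scales must be non-negative")
        if self.height_mean_m <= 0:
            raise ValueError("height_mean_m must be positive")


@dataclass
class KneeRecord:
    """Per-knee metadata, grades and outcomes for one visit."""

    knee_id: str
    visit: str
    side: str                    # left | right
    height_m: float
    severity: float              # latent, in [0, 1]
    klg: int                     # 0..4
    mjsn: int                    # 0..3
    ljsn: int                    # 0..3
    #: horizon_years -> 1 (event), 0 (no event); incident KOA is None
    #: ("not at risk") whenever baseline KLG >= 2
    incident_koa_within: dict[int, int | None] = field(default_factory=dict)
    tkr_within: dict[int, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _icosphere(subdivisions: int = 3) -> SurfaceMesh:
    import trimesh
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return SurfaceMesh(np.asarray(m.vertices, float), np.asarray(m.faces, np.int64))


def _ellipsoid(center, semi_axes, subdivisions: int = 3) -> SurfaceMesh:
    m = _icosphere(subdivisions)
    m.vertices = m.vertices * np.asarray(semi_axes, float) + np.asarray(center, float)
    return m


def _capped_cylinder(radius: float, z0: float, z1: float,
                     n_theta: int = 48, n_z: int = 8) -> SurfaceMesh:
    """Closed cylinder with axis along SI, fan-capped ends, outward winding."""
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    zs = np.linspace(z0, z1, n_z + 1)
    ring = np.stack([radius * np.cos(thetas), radius * np.sin(thetas)], axis=1)
    verts = []
    for z in zs:
        verts.append(np.column_stack([ring, np.full(n_theta, z)]))
    verts = np.concatenate(verts)
    faces = []
    for i in range(n_z):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append((a, b, d))
            faces.append((a, d, c))
    bot_c = len(verts)
    top_c = len(verts) + 1
    verts = np.vstack([verts, [0.0, 0.0, z0], [0.0, 0.0, z1]])
    for j in range(n_theta):
        faces.append((bot_c, (j + 1) % n_theta, j))                     # bottom cap
        faces.append((top_c, n_z * n_theta + j,
                      n_z * n_theta + (j + 1) % n_theta))               # top cap
    return SurfaceMesh(verts, np.asarray(faces, np.int64))


def _meniscus(center_ml: float, outer_theta_deg: float,
              r_mid: float = 14.0, half_width: float = 5.0,
              z0: float = 6.8, z1: float = 11.3,
              arc_deg: float = 220.0, n_seg: int = 48) -> SurfaceMesh:
    """C-shaped wedge: trapezoidal cross-section swept along a circular arc.

    The cross-section is tall at the peripheral (outer) rim and tapers to a
    short vertical inner edge, the classic meniscal wedge.  Both rims are
    vertical-walled so the axial footprint of the solid has full thickness
    everywhere — planted footprint fractions are then recoverable from
    voxelized data without vanishing-thickness bias.  The arc is centred on
    the compartment's outer direction, so the C opens toward the
    intercondylar notch.
    """
    # profile polygon in (radial, z): outer wall tall, inner wall short
    zm = z0 + 0.25 * (z1 - z0)
    profile = np.array([
        [r_mid + half_width, z0],
        [r_mid + half_width, z1],
        [r_mid - half_width, zm + 0.75],
        [r_mid - half_width, zm - 0.75],
    ])
    th_c = math.radians(outer_theta_deg)
    half = math.radians(arc_deg) / 2.0
    thetas = np.linspace(th_c - half, th_c + half, n_seg + 1)
    m = len(profile)
    verts = np.empty(((n_seg + 1) * m, 3))
    for i, th in enumerate(thetas):
        c, s = math.cos(th), math.sin(th)
        verts[i * m:(i + 1) * m, 0] = center_ml + profile[:, 0] * c
        verts[i * m:(i + 1) * m, 1] = profile[:, 0] * s
        verts[i * m:(i + 1) * m, 2] = profile[:, 1]
    faces = []
    for i in range(n_seg):
        for j in range(m):
            a = i * m + j
            b = i * m + (j + 1) % m
            c2 = (i + 1) * m + j
            d = (i + 1) * m + (j + 1) % m
            faces.append((a, b, d))
            faces.append((a, d, c2))
    # end caps: fan triangulation of the profile polygon
    for j in range(1, m - 1):
        faces.append((0, j, j + 1))
    last = n_seg * m
    for j in range(1, m - 1):
        faces.append((last, last + j + 1, last + j))
    import trimesh
    tm = trimesh.Trimesh(verts, np.asarray(faces, np.int64), process=False)
    trimesh.repair.fix_normals(tm)  # consistent outward winding
    mesh = SurfaceMesh(np.asarray(tm.vertices, float),
                       np.asarray(tm.faces, np.int64))
    _fix_winding(mesh)
    return mesh


def _fix_winding(mesh: SurfaceMesh) -> None:
    from .geometry import mesh_enclosed_volume
    if mesh_enclosed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1]


def _condyle_bumps(mesh: SurfaceMesh, amplitude: float, z_center: float,
                   z_sigma: float = 8.0) -> None:
    """Two smooth radial condyle bumps at +-18 mm ML, in place."""
    x, y, z = mesh.vertices.T
    rho = np.hypot(x, y)
    ok = rho > 1e-9
    g = np.exp(-((z - z_center) ** 2) / (2 * z_sigma ** 2))
    bump = np.exp(-((x - 18.0) ** 2 + y ** 2) / (2 * 12.0 ** 2)) \
        + np.exp(-((x + 18.0) ** 2 + y ** 2) / (2 * 12.0 ** 2))
    d = amplitude * g * bump
    mesh.vertices[ok, 0] += d[ok] * x[ok] / rho[ok]
    mesh.vertices[ok, 1] += d[ok] * y[ok] / rho[ok]


def build_templates() -> dict[str, SurfaceMesh]:
    """Six closed template meshes in a shared right-knee anatomical frame.

    Frame: axis 0 medio-lateral (medial = negative ML for a right knee),
    axis 1 antero-posterior, axis 2 inferio-superior; the tibial plateau
    top sits just below z = 0.  Menisci sit on the tibial-plateau footprint
    with their peripheral rim exactly at the plateau edge, so baseline
    meniscal extrusion is 0 mm.  Deterministic: repeated calls return
    identical vertex arrays.
    """
    templates: dict[str, SurfaceMesh] = {}
    fb = _capped_cylinder(radius=36.0, z0=25.0, z1=65.0)
    _condyle_bumps(fb, amplitude=3.0, z_center=30.0)
    templates["FB"] = fb
    templates["TB"] = _capped_cylinder(radius=40.0, z0=-40.0, z1=-0.75)
    templates["FC"] = _ellipsoid((0.0, 0.0, 20.0), (36.0, 28.0, 3.2))
    templates["mTC"] = _ellipsoid((-18.0, 0.0, 3.0), (14.0, 18.0, 3.0))
    templates["lTC"] = _ellipsoid((18.0, 0.0, 3.0), (14.0, 18.0, 3.0))
    # peripheral rim at |ML| = 21 + 19 = 40 = plateau radius -> extrusion 0
    templates["mM"] = _meniscus(center_ml=-21.0, outer_theta_deg=180.0)
    templates["lM"] = _meniscus(center_ml=21.0, outer_theta_deg=0.0)
    for mesh in templates.values():
        _fix_winding(mesh)
    return templates


# ---------------------------------------------------------------------------
# planted variation modes
# ---------------------------------------------------------------------------

def _vertex_adjacency(mesh: SurfaceMesh) -> list[np.ndarray]:
    nb: list[set[int]] = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.faces:
        nb[a].update((b, c)); nb[b].update((a, c)); nb[c].update((a, b))
    return [np.fromiter(s, dtype=np.int64) for s in nb]


def _rigid_basis(vertices: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 3V) of infinitesimal rigid motions at a shape."""
    v = vertices - vertices.mean(axis=0)
    n = len(v)
    basis = np.zeros((6, n, 3))
    for i in range(3):
        basis[i, :, i] = 1.0                     # translations
    axes = np.eye(3)
    for i in range(3):
        basis[3 + i] = np.cross(axes[i], v)      # rotations about centroid
    flat = basis.reshape(6, -1)
    q, _ = np.linalg.qr(flat.T)
    return q.T                                   # (6, 3V)


def planted_modes(mesh: SurfaceMesh, k: int,
                  seed: int = _TEMPLATE_MODE_SEED) -> np.ndarray:
    """``k`` smooth orthonormal displacement fields, shape (k, V, 3).

    Fields are mutually orthonormal in R^(3V) and orthogonal to the
    six-dimensional space of infinitesimal rigid motions of the template,
    so rigid Procrustes alignment downstream cannot absorb any part of
    them.  Deterministic for a given mesh and seed.
    """
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((k, mesh.n_vertices, 3))
    nb = _vertex_adjacency(mesh)
    for _ in range(10):  # Laplacian smoothing for spatial coherence
        sm = np.empty_like(raw)
        for i, neigh in enumerate(nb):
            sm[:, i] = 0.5 * raw[:, i] + 0.5 * raw[:, neigh].mean(axis=1)
        raw = sm
    flat = raw.reshape(k, -1)
    rig = _rigid_basis(mesh.vertices)
    flat = flat - (flat @ rig.T) @ rig
    q, _ = np.linalg.qr(flat.T)
    modes = q.T.reshape(k, mesh.n_vertices, 3)
    # sign convention: largest-magnitude component positive
    for mk in modes:
        fl = mk.ravel()
        if fl[np.argmax(np.abs(fl))] < 0:
            mk *= -1.0
    return modes


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _grade(severity: float, thresholds, noise: float) -> int:
    g = severity + noise
    return int(np.sum(g >= np.asarray(thresholds)))


def _deform_knee(templates: dict[str, SurfaceMesh],
                 modes: dict[str, np.ndarray],
                 coeffs: dict[str, np.ndarray],
                 severity: dict[str, float],
                 eff: SeverityEffects,
                 side: str) -> dict[str, SurfaceMesh]:
    out: dict[str, SurfaceMesh] = {}
    for name, tpl in templates.items():
        v = tpl.vertices.copy()
        s = severity[name]
        if name in modes and len(coeffs.get(name, ())):
            v = v + np.tensordot(coeffs[name], modes[name], axes=(0, 0))
        if name in ("FC", "mTC", "lTC") and eff.cartilage_shrink:
            cz = v[:, 2].mean()
            v[:, 2] = cz + (v[:, 2] - cz) * (1.0 - eff.cartilage_shrink * s)
        if name in ("mM", "lM"):
            if eff.meniscus_flatten:
                f = 1.0 - eff.meniscus_flatten * s
                c = v.mean(axis=0)
                v[:, 2] = c[2] + (v[:, 2] - c[2]) * f
                v[:, :2] = c[:2] + (v[:, :2] - c[:2]) / math.sqrt(f)
            if eff.extrusion_mm:
                outward = -1.0 if name == "mM" else 1.0  # right-knee frame
                v[:, 0] += outward * eff.extrusion_mm * s
        if name in ("FB", "TB") and eff.bone_bump_mm:
            x, y, z = v.T
            rho = np.hypot(x, y)
            ok = rho > 1e-9
            ap = np.zeros_like(rho)
            ap[ok] = np.abs(y[ok]) / rho[ok]
            w = np.clip((ap - 0.7) / 0.3, 0.0, 1.0)   # AP aspect only
            zj = 25.0 if name == "FB" else -0.75       # joint-line end
            g = np.exp(-((z - zj) ** 2) / (2 * 10.0 ** 2))
            d = eff.bone_bump_mm * s * w * g
            v[ok, 0] += d[ok] * x[ok] / rho[ok]
            v[ok, 1] += d[ok] * y[ok] / rho[ok]
        faces = tpl.faces
        if side == "left":  # mirror ML, restore outward winding
            v = v.copy()
            v[:, 0] *= -1.0
            faces = faces[:, ::-1]
        out[name] = SurfaceMesh(v, faces.copy())
    return out


def sample_cohort(cfg: CohortConfig, *, return_meshes: bool = True
                  ) -> tuple[list[KneeRecord], list[dict[str, SurfaceMesh]]]:
    """Draw one synthetic cohort.

    Per knee: ``severity ~ Uniform(0, 1)``; shapes are the templates plus
    planted-mode displacements with per-mode Normal coefficients plus
    severity-scaled deterministic deformations; grades are thresholded
    noisy severity; outcomes follow a per-horizon logistic link made
    monotone (nested) across horizons through a shared uniform draw.

    Returns ``(records, meshes)``; ``meshes`` is empty when
    ``return_meshes`` is disabled (grades/outcomes only, e.g. for large-n
    calibration checks).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    templates = build_templates()
    modes = {s: planted_modes(templates[s], cfg.n_shape_modes)
             for s in SHAPE_STRUCTURES} if cfg.n_shape_modes else {}
    sds = np.asarray(cfg.mode_sd_mm, float)

    records: list[KneeRecord] = []
    meshes: list[dict[str, SurfaceMesh]] = []
    for i in range(cfg.n_knees):
        severity = float(rng.uniform())
        height = float(rng.normal(cfg.height_mean_m, cfg.height_sd_m))
        side = "right" if rng.uniform() < 0.5 else "left"
        coeffs = {s: rng.normal(0.0, sds) if cfg.n_shape_modes else np.empty(0)
                  for s in SHAPE_STRUCTURES}
        # per-structure disease expression: noisy readouts of the latent
        expr = rng.normal(0.0, cfg.expression_noise_sd, size=len(STRUCTURES))
        struct_sev = {s: float(np.clip(severity + e, 0.0, 1.0))
                      for s, e in zip(STRUCTURES, expr)}
        noise = (rng.normal(0.0, cfg.grade_noise_sd, size=3)
                 if cfg.grade_noise_sd > 0 else np.zeros(3))
        klg = _grade(severity, cfg.klg_thresholds, float(noise[0]))
        mjsn = _grade(severity, cfg.mjsn_thresholds, float(noise[1]))
        ljsn = _grade(severity, cfg.ljsn_thresholds, float(noise[2]))
        u_tkr, u_koa = rng.uniform(), rng.uniform()
        tkr = {h: int(u_tkr < _logistic(cfg.tkr_beta0[j] + cfg.tkr_beta1 * severity))
               for j, h in enumerate(HORIZONS)}
        if klg >= 2:
            koa: dict[int, int | None] = {h: None for h in HORIZONS}
        else:
            koa = {h: int(u_koa < _logistic(cfg.koa_beta0[j] + cfg.koa_beta1 * severity))
                   for j, h in enumerate(HORIZONS)}
        records.append(KneeRecord(
            knee_id=f"K{i:05d}", visit=cfg.visit, side=side, height_m=height,
            severity=severity, klg=klg, mjsn=mjsn, ljsn=ljsn,
            incident_koa_within=koa, tkr_within=tkr))
        if return_meshes:
            meshes.append(_deform_knee(templates, modes, coeffs, struct_sev,
                                       cfg.severity_effects, side))
    return records, meshes


# ---------------------------------------------------------------------------
# voxelization (scanline rasterizer, voxel-center-in-interior)
# ---------------------------------------------------------------------------

def _rasterize(mesh: SurfaceMesh, origin: np.ndarray,
               spacing: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean mask of voxels whose center lies inside the closed mesh.

    Casts one ray per (ML, AP) voxel column along SI and fills between
    crossing pairs (even-odd rule).  Ray origins are jittered by a tiny
    irrational offset so rays never hit triangle edges exactly.
    """
    nx, ny, nz = shape
    jx = 1e-6 * spacing[0] * math.sqrt(2.0)
    jy = 1e-6 * spacing[1] * math.sqrt(3.0)
    tri = mesh.vertices[mesh.faces]              # (T, 3, 3)

    cx = origin[0] + (np.arange(nx) + 0.5) * spacing[0] + jx
    cy = origin[1] + (np.arange(ny) + 0.5) * spacing[1] + jy

    # candidate (triangle, column) pairs from projected bounding boxes
    txmin, txmax = tri[:, :, 0].min(1), tri[:, :, 0].max(1)
    tymin, tymax = tri[:, :, 1].min(1), tri[:, :, 1].max(1)
    ix0 = np.ceil((txmin - origin[0] - jx) / spacing[0] - 0.5).astype(np.int64)
    ix1 = np.floor((txmax - origin[0] - jx) / spacing[0] - 0.5).astype(np.int64)
    iy0 = np.ceil((tymin - origin[1] - jy) / spacing[1] - 0.5).astype(np.int64)
    iy1 = np.floor((tymax - origin[1] - jy) / spacing[1] - 0.5).astype(np.int64)
    np.clip(ix0, 0, nx - 1, out=ix0); np.clip(ix1, 0, nx - 1, out=ix1)
    np.clip(iy0, 0, ny - 1, out=iy0); np.clip(iy1, 0, ny - 1, out=iy1)
    ncx = np.maximum(ix1 - ix0 + 1, 0)
    ncy = np.maximum(iy1 - iy0 + 1, 0)
    counts = ncx * ncy
    keep = counts > 0
    if not keep.any():
        return np.zeros(shape, dtype=bool)
    tri, ix0, iy0, ncx, ncy, counts = (a[keep] for a in
                                       (tri, ix0, iy0, ncx, ncy, counts))
    total = int(counts.sum())
    t_idx = np.repeat(np.arange(len(tri)), counts)
    offs = np.concatenate([[0], np.cumsum(counts)[:-1]])
    k = np.arange(total) - np.repeat(offs, counts)
    ix = ix0[t_idx] + k // ncy[t_idx]
    iy = iy0[t_idx] + k % ncy[t_idx]

    px, py = cx[ix], cy[iy]
    a, b, c = tri[t_idx, 0], tri[t_idx, 1], tri[t_idx, 2]
    v0 = b[:, :2] - a[:, :2]
    v1 = c[:, :2] - a[:, :2]
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    nz_det = np.abs(det) > 1e-12
    p = np.column_stack([px, py]) - a[:, :2]
    safe_det = np.where(nz_det, det, 1.0)
    u = (p[:, 0] * v1[:, 1] - p[:, 1] * v1[:, 0]) / safe_det
    w = (v0[:, 0] * p[:, 1] - v0[:, 1] * p[:, 0]) / safe_det
    hit = nz_det & (u >= 0) & (w >= 0) & (u + w <= 1)
    if not hit.any():
        return np.zeros(shape, dtype=bool)
    zc = a[hit, 2] + u[hit] * (b[hit, 2] - a[hit, 2]) + w[hit] * (c[hit, 2] - a[hit, 2])
    col = ix[hit] * ny + iy[hit]

    order = np.lexsort((zc, col))
    col, zc = col[order], zc[order]
    _, start, ccount = np.unique(col, return_index=True, return_counts=True)
    if np.any(ccount % 2):
        raise ValueError("odd ray-crossing count; mesh is not closed")
    z0, z1 = zc[0::2], zc[1::2]
    pcol = col[0::2]
    k0 = np.ceil((z0 - origin[2]) / spacing[2] - 0.5).astype(np.int64)
    k1 = np.floor((z1 - origin[2]) / spacing[2] - 0.5).astype(np.int64)
    np.clip(k0, 0, nz - 1, out=k0); np.clip(k1, 0, nz - 1, out=k1)
    ok = k1 >= k0
    diff = np.zeros((nx * ny, nz + 1), dtype=np.int16)
    np.add.at(diff, (pcol[ok], k0[ok]), 1)
    np.add.at(diff, (pcol[ok], k1[ok] + 1), -1)
    return (np.cumsum(diff[:, :-1], axis=1) > 0).reshape(nx, ny, nz)


def voxelize(meshes: dict[str, SurfaceMesh],
             spacing: tuple[float, float, float],
             side: str = "right",
             margin_voxels: int = 2) -> LabelVolume:
    """Label volume from closed structure meshes.

    Each voxel is labeled by the structure whose interior contains its
    center, 0 otherwise.  Raises :class:`OverlapError` naming the first
    colliding structure pair if two interiors claim the same voxel.
    An empty mesh map yields an all-background 1-voxel volume.
    """
    spacing_arr = np.asarray(spacing, float)
    if len(meshes) == 0:
        return LabelVolume(np.zeros((1, 1, 1), dtype=np.uint8), tuple(spacing_arr),
                           side=side)
    lo = np.min([m.vertices.min(axis=0) for m in meshes.values()], axis=0)
    hi = np.max([m.vertices.max(axis=0) for m in meshes.values()], axis=0)
    origin = lo - margin_voxels * spacing_arr
    shape = tuple(int(np.ceil((h - o) / s)) + margin_voxels
                  for h, o, s in zip(hi, origin, spacing_arr))
    labels = np.zeros(shape, dtype=np.uint8)
    owner: dict[int, str] = {}
    for name, mesh in meshes.items():
        mask = _rasterize(mesh, origin, spacing_arr, shape)
        clash = mask & (labels != 0)
        if clash.any():
            prev = owner[int(labels[clash][0])]
            raise OverlapError(f"structures {prev!r} and {name!r} overlap "
                               f"at {int(clash.sum())} voxel(s)")
        labels[mask] = LABELS[name]
        owner[LABELS[name]] = name
    return LabelVolume(labels, tuple(spacing_arr), side=side)
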