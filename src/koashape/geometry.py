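"""Label volumes, boundary meshes and primitive geometric measures.

A :class:`LabelVolume` is a 3-D voxel grid of disjoint integer structure
labels with physical spacing.  The axis convention used throughout the
package is

* axis 0 — medio-lateral (ML),
* axis 1 — antero-posterior (AP),
* axis 2 — inferio-superior (SI),

and world coordinates are ``index * spacing`` (no origin offset).  Surfaces
are extracted per structure as triangulated iso-surfaces of the binarized
mask at iso-level 0.5.  Volume features are computed by voxel counting; the
mesh-enclosed (divergence-theorem) volume is provided as an independent
cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure as _skmeasure

#: Fixed label encoding, identical in every NIfTI header this package writes.
LABELS = {
    "background": 0,
    "FB": 1,   # femoral bone
    "TB": 2,   # tibial bone
    "FC": 3,   # femoral cartilage
    "mTC": 4,  # medial tibial cartilage
    "lTC": 5,  # lateral tibial cartilage
    "mM": 6,   # medial meniscus
    "lM": 7,   # lateral meniscus
}

#: The anatomical structures, in label order.
STRUCTURES = ("FB", "TB", "FC", "mTC", "lTC", "mM", "lM")

AXIS_CONVENTION = "axis0=ML, axis1=AP, axis2=SI"


class EmptyStructureError(ValueError):
    """Raised when an operation requires a label that is absent from a volume."""


class OpenMeshError(ValueError):
    """Raised when a closed surface is required but the mesh has boundary edges."""


@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices in mm, triangle vertex indices."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray     # (F, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy())

    def is_closed(self) -> bool:
        """True if the surface is watertight *and* consistently oriented:
        every undirected edge shared by exactly two faces, every directed
        edge used exactly once."""
        directed = np.concatenate([self.faces[:, [0, 1]],
                                   self.faces[:, [1, 2]],
                                   self.faces[:, [2, 0]]])
        if len(directed) == 0:
            return False
        _, d_counts = np.unique(directed, axis=0, return_counts=True)
        if np.any(d_counts != 1):
            return False
        edges = np.sort(directed, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


@dataclass
class LabelVolume:
    """Voxel grid of disjoint structure labels with physical spacing (mm)."""

    labels: np.ndarray            # (nx, ny, nz) integer
    spacing_mm: tuple[float, float, float]
    side: str = "right"           # left | right
    axis_convention: str = AXIS_CONVENTION

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label array must be rank 3")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be three positive values")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        lab = np.unique(self.labels)
        if lab.size and (lab.min() < 0 or lab.max() > 7):
            raise ValueError("labels must lie in 0..7")

    def mask(self, structure: str) -> np.ndarray:
        return self.labels == LABELS[structure]

    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel."""
        return float(np.prod(self.spacing_mm))

    def mirrored_ml(self) -> "LabelVolume":
        """Mirror on the medio-lateral axis, flipping the side flag."""
        other = "left" if self.side == "right" else "right"
        return LabelVolume(self.labels[::-1].copy(), self.spacing_mm, side=other)


# ---------------------------------------------------------------------------
# primitive measures
# ---------------------------------------------------------------------------

def voxel_volume(vol: LabelVolume, structure: str) -> float:
    """Structure volume in mm^3 by voxel counting (0.0 if absent)."""
    return int(np.count_nonzero(vol.mask(structure))) * vol.voxel_volume_mm3()


#: Default Gaussian pre-smoothing of the binary mask, in voxels, before
#: iso-surfacing.  A binarized mask produces a staircase surface whose area
#: overestimates the true area by ~9% for a sphere; a small smoothing kernel
#: removes that bias while keeping corner rounding negligible.  0.6 voxels
#: keeps both the analytic sphere-area and cube-volume oracles within their
#: tolerances at 0.5-1.0 mm spacing (see the geometry tests).
SMOOTH_SIGMA_VOX = 0.6

_PAD = 3  # background padding so smoothed structures never touch the border


def extract_surface(vol: LabelVolume, structure: str,
                    smooth_sigma_vox: float = SMOOTH_SIGMA_VOX) -> SurfaceMesh:
    """Iso-surface (level 0.5) of the binarized structure mask.

    The mask is padded with background, optionally smoothed with a small
    Gaussian (``smooth_sigma_vox`` in voxel units, 0 disables), and
    triangulated by marching cubes at iso-level 0.5.  Vertices are returned
    in world mm, ``index * spacing``; the mesh is closed whenever the
    structure does not touch the volume border.

    Raises
    ------
    EmptyStructureError
        If the label does not occur in the volume.
    """
    binary = vol.mask(structure)
    if not binary.any():
        raise EmptyStructureError(
            f"structure {structure!r} (label {LABELS[structure]}) "
            "is absent from the volume")
    field_ = np.pad(binary, _PAD).astype(np.float32)
    if smooth_sigma_vox > 0:
        from scipy import ndimage
        field_ = ndimage.gaussian_filter(field_, smooth_sigma_vox)
    verts, faces, _normals, _vals = _skmeasure.marching_cubes(
        field_, level=0.5, spacing=vol.spacing_mm)
    verts = verts - _PAD * np.asarray(vol.spacing_mm)  # undo the padding
    mesh = SurfaceMesh(verts, faces)
    if mesh_enclosed_volume(mesh) < 0:  # enforce outward winding
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def mesh_surface_area(mesh: SurfaceMesh) -> float:
    """Total triangle area in mm^2 (compensated summation, order invariant)."""
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    total = math.fsum(np.sort(areas).tolist())
    if total <= 0.0:
        raise ValueError("degenerate mesh: zero total surface area")
    return total


def mesh_enclosed_volume(mesh: SurfaceMesh, *, require_closed: bool = True) -> float:
    """Signed enclosed volume in mm^3 via the divergence theorem.

    Positive for outward-oriented (counter-clockwise seen from outside)
    winding.  Requires a closed mesh unless ``require_closed`` is disabled.
    """
    if require_closed and not mesh.is_closed():
        raise OpenMeshError("mesh has boundary edges; enclosed volume undefined")
    tri = mesh.vertices[mesh.faces]
    # signed tetra volumes against the origin
    vols = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(math.fsum(np.sort(vols).tolist()))


def axial_footprint(vol: LabelVolume, structure: str) -> np.ndarray:
    """Boolean (nx, ny) map of voxel columns containing the structure."""
    return vol.mask(structure).any(axis=2)
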