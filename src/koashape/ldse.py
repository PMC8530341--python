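"""Low-dimensional shape encoding (LDSE) via statistical shape models.

Corresponded surface meshes of one structure (identical triangulation and
vertex count across the cohort) are rigidly aligned by generalized
Procrustes analysis, a mean shape is computed, and the variation about the
mean is decomposed into orthonormal vertex-displacement modes ordered by
explained variance — PCA in the tangent space at the mean, the linearized
form of principal geodesic analysis, which is first-order exact for the
small deformations of interest here.  Each shape is then encoded by its
projections onto the leading modes (at most 300 per structure), and a
combined encoding concatenates the first 75 coefficients of four
structures into a single 300-vector.

Alignment is rigid (rotation + translation, no scaling): overall size is
disease-relevant for osteoarthritic bone, so scale is deliberately kept in
the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["CorrespondedShapeSet", "ShapeModel", "LdseVector", "align_shapes",
           "align_to", "fit_shape_model", "encode_shape", "decode",
           "combine_encodings", "MAX_MODES", "COMBINE_BLOCK"]

logger = logging.getLogger(__name__)

#: Maximum number of coefficients retained per structure.
MAX_MODES = 300
#: Leading coefficients per structure entering the combined encoding.
COMBINE_BLOCK = 75
#: Cumulative variance share retained by a fitted model: trailing modes
#: beyond this carry (numerically) negligible shape variation, and range
#: normalization downstream would inflate their coefficients into noise.
VARIANCE_SHARE = 0.999


@dataclass
class CorrespondedShapeSet:
    """Shapes of one structure sharing a single triangulation vertex-for-vertex."""

    structure: str
    faces: np.ndarray               # (F, 3) shared triangle list
    vertices: np.ndarray            # (n_shapes, V, 3)
    cohort: str = ""
    shape_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 3 or self.vertices.shape[2] != 3:
            raise ValueError("vertices must be (n_shapes, V, 3)")

    @property
    def n_shapes(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[1]


@dataclass
class ShapeModel:
    """Mean shape with orthonormal variation modes ordered by variance."""

    structure: str
    mean: np.ndarray        # (V, 3)
    modes: np.ndarray       # (k, V, 3), orthonormal in R^(3V)
    variances: np.ndarray   # (k,), non-increasing, mm^2
    n_train: int
    cohort: str = ""

    @property
    def n_modes(self) -> int:
        return len(self.variances)

    def variance_share(self) -> np.ndarray:
        """Cumulative fraction of total variance explained by leading modes."""
        total = self.variances.sum()
        if total <= 0:
            return np.ones_like(self.variances)
        return np.cumsum(self.variances) / total


@dataclass
class LdseVector:
    """Shape-encoding coefficients of one shape, ordered as the model's modes."""

    structure: str
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        if len(self.coefficients) > MAX_MODES:
            raise ValueError(f"encoding longer than {MAX_MODES}")


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid (R, t) minimizing ||R src + t - dst||; no scaling."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, dc - r @ sc


def align_to(reference: np.ndarray, shape: np.ndarray) -> np.ndarray:
    """Rigidly align one vertex array to a reference (same correspondence)."""
    if shape.shape != reference.shape:
        raise ValueError(f"vertex count mismatch: {shape.shape} vs {reference.shape}")
    r, t = _kabsch(shape, reference)
    return shape @ r.T + t


def align_shapes(shape_set: CorrespondedShapeSet,
                 tol_mm: float = 1e-6, max_iter: int = 100) -> CorrespondedShapeSet:
    """Generalized Procrustes alignment (rigid, no scaling).

    Iteratively aligns every shape to the evolving mean until the mean
    moves less than ``tol_mm`` (RMS per vertex) or ``max_iter`` rounds.
    """
    counts = {v.shape for v in shape_set.vertices}
    if len(counts) > 1:
        raise ValueError(f"inconsistent vertex arrays in set: {counts}")
    verts = shape_set.vertices.copy()
    verts -= verts.mean(axis=1, keepdims=True)      # center all shapes
    mean = verts[0].copy()
    for _ in range(max_iter):
        for i in range(len(verts)):
            verts[i] = align_to(mean, verts[i])
        new_mean = verts.mean(axis=0)
        shift = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        if shift < tol_mm:
            break
    return CorrespondedShapeSet(shape_set.structure, shape_set.faces, verts,
                                cohort=shape_set.cohort,
                                shape_ids=shape_set.shape_ids)


def fit_shape_model(shape_set: CorrespondedShapeSet,
                    variance_share: float = VARIANCE_SHARE) -> ShapeModel:
    """Fit mean + variation modes to an aligned corresponded set.

    The mean is the vertex-wise average; modes and variances come from the
    eigendecomposition of the centered vertex-coordinate covariance
    (computed via thin SVD).  Modes are orthonormal displacement fields
    ordered by non-increasing variance.  Retained are the leading
    non-degenerate modes — capped at ``min(300, n_train - 1, 3V - 7)``,
    above the matrix-rank tolerance on the singular values, and up to the
    smallest count whose cumulative explained variance reaches
    ``variance_share`` — trailing modes carry negligible shape variation
    and would only be inflated into noise by range normalization
    downstream.  Each mode's sign is fixed so its largest-magnitude
    component is positive, making encodings reproducible across runs and
    platforms.
    """
    n = shape_set.n_shapes
    if n < 2:
        raise ValueError("need at least 2 shapes to fit a shape model")
    v = shape_set.n_vertices
    mean = shape_set.vertices.mean(axis=0)
    x = (shape_set.vertices - mean).reshape(n, 3 * v)
    _u, s, vt = np.linalg.svd(x, full_matrices=False)
    variances = s ** 2 / (n - 1)
    rank = int(np.sum(s > s[0] * max(n, 3 * v) * np.finfo(float).eps)) if s.size else 0
    k = int(min(MAX_MODES, n - 1, 3 * v - 7, max(rank, 1)))
    total = variances.sum()
    if total > 0 and 0 < variance_share < 1:
        k_var = int(np.searchsorted(np.cumsum(variances[:k]) / total,
                                    variance_share) + 1)
        k = min(k, max(k_var, 1))
    variances, vt = variances[:k], vt[:k]
    for row in vt:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return ShapeModel(structure=shape_set.structure, mean=mean,
                      modes=vt.reshape(k, v, 3), variances=variances,
                      n_train=n, cohort=shape_set.cohort)


def encode_shape(model: ShapeModel, shape: np.ndarray,
                 n_coeff: int | None = None) -> LdseVector:
    """Project a (pre-aligned) shape onto the model's leading modes."""
    shape = np.asarray(shape, dtype=float)
    if shape.shape != model.mean.shape:
        raise ValueError(
            f"vertex count mismatch: shape {shape.shape} vs model {model.mean.shape}")
    k = model.n_modes if n_coeff is None else min(n_coeff, model.n_modes)
    diff = (shape - model.mean).ravel()
    coeff = model.modes[:k].reshape(k, -1) @ diff
    return LdseVector(model.structure, coeff)


def decode(model: ShapeModel, vec: LdseVector) -> np.ndarray:
    """Reconstruct a vertex array from an encoding (truncation residual remains)."""
    k = len(vec.coefficients)
    disp = vec.coefficients @ model.modes[:k].reshape(k, -1)
    return model.mean + disp.reshape(model.mean.shape)


def combine_encodings(fb: LdseVector, tb: LdseVector,
                      mm: LdseVector, lm: LdseVector) -> np.ndarray:
    """Combined encoding: first 75 coefficients of FB, TB, mM, lM, in that
    block order; short blocks are zero-padded to 75 (logged)."""
    blocks = []
    for vec in (fb, tb, mm, lm):
        c = vec.coefficients[:COMBINE_BLOCK]
        if len(c) < COMBINE_BLOCK:
            logger.warning("encoding for %s has %d < %d coefficients; zero-padding",
                           vec.structure, len(c), COMBINE_BLOCK)
            c = np.concatenate([c, np.zeros(COMBINE_BLOCK - len(c))])
        blocks.append(c)
    return np.concatenate(blocks)
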