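"""Thin-plate-spline warping of the reference mesh to group-mean landmarks,
plus scaling to average population size and canonical orientation.

The 3D TPS uses the biharmonic kernel U(r) = r (the r^2 log r kernel is the
2D special case and is not used here).  A fitted transform interpolates the
control landmarks exactly, and its nonlinear part vanishes whenever the
target configuration is an affine image of the source, so warps degrade
gracefully to similarity/affine maps.

Canonical jaw orientation: the most anterior point of the dentary in the
negative x direction, occlusal surfaces in positive y, the parasagittal
plane in positive z.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_io import DegenerateInputError, SurfaceMesh, ValidationError

__all__ = ["TPSTransform", "WarpedJaw", "fit_tps", "warp_mesh", "scale_and_orient"]


@dataclass
class TPSTransform:
    source: np.ndarray  # (k, 3) control sources
    target: np.ndarray  # (k, 3) control targets
    weights: np.ndarray  # (k, 3) nonlinear coefficients
    affine: np.ndarray  # (4, 3): rows = translation then linear map

    def __call__(self, points: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(P[:, None, :] - self.source[None, :, :], axis=2)
        out = r @ self.weights + self.affine[0] + P @ self.affine[1:]
        return out.reshape(np.shape(points))

    @property
    def bending_energy(self) -> float:
        """Bending energy -w' K w summed over output dimensions (the r kernel
        is conditionally negative definite in 3D, hence the sign); zero iff
        the map is purely affine (up to round-off)."""
        K = np.linalg.norm(
            self.source[:, None, :] - self.source[None, :, :], axis=2
        )
        return float(-np.sum(self.weights * (K @ self.weights)))


def fit_tps(source: np.ndarray, target: np.ndarray) -> TPSTransform:
    """Fit a 3D thin-plate spline mapping source landmarks onto targets.

    Requires >= 4 non-coplanar source points.  The side condition makes the
    nonlinear coefficients orthogonal to the affine space (P' w = 0), which
    gives exact affine reproduction for affine targets.
    """
    S = np.asarray(source, dtype=float)
    T = np.asarray(target, dtype=float)
    if S.shape != T.shape or S.ndim != 2 or S.shape[1] != 3 or S.shape[0] < 4:
        raise ValidationError("need matching (k>=4, 3) source and target matrices")
    k = S.shape[0]
    K = np.linalg.norm(S[:, None, :] - S[None, :, :], axis=2)
    scale_hint = max(1.0, float(K.max()))
    off = K + np.eye(k) * scale_hint
    if off.min() < 1e-8 * scale_hint:
        raise DegenerateInputError(
            "duplicated source landmarks; TPS system singular"
        )
    P = np.hstack([np.ones((k, 1)), S])
    if np.linalg.matrix_rank(P, tol=1e-9 * max(1.0, np.abs(S).max())) < 4:
        raise DegenerateInputError(
            "source landmarks are coplanar or duplicated; TPS system singular"
        )
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 4, 3))
    rhs[:k] = T
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(f"singular TPS system: {exc}") from exc
    return TPSTransform(S.copy(), T.copy(), sol[:k], sol[k:])


def warp_mesh(transform: TPSTransform, mesh: SurfaceMesh) -> SurfaceMesh:
    """Apply a fitted TPS vertex-wise; connectivity is unchanged."""
    return SurfaceMesh(transform(mesh.vertices), mesh.faces.copy())


# ---------------------------------------------------------------------------
# Scaling and canonical orientation
# ---------------------------------------------------------------------------


@dataclass
class WarpedJaw:
    """A population-average jaw: warped mesh + its landmark configuration.

    ``dataset`` identifies the bone (dentary/mandible) and sample (total or
    males only); ``scale_length`` is the landmark 1–3 distance in mm after
    scaling to average population size.
    """

    population: str
    bone: str  # "dentary" | "mandible"
    sample: str  # "total" | "male"
    mesh: SurfaceMesh
    landmarks: np.ndarray
    scale_length: float | None = None

    @property
    def dataset(self) -> str:
        return f"{self.bone}_{self.sample}"


def _orientation_rotation(
    landmarks: np.ndarray,
    anterior_idx: int,
    posterior_idx: int,
    dorsal_idx: int,
) -> np.ndarray:
    """Best-fit rotation taking landmark-based anatomical directions onto the
    canonical axes: anterior->posterior along +x (so the anterior tip sits at
    negative x), dorsal (occlusal) along +y, their cross product along +z."""
    x_dir = landmarks[posterior_idx] - landmarks[anterior_idx]
    nx = np.linalg.norm(x_dir)
    if nx <= 0:
        raise DegenerateInputError("anterior and posterior landmarks coincide")
    e1 = x_dir / nx
    up = landmarks[dorsal_idx] - landmarks.mean(axis=0)
    up = up - (up @ e1) * e1
    nu = np.linalg.norm(up)
    if nu <= 1e-12 * nx:
        raise DegenerateInputError("dorsal landmark lies on the long axis")
    e2 = up / nu
    e3 = np.cross(e1, e2)
    # rows of R' are the anatomical frame; R maps frame -> canonical axes
    return np.vstack([e1, e2, e3])


def scale_and_orient(
    jaw: WarpedJaw,
    target_length: float,
    anterior_idx: int = 0,
    posterior_idx: int = 2,
    dorsal_idx: int = 1,
) -> WarpedJaw:
    """Uniformly scale the jaw so the landmark 1–3 distance equals the target
    average population length, then rotate to the canonical orientation.

    Landmarks are transformed with the mesh.  Idempotent: reapplying with
    the same target leaves the jaw unchanged.
    """
    L = np.asarray(jaw.landmarks, dtype=float)
    cur = float(np.linalg.norm(L[anterior_idx] - L[posterior_idx]))
    if cur <= 0:
        raise DegenerateInputError("zero landmark 1-3 distance; cannot scale")
    if target_length <= 0:
        raise ValidationError("target_length must be positive")
    s = target_length / cur
    R = _orientation_rotation(L, anterior_idx, posterior_idx, dorsal_idx)
    center = L.mean(axis=0)

    def xform(pts: np.ndarray) -> np.ndarray:
        return (s * (pts - center)) @ R.T

    new_lms = xform(L)
    # put the jaw midpoint of the long axis at x = 0 so anterior is at -x
    shift = 0.5 * (new_lms[anterior_idx] + new_lms[posterior_idx])
    new_lms = new_lms - shift
    new_mesh = SurfaceMesh(xform(jaw.mesh.vertices) - shift, jaw.mesh.faces.copy())
    return replace(
        jaw, mesh=new_mesh, landmarks=new_lms, scale_length=float(target_length)
    )
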