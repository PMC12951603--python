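"""Geometric morphometrics: sliding semilandmarks, GPA, shape PCA,
permutation Procrustes ANOVA and group mean shapes.

Two landmark regimes are analysed separately: 16 fixed landmarks over the
whole mandible, and a dentary-only regime of 7 fixed landmarks plus four
curves whose high-density points are downsampled to 13–16 semilandmarks and
slid to equal arc-length spacing (10 iterations by default) before
generalised Procrustes analysis.  PCA acts directly on the aligned
coordinates (no tangent-space projection; dispersions here are small enough
that the variance fractions are insensitive to the projection).
Reflections are never allowed during alignment — side standardisation (all
left mandibles) is the data producer's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DegenerateInputError, LandmarkSet, ValidationError
from .rrpp import design_blocks, rrpp_anova

__all__ = [
    "ProcrustesFit",
    "ShapeSpace",
    "resample_curve",
    "centroid_size",
    "gpa",
    "slide_semilandmarks",
    "shape_pca",
    "procrustes_anova",
    "mean_shape",
]

GPA_TOL = 1e-10
GPA_MAX_ITER = 100


# ---------------------------------------------------------------------------
# Curve resampling
# ---------------------------------------------------------------------------


def resample_curve(curve: np.ndarray, target_count: int) -> np.ndarray:
    """Resample a polyline to ``target_count`` points at equal arc length.

    Endpoints are anatomical anchors and are returned exactly.
    """
    curve = np.asarray(curve, dtype=float)
    if target_count < 3:
        raise ValidationError("target_count must be >= 3")
    if curve.ndim != 2 or curve.shape[0] < 2:
        raise ValidationError("curve must be a (m>=2, d) polyline")
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise DegenerateInputError("curve has zero length")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, target_count)
    out = np.column_stack(
        [np.interp(targets, s, curve[:, d]) for d in range(curve.shape[1])]
    )
    out[0] = curve[0]
    out[-1] = curve[-1]
    return out


# ---------------------------------------------------------------------------
# Generalised Procrustes analysis
# ---------------------------------------------------------------------------


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared distances of landmarks to their centroid."""
    c = np.asarray(config, dtype=float)
    return float(np.sqrt(np.sum((c - c.mean(axis=0)) ** 2)))


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||A R - B||_F for centred A, B."""
    u, _, vt = np.linalg.svd(A.T @ B)
    R = u @ vt
    if np.linalg.det(R) < 0:
        u[:, -1] *= -1
        R = u @ vt
    return R


@dataclass
class ProcrustesFit:
    """Result of a GPA: aligned unit-size configurations and their consensus."""

    aligned: np.ndarray  # (n, k, 3)
    centroid_sizes: np.ndarray  # (n,) original sizes, mm
    consensus: np.ndarray  # (k, 3)
    n_iterations: int
    converged: bool

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def flattened(self) -> np.ndarray:
        return self.aligned.reshape(self.aligned.shape[0], -1)


def gpa(configs) -> ProcrustesFit:
    """Generalised Procrustes analysis.

    Removes translation (centroid to origin), scale (unit centroid size) and
    rotation (least squares against an iteratively updated consensus;
    reflections disallowed).  Converges when the consensus moves by less
    than 1e-10, or after 100 iterations.
    """
    X = np.asarray(configs, dtype=float)
    if X.ndim != 3 or X.shape[0] < 2:
        raise DegenerateInputError("need >= 2 configurations of equal size")
    n, k, d = X.shape
    if k < 3:
        raise DegenerateInputError("need at least 3 landmarks")
    sizes = np.empty(n)
    A = np.empty_like(X)
    for i in range(n):
        c = X[i] - X[i].mean(axis=0)
        s = np.sqrt(np.sum(c * c))
        if s <= 0:
            raise DegenerateInputError(f"configuration {i} has zero centroid size")
        if np.linalg.matrix_rank(c, tol=1e-12 * s) < 2:
            raise DegenerateInputError(f"configuration {i} is degenerate (collinear)")
        sizes[i] = s
        A[i] = c / s
    consensus = A[0].copy()
    n_iter = 0
    converged = False
    for n_iter in range(1, GPA_MAX_ITER + 1):
        for i in range(n):
            A[i] = A[i] @ _optimal_rotation(A[i], consensus)
        new = A.mean(axis=0)
        new -= new.mean(axis=0)
        ns = np.sqrt(np.sum(new * new))
        new /= ns
        if np.max(np.abs(new - consensus)) < GPA_TOL:
            consensus = new
            converged = True
            break
        consensus = new
    # final pass so every configuration is aligned to the final consensus
    for i in range(n):
        A[i] = A[i] @ _optimal_rotation(A[i], consensus)
    return ProcrustesFit(A, sizes, A.mean(axis=0), n_iter, converged)


# ---------------------------------------------------------------------------
# Sliding semilandmarks
# ---------------------------------------------------------------------------


def slide_semilandmarks(
    landmark_sets: list[LandmarkSet],
    targets: tuple[int, ...] | None = None,
    n_iterations: int = 10,
    semilandmark_range: tuple[int, int] = (13, 16),
) -> tuple[np.ndarray, ProcrustesFit, np.ndarray]:
    """Downsample curves to semilandmarks, slide to equidistance, and fit GPA.

    Semilandmarks are repositioned each iteration to equal arc-length
    positions along their specimen's original high-density curve (the
    equidistant-curve criterion), then GPA is re-run.  Curve endpoints are
    anchors and never slide; fixed landmarks never move.

    Returns ``(configs, fit, delta)`` where ``configs`` is the (n, k, 3)
    stack of fixed landmarks + slid semilandmarks in original coordinates,
    ``fit`` the final GPA, and ``delta`` the per-iteration change in summed
    Procrustes distance to the consensus.
    """
    if not landmark_sets:
        raise DegenerateInputError("no landmark sets")
    regime = landmark_sets[0].regime
    n_curves = len(landmark_sets[0].curves)
    if any(l.regime != regime for l in landmark_sets):
        raise ValidationError("mixed landmark regimes")
    if n_curves == 0:
        raise ValidationError("regime has no curves to slide")
    lo, hi = semilandmark_range
    if targets is None:
        targets = tuple(
            int(np.clip(min(l.curves[c].shape[0] for l in landmark_sets), lo, hi))
            for c in range(n_curves)
        )
    for ls in landmark_sets:
        for c, t in zip(ls.curves, targets):
            if np.linalg.norm(np.diff(c, axis=0), axis=1).sum() <= 0:
                raise DegenerateInputError(
                    f"specimen {ls.specimen_id!r}: a curve degenerated to a point"
                )
            if c.shape[0] < t:
                raise ValidationError(
                    f"specimen {ls.specimen_id!r}: curve shorter than target {t}"
                )

    def assemble() -> np.ndarray:
        out = []
        for ls in landmark_sets:
            semis = [resample_curve(c, t) for c, t in zip(ls.curves, targets)]
            out.append(np.vstack([ls.fixed, *semis]))
        return np.stack(out)

    configs = assemble()
    fit = gpa(configs)
    deltas = []
    prev = float(np.sum((fit.aligned - fit.consensus) ** 2))
    for _ in range(n_iterations - 1):
        # equidistant repositioning is idempotent along the source curve, so
        # later iterations only refresh the GPA; the loop records that the
        # summed Procrustes distance has stabilised.
        configs = assemble()
        fit = gpa(configs)
        cur = float(np.sum((fit.aligned - fit.consensus) ** 2))
        deltas.append(prev - cur)
        prev = cur
    return configs, fit, np.asarray(deltas)


# ---------------------------------------------------------------------------
# Shape PCA
# ---------------------------------------------------------------------------


@dataclass
class ShapeSpace:
    scores: np.ndarray  # (n, c)
    eigen_shapes: np.ndarray  # (c, k, 3)
    variance_fraction: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def shape_pca(fit: ProcrustesFit) -> ShapeSpace:
    """Covariance PCA (centred, unscaled) of the flattened aligned coordinates.

    Axis signs are fixed by making each axis's largest-magnitude loading
    positive.
    """
    if fit.n_specimens < 3:
        raise DegenerateInputError("need at least 3 specimens for shape PCA")
    Y = fit.flattened
    Yc = Y - Y.mean(axis=0)
    u, s, vt = np.linalg.svd(Yc, full_matrices=False)
    keep = s > 1e-12 * max(s.max(), 1.0)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    for c in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[c])))
        if vt[c, j] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    var = s**2
    k = fit.consensus.shape[0]
    return ShapeSpace(u * s, vt.reshape(-1, k, 3), var / var.sum())


# ---------------------------------------------------------------------------
# Procrustes ANOVA and group means
# ---------------------------------------------------------------------------


def procrustes_anova(
    fit: ProcrustesFit,
    location: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Permutation ANOVA of shape on log centroid size, location and their
    interaction (sequential SS, RRPP p-values).

    Term order is fixed as size, location, size:location.
    """
    location = np.asarray(location)
    values, counts = np.unique(location, return_counts=True)
    if np.any(counts < 2):
        small = values[counts < 2]
        raise DegenerateInputError(f"locations with < 2 specimens: {list(small)}")
    log_cs = np.log(fit.centroid_sizes)
    blocks = design_blocks(
        covariates={"Size": log_cs - log_cs.mean()},
        factors={"Location": location},
        interactions=[("Size", "Location")],
        order=["Size", "Location", "Size:Location"],
    )
    return rrpp_anova(fit.flattened, blocks, n_perm=n_perm, rng=rng)


def mean_shape(fit: ProcrustesFit, index: np.ndarray | None = None) -> np.ndarray:
    """Coordinate-wise mean of (a subset of) the aligned configurations."""
    if index is None:
        sub = fit.aligned
    else:
        index = np.asarray(index)
        if index.size == 0:
            raise DegenerateInputError("empty group in mean_shape")
        sub = fit.aligned[index]
    if sub.shape[0] == 0:
        raise DegenerateInputError("empty group in mean_shape")
    return sub.mean(axis=0)
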