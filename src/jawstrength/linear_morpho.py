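"""Linear morphometric shrinkage analysis.

Alcohol preservation shrinks soft tissue, so field-measured and
museum-measured animals from the same islet may occupy different regions of
linear morphospace.  This module quantifies that: a correlation-matrix PCA
of the five measurements (SVL, HH, PL, PW, MW), a sequential MANOVA (Pillai
trace) of morphology on collection method and location, permutation tests of
the fieldwork-vs-alcohol distance in morphospace per population, and
Spearman correlations of shrinkage metrics against time since collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    MEASUREMENTS,
    DegenerateInputError,
    SpecimenRecord,
    ValidationError,
    records_frame,
)
from .rrpp import permutation_pvalue

__all__ = [
    "PCAResult",
    "scaled_pca",
    "manova_pillai",
    "pairwise_method_distance",
    "shrinkage_summary",
    "shrinkage_correlations",
    "spearman",
]


# ---------------------------------------------------------------------------
# Scaled (correlation-matrix) PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: np.ndarray  # (n, c)
    loadings: np.ndarray  # (v, c), orthonormal columns
    variance_fraction: np.ndarray  # (c,)
    center: np.ndarray  # (v,)
    scale: np.ndarray  # (v,)
    variables: tuple[str, ...]

    def reconstruct(self) -> np.ndarray:
        """Undo the PCA: scores @ loadings', unscaled and uncentred."""
        return (self.scores @ self.loadings.T) * self.scale + self.center


def scaled_pca(
    records_or_matrix, variables: tuple[str, ...] = MEASUREMENTS
) -> PCAResult:
    """PCA of centred, unit-variance measurements (correlation-matrix PCA).

    Component signs are fixed so the first variable's loading (SVL) is >= 0
    on every component, breaking exact ties by the loading of PL.
    """
    if len(records_or_matrix) and isinstance(records_or_matrix[0], SpecimenRecord):
        X = np.array([r.measurements for r in records_or_matrix])
    else:
        X = np.asarray(records_or_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise DegenerateInputError("need a (n>=3, v) measurement matrix")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale <= 1e-12 * (np.abs(center) + 1)) or not np.all(
        np.isfinite(scale)
    ):
        bad = variables[int(np.argmin(scale))] if len(variables) == X.shape[1] else "?"
        raise DegenerateInputError(f"constant variable cannot be scaled: {bad}")
    Z = (X - center) / scale
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt.T
    scores = u * s
    var = s**2 / (X.shape[0] - 1)
    frac = var / var.sum()
    # sign convention
    svl_idx, pl_idx = 0, min(2, X.shape[1] - 1)
    for c in range(loadings.shape[1]):
        lead = loadings[svl_idx, c]
        if abs(lead) < 1e-12:
            lead = loadings[pl_idx, c]
        if lead < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return PCAResult(scores, loadings, frac, center, scale, tuple(variables))


# ---------------------------------------------------------------------------
# Sequential MANOVA with Pillai trace
# ---------------------------------------------------------------------------


def _pillai_f(V: float, p: int, q: int, df_res: int) -> tuple[float, int, int]:
    """Rao's approximate F for the Pillai trace of one term.

    p = number of responses, q = term df, df_res = residual df.
    """
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    n2 = (df_res - p - 1) / 2.0
    df1 = int(round(s * (2 * m + s + 1)))
    df2 = int(round(s * (2 * n2 + s + 1)))
    F = (V / (s - V)) * (df2 / df1)
    return F, df1, df2


def manova_pillai(
    responses: np.ndarray,
    method: np.ndarray,
    location: np.ndarray,
    scale: bool = True,
) -> pd.DataFrame:
    """Sequential (type-I) MANOVA of morphology on method, location and
    their interaction, reported as Pillai trace with Rao's approximate F.

    The response block is the centred (and by default unit-scaled) set of
    measurements; the Pillai trace is invariant under any nonsingular linear
    map of the responses, so scaled measurements and full-rank PC scores
    give identical tables.
    """
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    method = np.asarray(method)
    location = np.asarray(location)
    Yc = Y - Y.mean(axis=0)
    if scale:
        sd = Yc.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise DegenerateInputError("constant response variable")
        Yc = Yc / sd

    from .rrpp import _orthonormal_blocks, design_blocks

    blocks = design_blocks(
        factors={"Method": method, "Location": location},
        interactions=[("Method", "Location")],
        order=["Method", "Location", "Method:Location"],
    )
    ortho, _ = _orthonormal_blocks(blocks, n)
    model_df = sum(df for _, _, df in ortho)
    df_res = n - 1 - model_df
    if df_res <= p:
        raise DegenerateInputError("insufficient residual df for MANOVA")
    # E = residual SSCP of the full model
    Qall = np.hstack([np.ones((n, 1)) / np.sqrt(n)] + [q for _, q, _ in ortho])
    Resid = Yc - Qall @ (Qall.T @ Yc)
    E = Resid.T @ Resid
    rows = []
    for name, Q, df_t in ortho:
        B = Q.T @ Yc
        H = B.T @ B  # sequential hypothesis SSCP
        V = float(np.trace(H @ np.linalg.inv(H + E)))
        F, df1, df2 = _pillai_f(V, p, df_t, df_res)
        # survival function of the F distribution for the approximate test
        pval = float(stats.f.sf(F, df1, df2))
        rows.append(
            {
                "term": name,
                "df": df_t,
                "Pillai": V,
                "approx_F": F,
                "num_df": df1,
                "den_df": df2,
                "p": pval,
            }
        )
    rows.append(
        {
            "term": "Residuals",
            "df": df_res,
            "Pillai": np.nan,
            "approx_F": np.nan,
            "num_df": np.nan,
            "den_df": np.nan,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# Permutation test of method distance in morphospace, per population
# ---------------------------------------------------------------------------


def pairwise_method_distance(
    scores: np.ndarray,
    method: np.ndarray,
    population: np.ndarray,
    pop: str,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float] | None:
    """Euclidean distance between method-group mean score vectors within one
    population, with an RRPP permutation p-value.

    The null is built by permuting the within-population residuals (label
    permutation under the no-method-effect model restricted to this
    population).  Returns ``None`` (with a log warning) when either method
    group has fewer than 2 specimens.
    """
    import logging

    rng = np.random.default_rng(rng)
    scores = np.asarray(scores, dtype=float)
    mask = np.asarray(population) == pop
    S = scores[mask]
    meth = np.asarray(method)[mask]
    groups = [S[meth == m] for m in ("fieldwork", "alcohol")]
    if any(g.shape[0] < 2 for g in groups):
        logging.getLogger("jawstrength").warning(
            "population %r: a method group has < 2 specimens; test skipped", pop
        )
        return None
    observed = float(np.linalg.norm(groups[0].mean(axis=0) - groups[1].mean(axis=0)))
    n0 = groups[0].shape[0]
    n = S.shape[0]
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        A = S[perm[:n0]]
        B = S[perm[n0:]]
        null[i] = np.linalg.norm(A.mean(axis=0) - B.mean(axis=0))
    return observed, permutation_pvalue(observed, null)


# ---------------------------------------------------------------------------
# Shrinkage summaries and Spearman age correlations
# ---------------------------------------------------------------------------


def shrinkage_summary(
    records: list[SpecimenRecord],
    scores: np.ndarray,
    method: np.ndarray,
    population: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    reference_year: int = 2023,
) -> pd.DataFrame:
    """Per-population shrinkage table: morphospace distance between method
    means (with permutation p), signed percentage difference of each
    measurement (alcohol relative to fieldwork), and preservation age.

    Percentage difference = 100 * (alcohol mean - fieldwork mean) /
    fieldwork mean, sign preserved so directional shrinkage is visible.
    Age = reference year minus the population's mean collection year.
    """
    rng = np.random.default_rng(rng)
    df = records_frame(records)
    rows = []
    for pop in sorted(df["population"].unique()):
        sub = df[df["population"] == pop]
        fw = sub[sub["method"] == "fieldwork"]
        al = sub[sub["method"] == "alcohol"]
        if fw.empty or al.empty:
            raise ValidationError(f"population {pop!r} missing a method group")
        res = pairwise_method_distance(
            scores, method, population, pop, n_perm=n_perm, rng=rng
        )
        dist, p = res if res is not None else (np.nan, np.nan)
        row = {"population": pop, "distance": dist, "distance_p": p}
        for m in MEASUREMENTS:
            fmean = fw[m].mean()
            row[f"pct_diff_{m}"] = 100.0 * (al[m].mean() - fmean) / fmean
        years = al["collection_year"].dropna()
        row["age_years"] = (
            reference_year - float(years.mean()) if len(years) else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("population")


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Spearman rho with exact two-sided p for untied n <= 9.

    Returns (rho, p, approximated) where ``approximated`` is True when ties
    forced the large-sample approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise DegenerateInputError("need at least 4 pairs")
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if ties or n > 9:
        res = stats.spearmanr(x, y)
        return rho, float(res.pvalue), True
    # exact null: enumerate all rank permutations
    perms = np.array(list(_iter_permutations(range(1, n + 1))), dtype=float)
    rx_c = rx - rx.mean()
    denom = np.sqrt(np.sum(rx_c**2))
    pc = perms - perms.mean(axis=1, keepdims=True)
    null = (pc @ rx_c) / (denom * np.sqrt(np.sum(pc[0] ** 2)))
    p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    return rho, p, False


def shrinkage_correlations(summary: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations of each shrinkage metric against age.

    Tests morphospace distance and percentage difference in SVL, HH, PL, MW
    (the metrics reported per population) against years since collection.
    """
    metrics = ["distance", "pct_diff_svl", "pct_diff_hh", "pct_diff_pl", "pct_diff_mw"]
    age = summary["age_years"].to_numpy(dtype=float)
    if np.sum(np.isfinite(age)) < 4:
        raise DegenerateInputError("need >= 4 populations with known age")
    rows = []
    for m in metrics:
        v = summary[m].to_numpy(dtype=float)
        ok = np.isfinite(age) & np.isfinite(v)
        rho, p, approx = spearman(age[ok], v[ok])
        rows.append({"metric": m, "rho": rho, "p": p, "approximated": approx})
    return pd.DataFrame(rows).set_index("metric")
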