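"""Randomised-residual permutation procedure (RRPP) for linear models.

Shared engine behind the permutation tests in this package: sequential
(type-I) sums of squares for a multivariate linear model, with per-term
significance obtained by permuting the residuals of the reduced model (the
model containing every earlier term) and recomputing the term's pseudo-F.

For a sequence of design blocks X_1 .. X_T added after the intercept, let
Q_t be an orthonormal basis for the new column space contributed by block t.
Then the sequential SS of term t is ||Q_t' Y||_F^2, the full-model residual
SS is ||Y||_F^2 - sum_t ||Q_t' Y||_F^2 - ||Q_0' Y||_F^2, and under RRPP the
permuted statistic only involves the permuted reduced-model residual matrix
(the fitted reduced part is annihilated by the projectors), which keeps the
whole permutation loop as a handful of dense matmuls.

Conventions (used consistently package-wide):

* p-values use the add-one rule, p = (#{stat* >= stat_obs} + 1)/(n_perm + 1),
  so the minimum attainable p is 1/(n_perm + 1);
* the effect size Z is the observed pseudo-F standardised against the mean
  and SD of the permuted F distribution (observed value included);
* pseudo-F for every term uses the full-model residual mean square.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import DegenerateInputError

__all__ = ["rrpp_anova", "design_blocks", "permutation_pvalue"]


def permutation_pvalue(observed: float, permuted: np.ndarray) -> float:
    """Add-one permutation p-value; the observed value counts as one draw."""
    return (np.sum(permuted >= observed - 1e-12) + 1.0) / (permuted.size + 1.0)


def _orthonormal_blocks(blocks: list[tuple[str, np.ndarray]], n: int):
    """Incrementally orthonormalise design blocks (intercept first).

    Returns a list of (name, Q_t, df_t) where the Q_t are mutually orthogonal
    and each spans the *new* directions its block adds.  A block adding no
    new directions (aliased term) raises.
    """
    basis = np.ones((n, 1)) / np.sqrt(n)
    out = []
    for name, X in blocks:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        # remove span of existing basis, twice for numerical safety
        R = X - basis @ (basis.T @ X)
        R = R - basis @ (basis.T @ R)
        q, r = np.linalg.qr(R)
        keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(r).max())
        if not np.any(keep):
            raise DegenerateInputError(
                f"design term {name!r} is aliased with earlier terms"
            )
        Q = q[:, keep]
        basis = np.hstack([basis, Q])
        out.append((name, Q, int(Q.shape[1])))
    return out, basis


def rrpp_anova(
    Y: np.ndarray,
    blocks: list[tuple[str, np.ndarray]],
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sequential multivariate ANOVA with RRPP permutation p-values.

    Parameters
    ----------
    Y : (n, p) response matrix (a single column for univariate models).
    blocks : ordered ``(name, design_block)`` pairs, each block an (n, k)
        matrix of regressors added after the intercept.
    n_perm : number of residual permutations (999 by default; p-floor 1e-3).
    rng : seeded generator; required for reproducibility.

    Returns a table with one row per term plus ``Residuals``, ``Total`` and
    ``Full model`` rows (the latter tests all terms jointly against the
    intercept-only model).  Columns: df, SS, MS, R2, F, Z, p.
    """
    rng = np.random.default_rng(rng)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if n < 3:
        raise DegenerateInputError("need at least 3 observations")
    ortho, basis = _orthonormal_blocks(blocks, n)
    Yc = Y - Y.mean(axis=0)
    total_ss = float(np.sum(Yc * Yc))
    term_ss = np.array([float(np.sum((Q.T @ Y) ** 2)) for _, Q, _ in ortho])
    model_df = sum(df for _, _, df in ortho)
    df_res = n - 1 - model_df
    if df_res <= 0:
        raise DegenerateInputError("no residual degrees of freedom")
    ss_res = total_ss - term_ss.sum()
    ms_res = ss_res / df_res

    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])

    rows = []
    for t, (name, Q, df_t) in enumerate(ortho):
        # reduced model: intercept + earlier terms
        Qr = np.hstack([np.ones((n, 1)) / np.sqrt(n)] + [q for _, q, _ in ortho[:t]])
        R = Y - Qr @ (Qr.T @ Y)  # reduced-model residuals
        r_norm2 = float(np.sum(R * R))  # invariant under row permutation
        # permuted term SS and full-residual SS via projections of R[perm]
        Qt = Q  # (n, df_t)
        Qlater = np.hstack([q for _, q, _ in ortho[t:]])  # term + later blocks
        Rp = R[perms]  # (n_perm, n, p)
        proj_t = np.einsum("nd,qnp->qdp", Qt, Rp)
        ss_t_perm = np.einsum("qdp,qdp->q", proj_t, proj_t)
        proj_m = np.einsum("nd,qnp->qdp", Qlater, Rp)
        ss_res_perm = r_norm2 - np.einsum("qdp,qdp->q", proj_m, proj_m)
        f_perm = (ss_t_perm / df_t) / (ss_res_perm / df_res)
        f_obs = (term_ss[t] / df_t) / ms_res
        dist = np.concatenate([[f_obs], f_perm])
        sd = dist.std()
        z = (f_obs - dist.mean()) / sd if sd > 0 else 0.0
        rows.append(
            {
                "term": name,
                "df": df_t,
                "SS": term_ss[t],
                "MS": term_ss[t] / df_t,
                "R2": term_ss[t] / total_ss if total_ss > 0 else np.nan,
                "F": f_obs,
                "Z": z,
                "p": permutation_pvalue(f_obs, f_perm),
            }
        )

    # full model against intercept-only (permutation of raw centred rows)
    Qm = np.hstack([q for _, q, _ in ortho])
    ss_model = term_ss.sum()
    f_full = (ss_model / model_df) / ms_res
    Rp = Yc[perms]
    proj = np.einsum("nd,qnp->qdp", Qm, Rp)
    ss_model_perm = np.einsum("qdp,qdp->q", proj, proj)
    ss_res_perm = float(np.sum(Yc * Yc)) - ss_model_perm
    f_full_perm = (ss_model_perm / model_df) / (ss_res_perm / df_res)
    dist = np.concatenate([[f_full], f_full_perm])
    sd = dist.std()
    z_full = (f_full - dist.mean()) / sd if sd > 0 else 0.0

    rows.append(
        {
            "term": "Residuals",
            "df": df_res,
            "SS": ss_res,
            "MS": ms_res,
            "R2": ss_res / total_ss if total_ss > 0 else np.nan,
            "F": np.nan,
            "Z": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "SS": total_ss,
            "MS": np.nan,
            "R2": np.nan,
            "F": np.nan,
            "Z": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "term": "Full model",
            "df": model_df,
            "SS": ss_model,
            "MS": ss_model / model_df,
            "R2": ss_model / total_ss if total_ss > 0 else np.nan,
            "F": f_full,
            "Z": z_full,
            "p": permutation_pvalue(f_full, f_full_perm),
        }
    )
    return pd.DataFrame(rows).set_index("term")


def design_blocks(
    *,
    covariates: dict[str, np.ndarray] | None = None,
    factors: dict[str, np.ndarray] | None = None,
    interactions: list[tuple[str, str]] | None = None,
    order: list[str] | None = None,
) -> list[tuple[str, np.ndarray]]:
    """Build sequential design blocks from covariates and categorical factors.

    Factors are dummy-coded dropping the first level (treatment coding);
    interactions are elementwise products of the parent blocks.  ``order``
    fixes the sequential term order (defaults to covariates, factors,
    interactions in the order given).
    """
    built: dict[str, np.ndarray] = {}
    covariates = covariates or {}
    factors = factors or {}
    for name, x in covariates.items():
        built[name] = np.asarray(x, dtype=float).reshape(-1, 1)
    for name, labels in factors.items():
        labels = np.asarray(labels)
        levels = np.unique(labels)
        if levels.size < 2:
            raise DegenerateInputError(f"factor {name!r} has a single level")
        built[name] = (labels[:, None] == levels[None, 1:]).astype(float)
    for a, b in interactions or []:
        Xa, Xb = built[a], built[b]
        cols = [Xa[:, i] * Xb[:, j] for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
        built[f"{a}:{b}"] = np.column_stack(cols)
    names = order or list(built)
    return [(n, built[n]) for n in names]
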