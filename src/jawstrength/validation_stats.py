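"""Validation of in silico jaw strength against in vivo bite force.

All quantities are natural-log transformed before analysis (population
average bite = the mean of logged individual forces, not the log of the
arithmetic mean).  Three layers:

* Kendall tau-b rank correlation between population-level in silico
  strength and in vivo bite (exact enumeration p for tie-free n <= 8,
  tie-corrected normal approximation otherwise);
* a permutation linear model (RRPP, 999 permutations) of logged bite on
  logged size, collection method (in vivo vs in silico) and their
  interaction — if neither the method term nor the interaction is retained
  at alpha = 0.05, the two data sources follow the same bite~size
  allometry;
* z-score standardisation of bite within each method group, which removes
  scale/offset differences between the incommensurable units (N vs MA vs
  1/(N mm^-2)) before re-fitting the model.

A Shapiro–Wilk normality check is reported to justify the permutation
route; it never gates results.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DegenerateInputError, SpecimenRecord, ValidationError
from .rrpp import design_blocks, rrpp_anova

__all__ = [
    "KendallResult",
    "kendall_tau_b",
    "summarise_populations",
    "rrpp_lm",
    "zscore_standardise",
    "normality_check",
    "slope_permutation_interval",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Population summaries
# ---------------------------------------------------------------------------


def summarise_populations(
    records: list[SpecimenRecord],
    strengths: pd.DataFrame,
    sample: str = "total",
) -> pd.DataFrame:
    """Per-population averages on the log scale.

    ``strengths`` carries one row per population with in silico values
    (columns such as total_ma, adductor_ma, fe_dentary, ... and a size
    column); bite forces come from the fieldwork records.  Average bite is
    the mean of natural-log individual forces.  In silico values are single
    per-population quantities and are logged directly.
    """
    pops = sorted(strengths.index)
    rows = []
    for pop in pops:
        sub = [
            r
            for r in records
            if r.population == pop
            and r.method == "fieldwork"
            and r.bite_force is not None
            and (sample == "total" or r.sex == "male")
        ]
        if not sub:
            raise ValidationError(f"population {pop!r} has no in vivo bite data")
        row = {
            "population": pop,
            "n_bite": len(sub),
            "log_bite": float(np.mean([np.log(r.bite_force) for r in sub])),
            "log_size_vivo": float(np.mean([np.log(r.pl) for r in sub])),
        }
        for col in strengths.columns:
            v = float(strengths.loc[pop, col])
            if v <= 0:
                raise ValidationError(
                    f"population {pop!r}: non-positive in silico value {col}"
                )
            row[f"log_{col}"] = float(np.log(v))
        rows.append(row)
    missing = set(strengths.index) - {r["population"] for r in rows}
    if missing:
        raise ValidationError(f"populations missing in vivo data: {sorted(missing)}")
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# Kendall tau-b
# ---------------------------------------------------------------------------


@dataclass
class KendallResult:
    tau: float
    statistic: float  # concordant-pair count T (no ties) or z (ties / large n)
    statistic_name: str  # "T" or "z"
    p: float
    ties: bool
    n: int


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    n = x.size
    i, j = np.triu_indices(n, k=1)
    sx = np.sign(x[j] - x[i])
    sy = np.sign(y[j] - y[i])
    prod = sx * sy
    return int(np.sum(prod > 0)), int(np.sum(prod < 0))


def kendall_tau_b(x: np.ndarray, y: np.ndarray) -> KendallResult:
    """Kendall tau-b with tie corrections.

    Tie-free vectors of length <= 8 get an exact two-sided p by full
    enumeration of the n! permutation null (via the exact tau distribution);
    otherwise the tie-corrected normal approximation is used and a z
    statistic reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateInputError("tau undefined for a constant vector")
    n = x.size
    ties = np.unique(x).size < n or np.unique(y).size < n
    C, D = _pair_counts(x, y)
    if not ties and n <= 8:
        res = stats.kendalltau(x, y, method="exact")
        tau = float(res.statistic)
        return KendallResult(tau, float(C), "T", float(res.pvalue), False, n)
    res = stats.kendalltau(x, y, method="asymptotic")
    tau = float(res.statistic)
    # tie-corrected variance of S = C - D (standard tau-b z statistic)
    z = _tau_b_z(x, y, C - D)
    return KendallResult(tau, z, "z", float(res.pvalue), bool(ties), n)


def _tau_b_z(x: np.ndarray, y: np.ndarray, S: int) -> float:
    n = x.size

    def tie_terms(v: np.ndarray):
        _, counts = np.unique(v, return_counts=True)
        t = counts[counts > 1]
        v0 = np.sum(t * (t - 1) * (2 * t + 5))
        v1 = np.sum(t * (t - 1))
        v2 = np.sum(t * (t - 1) * (t - 2))
        return v0, v1, v2

    x0, x1, x2 = tie_terms(x)
    y0, y1, y2 = tie_terms(y)
    var = (
        (n * (n - 1) * (2 * n + 5) - x0 - y0) / 18.0
        + x1 * y1 / (2.0 * n * (n - 1))
        + x2 * y2 / (9.0 * n * (n - 1) * (n - 2))
    )
    return float(S / np.sqrt(var)) if var > 0 else 0.0


def exact_tau_null(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of tau for tie-free samples of size n:
    returns (tau values, probabilities) over all n! rank permutations."""
    from itertools import permutations

    if n > 9:
        raise ValidationError("exact enumeration limited to n <= 9")
    base = np.arange(n)
    taus = {}
    denom = n * (n - 1) / 2
    for perm in permutations(range(n)):
        p = np.array(perm)
        C, D = _pair_counts(base.astype(float), p.astype(float))
        t = (C - D) / denom
        taus[round(t, 12)] = taus.get(round(t, 12), 0) + 1
    vals = np.array(sorted(taus))
    probs = np.array([taus[v] for v in vals], dtype=float) / factorial(n)
    return vals, probs


# ---------------------------------------------------------------------------
# RRPP linear model of bite ~ size * method
# ---------------------------------------------------------------------------


def rrpp_lm(
    y: np.ndarray,
    size: np.ndarray,
    method: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Permutation linear model of logged bite on logged size, method and
    size:method (sequential SS, RRPP p-values).

    Returns the ANOVA table and a verdict dict:
    ``method_retained`` is True when the method term or the interaction is
    significant at alpha = 0.05 (the two data sources then do NOT share a
    single bite~size relationship).
    """
    y = np.asarray(y, dtype=float)
    size = np.asarray(size, dtype=float)
    method = np.asarray(method)
    levels = np.unique(method)
    if levels.size != 2:
        raise ValidationError("method must have exactly two levels")
    for lev in levels:
        if np.sum(method == lev) < 3:
            raise ValidationError(f"method level {lev!r} has fewer than 3 points")
    blocks = design_blocks(
        covariates={"Size": size - size.mean()},
        factors={"Method": method},
        interactions=[("Size", "Method")],
        order=["Size", "Method", "Size:Method"],
    )
    table = rrpp_anova(y, blocks, n_perm=n_perm, rng=rng)
    p_method = float(table.loc["Method", "p"])
    p_inter = float(table.loc["Size:Method", "p"])
    verdict = {
        "method_retained": bool(p_method <= ALPHA or p_inter <= ALPHA),
        "p_method": p_method,
        "p_interaction": p_inter,
        "p_size": float(table.loc["Size", "p"]),
        "same_allometry": not bool(p_method <= ALPHA or p_inter <= ALPHA),
    }
    return table, verdict


def slope_permutation_interval(
    y: np.ndarray,
    size: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    confidence: float = 0.95,
) -> tuple[float, float, float]:
    """OLS allometric slope with a residual-permutation interval.

    The interval is the percentile band of slopes refit on
    ``fitted + permuted residuals`` (RRPP-style resampling of the fitted
    model).  Returns (slope, lo, hi).
    """
    rng = np.random.default_rng(rng)
    y = np.asarray(y, dtype=float)
    x = np.asarray(size, dtype=float)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise DegenerateInputError("size has zero variance")
    slope = float(xc @ (y - y.mean())) / sxx
    resid = y - y.mean() - slope * xc
    perms = np.stack([rng.permutation(y.size) for _ in range(n_perm)])
    # slope(fitted + R[perm]) = slope + slope(R[perm])
    slopes = slope + (resid[perms] @ xc) / sxx
    a = (1 - confidence) / 2
    lo, hi = np.quantile(slopes, [a, 1 - a])
    return slope, float(lo), float(hi)


# ---------------------------------------------------------------------------
# Standardisation and normality
# ---------------------------------------------------------------------------


def zscore_standardise(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Within-group z-scores (n-1 denominator)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = np.empty_like(values)
    for g in np.unique(groups):
        m = groups == g
        if np.sum(m) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 values")
        sd = values[m].std(ddof=1)
        if sd <= 0:
            raise DegenerateInputError(f"group {g!r} has zero variance")
        out[m] = (values[m] - values[m].mean()) / sd
    return out


def normality_check(values: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk W and p (3 <= n <= 5000); reported, never gating."""
    values = np.asarray(values, dtype=float)
    if not (3 <= values.size <= 5000):
        raise ValidationError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.unique(values).size == 1:
        raise DegenerateInputError("constant vector")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)
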