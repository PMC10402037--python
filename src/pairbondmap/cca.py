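"""Canonical correlation analysis linking brain activity to behavior.

Classical CCA: both variable sets are z-scored, the cross-covariance is
whitened within each set, and its singular value decomposition yields
paired linear combinations (canonical correlates) ordered by their
correlation. Sequential Wilk's lambda tests with Rao's F approximation
say how many factors carry signal; correlations between raw variables
and the factor scores ("loadings") interpret each factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CCAResult:
    correlations: np.ndarray  # rho_1 >= rho_2 >= ... in [0, 1]
    x_weights: pd.DataFrame  # variable x factor, applied to z-scored X
    y_weights: pd.DataFrame
    x_scores: pd.DataFrame  # animal x factor, sd ~ 1
    y_scores: pd.DataFrame
    n: int
    rank_x: int
    rank_y: int
    dropped_animals: list = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return len(self.correlations)


def _whiten(Z: np.ndarray, tol: float = 1e-10):
    """SVD-based whitening; returns orthonormal basis Q, V, s, rank."""
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s > tol * s[0])) if s.size else 0
    return U[:, :rank], Vt[:rank].T, s[:rank], rank


def cca_fit(X: pd.DataFrame, Y: pd.DataFrame, n_factors: int | None = None) -> CCAResult:
    """Fit classical CCA between two variable sets on shared animals.

    Only complete cases (animals present and finite in both sets) are
    used; dropped animals are reported on the result. Variables are
    centered and scaled; dimensions beyond the rank of either set are
    dropped with a warning. Each factor is oriented so its
    largest-magnitude Y (behavior) loading is positive.
    """
    common = X.index.intersection(Y.index)
    Xc, Yc = X.loc[common], Y.loc[common]
    ok = ~(Xc.isna().any(axis=1) | Yc.isna().any(axis=1))
    dropped = list(X.index.union(Y.index).difference(common[ok]))
    Xc, Yc = Xc[ok], Yc[ok]
    n = len(Xc)
    p, q = Xc.shape[1], Yc.shape[1]
    if n < 3:
        raise ValueError("need at least 3 complete-case animals")
    if n <= p + q:
        warnings.warn(
            f"n = {n} does not exceed p + q = {p + q}; canonical correlations "
            "will be inflated",
            stacklevel=2,
        )

    def _scale(df):
        sd = df.std(axis=0, ddof=1)
        keep = sd[sd > 0].index
        if len(keep) < df.shape[1]:
            warnings.warn("dropping zero-variance variables", stacklevel=2)
        z = (df[keep] - df[keep].mean(axis=0)) / sd[keep]
        return z

    Zx, Zy = _scale(Xc), _scale(Yc)
    Qx, Vx, sx, rx = _whiten(Zx.to_numpy())
    Qy, Vy, sy, ry = _whiten(Zy.to_numpy())
    d = min(rx, ry)
    if d < min(Zx.shape[1], Zy.shape[1]):
        warnings.warn("rank-deficient variable set; dropping extra dimensions", stacklevel=2)
    if n_factors is not None:
        d = min(d, n_factors)
    U, rho, Vt = np.linalg.svd(Qx.T @ Qy)
    rho = np.clip(rho[:d], 0.0, 1.0)
    U, V = U[:, :d], Vt[:d].T

    # weights on the z-scored variables; scores have sd ~ 1
    wx = Vx @ (U / sx[:, None]) * np.sqrt(n - 1)
    wy = Vy @ (V / sy[:, None]) * np.sqrt(n - 1)
    sx_scores = Qx @ U * np.sqrt(n - 1)
    sy_scores = Qy @ V * np.sqrt(n - 1)

    # sign convention: largest-|loading| behavior variable loads positive
    for k in range(d):
        load = np.array([np.corrcoef(Zy[v], sy_scores[:, k])[0, 1] for v in Zy.columns])
        j = int(np.nanargmax(np.abs(load)))
        if load[j] < 0:
            wx[:, k] *= -1
            wy[:, k] *= -1
            sx_scores[:, k] *= -1
            sy_scores[:, k] *= -1

    factors = [f"CC{k+1}" for k in range(d)]
    return CCAResult(
        correlations=rho,
        x_weights=pd.DataFrame(wx, index=Zx.columns, columns=factors),
        y_weights=pd.DataFrame(wy, index=Zy.columns, columns=factors),
        x_scores=pd.DataFrame(sx_scores, index=Zx.index, columns=factors),
        y_scores=pd.DataFrame(sy_scores, index=Zy.index, columns=factors),
        n=n,
        rank_x=rx,
        rank_y=ry,
        dropped_animals=dropped,
    )


def wilks_test(result: CCAResult, n: int | None = None) -> pd.DataFrame:
    """Sequential Wilk's lambda tests with Rao's F approximation.

    Test k asks whether canonical correlations k..d are all zero:
    Lambda_k = prod_{i>=k} (1 - rho_i^2), converted to an F statistic
    on (df1, df2) degrees of freedom. Returns one row per factor.
    """
    n = n or result.n
    p, q = result.rank_x, result.rank_y
    if n <= p + q + 1:
        warnings.warn("sample size too small for a reliable Wilk's test", stacklevel=2)
    rho = result.correlations
    rows = []
    for k in range(len(rho)):
        pk, qk = p - k, q - k
        lam = float(np.prod(1.0 - rho[k:] ** 2))
        denom = pk**2 + qk**2 - 5
        t = np.sqrt((pk**2 * qk**2 - 4) / denom) if denom > 0 and pk * qk > 2 else 1.0
        w = n - (p + q + 3) / 2.0
        df1 = pk * qk
        df2 = w * t - pk * qk / 2.0 + 1.0
        if lam <= 0:
            F, pval = np.inf, 0.0
        else:
            lam_t = lam ** (1.0 / t)
            F = (1.0 - lam_t) / lam_t * df2 / df1
            pval = float(stats.f.sf(F, df1, df2)) if df2 > 0 else np.nan
        rows.append((f"CC{k+1}", lam, float(F), float(df1), float(df2), pval))
    return pd.DataFrame(rows, columns=["factor", "wilks_lambda", "F", "df1", "df2", "p"])


def score_loadings(result: CCAResult, X_raw: pd.DataFrame, Y_raw: pd.DataFrame) -> pd.DataFrame:
    """Correlate every raw variable with each factor score of its own set.

    Returns a long table (set, variable, factor, loading); zero-variance
    variables get a missing loading.
    """
    rows = []
    for set_name, raw, scores in (("brain", X_raw, result.x_scores), ("behavior", Y_raw, result.y_scores)):
        raw = raw.loc[scores.index]
        for var in raw.columns:
            v = raw[var].to_numpy(dtype=float)
            for fac in scores.columns:
                if np.std(v) == 0:
                    loading = np.nan
                else:
                    loading = float(np.corrcoef(v, scores[fac])[0, 1])
                rows.append((set_name, var, fac, loading))
    return pd.DataFrame(rows, columns=["set", "variable", "factor", "loading"])


def group_cc_scores(
    result: CCAResult,
    design: pd.DataFrame,
    set_name: str = "brain",
) -> pd.DataFrame:
    """Mean and sd of each factor score per experiment group.

    Groups are partner_type x sex x timepoint cells; empty cells get a
    missing mean with a warning.
    """
    scores = result.x_scores if set_name == "brain" else result.y_scores
    design = design.set_index("animal_id")
    missing = scores.index.difference(design.index)
    if len(missing):
        raise ValueError(f"design does not cover scored animals: {list(missing)[:5]}")
    meta = design.loc[scores.index, ["partner_type", "sex", "timepoint"]]
    rows = []
    cells = (
        design[["partner_type", "sex", "timepoint"]].drop_duplicates().itertuples(index=False)
    )
    for ptype, sex, tp in cells:
        mask = (
            (meta["partner_type"] == ptype) & (meta["sex"] == sex) & (meta["timepoint"] == tp)
        )
        sub = scores[mask.to_numpy()]
        if sub.empty:
            warnings.warn(f"empty group cell {(ptype, sex, tp)}", stacklevel=2)
        for fac in scores.columns:
            rows.append(
                (
                    fac,
                    ptype,
                    sex,
                    tp,
                    float(sub[fac].mean()) if len(sub) else np.nan,
                    float(sub[fac].std(ddof=1)) if len(sub) > 1 else np.nan,
                    len(sub),
                )
            )
    return pd.DataFrame(
        rows, columns=["factor", "partner_type", "sex", "timepoint", "mean", "sd", "n"]
    )
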