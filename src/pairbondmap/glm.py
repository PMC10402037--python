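"""Per-unit quasi-Poisson GLM screen with permutation-calibrated F tests.

Each brain unit (ROI or voxel) gets a nested model comparison: a null
log-link count model with sex, time (linear + quadratic) and block terms
against a "bonding" model that adds partner type and its interactions
with sex and time. Overdispersion is handled quasi-likelihood style: the
mean model is Poisson, the Pearson dispersion phi scales the F statistic

    F = ((D_null - D_full) / df1) / phi_full

and significance comes from a Monte-Carlo permutation null in which
partner-type labels are reshuffled at the pair level (both members of a
pair keep their sex, timepoint and block and always share a label).
A third, "reduced" model dropping only the partner-by-sex interaction
supports the sex-difference contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

NULL_FORMULA = "null"
BONDING_FORMULA = "bonding"
REDUCED_SEX_FORMULA = "reduced_sex"

_CONTRASTS = {
    "bonding_vs_null": (NULL_FORMULA, BONDING_FORMULA),
    "full_vs_reduced_sex": (REDUCED_SEX_FORMULA, BONDING_FORMULA),
}


class ConvergenceError(RuntimeError):
    pass


@dataclass
class GLMFit:
    """A fitted log-link count regression for one unit."""

    coef: np.ndarray
    deviance: float
    pearson_dispersion: float
    df_resid: int
    fitted: np.ndarray
    rank: int
    converged: bool
    n_iter: int
    columns: list[str] = field(default_factory=list)
    degenerate: bool = False  # all-zero response


def ortho_poly(x, degree: int) -> np.ndarray:
    """Orthonormal polynomial contrasts of ``x`` (R ``poly()`` style).

    Columns are orthogonal to the intercept and to each other; requires
    more distinct values than ``degree``.
    """
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) <= degree:
        raise ValueError(
            f"need more than {degree} distinct values for degree-{degree} polynomial"
        )
    V = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    Q = Q * np.sign(np.diag(R))
    return Q[:, 1:]


def _check_levels(design: pd.DataFrame, factors: list[str]) -> None:
    for f in factors:
        if design[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")


def build_design_matrix(
    design: pd.DataFrame,
    formula: str,
    block_as_factor: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Build the model matrix for one of the three nested formulas.

    Columns: intercept; sex dummy (M=1); orthogonal degree-1/degree-2
    polynomials of the ordinal timepoint codes; block (numeric 1-6 by
    default, dummy-coded if ``block_as_factor``); and, for the bonding
    formulas, a partner dummy (mate=1) with its sex and time products.
    """
    if formula not in (NULL_FORMULA, BONDING_FORMULA, REDUCED_SEX_FORMULA):
        raise ValueError(f"unknown formula {formula!r}")
    factors = ["sex", "timepoint", "block"]
    if formula != NULL_FORMULA:
        factors.append("partner_type")
    _check_levels(design, factors)
    if design["timepoint"].nunique() < 3:
        raise ValueError("factor 'timepoint' needs >= 3 levels for a quadratic term")

    n = len(design)
    sex = (design["sex"].to_numpy() == "M").astype(float)
    tpoly = ortho_poly(design["timepoint"].to_numpy(), 2)
    cols = [np.ones(n), sex, tpoly[:, 0], tpoly[:, 1]]
    names = ["intercept", "sex[M]", "time_lin", "time_quad"]
    if block_as_factor:
        blocks = np.sort(design["block"].unique())
        for b in blocks[1:]:
            cols.append((design["block"].to_numpy() == b).astype(float))
            names.append(f"block[{b}]")
    else:
        cols.append(design["block"].to_numpy().astype(float))
        names.append("block")
    if formula != NULL_FORMULA:
        partner = (design["partner_type"].to_numpy() == "mate").astype(float)
        cols.append(partner)
        names.append("partner[mate]")
        if formula == BONDING_FORMULA:
            cols.append(partner * sex)
            names.append("partner:sex")
        cols.append(partner * tpoly[:, 0])
        names.append("partner:time_lin")
        cols.append(partner * tpoly[:, 1])
        names.append("partner:time_quad")
    return np.column_stack(cols), names


def _poisson_deviance(y: np.ndarray, mu: np.ndarray, axis=0) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    return 2.0 * np.sum(term - (y - mu), axis=axis)


def fit_quasipoisson(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    columns: list[str] | None = None,
) -> GLMFit:
    """Fit one log-link count regression by IRLS.

    Converges when the relative deviance change drops below ``tol``.
    The Pearson dispersion is chi^2 / df_resid. An all-zero response is
    a degenerate saturated fit (deviance 0) and is returned flagged
    rather than driving the intercept to -inf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match length of y")
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    n, p = X.shape
    rank = int(np.linalg.matrix_rank(X))
    df_resid = n - rank
    if y.sum() == 0:
        return GLMFit(
            coef=np.zeros(p),
            deviance=0.0,
            pearson_dispersion=0.0,
            df_resid=df_resid,
            fitted=np.zeros(n),
            rank=rank,
            converged=True,
            n_iter=0,
            columns=list(columns or []),
            degenerate=True,
        )
    mu = y + y.mean() / 2 + 0.1
    eta = np.log(mu)
    dev = _poisson_deviance(y, mu)
    trace = [float(dev)]
    beta = np.zeros(p)
    for it in range(1, max_iter + 1):
        w = np.sqrt(mu)
        z = eta + (y - mu) / mu
        beta, *_ = np.linalg.lstsq(X * w[:, None], z * w, rcond=None)
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        new_dev = _poisson_deviance(y, mu)
        trace.append(float(new_dev))
        if abs(new_dev - dev) < tol * (abs(dev) + 0.1):
            dev = new_dev
            break
        dev = new_dev
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations; deviance trace tail: "
            f"{trace[-5:]}"
        )
    phi = float(np.sum((y - mu) ** 2 / mu) / df_resid) if df_resid > 0 else 0.0
    return GLMFit(
        coef=beta,
        deviance=float(dev),
        pearson_dispersion=phi,
        df_resid=df_resid,
        fitted=mu,
        rank=rank,
        converged=True,
        n_iter=it,
        columns=list(columns or []),
    )


def fit_quasipoisson_many(
    X: np.ndarray,
    Y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> dict:
    """Vectorized IRLS for many units sharing one design matrix.

    ``Y`` is animals x units. Returns per-unit deviance, Pearson
    dispersion, coefficients, plus the design rank / residual df. Units
    whose response is all zero are degenerate saturated fits (deviance
    and dispersion 0).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    U = Y.shape[1]
    rank = int(np.linalg.matrix_rank(X))
    df_resid = n - rank
    zero_mask = Y.sum(axis=0) == 0
    mu = Y + Y.mean(axis=0, keepdims=True) / 2 + 0.1
    eta = np.log(mu)
    dev = _poisson_deviance(Y, mu, axis=0)
    active = ~zero_mask
    beta = np.zeros((p, U))
    for _ in range(max_iter):
        if not active.any():
            break
        W = mu[:, active]
        Z = eta[:, active] + (Y[:, active] - W) / W
        A = np.einsum("np,nu,nq->upq", X, W, X, optimize=True)
        b = np.einsum("np,nu->up", X, W * Z, optimize=True)
        try:
            sol = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            sol = np.stack([np.linalg.lstsq(Ai, bi, rcond=None)[0] for Ai, bi in zip(A, b)])
        beta[:, active] = sol.T
        eta_a = np.clip(X @ sol.T, -30.0, 30.0)
        mu_a = np.exp(eta_a)
        new_dev = _poisson_deviance(Y[:, active], mu_a, axis=0)
        mu[:, active] = mu_a
        eta[:, active] = eta_a
        done = np.abs(new_dev - dev[active]) < tol * (np.abs(dev[active]) + 0.1)
        dev[active] = new_dev
        idx = np.flatnonzero(active)
        active[idx[done]] = False
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.sum((Y - mu) ** 2 / np.where(mu > 0, mu, 1.0), axis=0) / max(df_resid, 1)
    dev[zero_mask] = 0.0
    phi[zero_mask] = 0.0
    beta[:, zero_mask] = 0.0
    return {
        "coef": beta,
        "deviance": dev,
        "pearson_dispersion": phi,
        "rank": rank,
        "df_resid": df_resid,
    }


def f_statistic(fit_null: GLMFit, fit_full: GLMFit) -> tuple[float, int, int]:
    """ANOVA-style F comparing nested quasi-Poisson fits.

    F = ((D_null - D_full) / df1) / phi_full with df1 the rank difference
    and df2 the full model's residual df; clipped at zero.
    """
    df1 = fit_full.rank - fit_null.rank
    if df1 <= 0:
        raise ValueError("added columns are collinear: rank difference is zero")
    df2 = fit_full.df_resid
    return _f_from_parts(
        fit_null.deviance, fit_full.deviance, fit_full.pearson_dispersion, df1
    ), df1, df2


def _f_from_parts(dev_null, dev_full, phi_full, df1):
    num = (np.asarray(dev_null) - np.asarray(dev_full)) / df1
    phi = np.asarray(phi_full)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(phi > 0, num / np.where(phi > 0, phi, 1.0), np.where(num > 0, np.inf, 0.0))
    f = np.maximum(f, 0.0)
    return float(f) if f.ndim == 0 else f


def fdr_adjust(pvals, method: str = "bh", alpha: float = 0.1):
    """Multiple-test correction: BH step-up (default) or Storey q-values.

    Returns (q, flags) with flags = q < alpha. Order-preserving: sorting
    by p sorts by q.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        _, q, _, _ = multipletests(p, method="fdr_bh")
    elif method == "qvalue":
        # Storey with fixed lambda = 0.5
        pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5) if p.size else 1.0
        pi0 = max(pi0, 1.0 / p.size)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        q = pi0 * bh
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    return q, q < alpha


def _shuffled_partner(design_pairs: pd.DataFrame, rng, scheme: str) -> pd.Series:
    """Permute the mate/sibling label across pairs.

    ``pair_stratified`` (default) permutes labels within each
    timepoint x block stratum, i.e. within a testing day: pairs keep
    their members, sex composition, timepoint and block, and the label
    swap never crosses a block, which preserves exchangeability even
    when block effects are imperfectly modeled. ``pair_timepoint``
    stratifies by timepoint only; ``pair`` permutes across all pairs.
    """
    labels = design_pairs["partner_type"].to_numpy().copy()
    if scheme in ("pair_stratified", "pair_timepoint"):
        cols = ["timepoint"] if scheme == "pair_timepoint" else ["timepoint", "block"]
        strata = design_pairs.groupby(cols).indices
        for idx in strata.values():
            idx = np.asarray(idx)
            labels[idx] = labels[rng.permutation(idx)]
    elif scheme == "pair":
        labels = labels[rng.permutation(len(labels))]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return pd.Series(labels, index=design_pairs.index)


def permutation_screen(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: str = "bonding_vs_null",
    n_perm: int = 10000,
    seed: int = 0,
    scheme: str = "pair_stratified",
    fdr_method: str = "bh",
    alpha: float = 0.1,
    block_as_factor: bool = False,
) -> pd.DataFrame:
    """Permutation-calibrated nested-GLM screen over all units.

    For every unit the observed F is compared against F statistics from
    ``n_perm`` relabeled designs; one shuffle is applied to all units so
    permutation indices are shared within a replicate. p-values use the
    add-one estimator (1 + #{F_perm >= F_obs}) / (1 + n_perm); q-values
    come from :func:`fdr_adjust`.

    ``scheme``: ``pair_stratified`` (default) or ``pair`` shuffle
    partner labels at pair level; ``rows`` shuffles response rows.
    """
    if contrast not in _CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives very coarse p-value resolution", stacklevel=2)
    if scheme not in ("pair_stratified", "pair_timepoint", "pair", "rows"):
        raise ValueError(f"unknown scheme {scheme!r}")

    design = design.reset_index(drop=True)
    if "ieg_included" in design.columns:
        design = design[design["ieg_included"]].reset_index(drop=True)
    missing = set(design["animal_id"]) - set(counts.index)
    if missing:
        raise ValueError(f"counts matrix missing animals: {sorted(missing)[:5]}")
    Y = counts.loc[design["animal_id"]].to_numpy(dtype=float)
    units = list(counts.columns)

    reduced_name, full_name = _CONTRASTS[contrast]
    rng = np.random.default_rng(seed)

    def _fit_pair(dsgn):
        Xr, _ = build_design_matrix(dsgn, reduced_name, block_as_factor)
        Xf, names_f = build_design_matrix(dsgn, full_name, block_as_factor)
        red = fit_quasipoisson_many(Xr, Y)
        ful = fit_quasipoisson_many(Xf, Y)
        df1 = ful["rank"] - red["rank"]
        if df1 <= 0:
            return None
        F = _f_from_parts(red["deviance"], ful["deviance"], ful["pearson_dispersion"], df1)
        return F, df1, ful, names_f

    obs = _fit_pair(design)
    if obs is None:
        raise ValueError("full model adds no rank over the reduced model")
    F_obs, df1, full_fit, names_f = obs
    direction = np.sign(full_fit["coef"][names_f.index("partner[mate]")])

    # For the bonding contrast the null model has no partner term, so
    # its fit is invariant to label shuffles and is reused across perms.
    reduced_invariant = contrast == "bonding_vs_null" and scheme != "rows"
    if reduced_invariant:
        Xr, _ = build_design_matrix(design, reduced_name, block_as_factor)
        red_base = fit_quasipoisson_many(Xr, Y)

    pairs = design.drop_duplicates("pair_id")[
        ["pair_id", "timepoint", "block", "partner_type"]
    ].set_index("pair_id")

    exceed = np.zeros(len(units))
    for _ in range(n_perm):
        if scheme == "rows":
            perm = rng.permutation(len(Y))
            dsgn_b = design
            Yb = Y[perm]
            Xr, _ = build_design_matrix(dsgn_b, reduced_name, block_as_factor)
            Xf, _ = build_design_matrix(dsgn_b, full_name, block_as_factor)
            red = fit_quasipoisson_many(Xr, Yb)
            ful = fit_quasipoisson_many(Xf, Yb)
            d1 = ful["rank"] - red["rank"]
            if d1 <= 0:
                Fb = np.zeros(len(units))
            else:
                Fb = _f_from_parts(
                    red["deviance"], ful["deviance"], ful["pearson_dispersion"], d1
                )
        else:
            shuffled = _shuffled_partner(pairs.reset_index(), rng, scheme)
            shuffled.index = pairs.index
            dsgn_b = design.copy()
            dsgn_b["partner_type"] = dsgn_b["pair_id"].map(shuffled).to_numpy()
            if reduced_invariant:
                Xf, _ = build_design_matrix(dsgn_b, full_name, block_as_factor)
                ful = fit_quasipoisson_many(Xf, Y)
                d1 = ful["rank"] - red_base["rank"]
                if d1 <= 0:
                    Fb = np.zeros(len(units))
                else:
                    Fb = _f_from_parts(
                        red_base["deviance"],
                        ful["deviance"],
                        ful["pearson_dispersion"],
                        d1,
                    )
            else:
                res = _fit_pair(dsgn_b)
                Fb = res[0] if res is not None else np.zeros(len(units))
        exceed += Fb >= F_obs

    p = (1.0 + exceed) / (1.0 + n_perm)
    q, sig = fdr_adjust(p, method=fdr_method, alpha=alpha)
    return pd.DataFrame(
        {
            "F": F_obs,
            "df1": df1,
            "df2": full_fit["df_resid"],
            "p": p,
            "q": q,
            "significant": sig,
            "direction": direction,
        },
        index=pd.Index(units, name="unit"),
    )
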