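"""Behavioral group comparisons and the whole-brain count outlier screen.

Welch two-sample t-tests compare mate pairs with sibling controls,
paired t-tests compare female and male mates, and a generalized ESD
(Rosner) test screens per-animal whole-brain c-Fos totals for outliers.
Dyadic measures (mounting, huddling, vocalization) are tested at the
pair level -- one observation per dyad -- while individual measures use
one observation per animal. p-values across a batch of contrasts are
FDR-corrected (default alpha 0.05 for behavior).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glm import fdr_adjust
from .simulate import DYADIC_MEASURES


@dataclass
class TTestResult:
    measure: str
    groups: str
    n1: int
    n2: int
    t: float
    df: float
    p: float
    q: float | None = None
    kind: str = "welch"

    @property
    def defined(self) -> bool:
        return np.isfinite(self.t)


def welch_t(x, y, measure: str = "", groups: str = "A vs B") -> TTestResult:
    """Unequal-variance two-sample t-test with Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        warnings.warn("both groups constant: t undefined", stacklevel=2)
        return TTestResult(measure, groups, len(x), len(y), np.nan, np.nan, np.nan)
    res = stats.ttest_ind(x, y, equal_var=False)
    se2 = vx / len(x) + vy / len(y)
    df = se2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    return TTestResult(
        measure, groups, len(x), len(y), float(res.statistic), float(df), float(res.pvalue)
    )


def paired_t(x, y, measure: str = "", groups: str = "member1 vs member2") -> TTestResult:
    """Paired t-test on within-pair differences, df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("need n >= 2 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            return TTestResult(
                measure, groups, len(x), len(y), 0.0, len(x) - 1, 1.0, kind="paired"
            )
        warnings.warn("constant nonzero difference: p undefined (zero sd)", stacklevel=2)
        return TTestResult(
            measure, groups, len(x), len(y), np.nan, len(x) - 1, np.nan, kind="paired"
        )
    res = stats.ttest_rel(x, y)
    return TTestResult(
        measure,
        groups,
        len(x),
        len(y),
        float(res.statistic),
        float(len(x) - 1),
        float(res.pvalue),
        kind="paired",
    )


def batch_tests(
    behavior: pd.DataFrame,
    design: pd.DataFrame,
    contrasts: list[dict] | None = None,
    alpha: float = 0.05,
    fdr_method: str = "bh",
    dyadic_measures: list[str] | None = None,
) -> pd.DataFrame:
    """Run a batch of behavioral contrasts and FDR-correct the batch.

    Default contrasts: for every measure, mate vs sibling (Welch)
    overall and per timepoint, plus female vs male mates (paired)
    overall. A contrast dict holds ``measure``, ``kind``
    (``mate_vs_sibling`` | ``female_vs_male``) and optional
    ``timepoint``. Dyadic measures use one observation per pair.
    Contrasts with an empty or constant group are reported undefined
    and skipped in the correction.
    """
    dyadic = set(DYADIC_MEASURES if dyadic_measures is None else dyadic_measures)
    design = design[design["behavior_included"]] if "behavior_included" in design.columns else design
    merged = design.merge(behavior, left_on="animal_id", right_index=True, how="inner")

    if contrasts is None:
        contrasts = []
        tps = sorted(design["timepoint"].unique())
        for m in behavior.columns:
            contrasts.append({"measure": m, "kind": "mate_vs_sibling"})
            contrasts.extend(
                {"measure": m, "kind": "mate_vs_sibling", "timepoint": tp} for tp in tps
            )
            if m not in dyadic:
                contrasts.append({"measure": m, "kind": "female_vs_male"})

    results: list[TTestResult] = []
    meta: list[dict] = []
    for c in contrasts:
        m, kind, tp = c["measure"], c["kind"], c.get("timepoint")
        if m not in behavior.columns:
            raise KeyError(f"unknown measure {m!r}")
        sub = merged if tp is None else merged[merged["timepoint"] == tp]
        if m in dyadic:
            sub = sub.drop_duplicates("pair_id")
        if kind == "mate_vs_sibling":
            a = sub.loc[sub["partner_type"] == "mate", m].dropna()
            b = sub.loc[sub["partner_type"] == "sibling", m].dropna()
            if len(a) < 2 or len(b) < 2:
                warnings.warn(f"contrast on {m!r} (tp={tp}) has an empty group; skipped", stacklevel=2)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = welch_t(a, b, measure=m, groups="mate vs sibling")
        elif kind == "female_vs_male":
            mates = sub[sub["partner_type"] == "mate"]
            piv = mates.pivot_table(index="pair_id", columns="sex", values=m, aggfunc="first")
            piv = piv.dropna()
            if len(piv) < 2 or "F" not in piv or "M" not in piv:
                warnings.warn(f"paired contrast on {m!r} has too few pairs; skipped", stacklevel=2)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = paired_t(piv["F"], piv["M"], measure=m, groups="female vs male mates")
        else:
            raise ValueError(f"unknown contrast kind {kind!r}")
        results.append(res)
        meta.append({"timepoint": tp})

    table = pd.DataFrame(
        {
            "measure": [r.measure for r in results],
            "kind": [r.kind for r in results],
            "groups": [r.groups for r in results],
            "timepoint": [m["timepoint"] for m in meta],
            "n1": [r.n1 for r in results],
            "n2": [r.n2 for r in results],
            "t": [r.t for r in results],
            "df": [r.df for r in results],
            "p": [r.p for r in results],
        }
    )
    q = np.full(len(table), np.nan)
    ok = table["p"].notna().to_numpy()
    if ok.any():
        q[ok], _ = fdr_adjust(table.loc[ok, "p"].to_numpy(), method=fdr_method, alpha=alpha)
    table["q"] = q
    table["significant"] = table["q"] < alpha
    return table


def rosner_esd(values, max_outliers: int = 5, alpha: float = 0.05) -> pd.DataFrame:
    """Generalized extreme studentized deviate (Rosner) outlier test.

    Iteratively removes the most extreme point and computes
    R_i = max|x - mean| / sd against the critical value
    lambda_i = (n - i) t_{p, n-i-1} / sqrt((n-i-1+t^2)(n-i+1)) with
    p = 1 - alpha / (2 (n - i + 1)). The largest i with R_i > lambda_i
    determines the outlier count; all more-extreme candidates are
    flagged too. Returns one row per candidate (label, R, lambda,
    flagged).
    """
    s = pd.Series(values, dtype=float)
    n = len(s)
    if max_outliers < 1:
        raise ValueError("max_outliers must be >= 1")
    if n < max_outliers + 5:
        raise ValueError(f"need n >= max_outliers + 5 = {max_outliers + 5}, have {n}")
    if s.std(ddof=1) == 0:
        warnings.warn("constant sample: no outliers detectable", stacklevel=2)
        return pd.DataFrame(columns=["label", "R", "critical", "flagged"])

    work = s.copy()
    rows = []
    for i in range(1, max_outliers + 1):
        mu, sd = work.mean(), work.std(ddof=1)
        if sd == 0:
            break
        dev = (work - mu).abs()
        idx = dev.idxmax()
        r_stat = float(dev.loc[idx] / sd)
        ni = n - i + 1  # current sample size
        pcrit = 1.0 - alpha / (2.0 * ni)
        t = stats.t.ppf(pcrit, ni - 2)
        lam = float((ni - 1) * t / np.sqrt((ni - 2 + t**2) * ni))
        rows.append({"label": idx, "R": r_stat, "critical": lam})
        work = work.drop(idx)

    n_out = 0
    for i, row in enumerate(rows, start=1):
        if row["R"] > row["critical"]:
            n_out = i
    report = pd.DataFrame(rows)
    report["flagged"] = [i <= n_out for i in range(1, len(rows) + 1)]
    return report
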