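"""Within-pair neural coordination statistics.

For each ROI (or canonical-correlate score), the female and male values
of each mated pair form one observation; the Pearson correlation across
pairs measures how coordinated the two brains are. Partial correlations
controlling a pair-level behavior (the ejaculation count in the
emulated study) test whether mating intensity explains the coupling,
and the thresholded correlation table (default r > 0.75) defines the
coordination network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PairCorrResult:
    n_pairs: int
    df: int
    r: float
    p: float
    control: str | None = None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def pair_vectors(
    values: pd.Series,
    design: pd.DataFrame,
    timepoints,
    partner_type: str = "mate",
    ordering: str = "sex",
) -> pd.DataFrame:
    """Arrange a per-animal variable into one row per retained pair.

    With the default sex ordering (mate pairs), columns are (female,
    male); sibling pairs are same-sex and must use ``ordering='id'``,
    which orders members by animal id (Pearson r is order-invariant).
    Pairs are retained only when both members are IEG-included and have
    a value; dropped pairs are reported in ``.attrs['dropped_pairs']``.
    """
    timepoints = list(timepoints)
    if not timepoints:
        raise ValueError("timepoint subset must be non-empty")
    if ordering == "sex" and partner_type != "mate":
        raise ValueError("sex ordering requires mate pairs; use ordering='id' for siblings")
    d = design[
        (design["partner_type"] == partner_type) & design["timepoint"].isin(timepoints)
    ]
    if "ieg_included" in d.columns:
        d = d[d["ieg_included"]]
    rows, dropped = [], []
    cols = ("female", "male") if ordering == "sex" else ("member1", "member2")
    for pid, grp in d.groupby("pair_id"):
        if len(grp) != 2 or not grp["animal_id"].isin(values.index).all():
            dropped.append(pid)
            continue
        if ordering == "sex":
            grp = grp.sort_values("sex")  # F before M
            if list(grp["sex"]) != ["F", "M"]:
                dropped.append(pid)
                continue
        else:
            grp = grp.sort_values("animal_id")
        a, b = grp["animal_id"].tolist()
        va, vb = values.loc[a], values.loc[b]
        if pd.isna(va) or pd.isna(vb):
            dropped.append(pid)
            continue
        rows.append((pid, float(va), float(vb)))
    out = pd.DataFrame(rows, columns=["pair_id", *cols]).set_index("pair_id")
    out.attrs["dropped_pairs"] = dropped
    return out


def pearson_with_test(x, y) -> PairCorrResult:
    """Pearson r with a two-sided t-based test on n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need two equal-length vectors with n >= 3")
    df = n - 2
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return PairCorrResult(n_pairs=n, df=df, r=np.nan, p=np.nan)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PairCorrResult(n_pairs=n, df=df, r=r, p=p)


def partial_correlation(x, y, z) -> PairCorrResult:
    """First-order partial Pearson correlation of x and y given z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),
    tested on n - 3 df. Undefined (flagged NaN) when either variable is
    perfectly correlated with the control.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if n < 4 or len(y) != n or len(z) != n:
        raise ValueError("need three equal-length vectors with n >= 4")
    df = n - 3
    if np.std(x) == 0 or np.std(y) == 0 or np.std(z) == 0:
        warnings.warn("zero variance: partial correlation undefined", stacklevel=2)
        return PairCorrResult(n_pairs=n, df=df, r=np.nan, p=np.nan, control="z")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 0:
        warnings.warn("a variable is collinear with the control", stacklevel=2)
        return PairCorrResult(n_pairs=n, df=df, r=np.nan, p=np.nan, control="z")
    r = float((r_xy - r_xz * r_yz) / np.sqrt(denom))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PairCorrResult(n_pairs=n, df=df, r=r, p=p, control="z")


def coordination_matrix(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    timepoints,
    control: pd.Series | None = None,
    partner_type: str = "mate",
    mode: str = "roi",
    threshold: float = 0.75,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-pair correlation table plus the thresholded edge list.

    ``mode='roi'`` correlates each ROI's female value with the same
    ROI's male value (one row per ROI); ``mode='cross'`` correlates
    female ROI-a against male ROI-b for every ordered ROI pair. With a
    pair-level ``control`` (indexed by pair_id), partial correlations
    are reported instead. Entries with r > ``threshold`` form the edge
    list.
    """
    if mode not in ("roi", "cross"):
        raise ValueError(f"unknown mode {mode!r}")
    ordering = "sex" if partner_type == "mate" else "id"
    paired = {
        u: pair_vectors(counts[u], design, timepoints, partner_type, ordering)
        for u in counts.columns
    }
    # complete cases across units: keep pairs retained for every ROI
    common = None
    for df in paired.values():
        common = df.index if common is None else common.intersection(df.index)
    paired = {u: df.loc[common] for u, df in paired.items()}
    some = next(iter(paired.values()))
    n_pairs = len(some)
    if n_pairs < 4:
        raise ValueError(f"need at least 4 retained pairs, have {n_pairs}")
    ctrl = None
    if control is not None:
        ctrl = control.loc[some.index].to_numpy(dtype=float)

    c1, c2 = some.columns

    def corr(u, v):
        a = paired[u][c1].to_numpy()
        b = paired[v][c2].to_numpy()
        if ctrl is None:
            res = pearson_with_test(a, b)
        else:
            res = partial_correlation(a, b, ctrl)
        return res

    rows = []
    if mode == "roi":
        for u in counts.columns:
            res = corr(u, u)
            rows.append((u, u, res.r, res.df, res.p))
    else:
        for u in counts.columns:
            for v in counts.columns:
                res = corr(u, v)
                rows.append((u, v, res.r, res.df, res.p))
    table = pd.DataFrame(rows, columns=["roi_female", "roi_male", "r", "df", "p"])
    edges = table[table["r"] > threshold].reset_index(drop=True)
    table.attrs["n_pairs"] = n_pairs
    return table, edges
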