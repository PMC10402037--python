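"""Clustering and network characterization of the chosen ROIs.

Chosen ROIs are grouped by Ward (ward.D2) hierarchical clustering of a
Euclidean distance matrix over z-scored per-animal counts, embedded by
non-metric MDS for display, summarized as scaled per-cluster group-mean
time courses, and validated against a structural connectome: the mean
normalized connection density among cluster members is compared with a
null built by shuffling the rows of the connectivity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .atlas import AtlasHierarchy


def zscore_units(counts: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Scale each unit column to mean 0, sd 1 across animals.

    Zero-variance units are dropped with a warning. The column means
    and sds are stored in ``.attrs['center']`` / ``.attrs['scale']`` so
    the transform is invertible.
    """
    if len(counts) < 2:
        raise ValueError("need at least 2 animals to scale")
    sd = counts.std(axis=0, ddof=ddof)
    bad = sd[sd == 0].index
    if len(bad):
        warnings.warn(f"dropping {len(bad)} zero-variance units: {list(bad)[:5]}", stacklevel=2)
    kept = counts.drop(columns=bad)
    center = kept.mean(axis=0)
    scale = kept.std(axis=0, ddof=ddof)
    out = (kept - center) / scale
    out.attrs["center"] = center
    out.attrs["scale"] = scale
    return out


def unit_distance(scaled: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between unit columns (units x units)."""
    if scaled.shape[1] < 2:
        raise ValueError("need at least 2 units")
    d = squareform(pdist(scaled.to_numpy().T, metric="euclidean"))
    return pd.DataFrame(d, index=scaled.columns, columns=scaled.columns)


@dataclass
class LinkageTree:
    """Ward merge tree: scipy-format linkage matrix plus leaf labels."""

    merges: np.ndarray  # (n-1, 4): left, right, height, size
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def ward_linkage(dist: pd.DataFrame) -> LinkageTree:
    """ward.D2 agglomeration of a distance matrix.

    Heights are on the distance scale (the Lance-Williams update runs
    on squared distances internally). Ward heights are monotone, so no
    inversions occur.
    """
    if dist.shape[0] < 2:
        raise ValueError("need at least 2 units to cluster")
    Z = linkage(squareform(dist.to_numpy(), checks=False), method="ward")
    return LinkageTree(merges=Z, labels=list(dist.index))


def cut_tree(tree: LinkageTree, k: int) -> dict:
    """Cut the merge tree into ``k`` groups (drop the k-1 highest merges)."""
    n = len(tree.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    flat = fcluster(tree.merges, t=k, criterion="maxclust")
    return dict(zip(tree.labels, (int(c) for c in flat)))


def unit_correlations(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of unit counts across animals."""
    if len(counts) < 3:
        raise ValueError("need at least 3 animals")
    sd = counts.std(axis=0)
    if (sd == 0).any():
        warnings.warn(
            f"zero-variance units give undefined correlations: {list(sd[sd == 0].index)[:5]}",
            stacklevel=2,
        )
    return counts.corr()


@dataclass
class MDSResult:
    coords: pd.DataFrame  # unit x dims
    stress: float  # Kruskal stress-1


def _classical_mds(D: np.ndarray, dims: int, rng) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, dims))
    for d in range(min(dims, n)):
        if vals[d] > 1e-12:
            coords[:, d] = vecs[:, d] * np.sqrt(vals[d])
        else:
            coords[:, d] = rng.normal(0, 1e-6, size=n)
    return coords


def mds_embed(dist: pd.DataFrame, dims: int = 2, seed: int = 0) -> MDSResult:
    """Non-metric (Kruskal) MDS initialized from classical MDS.

    Monotone regression on dissimilarity ranks makes the solution
    invariant to monotone transforms of the distances; the reported
    stress is Kruskal stress-1 in [0, 1].
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    D = dist.to_numpy()
    rng = np.random.default_rng(seed)
    init = _classical_mds(D, dims, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MDS(
            n_components=dims,
            metric=False,
            dissimilarity="precomputed",
            n_init=1,
            normalized_stress=True,
            random_state=seed,
            max_iter=500,
            eps=1e-9,
        )
        coords = model.fit_transform(D, init=init)
    return MDSResult(
        coords=pd.DataFrame(coords, index=dist.index, columns=[f"dim{i+1}" for i in range(dims)]),
        stress=float(model.stress_),
    )


def cluster_time_course(
    counts: pd.DataFrame,
    assignment: dict,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Scaled per-cluster activity by experiment group.

    Per animal, cluster counts are summed, z-scored across animals, and
    averaged within each partner_type x sex x timepoint cell. Returns a
    long table (cluster, partner_type, sex, timepoint, mean, n).
    """
    design = design.set_index("animal_id").loc[counts.index]
    clusters = sorted(set(assignment.values()))
    rows = []
    groups = design.groupby(["partner_type", "sex", "timepoint"], observed=True).groups
    for c in clusters:
        members = [u for u, ci in assignment.items() if ci == c]
        total = counts[members].sum(axis=1)
        sd = total.std(ddof=1)
        if sd == 0:
            warnings.warn(f"cluster {c} has zero-variance totals", stacklevel=2)
            continue
        scaled = (total - total.mean()) / sd
        for (ptype, sex, tp), idx in groups.items():
            vals = scaled.loc[idx]
            if len(vals) == 0:
                warnings.warn(f"empty group cell {(ptype, sex, tp)}", stacklevel=2)
                rows.append((c, ptype, sex, tp, np.nan, 0))
            else:
                rows.append((c, ptype, sex, tp, float(vals.mean()), len(vals)))
    return pd.DataFrame(
        rows, columns=["cluster", "partner_type", "sex", "timepoint", "mean", "n"]
    )


def map_to_connectome(
    units: list[str],
    conn_labels: list[str],
    atlas: AtlasHierarchy,
) -> tuple[dict, list[str]]:
    """Map each unit onto a connectome row/column label.

    A unit present in the connectome maps to itself; otherwise it falls
    back to its nearest ancestor that is present (subregion borrows its
    parent structure's connectivity). Units with no resolvable ancestor
    are returned in the second element.
    """
    available = set(conn_labels)
    mapping: dict[str, str] = {}
    unresolved: list[str] = []
    for u in units:
        if u in available:
            mapping[u] = u
            continue
        anc = next((a for a in atlas.ancestors(u) if a in available), None)
        if anc is None:
            unresolved.append(u)
        else:
            mapping[u] = anc
    if unresolved:
        warnings.warn(f"{len(unresolved)} units unresolvable in connectome", stacklevel=2)
    return mapping, unresolved


def _cluster_members_idx(conn: pd.DataFrame, assignment: dict, cluster_subset=None):
    pos = {lbl: i for i, lbl in enumerate(conn.index)}
    clusters: dict = {}
    for u, c in assignment.items():
        if cluster_subset is not None and c not in cluster_subset:
            continue
        if u in pos:
            clusters.setdefault(c, []).append(pos[u])
    return clusters


def connectivity_density(
    conn: pd.DataFrame,
    assignment: dict,
    cluster_subset=None,
) -> tuple[dict, float]:
    """Mean off-diagonal connection density within each cluster.

    Both directions (u->v and v->u) count; the matrix diagonal is
    excluded. The overall value is the unweighted mean over clusters;
    clusters with fewer than 2 resolvable members are skipped.
    """
    if not conn.index.equals(conn.columns):
        raise ValueError("connectivity matrix must have identical row/column labels")
    M = conn.to_numpy(dtype=float)
    clusters = _cluster_members_idx(conn, assignment, cluster_subset)
    per_cluster = {}
    for c, idx in sorted(clusters.items()):
        if len(idx) < 2:
            warnings.warn(f"cluster {c} has < 2 members in the connectome; skipped", stacklevel=2)
            continue
        sub = M[np.ix_(idx, idx)]
        m = len(idx)
        per_cluster[c] = float((sub.sum() - np.trace(sub)) / (m * m - m))
    if not per_cluster:
        raise ValueError("no cluster has >= 2 resolvable members")
    overall = float(np.mean(list(per_cluster.values())))
    return per_cluster, overall


def connectivity_permutation_test(
    conn: pd.DataFrame,
    assignment: dict,
    n_perm: int = 10000,
    seed: int = 0,
    cluster_subset=None,
) -> tuple[float, float]:
    """Row-shuffling permutation test of the overall cluster density.

    Each permutation shuffles entire origin rows of the matrix (column
    labels fixed) and recomputes the overall mean cluster density with
    positional diagonal cells excluded after shuffling. p uses the
    add-one estimator over ``#{null >= observed}``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    M = conn.to_numpy(dtype=float)
    if np.allclose(M, M.flat[0]):
        warnings.warn("connectivity matrix is constant; p = 1 by construction", stacklevel=2)
    clusters = _cluster_members_idx(conn, assignment, cluster_subset)
    clusters = {c: np.asarray(idx) for c, idx in clusters.items() if len(idx) >= 2}
    if not clusters:
        raise ValueError("no cluster has >= 2 resolvable members")
    _, observed = connectivity_density(conn, assignment, cluster_subset)
    rng = np.random.default_rng(seed)
    n = M.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vals = []
        for idx in clusters.values():
            sub = M[np.ix_(perm[idx], idx)]
            diag = M[perm[idx], idx].sum()
            m = len(idx)
            vals.append((sub.sum() - diag) / (m * m - m))
        if np.mean(vals) >= observed:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return observed, p
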