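"""Synthetic study generator for the pair-bonding c-Fos pipeline.

Emulates the study design that the analysis assumes: mate (female+male)
and same-sex sibling control pairs cohabit for one of four durations
(0, 2.5, 6 or 22 h, coded ordinally 1-4), run in six testing blocks.
Per-unit c-Fos+ cell counts are drawn from a gamma-Poisson (negative
binomial) model whose mean follows a log-linear predictor with sex,
time, block and planted partner-type effects, and whose variance is
``dispersion * mean`` -- the mean-variance relation the quasi-Poisson
screen assumes. A pair-level log-normal latent (standing in for mating
intensity, observable as the ejaculation count) multiplicatively couples
designated units within mate pairs, planting within-pair coordination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import AtlasHierarchy, generate_atlas

TIMEPOINT_HOURS = {1: 0.0, 2: 2.5, 3: 6.0, 4: 22.0}
N_TIMEPOINTS = 4
N_BLOCKS = 6

DYADIC_MEASURES = ["mounts", "intromissions", "ejaculations", "huddling", "usv_rate"]
INDIVIDUAL_MEASURES = [
    "velocity",
    "net_movement",
    "anogenital_investigation",
    "self_grooming",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study: 12 pairs per partner-type x
    timepoint cell (192 animals), 6 blocks, overdispersed counts
    (variance = dispersion * mean), 68 planted partner-responsive units
    grouped into 6 clusters, and a pair-level latent coupling a subset
    of units during the mating timepoints.
    """

    n_pairs_per_cell: int = 12
    n_units: int = 800
    baseline_log_mean: float = 4.0
    unit_sd: float = 0.5
    sex_effect: float = 0.05
    time_profile: tuple = (0.0, 0.3, 0.3, 0.0)
    block_sd: float = 0.1
    dispersion: float = 2.5
    n_planted: int = 68
    effect_size: float = 0.7
    n_planted_clusters: int = 6
    cluster_latent_sd: float = 0.3
    n_coupled: int = 10
    coupling_gamma: float = 1.0
    coupling_timepoints: tuple = (2, 3)
    atlas_depth: int = 3
    seed: int = 0

    # explicit plantings override the counts above when provided
    effect_units: dict | None = None  # unit -> log-scale effect
    coupling_units: list | None = None

    def __post_init__(self):
        if self.dispersion < 1:
            raise ValueError("dispersion must be >= 1 (underdispersion unsupported)")


def generate_design(n_pairs_per_cell: int, seed: int = 0) -> pd.DataFrame:
    """Build the animal design table.

    Per timepoint: ``n`` mate pairs (one F + one M) and ``n`` sibling
    pairs (half F-F, half M-M; an odd extra pair alternates sex by
    timepoint). Blocks 1-6 are assigned round-robin over pairs with
    mate and sibling pairs interleaved, so each block is balanced across
    partner types within timepoint. The table is deterministic given
    ``n_pairs_per_cell``; ``seed`` is accepted for API uniformity.
    """
    if n_pairs_per_cell < 1:
        raise ValueError("n_pairs_per_cell must be >= 1")
    del seed
    rows = []
    animal = pair = 0
    for tp in range(1, N_TIMEPOINTS + 1):
        specs = []  # (partner_type, sex of member 1, sex of member 2)
        for i in range(n_pairs_per_cell):
            specs.append(("mate", "F", "M"))
        n_ff = n_pairs_per_cell // 2
        n_mm = n_pairs_per_cell // 2
        if n_pairs_per_cell % 2 == 1:
            if tp % 2 == 1:
                n_ff += 1
            else:
                n_mm += 1
        sib = [("sibling", "F", "F")] * n_ff + [("sibling", "M", "M")] * n_mm
        # interleave mate and sibling pairs so round-robin blocks balance
        interleaved = []
        for m, s in zip(specs, sib):
            interleaved.extend([m, s])
        for i, (ptype, s1, s2) in enumerate(interleaved):
            pair += 1
            # adjacent mate/sibling pairs share a block (a "testing day"),
            # keeping partner type balanced across blocks
            block = (i // 2 % N_BLOCKS) + 1
            for sex in (s1, s2):
                animal += 1
                rows.append(
                    {
                        "animal_id": f"A{animal:03d}",
                        "pair_id": f"P{pair:03d}",
                        "sex": sex,
                        "partner_type": ptype,
                        "timepoint": tp,
                        "block": block,
                        "behavior_included": True,
                        "ieg_included": True,
                    }
                )
    return pd.DataFrame(rows)


def apply_exclusions(design: pd.DataFrame, exclusions: list[tuple]) -> pd.DataFrame:
    """Flag animals excluded from behavior and/or IEG analyses.

    ``exclusions`` holds (animal_id, reason, scope) with scope
    ``behavior`` or ``ieg``. Returns a copy with flags updated.
    """
    out = design.copy()
    ids = set(out["animal_id"])
    for animal_id, _reason, scope in exclusions:
        if animal_id not in ids:
            raise KeyError(f"unknown animal_id in exclusions: {animal_id!r}")
        if scope not in ("behavior", "ieg"):
            raise ValueError(f"unknown exclusion scope {scope!r}")
        out.loc[out["animal_id"] == animal_id, f"{scope}_included"] = False
    return out


def study_default_exclusions(design: pd.DataFrame) -> list[tuple]:
    """Exclusions mirroring the emulated study's bookkeeping.

    Three animals leave the IEG analysis (one male sibling at the 6 h
    timepoint, one female mate at 0 h, one female mate at 6 h -- a
    perfusion failure and two whole-brain count outliers) and one 0 h
    mate pair loses behavior data to a camera malfunction.
    """

    def pick(sex, ptype, tp, skip=()):
        sel = design[
            (design["sex"] == sex)
            & (design["partner_type"] == ptype)
            & (design["timepoint"] == tp)
            & (~design["animal_id"].isin(skip))
        ]
        if sel.empty:
            raise ValueError("design too small for the study exclusion pattern")
        return sel.iloc[0]["animal_id"]

    ieg = [
        (pick("M", "sibling", 3), "perfusion failure", "ieg"),
        (pick("F", "mate", 1), "whole-brain count outlier", "ieg"),
        (pick("F", "mate", 3), "whole-brain count outlier", "ieg"),
    ]
    # a different 0 h mate pair than the excluded outlier's
    outlier_pair = design.loc[design["animal_id"] == ieg[1][0], "pair_id"].iloc[0]
    cam = design[
        (design["partner_type"] == "mate")
        & (design["timepoint"] == 1)
        & (design["pair_id"] != outlier_pair)
    ]
    cam_pair = cam.iloc[0]["pair_id"]
    behavior = [
        (aid, "camera malfunction", "behavior")
        for aid in design.loc[design["pair_id"] == cam_pair, "animal_id"]
    ]
    return ieg + behavior


def _negative_binomial(rng, mu, dispersion):
    """Gamma-Poisson draw with mean mu and variance dispersion * mu."""
    if dispersion == 1.0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=mu / (dispersion - 1.0), scale=dispersion - 1.0)
    return rng.poisson(lam)


def generate_counts(
    design: pd.DataFrame,
    units: list[str],
    config: SimConfig,
    pair_latent: dict | None = None,
    cluster_of: dict | None = None,
) -> pd.DataFrame:
    """Draw the animals x units count matrix.

    Log mean = unit baseline + sex + time + block effects, plus the
    planted partner effect (mates only) on effect units, a per-animal
    per-cluster latent that correlates units sharing a planted cluster,
    and ``gamma * z_pair`` on coupling units for mate pairs at the
    coupling timepoints. Counts are gamma-Poisson with variance
    ``dispersion * mean``. Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    units = list(units)
    effect_units = config.effect_units or {}
    unknown = set(effect_units) - set(units)
    if unknown:
        raise ValueError(f"effect units not in unit list: {sorted(unknown)[:5]}")
    coupling_units = [u for u in (config.coupling_units or []) if True]
    unknown = set(coupling_units) - set(units)
    if unknown:
        raise ValueError(f"coupling units not in unit list: {sorted(unknown)[:5]}")

    n = len(design)
    baselines = config.baseline_log_mean + rng.normal(0, config.unit_sd, size=len(units))
    block_eff = rng.normal(0, config.block_sd, size=N_BLOCKS)
    if pair_latent is None:
        pair_ids = design["pair_id"].unique()
        pair_latent = dict(zip(pair_ids, rng.lognormal(0.0, 1.0, size=len(pair_ids))))

    sex = (design["sex"].to_numpy() == "M").astype(float)
    tp = design["timepoint"].to_numpy()
    block = design["block"].to_numpy().astype(int)
    mate = (design["partner_type"].to_numpy() == "mate").astype(float)
    z = design["pair_id"].map(pair_latent).to_numpy()

    eta = np.tile(baselines, (n, 1))
    eta += (sex * config.sex_effect)[:, None]
    eta += np.array([config.time_profile[t - 1] for t in tp])[:, None]
    eta += block_eff[block - 1][:, None]

    for j, u in enumerate(units):
        if u in effect_units:
            eta[:, j] += mate * effect_units[u]

    if cluster_of:
        clusters = sorted(set(cluster_of.values()))
        animal_latent = rng.normal(0, config.cluster_latent_sd, size=(n, len(clusters)))
        cidx = {c: k for k, c in enumerate(clusters)}
        for j, u in enumerate(units):
            if u in cluster_of:
                eta[:, j] += animal_latent[:, cidx[cluster_of[u]]]

    if coupling_units and config.coupling_gamma != 0.0:
        # multiplicative coupling mu *= z^gamma: the count mean stays
        # (for gamma=1 exactly) linear in the pair latent, so a linear
        # partial correlation on z can remove the planted coordination
        in_window = np.isin(tp, config.coupling_timepoints).astype(float)
        boost = config.coupling_gamma * np.log(z) * mate * in_window
        for j, u in enumerate(units):
            if u in coupling_units:
                eta[:, j] += boost

    mu = np.exp(np.clip(eta, None, 30.0))
    counts = _negative_binomial(rng, mu, config.dispersion)
    return pd.DataFrame(
        counts, index=pd.Index(design["animal_id"], name="animal_id"), columns=units
    )


def generate_behavior(
    design: pd.DataFrame,
    latent: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the animals x measures behavior table.

    Mate pairs at the mating timepoints (2.5 and 6 h) get ejaculation
    counts drawn Poisson with mean proportional to the pair latent;
    mounts and intromissions scale with it. Mating is rare by 22 h and
    absent at 0 h (divider in place); siblings never mate. Dyadic
    measures (mounting, huddling, vocalization) are identical within a
    pair; individual measures are log-normal with mild partner-type
    shifts. Rates are per hour of the 1 h focal window; huddling is a
    proportion of it.
    """
    rng = np.random.default_rng(seed)
    pairs = design.drop_duplicates("pair_id")
    dyadic = {}
    for _, row in pairs.iterrows():
        pid, tp, ptype = row["pair_id"], row["timepoint"], row["partner_type"]
        z = latent[pid]
        interacting = tp > 1
        if ptype == "mate" and tp in (2, 3):
            # rate high enough that the count is a reliable readout of the
            # pair latent (repeated copulation over the 1 h focal window)
            ej = rng.poisson(6.0 * z)
            intro = ej + rng.poisson(8.0 * z)
            mounts = intro + rng.poisson(3.0)
        elif ptype == "mate" and tp == 4:
            ej = rng.poisson(0.2 * z)
            intro = ej + rng.poisson(0.5 * z)
            mounts = intro + rng.poisson(0.3)
        else:
            ej = intro = mounts = 0
        if interacting:
            base_huddle = 0.35 if ptype == "mate" and tp >= 3 else 0.25
            huddle = float(np.clip(rng.normal(base_huddle, 0.1), 0.0, 1.0))
            usv = float(rng.poisson(40.0 if ptype == "mate" and tp in (2, 3) else 15.0))
        else:
            huddle = 0.0
            usv = 0.0
        dyadic[pid] = {
            "mounts": float(mounts),
            "intromissions": float(intro),
            "ejaculations": float(ej),
            "huddling": huddle,
            "usv_rate": usv,
        }

    rows = []
    for _, row in design.iterrows():
        tp, ptype = row["timepoint"], row["partner_type"]
        interacting = tp > 1
        rec = {"animal_id": row["animal_id"]}
        rec.update(dyadic[row["pair_id"]])
        rec["velocity"] = float(rng.lognormal(1.0, 0.3))
        rec["net_movement"] = float(rng.lognormal(0.5, 0.4))
        if interacting:
            shift = 0.4 if ptype == "mate" else 0.0
            rec["anogenital_investigation"] = float(rng.lognormal(1.0 + shift, 0.4))
        else:
            rec["anogenital_investigation"] = 0.0
        rec["self_grooming"] = float(rng.lognormal(0.8, 0.3))
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("animal_id")
    return out[INDIVIDUAL_MEASURES + DYADIC_MEASURES]


def generate_connectivity(
    atlas_units: list[str],
    clusters: dict,
    within_density: float,
    between_density: float,
    noise_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Origin x target normalized-connection-density matrix.

    Entries are ``within_density`` when both ROIs share a cluster in
    ``clusters`` and ``between_density`` otherwise, plus truncated
    Gaussian noise clipped at zero. The diagonal is populated (it is
    excluded downstream, not here).
    """
    if not (within_density >= between_density >= 0):
        raise ValueError("require within_density >= between_density >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    units = list(atlas_units)
    c = np.array([clusters.get(u) for u in units], dtype=object)
    same = (c[:, None] == c[None, :]) & (c[:, None] != None)  # noqa: E711
    base = np.where(same, within_density, between_density).astype(float)
    if noise_sd > 0:
        base = base + rng.normal(0, noise_sd, size=base.shape)
    base = np.clip(base, 0.0, None)
    return pd.DataFrame(base, index=pd.Index(units, name="origin"), columns=units)


@dataclass
class SimulatedStudy:
    """Everything one synthetic run of the study produces, plus truth."""

    design: pd.DataFrame
    atlas: AtlasHierarchy
    counts: pd.DataFrame  # all animals x all non-root atlas units
    behavior: pd.DataFrame
    connectivity: pd.DataFrame
    planted_units: list[str] = field(default_factory=list)
    planted_clusters: dict = field(default_factory=dict)
    coupled_units: list[str] = field(default_factory=list)
    pair_latent: dict = field(default_factory=dict)
    config: SimConfig | None = None


def simulate_study(config: SimConfig | None = None) -> SimulatedStudy:
    """Run the full generator: design, atlas, counts, behavior, connectivity.

    Leaf units carry the generative model; counts for internal atlas
    structures are the sums over their leaf descendants, so planted leaf
    effects propagate to ancestors and exercise the exclusive-ROI
    selection exactly as nested atlas counts do. The same pair latent
    drives both the coupled count units and the ejaculation counts.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    atlas = generate_atlas(config.n_units, config.atlas_depth, seed=config.seed)
    leaves = sorted(atlas.leaves())
    design = generate_design(config.n_pairs_per_cell)
    design = apply_exclusions(design, study_default_exclusions(design))

    if config.effect_units is None:
        planted = sorted(
            map(str, rng.choice(leaves, size=min(config.n_planted, len(leaves)), replace=False))
        )
        effect_units = {u: config.effect_size for u in planted}
    else:
        effect_units = dict(config.effect_units)
        planted = sorted(effect_units)
    cluster_of = {
        u: (i % config.n_planted_clusters) + 1 for i, u in enumerate(planted)
    }
    if config.coupling_units is None:
        coupled = [u for u in planted if cluster_of[u] == 1][: config.n_coupled]
    else:
        coupled = list(config.coupling_units)

    pair_ids = design["pair_id"].unique()
    pair_latent = dict(zip(pair_ids, rng.lognormal(0.0, 1.0, size=len(pair_ids))))

    cfg = SimConfig(**{**config.__dict__, "effect_units": effect_units, "coupling_units": coupled})
    counts = generate_counts(
        design, leaves, cfg, pair_latent=pair_latent, cluster_of=cluster_of
    )

    # aggregate to internal structures: counts of a structure = sum of leaves below
    internal = [a for a in atlas.acronyms if a not in set(leaves) and a != atlas.root.acronym]
    agg = {}
    for node in internal:
        below = [u for u in leaves if node in atlas.ancestors(u)]
        if below:
            agg[node] = counts[below].sum(axis=1)
    if agg:
        counts = pd.concat([counts, pd.DataFrame(agg)], axis=1)

    behavior = generate_behavior(design, pair_latent, seed=config.seed + 1)
    connectivity = generate_connectivity(
        leaves,
        cluster_of,
        within_density=0.5,
        between_density=0.05,
        noise_sd=0.02,
        seed=config.seed + 2,
    )
    return SimulatedStudy(
        design=design,
        atlas=atlas,
        counts=counts,
        behavior=behavior,
        connectivity=connectivity,
        planted_units=list(planted),
        planted_clusters=cluster_of,
        coupled_units=coupled,
        pair_latent=pair_latent,
        config=cfg,
    )
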