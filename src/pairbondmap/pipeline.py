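"""End-to-end orchestration: simulate -> screen -> select -> cluster ->
connectivity -> CCA -> pair coordination -> behavior stats.

Every stage reads and writes plain CSV/JSON files, so each is runnable
standalone on the previous stage's outputs; :func:`run_pipeline` chains
them and records a manifest (config snapshot, per-stage seeds, output
checksums, wall-clock) sufficient to reproduce the run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cca as cca_mod
from . import cluster as cl
from . import io as pio
from .behavior import batch_tests, rosner_esd
from .coordination import coordination_matrix
from .glm import permutation_screen
from .roi import select_exclusive
from .simulate import SimConfig, simulate_study

log = logging.getLogger("pairbondmap")


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    Alphas default to the screen/behavior conventions (q < 0.1 for the
    brain screen, q < 0.05 for behavior tests). Seeds are per stage so
    stages can be re-run independently.
    """

    outdir: str = "pipeline_out"
    sim: SimConfig = field(default_factory=SimConfig)
    n_perm_screen: int = 200
    n_perm_connectivity: int = 10000
    screen_alpha: float = 0.1
    behavior_alpha: float = 0.05
    fdr_method: str = "bh"
    permutation_scheme: str = "pair_stratified"
    contrast: str = "bonding_vs_null"
    k_clusters: int = 8
    mds_dims: int = 2
    cca_factors: int | None = None
    coordination_timepoints: tuple = (2, 3)
    coordination_threshold: float = 0.75
    coordination_control: str | None = "ejaculations"
    max_outliers: int = 5
    outlier_alpha: float = 0.05
    screen_seed: int = 1
    connectivity_seed: int = 2
    mds_seed: int = 3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def validate_inputs(paths: dict) -> list[str]:
    """Schema and cross-file checks on the pipeline's input files.

    ``paths`` maps any of design/counts/behavior/atlas/connectivity to
    file paths. Returns a list of human-readable violations (empty when
    everything is consistent).
    """
    violations: list[str] = []
    loaded: dict = {}
    readers = {
        "design": pio.read_design,
        "counts": pio.read_counts,
        "behavior": pio.read_behavior,
        "atlas": pio.read_atlas,
        "connectivity": pio.read_connectivity,
    }
    for key, reader in readers.items():
        if key not in paths:
            continue
        try:
            loaded[key] = reader(paths[key])
        except Exception as exc:  # surface the file and the problem
            violations.append(f"{key} ({paths[key]}): {exc}")
    design = loaded.get("design")
    if design is not None:
        sizes = design.groupby("pair_id").size()
        bad = sizes[sizes != 2]
        if len(bad):
            violations.append(f"design: pairs without exactly 2 animals: {list(bad.index)[:5]}")
        if not design["timepoint"].isin([1, 2, 3, 4]).all():
            violations.append("design: timepoint outside 1-4")
        if not design["block"].between(1, 6).all():
            violations.append("design: block outside 1-6")
    for key in ("counts", "behavior"):
        tab = loaded.get(key)
        if tab is None or design is None:
            continue
        extra = set(tab.index) - set(design["animal_id"])
        if extra:
            violations.append(
                f"{key}: animal ids absent from design: {sorted(extra)[:5]}"
            )
    atlas = loaded.get("atlas")
    counts = loaded.get("counts")
    if atlas is not None and counts is not None:
        missing = [u for u in counts.columns if u not in atlas]
        if missing:
            violations.append(f"counts: units not in atlas: {missing[:5]}")
    return violations


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis chain on a synthetic study.

    Writes all stage outputs under ``config.outdir`` and returns the
    manifest (also written as ``manifest.json``). A stage failure is
    recorded and downstream stages are skipped.
    """
    outdir = pio.ensure_dir(config.outdir)
    manifest: dict = {
        "config": config.to_dict(),
        "stages": {},
        "checksums": {},
        "warnings": [],
    }
    state: dict = {}

    def _simulate():
        study = simulate_study(config.sim)
        state["study"] = study
        pio.write_design(study.design, outdir / "design.csv")
        pio.write_counts(study.counts, outdir / "counts.csv")
        pio.write_behavior(study.behavior, outdir / "behavior.csv")
        pio.write_connectivity(study.connectivity, outdir / "connectivity.csv")
        pio.write_atlas(study.atlas, outdir / "atlas.json")
        (outdir / "truth.json").write_text(
            json.dumps(
                {
                    "planted_units": study.planted_units,
                    "planted_clusters": study.planted_clusters,
                    "coupled_units": study.coupled_units,
                },
                indent=1,
            )
        )

    def _screen():
        study = state["study"]
        screen = permutation_screen(
            study.counts,
            study.design,
            contrast=config.contrast,
            n_perm=config.n_perm_screen,
            seed=config.screen_seed,
            scheme=config.permutation_scheme,
            fdr_method=config.fdr_method,
            alpha=config.screen_alpha,
        )
        state["screen"] = screen
        screen.to_csv(outdir / "screen.csv")

    def _select():
        study, screen = state["study"], state["screen"]
        sig = screen[screen["significant"]].reset_index()[["unit", "F"]]
        sel = select_exclusive(study.atlas, sig)
        state["selection"] = sel
        out = screen.reset_index()[["unit", "F", "q"]].copy()
        out["chosen"] = out["unit"].isin(sel.chosen_units)
        displaced = dict(zip(sel.rejected["unit"], sel.rejected["displaced_by"]))
        out["displaced_by"] = out["unit"].map(displaced)
        out.to_csv(outdir / "chosen_rois.csv", index=False)

    def _cluster():
        study, sel = state["study"], state["selection"]
        chosen = sel.chosen_units
        if len(chosen) < 2:
            raise RuntimeError("fewer than 2 chosen ROIs; cannot cluster")
        counts = study.counts.loc[
            study.design.loc[study.design["ieg_included"], "animal_id"], chosen
        ]
        scaled = cl.zscore_units(counts)
        dist = cl.unit_distance(scaled)
        tree = cl.ward_linkage(dist)
        k = min(config.k_clusters, len(chosen))
        assignment = cl.cut_tree(tree, k)
        state["assignment"] = assignment
        state["counts_chosen"] = counts
        pd.DataFrame(
            {"unit": list(assignment), "cluster": list(assignment.values())}
        ).to_csv(outdir / "clusters.csv", index=False)
        pd.DataFrame(
            tree.merges, columns=["left", "right", "height", "size"]
        ).to_csv(outdir / "linkage.csv", index=False)
        mds = cl.mds_embed(dist, dims=config.mds_dims, seed=config.mds_seed)
        mds.coords.assign(stress=mds.stress).to_csv(outdir / "mds.csv")
        tc = cl.cluster_time_course(counts, assignment, study.design)
        tc.to_csv(outdir / "timecourse.csv", index=False)

    def _connectivity():
        study, assignment = state["study"], state["assignment"]
        mapping, _ = cl.map_to_connectome(
            list(assignment), list(study.connectivity.index), study.atlas
        )
        mapped = {mapping[u]: c for u, c in assignment.items() if u in mapping}
        observed, p = cl.connectivity_permutation_test(
            study.connectivity,
            mapped,
            n_perm=config.n_perm_connectivity,
            seed=config.connectivity_seed,
        )
        state["connectivity_test"] = (observed, p)
        (outdir / "connectivity_test.json").write_text(
            json.dumps(
                {"observed_density": observed, "p": p, "n_perm": config.n_perm_connectivity}
            )
        )

    def _cca():
        study = state["study"]
        counts = state["counts_chosen"]
        behav = study.behavior.loc[counts.index]
        res = cca_mod.cca_fit(counts, behav, n_factors=config.cca_factors)
        tests = cca_mod.wilks_test(res)
        loadings = cca_mod.score_loadings(res, counts, behav)
        groups = cca_mod.group_cc_scores(res, study.design)
        state["cca"] = res
        scores = pd.concat(
            {"brain": res.x_scores, "behavior": res.y_scores}, axis=1
        )
        scores.columns = [f"{s}_{f}" for s, f in scores.columns]
        scores.to_csv(outdir / "cca_scores.csv", index_label="animal_id")
        loadings.to_csv(outdir / "cca_loadings.csv", index=False)
        tests.to_csv(outdir / "cca_tests.csv", index=False)
        groups.to_csv(outdir / "cca_group_scores.csv", index=False)

    def _pair_corr():
        study = state["study"]
        counts = state["counts_chosen"]
        control = None
        if config.coordination_control:
            pair_of = study.design.set_index("animal_id")["pair_id"]
            vals = study.behavior[config.coordination_control]
            control = (
                pd.DataFrame({"pair_id": pair_of.loc[vals.index], "v": vals})
                .groupby("pair_id")["v"]
                .first()
            )
        table, edges = coordination_matrix(
            counts,
            study.design,
            timepoints=config.coordination_timepoints,
            control=None,
            threshold=config.coordination_threshold,
        )
        table.to_csv(outdir / "pair_corr.csv", index=False)
        if control is not None:
            ptable, _ = coordination_matrix(
                counts,
                study.design,
                timepoints=config.coordination_timepoints,
                control=control,
                threshold=config.coordination_threshold,
            )
            ptable.to_csv(outdir / "pair_corr_controlled.csv", index=False)
        edges.to_csv(outdir / "coordination_edges.csv", index=False)
        state["coordination"] = (table, edges)

    def _behavior_stats():
        study = state["study"]
        tests = batch_tests(
            study.behavior,
            study.design,
            alpha=config.behavior_alpha,
            fdr_method=config.fdr_method,
        )
        tests.to_csv(outdir / "behavior_tests.csv", index=False)
        totals = study.counts.sum(axis=1)
        report = rosner_esd(
            totals, max_outliers=config.max_outliers, alpha=config.outlier_alpha
        )
        report.to_csv(outdir / "outliers.csv", index=False)

    stages = [
        ("simulate", _simulate),
        ("screen", _screen),
        ("select_rois", _select),
        ("cluster", _cluster),
        ("connectivity_test", _connectivity),
        ("cca", _cca),
        ("pair_corr", _pair_corr),
        ("behavior_stats", _behavior_stats),
    ]
    failed = False
    for name, fn in stages:
        if failed:
            manifest["stages"][name] = {"status": "skipped"}
            continue
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fn()
            for w in caught:
                manifest["warnings"].append(f"{name}: {w.message}")
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
            log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            log.error("stage %s failed: %s", name, exc)
            failed = True

    for f in sorted(outdir.glob("*")):
        if f.name != "manifest.json" and f.is_file():
            manifest["checksums"][f.name] = _checksum(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
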