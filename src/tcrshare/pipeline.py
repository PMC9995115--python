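"""End-to-end orchestration: simulate, spatial, temporal, network, diversity.

Each stage reads repertoires (from the synthetic generator or a sample
sheet), runs the corresponding analysis modules, and writes tab-separated
tables with a provenance header line (package version, stage, seed, config
hash). Every random stage derives its seed deterministically from the global
seed and the stage name, so a full run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, overlap
from .cohort import CohortConfig, GroundTruth, PlantedClusterSpec, PlantedSharedSpec, generate_cohort
from .convergence import convergence_report
from .diversity import AbundanceVector, compare_group_diversity, default_m_grid, rarefy_richness, rarefy_shannon
from .io import Repertoire, collapse_by_junction_aa, write_clonotype_table, write_sample_sheet
from .network import (
    LABEL_LEFT,
    LABEL_RIGHT,
    NetworkConfig,
    build_network,
    cluster_statistics,
    compare_to_random,
    network_to_edge_frame,
    write_graphml,
)
from .vdj import RecombinationModel, default_model

logger = logging.getLogger("tcrshare.pipeline")


@dataclass(frozen=True)
class NetworkStageConfig:
    k: int = 3
    tau: int = 8
    n_random: int = 100
    top_c: int = 5
    trim_anchors: int = 0
    purity_mode: str = "label"
    subset: str = "TREG"
    visit: int = 0


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    outdir: str = "tcrshare_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    network: NetworkStageConfig = field(default_factory=NetworkStageConfig)
    top_n_grid: tuple[int, ...] = tuple(int(x) for x in np.unique(np.round(np.geomspace(1, 1000, 16))))
    venn_top_n: int = 100
    shannon_reps: int = 200
    freq_mode: str = "max"
    scale: str = "LOG10"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs:
            c = dict(kwargs["cohort"])
            if "planted_shared" in c:
                c["planted_shared"] = tuple(PlantedSharedSpec(**_tuplify(s)) for s in c["planted_shared"])
            if "planted_clusters" in c:
                c["planted_clusters"] = tuple(PlantedClusterSpec(**_tuplify(s)) for s in c["planted_clusters"])
            for key in ("compartments", "subsets"):
                if key in c:
                    c[key] = tuple(c[key])
            kwargs["cohort"] = CohortConfig(**c)
        if "network" in kwargs:
            kwargs["network"] = NetworkStageConfig(**kwargs["network"])
        if "top_n_grid" in kwargs:
            kwargs["top_n_grid"] = tuple(int(x) for x in kwargs["top_n_grid"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        plain = _as_plain(self)
        plain.pop("outdir", None)  # hash the scientific config, not the output path
        blob = yaml.safe_dump(plain, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write_table(df: pd.DataFrame, path: str, stage: str, cfg: RunConfig) -> None:
    os.makedirs(os.path.dirname(path), exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# tcrshare={__version__} stage={stage} seed={cfg.seed} config_sha={cfg.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _log_stage(stage: str, n_items: int, seed: int, t0: float) -> None:
    logger.info("stage=%s items=%d seed=%d elapsed=%.2fs", stage, n_items, seed, time.time() - t0)


def _collapsed(reps: Sequence[Repertoire]) -> list[Repertoire]:
    return [collapse_by_junction_aa(r) for r in reps]


def _by(reps: Sequence[Repertoire], **match) -> list[Repertoire]:
    out = []
    for r in reps:
        if all(getattr(r, k) == v for k, v in match.items()):
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: RunConfig, model: RecombinationModel | None = None) -> tuple[list[Repertoire], GroundTruth]:
    """Generate the synthetic cohort and write tables, sample sheet and truth."""
    t0 = time.time()
    cohort_cfg = dataclasses.replace(cfg.cohort, seed=stage_seed(cfg.seed, "simulate"))
    reps, truth = generate_cohort(cohort_cfg, model)
    data_dir = os.path.join(cfg.outdir, "cohort")
    os.makedirs(data_dir, exist_ok=True)
    paths = []
    for rep in reps:
        name = f"{rep.sample_id}.tsv"
        write_clonotype_table(rep, os.path.join(data_dir, name))
        paths.append(name)
    write_sample_sheet(reps, paths, os.path.join(data_dir, "samples.tsv"))
    with open(os.path.join(data_dir, "ground_truth.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "mode": truth.mode,
                "shared_clone_keys": {f"{p}/{s}": sorted(v) for (p, s), v in truth.shared_clone_keys.items()},
                "cluster_families": {f"{p}/{s}/{i}": list(v) for (p, s, i) in sorted(truth.cluster_families)
                                     for v in [truth.cluster_families[(p, s, i)]]},
            },
            fh,
            sort_keys=True,
        )
    _log_stage("simulate", len(reps), cohort_cfg.seed, t0)
    return reps, truth


def run_spatial(reps: Sequence[Repertoire], cfg: RunConfig, model: RecombinationModel | None = None) -> dict:
    """Cross-compartment sharing: proportions, top-N curves, classes, pairs, convergence."""
    t0 = time.time()
    model = model or default_model()
    reps = _collapsed(reps)
    out = os.path.join(cfg.outdir, "spatial")
    bundle: dict = {}

    prop_rows = []
    for rep in reps:
        t = overlap.clonal_proportion_summary(rep)
        t.insert(0, "sample_id", rep.sample_id)
        prop_rows.append(t)
    bundle["clonal_proportions"] = pd.concat(prop_rows, ignore_index=True)
    _write_table(bundle["clonal_proportions"], os.path.join(out, "clonal_proportions.tsv"), "spatial", cfg)

    curve_rows, class_rows, pair_rows = [], [], []
    conv_inputs: list[Repertoire] = []
    patients = sorted({r.patient for r in reps})
    for patient in patients:
        for subset in sorted({r.subset for r in reps}):
            for visit in sorted({r.visit for r in reps}):
                group = _by(reps, patient=patient, subset=subset, visit=visit)
                comps = {r.compartment: r for r in group}
                if "SF_LEFT" not in comps or "SF_RIGHT" not in comps:
                    logger.warning("spatial: %s/%s/v%d lacks SF_LEFT+SF_RIGHT; skipped", patient, subset, visit)
                    continue
                if "PB" not in comps:
                    logger.info("spatial: no PB sample for %s/%s/v%d; 2-sample analyses only", patient, subset, visit)
                members = [comps[c] for c in ("PB", "SF_LEFT", "SF_RIGHT") if c in comps]
                conv_inputs.extend(members)
                import itertools as _it

                for ra, rb in _it.combinations(members, 2):
                    curve = overlap.top_n_intersection(ra, rb, cfg.top_n_grid)
                    for n, pct in zip(curve.n_values, curve.percent_overlap):
                        curve_rows.append(
                            {"patient": patient, "subset": subset, "visit": visit,
                             "sample_a": ra.sample_id, "sample_b": rb.sample_id, "n": n, "percent": pct}
                        )
                classes = overlap.classify_sharing(members)
                classes.insert(0, "visit", visit)
                classes.insert(0, "subset", subset)
                classes.insert(0, "patient", patient)
                class_rows.append(classes)
                pair = overlap.paired_frequency_table(
                    comps["SF_LEFT"], comps["SF_RIGHT"], context=[comps["PB"]] if "PB" in comps else ()
                )
                pair.insert(0, "visit", visit)
                pair.insert(0, "subset", subset)
                pair.insert(0, "patient", patient)
                pair_rows.append(pair)
    bundle["top_n_curves"] = pd.DataFrame(curve_rows)
    bundle["sharing_classes"] = pd.concat(class_rows, ignore_index=True) if class_rows else pd.DataFrame()
    bundle["paired_frequencies"] = pd.concat(pair_rows, ignore_index=True) if pair_rows else pd.DataFrame()
    _write_table(bundle["top_n_curves"], os.path.join(out, "top_n_curves.tsv"), "spatial", cfg)
    _write_table(bundle["sharing_classes"], os.path.join(out, "sharing_classes.tsv"), "spatial", cfg)
    _write_table(bundle["paired_frequencies"], os.path.join(out, "paired_frequencies.tsv"), "spatial", cfg)

    seen = set()
    conv_unique = [r for r in conv_inputs if not (r.sample_id in seen or seen.add(r.sample_id))]
    same_visit = [r for r in conv_unique if r.visit == min((x.visit for x in conv_unique), default=0)]
    bundle["convergence"] = convergence_report(same_visit, model, cfg.freq_mode, cfg.scale)
    _write_table(bundle["convergence"], os.path.join(out, "convergence.tsv"), "spatial", cfg)
    _log_stage("spatial", len(reps), cfg.seed, t0)
    return bundle


def run_temporal(reps: Sequence[Repertoire], cfg: RunConfig, model: RecombinationModel | None = None) -> dict:
    """Persistence over visits: Jaccard matrices, Venn counts, paired tables, convergence."""
    t0 = time.time()
    model = model or default_model()
    reps = _collapsed(reps)
    out = os.path.join(cfg.outdir, "temporal")
    bundle: dict = {}
    subsets = sorted({r.subset for r in reps})
    patients = sorted({r.patient for r in reps})

    jac_rows = []
    for subset in subsets:
        members = sorted(_by(reps, subset=subset), key=lambda r: r.sample_id)
        if len(members) >= 2:
            mat = overlap.jaccard_matrix(members)
            frame = mat.to_frame().reset_index(names="sample_id")
            frame.insert(0, "subset", subset)
            jac_rows.append(frame)
    bundle["jaccard"] = pd.concat(jac_rows, ignore_index=True) if jac_rows else pd.DataFrame()
    _write_table(bundle["jaccard"], os.path.join(out, "jaccard_matrix.tsv"), "temporal", cfg)

    venn_rows, pair_rows = [], []
    conv_pairs: list[Repertoire] = []
    sharing_metric_rows = []
    for subset in subsets:
        for patient in patients:
            for compartment in sorted({r.compartment for r in reps}):
                series = sorted(_by(reps, patient=patient, subset=subset, compartment=compartment), key=lambda r: r.visit)
                if len(series) < 2:
                    if series:
                        logger.info("temporal: single visit for %s/%s/%s; excluded", patient, subset, compartment)
                    continue
                regions = overlap.venn_counts(series[: 4], top_n=cfg.venn_top_n)
                for region, count in sorted(regions.items()):
                    venn_rows.append(
                        {"patient": patient, "subset": subset, "compartment": compartment,
                         "region": "&".join(region), "count": count}
                    )
                for ra, rb in zip(series, series[1:]):
                    pair = overlap.paired_frequency_table(ra, rb)
                    pair.insert(0, "sample_b", rb.sample_id)
                    pair.insert(0, "sample_a", ra.sample_id)
                    pair.insert(0, "subset", subset)
                    pair.insert(0, "patient", patient)
                    pair_rows.append(pair)
                    jac = overlap.jaccard_index(ra.junction_set(), rb.junction_set())
                    sharing_metric_rows.append(
                        {"subset": subset, "patient": patient, "compartment": compartment,
                         "visit_a": ra.visit, "visit_b": rb.visit, "jaccard": jac}
                    )
                conv_pairs.extend(series)
    bundle["venn_counts"] = pd.DataFrame(venn_rows)
    bundle["persistence_pairs"] = pd.concat(pair_rows, ignore_index=True) if pair_rows else pd.DataFrame()
    bundle["visit_sharing"] = pd.DataFrame(sharing_metric_rows)
    _write_table(bundle["venn_counts"], os.path.join(out, "venn_top100.tsv"), "temporal", cfg)
    _write_table(bundle["persistence_pairs"], os.path.join(out, "persistence_pairs.tsv"), "temporal", cfg)
    _write_table(bundle["visit_sharing"], os.path.join(out, "visit_sharing.tsv"), "temporal", cfg)

    seen = set()
    conv_unique = [r for r in conv_pairs if not (r.sample_id in seen or seen.add(r.sample_id))]
    bundle["convergence"] = convergence_report(conv_unique, model, cfg.freq_mode, cfg.scale)
    _write_table(bundle["convergence"], os.path.join(out, "convergence.tsv"), "temporal", cfg)
    _log_stage("temporal", len(reps), cfg.seed, t0)
    return bundle


def run_network(reps: Sequence[Repertoire], cfg: RunConfig, model: RecombinationModel | None = None) -> dict:
    """Per-patient left/right similarity networks with random-repertoire benchmark."""
    t0 = time.time()
    model = model or default_model()
    reps = _collapsed(reps)
    out = os.path.join(cfg.outdir, "network")
    os.makedirs(out, exist_ok=True)
    ncfg = cfg.network
    bundle: dict = {}
    stats_rows, comparison_rows, test_rows = [], [], []
    for patient in sorted({r.patient for r in reps}):
        group = _by(reps, patient=patient, subset=ncfg.subset, visit=ncfg.visit)
        comps = {r.compartment: r for r in group}
        if "SF_LEFT" not in comps or "SF_RIGHT" not in comps:
            logger.warning("network: %s lacks SF left/right at subset=%s visit=%d; skipped",
                           patient, ncfg.subset, ncfg.visit)
            continue
        left, right = comps["SF_LEFT"], comps["SF_RIGHT"]
        pairs = [(c.junction_aa, LABEL_LEFT) for c in left.clonotypes if c.productive]
        pairs += [(c.junction_aa, LABEL_RIGHT) for c in right.clonotypes if c.productive]
        net_cfg = NetworkConfig(
            k=ncfg.k, tau=ncfg.tau, n_random=ncfg.n_random, top_c=ncfg.top_c,
            seed=stage_seed(cfg.seed, f"network:{patient}"),
            trim_anchors=ncfg.trim_anchors, purity_mode=ncfg.purity_mode,
        )
        weights = {**left.junction_counts(), **right.junction_counts()}
        net = build_network(pairs, net_cfg, weights=weights)
        stats = cluster_statistics(net, net_cfg.top_c, net_cfg.purity_mode)
        sizes = (len(left.junction_set(productive_only=True)), len(right.junction_set(productive_only=True)))
        comparison = compare_to_random(stats, model, sizes, net_cfg)
        _write_table(network_to_edge_frame(net), os.path.join(out, f"{patient}_edges.tsv"), "network", cfg)
        write_graphml(net, os.path.join(out, f"{patient}_network.graphml"))
        for st in stats:
            stats_rows.append({"patient": patient, "cluster_id": st.cluster_id, "n_sequences": st.n_sequences,
                               "n_connections": st.n_connections, "purity": st.purity, "top_label": st.top_label})
        rnd = comparison.random_stats.copy()
        rnd.insert(0, "patient", patient)
        comparison_rows.append(rnd)
        test_rows.append({"patient": patient, "u_statistic": comparison.purity_test.statistic,
                          "p_value": comparison.purity_test.p_value,
                          "n_patient": comparison.purity_test.n[0], "n_random": comparison.purity_test.n[1],
                          "flag": comparison.flag or ""})
        bundle[patient] = {"network": net, "stats": stats, "comparison": comparison}
    frames = {
        "cluster_stats": pd.DataFrame(stats_rows),
        "random_cluster_stats": pd.concat(comparison_rows, ignore_index=True) if comparison_rows else pd.DataFrame(),
        "purity_tests": pd.DataFrame(test_rows),
    }
    for name, frame in frames.items():
        _write_table(frame, os.path.join(out, f"{name}.tsv"), "network", cfg)
    bundle.update(frames)
    _log_stage("network", len(bundle), cfg.seed, t0)
    return bundle


def run_diversity(reps: Sequence[Repertoire], cfg: RunConfig) -> dict:
    """Rarefaction/extrapolation curves per sample plus Treg vs non-Treg contrast."""
    t0 = time.time()
    reps = _collapsed(reps)
    out = os.path.join(cfg.outdir, "diversity")
    vectors = {r.sample_id: AbundanceVector.from_repertoire(r) for r in reps}
    common_m = min(v.n for v in vectors.values())
    rows = []
    curves_q0, curves_q1 = {}, {}
    for rep in reps:
        av = vectors[rep.sample_id]
        grid = sorted(set(default_m_grid(av.n)) | {common_m})
        c0 = rarefy_richness(av, grid)
        c1 = rarefy_shannon(av, grid, b_reps=cfg.shannon_reps,
                            seed=stage_seed(cfg.seed, f"diversity:{rep.sample_id}"))
        curves_q0[rep.sample_id] = c0
        curves_q1[rep.sample_id] = c1
        for curve in (c0, c1):
            for m, est, regime in zip(curve.m_grid, curve.estimates, curve.regimes):
                rows.append({"sample_id": rep.sample_id, "subset": rep.subset, "q": curve.q,
                             "m": m, "regime": regime, "estimate": est})
    table = pd.DataFrame(rows)
    _write_table(table, os.path.join(out, "curves.tsv"), "diversity", cfg)

    comp_rows = []
    treg = [r.sample_id for r in reps if r.subset == "TREG"]
    non = [r.sample_id for r in reps if r.subset == "NON_TREG"]
    if treg and non:
        for q, curves in ((0, curves_q0), (1, curves_q1)):
            comp = compare_group_diversity([curves[s] for s in treg], [curves[s] for s in non], common_m)
            comp_rows.append({"q": q, "at_m": comp.at_m, "u_statistic": comp.test.statistic,
                              "p_value": comp.test.p_value, "median_treg": comp.median_a,
                              "median_non_treg": comp.median_b, "flag": comp.flag or comp.test.flag or ""})
    comparison = pd.DataFrame(comp_rows)
    _write_table(comparison, os.path.join(out, "group_comparison.tsv"), "diversity", cfg)
    _log_stage("diversity", len(reps), cfg.seed, t0)
    return {"curves": table, "comparison": comparison, "q0": curves_q0, "q1": curves_q1}


def run_all(cfg: RunConfig, model: RecombinationModel | None = None) -> dict:
    model = model or default_model()
    reps, truth = run_simulate(cfg, model)
    return {
        "reps": reps,
        "truth": truth,
        "spatial": run_spatial(reps, cfg, model),
        "temporal": run_temporal(reps, cfg, model),
        "network": run_network(reps, cfg, model),
        "diversity": run_diversity(reps, cfg),
    }
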