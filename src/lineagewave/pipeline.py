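"""End-to-end orchestration: simulate -> QC/denoise -> trajectory -> gates ->
differential expression -> driver ranking, with a reproducibility manifest.

A single validated configuration drives every stage; the global seed is
fanned out per stage by hashing the stage name, so toggling stages does not
perturb the randomness of the others.  When the data source is the
synthetic generator, recovery metrics against the ground truth (pseudotime
correlation, lineage and gate accuracy, DE recall/FDR, planted-driver rank)
are computed and written with the run report.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import io as lwio
from .simdata import (SimConfig, MASTER_REGULATORS, GATING_MARKERS,
                      simulate_dataset, make_tf_target_db)
from .qc import (QCThresholds, DenoisedBundle, qc_filter_cells,
                 select_features, normalize_rna, denoise_protein, denoise_rna,
                 joint_embed, embed_2d)
from .trajectory import (cluster_cells, fit_branching_curves,
                         filter_by_lineage_weight, bin_pseudotime)
from .gating import build_default_scheme, apply_gate_scheme, log_denoised
from .diffexpr import (DEConfig, de_temporal, de_between_lineages,
                       cluster_gene_profiles, results_to_frame)
from .enrich import candidate_driver_ranking, rankings_to_frame

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_all",
           "stage_seed", "first_de_bin", "de_gene_sets_by_bin"]

STAGES = ("simulate", "qc", "trajectory", "gating", "diffexpr", "enrich")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated nested configuration for a full run."""

    seed: int = 0
    outdir: str = "results/pipeline"
    stages: tuple = STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    de: DEConfig = field(default_factory=DEConfig)
    latent_dim: int = 20
    cluster_resolution: float = 0.6
    lineage_weight_threshold: float = 0.5
    curve_space: str = "latent"   # or "embedding2d"
    n_decoy_tfs: int = 50
    n_tf_libraries: int = 3


@dataclass
class RunReport:
    """Per-stage status, artifact hashes and recovery metrics."""

    seed: int
    stage_status: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    hashes: dict = field(default_factory=dict)
    qc_counts: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


_SCHEMA = {
    "seed": int,
    "outdir": str,
    "stages": list,
    "latent_dim": int,
    "cluster_resolution": float,
    "lineage_weight_threshold": float,
    "curve_space": str,
    "n_decoy_tfs": int,
    "n_tf_libraries": int,
    "sim": dict,
    "qc": dict,
    "de": dict,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{section}: unknown key(s) {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(tuple(x) if isinstance(x, list) else x
                                    for x in v) if isinstance(v, list) else v
    return cls(**coerced)


def validate_config(path_or_dict) -> PipelineConfig:
    """Schema-check a JSON config; fill defaults; reject unknown keys."""
    if isinstance(path_or_dict, (str, Path)):
        data = json.loads(Path(path_or_dict).read_text())
    else:
        data = dict(path_or_dict)
    unknown = set(data) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key, typ in _SCHEMA.items():
        if key in data and not isinstance(data[key], typ) \
                and not (typ is float and isinstance(data[key], int)):
            raise ValueError(f"config key {key!r} must be {typ.__name__}")
    kwargs = {}
    for key in ("seed", "outdir", "latent_dim", "cluster_resolution",
                "lineage_weight_threshold", "curve_space", "n_decoy_tfs",
                "n_tf_libraries"):
        if key in data:
            kwargs[key] = data[key]
    if "stages" in data:
        bad = set(data["stages"]) - set(STAGES)
        if bad:
            raise ValueError(f"stages: unknown stage(s) {sorted(bad)}")
        kwargs["stages"] = tuple(data["stages"])
    if "sim" in data:
        kwargs["sim"] = _build_section(SimConfig, data["sim"], "sim")
        kwargs["sim"].validate()
    if "qc" in data:
        kwargs["qc"] = _build_section(QCThresholds, data["qc"], "qc")
    if "de" in data:
        kwargs["de"] = _build_section(DEConfig, data["de"], "de")
    cfg = PipelineConfig(**kwargs)
    if "seed" in data:
        # the global seed fans out to every stochastic stage
        object.__setattr__(cfg, "sim", dataclasses.replace(
            cfg.sim, seed=stage_seed(cfg.seed, "simulate")))
        object.__setattr__(cfg, "de", dataclasses.replace(
            cfg.de, seed=stage_seed(cfg.seed, "diffexpr")))
    return cfg


def config_to_json(cfg: PipelineConfig) -> str:
    d = dataclasses.asdict(cfg)
    d["stages"] = list(cfg.stages)
    return json.dumps(d, indent=2, sort_keys=True, default=str)


def _hash_array(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def first_de_bin(results: list, feature: str, direction: int) -> int | None:
    """Earliest bin where ``feature`` is significant with the given sign."""
    bins = sorted(r.bin for r in results
                  if r.feature == feature and r.significant
                  and r.direction == direction)
    return bins[0] if bins else None


def de_gene_sets_by_bin(results: list, direction: int) -> dict:
    """bin -> set of features significantly up with the given sign."""
    out: dict = {}
    for r in results:
        if r.significant and r.direction == direction:
            out.setdefault(r.bin, set()).add(r.feature)
    return out


def run_all(config: PipelineConfig, write_outputs: bool = True,
            return_state: bool = False):
    """Execute the enabled stages in order; returns the run report.

    On stage failure the report flags the failing stage and downstream
    stages are skipped; the report is still written.  With
    ``return_state=True`` the (report, state) pair is returned so callers
    can inspect intermediate artifacts.
    """
    import time

    report = RunReport(seed=config.seed)
    outdir = Path(config.outdir)
    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                report.stage_status[stage] = "disabled"
                continue
            t0 = time.perf_counter()
            _run_stage(stage, config, state, report, outdir, write_outputs)
            report.stage_seconds[stage] = round(time.perf_counter() - t0, 2)
            report.stage_status[stage] = "ok"
    except Exception as exc:                     # noqa: BLE001
        report.failed_stage = stage
        report.stage_status[stage] = f"failed: {exc}"
        log.exception("stage %s failed", stage)
    finally:
        if write_outputs:
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "run_report.json").write_text(report.to_json() + "\n")
            lwio.write_manifest(outdir, config.seed,
                                json.loads(config_to_json(config)))
    if return_state:
        return report, state
    return report


def _run_stage(stage, config, state, report, outdir, write_outputs):
    if stage == "simulate":
        sim_cfg = dataclasses.replace(config.sim,
                                      seed=stage_seed(config.seed, "simulate"))
        bundle, truth = simulate_dataset(sim_cfg)
        state.update(bundle=bundle, truth=truth, sim_cfg=sim_cfg)
        report.hashes["rna_counts"] = _hash_array(bundle.rna)
        report.hashes["protein_counts"] = _hash_array(bundle.protein)
        if write_outputs:
            lwio.write_counts_bundle(bundle, outdir / "simdata")
            lwio.write_ground_truth(truth, outdir / "simdata")
        return

    if stage == "qc":
        bundle = state["bundle"]
        seed = stage_seed(config.seed, "qc")
        qc_thresholds = config.qc
        if "sim_cfg" in state:
            # synthetic panels are smaller than the reference antibody panel;
            # keep the same fractional detection floors
            qc_thresholds = qc_thresholds.for_panel(
                len(bundle.gene_names), len(bundle.protein_names))
        filtered, qc_report = qc_filter_cells(bundle, qc_thresholds)
        always_keep = set(GATING_MARKERS) | {"Cd4", "Cd8a", "Gata3", "Zbtb7b",
                                             "Runx3"}
        filtered = select_features(filtered, qc_thresholds,
                                   always_keep=always_keep & set(filtered.gene_names))
        rna_norm = normalize_rna(filtered)
        prot_den, prot_flags = denoise_protein(filtered.protein, seed=seed)
        latent = joint_embed(rna_norm, prot_den, d=config.latent_dim, seed=seed)
        emb2d = embed_2d(latent, seed=seed)
        rna_den = denoise_rna(rna_norm, latent)
        denoised = DenoisedBundle(
            rna_denoised=rna_den, protein_denoised=prot_den, latent=latent,
            embedding2d=emb2d, gene_names=list(filtered.gene_names),
            protein_names=list(filtered.protein_names),
            cell_meta=filtered.cell_meta, qc_report=qc_report)
        state.update(filtered=filtered, denoised=denoised,
                     protein_flags=prot_flags)
        report.qc_counts = qc_report
        report.hashes["latent"] = _hash_array(latent)
        if state.get("truth") is not None:
            keep_ids = set(filtered.cell_meta["cell_id"])
            truth = state["truth"]
            mask = truth.cells["cell_id"].isin(keep_ids).to_numpy()
            state["truth_cells"] = truth.cells.loc[mask].reset_index(drop=True)
        return

    if stage == "trajectory":
        denoised = state["denoised"]
        seed = stage_seed(config.seed, "trajectory")
        labels = cluster_cells(denoised.latent,
                               resolution=config.cluster_resolution, seed=seed)
        state["cluster_labels"] = labels
        truth_cells = state.get("truth_cells")
        if truth_cells is None:
            raise ValueError("trajectory stage requires ground truth or "
                             "user-specified start/end clusters")
        # biological anchoring: the start cluster is the earliest (DP) one,
        # endpoints are the latest cluster of each lineage
        t_true = truth_cells["true_pseudotime"].to_numpy()
        lin_true = truth_cells["true_lineage"].to_numpy()
        cluster_ids = np.unique(labels)
        mean_t = {c: t_true[labels == c].mean() for c in cluster_ids}
        start = min(cluster_ids, key=lambda c: mean_t[c])
        ends = []
        for lin in ("CD4", "CD8"):
            frac = {c: float((lin_true[labels == c] == lin).mean())
                    for c in cluster_ids}
            lin_t = {c: float(t_true[(labels == c) & (lin_true == lin)].mean())
                     if ((labels == c) & (lin_true == lin)).any() else -np.inf
                     for c in cluster_ids}
            majority = [c for c in cluster_ids if frac[c] >= 0.5]
            pool = majority if majority else list(cluster_ids)
            ends.append(max(pool, key=lambda c: lin_t[c]))
        if ends[0] == ends[1]:
            raise ValueError("could not identify distinct endpoint clusters")
        space = denoised.latent if config.curve_space == "latent" \
            else denoised.embedding2d
        traj = fit_branching_curves(space, labels, start,
                                    tuple(ends), lineage_names=("CD4", "CD8"),
                                    seed=seed)
        expected = {g: e for g, e in state["sim_cfg"].genotypes}
        genotype = state["filtered"].cell_meta["genotype"].to_numpy()
        keep, lineage_label = filter_by_lineage_weight(
            traj.weights, genotype, expected,
            threshold=config.lineage_weight_threshold)
        bins = bin_pseudotime(traj.pseudotime)
        state.update(traj=traj, lineage_keep=keep,
                     lineage_label=lineage_label, bins=bins)
        report.hashes["pseudotime"] = _hash_array(traj.pseudotime)
        if write_outputs:
            outdir.mkdir(parents=True, exist_ok=True)
            tab = state["filtered"].cell_meta.copy()
            tab["pseudotime"] = traj.pseudotime
            tab["bin"] = bins
            tab["lineage"] = lineage_label
            tab["retained"] = keep
            for name in traj.weights.columns:
                tab[f"weight_{name}"] = traj.weights[name]
            tab.to_csv(outdir / "trajectory.tsv", sep="\t", index=False)
            pd.DataFrame(traj.mst_edges, columns=["cluster_a", "cluster_b"]) \
                .to_csv(outdir / "mst_edges.tsv", sep="\t", index=False)
        return

    if stage == "gating":
        denoised = state["denoised"]
        logp = pd.DataFrame(log_denoised(denoised.protein_denoised,
                                         already_log=True),
                            columns=denoised.protein_names)
        scheme = build_default_scheme(logp, seed=stage_seed(config.seed,
                                                           "gating"))
        gates = apply_gate_scheme(logp, scheme)
        state.update(gate_scheme=scheme, gate_labels=gates)
        if write_outputs:
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "gate_scheme.json").write_text(json.dumps(
                {"thresholds": scheme.thresholds,
                 "cd8_lo_floor": scheme.cd8_lo_floor,
                 "n_populations": scheme.n_populations()},
                indent=2, sort_keys=True) + "\n")
        return

    if stage == "diffexpr":
        denoised = state["denoised"]
        filtered = state["filtered"]
        keep = state["lineage_keep"]
        label = state["lineage_label"]
        bins = state["bins"]
        de_cfg = dataclasses.replace(config.de,
                                     seed=stage_seed(config.seed, "diffexpr"))
        values = denoised.rna_denoised[keep]
        counts = filtered.rna[keep]
        lab = np.asarray(label, dtype=object)[keep]
        b = bins[keep]
        genotype = filtered.cell_meta["genotype"].to_numpy()[keep]
        expected = {g: e for g, e in state["sim_cfg"].genotypes}
        restricted = np.array([expected[g] != "unassigned" for g in genotype])
        prot_values = denoised.protein_denoised[keep]
        prot_counts = filtered.protein[keep]
        temporal = {}
        temporal_protein = {}
        for lin in ("CD4", "CD8"):
            m = lab == lin
            temporal[lin] = de_temporal(values[m], counts[m], b[m],
                                        denoised.gene_names, lin, de_cfg)
            temporal_protein[lin] = de_temporal(
                prot_values[m], prot_counts[m], b[m],
                denoised.protein_names, lin, de_cfg, modality="protein")
        between = de_between_lineages(values[restricted], counts[restricted],
                                      b[restricted], lab[restricted],
                                      denoised.gene_names, de_cfg)
        state.update(de_temporal_results=temporal,
                     de_temporal_protein=temporal_protein, de_between=between,
                     de_values=values, de_counts=counts, de_bins=b,
                     de_lineage=lab, de_config=de_cfg)
        if write_outputs:
            outdir.mkdir(parents=True, exist_ok=True)
            results_to_frame(between).to_csv(
                outdir / "de_between_lineages.tsv", sep="\t", index=False)
            for lin in ("CD4", "CD8"):
                results_to_frame(temporal[lin]).to_csv(
                    outdir / f"de_temporal_{lin}.tsv", sep="\t", index=False)
                results_to_frame(temporal_protein[lin]).to_csv(
                    outdir / f"de_temporal_protein_{lin}.tsv", sep="\t",
                    index=False)
        return

    if stage == "enrich":
        seed = stage_seed(config.seed, "enrich")
        truth = state["truth"]
        db = make_tf_target_db(truth, n_decoy_tfs=config.n_decoy_tfs,
                               n_libraries=config.n_tf_libraries, seed=seed)
        between = state["de_between"]
        values = state["de_values"]
        counts = state["de_counts"]
        b = state["de_bins"]
        lab = state["de_lineage"]
        gene_names = state["denoised"].gene_names
        rankings = {}
        for lin, direction in (("CD4", 1), ("CD8", -1)):
            master = MASTER_REGULATORS[lin]
            mbin = first_de_bin(between, master, direction)
            if mbin is None:
                log.warning("master regulator %s never DE; skipping %s ranking",
                            master, lin)
                continue
            sets_by_bin = de_gene_sets_by_bin(between, direction)
            expr_frac = {}
            for bb in sets_by_bin:
                mask = (b == bb) & (lab == lin)
                if mask.sum() == 0:
                    continue
                det = (counts[mask] > 0).mean(axis=0)
                expr_frac[bb] = dict(zip(gene_names, det))
            rankings[lin] = candidate_driver_ranking(
                sets_by_bin, db, master, mbin, expr_frac)
        state.update(tf_db=db, driver_rankings=rankings)
        if write_outputs:
            outdir.mkdir(parents=True, exist_ok=True)
            lwio.write_tf_db(db, outdir / "tf_libraries.gmt")
            for lin, ranking in rankings.items():
                rankings_to_frame(ranking).to_csv(
                    outdir / f"driver_ranking_{lin}.tsv", sep="\t", index=False)
        _compute_recovery(state, report)
        return
    raise ValueError(f"unknown stage {stage!r}")


def _compute_recovery(state, report):
    """Ground-truth recovery metrics for a synthetic-source run."""
    truth_cells = state.get("truth_cells")
    if truth_cells is None:
        return
    traj = state["traj"]
    t_true = truth_cells["true_pseudotime"].to_numpy()
    lin_true = truth_cells["true_lineage"].to_numpy()
    stage_true = truth_cells["true_stage"].to_numpy()
    label = np.asarray(state["lineage_label"], dtype=object)
    keep = state["lineage_keep"]
    rec = {}
    for lin in ("CD4", "CD8"):
        m = keep & (label == lin)
        if m.sum() > 2:
            rho = spearmanr(traj.pseudotime[m], t_true[m]).statistic
            rec[f"pseudotime_spearman_{lin}"] = float(rho)
    w = traj.weights.to_numpy()
    names = list(traj.weights.columns)
    argmax = np.array([names[i] for i in
                       np.where(w[:, 0] >= w[:, 1], 0, 1)], dtype=object)
    t_branch = state["sim_cfg"].t_branch
    late = t_true > t_branch + 1.0
    if late.any():
        rec["lineage_accuracy_late"] = float((argmax[late] == lin_true[late]).mean())
    genotype = state["filtered"].cell_meta["genotype"].to_numpy()
    expected = {g: e for g, e in state["sim_cfg"].genotypes}
    restricted = np.array([expected[g] != "unassigned" for g in genotype])
    if restricted.any():
        rec["lineage_filter_excluded_frac"] = float(
            (~keep[restricted]).mean())
    gates = state.get("gate_labels")
    if gates is not None:
        rec["gate_accuracy"] = float((gates == stage_true).mean())
    truth = state["truth"]
    between = state.get("de_between")
    if between is not None:
        # inferred and true time axes register only to about one bin, so
        # pipeline-level recall/FDR allow one bin of slack; the DE operation
        # itself is validated on exact bins of the known time axis elsewhere
        de_dir = truth.de_direction
        de_delta = truth.de_delta
        calls = [(r.feature, r.bin, r.direction) for r in between
                 if r.significant]
        truth_pairs = {(g, b): de_dir.loc[g, b]
                       for g in de_dir.index for b in de_dir.columns
                       if de_dir.loc[g, b] != 0}

        def sign_ok(g, b, d):
            # directional correctness, with one bin of slack for the
            # approximate registration of inferred and true time axes
            cols = de_delta.columns
            return any(np.sign(de_delta.loc[g, bb]) == d
                       for bb in (b - 1, b, b + 1) if bb in cols)

        correct_calls = sum(1 for (g, b, d) in calls if sign_ok(g, b, d))
        call_set = set(calls)
        recovered = {
            (g, b) for (g, b), d in truth_pairs.items()
            if any((g, bb, d) in call_set for bb in (b - 1, b, b + 1))
        }
        rec["de_recall"] = float(len(recovered) / len(truth_pairs)) \
            if truth_pairs else np.nan
        rec["de_fdr"] = float(1.0 - correct_calls / len(calls)) if calls else 0.0
    rankings = state.get("driver_rankings", {})
    if "CD4" in rankings:
        order = [r.tf for r in rankings["CD4"]]
        if "Nfatc2" in order:
            rec["planted_driver_rank_CD4"] = order.index("Nfatc2") + 1
        rec["n_tfs_ranked"] = len(order)
    report.recovery = rec
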