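"""Gene-set enrichment and candidate-driver transcription-factor ranking.

Hypergeometric upper-tail tests with Benjamini-Hochberg correction for gene
clusters (e.g. TCR-target enrichment), per-library TF ranking by overlap
p-value with MeanRank integration across libraries, and the aggregation of
per-bin MeanRanks across the pseudotime window immediately preceding
master-regulator differential expression, with the workflow's exclusion
rules (the master-regulator bin never contributes; bins where a TF is
detected in under 5% of the population of interest never contribute).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simdata import TFTargetDB

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "TFRanking",
    "hypergeom_upper_p",
    "bh_adjust",
    "tcr_enrichment",
    "rank_tfs",
    "candidate_driver_ranking",
]


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of one gene set against a pathway."""

    set_id: str
    k: int          # pathway genes in the set
    K: int          # pathway genes in the background
    n: int          # set size
    N: int          # background size
    p: float
    p_adjusted: float = np.nan
    enriched: bool = False


@dataclass
class TFRanking:
    """Per-bin enrichment ranks of one TF and their aggregate score."""

    tf: str
    per_library_rank: dict        # (library, bin) -> rank
    mean_rank_per_bin: dict       # bin -> MeanRank across libraries
    contributing_bins: list
    overall_score: float          # mean of contributing per-bin MeanRanks
    expressed_fraction: dict = field(default_factory=dict)   # bin -> fraction
    is_de: bool = False
    targets_master_regulator: bool = False
    tcr_pathway: bool = False
    visualization_only_bin: int | None = None


def hypergeom_upper_p(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), stable in log space.

    N: background size, K: pathway genes in the background, n: query set
    size, k: observed overlap.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"inconsistent hypergeometric arguments "
                         f"k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    # P(X >= k) = sf(k - 1); scipy computes the tail stably
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tcr_enrichment(cluster_sets: dict, pathway_genes, background) -> list:
    """Hypergeometric test of each gene cluster against a pathway gene set.

    ``cluster_sets`` maps cluster id -> gene collection; the background must
    contain every cluster gene (it is the universe of DE-tested genes).
    Enriched means BH-adjusted p < 0.05.
    """
    pathway_genes = set(pathway_genes)
    background = set(background)
    if not pathway_genes:
        raise ValueError("empty pathway gene set")
    for cid, genes in cluster_sets.items():
        missing = set(genes) - background
        if missing:
            raise ValueError(
                f"cluster {cid} contains genes outside the background: "
                f"{sorted(missing)[:5]}")
    K = len(pathway_genes & background)
    N = len(background)
    results = []
    for cid in sorted(cluster_sets, key=str):
        genes = set(cluster_sets[cid])
        k = len(genes & pathway_genes)
        n = len(genes)
        p = hypergeom_upper_p(k, K, n, N)
        results.append(EnrichmentResult(set_id=str(cid), k=k, K=K, n=n, N=N, p=p))
    adj = bh_adjust(np.array([r.p for r in results]))
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
        r.enriched = bool(a < 0.05)
    return results


def rank_tfs(query_genes, db: TFTargetDB, universe=None) -> pd.DataFrame:
    """Per-library hypergeometric ranks and the MeanRank integration.

    Within each library, TFs are ranked ascending by the upper-tail p of the
    overlap between their target set and the query (ties get average ranks);
    MeanRank is the mean of a TF's ranks over the libraries containing it.
    Returns a frame with columns tf, mean_rank and rank_<library>.
    """
    query = set(query_genes)
    universe = set(universe) if universe is not None else set(db.universe)
    if not query <= universe:
        raise ValueError("query gene set must be a subset of the universe")
    n = len(query & universe)
    N = len(universe)
    per_lib_ranks = {}
    for lib_name, lib in db.libraries.items():
        tfs = sorted(lib)
        pvals = []
        for tf in tfs:
            targets = set(lib[tf]) & universe
            K = len(targets)
            k = len(targets & query)
            pvals.append(hypergeom_upper_p(k, K, n, N))
        ranks = stats.rankdata(pvals, method="average")
        per_lib_ranks[lib_name] = dict(zip(tfs, ranks))
    all_tfs = sorted({tf for lib in per_lib_ranks.values() for tf in lib})
    rows = []
    for tf in all_tfs:
        ranks = [per_lib_ranks[ln][tf] for ln in per_lib_ranks
                 if tf in per_lib_ranks[ln]]
        row = {"tf": tf, "mean_rank": float(np.mean(ranks))}
        for ln in per_lib_ranks:
            row[f"rank_{ln}"] = per_lib_ranks[ln].get(tf, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def candidate_driver_ranking(de_gene_sets_by_bin: dict, db: TFTargetDB,
                             master_regulator: str, master_first_de_bin: int,
                             expressed_fraction_by_bin: dict,
                             de_genes_by_bin: dict | None = None,
                             tcr_pathway_genes=frozenset(),
                             n_prior_bins: int = 3,
                             detection_min: float = 0.05) -> list:
    """Aggregate per-bin TF MeanRanks into an overall driver ranking.

    The relevant bins are the ``n_prior_bins`` immediately preceding the
    master regulator's first differential-expression bin; the master-
    regulator bin itself is scored for visualization only and never
    contributes.  A bin where a TF is detected in under ``detection_min`` of
    the population of interest is dropped from that TF's mean.  Returns
    TFRanking objects sorted ascending by overall score (lower = stronger).

    Parameters
    ----------
    de_gene_sets_by_bin : bin -> lineage-specific upregulated gene set.
    expressed_fraction_by_bin : bin -> {gene name -> detection fraction}.
    de_genes_by_bin : optional bin -> genes significantly up in the lineage,
        used for the "is DE" annotation (defaults to de_gene_sets_by_bin).
    """
    if master_first_de_bin is None:
        raise ValueError("master regulator is never differentially expressed")
    relevant = [b for b in range(master_first_de_bin - n_prior_bins,
                                 master_first_de_bin)
                if b in de_gene_sets_by_bin]
    if len(relevant) < n_prior_bins:
        log.warning("only %d of %d requested prior bins available",
                    len(relevant), n_prior_bins)
    if not relevant:
        raise ValueError("no usable bins precede master-regulator DE")
    de_genes_by_bin = de_genes_by_bin or de_gene_sets_by_bin

    scored_bins = list(relevant)
    viz_bin = master_first_de_bin if master_first_de_bin in de_gene_sets_by_bin \
        else None
    all_bins = scored_bins + ([viz_bin] if viz_bin is not None else [])

    rank_frames = {b: rank_tfs(de_gene_sets_by_bin[b], db) for b in all_bins}
    tf_names = db.tf_names()
    mr_targets = {tf: any(master_regulator in lib.get(tf, frozenset())
                          for lib in db.libraries.values())
                  for tf in tf_names}
    tcr_pathway_genes = set(tcr_pathway_genes)

    rankings = []
    for tf in tf_names:
        per_lib = {}
        mean_rank_per_bin = {}
        expressed = {}
        for b in all_bins:
            frame = rank_frames[b]
            row = frame.loc[frame["tf"] == tf]
            if row.empty:
                continue
            mean_rank_per_bin[b] = float(row["mean_rank"].iloc[0])
            for col in row.columns:
                if col.startswith("rank_"):
                    per_lib[(col[len("rank_"):], b)] = float(row[col].iloc[0])
            expressed[b] = float(expressed_fraction_by_bin.get(b, {})
                                 .get(tf, 1.0))
        contributing = [b for b in scored_bins
                        if b in mean_rank_per_bin
                        and expressed.get(b, 1.0) >= detection_min]
        score = float(np.mean([mean_rank_per_bin[b] for b in contributing])) \
            if contributing else np.inf
        is_de = any(tf in de_genes_by_bin.get(b, ()) for b in scored_bins)
        rankings.append(TFRanking(
            tf=tf,
            per_library_rank=per_lib,
            mean_rank_per_bin=mean_rank_per_bin,
            contributing_bins=contributing,
            overall_score=score,
            expressed_fraction=expressed,
            is_de=is_de,
            targets_master_regulator=mr_targets[tf],
            tcr_pathway=tf in tcr_pathway_genes,
            visualization_only_bin=viz_bin,
        ))
    rankings.sort(key=lambda r: (r.overall_score, r.tf))
    return rankings


def rankings_to_frame(rankings: list) -> pd.DataFrame:
    rows = []
    for r in rankings:
        rows.append({
            "tf": r.tf,
            "overall_score": r.overall_score,
            "contributing_bins": ",".join(map(str, r.contributing_bins)),
            "is_de": r.is_de,
            "targets_master_regulator": r.targets_master_regulator,
            "tcr_pathway": r.tcr_pathway,
            **{f"mean_rank_bin{b}": v for b, v in r.mean_rank_per_bin.items()},
        })
    return pd.DataFrame(rows)
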