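"""In silico flow cytometry on log-denoised surface proteins.

Density-valley threshold suggestion per marker, the eight-population gate
scheme over CD4 / CD8a / TCRb / CD69 / CD127 (DP1, DP2, CD4+CD8lo, DP3,
semimature and mature CD4 and CD8 single positives), Youden-index alignment
of gated populations to pseudotime, and a condition-versus-reference
cluster-proportion log fold enrichment statistic for perturbation panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from scipy.signal import argrelextrema

log = logging.getLogger(__name__)

__all__ = [
    "GateScheme",
    "GateTimeline",
    "NoValleyError",
    "log_denoised",
    "suggest_threshold_density",
    "build_default_scheme",
    "apply_gate_scheme",
    "align_gates_to_pseudotime",
    "proportion_log_enrichment",
    "GATE_LABELS",
]

GATE_LABELS = (
    "DP1", "DP2", "CD4+CD8lo", "DP3",
    "CD4 SM", "CD4 Mature", "CD8 SM", "CD8 Mature",
)


class NoValleyError(ValueError):
    """Raised when a marker distribution has no density valley to gate on."""

    def __init__(self, mode=None):
        self.mode = mode
        msg = "no valley: distribution is unimodal"
        if mode is not None:
            msg += f" (single mode at {mode:.3g})"
        super().__init__(msg)


@dataclass
class GateScheme:
    """Marker thresholds plus the decision table resolving eight populations.

    ``thresholds`` maps each of the five markers to its positivity cutoff on
    the log-denoised scale; CD8a additionally carries a low floor
    (``cd8_lo_floor``) separating CD8-negative from CD8-low, so CD8a has
    three levels (neg / lo / hi).  Patterns not covered by the table map to
    "ungated"; the table is exhaustive and mutually exclusive over sign
    patterns.
    """

    thresholds: dict                    # marker -> positivity threshold
    cd8_lo_floor: float
    metadata: dict = field(default_factory=dict)

    def n_populations(self) -> int:
        """Number of distinct population labels the decision table resolves."""
        return len(GATE_LABELS)


def log_denoised(protein_denoised: np.ndarray, already_log: bool = False):
    """log1p for linear-scale input; identity (flagged) for log-scale input."""
    x = np.asarray(protein_denoised, dtype=float)
    if (x < 0).any():
        raise ValueError("negative values: input is not a denoised intensity")
    if already_log:
        return x
    return np.log1p(x)


def suggest_threshold_density(values, bw_method=0.25, grid_size=512) -> float:
    """Threshold at the density minimum between the two highest KDE modes.

    Raises :class:`NoValleyError` (reporting the single mode) when the kernel
    density estimate is unimodal or degenerate.  Requires >= 100 values.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise ValueError("need at least 100 values to estimate a density")
    if np.ptp(values) < 1e-12:
        raise NoValleyError(mode=float(values[0]))
    kde = gaussian_kde(values, bw_method=bw_method)
    grid = np.linspace(values.min(), values.max(), grid_size)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    # include boundary maxima
    if dens[0] > dens[1]:
        maxima = np.concatenate([[0], maxima])
    if dens[-1] > dens[-2]:
        maxima = np.concatenate([maxima, [grid_size - 1]])
    if len(maxima) < 2:
        mode = float(grid[int(np.argmax(dens))])
        raise NoValleyError(mode=mode)
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    a, b = int(top2.min()), int(top2.max())
    valley = a + int(np.argmin(dens[a:b + 1]))
    return float(grid[valley])


def build_default_scheme(log_proteins: pd.DataFrame, seed: int = 0,
                         bw_method: float = 0.15) -> GateScheme:
    """Derive per-marker thresholds from density valleys of the data.

    CD4, TCRb, CD69 and CD127 get a single valley threshold.  CD8a is
    three-level: the density valley between the negative and expressing cells
    is the low floor (below it CD8 is negative), and a second valley within
    the expressing cells separates CD8-low from CD8-high.
    """
    thresholds = {}
    for marker in ("CD4", "TCRb", "CD69", "CD127"):
        thresholds[marker] = suggest_threshold_density(log_proteins[marker],
                                                       bw_method=bw_method)
    cd8 = log_proteins["CD8a"].to_numpy()
    floor = suggest_threshold_density(cd8, bw_method=bw_method)
    positive = cd8[cd8 >= floor]
    try:
        t_hi = suggest_threshold_density(positive, bw_method=bw_method)
    except (NoValleyError, ValueError):
        log.warning("CD8a has no low/high substructure; collapsing lo gate")
        t_hi = floor
    thresholds["CD8a"] = float(t_hi)
    return GateScheme(thresholds=thresholds, cd8_lo_floor=float(floor),
                      metadata={"method": "kde-valley", "seed": seed,
                                "bw_method": bw_method})


def apply_gate_scheme(log_proteins: pd.DataFrame, scheme: GateScheme) -> np.ndarray:
    """Assign each cell one of the eight gate labels (or "ungated").

    A value exactly at a threshold counts as positive (>= convention).
    Decision table: DP1 = CD4+CD8+CD69-CD127-; DP2 = CD4+CD8+CD69+CD127-;
    DP3 = CD4+CD8+TCRbhi CD69+CD127+; CD4+CD8lo = CD4+ with CD8 between the
    low floor and the high threshold; semimature (SM) = single positive
    CD69+CD127+; Mature = single positive CD69-CD127+.
    """
    for marker in ("CD4", "CD8a", "TCRb", "CD69", "CD127"):
        if marker not in log_proteins.columns:
            raise ValueError(f"missing marker: {marker}")
    th = scheme.thresholds
    cd4 = log_proteins["CD4"].to_numpy() >= th["CD4"]
    cd8v = log_proteins["CD8a"].to_numpy()
    cd8_hi = cd8v >= th["CD8a"]
    cd8_lo = (cd8v >= scheme.cd8_lo_floor) & ~cd8_hi
    cd8_neg = cd8v < scheme.cd8_lo_floor
    tcrb = log_proteins["TCRb"].to_numpy() >= th["TCRb"]
    cd69 = log_proteins["CD69"].to_numpy() >= th["CD69"]
    cd127 = log_proteins["CD127"].to_numpy() >= th["CD127"]

    labels = np.full(len(log_proteins), "ungated", dtype=object)
    dp = cd4 & cd8_hi
    labels[dp & ~cd69 & ~cd127] = "DP1"
    labels[dp & cd69 & ~cd127] = "DP2"
    labels[dp & tcrb & cd69 & cd127] = "DP3"
    labels[cd4 & cd8_lo] = "CD4+CD8lo"
    cd4sp = cd4 & cd8_neg
    labels[cd4sp & cd69 & cd127] = "CD4 SM"
    labels[cd4sp & ~cd69 & cd127] = "CD4 Mature"
    cd8sp = ~cd4 & cd8_hi
    labels[cd8sp & cd69 & cd127] = "CD8 SM"
    labels[cd8sp & ~cd69 & cd127] = "CD8 Mature"
    return labels


@dataclass
class GateTimeline:
    """Gate labels ordered by median pseudotime with Youden-J boundaries."""

    order: list                        # gate labels by median pseudotime
    boundaries: pd.DataFrame           # earlier, later, threshold, youden_j, low_confidence
    excluded: list = field(default_factory=list)


def _youden_best_threshold(earlier: np.ndarray, later: np.ndarray):
    """Exhaustive scan of candidate thresholds (midpoints of pooled values).

    J(c) = sensitivity + specificity - 1 for the classifier "later if
    pseudotime >= c".  Ties break toward the smallest threshold.
    """
    pooled = np.sort(np.unique(np.concatenate([earlier, later])))
    if len(pooled) < 2:
        return float(pooled[0]), 0.0
    candidates = 0.5 * (pooled[:-1] + pooled[1:])
    best_c, best_j = candidates[0], -np.inf
    for c in candidates:
        sens = np.mean(later >= c)
        spec = np.mean(earlier < c)
        j = sens + spec - 1.0
        if j > best_j + 1e-15:
            best_j, best_c = j, c
    return float(best_c), float(best_j)


def align_gates_to_pseudotime(gate_labels, pseudotime, min_cells: int = 20) -> GateTimeline:
    """Order gates by median pseudotime; place Youden-optimal boundaries.

    Gates with fewer than ``min_cells`` cells are excluded with a warning.
    Boundaries with J close to zero are flagged low-confidence.
    """
    gate_labels = np.asarray(gate_labels, dtype=object)
    pseudotime = np.asarray(pseudotime, dtype=float)
    counts = pd.Series(gate_labels).value_counts()
    usable = [g for g in counts.index
              if g != "ungated" and counts[g] >= min_cells]
    excluded = [g for g in counts.index
                if g != "ungated" and counts[g] < min_cells]
    if excluded:
        log.warning("gates excluded (<%d cells): %s", min_cells, excluded)
    if len(usable) < 2:
        raise ValueError("need at least 2 gates with enough cells")
    medians = {g: float(np.median(pseudotime[gate_labels == g])) for g in usable}
    order = sorted(usable, key=lambda g: (medians[g], g))
    rows = []
    for earlier, later in zip(order[:-1], order[1:]):
        te = pseudotime[gate_labels == earlier]
        tl = pseudotime[gate_labels == later]
        c, j = _youden_best_threshold(te, tl)
        rows.append({"earlier": earlier, "later": later, "threshold": c,
                     "youden_j": j, "low_confidence": bool(j < 0.1)})
    return GateTimeline(order=order, boundaries=pd.DataFrame(rows),
                        excluded=excluded)


def proportion_log_enrichment(labels, sample_id, condition_by_sample: dict,
                              reference_condition, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-(sample, cluster) log2 fold enrichment versus a reference condition.

    Cluster proportions per sample (with a Haldane-style pseudocount of 0.5
    cells added to every sample x cluster count) are divided by the mean
    proportion of that cluster over reference-condition samples; the log2 of
    the ratio is returned.  Clusters absent from every reference sample are
    flagged with an undefined (NaN) enrichment.
    """
    labels = np.asarray(labels, dtype=object)
    sample_id = np.asarray(sample_id, dtype=object)
    samples = sorted(set(sample_id.tolist()))
    clusters = sorted(set(labels.tolist()))
    ref_samples = [s for s in samples
                   if condition_by_sample[s] == reference_condition]
    if not ref_samples:
        raise ValueError("reference condition has no samples")
    counts = pd.DataFrame(0.0, index=samples, columns=clusters)
    for s in samples:
        vc = pd.Series(labels[sample_id == s]).value_counts()
        for c in vc.index:
            counts.loc[s, c] = vc[c]
    counts += pseudocount
    props = counts.div(counts.sum(axis=1), axis=0)
    ref_mean = props.loc[ref_samples].mean(axis=0)
    rows = []
    for s in samples:
        for c in clusters:
            raw_ref = sum(
                (labels[sample_id == r] == c).sum() for r in ref_samples)
            undefined = raw_ref == 0
            value = np.log2(props.loc[s, c] / ref_mean[c])
            rows.append({
                "sample": s, "cluster": c,
                "condition": condition_by_sample[s],
                "log2_enrichment": np.nan if undefined else float(value),
                "undefined": bool(undefined),
            })
    out = pd.DataFrame(rows)
    out.attrs["log_base"] = 2
    out.attrs["pseudocount"] = pseudocount
    return out
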