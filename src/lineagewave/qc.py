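"""Quality control, feature selection, normalisation and joint embedding.

Implements the preprocessing contracts of the CITE-seq workflow: cell filters
(mitochondrial fraction, detected genes, protein library size, detected
proteins), a Seurat-v3-style highly-variable-gene ranking, library-size
normalisation, mixture-model protein background removal, and a deterministic
weighted linear projection standing in for the variational joint latent
space (default 20 dimensions).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from statsmodels.nonparametric.smoothers_lowess import lowess

from .simdata import CountsBundle

log = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "DenoisedBundle",
    "qc_filter_cells",
    "select_features",
    "normalize_rna",
    "denoise_protein",
    "denoise_rna",
    "joint_embed",
    "embed_2d",
]


@dataclass(frozen=True)
class QCThresholds:
    """Cell- and gene-level filter settings.

    Defaults follow the workflow's stated cutoffs: cells with >15%
    mitochondrial UMIs, <200 detected genes, protein library size outside
    [1000, 10000] or <70 detected proteins are removed; genes detected in
    fewer than 4 cells are dropped; the top 5,000 highly variable genes are
    kept.  Boundary conventions: "<200 genes removed" means >=200 retained;
    the protein library range is inclusive at both ends.
    """

    mito_frac_max: float = 0.15
    min_genes_per_cell: int = 200
    protein_lib_range: tuple = (1000, 10000)
    min_proteins_detected: int = 70
    min_cells_per_gene: int = 4
    n_hvg: int = 5000

    def __post_init__(self):
        lo, hi = self.protein_lib_range
        if not (lo < hi):
            raise ValueError("protein_lib_range lower bound must be < upper")
        for name in ("mito_frac_max", "min_genes_per_cell",
                     "min_proteins_detected", "min_cells_per_gene", "n_hvg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def for_panel(self, n_genes: int, n_proteins: int,
                  ref_genes: int = 5000, ref_proteins: int = 111) -> "QCThresholds":
        """Rescale per-cell detection floors to a smaller measured panel.

        The default floors assume the reference panel sizes (~5,000 genes,
        111 antibodies); a synthetic or boutique panel keeps the same
        *fractional* detection requirements.
        """
        import dataclasses as _dc
        min_genes = max(1, int(round(self.min_genes_per_cell *
                                     min(1.0, n_genes / ref_genes))))
        min_prot = max(1, int(round(self.min_proteins_detected *
                                    min(1.0, n_proteins / ref_proteins))))
        return _dc.replace(self, min_genes_per_cell=min_genes,
                           min_proteins_detected=min_prot)


@dataclass
class DenoisedBundle:
    """Normalised/denoised expression plus the joint latent representation."""

    rna_denoised: np.ndarray       # cells x genes, log scale
    protein_denoised: np.ndarray   # cells x proteins, background-removed log scale
    latent: np.ndarray             # cells x d
    embedding2d: np.ndarray        # cells x 2
    gene_names: list
    protein_names: list
    cell_meta: pd.DataFrame
    qc_report: dict = field(default_factory=dict)

    def __post_init__(self):
        for m in (self.rna_denoised, self.protein_denoised, self.latent,
                  self.embedding2d):
            if np.isnan(m).any():
                raise ValueError("denoised bundle contains missing values")


def qc_filter_cells(bundle: CountsBundle, thresholds: QCThresholds,
                    mito_gene_set=frozenset()):
    """Apply the four cell-level filters; returns (filtered bundle, report).

    The report counts removals per criterion; a cell failing several criteria
    is counted under each.
    """
    mito_gene_set = set(mito_gene_set)
    unknown = mito_gene_set - set(bundle.gene_names)
    if unknown:
        raise ValueError(f"mito_gene_set contains unknown genes: {sorted(unknown)[:5]}")
    n = bundle.n_cells
    report = {"n_input": n}
    if n == 0:
        report.update(mito=0, min_genes=0, protein_lib=0, min_proteins=0,
                      n_retained=0)
        return bundle.subset_cells(np.zeros(0, dtype=bool)), report

    rna_total = bundle.rna.sum(axis=1)
    genes_detected = (bundle.rna > 0).sum(axis=1)
    prot_total = bundle.protein.sum(axis=1)
    prot_detected = (bundle.protein > 0).sum(axis=1)

    if mito_gene_set:
        idx = [i for i, g in enumerate(bundle.gene_names) if g in mito_gene_set]
        mito_frac = bundle.rna[:, idx].sum(axis=1) / np.maximum(rna_total, 1)
        keep_mito = mito_frac <= thresholds.mito_frac_max
    else:
        warnings.warn("empty mitochondrial gene set; mito filter skipped")
        log.warning("mito filter skipped: empty gene set")
        keep_mito = np.ones(n, dtype=bool)

    lo, hi = thresholds.protein_lib_range
    keep_genes = genes_detected >= thresholds.min_genes_per_cell
    keep_plib = (prot_total >= lo) & (prot_total <= hi)
    keep_pdet = prot_detected >= thresholds.min_proteins_detected
    keep = keep_mito & keep_genes & keep_plib & keep_pdet

    report.update(
        mito=int((~keep_mito).sum()),
        min_genes=int((~keep_genes).sum()),
        protein_lib=int((~keep_plib).sum()),
        min_proteins=int((~keep_pdet).sum()),
        n_retained=int(keep.sum()),
    )
    return bundle.subset_cells(keep), report


def _hvg_statistic(counts: np.ndarray) -> np.ndarray:
    """Variance of clipped standardised counts under a mean-variance trend.

    Seurat-v3-style: a lowess trend of log10(variance) against log10(mean)
    yields an expected sd per gene; counts are standardised by it, clipped at
    sqrt(n), and the variance of the standardised values ranks the genes.
    """
    n = counts.shape[0]
    mean = counts.mean(axis=0)
    var = counts.var(axis=0)
    stat = np.zeros(counts.shape[1])
    ok = (mean > 0) & (var > 0)
    if ok.sum() >= 3:
        x = np.log10(mean[ok])
        y = np.log10(var[ok])
        fit = lowess(y, x, frac=0.3, it=0, xvals=x)
        # degenerate trends (e.g. all means equal) fall back to the raw value
        bad = ~np.isfinite(fit)
        fit[bad] = y[bad]
        exp_sd = np.sqrt(10.0 ** fit)
        z = (counts[:, ok] - mean[ok]) / exp_sd
        z = np.clip(z, -np.sqrt(n), np.sqrt(n))
        stat[ok] = z.var(axis=0)
    else:
        stat[ok] = var[ok]
    return stat


def select_features(bundle: CountsBundle, thresholds: QCThresholds,
                    always_keep=frozenset()) -> CountsBundle:
    """Drop rare genes, rank the rest by variable-gene statistic, keep top n.

    Genes detected in fewer than ``min_cells_per_gene`` cells are removed
    unless listed in ``always_keep`` (the always-keep union is the documented
    exception to the rare-gene floor).  Ties in the statistic break by gene
    name order.  All proteins are always retained.
    """
    always_keep = set(always_keep)
    detected_in = (bundle.rna > 0).sum(axis=0)
    names = np.array(bundle.gene_names)
    passes_floor = detected_in >= thresholds.min_cells_per_gene
    candidates = names[passes_floor]
    cand_idx = np.flatnonzero(passes_floor)

    n_hvg = thresholds.n_hvg
    if n_hvg >= len(candidates):
        log.info("n_hvg >= available genes (%d); keeping all", len(candidates))
        chosen = set(candidates)
    else:
        stat = _hvg_statistic(bundle.rna[:, cand_idx].astype(float))
        order = sorted(range(len(candidates)),
                       key=lambda i: (-stat[i], candidates[i]))
        chosen = {candidates[i] for i in order[:n_hvg]}
    chosen |= (always_keep & set(names))
    keep = [g for g in bundle.gene_names if g in chosen]
    return bundle.subset_genes(keep)


def normalize_rna(bundle_or_counts, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalisation to ``target_sum`` followed by log1p.

    Monotone in counts within each cell; a zero-count cell yields a zero row
    with a warning.
    """
    counts = bundle_or_counts.rna if isinstance(bundle_or_counts, CountsBundle) \
        else np.asarray(bundle_or_counts)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    counts = counts.astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        warnings.warn("zero-count cell(s): normalised rows set to zero")
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals),
                      where=totals > 0)
    return np.log1p(counts * scale)


def denoise_protein(protein_counts: np.ndarray, seed: int = 0,
                    n_restarts: int = 5, min_sep: float = 3.5,
                    return_fits: bool = False):
    """Two-component mixture background removal on log1p ADT counts.

    Per protein, a tied-variance two-Gaussian mixture is fitted by EM with
    multiple seeded restarts; the denoised value is
    ``max(0, log1p(count) - mu_background)`` shrunk toward zero by the
    posterior background probability.  When the two fitted means are closer
    than ``min_sep`` log units the protein is treated as unimodal and values
    are reported relative to the single fitted mode.  Tied variances make the
    foreground posterior monotone in the input, so the output is weakly
    monotone in counts for a fixed fit.

    Returns (denoised matrix, flags) where flags maps protein column index to
    "constant" or "unimodal" for degenerate columns.  Pass
    ``return_fits=True`` to additionally get per-protein fitted component
    means (log1p scale) for diagnostics.
    """
    counts = np.asarray(protein_counts)
    if counts.shape[0] < 50:
        raise ValueError("denoise_protein requires at least 50 cells")
    x = np.log1p(counts.astype(float))
    out = np.zeros_like(x)
    flags = {}
    fits = {}
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.ptp(col) < 1e-12:
            flags[j] = "constant"
            continue
        gm = GaussianMixture(n_components=2, covariance_type="tied",
                             n_init=n_restarts, random_state=seed,
                             max_iter=200)
        gm.fit(col[:, None])
        means = gm.means_.ravel()
        bg = int(np.argmin(means))
        fits[j] = (float(means[bg]), float(means[1 - bg]))
        sd_tied = float(np.sqrt(gm.covariances_.ravel()[0]))
        if abs(means[1] - means[0]) < min_sep * max(sd_tied, 1e-9) \
                or gm.weights_.min() < 0.02:
            flags[j] = "unimodal"
            mode = float(np.average(means, weights=gm.weights_))
            out[:, j] = np.maximum(0.0, col - mode)
            continue
        post_fg = gm.predict_proba(col[:, None])[:, 1 - bg]
        out[:, j] = np.maximum(0.0, col - means[bg]) * post_fg
    if return_fits:
        return out, flags, fits
    return out, flags


def denoise_rna(rna_norm: np.ndarray, latent: np.ndarray) -> np.ndarray:
    """Denoised RNA expression: per-gene linear decoding of the joint latent.

    Each gene's log-normalised profile is regressed (with intercept) on the
    latent coordinates and replaced by its fitted values -- the deterministic
    analogue of decoding a denoised rate from a learned latent space.
    Fitted values are continuous and smooth along the manifold, so group
    medians behave like those of model-denoised expression rather than
    jumping between discrete count levels; they are clipped at zero to stay
    on the nonnegative log scale.
    """
    rna_norm = np.asarray(rna_norm, dtype=float)
    latent = np.asarray(latent, dtype=float)
    if rna_norm.shape[0] != latent.shape[0]:
        raise ValueError("rna_norm and latent must share cell order")
    design = np.hstack([np.ones((latent.shape[0], 1)), latent])
    beta, *_ = np.linalg.lstsq(design, rna_norm, rcond=None)
    return np.clip(design @ beta, 0.0, None)


def joint_embed(rna_norm: np.ndarray, protein_denoised: np.ndarray,
                d: int = 20, seed: int = 0) -> np.ndarray:
    """Deterministic rank-d linear projection of both modalities.

    Features are standardised per column, each modality block is rescaled so
    the two contribute equal total variance, and the concatenation is
    projected onto its top d principal components.  Component signs are fixed
    by the largest-magnitude loading, making the output deterministic and
    invariant to feature order up to sign.
    """
    if rna_norm.shape[0] != protein_denoised.shape[0]:
        raise ValueError("modalities must share cell order")
    n_features = rna_norm.shape[1] + protein_denoised.shape[1]
    if d > n_features:
        raise ValueError(f"d={d} exceeds total feature count {n_features}")

    def standardise(m):
        m = np.asarray(m, dtype=float)
        mu = m.mean(axis=0)
        sd = m.std(axis=0)
        sd[sd == 0] = 1.0
        return (m - mu) / sd

    blocks = []
    for m in (rna_norm, protein_denoised):
        z = standardise(m)
        total_var = z.var(axis=0).sum()
        if total_var > 0:
            z = z / np.sqrt(total_var)
        blocks.append(z)
    joint = np.hstack(blocks)
    d_eff = min(d, min(joint.shape) - 1) if min(joint.shape) > 1 else 1
    pca = PCA(n_components=d_eff, svd_solver="full", random_state=seed)
    latent = pca.fit_transform(joint)
    # sign convention: largest-|loading| entry of each component is positive
    for k in range(latent.shape[1]):
        i = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, i] < 0:
            latent[:, k] *= -1.0
    if latent.shape[1] < d:
        latent = np.hstack([latent,
                            np.zeros((latent.shape[0], d - latent.shape[1]))])
    return latent


def embed_2d(latent: np.ndarray, seed: int = 0, n_neighbors: int = 50,
             min_dist: float = 0.3) -> np.ndarray:
    """Two-dimensional neighbour-graph layout of the latent space (UMAP).

    Deterministic for a fixed seed; preserves cluster adjacency.  The fairly
    large neighbourhood keeps the layout globally faithful so that curves
    fitted in 2-D agree with curves fitted in the full latent space.
    Requires at least 10 cells.
    """
    import umap  # deferred: numba compilation is slow at import time

    latent = np.asarray(latent, dtype=float)
    if latent.shape[0] < 10:
        raise ValueError("embed_2d requires at least 10 cells")
    nn = min(n_neighbors, latent.shape[0] - 1)
    reducer = umap.UMAP(n_components=2, n_neighbors=nn, min_dist=min_dist,
                        random_state=seed, init="spectral")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(reducer.fit_transform(latent), dtype=float)
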