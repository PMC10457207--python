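"""QC filters, feature selection, denoising and the joint embedding."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import cross_val_predict
from sklearn.neighbors import KNeighborsClassifier

from lineagewave.qc import (
    QCThresholds,
    denoise_protein,
    denoise_rna,
    embed_2d,
    joint_embed,
    normalize_rna,
    qc_filter_cells,
    select_features,
)
from lineagewave.simdata import CountsBundle


def _bundle(rna, protein, gene_names=None, protein_names=None):
    rna = np.asarray(rna)
    protein = np.asarray(protein)
    gene_names = gene_names or [f"g{i}" for i in range(rna.shape[1])]
    protein_names = protein_names or [f"p{i}" for i in range(protein.shape[1])]
    meta = pd.DataFrame({"cell_id": [f"c{i}" for i in range(rna.shape[0])],
                         "genotype": "wt", "batch": "b0"})
    return CountsBundle(rna=rna, protein=protein, cell_meta=meta,
                        gene_names=gene_names, protein_names=protein_names)


# ---------------------------------------------------------------------------
# cell filters


def _qc_test_bundle():
    """Four cells around the protein/gene thresholds plus one good cell."""
    rng = np.random.default_rng(0)
    n_genes, n_prot = 300, 100
    rna = rng.poisson(3, size=(5, n_genes))
    rna[rna == 0] = 1                       # every gene detected
    protein = np.full((5, n_prot), 20)
    # cell 0: protein library 999 (too small)
    protein[0] = 0
    protein[0, :99] = 9
    protein[0, 99] = 999 - 9 * 99
    # cell 1: 199 detected genes
    rna[1] = 0
    rna[1, :199] = 5
    # cell 2: exactly 200 detected genes (retained)
    rna[2] = 0
    rna[2, :200] = 5
    # cell 3: only 69 proteins detected
    protein[3] = 0
    protein[3, :69] = 30
    return _bundle(rna, protein)


def test_cell_filters_respect_the_stated_boundaries():
    bundle = _qc_test_bundle()
    filtered, report = qc_filter_cells(bundle, QCThresholds())
    kept = set(filtered.cell_meta["cell_id"])
    assert "c0" not in kept          # protein library 999 < 1000
    assert "c1" not in kept          # 199 genes < 200
    assert "c2" in kept              # exactly 200 genes retained
    assert "c3" not in kept          # 69 proteins < 70
    assert "c4" in kept
    assert report["protein_lib"] >= 1 and report["min_genes"] >= 1
    assert report["min_proteins"] >= 1


def test_mito_filter_removes_high_fraction_cells():
    rna = np.full((4, 10), 10)
    rna[0, 0] = 1000                 # mito fraction ~0.9
    protein = np.full((4, 80), 30)
    bundle = _bundle(rna, protein)
    filtered, report = qc_filter_cells(
        bundle, QCThresholds(min_genes_per_cell=5, min_proteins_detected=10),
        mito_gene_set={"g0"})
    assert "c0" not in set(filtered.cell_meta["cell_id"])
    assert report["mito"] == 1


def test_empty_mito_set_warns_and_skips_the_filter():
    bundle = _qc_test_bundle()
    with pytest.warns(UserWarning, match="mito"):
        qc_filter_cells(bundle, QCThresholds())


def test_empty_input_gives_empty_output_and_zero_counts():
    bundle = _bundle(np.zeros((0, 5), dtype=int), np.zeros((0, 4), dtype=int))
    filtered, report = qc_filter_cells(bundle, QCThresholds())
    assert filtered.n_cells == 0
    assert report["n_retained"] == 0 and report["mito"] == 0


def test_qc_is_idempotent():
    bundle = _qc_test_bundle()
    with pytest.warns(UserWarning):
        once, _ = qc_filter_cells(bundle, QCThresholds())
        twice, report = qc_filter_cells(once, QCThresholds())
    assert twice.n_cells == once.n_cells
    assert report["n_retained"] == report["n_input"]


# ---------------------------------------------------------------------------
# feature selection


def test_rare_genes_drop_unless_always_kept():
    rng = np.random.default_rng(1)
    rna = rng.poisson(5, size=(50, 6))
    rna[:, 0] = 0
    rna[:3, 0] = 1                  # detected in 3 cells only
    rna[:, 1] = 0
    rna[:3, 1] = 1
    bundle = _bundle(rna, np.zeros((50, 2), dtype=int))
    out = select_features(bundle, QCThresholds(n_hvg=10),
                          always_keep={"g1"})
    assert "g0" not in out.gene_names
    assert "g1" in out.gene_names


def test_equal_variance_ties_break_on_gene_name_order():
    rng = np.random.default_rng(2)
    base = rng.poisson(5, size=(60, 1))
    rna = np.tile(base, (1, 6))     # identical columns -> identical statistic
    bundle = _bundle(rna, np.zeros((60, 2), dtype=int),
                     gene_names=["gD", "gB", "gF", "gA", "gC", "gE"])
    out = select_features(bundle, QCThresholds(n_hvg=3))
    assert sorted(out.gene_names) == ["gA", "gB", "gC"]


def test_planted_high_variance_genes_are_all_selected():
    rng = np.random.default_rng(3)
    n, g = 400, 60
    rates = rng.uniform(2, 50, size=g)
    rna = rng.poisson(rates, size=(n, g))
    hot = [3, 17, 29, 41, 55]
    for j in hot:
        # same mean, ~10x Poisson variance via a gamma-Poisson mixture
        phi = 9.0 / rates[j]
        lam = rng.gamma(1.0 / phi, phi * rates[j], size=n)
        rna[:, j] = rng.poisson(lam)
    bundle = _bundle(rna, np.zeros((n, 2), dtype=int))
    out = select_features(bundle, QCThresholds(n_hvg=len(hot)))
    assert {f"g{j}" for j in hot} <= set(out.gene_names)


# ---------------------------------------------------------------------------
# normalisation


def test_all_zero_gene_stays_zero():
    rna = np.array([[1, 0, 3], [2, 0, 1]])
    norm = normalize_rna(rna)
    assert (norm[:, 1] == 0).all()


def test_per_cell_scale_invariance():
    rna = np.array([[1, 2, 3], [10, 0, 5]])
    doubled = rna.copy()
    doubled[0] *= 2
    assert np.allclose(normalize_rna(rna)[0], normalize_rna(doubled)[0])


def test_within_cell_rank_order_is_preserved():
    rng = np.random.default_rng(4)
    rna = rng.poisson(4, size=(20, 30))
    norm = normalize_rna(rna)
    for i in range(20):
        assert (np.argsort(norm[i], kind="stable")
                == np.argsort(rna[i], kind="stable")).all()


def test_zero_count_cell_warns_and_returns_zeros():
    rna = np.array([[0, 0], [1, 2]])
    with pytest.warns(UserWarning, match="zero-count"):
        norm = normalize_rna(rna)
    assert (norm[0] == 0).all()


# ---------------------------------------------------------------------------
# protein background removal


def test_background_only_protein_denoises_to_zero():
    rng = np.random.default_rng(5)
    counts = rng.poisson(8, size=(500, 1))
    out, flags = denoise_protein(counts, seed=0)
    assert (out <= 1e-9).mean() >= 0.95 or 0 in flags


def test_mixture_component_means_recovered_within_20_percent():
    rng = np.random.default_rng(6)
    n = 1000
    bg = rng.poisson(10, n // 2)
    fg = rng.poisson(200, n // 2)
    counts = np.concatenate([bg, fg])[:, None]
    _, _, fits = denoise_protein(counts, seed=0, return_fits=True)
    mu_bg, mu_fg = fits[0]
    assert abs(mu_bg - np.log1p(10)) / np.log1p(10) < 0.2
    assert abs(mu_fg - np.log1p(200)) / np.log1p(200) < 0.2


def test_constant_protein_column_is_flagged_not_fatal():
    counts = np.full((100, 2), 7)
    counts[:, 1] = np.random.default_rng(7).poisson(50, 100)
    out, flags = denoise_protein(counts, seed=0)
    assert flags.get(0) == "constant"
    assert (out[:, 0] == 0).all()


def test_denoised_protein_is_nonnegative_and_weakly_monotone():
    rng = np.random.default_rng(8)
    counts = np.concatenate([rng.poisson(8, 300), rng.poisson(150, 300)])[:, None]
    out, _ = denoise_protein(counts, seed=0)
    assert (out >= 0).all()
    order = np.argsort(counts.ravel(), kind="stable")
    assert (np.diff(out.ravel()[order]) >= -1e-9).all()


def test_too_few_cells_is_an_error():
    with pytest.raises(ValueError, match="50 cells"):
        denoise_protein(np.ones((10, 2), dtype=int))


# ---------------------------------------------------------------------------
# latent decoding and embedding


def test_denoise_rna_flattens_pure_noise_genes():
    rng = np.random.default_rng(9)
    latent = rng.normal(size=(400, 10))
    noise = rng.normal(5, 1, size=(400, 3))
    den = denoise_rna(noise, latent)
    assert den.var(axis=0).max() < 0.2 * noise.var(axis=0).min()
    assert (den >= 0).all()


def test_joint_embed_default_dimension_is_20():
    rng = np.random.default_rng(10)
    latent = joint_embed(rng.normal(size=(100, 40)), rng.normal(size=(100, 10)))
    assert latent.shape == (100, 20)


def test_rank_one_data_concentrates_variance_on_first_component():
    rng = np.random.default_rng(11)
    direction = rng.normal(size=30)
    scores = rng.normal(size=(200, 1))
    rna = scores * direction + 1e-6 * rng.normal(size=(200, 30))
    latent = joint_embed(rna, np.zeros((200, 2)), d=5)
    var = latent.var(axis=0)
    assert var[0] / var.sum() >= 0.99


def test_joint_embed_invariant_to_feature_order_up_to_sign():
    rng = np.random.default_rng(12)
    rna = rng.normal(size=(150, 25))
    prot = rng.normal(size=(150, 6))
    a = joint_embed(rna, prot, d=4)
    perm = rng.permutation(25)
    b = joint_embed(rna[:, perm], prot, d=4)
    for k in range(4):
        assert (np.allclose(a[:, k], b[:, k], atol=1e-8)
                or np.allclose(a[:, k], -b[:, k], atol=1e-8))


def test_embedding_dimension_larger_than_features_errors():
    with pytest.raises(ValueError, match="exceeds"):
        joint_embed(np.ones((30, 3)), np.ones((30, 2)), d=10)


def test_embed_2d_shape_determinism_and_minimum_size():
    rng = np.random.default_rng(13)
    latent = rng.normal(size=(80, 6))
    a = embed_2d(latent, seed=4)
    b = embed_2d(latent, seed=4)
    assert a.shape == (80, 2)
    assert np.allclose(a, b)
    with pytest.raises(ValueError, match="10 cells"):
        embed_2d(latent[:5], seed=4)


def test_separated_blobs_stay_separated_in_2d():
    from sklearn.metrics import silhouette_score

    rng = np.random.default_rng(14)
    centers = np.array([[0] * 6, [25] * 6, [-25, 25, -25, 25, -25, 25]])
    latent = np.vstack([rng.normal(c, 1, size=(60, 6)) for c in centers])
    labels = np.repeat([0, 1, 2], 60)
    emb = embed_2d(latent, seed=5)
    assert silhouette_score(emb, labels) > 0.5


def test_latent_label_transfer_recovers_stages(pipeline_run, truth_arrays):
    """15-NN majority vote in the latent recovers true stages >=90%."""
    _, _, state = pipeline_run
    latent = state["denoised"].latent
    stage = truth_arrays["stage"]
    pred = cross_val_predict(KNeighborsClassifier(15), latent, stage, cv=5)
    assert (pred == stage).mean() >= 0.90
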