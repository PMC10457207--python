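# lineagewave

Branching pseudotime, in silico flow cytometry and lineage-program
discovery for CITE-seq data on developing thymocytes — with a fully
ground-truthed synthetic generator, so every stage of the analysis is
verifiable without downloading anything.

## The problem

During positive selection, double-positive (CD4⁺CD8⁺) thymocytes commit to
either the CD4 helper or the CD8 cytotoxic lineage. CITE-seq measures each
cell's transcriptome together with its surface proteins (ADTs), which makes
it possible to order cells along a branching developmental trajectory,
translate the ordering back into flow-cytometry-style gates, and ask *when*
and *through which regulators* the two lineages diverge. The biological
picture this package's workflow supports: a first wave of TCR signaling
shared by all cells but **sustained in CD4-fated and transient in CD8-fated
cells** (the "CD4 audition"), followed by a **second, CD8-specific wave**
that coincides with CD8 lineage specification.

`lineagewave` is aimed at computational immunologists and methods
developers who want this analysis chain as tested, seed-stable library
code: every step is an importable function, every stage's output carries a
recoverable ground truth on synthetic data, and the whole chain runs on a
laptop in minutes.

## The model and statistics at the core

- **Synthetic CITE-seq** (`lineagewave.simdata`): cells with true
  pseudotime `t ~ U(0, 12)` branching at `t = 3`; RNA counts
  `NB(mu(t, lineage), phi)` driven by temporal kernels (sustained/transient
  first wave, late CD8 wave, maturation ramps, coreceptor dip/recovery);
  ADT counts as background + stage-driven foreground NB mixtures matching
  the 8-gate scheme (DP1, DP2, CD4⁺CD8^lo, DP3, semimature/mature CD4 and
  CD8); a planted TF→target database.
- **QC and denoising** (`qc`): the published cell filters (mito ≤ 15%,
  ≥ 200 genes, protein library ∈ [1000, 10000], ≥ 70 proteins), variable-
  gene selection, per-protein mixture background removal, a rank-20 joint
  latent and decoded (latent-fitted) denoised expression.
- **Trajectory** (`trajectory`): Leiden clusters (resolution 0.6), a
  connectivity-weighted cluster MST, iterated principal curves with a
  shared trunk, inverse-distance lineage weights `w_L = d_other/(d_L +
  d_other)`, the weight > 0.5 genotype filter, unit pseudotime bins.
- **Gating** (`gating`): KDE density-valley thresholds per marker, the
  eight-population decision table over CD4/CD8a/TCRβ/CD69/CD127, and gate →
  pseudotime alignment by maximising Youden's `J = sensitivity +
  specificity − 1`.
- **Differential expression** (`diffexpr`): per pseudotime bin, one-vs-all
  within lineage and CD4-vs-CD8 between lineages; bootstrap sign-evidence
  `|log(p⁺/(1−p⁺))| > 2.0` (RNA) with `|median LFC| > 0.2` (natural log)
  and > 5% detection; loess-smoothed scaled profiles and Leiden gene
  clusters.
- **Driver ranking** (`enrich`): hypergeometric upper-tail enrichment with
  BH correction; per-library TF ranks integrated by **MeanRank** and
  averaged over the three pseudotime bins preceding the master regulator's
  first differential expression (Zbtb7b for CD4, Runx3 for CD8), excluding
  the master-regulator bin and bins where a TF is detected in < 5% of
  cells.

Full derivations, defaults and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the study end to end; each is a
thin driver over the library. For example, fitting the branching
trajectory on the default synthetic conditions:

```bash
$ python analysis/03_fit_trajectory.py
9 Leiden clusters (resolution 0.6); shared trunk: [7, 0, 2]
lineage paths: {'CD4': [7, 0, 2, 5, 8, 1], 'CD8': [7, 0, 2, 4, 3, 6]}
lineage-weight filter: 1 of 2001 cells excluded
  CD4: n=960  Spearman(inferred, true) = 0.939
  CD8: n=1040  Spearman(inferred, true) = 0.964
argmax-weight lineage accuracy (true t > 4): 0.943
written to results/trajectory/
```

Reading: the two MST paths share a trunk of three clusters (the
double-positive stages before the branch), then split into a CD4 and a CD8
arm. The inferred pseudotime orders cells almost exactly as the generator
planted them (Spearman 0.94/0.96 per lineage), 94% of cells more than one
unit past the branch are assigned to their true lineage by argmax weight,
and the weight > 0.5 genotype filter excludes almost nothing — the
synthetic genotypes develop along their expected lineage.

The other scripts follow the same pattern: `01` writes the dataset and its
ground truth (MTX/TSV/GMT), `02` the QC report and joint embedding, `04`
the gate scheme and Youden timeline, `05` the binned DE tables and profile
clusters, `06` the candidate-driver TF ranking.

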