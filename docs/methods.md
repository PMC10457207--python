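# Methods

`lineagewave` re-implements, as a tested pipeline over synthetic data, the
computational workflow used to order developing thymocytes along a branching
CD4/CD8 trajectory and to detect lineage-specific temporal expression
programs and candidate driver transcription factors. This note documents the
generative model, the analysis procedures, the numerical choices, and what
the synthetic study does and does not establish about real data.

## The synthetic generator (`simdata`)

The generator emulates positive selection as measured by CITE-seq: paired
RNA and surface-protein (ADT) UMI counts for cells drawn from genotypes that
are fated to the CD4 lineage, the CD8 lineage, or unrestricted (wild type,
split 50/50 at random). Each cell carries a true pseudotime `t`, drawn
uniformly on the span `[0, 12]`; uniform arrival maximises bin occupancy for
the binned tests downstream. The two lineages share one trajectory until the
branch at `t = 3` — every lineage-dependent kernel term is constructed to
vanish identically for `t < 3`, so pre-branch feature distributions are
exchangeable between lineages by construction, not approximately.

### Expression programs

RNA means follow per-gene temporal kernels on the linear scale, with
per-gene amplitudes drawn once from a program-specific range:

| program | kernel | default shape |
| --- | --- | --- |
| constitutive / background | constant | amplitudes U(1, 6) / U(0.05, 0.8) |
| maturation up / down | logistic in `t` | centre 6, width 1.5 |
| wave1 (shared TCR response) | rise to peak at `t = 3`, lineage-specific decay | decay 2.6 (CD4) vs 0.8 (CD8) |
| wave1 (sustained, audition) | as above, peak 3.5 | decay 4.0 (CD4) vs 1.1 (CD8) |
| wave2 (CD8-specific) | Gaussian bump, zero in CD4 | centre 9.5, width 1.3 |
| TF trio | Gata3 / Zbtb7b / Runx3 analogues | early CD4-sustained bump; audition rise decaying in CD8 after 7.2; CD8-only late rise at 8.7 |
| coreceptor | Cd4 / Cd8a analogues | shared early dip; CD8a mid-dip then recovery in CD8 and late loss in CD4; Cd4 late loss in CD8 |

The first-wave decay constants are the central free parameters. They were
fixed so that the transient first wave in CD8-fated cells decays within
about one pseudotime unit of the branch: with slower decays the two
lineages remain statistically indistinguishable until ~3 units past the
branch, which contradicts the published observation that between-lineage
differences in first-wave TCR targets (and the Gata3 analogue) are already
significant at pseudotime bin 4–5, one unit past our branch. The sharp
transient is also the kinetic-signaling picture: MHCI-specific cells lose
coreceptor support and their first signaling wave collapses quickly.

Counts are negative binomial (gamma–Poisson) with `var = mu + phi mu^2`
(`phi = 0.25` for RNA, a typical droplet-data value at this depth), scaled
by a per-cell lognormal library factor (sd 0.25 in the log). Median library
size is ~1,000 RNA UMIs over 600 genes — deliberately shallow, so sampling
noise is a real obstacle, as in the experiment.

### Proteins and stages

Protein counts are a background NB (mean 8) plus a foreground NB whose mean
is `8 x 20 x level(t, lineage)`; `level` is a piecewise-logistic activation
profile per gating marker (CD4, CD8a, TCRb, CD69, CD127) that follows the
eight-stage timeline: DP1 `[0,4)`, DP2 `[4,6)`, CD4+CD8lo `[6,8)`, then CD4
SM `[8,10)` / CD4 Mature `[10,12]` on the CD4 branch and DP3 `[8,10)` / CD8
SM `[10,11)` / CD8 Mature `[11,12]` on the CD8 branch. CD8a is three-level
(negative / low / high) to produce the CD4+CD8lo intermediate and the DP3
dip-and-recovery. Transitions have width 0.15 pseudotime units, so a few
percent of cells near each boundary are intrinsically ambiguous — the gate
accuracy ceiling is below 1. Protein background is cell-independent; the
cell-specific background of the variational model is not emulated.

### Ground truth

`GroundTruth` records per-cell pseudotime/lineage/stage, per-gene program,
the planted TF→target map (an NFAT-family analogue driving the sustained
audition wave, an AP-1 analogue driving the shared wave, and the CD8 master
regulator driving the late wave), and a per-(gene, bin) between-lineage
difference table. The difference table is computed on the same estimand the
DE test measures — the expected log1p of library-scaled counts under the NB
model, averaged over the bin — with the test's own effect-size floor (0.2
natural-log units) defining the planted direction, and the raw differences
retained (`de_delta`) so evaluations can distinguish "wrong sign" from
"real but small". A `lineage_effects=False` switch produces a global null
(every cell follows the CD4-form kernels for RNA *and* protein) for
calibration studies.

## QC and denoising (`qc`)

Cell filters use the published thresholds: mitochondrial fraction ≤ 15%,
≥ 200 detected genes, protein library in [1000, 10000] (inclusive), ≥ 70
detected proteins; genes detected in < 4 cells are dropped; the top 5,000
genes by a Seurat-v3-style clipped standardised variance (lowess
mean–variance trend, name-order tie break) are kept together with an
`always_keep` union. For panels smaller than the reference (~5,000 genes,
111 antibodies) the per-cell detection floors are rescaled proportionally
(`QCThresholds.for_panel`) — a 20-protein panel cannot satisfy a 70-protein
floor for reasons that have nothing to do with cell quality.

Protein background removal fits a two-component tied-variance Gaussian
mixture to log1p counts per protein (5 seeded EM restarts). The denoised
value is `max(0, log1p(count) − mu_bg)` shrunk by the posterior foreground
probability; tied variances make this weakly monotone in the count. A
protein is called unimodal — and reported relative to its single mode —
when the fitted means are separated by fewer than 3.5 tied standard
deviations: a unimodal distribution split in half lands near 2 on this
statistic, true background/foreground mixtures at 5 and above.

The joint latent is a deterministic stand-in for the variational model:
per-feature standardisation, equal total variance per modality, rank-20
PCA with a sign convention (largest-magnitude loading positive) that makes
it reproducible and feature-order invariant. Denoised RNA is then the
*decoded* expression: each gene's log-normalised profile regressed on the
latent (with intercept) and replaced by its fitted values, clipped at zero.
This mirrors decoding a denoised rate from a learned latent space, and it
matters statistically: per-cell log counts at this depth sit on discrete
atoms ~0.5 log-units apart, so group medians of raw values jump between
atoms and a median-based test cannot be calibrated at bin-level group
sizes. Decoded values are continuous along the manifold and group medians
behave classically. The 2-D layout is UMAP with a deliberately global
neighbourhood (50 neighbours, min_dist 0.3) so curves fitted in 2-D agree
with curves fitted in the full latent (Spearman ≥ 0.95).

## Branching pseudotime (`trajectory`)

Clustering is Leiden (resolution 0.6) on a Jaccard-weighted shared-nearest-
neighbour graph (k = 15); communities that remain embedded in one another
(more than 8 cross k-NN edges per member of the smaller one) are merged —
over-splits of one mode sit near 10 on this statistic, genuinely adjacent
stages below 6.

The trajectory is a cluster-MST / principal-curve fit. Two choices deviate
from the naive recipe, both forced by failure modes observed on the study
conditions:

* **MST edge costs are inverse inter-cluster connectivities** (cross k-NN
  edge counts normalised by the smaller cluster), not Euclidean centroid
  distances, with Euclidean as a fallback for disconnected graphs.
  Same-stage clusters of *different* lineages have nearby centroids but
  almost no cell-level edges; a Euclidean MST repeatedly routed one
  lineage's path through the other lineage's cluster, dragging it into the
  shared trunk.
* **Curve fits are fold-guarded.** Principal-curve inits follow MST path
  order; after the iterated projection/lowess-resmoothing fit (span 0.3,
  tolerance 1e-3, ≤ 20 iterations) the curve must still order its clusters
  monotonically (|Spearman| ≥ 0.8 of mean arc length vs path position),
  otherwise the smoothed init polyline is kept. Trunks containing parallel
  same-stage subclusters occasionally folded into a U otherwise.

A single shared curve is fitted to the trunk clusters and both lineage
curves extend it verbatim, so cells projecting onto the shared segment have
*identical* pseudotime on both lineage paths. Weights are the
inverse-distance ratio `w_L = d_other / (d_L + d_other)`, with trunk cells
(both projections within the shared arc) at weight 1 on both lineages.
Argmax ties break by distance to the branch-specific curve segments; only
exactly equidistant cells fall back to index parity. The genotype filter
follows the published rule: lineage-restricted cells need weight strictly
> 0.5 on their expected lineage; unrestricted cells take the argmax and are
never excluded. Pseudotime is the weight-averaged arc length, rescaled so
the longest lineage spans [0, 12] (unit bins then match the simulated
span); bins are `floor(t)` with the global maximum joining the last bin.

Fitting runs in the full 20-dimensional latent by default
(`curve_space="embedding2d"` reproduces the 2-D route): on these conditions
the 2-D layout compresses the early post-branch divergence enough to cost
~0.06 of CD4 pseudotime correlation, and the agreement property between the
two routes is tested rather than assumed.

## Gating (`gating`)

Per-marker thresholds are density valleys: the minimum of a Gaussian KDE
(bandwidth 0.15 x data sd) between the two highest modes, with an
informative error for unimodal input. CD8a gets two cutoffs: the
negative/expressing valley is the low floor, a second valley inside the
expressing cells separates low from high. (A floor at the 10th percentile
of CD8-positive cells — one obvious alternative — lands *inside* the
CD8-low population whenever that population is a modest fraction of
expressing cells, and misclassifies ~40% of true CD4+CD8lo cells; the
valley floor is used instead.) The decision table maps marker sign
patterns (≥ threshold = positive) to the eight populations; unmatched
patterns are "ungated". Gates are aligned to pseudotime by ordering on
median pseudotime and placing, per adjacent pair, the threshold maximising
Youden's J over all midpoints of pooled values (smallest maximiser on
ties; J < 0.1 flagged low-confidence). The cluster-proportion statistic
for perturbation panels is log2 of (sample proportion / mean reference
proportion) with a 0.5-cell Haldane pseudocount.

## Differential expression (`diffexpr`)

The evidence score replaces the posterior Bayes factor while keeping its
reporting contract. Per comparison, `n_boot = 500` bootstrap replicates
resample each group (indices derived only from the seed and group size, so
swapping labels negates the LFC exactly); the replicate LFC is the
difference of group medians of denoised log expression (natural-log
units); evidence is `|log(p+ / (1 − p+))|` with `p+` the clipped fraction
of positive-sign replicates (zero-LFC replicates split evenly).
Significance requires evidence > 2.0 (RNA; 1.0 protein), |median LFC| >
0.2, and detection (raw count > 0) in > 5% of the population whose
upregulation is claimed. Groups under 20 cells are untestable; bins where
either lineage is under 20 cells are skipped.

Evaluation against the planted truth uses two distinct notions: *recall*
over (gene, bin) pairs whose true difference exceeds the 0.2 floor, and a
*directional* false-discovery rate — a call is false when the sign of the
true difference contradicts it (including exactly-zero pre-branch
differences). Calls on real differences smaller than the floor are not
counted as false: the library-size normalisation makes small opposite-sign
shifts in all other genes a genuine property of the data (compositional
coupling), and asserting such a difference with the correct sign is not an
error, though its reported magnitude partly reflects amplification by the
denoiser.

Loess smoothing is local-linear with tricube weights (statsmodels lowess,
span 0.3, no robustness iterations — exact on linear data) on a 100-point
grid. Gene-profile clustering standardises genes, reduces cells by PCA,
and runs Leiden (resolution 0.6, k = 10, no merge heuristic) on the gene
k-NN graph; per-cluster mean profiles are the loess-smoothed mean of the
scaled member genes within the lineage in which they were upregulated.

## Enrichment and driver ranking (`enrich`)

Hypergeometric upper tails are computed through the log-survival function
(stable for extreme arguments; matches exact integer enumeration to 1e-12
for all backgrounds up to 25). BH adjustment is the standard step-up
(statsmodels), and cluster enrichment calls adjusted p < 0.05. TF ranking
collapses the multi-method scoring of hosted TF-enrichment services to one
transparent rule: within each library, TFs rank ascending by the
hypergeometric p of target/query overlap (average ranks on ties), and
MeanRank averages a TF's ranks over the libraries containing it. The
candidate-driver score averages per-bin MeanRanks over the three bins
immediately preceding the master regulator's first significant DE bin; the
master-regulator bin itself is reported for visualisation only and never
contributes, and bins where a TF is detected in under 5% of the population
of interest drop out of that TF's mean. Annotations record whether the TF
itself was DE in the window, whether any library lists a master regulator
among its targets, and membership in a user-supplied TCR-pathway list.

## Orchestration, determinism, problem sizes

`pipeline.run_all` executes simulate → QC → trajectory → gating → DE →
enrichment from one validated configuration. The global seed fans out per
stage by hashing the stage name (all derived seeds < 2^31), so disabling a
stage does not perturb the others; reports carry artifact hashes, per-stage
wall times, QC counts and (for synthetic sources) recovery metrics. Start
and endpoint clusters are anchored biologically, as in the study: the
cluster with the earliest cells starts the trajectory and the latest
cluster of each lineage terminates it. Because inferred and true time axes
register only to about one bin, the pipeline-level DE recovery metrics
allow one bin of slack; the DE operation itself is evaluated on exact bins
of the known time axis.

Default problem sizes — ~2,000 cells, 600 genes, 20 proteins, 500
bootstrap replicates, 50 decoy TFs, three libraries — were chosen so a full
run completes in a few minutes on one core while leaving every recovery
question statistically non-trivial (bin-level groups of ~55 cells, shallow
libraries, overlapping protein modes).

## What passing does and does not show

The generator plants exactly the structures the pipeline is asked to find,
with known clean geometry: one branch, no doublets, no ambient
contamination, no batch structure beyond a scalar library factor, uniform
arrival times, and protein stages aligned to the same clock as the RNA
programs. Passing therefore demonstrates that each procedure recovers what
it is specified to recover under honest noise at realistic depth — not
that it is robust to the full pathology of real thymus data (negative
selection and agonist branches, cell-cycle structure, batch effects,
cell-specific ADT background). The printed cell counts of the original
study depend on the deposited accession and a trained variational model
and are outside what this synthetic study can reproduce; the one criterion
tied to them is expected to fail without the accession staged locally.
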