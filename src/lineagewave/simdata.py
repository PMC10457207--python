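"""Synthetic branching CITE-seq generator with recoverable ground truth.

Emulates thymocytes undergoing positive selection: two genotype groups fated
to distinct lineages (CD4 or CD8) share an initial trajectory segment, then
branch at a known pseudotime.  RNA UMI counts are negative-binomial draws
whose means follow temporal kernels (a sustained early wave, a transient
early wave, a late CD8-specific wave, monotone maturation programs, and
coreceptor dip/recovery dynamics); surface-protein (ADT) counts are
background + foreground negative-binomial mixtures whose foreground levels
track the eight-gate staging scheme (DP1, DP2, CD4+CD8lo, DP3, semimature
and mature single positives).  Every cell carries a true pseudotime, lineage
and stage; every gene carries a program label; and a planted TF -> target map
links driver transcription factors to the expression programs they control.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimConfigError",
    "CountsBundle",
    "GroundTruth",
    "TFTargetDB",
    "program_mean",
    "simulate_dataset",
    "make_tf_target_db",
    "true_stage",
    "PROGRAMS",
    "LINEAGES",
    "STAGES",
    "GATING_MARKERS",
]

LINEAGES = ("CD4", "CD8")

#: expression programs recognised by the generator; genes not assigned to a
#: program are labelled "background" (constant low-level expression).
PROGRAMS = (
    "constitutive",
    "maturation_up",
    "maturation_down",
    "wave1_shared",
    "wave1_sustained_CD4",
    "wave2_CD8",
    "lineage_TF_trio",
    "coreceptor",
)

#: the eight stages of the gating scheme, in developmental order per lineage
STAGES = (
    "DP1",
    "DP2",
    "CD4+CD8lo",
    "DP3",
    "CD4 SM",
    "CD4 Mature",
    "CD8 SM",
    "CD8 Mature",
)

#: surface markers used by the in silico gating scheme
GATING_MARKERS = ("CD4", "CD8a", "TCRb", "CD69", "CD127")

# Stage boundaries (pseudotime cut points) for the default [0, 12] span.
# Both lineages: DP1 [0,4), DP2 [4,6), CD4+CD8lo [6,8).
# CD4 lineage:   CD4 SM [8,10), CD4 Mature [10,12].
# CD8 lineage:   DP3 [8,10), CD8 SM [10,11), CD8 Mature [11,12].
STAGE_CUTS = (4.0, 6.0, 8.0, 10.0, 11.0)

# names of the planted driver TFs and the programs they control
PLANTED_TFS = {
    "Nfatc2": "wave1_sustained_CD4",   # early, CD4-sustained wave (audition)
    "Junb": "wave1_shared",            # shared TCR-response wave
    "Runx3": "wave2_CD8",              # late CD8-specific wave
}

#: lineage-defining master regulators among the simulated genes
MASTER_REGULATORS = {"CD4": "Zbtb7b", "CD8": "Runx3"}


class SimConfigError(ValueError):
    """Raised when a SimConfig field violates its contract."""


def _default_module_sizes() -> dict:
    return {
        "constitutive": 60,
        "maturation_up": 80,
        "maturation_down": 80,
        "wave1_shared": 60,
        "wave1_sustained_CD4": 40,
        "wave2_CD8": 50,
        "lineage_TF_trio": 3,
        "coreceptor": 2,
    }


def _default_kernel_params() -> dict:
    # amplitudes are (low, high) ranges for per-gene draws; times in pseudotime
    # units on the default [0, 12] span.  Waves peak early (shared rise ending
    # at the branch) with a lineage-specific decay constant; the CD8 wave is a
    # late bump absent from the CD4 lineage.
    return {
        "constitutive": {"amp": (1.0, 6.0)},
        "maturation_up": {"base": 0.1, "amp": (2.0, 8.0), "center": 6.0, "width": 1.5},
        "maturation_down": {"base": 0.1, "amp": (2.0, 8.0), "center": 6.0, "width": 1.5},
        "wave1_shared": {
            "base": 0.1, "amp": (4.0, 10.0), "peak": 3.0, "rise": 1.2,
            "decay_cd4": 2.6, "decay_cd8": 0.8,
        },
        "wave1_sustained_CD4": {
            "base": 0.1, "amp": (4.0, 10.0), "peak": 3.5, "rise": 1.3,
            "decay_cd4": 4.0, "decay_cd8": 1.1,
        },
        "wave2_CD8": {"base": 0.1, "amp": (4.0, 10.0), "center": 9.5, "width": 1.3},
        "lineage_TF_trio": {
            # Gata3-like: early bump, more sustained in the CD4 lineage
            "gata3": {"base": 0.1, "amp": 6.0, "peak": 4.0, "rise": 1.5,
                      "decay_cd4": 3.5, "decay_cd8": 1.0},
            # Zbtb7b-like: audition rise in both lineages, decays in CD8
            "zbtb7b": {"base": 0.1, "amp": 6.0, "center": 6.3, "width": 0.5,
                       "cd8_off": 7.2, "cd8_tau": 1.0},
            # Runx3-like: late CD8-only logistic rise
            "runx3": {"base": 0.1, "amp": 6.0, "center": 8.7, "width": 0.5},
        },
        "coreceptor": {
            "cd4": {"base": 0.2, "amp": 12.0, "dip_center": 2.0, "dip_width": 0.9,
                    "dip_depth": 0.35, "cd8_off": 9.3, "cd8_off_width": 0.4},
            "cd8a": {"base": 0.2, "amp": 12.0, "dip_center": 2.0, "dip_width": 0.9,
                     "dip_depth": 0.3, "cd4_off": 6.5, "cd4_off_width": 0.5,
                     "cd8_dip_center": 7.0, "cd8_dip_width": 1.1,
                     "cd8_dip_depth": 0.75},
        },
        "background": {"amp": (0.05, 0.8)},
    }


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic CITE-seq experiment.

    Defaults give ~2,000 cells (three genotypes), 600 genes and 20 proteins on
    a [0, 12] pseudotime span branching at t = 3, matching the temporal layout
    of positive selection that the generator emulates.
    """

    n_cells_per_genotype: int = 667
    genotypes: tuple = (
        ("MHC2_restricted", "CD4"),
        ("MHC1_restricted", "CD8"),
        ("wildtype", "unassigned"),
    )
    n_genes: int = 600
    n_proteins: int = 20
    t_span: tuple = (0.0, 12.0)
    t_branch: float = 3.0
    module_sizes: Mapping[str, int] = field(default_factory=_default_module_sizes)
    kernel_params: Mapping[str, dict] = field(default_factory=_default_kernel_params)
    nb_dispersion: float = 0.25            # RNA: var = mu + disp * mu^2
    protein_dispersion: float = 0.05
    libsize_lognormal: tuple = (0.0, 0.25)  # (mean, sd) of log library factor
    protein_bg: tuple = (8.0, 20.0)         # (background mean, foreground fold)
    #: False gives a global null: every cell follows the CD4-lineage kernel
    #: forms (RNA and protein), whatever its genotype label -- the two
    #: genotype groups then differ only by sampling noise
    lineage_effects: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_genotype < 0:
            raise SimConfigError("n_cells_per_genotype must be >= 0")
        if self.n_genes < 0 or self.n_proteins < 0:
            raise SimConfigError("n_genes and n_proteins must be >= 0")
        lo, hi = self.t_span
        if not lo < hi:
            raise SimConfigError("t_span must be a nonempty interval")
        if not (lo < self.t_branch < hi):
            raise SimConfigError("t_branch must lie strictly inside t_span")
        for name, lineage in self.genotypes:
            if lineage not in ("CD4", "CD8", "unassigned"):
                raise SimConfigError(
                    f"genotypes: expected lineage of {name!r} must be CD4, CD8 "
                    f"or unassigned, got {lineage!r}"
                )
        total = sum(self.module_sizes.values())
        if total > self.n_genes:
            raise SimConfigError(
                f"module_sizes sum to {total} which exceeds n_genes={self.n_genes}"
            )
        for prog in self.module_sizes:
            if prog not in PROGRAMS:
                raise SimConfigError(f"module_sizes: unknown program {prog!r}")
        if self.nb_dispersion <= 0 or self.protein_dispersion <= 0:
            raise SimConfigError("dispersions must be > 0")
        if self.protein_bg[0] <= 0 or self.protein_bg[1] <= 0:
            raise SimConfigError("protein_bg entries must be > 0")
        if self.n_proteins and self.n_proteins < len(GATING_MARKERS):
            raise SimConfigError(
                f"n_proteins must be 0 or >= {len(GATING_MARKERS)} (gating markers)"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["module_sizes"] = dict(self.module_sizes)
        return d


@dataclass
class CountsBundle:
    """Paired RNA and protein UMI count matrices with metadata.

    rna: (cells x genes) nonnegative integers; protein: (cells x proteins);
    cell_meta: DataFrame with cell_id, genotype, batch.
    """

    rna: np.ndarray
    protein: np.ndarray
    cell_meta: pd.DataFrame
    gene_names: list
    protein_names: list

    def __post_init__(self) -> None:
        if self.rna.shape != (len(self.cell_meta), len(self.gene_names)):
            raise ValueError("rna shape inconsistent with metadata")
        if self.protein.shape != (len(self.cell_meta), len(self.protein_names)):
            raise ValueError("protein shape inconsistent with metadata")

    @property
    def n_cells(self) -> int:
        return self.rna.shape[0]

    def subset_cells(self, mask: np.ndarray) -> "CountsBundle":
        return CountsBundle(
            rna=self.rna[mask],
            protein=self.protein[mask],
            cell_meta=self.cell_meta.loc[mask].reset_index(drop=True),
            gene_names=list(self.gene_names),
            protein_names=list(self.protein_names),
        )

    def subset_genes(self, keep: Sequence[str]) -> "CountsBundle":
        idx = [self.gene_names.index(g) for g in keep]
        return CountsBundle(
            rna=self.rna[:, idx],
            protein=self.protein,
            cell_meta=self.cell_meta,
            gene_names=list(keep),
            protein_names=list(self.protein_names),
        )


@dataclass
class GroundTruth:
    """Per-cell, per-gene and per-(gene, bin) truth for a simulated dataset.

    cells: cell_id, genotype, true_pseudotime, true_lineage, true_stage.
    genes: gene, program.
    de_direction: genes x bins frame; +1 = CD4-up, -1 = CD8-up, 0 = no
    between-lineage difference exceeding the effect-size floor on the
    log-normalised scale.
    tf_targets: planted TF name -> set of target gene names.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    de_direction: pd.DataFrame
    tf_targets: dict
    de_delta: pd.DataFrame = None   # underlying true median-log differences

    def program_genes(self, program: str) -> list:
        return list(self.genes.loc[self.genes["program"] == program, "gene"])


@dataclass
class TFTargetDB:
    """Named libraries of TF -> target-gene sets (GMT-style)."""

    libraries: dict  # library name -> {tf name -> frozenset of gene names}
    universe: frozenset

    def tf_names(self) -> list:
        names = set()
        for lib in self.libraries.values():
            names.update(lib)
        return sorted(names)


# ---------------------------------------------------------------------------
# temporal kernels


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _gauss(t, center, width):
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _clip_at_branch(values, value_at_branch):
    """Shift/clip a rising curve so it is exactly zero at and before the branch."""
    denom = max(1.0 - value_at_branch, 1e-12)
    return np.maximum(0.0, (values - value_at_branch) / denom)


def _asym_bump(t, peak, rise, decay):
    t = np.asarray(t, dtype=float)
    return np.where(
        t <= peak,
        np.exp(-0.5 * ((t - peak) / rise) ** 2),
        np.exp(-0.5 * ((t - peak) / decay) ** 2),
    )


def program_mean(t, lineage, program, params=None, *, t_span=(0.0, 12.0),
                 t_branch=3.0, amp=None, variant=None):
    """Expected linear-scale expression of one program at pseudotime ``t``.

    Parameters
    ----------
    t : scalar or array of pseudotime values within ``t_span``.
    lineage : "CD4" or "CD8".
    program : one of PROGRAMS or "background".
    params : kernel parameter mapping (defaults used when omitted).
    amp : per-gene amplitude; defaults to the midpoint of the program's range.
    variant : sub-kernel name for "lineage_TF_trio" ("gata3", "zbtb7b",
        "runx3") and "coreceptor" ("cd4", "cd8a").

    Lineage-dependent terms are constructed to vanish identically for
    ``t < t_branch``, so the two lineages agree exactly before the branch.
    """
    t = np.asarray(t, dtype=float)
    lo, hi = t_span
    if np.any(t < lo) or np.any(t > hi):
        raise ValueError(f"pseudotime outside t_span {t_span}")
    if lineage not in LINEAGES:
        raise ValueError(f"unknown lineage {lineage!r}")
    defaults = _default_kernel_params()
    p = dict(defaults.get(program, {}))
    if params is not None:
        p.update(params)

    def _amp(default_range):
        if amp is not None:
            return amp
        rng_lo, rng_hi = default_range
        return 0.5 * (rng_lo + rng_hi)

    if program == "constitutive":
        return np.full_like(t, _amp(p["amp"]))
    if program == "background":
        return np.full_like(t, _amp(p["amp"]))
    if program == "maturation_up":
        return p["base"] + _amp(p["amp"]) * _sigmoid((t - p["center"]) / p["width"])
    if program == "maturation_down":
        return p["base"] + _amp(p["amp"]) * _sigmoid(-(t - p["center"]) / p["width"])
    if program in ("wave1_shared", "wave1_sustained_CD4"):
        decay = p["decay_cd4"] if lineage == "CD4" else p["decay_cd8"]
        bump = _asym_bump(t, p["peak"], p["rise"], decay)
        return p["base"] + _amp(p["amp"]) * bump
    if program == "wave2_CD8":
        g = _gauss(t, p["center"], p["width"])
        gb = float(_gauss(np.array(t_branch), p["center"], p["width"]))
        h = _clip_at_branch(g, gb)
        mult = 1.0 if lineage == "CD8" else 0.0
        return p["base"] + _amp(p["amp"]) * h * mult
    if program == "lineage_TF_trio":
        if variant not in ("gata3", "zbtb7b", "runx3"):
            raise ValueError("lineage_TF_trio requires variant gata3|zbtb7b|runx3")
        q = defaults["lineage_TF_trio"][variant] | (params or {})
        a = amp if amp is not None else q["amp"]
        if variant == "gata3":
            decay = q["decay_cd4"] if lineage == "CD4" else q["decay_cd8"]
            return q["base"] + a * _asym_bump(t, q["peak"], q["rise"], decay)
        if variant == "zbtb7b":
            rise = _sigmoid((t - q["center"]) / q["width"])
            if lineage == "CD8":
                off = np.exp(-np.maximum(t - q["cd8_off"], 0.0) / q["cd8_tau"])
            else:
                off = 1.0
            return q["base"] + a * rise * off
        # runx3: clipped logistic, CD8 only
        s = _sigmoid((t - q["center"]) / q["width"])
        sb = float(_sigmoid((t_branch - q["center"]) / q["width"]))
        h = _clip_at_branch(s, sb)
        mult = 1.0 if lineage == "CD8" else 0.0
        return q["base"] + a * h * mult
    if program == "coreceptor":
        if variant not in ("cd4", "cd8a"):
            raise ValueError("coreceptor requires variant cd4|cd8a")
        q = defaults["coreceptor"][variant] | (params or {})
        a = amp if amp is not None else q["amp"]
        dip = q["dip_depth"] * _gauss(t, q["dip_center"], q["dip_width"])
        shared = 1.0 - dip
        if variant == "cd4":
            if lineage == "CD8":
                s = _sigmoid((t - q["cd8_off"]) / q["cd8_off_width"])
                sb = float(_sigmoid((t_branch - q["cd8_off"]) / q["cd8_off_width"]))
                shared = shared * (1.0 - 0.97 * _clip_at_branch(s, sb))
            return q["base"] + a * shared
        # cd8a
        if lineage == "CD4":
            s = _sigmoid((t - q["cd4_off"]) / q["cd4_off_width"])
            sb = float(_sigmoid((t_branch - q["cd4_off"]) / q["cd4_off_width"]))
            shared = shared * (1.0 - 0.97 * _clip_at_branch(s, sb))
        else:
            g = _gauss(t, q["cd8_dip_center"], q["cd8_dip_width"])
            gb = float(_gauss(np.array(t_branch), q["cd8_dip_center"],
                              q["cd8_dip_width"]))
            shared = shared * (1.0 - q["cd8_dip_depth"] * _clip_at_branch(g, gb))
        return q["base"] + a * shared
    raise ValueError(f"unknown program {program!r}")


# ---------------------------------------------------------------------------
# gene table construction


def _build_gene_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign programs, names and per-gene amplitudes/variants."""
    rows = []
    sizes = dict(config.module_sizes)
    kp = config.kernel_params

    def amp_draw(program, n):
        rng_lo, rng_hi = kp.get(program, _default_kernel_params()[program])["amp"]
        return rng.uniform(rng_lo, rng_hi, size=n)

    for program in PROGRAMS:
        n = sizes.get(program, 0)
        if n == 0:
            continue
        if program == "lineage_TF_trio" and n:
            if n != 3:
                raise SimConfigError("lineage_TF_trio size must be 3 (Gata3, Zbtb7b, Runx3)")
            for name, variant in (("Gata3", "gata3"), ("Zbtb7b", "zbtb7b"),
                                  ("Runx3", "runx3")):
                rows.append({"gene": name, "program": program, "variant": variant,
                             "amp": kp["lineage_TF_trio"][variant]["amp"]})
            continue
        if program == "coreceptor" and n:
            if n != 2:
                raise SimConfigError("coreceptor size must be 2 (Cd4, Cd8a)")
            for name, variant in (("Cd4", "cd4"), ("Cd8a", "cd8a")):
                rows.append({"gene": name, "program": program, "variant": variant,
                             "amp": kp["coreceptor"][variant]["amp"]})
            continue
        amps = amp_draw(program, n)
        for i in range(n):
            rows.append({"gene": f"{program}_{i:03d}", "program": program,
                         "variant": None, "amp": float(amps[i])})
    n_bg = config.n_genes - len(rows)
    amps = amp_draw("background", n_bg) if n_bg else []
    for i in range(n_bg):
        rows.append({"gene": f"background_{i:03d}", "program": "background",
                     "variant": None, "amp": float(amps[i])})
    return pd.DataFrame(rows)


def _gene_mean_matrix(t: np.ndarray, lineage: np.ndarray, genes: pd.DataFrame,
                      config: SimConfig) -> np.ndarray:
    """Expected counts (cells x genes) before library-size scaling."""
    n_cells = len(t)
    mean = np.zeros((n_cells, len(genes)))
    for lin in LINEAGES:
        mask = lineage == lin
        if not mask.any():
            continue
        tt = t[mask]
        for j, row in enumerate(genes.itertuples()):
            mean[mask, j] = program_mean(
                tt, lin, row.program,
                params=config.kernel_params.get(row.program)
                if row.program not in ("lineage_TF_trio", "coreceptor") else None,
                t_span=config.t_span, t_branch=config.t_branch,
                amp=row.amp, variant=row.variant,
            )
    return mean


# ---------------------------------------------------------------------------
# protein (ADT) model


def _marker_level(t, lineage, marker, t_branch=3.0):
    """Foreground activation level in [0, 1] for each gating marker.

    Steps are logistic with width 0.15 pseudotime units; lineage-dependent
    steps are clipped so both lineages agree exactly before the branch.
    """
    t = np.asarray(t, dtype=float)
    w = 0.15

    def step(a):
        return _sigmoid((t - a) / w)

    def cstep(a):
        s = _sigmoid((t - a) / w)
        sb = float(_sigmoid((t_branch - a) / w))
        return _clip_at_branch(s, sb)

    s1, s2, s3, s4, s5 = STAGE_CUTS
    if marker == "CD4":
        return np.ones_like(t) if lineage == "CD4" else 1.0 - cstep(s4)
    if marker == "CD8a":
        shared = 1.0 - 0.75 * step(s2)
        if lineage == "CD4":
            return np.clip(shared - 0.25 * cstep(s3), 0.0, 1.0)
        return np.clip(shared + 0.75 * cstep(s3), 0.0, 1.0)
    if marker == "TCRb":
        return 0.15 + 0.85 * step(s2)
    if marker == "CD69":
        off = cstep(s4) if lineage == "CD4" else cstep(s5)
        return np.clip(step(s1) - off, 0.0, 1.0)
    if marker == "CD127":
        return step(s3)
    raise ValueError(f"unknown marker {marker!r}")


def _protein_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = [{"protein": m, "kind": "marker"} for m in GATING_MARKERS]
    n_decoy = config.n_proteins - len(rows)
    levels = rng.uniform(0.2, 1.0, size=max(n_decoy, 0))
    for i in range(n_decoy):
        rows.append({"protein": f"ADT_decoy_{i:02d}", "kind": "decoy",
                     "level": float(levels[i])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage labels and truth tables


def true_stage(t, lineage, t_span=(0.0, 12.0)):
    """Ground-truth gate label for pseudotime ``t`` in the given lineage.

    Stages are a nondecreasing step function of pseudotime within a lineage,
    with cut points at 4, 6, 8, 10 (and 11 for the CD8 lineage) on the
    default [0, 12] span.
    """
    t = np.asarray(t, dtype=float)
    s1, s2, s3, s4, s5 = STAGE_CUTS
    out = np.empty(t.shape, dtype=object)
    out[t < s1] = "DP1"
    out[(t >= s1) & (t < s2)] = "DP2"
    out[(t >= s2) & (t < s3)] = "CD4+CD8lo"
    late = t >= s3
    if lineage == "CD4":
        out[late & (t < s4)] = "CD4 SM"
        out[t >= s4] = "CD4 Mature"
    else:
        out[late & (t < s4)] = "DP3"
        out[(t >= s4) & (t < s5)] = "CD8 SM"
        out[t >= s5] = "CD8 Mature"
    return out


def _expected_lognorm(genes: pd.DataFrame, config: SimConfig, target_sum=1e4,
                      grid_per_bin=9):
    """Per-(gene, bin) true between-lineage difference tables.

    The DE tests run on denoised expression (a smooth fit of log1p-normalised
    counts over the latent manifold), whose per-cell values estimate
    E[log1p(scaled count)] at the cell's (pseudotime, lineage) position.  The
    ground-truth tables therefore hold that expectation under the NB model,
    averaged over each unit pseudotime bin.  Returns (direction frame with
    the 0.2 effect-size floor, delta frame of the underlying differences).
    """
    from scipy.stats import nbinom

    lo, hi = config.t_span
    n_bins = int(np.ceil(hi - lo))
    disp = config.nb_dispersion
    r = 1.0 / disp
    vals = {}
    for lin in LINEAGES:
        kernel_lin = lin if config.lineage_effects else LINEAGES[0]
        per_bin = np.zeros((len(genes), n_bins))
        for b in range(n_bins):
            tt = np.linspace(lo + b + 0.05, min(lo + b + 0.95, hi), grid_per_bin)
            m = _gene_mean_matrix(tt, np.array([kernel_lin] * len(tt)), genes,
                                  config)
            totals = m.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            scale = target_sum / totals.mean()
            hi_count = max(int(np.ceil(m.max() * 4 + 20)), 4)
            xs = np.arange(hi_count)
            log_vals = np.log1p(scale * xs)
            # E[log1p(scale * c)] under NB(mean, dispersion), grid-averaged
            p = r / (r + np.maximum(m, 1e-12))          # (grid, genes)
            expect = np.zeros(m.shape[1])
            for j in range(m.shape[1]):
                pmf = nbinom.pmf(xs[None, :], r, p[:, j][:, None])
                expect[j] = float((pmf * log_vals[None, :]).sum(axis=1).mean())
            per_bin[:, b] = expect
        vals[lin] = per_bin
    delta = vals["CD4"] - vals["CD8"]
    directions = np.zeros_like(delta, dtype=int)
    directions[delta > 0.2] = 1
    directions[delta < -0.2] = -1
    gene_names = genes["gene"].to_numpy()
    cols = list(range(n_bins))
    return (pd.DataFrame(directions, index=gene_names, columns=cols),
            pd.DataFrame(delta, index=gene_names, columns=cols))


# ---------------------------------------------------------------------------
# main entry points


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, scale=mean[pos] * dispersion)
        out[pos] = rng.poisson(lam)
    return out


def simulate_dataset(config: SimConfig):
    """Draw one (CountsBundle, GroundTruth) pair from the generative model.

    Cells receive a true pseudotime uniform on t_span; lineage comes from the
    genotype (unassigned genotypes are split 50/50 at random).  RNA counts are
    NB with mean = library-factor x program kernel; protein counts are NB
    background + NB foreground scaled by the marker's stage-activation level.
    Identical seeds give byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.t_span

    # cells -----------------------------------------------------------------
    cell_rows = []
    for geno, expected in config.genotypes:
        n = config.n_cells_per_genotype
        t = rng.uniform(lo, hi, size=n)
        if expected == "unassigned":
            lineage = np.where(rng.random(n) < 0.5, "CD4", "CD8")
        else:
            lineage = np.array([expected] * n, dtype=object)
        for i in range(n):
            cell_rows.append({"genotype": geno, "true_pseudotime": t[i],
                              "true_lineage": lineage[i]})
    cells = pd.DataFrame(cell_rows, columns=["genotype", "true_pseudotime",
                                             "true_lineage"])
    cells.insert(0, "cell_id", [f"cell_{i:05d}" for i in range(len(cells))])
    cells["batch"] = "batch0"
    n_cells = len(cells)

    genes = _build_gene_table(config, rng)
    prot = _protein_table(config, rng)

    t = cells["true_pseudotime"].to_numpy() if n_cells else np.zeros(0)
    lineage = cells["true_lineage"].to_numpy() if n_cells else np.zeros(0, dtype=object)

    # RNA counts ------------------------------------------------------------
    mu_ls, sd_ls = config.libsize_lognormal
    libfac = np.exp(rng.normal(mu_ls, sd_ls, size=n_cells))
    kernel_lineage = lineage if config.lineage_effects else \
        np.array(["CD4"] * n_cells, dtype=object)
    mean_rna = _gene_mean_matrix(t, kernel_lineage, genes, config) if n_cells else \
        np.zeros((0, len(genes)))
    mean_rna = mean_rna * libfac[:, None] if n_cells else mean_rna
    rna = _nb_draw(rng, mean_rna, config.nb_dispersion)

    # protein counts --------------------------------------------------------
    bg_mean, fg_fold = config.protein_bg
    libfac_p = np.exp(rng.normal(0.0, 0.15, size=n_cells))
    prot_counts = np.zeros((n_cells, len(prot)), dtype=np.int64)
    for j, row in enumerate(prot.itertuples()):
        if row.kind == "marker":
            level = np.zeros(n_cells)
            for lin in LINEAGES:
                mask = kernel_lineage == lin
                if mask.any():
                    level[mask] = _marker_level(t[mask], lin, row.protein,
                                                config.t_branch)
        else:
            level = np.full(n_cells, row.level)
        bg = _nb_draw(rng, bg_mean * libfac_p, config.protein_dispersion)
        fg = _nb_draw(rng, bg_mean * fg_fold * level * libfac_p,
                      config.protein_dispersion)
        prot_counts[:, j] = bg + fg

    bundle = CountsBundle(
        rna=rna, protein=prot_counts,
        cell_meta=cells[["cell_id", "genotype", "batch"]].copy(),
        gene_names=list(genes["gene"]),
        protein_names=list(prot["protein"]),
    )

    # ground truth ----------------------------------------------------------
    stage = np.empty(n_cells, dtype=object)
    for lin in LINEAGES:
        mask = kernel_lineage == lin
        if mask.any():
            stage[mask] = true_stage(t[mask], lin, config.t_span)
    truth_cells = cells.copy()
    truth_cells["true_stage"] = stage if n_cells else pd.Series(dtype=object)

    de_dir, de_delta = _expected_lognorm(genes, config)

    tf_targets = {}
    for tf, program in PLANTED_TFS.items():
        targets = set(genes.loc[genes["program"] == program, "gene"])
        if tf == "Nfatc2":
            targets.add("Gata3")  # the NFAT-driven audition program includes Gata3
        if len(targets) >= 5:
            tf_targets[tf] = frozenset(targets)

    truth = GroundTruth(
        cells=truth_cells,
        genes=genes[["gene", "program"]].copy(),
        de_direction=de_dir,
        tf_targets=tf_targets,
        de_delta=de_delta,
    )
    return bundle, truth


def make_tf_target_db(truth: GroundTruth, n_decoy_tfs: int = 50,
                      n_libraries: int = 3, seed: int = 0) -> TFTargetDB:
    """Build ChEA3-style TF -> target libraries around the planted truth.

    Planted TFs receive target sets overlapping their true program genes
    (85% of the program plus a few random genes, independently per library);
    decoy TFs (named after expressed non-program genes so their detection
    fraction is measurable) receive uniformly drawn target sets.
    """
    if n_decoy_tfs < 0:
        raise ValueError("n_decoy_tfs must be >= 0")
    if not truth.tf_targets:
        raise ValueError("ground truth contains no planted TFs")
    rng = np.random.default_rng(seed)
    universe = list(truth.genes["gene"])
    pool = truth.genes.loc[
        truth.genes["program"].isin(["background", "constitutive"]), "gene"
    ].tolist()
    decoy_names = list(rng.choice(pool, size=min(n_decoy_tfs, len(pool)),
                                  replace=False))
    libraries = {}
    for li in range(n_libraries):
        lib = {}
        for tf, targets in truth.tf_targets.items():
            targets = sorted(targets)
            keep = max(5, int(round(0.85 * len(targets))))
            chosen = set(rng.choice(targets, size=min(keep, len(targets)),
                                    replace=False))
            extra = rng.choice(universe, size=3, replace=False)
            lib[tf] = frozenset(chosen | set(extra))
        for name in decoy_names:
            size = int(rng.integers(10, 41))
            lib[name] = frozenset(rng.choice(universe, size=size, replace=False))
        libraries[f"library_{li}"] = lib
    return TFTargetDB(libraries=libraries, universe=frozenset(universe))
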