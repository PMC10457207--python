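"""Readers/writers for the plain-text formats the pipeline exchanges.

Counts travel as MatrixMarket (MTX) plus feature/barcode TSVs, gene-set
libraries as GMT, configuration echoes as JSON.  Every writer directory gets
a manifest recording the seed and a hash of the generating configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simdata import CountsBundle, GroundTruth, TFTargetDB


def config_hash(config_dict: dict) -> str:
    payload = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(outdir, seed, config_dict, extra=None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": int(seed), "config_hash": config_hash(config_dict)}
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_counts_bundle(bundle: CountsBundle, outdir) -> None:
    """MTX + TSV layout: rna.mtx / protein.mtx, features and barcodes TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "rna.mtx"), sparse.csr_matrix(bundle.rna))
    spio.mmwrite(str(outdir / "protein.mtx"), sparse.csr_matrix(bundle.protein))
    pd.Series(bundle.gene_names, name="gene").to_csv(
        outdir / "genes.tsv", sep="\t", index=False)
    pd.Series(bundle.protein_names, name="protein").to_csv(
        outdir / "proteins.tsv", sep="\t", index=False)
    bundle.cell_meta.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_counts_bundle(indir) -> CountsBundle:
    indir = Path(indir)
    rna = np.asarray(spio.mmread(str(indir / "rna.mtx")).todense()).astype(np.int64)
    protein = np.asarray(spio.mmread(str(indir / "protein.mtx")).todense()).astype(np.int64)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene"].tolist()
    proteins = pd.read_csv(indir / "proteins.tsv", sep="\t")["protein"].tolist()
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    return CountsBundle(rna=rna, protein=protein, cell_meta=cells,
                        gene_names=genes, protein_names=proteins)


def write_ground_truth(truth: GroundTruth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    truth.de_direction.to_csv(outdir / "truth_de_direction.tsv", sep="\t")
    write_gmt({"planted": truth.tf_targets}, outdir / "truth_tf_targets.gmt")


def write_gmt(libraries: dict, path) -> None:
    """GMT: one line per set -- name <tab> description <tab> genes..."""
    path = Path(path)
    lines = []
    for lib_name in sorted(libraries):
        for tf in sorted(libraries[lib_name]):
            genes = "\t".join(sorted(libraries[lib_name][tf]))
            lines.append(f"{tf}\t{lib_name}\t{genes}")
    path.write_text("\n".join(lines) + "\n")


def read_gmt(path) -> dict:
    """Inverse of write_gmt: returns {library name -> {tf -> frozenset}}."""
    libraries: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        tf, lib_name, genes = parts[0], parts[1], parts[2:]
        libraries.setdefault(lib_name, {})[tf] = frozenset(genes)
    return libraries


def write_tf_db(db: TFTargetDB, path) -> None:
    write_gmt(db.libraries, path)


def read_tf_db(path) -> TFTargetDB:
    libraries = read_gmt(path)
    universe = set()
    for lib in libraries.values():
        for targets in lib.values():
            universe.update(targets)
    return TFTargetDB(libraries=libraries, universe=frozenset(universe))
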