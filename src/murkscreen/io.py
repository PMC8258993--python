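"""On-disk dataset archives: Matrix Market layers + TSV metadata + manifest.

Layout of an archive directory::

    spliced.mtx     Matrix Market coordinate, 1-based; integer for raw counts
    unspliced.mtx   same shape and dialect
    genes.tsv       gene_id [, is_murk, true_alpha1, true_alpha2, true_beta, true_gamma]
    cells.tsv       cell_id, latent_time, population, genotype
    manifest.json   stage, seed, config hash, package version, population order

The language-agnostic text formats round-trip raw count archives bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__
from .containers import PairedLayers, make_cell_table
from .errors import DataFormatError


def _validate_mtx(path: Path) -> None:
    """Light structural checks before delegating to scipy: coordinate header,
    1-based indices, body length matching the declared nnz."""
    header_seen = False
    dims = None
    n_entries = 0
    min_index = None
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("%%MatrixMarket matrix coordinate"):
            raise DataFormatError(f"{path.name}: not a coordinate MatrixMarket file")
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            parts = line.split()
            if not header_seen:
                if len(parts) != 3:
                    raise DataFormatError(f"{path.name}: malformed size line {line!r}")
                dims = tuple(int(x) for x in parts)
                header_seen = True
                continue
            n_entries += 1
            i, j = int(parts[0]), int(parts[1])
            lo = min(i, j)
            min_index = lo if min_index is None else min(min_index, lo)
    if dims is None:
        raise DataFormatError(f"{path.name}: missing size header")
    if n_entries != dims[2]:
        raise DataFormatError(
            f"{path.name}: header declares {dims[2]} entries but body has {n_entries}"
        )
    if min_index is not None and min_index < 1:
        raise DataFormatError(f"{path.name}: 0-based indices; MatrixMarket must be 1-based")


def _read_mtx(path: Path) -> np.ndarray:
    if not path.exists():
        raise DataFormatError(f"missing layer file {path}")
    _validate_mtx(path)
    try:
        M = scipy.io.mmread(path)
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise DataFormatError(f"{path.name}: {exc}") from exc
    return np.asarray(M.todense()) if sp.issparse(M) else np.asarray(M)


def write_dataset(
    path,
    layers: PairedLayers,
    cells: pd.DataFrame,
    gene_meta: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
) -> Path:
    """Persist an archive directory; integer MTX for raw counts, real otherwise."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    field = "integer" if layers.stage == "raw_counts" else "real"
    for name, M in (("unspliced", layers.U), ("spliced", layers.S)):
        scipy.io.mmwrite(
            path / f"{name}.mtx",
            sp.coo_matrix(M),
            field=field,
            precision=None if field == "integer" else 17,
        )
    if gene_meta is None:
        gene_meta = pd.DataFrame({"gene_id": layers.gene_ids})
    gene_meta.to_csv(path / "genes.tsv", sep="\t", index=False)
    cells.to_csv(path / "cells.tsv", sep="\t", index=False)
    manifest = {
        "stage": layers.stage,
        "n_cells": layers.n_cells,
        "n_genes": layers.n_genes,
        "seed": seed,
        "config_hash": config_hash,
        "population_order": list(cells["population"].cat.categories),
        "package_version": __version__,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def read_dataset(path):
    """Load an archive; returns (PairedLayers, cell table, gene metadata)."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise DataFormatError(f"missing manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    U = _read_mtx(path / "unspliced.mtx")
    S = _read_mtx(path / "spliced.mtx")
    genes = pd.read_csv(path / "genes.tsv", sep="\t", float_precision="round_trip")
    cells_raw = pd.read_csv(path / "cells.tsv", sep="\t", float_precision="round_trip")
    if "gene_id" not in genes.columns:
        raise DataFormatError("genes.tsv lacks a gene_id column")
    for col in ("cell_id", "latent_time", "population", "genotype"):
        if col not in cells_raw.columns:
            raise DataFormatError(f"cells.tsv lacks a {col} column")
    if genes["gene_id"].duplicated().any():
        raise DataFormatError("duplicate gene identifiers in genes.tsv")
    if cells_raw["cell_id"].duplicated().any():
        raise DataFormatError("duplicate cell identifiers in cells.tsv")
    if U.shape != S.shape:
        raise DataFormatError(f"layer shape mismatch: {U.shape} vs {S.shape}")
    if U.shape != (len(cells_raw), len(genes)):
        raise DataFormatError(
            f"matrix shape {U.shape} inconsistent with metadata "
            f"({len(cells_raw)} cells, {len(genes)} genes)"
        )
    stage = manifest.get("stage", "raw_counts")
    if stage == "raw_counts":
        U = U.astype(np.int64)
        S = S.astype(np.int64)
    cells = make_cell_table(
        cells_raw["cell_id"].astype(str),
        cells_raw["latent_time"].to_numpy(),
        cells_raw["population"].astype(str),
        manifest.get("population_order", sorted(cells_raw["population"].astype(str).unique())),
        cells_raw["genotype"].astype(str),
    )
    layers = PairedLayers(
        U=U,
        S=S,
        cell_ids=cells["cell_id"],
        gene_ids=genes["gene_id"].astype(str),
        stage=stage,
    )
    return layers, cells, genes


def read_gene_list(path) -> list[str]:
    """One identifier per line; a first line named 'gene_id' or 'gene' is a header."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].lower() in ("gene_id", "gene", "symbol"):
        lines = lines[1:]
    return lines


def config_hash(obj) -> str:
    """Stable short hash of a config mapping for the manifest."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
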