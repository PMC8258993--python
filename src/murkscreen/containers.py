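"""In-memory containers shared by every stage of the pipeline.

The central object is :class:`PairedLayers`: matched unspliced (U) and spliced
(S) matrices over the same cells x genes, tagged with the processing stage
(``raw_counts`` -> ``normalized`` -> ``imputed``).  Cell metadata (latent time,
ordered population label, genotype) travels in a plain pandas DataFrame built
by :func:`make_cell_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

STAGES = ("raw_counts", "normalized", "imputed")

#: canonical column order of a cell table
CELL_COLUMNS = ("cell_id", "latent_time", "population", "genotype")


@dataclass
class PairedLayers:
    """Matched unspliced/spliced matrices over identical cell and gene index sets.

    Parameters
    ----------
    U, S
        Dense ``(n_cells, n_genes)`` arrays of unspliced / spliced values.
    cell_ids, gene_ids
        Identifier sequences; lengths must match the matrix shape.
    stage
        One of ``raw_counts``, ``normalized``, ``imputed``.  Raw counts must be
        non-negative integers.
    """

    U: np.ndarray
    S: np.ndarray
    cell_ids: pd.Index
    gene_ids: pd.Index
    stage: str = "raw_counts"

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U)
        self.S = np.asarray(self.S)
        self.cell_ids = pd.Index(self.cell_ids)
        self.gene_ids = pd.Index(self.gene_ids)
        if self.U.shape != self.S.shape:
            raise InvalidParameterError(
                f"U and S shapes differ: {self.U.shape} vs {self.S.shape}"
            )
        if self.U.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise InvalidParameterError(
                f"matrix shape {self.U.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.stage not in STAGES:
            raise InvalidParameterError(f"unknown stage {self.stage!r}")
        if self.stage == "raw_counts":
            for name, M in (("U", self.U), ("S", self.S)):
                if np.any(M < 0):
                    raise InvalidParameterError(f"raw {name} counts contain negatives")
        if not self.cell_ids.is_unique or not self.gene_ids.is_unique:
            raise InvalidParameterError("duplicate cell or gene identifiers")

    @property
    def n_cells(self) -> int:
        return self.U.shape[0]

    @property
    def n_genes(self) -> int:
        return self.U.shape[1]

    def subset_genes(self, mask_or_ids) -> "PairedLayers":
        """Return a new PairedLayers restricted to a boolean mask or list of gene ids."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            mask = mask_or_ids
        else:
            mask = self.gene_ids.isin(pd.Index(mask_or_ids))
        return replace(
            self,
            U=self.U[:, mask],
            S=self.S[:, mask],
            gene_ids=self.gene_ids[mask],
        )

    def subset_cells(self, mask: np.ndarray) -> "PairedLayers":
        return replace(
            self,
            U=self.U[mask, :],
            S=self.S[mask, :],
            cell_ids=self.cell_ids[mask],
        )

    def with_stage(self, U: np.ndarray, S: np.ndarray, stage: str) -> "PairedLayers":
        return replace(self, U=U, S=S, stage=stage)


def make_cell_table(
    cell_ids: Sequence[str],
    latent_time: np.ndarray,
    populations: Sequence[str],
    population_order: Sequence[str],
    genotype: Sequence[str],
) -> pd.DataFrame:
    """Assemble the per-cell metadata table with an ordered population categorical."""
    t = np.asarray(latent_time, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise InvalidParameterError("latent_time must lie in [0, 1]")
    geno = pd.Categorical(genotype, categories=["WT", "KO"])
    if geno.isna().any():
        raise InvalidParameterError("genotype must be 'WT' or 'KO'")
    return pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "latent_time": t,
            "population": pd.Categorical(
                populations, categories=list(population_order), ordered=True
            ),
            "genotype": geno,
        }
    )


def assign_populations(
    latent_time: np.ndarray,
    breakpoints: Sequence[float],
    names: Sequence[str],
) -> np.ndarray:
    """Map latent times onto ordered population labels via cut points.

    ``breakpoints`` are the interior boundaries; ``names`` has one more entry.
    Cells with t exactly on a boundary join the later population.
    """
    bp = np.asarray(breakpoints, dtype=float)
    if len(names) != len(bp) + 1:
        raise InvalidParameterError("need len(names) == len(breakpoints) + 1")
    if np.any(np.diff(bp) <= 0) or np.any((bp <= 0) | (bp >= 1)):
        raise InvalidParameterError("breakpoints must be strictly increasing in (0,1)")
    idx = np.searchsorted(bp, np.asarray(latent_time, dtype=float), side="right")
    return np.asarray(names, dtype=object)[idx]
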