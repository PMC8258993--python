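"""Steady-state RNA velocity and a trajectory-direction score.

A deliberately simple estimator: per gene, the steady-state line slope
``gamma_hat`` is fit through the origin on the cells in the extreme quantiles
of spliced expression, and velocity is the residual v = u - gamma_hat * s.
Positive v means the cell sits above the steady-state line (the gene is being
induced); negative v, below (repression).

The direction score asks whether the velocity field points forward along the
known latent time: for each cell, cosine similarities between its velocity
vector (in the retained-gene expression space) and the displacement vectors to
its graph neighbours are softmax-converted to transition weights, and the
weighted mean sign of the neighbours' latent-time offsets is averaged over
cells.  +1 means velocity always points at later cells, -1 at earlier cells.
This is the apparatus used to show that genes with a late transcription boost
flip the inferred direction and that removing them restores it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PairedLayers
from .errors import EmptyPanelError, InvalidParameterError
from .preprocess import NeighborGraph

logger = logging.getLogger(__name__)

#: minimum pooled extreme-quantile cells for a usable gamma fit
_MIN_EXTREME_CELLS = 10


@dataclass
class VelocityFit:
    """Per-gene steady-state fit and residual velocities."""

    gene_ids: pd.Index
    gamma_hat: np.ndarray  # (n_genes,)
    velocity: np.ndarray  # (n_cells, n_genes)
    retained: np.ndarray  # bool (n_genes,) — genes with a defined fit


def fit_gamma_steady_state(u: np.ndarray, s: np.ndarray, quantile: float = 0.05) -> float:
    """Through-origin OLS slope of u on s over the lower+upper `quantile`
    tails of s.  Returns NaN for degenerate extremes (no variation in s)."""
    s = np.asarray(s, dtype=float)
    u = np.asarray(u, dtype=float)
    if not 0 < quantile < 0.5:
        raise InvalidParameterError("quantile must be in (0, 0.5)")
    lo, hi = np.quantile(s, [quantile, 1 - quantile])
    mask = (s <= lo) | (s >= hi)
    if mask.sum() < _MIN_EXTREME_CELLS:
        mask = np.ones_like(s, dtype=bool)
    ss = float((s[mask] ** 2).sum())
    if ss <= 0 or np.isclose(s.max(), s.min()):
        return float("nan")
    return float((u[mask] * s[mask]).sum() / ss)


def fit_velocity(layers: PairedLayers, quantile: float = 0.05) -> VelocityFit:
    """Fit gamma_hat per gene and compute residual velocities on the imputed
    layers.  Genes with degenerate extremes are dropped (retained=False)."""
    n_genes = layers.n_genes
    gamma_hat = np.full(n_genes, np.nan)
    for j in range(n_genes):
        gamma_hat[j] = fit_gamma_steady_state(layers.U[:, j], layers.S[:, j], quantile)
    retained = np.isfinite(gamma_hat) & (gamma_hat >= 0)
    n_dropped = int((~retained).sum())
    if n_dropped:
        logger.info("%d genes dropped from velocity (degenerate steady-state fit)", n_dropped)
    velocity = layers.U - gamma_hat[None, :] * layers.S
    velocity[:, ~retained] = 0.0
    return VelocityFit(
        gene_ids=layers.gene_ids, gamma_hat=gamma_hat, velocity=velocity, retained=retained
    )


def compute_velocity(u: np.ndarray, s: np.ndarray, gamma_hat: float) -> np.ndarray:
    """Residual velocity v = u - gamma_hat * s per cell."""
    return np.asarray(u, dtype=float) - gamma_hat * np.asarray(s, dtype=float)


def direction_score(
    velocity: np.ndarray,
    expression: np.ndarray,
    latent_time: np.ndarray,
    graph: NeighborGraph,
    gene_mask: np.ndarray | None = None,
    chunk: int = 256,
) -> float:
    """Agreement in [-1, 1] between the velocity field and true latent time.

    ``expression`` is the (cells x genes) matrix in which neighbour
    displacements are measured (the imputed spliced layer).  ``gene_mask``
    restricts both velocity and displacement space to a gene panel.  Cells
    with an exactly zero velocity vector contribute 0.
    """
    V = np.asarray(velocity, dtype=float)
    X = np.asarray(expression, dtype=float)
    t = np.asarray(latent_time, dtype=float)
    if gene_mask is not None:
        gene_mask = np.asarray(gene_mask, dtype=bool)
        if not gene_mask.any():
            raise EmptyPanelError("gene_mask removes every gene")
        V = V[:, gene_mask]
        X = X[:, gene_mask]
    if V.shape != X.shape or V.shape[0] != graph.n_cells or t.shape[0] != V.shape[0]:
        raise InvalidParameterError("velocity/expression/graph/latent_time shapes disagree")

    n = V.shape[0]
    contributions = np.zeros(n)
    vnorm = np.linalg.norm(V, axis=1)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        idx = graph.indices[start:stop]  # (c, k)
        disp = X[idx] - X[start:stop, None, :]  # (c, k, g)
        dnorm = np.linalg.norm(disp, axis=2)
        dots = np.einsum("ckg,cg->ck", disp, V[start:stop])
        with np.errstate(divide="ignore", invalid="ignore"):
            cos = dots / (dnorm * vnorm[start:stop, None])
        cos = np.where(np.isfinite(cos), cos, 0.0)
        w = np.exp(cos - cos.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        signs = np.sign(t[idx] - t[start:stop, None])
        # subtract the uniform-weight baseline: neighbour sets need not be
        # time-symmetric (cells crowd where expression saturates), and without
        # centring the score measures sampling density, not velocity
        baseline = signs.mean(axis=1)
        contributions[start:stop] = (w * signs).sum(axis=1) - baseline
    contributions[vnorm == 0] = 0.0
    return float(np.clip(contributions.mean(), -1.0, 1.0))
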