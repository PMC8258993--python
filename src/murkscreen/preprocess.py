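"""Gene filtering, per-layer normalization and kNN moment imputation.

These are the standard preparation steps the slope screen regresses on:
genes with fewer than ``min_shared_counts`` (default 20) shared counts between
the spliced and unspliced layers are dropped; each layer is scaled per cell by
its own median-ratio size factor and log1p-transformed; and each cell's value
is replaced by the mean over itself and its ``k_neighbors`` (default 30)
nearest neighbours in a PCA embedding of the spliced layer (first-order
moments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import PairedLayers
from .errors import ConfigError, EmptyPanelError, InvalidParameterError


@dataclass
class PreprocessConfig:
    min_shared_counts: int = 20
    n_top_hvg: Optional[int] = None  # None = keep all genes
    k_neighbors: int = 30
    n_pca: int = 30
    neighbor_source: str = "pca_on_spliced"  # or "provided_embedding"
    seed: int = 0

    def validate(self, n_cells: Optional[int] = None, n_genes: Optional[int] = None) -> None:
        if self.min_shared_counts < 0:
            raise ConfigError("min_shared_counts must be >= 0")
        if self.k_neighbors < 1:
            raise ConfigError("k_neighbors must be >= 1")
        if self.n_pca < 1:
            raise ConfigError("n_pca must be >= 1")
        if self.neighbor_source not in ("pca_on_spliced", "provided_embedding"):
            raise ConfigError(f"unknown neighbor_source {self.neighbor_source!r}")
        if n_cells is not None and self.k_neighbors >= n_cells:
            raise ConfigError("k_neighbors must be < n_cells")


@dataclass
class NeighborGraph:
    """Per-cell neighbour indices and distances, self excluded from the k."""

    indices: np.ndarray  # (n_cells, k)
    distances: np.ndarray  # (n_cells, k)
    self_included: bool = False

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]

    @property
    def k(self) -> int:
        return self.indices.shape[1]


def shared_counts(layers: PairedLayers) -> np.ndarray:
    """Per-gene shared-count score: min(spliced sum, unspliced sum) over the
    cells that express the gene in BOTH layers."""
    both = (layers.U > 0) & (layers.S > 0)
    s_sum = np.where(both, layers.S, 0).sum(axis=0)
    u_sum = np.where(both, layers.U, 0).sum(axis=0)
    return np.minimum(s_sum, u_sum)


def filter_genes_shared_counts(layers: PairedLayers, min_shared_counts: int = 20) -> PairedLayers:
    """Drop genes whose shared-count score falls below the threshold (gene
    order preserved)."""
    if layers.stage != "raw_counts":
        raise InvalidParameterError("shared-count filtering applies to raw counts")
    keep = shared_counts(layers) >= min_shared_counts
    if not keep.any():
        raise EmptyPanelError(
            f"no gene reaches {min_shared_counts} shared counts; panel is empty"
        )
    return layers.subset_genes(keep)


def select_hvg(layers: PairedLayers, n_top: int) -> PairedLayers:
    """Keep the n_top genes with highest dispersion (variance/mean of spliced
    counts).  Off by default for synthetic data; intended for real-data mode."""
    mean = layers.S.mean(axis=0)
    var = layers.S.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(disp)[::-1][:n_top]
    keep = np.zeros(layers.n_genes, dtype=bool)
    keep[order] = True
    return layers.subset_genes(keep)


def _layer_size_factors(M: np.ndarray) -> np.ndarray:
    totals = M.sum(axis=1).astype(float)
    positive = totals[totals > 0]
    if positive.size == 0:
        warnings.warn("layer has no counts; size factors set to 1", stacklevel=3)
        return np.ones_like(totals)
    med = np.median(positive)
    factors = totals / med
    if np.any(totals == 0):
        warnings.warn("cells with zero layer total get size factor 1", stacklevel=3)
        factors[totals == 0] = 1.0
    return factors


def normalize_layers(layers: PairedLayers) -> PairedLayers:
    """Median-ratio size-factor scaling per cell per layer, then log1p."""
    if layers.stage != "raw_counts":
        raise InvalidParameterError("normalize_layers expects raw counts")
    fu = _layer_size_factors(layers.U)
    fs = _layer_size_factors(layers.S)
    U = np.log1p(layers.U / fu[:, None])
    S = np.log1p(layers.S / fs[:, None])
    return layers.with_stage(U, S, "normalized")


def build_neighbor_graph(
    layers: PairedLayers,
    config: PreprocessConfig,
    embedding: Optional[np.ndarray] = None,
) -> NeighborGraph:
    """Euclidean kNN in a PCA embedding of the log-normalized spliced layer
    (or in a caller-provided embedding, e.g. precomputed UMAP coordinates).
    The cell itself is excluded from its k neighbours."""
    config.validate(n_cells=layers.n_cells)
    if layers.stage == "raw_counts":
        raise InvalidParameterError("build the graph on normalized layers")
    if config.neighbor_source == "provided_embedding" or embedding is not None:
        if embedding is None:
            raise ConfigError("neighbor_source='provided_embedding' but none given")
        X = np.asarray(embedding, dtype=float)
        if X.shape[0] != layers.n_cells:
            raise InvalidParameterError("embedding rows != n_cells")
    else:
        n_comp = min(config.n_pca, layers.n_cells - 1, layers.n_genes)
        X = PCA(n_components=n_comp, random_state=config.seed).fit_transform(layers.S)
    nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    # drop self wherever it appears among the k+1 (ties at distance 0 may put
    # it anywhere in the zero-distance block, or push it out entirely)
    n = X.shape[0]
    keep_idx = np.empty((n, config.k_neighbors), dtype=np.int64)
    keep_dist = np.empty((n, config.k_neighbors), dtype=float)
    for i in range(n):
        mask = idx[i] != i
        if mask.all():  # self displaced by duplicate points: drop farthest
            mask[-1] = False
        elif mask.sum() < config.k_neighbors:  # defensive; cannot happen
            raise RuntimeError("duplicate self in neighbor query")
        keep_idx[i] = idx[i, mask][: config.k_neighbors]
        keep_dist[i] = dist[i, mask][: config.k_neighbors]
    return NeighborGraph(indices=keep_idx, distances=keep_dist, self_included=False)


def knn_impute(layers: PairedLayers, graph: NeighborGraph) -> PairedLayers:
    """First-order moments: each value replaced by the unweighted mean over
    the cell itself and its k neighbours, identically in both layers."""
    if graph.n_cells != layers.n_cells:
        raise InvalidParameterError("graph and layers cover different cells")
    if layers.stage != "normalized":
        raise InvalidParameterError("impute normalized layers")
    n, k = graph.n_cells, graph.k
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate([np.arange(n)[:, None], graph.indices], axis=1).ravel()
    W = sp.csr_matrix(
        (np.full(n * (k + 1), 1.0 / (k + 1)), (rows, cols)), shape=(n, n)
    )
    return layers.with_stage(W @ layers.U, W @ layers.S, "imputed")


def preprocess(
    layers: PairedLayers,
    config: Optional[PreprocessConfig] = None,
    embedding: Optional[np.ndarray] = None,
) -> tuple[PairedLayers, NeighborGraph]:
    """Filter -> (optional HVG) -> normalize -> graph -> impute; returns the
    imputed layers and the graph for reuse downstream."""
    config = config or PreprocessConfig()
    filtered = filter_genes_shared_counts(layers, config.min_shared_counts)
    if config.n_top_hvg is not None and config.n_top_hvg < filtered.n_genes:
        filtered = select_hvg(filtered, config.n_top_hvg)
    normalized = normalize_layers(filtered)
    graph = build_neighbor_graph(normalized, config, embedding=embedding)
    imputed = knn_impute(normalized, graph)
    return imputed, graph
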