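"""Synthetic paired spliced/unspliced datasets along a differentiation trajectory.

The generator realizes the study scenario: cells ordered by a latent time in
[0, 1] and partitioned into ordered populations (Prog < Ery1 < Ery2 < Ery3 by
default), genes obeying first-order transcription/splicing/degradation
kinetics, and a designated MURK subset whose transcription rate steps up by
``boost_factor`` at ``switch_time``.  Knockout-genotype cells are evaluated
with the boost removed — the MURK genes simply never step up — while all other
genes behave identically in both genotypes.

Counts are Poisson around capture-scaled expected abundances; unspliced
capture defaults to 0.3 of spliced, reflecting the poor intron capture of
oligo-dT protocols.  Negative-binomial overdispersion is available via
``dispersion``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import PairedLayers, assign_populations, make_cell_table
from .errors import ConfigError
from .kinetics import GeneKinetics, propagate_regimes

DEFAULT_POPULATIONS = ("Prog", "Ery1", "Ery2", "Ery3")


@dataclass
class SimulationConfig:
    """Everything that determines a synthetic dataset, given the seed.

    ``rate_priors`` maps each rate to a uniform sampling range; the defaults
    put splicing/degradation timescales (1/beta, 1/gamma) at a fraction of the
    trajectory so a transcription boost late in the trajectory produces a
    visible unspliced-leads-spliced transient.  ``switch_time`` defaults to the
    boundary between the last two populations, where the erythroid boost sits.
    """

    n_cells: int = 4000
    n_genes: int = 500
    murk_fraction: float = 0.1
    boost_factor: float = 4.0
    switch_time: float = 0.75
    population_breakpoints: Sequence[float] = (0.25, 0.5, 0.75)
    population_names: Sequence[str] = DEFAULT_POPULATIONS
    rate_priors: dict = field(
        default_factory=lambda: {
            "alpha": (5.0, 20.0),
            "beta": (3.0, 8.0),
            "gamma": (0.5, 1.5),
        }
    )
    capture_scale_spliced: float = 1.0
    capture_scale_unspliced: float = 0.3
    dispersion: Optional[float] = None  # NB overdispersion; None = pure Poisson
    genotype_mix: float = 0.0  # fraction of KO cells
    initial_condition: str = "steady_state_of_first_regime"
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ConfigError("n_cells and n_genes must be positive")
        if not 0 <= self.murk_fraction <= 1:
            raise ConfigError("murk_fraction must be in [0, 1]")
        if self.boost_factor < 1:
            raise ConfigError("boost_factor must be >= 1")
        if not 0 < self.switch_time < 1:
            raise ConfigError("switch_time must be in (0, 1)")
        if not 0 <= self.genotype_mix <= 1:
            raise ConfigError("genotype_mix must be in [0, 1]")
        if len(self.population_names) != len(self.population_breakpoints) + 1:
            raise ConfigError("need one more population name than breakpoint")
        if self.capture_scale_unspliced > self.capture_scale_spliced:
            raise ConfigError("unspliced capture cannot exceed spliced capture")
        if self.capture_scale_spliced <= 0 or self.capture_scale_unspliced <= 0:
            raise ConfigError("capture scales must be > 0")
        for key in ("alpha", "beta", "gamma"):
            lo, hi = self.rate_priors[key]
            if not (0 < lo <= hi):
                raise ConfigError(f"rate prior for {key} must satisfy 0 < lo <= hi")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0 when set")
        if self.initial_condition not in ("steady_state_of_first_regime", "zero"):
            raise ConfigError(f"unknown initial_condition {self.initial_condition!r}")


def rescue_demo_config(seed: int = 0) -> SimulationConfig:
    """Pilot configuration for the velocity corruption-and-rescue demonstration.

    Genes are induced from zero along the trajectory (the classic phase-plot
    scenario), and the MURK program makes up a fifth of the panel — in real
    erythroid branches the variable-gene panel is dominated by the erythroid
    program, so a MURK-heavy panel is the regime where velocity corruption
    shows.  Splicing is fast relative to degradation (minutes vs hours), so a
    transcription boost sends unspliced counts up quickly while spliced counts
    lag: exactly the geometry that steepens the steady-state fit and flips
    velocities of mid-trajectory cells.
    """
    return SimulationConfig(
        n_cells=2000,
        n_genes=300,
        murk_fraction=0.2,
        boost_factor=4.0,
        initial_condition="zero",
        seed=seed,
    )


def draw_gene_kinetics(config: SimulationConfig, rng: np.random.Generator) -> list[GeneKinetics]:
    """Sample per-gene rates from the priors and flag the MURK subset.

    The first ``round(murk_fraction * n_genes)`` gene slots (after a seeded
    shuffle of indices) get a second regime with alpha boosted by
    ``boost_factor``; with boost_factor == 1 no gene is flagged.
    """
    n_murk = int(round(config.murk_fraction * config.n_genes))
    if n_murk == 0 and config.boost_factor > 1 and config.murk_fraction > 0:
        warnings.warn("murk_fraction rounds to zero MURK genes", stacklevel=2)
    murk_idx = set(rng.permutation(config.n_genes)[:n_murk].tolist())

    lo_a, hi_a = config.rate_priors["alpha"]
    lo_b, hi_b = config.rate_priors["beta"]
    lo_g, hi_g = config.rate_priors["gamma"]
    alphas = rng.uniform(lo_a, hi_a, size=config.n_genes)
    betas = rng.uniform(lo_b, hi_b, size=config.n_genes)
    gammas = rng.uniform(lo_g, hi_g, size=config.n_genes)

    width = len(str(config.n_genes - 1))
    genes = []
    for j in range(config.n_genes):
        boosted = j in murk_idx and config.boost_factor > 1
        if boosted:
            gk = GeneKinetics(
                gene_id=f"g{j:0{width}d}",
                alpha_regimes=(alphas[j], config.boost_factor * alphas[j]),
                switch_times=(config.switch_time,),
                beta=betas[j],
                gamma=gammas[j],
                is_murk=True,
            )
        else:
            gk = GeneKinetics(
                gene_id=f"g{j:0{width}d}",
                alpha_regimes=(alphas[j],),
                switch_times=(),
                beta=betas[j],
                gamma=gammas[j],
                is_murk=False,
            )
        genes.append(gk)
    return genes


def expected_abundances(
    genes: Sequence[GeneKinetics],
    latent_time: np.ndarray,
    genotype: Sequence[str],
    initial_condition: str = "steady_state_of_first_regime",
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expected (U, S) for every cell x gene.

    KO cells see each MURK gene with its boost removed (first-regime alpha
    throughout); non-MURK genes are genotype-independent.
    """
    t = np.asarray(latent_time, dtype=float)
    ko = np.asarray(genotype, dtype=object) == "KO"
    n, g = len(t), len(genes)
    U = np.empty((n, g))
    S = np.empty((n, g))
    for j, gene in enumerate(genes):
        u_wt, s_wt = propagate_regimes(gene, t, initial_condition)
        U[:, j], S[:, j] = u_wt, s_wt
        if gene.is_murk and ko.any():
            u_ko, s_ko = propagate_regimes(gene.without_boost(), t[ko], initial_condition)
            U[ko, j], S[ko, j] = u_ko, s_ko
    return U, S


def simulate_dataset(config: SimulationConfig):
    """Generate (PairedLayers raw_counts, cell table, list of GeneKinetics).

    Deterministic for identical config + seed: every stochastic draw flows
    from one ``numpy.random.default_rng(seed)`` in a fixed order (MURK gene
    placement, rates, latent times, genotypes, then count noise U before S).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = draw_gene_kinetics(config, rng)
    latent_time = rng.uniform(0.0, 1.0, size=config.n_cells)
    genotype = np.where(
        rng.uniform(size=config.n_cells) < config.genotype_mix, "KO", "WT"
    ).astype(object)

    populations = assign_populations(
        latent_time, config.population_breakpoints, config.population_names
    )
    width = len(str(config.n_cells - 1))
    cells = make_cell_table(
        [f"c{i:0{width}d}" for i in range(config.n_cells)],
        latent_time,
        populations,
        config.population_names,
        genotype,
    )

    EU, ES = expected_abundances(genes, latent_time, genotype, config.initial_condition)
    mean_u = config.capture_scale_unspliced * EU
    mean_s = config.capture_scale_spliced * ES
    if config.dispersion is None:
        U = rng.poisson(mean_u)
        S = rng.poisson(mean_s)
    else:
        # NB via gamma-Poisson mixture; variance = m + m^2 / dispersion
        r = config.dispersion
        U = rng.poisson(rng.gamma(r, mean_u / r))
        S = rng.poisson(rng.gamma(r, mean_s / r))

    layers = PairedLayers(
        U=U.astype(np.int64),
        S=S.astype(np.int64),
        cell_ids=cells["cell_id"],
        gene_ids=[g.gene_id for g in genes],
        stage="raw_counts",
    )
    return layers, cells, genes


def gene_metadata(genes: Sequence[GeneKinetics]) -> pd.DataFrame:
    """Ground-truth gene table for persistence alongside the layers."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "is_murk": [g.is_murk for g in genes],
            "true_alpha1": [g.alpha_regimes[0] for g in genes],
            "true_alpha2": [g.alpha_regimes[-1] for g in genes],
            "true_beta": [g.beta for g in genes],
            "true_gamma": [g.gamma for g in genes],
        }
    )
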