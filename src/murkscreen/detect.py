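"""MURK gene screen: per-population phase-plot slope regression and the
slope-increase test.

For every gene and every population along the trajectory, the unspliced values
are regressed on the spliced values (ordinary least squares with intercept) on
the normalized, imputed layers; the slope and its standard error are the
test's sufficient statistics.  A gene is called MURK when

* the slope in the designated late population is significantly higher than in
  the designated early population (one-sided Welch t-test, raw p < alpha —
  deliberately no multiple-testing correction),
* its mean imputed spliced expression in the late population is strictly the
  greatest over all populations, and
* the late-population slope is positive.

Called genes are ranked by the slope increase, descending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import PairedLayers
from .errors import InvalidParameterError

logger = logging.getLogger(__name__)

#: populations smaller than this are not fitted (slope SEs become unstable)
MIN_CELLS_PER_POPULATION = 20


@dataclass
class PopulationSlopeFit:
    """OLS fit of unspliced on spliced within one population, for one gene."""

    gene_id: str
    population: str
    slope: float
    se_slope: float
    n_cells: int
    mean_spliced: float


def fit_population_slopes(
    layers: PairedLayers,
    populations: Sequence[str],
    population_of_cell: np.ndarray,
    min_cells: int = MIN_CELLS_PER_POPULATION,
    fit_intercept: bool = True,
) -> pd.DataFrame:
    """Vectorized per-gene OLS over each population.

    Returns a long DataFrame with columns gene_id, population, slope,
    se_slope, n_cells, mean_spliced.  Genes with constant spliced values in a
    population get NaN slope/se (undefined fit) and are excluded from testing
    downstream.
    """
    if layers.stage != "imputed":
        logger.warning("slope regression is intended for imputed layers (stage=%s)", layers.stage)
    frames = []
    pop_arr = np.asarray(population_of_cell, dtype=object)
    for pop in populations:
        mask = pop_arr == pop
        n = int(mask.sum())
        if n < min_cells:
            logger.info("population %s has %d < %d cells; skipped", pop, n, min_cells)
            continue
        S = layers.S[mask]
        U = layers.U[mask]
        slope, se = _ols_slope_se(S, U, fit_intercept=fit_intercept)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": layers.gene_ids,
                    "population": pop,
                    "slope": slope,
                    "se_slope": se,
                    "n_cells": n,
                    "mean_spliced": S.mean(axis=0),
                }
            )
        )
    if not frames:
        raise InvalidParameterError("no population reaches the minimum cell count")
    return pd.concat(frames, ignore_index=True)


def _ols_slope_se(S: np.ndarray, U: np.ndarray, fit_intercept: bool = True):
    """Columnwise OLS slope of U on S with its standard error.

    With intercept: b = Sxy/Sxx, Var(b) = RSS/(n-2)/Sxx.  Through-origin:
    b = <SU>/<S^2>, Var(b) = RSS/(n-1)/<S^2>.  Columns with zero design
    variance return NaN.
    """
    n = S.shape[0]
    if fit_intercept:
        Sc = S - S.mean(axis=0)
        Uc = U - U.mean(axis=0)
        sxx = (Sc * Sc).sum(axis=0)
        sxy = (Sc * Uc).sum(axis=0)
        dof = n - 2
    else:
        Sc, Uc = S, U
        sxx = (Sc * Sc).sum(axis=0)
        sxy = (Sc * Uc).sum(axis=0)
        dof = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        rss = (Uc * Uc).sum(axis=0) - slope * sxy
        rss = np.maximum(rss, 0.0)  # guard tiny negative round-off
        se = np.sqrt(rss / max(dof, 1) / sxx)
    bad = sxx <= 0
    slope[bad] = np.nan
    se[bad] = np.nan
    return slope, se


def fit_population_slope(
    u: np.ndarray, s: np.ndarray, gene_id: str = "", population: str = "",
    fit_intercept: bool = True,
) -> PopulationSlopeFit:
    """Single-gene convenience wrapper around the vectorized fit."""
    u = np.asarray(u, dtype=float)[:, None]
    s = np.asarray(s, dtype=float)[:, None]
    slope, se = _ols_slope_se(s, u, fit_intercept=fit_intercept)
    return PopulationSlopeFit(
        gene_id=gene_id,
        population=population,
        slope=float(slope[0]),
        se_slope=float(se[0]),
        n_cells=u.shape[0],
        mean_spliced=float(s.mean()),
    )


def slope_increase_test(
    slope_late, se_late, n_late, slope_early, se_early, n_early,
    method: str = "welch",
):
    """One-sided p-value for slope_late > slope_early.

    T = (b_late - b_early) / sqrt(se_late^2 + se_early^2), referred to a t
    distribution with Welch-Satterthwaite degrees of freedom built from
    (se^2, n-2) of each fit (``method="normal"`` uses the standard normal
    instead).  Degenerate zero-SE cases: equal slopes -> 0.5; strictly larger
    late slope -> 0; smaller -> 1.
    """
    slope_late = np.asarray(slope_late, dtype=float)
    slope_early = np.asarray(slope_early, dtype=float)
    se_late = np.asarray(se_late, dtype=float)
    se_early = np.asarray(se_early, dtype=float)
    v = se_late**2 + se_early**2
    diff = slope_late - slope_early
    with np.errstate(divide="ignore", invalid="ignore"):
        T = diff / np.sqrt(v)
        if method == "welch":
            df = v**2 / (
                se_late**4 / np.maximum(np.asarray(n_late) - 2, 1)
                + se_early**4 / np.maximum(np.asarray(n_early) - 2, 1)
            )
            p = st.t.sf(T, df)
        elif method == "normal":
            p = st.norm.sf(T)
        else:
            raise InvalidParameterError(f"unknown test method {method!r}")
    # zero-SE degeneracies by convention
    p = np.where(v == 0, np.where(diff > 0, 0.0, np.where(diff < 0, 1.0, 0.5)), p)
    if p.ndim == 0:
        return float(p)
    return p


def call_murk_genes(
    fits: pd.DataFrame,
    early_pop: str,
    late_pop: str,
    alpha: float = 0.05,
    method: str = "welch",
) -> pd.DataFrame:
    """Apply the three MURK criteria to the long table of population slope fits.

    Returns one row per testable gene: p_value, slope_increase, the three
    criterion flags, is_murk (their conjunction) and rank (1..n_murk by
    slope_increase descending; NaN for non-called genes).  Genes whose early-
    or late-population fit is undefined (constant spliced values) are excluded
    and logged.
    """
    pops = fits["population"].unique().tolist()
    for pop in (early_pop, late_pop):
        if pop not in pops:
            raise InvalidParameterError(f"population {pop!r} missing from fits")

    wide_slope = fits.pivot(index="gene_id", columns="population", values="slope")
    wide_se = fits.pivot(index="gene_id", columns="population", values="se_slope")
    wide_mean = fits.pivot(index="gene_id", columns="population", values="mean_spliced")
    n_cells = fits.pivot(index="gene_id", columns="population", values="n_cells")

    ok = wide_slope[early_pop].notna() & wide_slope[late_pop].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%d genes excluded: undefined slope in early or late population", n_dropped)
    idx = wide_slope.index[ok]

    p = slope_increase_test(
        wide_slope.loc[idx, late_pop].to_numpy(),
        wide_se.loc[idx, late_pop].to_numpy(),
        n_cells.loc[idx, late_pop].to_numpy(),
        wide_slope.loc[idx, early_pop].to_numpy(),
        wide_se.loc[idx, early_pop].to_numpy(),
        n_cells.loc[idx, early_pop].to_numpy(),
        method=method,
    )
    slope_increase = (
        wide_slope.loc[idx, late_pop] - wide_slope.loc[idx, early_pop]
    ).to_numpy()

    other_pops = [pp for pp in pops if pp != late_pop]
    late_mean = wide_mean.loc[idx, late_pop].to_numpy()
    max_other = wide_mean.loc[idx, other_pops].max(axis=1).to_numpy()
    passes_max_expression = late_mean > max_other  # strict: ties break against
    passes_significance = p < alpha
    passes_positive_slope = wide_slope.loc[idx, late_pop].to_numpy() > 0
    is_murk = passes_significance & passes_max_expression & passes_positive_slope

    out = pd.DataFrame(
        {
            "gene_id": idx,
            "p_value": p,
            "slope_increase": slope_increase,
            "passes_significance": passes_significance,
            "passes_max_expression": passes_max_expression,
            "passes_positive_slope": passes_positive_slope,
            "is_murk": is_murk,
        }
    ).reset_index(drop=True)
    out["rank"] = np.nan
    called = out.index[out["is_murk"]]
    order = out.loc[called, "slope_increase"].sort_values(ascending=False).index
    out.loc[order, "rank"] = np.arange(1, len(order) + 1)
    return out


def detect_murk(
    layers: PairedLayers,
    cells: pd.DataFrame,
    early_pop: str,
    late_pop: str,
    alpha: float = 0.05,
    min_cells: int = MIN_CELLS_PER_POPULATION,
    method: str = "welch",
    fit_intercept: bool = True,
) -> pd.DataFrame:
    """End-to-end screen on imputed layers restricted to the cells given."""
    populations = list(cells["population"].cat.categories)
    fits = fit_population_slopes(
        layers,
        populations,
        cells["population"].to_numpy(dtype=object),
        min_cells=min_cells,
        fit_intercept=fit_intercept,
    )
    return call_murk_genes(fits, early_pop, late_pop, alpha=alpha, method=method)
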