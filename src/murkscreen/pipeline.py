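"""Run configuration and the simulate -> preprocess -> detect -> velocity ->
overlap pipeline with a machine-readable report."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .detect import detect_murk
from .errors import ConfigError, MurkscreenError, StageError
from .preprocess import PreprocessConfig, preprocess
from .simulate import SimulationConfig, gene_metadata, simulate_dataset
from .velocity import direction_score, fit_velocity

logger = logging.getLogger(__name__)


@dataclass
class DetectionConfig:
    early_pop: str = "Ery2"
    late_pop: str = "Ery3"
    alpha: float = 0.05
    min_cells: int = 20
    method: str = "welch"
    fit_intercept: bool = True

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.method not in ("welch", "normal"):
            raise ConfigError(f"unknown test method {self.method!r}")


@dataclass
class VelocityConfig:
    quantile: float = 0.05

    def validate(self) -> None:
        if not 0 < self.quantile < 0.5:
            raise ConfigError("quantile must be in (0, 0.5)")


@dataclass
class OverlapConfig:
    query_list: Optional[str] = None  # paths to gene list files
    reference_list: Optional[str] = None
    universe_list: Optional[str] = None

    def validate(self) -> None:
        given = [self.query_list, self.reference_list, self.universe_list]
        if any(given) and not all(given):
            raise ConfigError("overlap needs query, reference and universe lists together")


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    velocity: VelocityConfig = field(default_factory=VelocityConfig)
    overlap: OverlapConfig = field(default_factory=OverlapConfig)
    seed: int = 0
    outdir: str = "murkscreen_run"

    def __post_init__(self):
        # the global seed flows into every seeded stage
        self.simulation.seed = self.seed
        self.preprocess.seed = self.seed

    def validate(self) -> None:
        self.simulation.validate()
        self.preprocess.validate()
        self.detection.validate()
        self.velocity.validate()
        self.overlap.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_section(cls, data: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in section '{name}': {sorted(unknown)}")
    kw = dict(data)
    if "rate_priors" in kw and kw["rate_priors"] is not None:
        kw["rate_priors"] = {k: tuple(v) for k, v in kw["rate_priors"].items()}
    for tup_field in ("population_breakpoints", "population_names"):
        if tup_field in kw and kw[tup_field] is not None:
            kw[tup_field] = tuple(kw[tup_field])
    return cls(**kw)


def load_run_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return run_config_from_dict(data)


def run_config_from_dict(data: dict) -> RunConfig:
    sections = {
        "simulation": SimulationConfig,
        "preprocess": PreprocessConfig,
        "detection": DetectionConfig,
        "velocity": VelocityConfig,
        "overlap": OverlapConfig,
    }
    known_top = set(sections) | {"seed", "outdir"}
    unknown = set(data) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in sections.items():
        if name in data:
            if not isinstance(data[name], dict):
                raise ConfigError(f"section '{name}' must be a mapping")
            kwargs[name] = _build_section(cls, data[name], name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "outdir" in data:
        kwargs["outdir"] = str(data["outdir"])
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def run_pipeline(config: RunConfig, dataset_path: Optional[str] = None) -> dict:
    """Execute all stages, persisting each stage's outputs under config.outdir.

    If ``dataset_path`` is given, the raw archive is loaded from disk instead
    of simulated (real-data mode).  Returns the report dict; also written as
    report.json plus a human-readable summary.txt.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hashed = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    chash = mio.config_hash(hashed)
    report: dict = {"seed": config.seed, "config_hash": chash, "stages": {}}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except MurkscreenError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
        dt = time.perf_counter() - t0
        logger.info("stage %s finished in %.2fs", name, dt)
        report["stages"][name] = {"seconds": round(dt, 3)}
        return out

    # --- simulate (or load) ------------------------------------------------
    if dataset_path is None:
        def _sim():
            layers, cells, genes = simulate_dataset(config.simulation)
            mio.write_dataset(outdir / "raw", layers, cells, gene_metadata(genes),
                              seed=config.seed, config_hash=chash)
            return layers, cells, gene_metadata(genes)
        layers, cells, gmeta = _stage("simulate", _sim)
    else:
        layers, cells, gmeta = _stage("load", lambda: mio.read_dataset(dataset_path))
    report["n_cells"], report["n_genes"] = layers.n_cells, layers.n_genes

    # --- preprocess ---------------------------------------------------------
    def _prep():
        imputed, graph = preprocess(layers, config.preprocess)
        mio.write_dataset(outdir / "imputed", imputed, cells,
                          gmeta[gmeta["gene_id"].isin(imputed.gene_ids)].reset_index(drop=True),
                          seed=config.seed, config_hash=chash)
        return imputed, graph
    imputed, graph = _stage("preprocess", _prep)
    report["n_genes_after_filter"] = imputed.n_genes
    logger.info("%d/%d genes survive the shared-count filter",
                imputed.n_genes, layers.n_genes)

    # --- detect -------------------------------------------------------------
    def _detect():
        dec = detect_murk(
            imputed, cells,
            early_pop=config.detection.early_pop,
            late_pop=config.detection.late_pop,
            alpha=config.detection.alpha,
            min_cells=config.detection.min_cells,
            method=config.detection.method,
            fit_intercept=config.detection.fit_intercept,
        )
        dec.to_csv(outdir / "murk_decisions.tsv", sep="\t", index=False)
        return dec
    decisions = _stage("detect", _detect)
    murk_ids = decisions.loc[decisions["is_murk"], "gene_id"].tolist()
    report["n_murk"] = len(murk_ids)
    report["murk_fraction_of_tested"] = (
        len(murk_ids) / len(decisions) if len(decisions) else 0.0
    )

    # --- velocity + direction scores ----------------------------------------
    def _velocity():
        vfit = fit_velocity(imputed, quantile=config.velocity.quantile)
        t = cells["latent_time"].to_numpy()
        score_all = direction_score(
            vfit.velocity, imputed.S, t, graph, gene_mask=vfit.retained
        )
        keep = vfit.retained & ~np.asarray(imputed.gene_ids.isin(murk_ids))
        score_removed = direction_score(
            vfit.velocity, imputed.S, t, graph, gene_mask=keep
        )
        pd.DataFrame(
            {"gene_id": imputed.gene_ids, "gamma_hat": vfit.gamma_hat,
             "retained": vfit.retained}
        ).to_csv(outdir / "velocity_fits.tsv", sep="\t", index=False)
        return score_all, score_removed
    score_all, score_removed = _stage("velocity", _velocity)
    report["direction_score_all_genes"] = score_all
    report["direction_score_murk_removed"] = score_removed

    # --- overlap (optional) --------------------------------------------------
    if config.overlap.query_list:
        from .overlap import hypergeom_tail, overlap_from_lists

        def _overlap():
            inputs = overlap_from_lists(
                mio.read_gene_list(config.overlap.query_list),
                mio.read_gene_list(config.overlap.reference_list),
                mio.read_gene_list(config.overlap.universe_list),
            )
            res = hypergeom_tail(inputs)
            return {
                "m": inputs.m, "n": inputs.n, "A": inputs.A, "N": inputs.N,
                "p_value": res.p_value, "log10_p": res.log10_p,
                "expected_overlap": res.expected_overlap,
                "fold_enrichment": res.fold_enrichment,
            }
        report["overlap"] = _stage("overlap", _overlap)

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float) + "\n")
    (outdir / "summary.txt").write_text(_summarize(report, decisions))
    return report


def _summarize(report: dict, decisions: pd.DataFrame) -> str:
    lines = [
        f"murkscreen run (seed {report['seed']}, config {report['config_hash']})",
        f"cells: {report['n_cells']}  genes: {report['n_genes']} "
        f"({report['n_genes_after_filter']} after filtering)",
        f"MURK genes called: {report['n_murk']} "
        f"({100 * report['murk_fraction_of_tested']:.1f}% of tested)",
        f"direction score, all genes:        {report['direction_score_all_genes']:+.3f}",
        f"direction score, MURK removed:     {report['direction_score_murk_removed']:+.3f}",
    ]
    if "overlap" in report:
        ov = report["overlap"]
        lines.append(
            f"overlap: {ov['m']}/{ov['n']} in reference set of {ov['A']} "
            f"(universe {ov['N']}), p = {ov['p_value']:.3g}, "
            f"fold enrichment {ov['fold_enrichment']:.2f}"
        )
    top = decisions[decisions["is_murk"]].nsmallest(10, "rank")
    if len(top):
        lines.append("top MURK genes by slope increase:")
        for _, row in top.iterrows():
            lines.append(
                f"  {row['gene_id']}: slope increase {row['slope_increase']:.3f}, "
                f"p = {row['p_value']:.3g}"
            )
    return "\n".join(lines) + "\n"
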