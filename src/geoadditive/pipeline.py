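"""File-oriented pipeline stages tying the library together.

Each stage reads/writes plain-text artefacts (CSV tables, edge-list/.gra
graphs, JSON manifests) and is deterministic under its seed: all
stage-level randomness is derived from a single top-level seed via
``numpy.random.SeedSequence``.  Every output directory receives a
``manifest.json`` echoing the full configuration, sufficient to re-run the
stage bit-identically.

Stages: :func:`simulate_run`, :func:`fit_run`, :func:`suite_run`,
:func:`moran_run`, :func:`crosstab_run`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import AdjacencyGraph, read_graph, write_graph
from .inference import (
    classify_spatial_effects,
    dic,
    fit_model_suite,
    posterior_odds_ratios,
    predicted_prevalence,
    weighted_prevalence_table,
)
from .model import DEFAULT_COVARIATES, build_model_terms
from .moran import morans_i_test
from .sampler import MCMCConfig, run_mcmc
from .simulate import (
    GeneratorConfig,
    draw_truth,
    listwise_deletion,
    make_lattice_graph,
    simulate_dataset,
    write_truth,
)

__all__ = ["RunConfig", "simulate_run", "fit_run", "suite_run", "moran_run", "crosstab_run"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Top-level run settings shared by the pipeline stages."""

    seed: int = 0
    n_mothers: int = 5000
    lattice: tuple[int, int] = (6, 6)
    model: str = "m6"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    n_interior_knots: int = 20
    missing_rate: float = 0.0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_mothers < 1:
            raise ValueError("n_mothers must be positive")
        self.generator.validate()

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_seed(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG derived from the single top-level seed."""
    child = np.random.SeedSequence(seed).spawn(
        {"simulate": 1, "fit": 2, "suite": 3, "moran": 4, "crosstab": 5}[stage]
    )[-1]
    return np.random.default_rng(child)


def _write_manifest(outdir: Path, stage: str, config: dict, extra: dict | None = None) -> None:
    payload = {"stage": stage, "config": config}
    payload.update(extra or {})
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=1, default=str))


def _require_dir(outdir: str | Path) -> Path:
    outdir = Path(outdir)
    if not outdir.parent.exists():
        raise FileNotFoundError(f"output location {outdir.parent} does not exist")
    outdir.mkdir(exist_ok=True)
    return outdir


def simulate_run(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a dataset + truth + graph and write them as text files."""
    config.validate()
    outdir = _require_dir(outdir)
    rng = _stage_seed(config.seed, "simulate")
    graph = make_lattice_graph(*config.lattice)
    truth = draw_truth(graph, config.generator, rng=rng)
    table = simulate_dataset(truth, graph, n_mothers=config.n_mothers, rng=rng)
    if config.missing_rate > 0:
        from .simulate import inject_missingness

        table = inject_missingness(
            table, config.missing_rate, seed=int(rng.integers(2**31))
        )
    paths = {
        "dataset": outdir / "dataset.csv",
        "truth": outdir / "truth.json",
        "graph": outdir / "graph.gra",
    }
    table.to_csv(paths["dataset"], index=False)
    write_truth(truth, paths["truth"])
    write_graph(graph, paths["graph"], dialect="gra")
    _write_manifest(outdir, "simulate", config.to_dict(), {"n_girls": len(table)})
    return paths


def _read_table(dataset: str | Path) -> pd.DataFrame:
    # only empty cells are missing: covariate levels like "None" are real data
    return pd.read_csv(dataset, keep_default_na=False, na_values=[""])


def _load_inputs(dataset: str | Path, graph: str | Path | AdjacencyGraph):
    table = _read_table(dataset)
    if not isinstance(graph, AdjacencyGraph):
        graph = Path(graph)
        graph = read_graph(graph, dialect="gra" if graph.suffix == ".gra" else "edge_list")
    return table, graph


def fit_run(
    dataset: str | Path,
    graph: str | Path | AdjacencyGraph,
    config: RunConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Fit one model and write all posterior summaries plus the chain archive."""
    config.validate()
    outdir = _require_dir(outdir)
    table, graph = _load_inputs(dataset, graph)

    analysis_cols = ["fgm", "state", "year", "survey", "mother_age", *config.covariates]
    analysis_cols = [c for c in analysis_cols if c in table.columns]
    table, n_dropped = listwise_deletion(table, tuple(analysis_cols))
    logger.info("listwise deletion dropped %d rows", n_dropped)

    terms = build_model_terms(
        table,
        graph,
        model=config.model,
        covariates=config.covariates,
        n_interior_knots=config.n_interior_knots,
    )
    samples = run_mcmc(np.asarray(table["fgm"], dtype=float), terms, config.mcmc)

    d, p_d, d_bar, d_hat = dic(samples, table["fgm"])
    pd.DataFrame(
        [{"model": config.model, "dic": d, "p_d": p_d, "d_bar": d_bar, "d_at_mean": d_hat}]
    ).to_csv(outdir / "dic_table.csv", index=False)

    por_frames = [
        posterior_odds_ratios(samples, cov)
        for cov in samples.term("fixed").components
        if cov != "intercept"
    ]
    (pd.concat(por_frames, ignore_index=True) if por_frames else pd.DataFrame()).to_csv(
        outdir / "por_table.csv", index=False
    )
    predicted_prevalence(samples, table["state"], graph.n_regions).to_csv(
        outdir / "prevalence_by_state.csv", index=False
    )
    classify_spatial_effects(samples).to_csv(outdir / "spatial_class.csv", index=False)

    chains = outdir / "chains"
    chains.mkdir(exist_ok=True)
    for name, draws in samples.coef.items():
        cols = samples.term(name).column_labels or [f"b{k}" for k in range(draws.shape[1])]
        pd.DataFrame(draws, columns=cols).to_csv(chains / f"coef_{_safe(name)}.csv", index=False)
    if samples.tau2:
        pd.DataFrame(samples.tau2).to_csv(chains / "tau2.csv", index=False)

    _write_manifest(
        outdir,
        "fit",
        config.to_dict(),
        {
            "n_rows_dropped": n_dropped,
            "n_rows_used": len(table),
            "retained_draws": samples.n_draws,
            "acceptance": samples.acceptance,
        },
    )
    return {"outdir": outdir, "dic_table": outdir / "dic_table.csv"}


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in name)


def suite_run(
    dataset: str | Path,
    graph: str | Path | AdjacencyGraph,
    config: RunConfig,
    outdir: str | Path,
    models=("m1", "m2", "m3", "m4", "m5", "m6"),
) -> Path:
    """Fit the nested model suite and write the DIC comparison table."""
    config.validate()
    if len(set(models)) != len(models):
        raise ValueError("duplicate model ids in suite configuration")
    outdir = _require_dir(outdir)
    table, graph = _load_inputs(dataset, graph)
    analysis_cols = [c for c in ("fgm", "state", "year", "survey", "mother_age",
                                 *config.covariates) if c in table.columns]
    table, n_dropped = listwise_deletion(table, tuple(analysis_cols))
    dic_table, fits = fit_model_suite(
        table,
        graph,
        models=models,
        config=config.mcmc,
        covariates=config.covariates,
        n_interior_knots=config.n_interior_knots,
    )
    dic_table.to_csv(outdir / "dic_table.csv", index=False)
    for mid, samples in fits.items():
        _write_manifest(
            _require_dir(outdir / f"model_{_safe(mid)}"),
            "fit",
            {**config.to_dict(), "model": mid},
            {"retained_draws": samples.n_draws, "n_rows_dropped": n_dropped},
        )
    _write_manifest(outdir, "suite", config.to_dict(), {"models": list(models)})
    return outdir / "dic_table.csv"


def moran_run(
    dataset: str | Path,
    graph: str | Path | AdjacencyGraph,
    outdir: str | Path,
    seed: int = 0,
    n_sims: int = 999,
) -> Path:
    """Global clustering test on per-region observed prevalence."""
    outdir = _require_dir(outdir)
    table, graph = _load_inputs(dataset, graph)
    prev = (
        table.groupby("state")["fgm"].mean().reindex(range(1, graph.n_regions + 1))
    )
    if prev.isna().any():
        raise ValueError("every region needs at least one observation for the Moran test")
    values = prev.to_numpy()
    i_an, p_an = morans_i_test(values, graph, method="analytic")
    i_mc, p_mc = morans_i_test(values, graph, method="monte_carlo", n_sims=n_sims, seed=seed)
    out = pd.DataFrame(
        [
            {"method": "analytic", "moran_i": i_an, "p_value": p_an},
            {"method": "monte_carlo", "moran_i": i_mc, "p_value": p_mc},
        ]
    )
    out.to_csv(outdir / "moran.csv", index=False)
    _write_manifest(outdir, "moran", {"seed": seed, "n_sims": n_sims}, {})
    return outdir / "moran.csv"


def crosstab_run(
    dataset: str | Path, outdir: str | Path, by: tuple[str, ...] = ("year", "education")
) -> Path:
    """Weighted bivariate prevalence crosstabs for the requested covariates."""
    outdir = _require_dir(outdir)
    table = _read_table(dataset)
    weights = table["weight"] if "weight" in table.columns else np.ones(len(table))
    frames = []
    for cov in by:
        tab = weighted_prevalence_table(table, weights, by=cov)
        tab.insert(0, "covariate", cov)
        tab = tab.rename(columns={cov: "level"})
        frames.append(tab)
    pd.concat(frames, ignore_index=True).to_csv(outdir / "crosstab.csv", index=False)
    _write_manifest(outdir, "crosstab", {"by": list(by)}, {})
    return outdir / "crosstab.csv"
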