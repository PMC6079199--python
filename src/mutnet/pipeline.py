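"""End-to-end orchestration: network → centrality → quantgen → association.

A single YAML config drives the four stages (plus optional simulation of the
trait data when no measured table is supplied).  Every stage writes its
outputs before the next starts; all randomness flows from named seeds in the
config; every TSV output carries a header comment recording the package
version, a config hash, and the seed, so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association as assoc
from . import centrality as cent
from . import ma_quantgen as qg
from . import reaction_net as rnet
from . import synthetic_data as synth

logger = logging.getLogger("mutnet.pipeline")

__all__ = ["RunConfig", "RunReport", "validate_config", "run_all"]

_SIM_KEYS = {
    "n_nodes", "mean_out_degree", "n_lines", "n_ancestor_reps",
    "mutations_per_line", "alpha_log_mean", "alpha_log_sd", "decay_lambda",
    "residual_cv", "ancestral_mean",
}


@dataclass
class RunConfig:
    """Typed, defaulted pipeline configuration.

    File-path fields are resolved against the config file's directory and
    must exist at validation time.  ``simulate`` holds toy-network and
    effect-model settings used only when no ``traits`` file is given.
    """

    out_dir: Path
    seed: int = 0
    t: int = 250
    bootstrap_iters: int = 10000
    fdr_level: float = 0.05
    reactions: Path | None = None
    currency: Path | None = None
    seed_metabolites: Path | None = None
    focal_metabolites: Path | None = None
    traits: Path | None = None
    simulate: dict[str, Any] = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in dataclasses.asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML pipeline config (fail fast, name the key)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "out_dir" not in raw:
        raise ValueError("config key 'out_dir' is required")
    sim = raw.get("simulate") or {}
    bad_sim = set(sim) - _SIM_KEYS
    if bad_sim:
        raise ValueError(f"unknown simulate key(s): {sorted(bad_sim)}")
    base = path.parent

    def _resolve(key: str, must_exist: bool = True) -> Path | None:
        val = raw.get(key)
        if val is None:
            return None
        p = Path(val)
        if not p.is_absolute():
            p = base / p
        if must_exist and not p.exists():
            raise FileNotFoundError(f"config key {key!r}: file not found: {p}")
        return p

    for key, typ in (("seed", int), ("t", int), ("bootstrap_iters", int)):
        if key in raw and not isinstance(raw[key], int):
            raise TypeError(f"config key {key!r} must be an integer")
    if "fdr_level" in raw and not isinstance(raw["fdr_level"], (int, float)):
        raise TypeError("config key 'fdr_level' must be a number")

    out_dir = Path(raw["out_dir"])
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    return RunConfig(
        out_dir=out_dir,
        seed=raw.get("seed", 0),
        t=raw.get("t", 250),
        bootstrap_iters=raw.get("bootstrap_iters", 10000),
        fdr_level=float(raw.get("fdr_level", 0.05)),
        reactions=_resolve("reactions"),
        currency=_resolve("currency"),
        seed_metabolites=_resolve("seed_metabolites"),
        focal_metabolites=_resolve("focal_metabolites"),
        traits=_resolve("traits"),
        simulate=dict(sim),
    )


@dataclass
class RunReport:
    """Paths and headline statistics of one pipeline run."""

    outputs: dict[str, str]
    stage_rows: dict[str, int]
    n_metabolites: int
    gsc_size: int
    excluded_metabolites: list[str]
    n_cross_correlations: int
    sign_patterns: dict[str, float]
    rho: dict[str, dict[str, float]]     # variant -> observed / ci / p
    familywise_alpha: float
    seed: int
    config_hash: str


def _jsonify(obj):
    """Strict-JSON view: non-finite floats become null."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def _read_id_list(path: Path | None) -> list[str] | None:
    if path is None:
        return None
    return [ln.strip() for ln in path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index_label: str) -> None:
    with path.open("w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=True, index_label=index_label, na_rep="NA")


def run_all(config: RunConfig) -> RunReport:
    """Execute all stages in dependency order and write a summary report."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    header = f"mutnet {__version__} seed={config.seed} config={config.config_hash()}"
    outputs: dict[str, str] = {}
    stage_rows: dict[str, int] = {}

    # ---- stage 1: network -------------------------------------------------
    logger.info("[network] building metabolite network")
    if config.traits is None and config.reactions is None and not config.simulate:
        raise ValueError("config needs 'reactions', 'traits', or a 'simulate' section")
    if config.reactions is not None:
        records = rnet.parse_reactions(config.reactions)
        currency = (_read_id_list(config.currency)
                    if config.currency else rnet.default_currency_metabolites())
        network = rnet.build_network(records, currency)
        seeds = _read_id_list(config.seed_metabolites)
        if seeds:
            network = rnet.expand_from_seeds(network, seeds)
    else:
        sim = config.simulate
        network = synth.generate_toy_network(
            n_nodes=int(sim.get("n_nodes", 29)),
            mean_out_degree=float(sim.get("mean_out_degree", 1.6)),
            seed=config.seed,
        )
    net_path = out / "network_edges.tsv"
    rnet.write_edgelist_tsv(network, net_path, header_comment=header)
    rnet.write_pajek(network, out / "network.net")
    outputs["network"] = str(net_path)
    stage_rows["network_edges"] = network.graph.number_of_edges()
    logger.info("[network] %d nodes, %d edges",
                network.graph.number_of_nodes(), network.graph.number_of_edges())

    # ---- stage 2: centrality ---------------------------------------------
    logger.info("[centrality] computing the six network parameters")
    ctable = cent.centrality_table(network)
    paths_dir = cent.shortest_paths(network, mode="directed")
    paths_und = cent.shortest_paths(network, mode="undirected")
    _write_tsv(ctable, out / "centrality.tsv", header, "metabolite")
    _write_tsv(paths_dir.values, out / "paths_directed.tsv", header, "metabolite")
    _write_tsv(paths_und.values, out / "paths_undirected.tsv", header, "metabolite")
    outputs["centrality"] = str(out / "centrality.tsv")
    stage_rows["centrality"] = len(ctable)

    # ---- stage 3: quantgen -----------------------------------------------
    if config.traits is not None:
        logger.info("[quantgen] loading trait table %s", config.traits)
        table = qg.MATraitTable.from_tsv(config.traits, t=config.t)
    else:
        logger.info("[quantgen] simulating MA experiment (seed=%d)", config.seed)
        focal = _read_id_list(config.focal_metabolites)
        sim_kwargs = {k: v for k, v in config.simulate.items()
                      if k not in ("n_nodes", "mean_out_degree")}
        sim_cfg = synth.SimConfig(t=config.t, seed=config.seed, **sim_kwargs)
        table, _truth = synth.simulate_MA(sim_cfg, network, metabolites=focal)
        table.to_tsv(out / "traits_simulated.tsv", header_comment=header)
        outputs["traits"] = str(out / "traits_simulated.tsv")
    params = qg.mutational_params(table)
    _write_tsv(params, out / "mutational_params.tsv", header, "metabolite")
    outputs["mutational_params"] = str(out / "mutational_params.tsv")
    stage_rows["mutational_params"] = len(params)

    logger.info("[quantgen] pairwise mutational correlations (%d traits)",
                len(table.metabolites))
    rm = qg.rM_matrix(table, alpha=config.fdr_level)
    _write_tsv(rm.r, out / "rm_matrix.tsv", header, "metabolite")
    _write_tsv(rm.p, out / "rm_pvalues.tsv", header, "metabolite")
    outputs["rm_matrix"] = str(out / "rm_matrix.tsv")
    stage_rows["rm_pairs"] = rm.n_pairs

    # ---- stage 4: association --------------------------------------------
    logger.info("[associate] correlations, CCA, sign patterns, bootstrap nulls")
    corr = assoc.pairwise_correlations(params, ctable)
    _write_tsv(corr.full, out / "parameter_correlations.tsv", header, "parameter")
    _write_tsv(corr.cross_q, out / "cross_correlations_fdr.tsv", header, "parameter")
    outputs["parameter_correlations"] = str(out / "parameter_correlations.tsv")

    cca_rows = []
    try:
        y = params[list(assoc.MUTATIONAL_COLUMNS)]
        full, singles, qvals = assoc.hierarchical_cca(
            ctable[list(assoc.NETWORK_COLUMNS)], y.dropna())
        for i, (r, p) in enumerate(zip(full.correlations, full.p_values), start=1):
            cca_rows.append({"analysis": "full", "root": i,
                             "canonical_r": r, "p_value": p, "q_value": math.nan})
        for (name, res), qv in zip(singles.items(), qvals):
            cca_rows.append({"analysis": name, "root": 1,
                             "canonical_r": res.correlations[0],
                             "p_value": res.p_values[0], "q_value": qv})
    except ValueError as exc:
        logger.warning("[associate] CCA skipped: %s", exc)
    cca_df = pd.DataFrame(cca_rows)
    with (out / "cca_report.tsv").open("w") as fh:
        fh.write(f"# {header}\n")
        cca_df.to_csv(fh, sep="\t", index=False, na_rep="NA")
    outputs["cca_report"] = str(out / "cca_report.tsv")

    patterns = assoc.sign_pattern_tests(corr)

    gsc = rnet.great_strong_component(network, focal=list(rm.r.index))
    included = list(gsc.focal_inside)
    excluded = list(gsc.focal_outside)
    logger.info("[associate] %d of %d traits inside the great strong component",
                len(included), len(rm.r))
    rho_report: dict[str, dict[str, float]] = {}
    rm_in = rm.r.loc[included, included]
    for variant in ("signed", "absolute", "undirected"):
        null = assoc.bootstrap_rho_null(
            rm_in, paths_dir, n_iter=config.bootstrap_iters,
            seed=config.seed, variant=variant)
        rho_report[variant] = {
            "observed": null.observed, "ci_low": null.ci_low,
            "ci_high": null.ci_high, "p_value": null.p_value,
        }
        np.savetxt(out / f"rho_null_{variant}.tsv", null.samples,
                   header=header, comments="# ")
        assoc.plot_null_histogram(null, str(out / f"rho_null_{variant}.png"))

    report = RunReport(
        outputs=outputs,
        stage_rows=stage_rows,
        n_metabolites=len(table.metabolites),
        gsc_size=len(gsc.members),
        excluded_metabolites=excluded,
        n_cross_correlations=int(corr.cross_r.size),
        sign_patterns=patterns,
        rho=rho_report,
        familywise_alpha=rm.familywise_alpha,
        seed=config.seed,
        config_hash=config.config_hash(),
    )
    summary = _jsonify(dataclasses.asdict(report))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs["summary"] = str(out / "summary.json")
    logger.info("[done] summary written to %s", out / "summary.json")
    return report
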