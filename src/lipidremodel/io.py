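"""Readers, writers, run configuration and the end-to-end pipeline.

On-disk formats are plain text: tab-separated time courses and edge lists,
JSON for fit reports, relative-rate reports, control reports and run
configuration.  Every report embeds the configuration and seed that produced
it so a run can be repeated exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .controls import ControlReport, permutation_test
from .dynamic_fit import FitResult, OdeSystem, SplineModel, build_ode, fit_dynamics
from .lipid_model import (
    Edge,
    RemodelingNetwork,
    SpeciesId,
    TimeCourse,
    parse_species,
)
from .network_inference import InferenceConfig, bidirectionalize, infer_network
from .rate_analysis import (
    AcylChain,
    RateTable,
    relative_deacylation,
    relative_reacylation,
)

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "read_network",
    "write_network",
    "write_graphml",
    "write_fit_report",
    "read_fit_report",
    "read_rate_table",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_TC_COLUMNS = ["species", "time_h", "replicate", "concentration"]


def read_timecourse(path: str | Path, sep: str = "-") -> TimeCourse:
    """Read a time-course TSV (species, time_h, replicate, concentration).

    Duplicate (species, time, replicate) rows and negative concentrations are
    rejected with the offending row number (1-based, excluding the header).
    Species observed at only some time points are zero-filled at the missing
    times with a warning; species absent everywhere simply are not rows.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_TC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    neg = df.index[df["concentration"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative concentration at row {int(neg[0]) + 1}")
    dup = df.duplicated(subset=["species", "time_h", "replicate"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (species, time, replicate) at row {int(df.index[dup][0]) + 1}"
        )
    times = sorted(float(t) for t in df["time_h"].unique())
    filled = []
    for lbl, sub in df.groupby("species", sort=False):
        have = set(float(t) for t in sub["time_h"])
        for t in times:
            if t not in have:
                logger.warning("%s: species %s missing at t=%g; zero-filled", path, lbl, t)
                filled.append((lbl, t, 1, 0.0))
    if filled:
        df = pd.concat([df, pd.DataFrame(filled, columns=_TC_COLUMNS)], ignore_index=True)
    return TimeCourse.from_frame(df, sep=sep)


def write_timecourse(tc: TimeCourse, path: str | Path, sep: str = "-") -> None:
    tc.to_frame(sep).to_csv(path, sep="\t", index=False)


_NET_COLUMNS = ["source", "target", "position", "score", "window_start", "window_end"]


def write_network(net: RemodelingNetwork, path: str | Path, sep: str = "-") -> None:
    rows = [
        (e.source.render(sep), e.target.render(sep), e.position, e.score,
         e.window[0], e.window[1])
        for e in net.edges
    ]
    pd.DataFrame(rows, columns=_NET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_network(path: str | Path, sep: str = "-") -> RemodelingNetwork:
    df = pd.read_csv(path, sep="\t")
    missing = set(_NET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    edges = [
        Edge(
            source=parse_species(r.source, sep),
            target=parse_species(r.target, sep),
            position=r.position,
            score=float(r.score),
            window=(int(r.window_start), int(r.window_end)),
        )
        for r in df.itertuples()
    ]
    return RemodelingNetwork.from_edges(edges)


def write_graphml(net: RemodelingNetwork, path: str | Path, sep: str = "-") -> None:
    """Export for network viewers (Cytoscape, Gephi)."""
    import networkx as nx

    g = nx.DiGraph()
    for s in sorted(net.nodes):
        g.add_node(s.render(sep))
    for e in net.edges:
        g.add_edge(
            e.source.render(sep),
            e.target.render(sep),
            position=e.position,
            score=float(e.score),
        )
    nx.write_graphml(g, path)


def write_fit_report(
    fit: FitResult,
    sys: OdeSystem,
    path: str | Path,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
    sep: str = "-",
) -> None:
    """Persist a fit as JSON: per-edge rates, error traces, provenance."""
    report = {
        "software_version": __version__,
        "seed": seed,
        "config": dict(config or {}),
        "converged": fit.converged,
        "iterations": fit.iterations,
        "lambda": fit.lam,
        "rank_deficient": fit.rank_deficient,
        "best_iteration": fit.best_iteration,
        "rates": [
            {
                "source": e.source.render(sep),
                "target": e.target.render(sep),
                "position": e.position,
                "initial_chain": str(e.source.chain_at(e.position)),
                "new_chain": str(e.target.chain_at(e.position)),
                "score": float(e.score),
                "rate_per_h": float(th),
            }
            for e, th in zip(sys.edges, fit.theta)
        ],
        "error_obs": list(map(float, fit.error_obs)),
        "error_ode": list(map(float, fit.error_ode)),
        "error_total": list(map(float, fit.error_total)),
    }
    Path(path).write_text(json.dumps(report, indent=2))


def read_fit_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_rate_table(path: str | Path) -> dict[str, RateTable]:
    """Read a rate TSV (position, [experiment,] initial_chain, new_chain, rate)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "experiment" not in df.columns:
        df["experiment"] = None
    out: dict[str, RateTable] = {}
    for pos, sub in df.groupby("position"):
        records = [
            (
                r.experiment,
                AcylChain.parse(str(r.initial_chain)),
                AcylChain.parse(str(r.new_chain)),
                float(r.rate),
            )
            for r in sub.itertuples()
        ]
        out[str(pos)] = RateTable.from_records(pos, records)
    return out


@dataclass
class RunConfig:
    """Everything needed to rerun the two-step pipeline exactly."""

    input_path: str
    out_dir: str
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    lam: float = 1.0
    max_iter: int = 1000
    tol: float = 1e-6
    n_basis_init: int = 5
    n_basis: int = 21
    n_collocation: int = 49
    ref_deacyl: str = "14:0"
    ref_reacyl: str = "18:1"
    run_permutation_control: bool = False
    n_permutations: int = 100
    seed: int = 0
    species_sep: str = "-"
    log_level: str = "INFO"

    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        if not np.isscalar(d["inference"]["alpha"]):
            d["inference"]["alpha"] = list(d["inference"]["alpha"])
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        d = json.loads(p.read_text() if p.exists() else str(source))
        inf = d.pop("inference", {})
        return cls(inference=InferenceConfig(**inf), **d)

    def spline(self) -> SplineModel:
        return SplineModel(
            n_basis_init=self.n_basis_init,
            n_basis=self.n_basis,
            n_collocation=self.n_collocation,
        )


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Run infer-network -> bidirectionalize -> fit -> decompose (-> controls).

    Returns a mapping of artifact names to paths; every artifact embeds the
    configuration and seed.  A stage failure aborts with a stage-tagged error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    cfg_echo = json.loads(cfg.to_json())

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    try:
        t = stage("read")
        tc = read_timecourse(cfg.input_path, sep=cfg.species_sep)
        logger.info("read %d species, %d times (%.2fs)", tc.n_species, tc.n_times,
                    time.perf_counter() - t)
    except Exception as exc:
        raise RuntimeError(f"stage 'read' failed: {exc}") from exc

    try:
        t = stage("infer-network")
        net = bidirectionalize(infer_network(tc, cfg.inference))
        net_path = out / "network.tsv"
        write_network(net, net_path, sep=cfg.species_sep)
        artifacts["network"] = str(net_path)
        logger.info("%d directed edges (%.2fs)", net.n_edges, time.perf_counter() - t)
    except Exception as exc:
        raise RuntimeError(f"stage 'infer-network' failed: {exc}") from exc

    try:
        t = stage("fit")
        sys = build_ode(net)
        fit = fit_dynamics(
            tc, sys, spline=cfg.spline(), lam=cfg.lam, max_iter=cfg.max_iter, tol=cfg.tol
        )
        fit_path = out / "fit.json"
        write_fit_report(fit, sys, fit_path, config=cfg_echo, seed=cfg.seed,
                         sep=cfg.species_sep)
        artifacts["fit"] = str(fit_path)
        logger.info("fit E_total=%.4g in %d iterations (%.2fs)", fit.final_errors[2],
                    fit.iterations, time.perf_counter() - t)
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc

    try:
        t = stage("decompose")
        records: dict[str, list] = {"sn1": [], "sn2": []}
        for e, th in zip(sys.edges, fit.theta):
            if th <= 0:
                continue  # relative rates need positive entries
            records[e.position].append(
                (e.source.render(cfg.species_sep), e.source.chain_at(e.position),
                 e.target.chain_at(e.position), float(th))
            )
        rel: dict[str, dict] = {}
        for pos, recs in records.items():
            if not recs:
                continue
            table = RateTable.from_records(pos, recs)  # type: ignore[arg-type]
            entry: dict[str, Any] = {}
            ref_d = AcylChain.parse(cfg.ref_deacyl)
            ref_a = AcylChain.parse(cfg.ref_reacyl)
            if table.rows_for(ref_d):
                rr = relative_deacylation(table, ref_d)
                entry["deacylation"] = {str(c): v for c, v in rr.ratios.items()}
                entry["deacylation_reference"] = cfg.ref_deacyl
            if any(ref_a in r.rates for r in table.rows):
                rr = relative_reacylation(table, ref_a)
                entry["reacylation"] = {str(c): v for c, v in rr.ratios.items()}
                entry["reacylation_reference"] = cfg.ref_reacyl
            rel[pos] = entry
        rel_path = out / "relative_rates.json"
        rel_path.write_text(json.dumps(
            {"config": cfg_echo, "seed": cfg.seed, "relative_rates": rel}, indent=2))
        artifacts["relative_rates"] = str(rel_path)
        logger.info("decompose done (%.2fs)", time.perf_counter() - t)
    except Exception as exc:
        raise RuntimeError(f"stage 'decompose' failed: {exc}") from exc

    if cfg.run_permutation_control:
        try:
            t = stage("permutation-control")
            report = permutation_test(
                tc,
                net,
                fit_kwargs={"spline": cfg.spline(), "lam": cfg.lam,
                            "max_iter": cfg.max_iter, "tol": cfg.tol},
                n=cfg.n_permutations,
                seed=cfg.seed,
            )
            ctrl_path = out / "permutation_control.json"
            ctrl_path.write_text(json.dumps(
                {
                    "config": cfg_echo,
                    "seed": cfg.seed,
                    "real_error": report.real_error,
                    "null_errors": list(report.null_errors),
                    "null_mean": report.mean,
                    "null_stddev": report.stddev,
                    "empirical_p": report.empirical_p,
                    "n_failed": report.n_failed,
                },
                indent=2,
            ))
            artifacts["permutation_control"] = str(ctrl_path)
            logger.info("control done (%.2fs)", time.perf_counter() - t)
        except Exception as exc:
            raise RuntimeError(f"stage 'permutation-control' failed: {exc}") from exc

    cfg_path = out / "run_config.json"
    cfg.to_json(cfg_path)
    artifacts["config"] = str(cfg_path)
    return artifacts
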