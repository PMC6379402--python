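"""End-to-end orchestration from a flat key-value config file.

A run reads condition-specific network layers, aligns them onto shared
gene indexes, factorizes each condition, extracts integrated networks and
hard clusterings, and (when the inputs are provided) computes cluster
enrichment, rewiring rankings and marker enrichment of the top rewired
genes.  Optional stages evaluate a k grid by stability analysis and fit
random-graph models to the integrated networks.

Every output file is recorded in a manifest with a SHA-256 content hash;
re-running with the same config and seeds reproduces identical hashes.

Config format: ``key = value`` lines, ``#`` comments.  Keys:

======================  ======================================================
control_layers          comma-separated edge-list paths (required)
case_layers             comma-separated edge-list paths (optional)
expression              binary expression TSV with 'control'/'case' columns
annotations             GMT file for cluster enrichment
markers                 gene-list file for top-rewired enrichment
background              gene-list file naming the enrichment background
node_policy             union (default) | intersection
k                       cluster count (required)
max_iter, epsilon       solver budget / ridge (1000, 1e-10)
init, seed              svd (default) | random, RNG seed
threshold_fraction      integrated-network threshold (0.01)
top_n                   prefix size for rewired-gene enrichment (500)
alpha                   BH significance threshold (0.05)
k_grid                  e.g. '10:100:10' or '2,3,4' -> stability stage
stability_runs          random-init runs per k (10)
nullfit_models          e.g. 'ER,GEO' -> model-fitting stage on the iCell
nullfit_reps            replicas per model (30)
out_dir                 output directory (required)
======================  ======================================================
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import net_io
from .enrichment import cluster_enrichment
from .fusion import (
    SolverConfig,
    build_icell,
    build_icell_pair,
    fuse,
    fuse_pair,
    hard_cluster,
)
from .null_models import fit_models
from .rewiring import partition_genes, rewiring_scores, top_rewired_enrichment
from .stability import select_k


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    control_layers: list[Path]
    out_dir: Path
    k: int
    case_layers: list[Path] = field(default_factory=list)
    expression: Path | None = None
    annotations: Path | None = None
    markers: Path | None = None
    background: Path | None = None
    node_policy: str = "union"
    max_iter: int = 1000
    epsilon: float = 1e-10
    init: str = "svd"
    seed: int = 0
    threshold_fraction: float = 0.01
    top_n: int = 500
    alpha: float = 0.05
    k_grid: list[int] = field(default_factory=list)
    stability_runs: int = 10
    nullfit_models: list[str] = field(default_factory=list)
    nullfit_reps: int = 30

    def validate(self) -> None:
        if not self.control_layers:
            raise ConfigError("control_layers is required")
        for path in [
            *self.control_layers,
            *self.case_layers,
            *(p for p in (self.expression, self.annotations, self.markers,
                          self.background) if p is not None),
        ]:
            if not Path(path).exists():
                raise ConfigError(f"input file does not exist: {path}")
        if self.k < 1:
            raise ConfigError("k must be >= 1")


def _parse_grid(text: str) -> list[int]:
    text = text.strip()
    if ":" in text:
        start, stop, step = (int(x) for x in text.split(":"))
        return list(range(start, stop + 1, step))
    return [int(x) for x in text.split(",") if x.strip()]


def read_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = stripped.partition("=")
        raw[key.strip()] = value.strip()
    try:
        cfg = RunConfig(
            control_layers=[Path(p) for p in raw.get("control_layers", "").split(",") if p],
            case_layers=[Path(p) for p in raw.get("case_layers", "").split(",") if p],
            expression=Path(raw["expression"]) if "expression" in raw else None,
            annotations=Path(raw["annotations"]) if "annotations" in raw else None,
            markers=Path(raw["markers"]) if "markers" in raw else None,
            background=Path(raw["background"]) if "background" in raw else None,
            node_policy=raw.get("node_policy", "union"),
            k=int(raw["k"]),
            max_iter=int(raw.get("max_iter", 1000)),
            epsilon=float(raw.get("epsilon", 1e-10)),
            init=raw.get("init", "svd"),
            seed=int(raw.get("seed", 0)),
            threshold_fraction=float(raw.get("threshold_fraction", 0.01)),
            top_n=int(raw.get("top_n", 500)),
            alpha=float(raw.get("alpha", 0.05)),
            k_grid=_parse_grid(raw["k_grid"]) if "k_grid" in raw else [],
            stability_runs=int(raw.get("stability_runs", 10)),
            nullfit_models=[m for m in raw.get("nullfit_models", "").split(",") if m],
            nullfit_reps=int(raw.get("nullfit_reps", 30)),
            out_dir=Path(raw["out_dir"]),
        )
    except KeyError as exc:
        raise ConfigError(f"missing required config key: {exc.args[0]}") from exc
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv_matrix(path: Path, matrix: np.ndarray, row_names, col_names) -> None:
    with path.open("w") as fh:
        fh.write("id\t" + "\t".join(map(str, col_names)) + "\n")
        for name, row in zip(row_names, matrix):
            fh.write(str(name) + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def run_pipeline(config: RunConfig, log=None) -> dict:
    """Execute all configured stages; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: str(v) for k, v in vars(config).items()},
        "files": {},
        "metrics": {},
        "stages": [],
        "failed_stage": None,
    }

    def log_stage(name: str, t0: float) -> None:
        manifest["stages"].append(name)
        if log is not None:
            log(f"stage={name} seed={config.seed} wall={time.time() - t0:.2f}s")

    def register(path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = _sha256(path)

    conditions: dict[str, list[net_io.GeneNetwork]] = {}
    stage = "load"
    try:
        t0 = time.time()
        conditions["control"] = [
            net_io.read_edge_list(p, layer_label=Path(p).stem)
            for p in config.control_layers
        ]
        if config.case_layers:
            conditions["case"] = [
                net_io.read_edge_list(p, layer_label=Path(p).stem)
                for p in config.case_layers
            ]
        expression = (
            net_io.read_expression_table(config.expression)
            if config.expression else None
        )
        annotations = net_io.read_gmt(config.annotations) if config.annotations else None
        markers = net_io.read_gene_list(config.markers) if config.markers else None
        background = (
            net_io.read_gene_list(config.background) if config.background else None
        )
        log_stage(stage, t0)

        solver = SolverConfig(
            k=config.k, max_iter=config.max_iter, epsilon=config.epsilon,
            init=config.init, seed=config.seed,
        )
        multiplexes = {}
        for cond, nets in conditions.items():
            if expression is not None and cond in expression.tissues:
                nets = [
                    net_io.make_tissue_specific(net, expression.expressed_in(cond))
                    for net in nets
                ]
            multiplexes[cond] = net_io.align_networks(
                nets, node_policy=config.node_policy
            )

        # With two conditions over one gene index, factorize from a shared
        # initialization and threshold at common cutoffs so the comparison
        # reflects data differences rather than solver noise.
        paired = (
            "case" in multiplexes
            and multiplexes["control"].gene_index == multiplexes["case"].gene_index
            and multiplexes["control"].n_layers == multiplexes["case"].n_layers
        )
        results = {}
        icells = {}
        clusterings = {}
        if paired:
            stage = "fuse:paired"
            t0 = time.time()
            results["control"], results["case"] = fuse_pair(
                multiplexes["control"], multiplexes["case"], solver
            )
            icells["control"], icells["case"] = build_icell_pair(
                results["control"].G, results["case"].G,
                multiplexes["control"].gene_index,
                threshold_fraction=config.threshold_fraction,
            )
            log_stage(stage, t0)
        for cond, multiplex in multiplexes.items():
            stage = f"fuse:{cond}"
            t0 = time.time()
            if cond not in results:
                results[cond] = fuse(multiplex, solver)
                icells[cond] = build_icell(
                    results[cond].G, multiplex.gene_index,
                    threshold_fraction=config.threshold_fraction,
                    layer_label=f"icell_{cond}",
                )
            result = results[cond]
            icell = icells[cond]
            clustering = hard_cluster(result.G, multiplex.gene_index)
            clusterings[cond] = clustering
            manifest["metrics"][f"rse_{cond}"] = result.final_rse
            manifest["metrics"][f"icell_edges_{cond}"] = icell.network.n_edges

            _write_tsv_matrix(
                out / f"G_{cond}.tsv", result.G, multiplex.gene_index,
                [f"c{i + 1}" for i in range(config.k)],
            )
            register(out / f"G_{cond}.tsv")
            net_io.write_edge_list(icell.network, out / f"icell_{cond}.tsv")
            register(out / f"icell_{cond}.tsv")
            with (out / f"clusters_{cond}.tsv").open("w") as fh:
                for g in multiplex.gene_index:
                    fh.write(f"{g}\t{clustering.assignment[g]}\n")
            register(out / f"clusters_{cond}.tsv")
            with (out / f"rse_{cond}.tsv").open("w") as fh:
                for i, v in enumerate(result.rse_trace, start=1):
                    fh.write(f"{i}\t{v:.12g}\n")
            register(out / f"rse_{cond}.tsv")
            log_stage(stage, t0)

        if annotations is not None:
            stage = "cluster_enrichment"
            t0 = time.time()
            results, percent = cluster_enrichment(
                clusterings["control"], annotations, alpha=config.alpha
            )
            manifest["metrics"]["percent_genes_enriched"] = percent
            with (out / "cluster_enrichment.tsv").open("w") as fh:
                fh.write("cluster\tterm\tX\tN\tK\tM\tfold\tp\tp_adj\tdirection\n")
                for r in results:
                    fh.write(
                        f"{r.set_id}\t{r.term}\t{r.X}\t{r.N}\t{r.K}\t{r.M}"
                        f"\t{r.fold:.6g}\t{r.p_raw:.6g}\t{r.p_adjusted:.6g}"
                        f"\t{r.direction}\n"
                    )
            register(out / "cluster_enrichment.tsv")
            log_stage(stage, t0)

        if "case" in icells:
            stage = "rewiring"
            t0 = time.time()
            shared = set(icells["control"].network.nodes) & set(
                icells["case"].network.nodes
            )
            if expression is not None and {"control", "case"} <= set(expression.tissues):
                part = partition_genes(
                    expression.expressed_in("control") & shared,
                    expression.expressed_in("case") & shared,
                    shared,
                )
                candidates = part.always_expressed
                with (out / "gene_partition.tsv").open("w") as fh:
                    for name, genes in part.as_dict().items():
                        for g in sorted(genes):
                            fh.write(f"{g}\t{name}\n")
                register(out / "gene_partition.tsv")
            else:
                candidates = shared
            ranking = rewiring_scores(icells["control"], icells["case"], candidates)
            with (out / "rewiring.tsv").open("w") as fh:
                fh.write("gene\tscore\trank\n")
                for rank, (g, s) in enumerate(ranking.ranking, start=1):
                    fh.write(f"{g}\t{s:.10g}\t{rank}\n")
            register(out / "rewiring.tsv")
            log_stage(stage, t0)

            if markers is not None:
                stage = "top_rewired_enrichment"
                t0 = time.time()
                bg = set(background) if background is not None else set(candidates)
                top_n = min(config.top_n, len(ranking.ranking))
                res = top_rewired_enrichment(ranking, markers, bg, top_n=top_n)
                manifest["metrics"]["top_rewired_fold"] = res.fold
                manifest["metrics"]["top_rewired_p"] = res.p_raw
                manifest["metrics"]["top_rewired_direction"] = res.direction
                log_stage(stage, t0)

        if config.k_grid:
            stage = "stability"
            t0 = time.time()
            multiplex = net_io.align_networks(
                conditions["control"], node_policy=config.node_policy
            )
            report = select_k(
                multiplex, config.k_grid, runs=config.stability_runs,
                seed=config.seed, max_iter=config.max_iter,
            )
            manifest["metrics"]["chosen_k"] = report.chosen_k
            with (out / "stability.tsv").open("w") as fh:
                fh.write("k\teta\tnu\n")
                for k in report.k_grid:
                    fh.write(f"{k}\t{report.eta[k]:.10g}\t{report.nu[k]:.10g}\n")
            register(out / "stability.tsv")
            log_stage(stage, t0)

        if config.nullfit_models:
            stage = "nullfit"
            t0 = time.time()
            fit = fit_models(
                icells["control"].network, models=config.nullfit_models,
                reps=config.nullfit_reps, seed=config.seed,
            )
            with (out / "nullfit.tsv").open("w") as fh:
                fh.write("model\tmean_gcd11\tsd_gcd11\tmwu_p\trejected\n")
                for model, f in fit.fits.items():
                    fh.write(
                        f"{model}\t{f.mean_distance:.6g}\t{f.sd_distance:.6g}"
                        f"\t{f.mwu_p:.6g}\t{int(f.rejected)}\n"
                    )
            register(out / "nullfit.tsv")
            log_stage(stage, t0)
    except ConfigError:
        raise
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
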