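"""Configuration-driven end-to-end pipeline with deterministic seeding.

A single master seed spawns a named child seed per stage (via
``numpy.random.SeedSequence`` keyed on a stable stage hash), so any
stage can be re-run independently yet reproducibly, and two runs with
the same manifest produce byte-identical result files.
"""
from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import comparison, communities, metrics, preprocess, simulate, stability
from .datatypes import ConfigError, Network, PairedPanel, PipelineError
from .estimation import EstimatorSettings, estimate_network, write_network
from .preprocess import correlation, nonparanormal_transform

logger = logging.getLogger(__name__)


def threshold_for_display(net: Network, min_abs: float = 0.05) -> Network:
    """Copy with |weight| < min_abs zeroed; display only, never analysis."""
    if min_abs < 0:
        raise ConfigError("min_abs must be nonnegative")
    weights = net.weights.copy()
    weights[np.abs(weights) < min_abs] = 0.0
    return Network(weights, net.item_labels)


def fr_layout(net: Network, seed: int | None = None, iterations: int = 500) -> dict:
    """Force-directed 2-D layout with |weight| as attraction, in [-1, 1]^2."""
    graph = nx.Graph()
    graph.add_nodes_from(net.item_labels)
    p = net.n_items
    for i in range(p):
        for j in range(i + 1, p):
            w = abs(net.weights[i, j])
            if w > 0:
                graph.add_edge(net.item_labels[i], net.item_labels[j], weight=w)
    pos = nx.spring_layout(graph, weight="weight", iterations=iterations, seed=seed)
    return {label: (float(xy[0]), float(xy[1])) for label, xy in pos.items()}


@dataclass
class PipelineConfig:
    """Everything a full run needs; parseable from YAML/JSON."""

    outdir: Path
    seed: int = 0
    generator: simulate.GeneratorConfig | None = None
    input_baseline: Path | None = None
    input_followup: Path | None = None
    exclude: list[str] = field(default_factory=list)
    estimator: EstimatorSettings = field(default_factory=EstimatorSettings)
    edge_bootstrap_B: int = 1000
    case_drop_B: int = 250
    case_drop_proportions: tuple = stability.DEFAULT_PROPORTIONS
    nct_B: int = 1000
    alpha: float = 0.05
    edge_tests: str = "auto"
    community_runs: int = 10000
    community_params: dict = field(default_factory=dict)
    display_threshold: float = 0.05
    threads: int = 1

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.generator is None and self.input_baseline is None:
            raise ConfigError("config needs either a generator block or input paths")
        if self.generator is not None and self.input_baseline is not None:
            raise ConfigError("give a generator block or input paths, not both")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "generator" in data and data["generator"] is not None:
            gen = dict(data["generator"])
            gen.setdefault("seed", data.get("seed", 0))
            if set(gen) <= {
                "n_subjects", "seed", "within_weight", "between_weight",
                "strength_scale_followup", "subject_dependence",
                "mean_shift_followup", "thresholds", "missing_rate",
            }:
                data["generator"] = simulate.default_config(**gen)
            else:
                data["generator"] = simulate.GeneratorConfig(**gen)
        if "estimator" in data and isinstance(data["estimator"], dict):
            data["estimator"] = EstimatorSettings(**data["estimator"])
        if "case_drop_proportions" in data:
            data["case_drop_proportions"] = tuple(data["case_drop_proportions"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "generator": self.generator.to_dict() if self.generator else None,
            "input_baseline": str(self.input_baseline) if self.input_baseline else None,
            "input_followup": str(self.input_followup) if self.input_followup else None,
            "exclude": list(self.exclude),
            "estimator": self.estimator.to_dict(),
            "edge_bootstrap_B": self.edge_bootstrap_B,
            "case_drop_B": self.case_drop_B,
            "case_drop_proportions": list(self.case_drop_proportions),
            "nct_B": self.nct_B,
            "alpha": self.alpha,
            "edge_tests": self.edge_tests,
            "community_runs": self.community_runs,
            "community_params": dict(self.community_params),
            "display_threshold": self.display_threshold,
            "threads": self.threads,
        }


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic, platform-independent child seed for a named stage."""
    digest = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence([master_seed, digest]).generate_state(1)[0])


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    On stage failure the partial outputs plus the manifest are kept and
    :class:`PipelineError` names the failed stage.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "versions": _versions(),
        "stages": {},
        "outputs": [],
    }
    current_stage = "setup"

    def record(stage: str, t0: float, **info):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **info}

    def emit(path: Path):
        manifest["outputs"].append(str(path.relative_to(outdir)))

    try:
        # ------------------------------------------------ load / generate
        current_stage = "input"
        t0 = time.time()
        truth = None
        followup_present = True
        if config.generator is not None:
            pair, truth = simulate.make_paired_panel(config.generator)
            for panel in (pair.baseline, pair.followup):
                path = outdir / f"panel_{panel.time_label}.csv"
                missing_frame = None
                if config.generator.missing_rate > 0:
                    missing_frame = simulate.apply_missingness(
                        panel,
                        config.generator.missing_rate,
                        np.random.default_rng(
                            stage_seed(config.seed, f"missing_{panel.time_label}")
                        ),
                    )
                simulate.write_panel(panel, path, missing_frame)
                emit(path)
            for path in truth.write(outdir / "truth"):
                emit(path)
            record("input", t0, source="generator", n_subjects=pair.n_subjects)
        else:
            baseline = preprocess.load_panel(config.input_baseline, "baseline")
            if config.input_followup is not None:
                followup = preprocess.load_panel(config.input_followup, "followup")
                pair = preprocess.pair_panels(baseline, followup)
            else:
                followup_present = False
                pair = None
            record(
                "input", t0, source="files",
                n_subjects=(pair.n_subjects if pair else baseline.n_subjects),
            )
        if pair is None:
            waves = {"baseline": baseline}
        else:
            waves = {"baseline": pair.baseline, "followup": pair.followup}

        # ------------------------------------------------ item exclusion
        current_stage = "exclude"
        if config.exclude:
            waves = {
                k: preprocess.exclude_items(v, config.exclude) for k, v in waves.items()
            }
            if pair is not None:
                pair = PairedPanel(waves["baseline"], waves["followup"])

        # ------------------------------------------------ estimation
        current_stage = "estimate"
        t0 = time.time()
        nets = {}
        for name, panel in waves.items():
            t = nonparanormal_transform(panel)
            corr = correlation(t)
            path_obj = estimate_network(
                corr,
                panel.n_subjects,
                gamma=config.estimator.gamma,
                n_lambdas=config.estimator.n_lambdas,
                lambda_min_ratio=config.estimator.lambda_min_ratio,
                penalty=config.estimator.penalty,
                tol=config.estimator.tol,
                max_sweeps=config.estimator.max_sweeps,
            )
            nets[name] = path_obj.network
            for out in write_network(path_obj.network, outdir / f"network_{name}"):
                emit(out)
            path_csv = outdir / f"path_{name}.csv"
            path_obj.to_frame().to_csv(path_csv, index=False)
            emit(path_csv)
            corr_csv = outdir / f"correlation_{name}.csv"
            corr.to_frame().to_csv(corr_csv, index_label="item")
            emit(corr_csv)
        record("estimate", t0, edges={k: v.edge_count for k, v in nets.items()})

        # ------------------------------------------------ centrality
        current_stage = "centrality"
        t0 = time.time()
        for name, net in nets.items():
            table = metrics.centrality_table(net)
            path = outdir / f"centrality_{name}.csv"
            table.to_csv(path)
            emit(path)
        record("centrality", t0)

        # ------------------------------------------------ stability
        current_stage = "stability"
        t0 = time.time()
        cs_all = {}
        for name, panel in waves.items():
            edge_res = stability.edge_bootstrap(
                panel,
                config.estimator,
                B=config.edge_bootstrap_B,
                seed=stage_seed(config.seed, f"edge_bootstrap_{name}"),
            )
            path = outdir / f"edge_bootstrap_{name}.csv"
            edge_res.to_frame().to_csv(path, index=False)
            emit(path)
            case_res = stability.case_drop_bootstrap(
                panel,
                config.estimator,
                proportions=config.case_drop_proportions,
                B=config.case_drop_B,
                seed=stage_seed(config.seed, f"case_drop_{name}"),
            )
            path = outdir / f"case_drop_{name}.csv"
            case_res.summary().to_csv(path, index=False)
            emit(path)
            cs_all[name] = stability.cs_coefficient(case_res)
        path = outdir / "stability_summary.json"
        _dump_json({"cs_coefficients": cs_all}, path)
        emit(path)
        record("stability", t0)

        # ------------------------------------------------ comparison
        current_stage = "comparison"
        t0 = time.time()
        if followup_present and pair is not None:
            nct = comparison.nct_dependent(
                pair,
                config.estimator,
                B=config.nct_B,
                seed=stage_seed(config.seed, "nct"),
                edge_tests=config.edge_tests,
                alpha=config.alpha,
            )
            for out in nct.write(outdir / "nct"):
                emit(out)
            record("comparison", t0, p_M=nct.p_M, p_S=nct.p_S)
        else:
            record("comparison", t0, skipped="no follow-up input")

        # ------------------------------------------------ communities
        current_stage = "communities"
        t0 = time.time()
        skipped_waves = []
        for name, net in nets.items():
            if net.edge_count == 0:
                skipped_waves.append(name)
                logger.warning("communities: %s network is empty; tally skipped", name)
                continue
            tally = communities.community_tally(
                net,
                n_runs=config.community_runs,
                seed=stage_seed(config.seed, f"communities_{name}"),
                **config.community_params,
            )
            for out in tally.write(outdir / f"communities_{name}"):
                emit(out)
        record("communities", t0, skipped=skipped_waves)

        # ------------------------------------------------ display export
        current_stage = "display"
        t0 = time.time()
        for name, net in nets.items():
            shown = threshold_for_display(net, config.display_threshold)
            path = outdir / f"display_{name}.tsv"
            shown.edge_list().to_csv(path, sep="\t", index=False)
            emit(path)
            layout = fr_layout(shown, seed=stage_seed(config.seed, f"layout_{name}") % (2**32))
            path = outdir / f"layout_{name}.csv"
            pd.DataFrame(
                [(k, x, y) for k, (x, y) in layout.items()],
                columns=["item", "x", "y"],
            ).to_csv(path, index=False)
            emit(path)
        record("display", t0)
    except Exception as exc:
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        _dump_json(manifest, outdir / "manifest.json")
        raise PipelineError(current_stage, str(exc)) from exc

    _dump_json(manifest, outdir / "manifest.json")
    return manifest


def _versions() -> dict:
    import networkx
    import numpy
    import pandas
    import scipy

    from . import __version__

    return {
        "ordnet": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
    }
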