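"""End-to-end analysis pipeline with reproducibility metadata.

Chains the stages build-matrix -> logistic PCA -> subsystem loadings ->
similarity/cophenetic validation -> MLR importance -> summary report,
driven by a single YAML/dict configuration.  Every numeric output is a TSV
accompanied by a JSON sidecar recording the parameters, seed and input
digests that produced it; identical configuration and seed yield
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import loadings as loadings_mod
from . import lpca as lpca_mod
from . import mlr as mlr_mod
from . import similarity as similarity_mod
from . import synthgen as synthgen_mod
from .mlr import ClusterLabels
from .reaction_matrix import (
    BinaryReactionMatrix,
    SubsystemMap,
    build_pan_matrix,
    differentialize,
    read_model_collection,
    read_subsystem_overrides,
)

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.12g"

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "out_prefix": "run",
    "stages": {
        "simulate": False,
        "build_matrix": False,
        "lpca": True,
        "loadings": True,
        "similarity": True,
        "mlr": True,
        "report": True,
    },
    "inputs": {
        "matrix": None,
        "subsystem_map": None,
        "labels": None,
        "tree": None,
        "models_dir": None,
        "model_format": None,
        "subsystem_remap": None,
    },
    "simulate": {},
    "lpca": {"k": 2, "m": 4.0, "tol": 1e-6, "max_iter": 1000},
    "loadings": {"n_comp": 2, "top_n": 5},
    "similarity": {"metrics": ["manhattan", "euclidean"], "linkage": "complete"},
    "mlr": {"ridge": 1e-4},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (see :data:`DEFAULT_CONFIG`)."""

    config: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = _deep_merge(DEFAULT_CONFIG, self.config)
        unknown = set(self.config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        self.config = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data)

    def __getitem__(self, key: str) -> Any:
        return self.config[key]


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _deep_merge(base[k], v)
        else:
            out[k] = v
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Emitter:
    """Write TSVs with JSON sidecars under a common prefix."""

    def __init__(self, prefix: Path, config: dict, input_digests: dict[str, str]):
        self.prefix = prefix
        self.config = config
        self.input_digests = input_digests
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.written: list[str] = []

    def tsv(self, name: str, df: pd.DataFrame, stage: str, index_label: str = "id") -> Path:
        path = Path(f"{self.prefix}.{name}.tsv")
        df.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT, index_label=index_label)
        self._sidecar(path, stage)
        self.written.append(path.name)
        return path

    def text(self, name: str, content: str, stage: str) -> Path:
        path = Path(f"{self.prefix}.{name}")
        path.write_text(content)
        self._sidecar(path, stage)
        self.written.append(path.name)
        return path

    def json(self, name: str, payload: dict, stage: str) -> Path:
        return self.text(name, json.dumps(payload, indent=2, sort_keys=True) + "\n", stage)

    def _sidecar(self, path: Path, stage: str) -> None:
        meta = {
            "package": "gsmm-lpca",
            "version": __version__,
            "stage": stage,
            "seed": self.config["seed"],
            "parameters": self.config.get(stage, {}),
            "inputs": self.input_digests,
        }
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig | dict[str, Any]) -> dict[str, Any]:
    """Execute the enabled stages in order and return the summary report.

    Stage failures abort with the stage name; outputs of completed stages
    remain on disk.  Matrix/labels/tree inputs are taken from files unless
    the ``simulate`` stage is enabled, in which case the canonical
    synthetic fixture (or the configured variant) supplies them.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(dict(config))
    cfg = config.config
    seed = int(cfg["seed"])
    prefix = Path(cfg["out_prefix"])
    stages = cfg["stages"]
    inputs = cfg["inputs"]

    digests = {
        key: _digest(Path(p))
        for key, p in inputs.items()
        if p and Path(str(p)).is_file()
    }
    emit = _Emitter(prefix, cfg, digests)
    report: dict[str, Any] = {"stages_run": []}

    matrix: BinaryReactionMatrix | None = None
    smap: SubsystemMap | None = None
    labels: ClusterLabels | None = None
    truth = None
    tree: similarity_mod.LinkageTree | None = None

    def stage(name: str):
        report["stages_run"].append(name)
        logger.info("pipeline stage: %s", name)

    try:
        if stages.get("simulate"):
            stage("simulate")
            spec = synthgen_mod.SynthSpec(**{**cfg["simulate"], "seed": seed})
            raw, smap, truth = synthgen_mod.generate_matrix(spec)
            matrix, diff_report = differentialize(raw)
            labels = truth.labels
            if truth.true_tree is not None:
                tree = truth.true_tree
                emit.text("true_tree.nwk", tree.to_newick() + "\n", "simulate")
            emit.tsv("matrix", matrix.to_frame(), "simulate", index_label="model_id")
            emit.tsv(
                "subsystems",
                pd.DataFrame({"subsystem": pd.Series(smap.assignment)}).sort_index(),
                "simulate",
                index_label="reaction_id",
            )
            emit.tsv(
                "labels",
                pd.DataFrame({"label": pd.Series(labels.labels)}).sort_index(),
                "simulate",
                index_label="model_id",
            )
            report["differentialize"] = diff_report.__dict__

        if stages.get("build_matrix"):
            stage("build_matrix")
            models = read_model_collection(
                inputs["models_dir"], inputs.get("model_format")
            )
            overrides = (
                read_subsystem_overrides(inputs["subsystem_remap"])
                if inputs.get("subsystem_remap")
                else None
            )
            raw, smap = build_pan_matrix(models, overrides)
            matrix, diff_report = differentialize(raw)
            emit.tsv("matrix", matrix.to_frame(), "build_matrix", index_label="model_id")
            emit.tsv(
                "subsystems",
                pd.DataFrame({"subsystem": pd.Series(smap.assignment)}).sort_index(),
                "build_matrix",
                index_label="reaction_id",
            )
            report["differentialize"] = diff_report.__dict__

        if matrix is None and inputs.get("matrix"):
            matrix = BinaryReactionMatrix.from_tsv(inputs["matrix"], is_differential=True)
        if smap is None and inputs.get("subsystem_map"):
            smap = SubsystemMap.from_tsv(inputs["subsystem_map"])
        if labels is None and inputs.get("labels"):
            labels = ClusterLabels.from_tsv(inputs["labels"])
        if tree is None and inputs.get("tree"):
            tree = similarity_mod.LinkageTree.from_newick(inputs["tree"])

        model = None
        if stages.get("lpca"):
            stage("lpca")
            if matrix is None:
                raise ValueError("lpca stage requires a matrix input")
            lp = cfg["lpca"]
            lpca_config = lpca_mod.LPCAConfig(
                k=int(lp.get("k", 2)),
                m=lp.get("m", 4.0),
                tol=float(lp.get("tol", 1e-6)),
                max_iter=int(lp.get("max_iter", 1000)),
                seed=seed,
                partial_eigen=bool(lp.get("partial_eigen", False)),
            )
            model = lpca_mod.fit_lpca(matrix, lpca_config)
            emit.tsv("scores", model.scores_frame(), "lpca", index_label="model_id")
            emit.tsv("loadings", model.loadings_frame(), "lpca", index_label="reaction_id")
            emit.tsv("mu", model.mu_frame(), "lpca", index_label="reaction_id")
            emit.json(
                "lpca_meta.json",
                {
                    "m": model.m,
                    "m_selection": model.m_selection,
                    "k": model.k,
                    "iterations": model.n_iter,
                    "final_deviance": model.deviance,
                    "converged": model.converged,
                },
                "lpca",
            )
            report["lpca"] = {
                "deviance": model.deviance,
                "iterations": model.n_iter,
                "converged": model.converged,
                "m": model.m,
            }

        ranking = None
        if stages.get("loadings"):
            stage("loadings")
            if model is None or smap is None:
                raise ValueError("loadings stage requires a fitted model and subsystem map")
            lcfg = cfg["loadings"]
            n_comp = min(int(lcfg.get("n_comp", 2)), model.k)
            table = loadings_mod.reaction_loadings(model, n_comp)
            ranking = loadings_mod.subsystem_ranking(model, smap, n_comp)
            emit.tsv("reaction_loadings", table, "loadings", index_label="reaction_id")
            emit.tsv("subsystem_ranking", ranking, "loadings", index_label="subsystem")
            top = loadings_mod.top_drivers(
                ranking, table, smap, n=int(lcfg.get("top_n", 5))
            )
            top5 = loadings_mod.top_drivers(
                ranking, table, smap, n=int(lcfg.get("top_n", 5)),
                statistic="avg_of_norms",
            )
            report["top_drivers_norm_of_avg"] = {k: v[:10] for k, v in top.items()}
            report["top_drivers_avg_of_norms"] = {k: v[:10] for k, v in top5.items()}
            arrows = ranking.loc[
                [s for s in ranking.index if s != smap.unassigned_label],
                [c for c in ranking.columns if c.startswith("PC")][:2],
            ]
            emit.tsv("subsystem_arrows", arrows, "loadings", index_label="subsystem")

        if stages.get("similarity"):
            stage("similarity")
            if matrix is None:
                raise ValueError("similarity stage requires a matrix input")
            scfg = cfg["similarity"]
            jac = similarity_mod.jaccard_matrix(matrix)
            emit.tsv("jaccard", jac.to_frame(), "similarity")
            jac_dist = similarity_mod.PairwiseMatrix(
                1.0 - jac.values, jac.ids, "jaccard_distance"
            )
            jac_tree = similarity_mod.hierarchical_cluster(
                jac_dist, scfg.get("linkage", "complete")
            )
            report["jaccard_leaf_order"] = jac_tree.leaf_order()
            if model is not None:
                coph: dict[str, float] = {}
                for metric in scfg.get("metrics", ["manhattan", "euclidean"]):
                    dist = similarity_mod.score_distances(
                        model.S, metric, ids=list(matrix.row_ids)
                    )
                    dend = similarity_mod.hierarchical_cluster(
                        dist, scfg.get("linkage", "complete")
                    )
                    emit.text(
                        f"dendrogram_{metric}.nwk", dend.to_newick() + "\n", "similarity"
                    )
                    if tree is not None:
                        coph[metric] = similarity_mod.cophenetic_correlation(dend, tree)
                if coph:
                    report["cophenetic_correlation"] = coph

        if stages.get("mlr"):
            stage("mlr")
            if matrix is None or labels is None:
                raise ValueError("mlr stage requires a matrix and cluster labels")
            coef = mlr_mod.fit_mlr(matrix, labels, ridge=float(cfg["mlr"].get("ridge", 1e-4)))
            emit.tsv("mlr_slopes", coef.slopes, "mlr", index_label="reaction_id")
            if smap is not None:
                importance = mlr_mod.subsystem_mlr_importance(coef, smap)
                emit.tsv("mlr_importance", importance, "mlr", index_label="subsystem")
                if ranking is not None:
                    comparison = mlr_mod.compare_rankings(
                        ranking, importance, n=int(cfg["loadings"].get("top_n", 5))
                    )
                    report["lpca_vs_mlr"] = comparison

        if stages.get("report"):
            stage("report")
            emit.json("report.json", report, "report")
    except Exception as exc:
        failed = report["stages_run"][-1] if report["stages_run"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    report["outputs"] = emit.written
    return report
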