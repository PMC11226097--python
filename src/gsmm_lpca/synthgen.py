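"""Synthetic model collections with planted cluster structure.

The generator emulates what a curated GSMM collection looks like after it
has been reduced to a pan-reaction matrix: ``N`` models fall into ``K``
clusters (think clades or tissue types), reactions are organised into
subsystem blocks, and each cluster carries one *discriminative* subsystem
whose reactions are common inside the cluster (presence probability
``p_disc_in``, default 0.9) and rare outside it (``p_disc_out``, default
0.1).  All remaining "background" reactions are present with probability
``p_background`` (default 0.5) regardless of cluster, mimicking the large
mass of reactions whose presence varies without tracking the clustering.

In hierarchical mode clusters are additionally paired into superclusters
with their own discriminative blocks, and the generator emits the true
ultrametric tree over models, which downstream cophenetic-correlation
analyses can be validated against.

Everything is fully determined by the seed.  The default dimensions
(N=120, R=300, K=3, 30-reaction blocks) are the canonical fixture used
throughout the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

from .mlr import ClusterLabels
from .reaction_matrix import BinaryReactionMatrix, SubsystemMap
from .similarity import LinkageTree


@dataclass
class SynthSpec:
    """Parameters of a planted-cluster binary matrix."""

    n_models: int = 120
    n_reactions: int = 300
    n_clusters: int = 3
    cluster_sizes: list[int] | None = None
    disc_block_size: int = 30
    background_block_size: int = 30
    p_disc_in: float = 0.9
    p_disc_out: float = 0.1
    p_background: float = 0.5
    hierarchical: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_sizes is None:
            base = self.n_models // self.n_clusters
            sizes = [base] * self.n_clusters
            for i in range(self.n_models - base * self.n_clusters):
                sizes[i] += 1
            self.cluster_sizes = sizes
        if sum(self.cluster_sizes) != self.n_models:
            raise ValueError("cluster sizes must sum to n_models")
        for p in (self.p_disc_in, self.p_disc_out, self.p_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        n_disc_blocks = self.n_clusters + (
            self._n_superclusters() if self.hierarchical else 0
        )
        if n_disc_blocks * self.disc_block_size > self.n_reactions:
            raise ValueError("discriminative blocks exceed n_reactions")

    def _n_superclusters(self) -> int:
        return math.ceil(self.n_clusters / 2)


@dataclass
class SynthTruth:
    """Ground truth accompanying a generated matrix."""

    labels: ClusterLabels
    discriminative_subsystems: set[str]
    spec: SynthSpec
    true_tree: LinkageTree | None = None
    supercluster_subsystems: set[str] = field(default_factory=set)


def _block_layout(spec: SynthSpec) -> list[tuple[str, int, str]]:
    """(subsystem name, size, role) per reaction block, in column order."""
    blocks: list[tuple[str, int, str]] = []
    for c in range(spec.n_clusters):
        blocks.append((f"disc_cluster_{c + 1}", spec.disc_block_size, f"disc:{c}"))
    if spec.hierarchical:
        for s in range(spec._n_superclusters()):
            blocks.append(
                (f"disc_supercluster_{s + 1}", spec.disc_block_size, f"super:{s}")
            )
    used = sum(size for _, size, _ in blocks)
    remaining = spec.n_reactions - used
    b = 0
    while remaining > 0:
        size = min(spec.background_block_size, remaining)
        blocks.append((f"background_{b + 1:02d}", size, "background"))
        remaining -= size
        b += 1
    return blocks


def generate_matrix(
    spec: SynthSpec,
) -> tuple[BinaryReactionMatrix, SubsystemMap, SynthTruth]:
    """Draw a planted-cluster binary matrix with its subsystem map and truth.

    Entry ``(n, r)`` is Bernoulli with a probability set by the cluster of
    model ``n`` and the block of reaction ``r``.  Reaction ids are
    zero-padded so lexicographic order equals generation order.
    """
    rng = np.random.default_rng(spec.seed)
    cluster_of = np.repeat(np.arange(spec.n_clusters), spec.cluster_sizes)
    super_of = cluster_of // 2

    blocks = _block_layout(spec)
    probs = np.empty((spec.n_models, spec.n_reactions))
    subsystems: dict[str, str] = {}
    col = 0
    width = len(str(spec.n_reactions))
    col_ids: list[str] = []
    for name, size, role in blocks:
        for _ in range(size):
            rid = f"R{col + 1:0{width}d}"
            col_ids.append(rid)
            subsystems[rid] = name
            if role == "background":
                probs[:, col] = spec.p_background
            elif role.startswith("disc:"):
                c = int(role.split(":")[1])
                probs[:, col] = np.where(
                    cluster_of == c, spec.p_disc_in, spec.p_disc_out
                )
            else:  # super:<s>
                s = int(role.split(":")[1])
                probs[:, col] = np.where(super_of == s, spec.p_disc_in, spec.p_disc_out)
            col += 1

    values = (rng.random((spec.n_models, spec.n_reactions)) < probs).astype(np.int8)
    mwidth = len(str(spec.n_models))
    row_ids = [f"M{i + 1:0{mwidth}d}" for i in range(spec.n_models)]
    matrix = BinaryReactionMatrix(values, row_ids, col_ids)
    smap = SubsystemMap(subsystems)

    labels = ClusterLabels(
        {rid: f"cluster_{cluster_of[i] + 1}" for i, rid in enumerate(row_ids)}
    )
    truth = SynthTruth(
        labels=labels,
        discriminative_subsystems={
            name for name, _, role in blocks if role.startswith("disc:")
        },
        supercluster_subsystems={
            name for name, _, role in blocks if role.startswith("super:")
        },
        spec=spec,
    )
    if spec.hierarchical:
        truth.true_tree = _true_tree(row_ids, cluster_of, super_of)
    return matrix, smap, truth


def _true_tree(
    row_ids: list[str], cluster_of: np.ndarray, super_of: np.ndarray
) -> LinkageTree:
    """Ultrametric truth: leaves join at depth 1 (cluster), 2 (supercluster), 3 (root)."""
    superclusters: dict[int, dict[int, list[str]]] = {}
    for rid, c, s in zip(row_ids, cluster_of, super_of):
        superclusters.setdefault(int(s), {}).setdefault(int(c), []).append(rid)

    super_parts = []
    for s in sorted(superclusters):
        cluster_parts = []
        for c in sorted(superclusters[s]):
            leaves = ",".join(f"{rid}:1" for rid in superclusters[s][c])
            cluster_parts.append(f"({leaves}):1")
        if len(cluster_parts) == 1:
            # lone cluster: stretch its branch so all leaves stay at depth 3
            super_parts.append(f"({cluster_parts[0]}):1")
        else:
            super_parts.append("(" + ",".join(cluster_parts) + "):1")
    newick = "(" + ",".join(super_parts) + ");"
    return LinkageTree.from_newick(newick)


def generate_model_files(
    matrix: BinaryReactionMatrix,
    smap: SubsystemMap,
    out_dir: str | Path,
    format: Literal["json", "sbml"] = "json",
    gprs: Mapping[str, str] | None = None,
) -> list[Path]:
    """Write one COBRA JSON or SBML file per matrix row.

    Each model contains exactly the reactions present in its row, annotated
    with the subsystem map (SBML: groups; JSON: ``subsystem`` field) and
    optional gene rules, so that reading the files back through
    :mod:`gsmm_lpca.reaction_matrix` reproduces matrix and map exactly.
    """
    import cobra
    import cobra.io
    from cobra.core.group import Group

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gprs = dict(gprs or {})
    paths: list[Path] = []
    for i, model_id in enumerate(matrix.row_ids):
        model = cobra.Model(model_id)
        present = [rid for rid, v in zip(matrix.col_ids, matrix.values[i]) if v]
        reactions = []
        for rid in present:
            rxn = cobra.Reaction(rid)
            rxn.subsystem = smap.assignment.get(rid, "")
            reactions.append(rxn)
        model.add_reactions(reactions)
        for rxn in model.reactions:
            if rxn.id in gprs:
                rxn.gene_reaction_rule = gprs[rxn.id]
        if format == "sbml":
            by_subsystem: dict[str, list] = {}
            for rxn in model.reactions:
                if rxn.subsystem:
                    by_subsystem.setdefault(rxn.subsystem, []).append(rxn)
            model.add_groups(
                [
                    Group(f"g{gi + 1}", name=sub, members=members)
                    for gi, (sub, members) in enumerate(sorted(by_subsystem.items()))
                ]
            )
            path = out_dir / f"{model_id}.xml"
            cobra.io.write_sbml_model(model, str(path))
        elif format == "json":
            path = out_dir / f"{model_id}.json"
            cobra.io.save_json_model(model, str(path))
        else:
            raise ValueError(f"unknown format: {format!r}")
        paths.append(path)
    return paths


def generate_expression_fixture(
    target: Mapping[str, bool],
    threshold: float = 0.2,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, str]]:
    """Expression table + gene rules realising a target presence pattern.

    For every reaction the rule references one gene expressed above the
    threshold and one below it; reactions meant to be present get an ``or``
    rule (satisfied by the expressed gene), reactions meant to be absent an
    ``and`` rule (broken by the silent gene).  Silent genes sit exactly at
    the threshold half the time, exercising the strict-inequality boundary.
    """
    rng = np.random.default_rng(seed)
    expression: dict[str, float] = {}
    gprs: dict[str, str] = {}
    for rid, present in target.items():
        g_on, g_off = f"g_{rid}_on", f"g_{rid}_off"
        expression[g_on] = threshold + 0.1 + round(float(rng.random()), 3)
        # at the threshold exactly (not expressed: calls are strict) or below
        expression[g_off] = threshold if rng.random() < 0.5 else round(
            float(rng.random()) * threshold * 0.99, 6
        )
        op = "or" if present else "and"
        gprs[rid] = f"{g_on} {op} {g_off}"
    return expression, gprs
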