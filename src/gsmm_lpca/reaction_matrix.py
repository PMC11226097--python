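"""Binary pan-reaction matrices from collections of metabolic models.

A collection of genome-scale metabolic models (GSMMs) is summarised as an
``N x R`` 0/1 matrix: one row per model, one column per reaction that occurs
in at least one model of the collection.  Columns that are constant across
the collection carry no comparative signal and are removed to obtain the
*differential* matrix used by logistic PCA.

Reactions are grouped into named subsystems (pathways); the merged
reaction -> subsystem assignment travels with the matrix as a
:class:`SubsystemMap`.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = "Unassigned"


@dataclass(frozen=True)
class ModelDescriptor:
    """Reaction content of a single metabolic model.

    Parameters
    ----------
    model_id
        Unique identifier of the model within its collection.
    reactions
        Identifiers of all reactions present in the model.
    subsystems
        Partial mapping reaction id -> subsystem name.
    gprs
        Partial mapping reaction id -> boolean gene-reaction rule string
        (identifiers combined with ``and`` / ``or`` and parentheses).
    """

    model_id: str
    reactions: frozenset[str]
    subsystems: Mapping[str, str] = field(default_factory=dict)
    gprs: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.model_id:
            raise ValueError("model_id must be non-empty")
        object.__setattr__(self, "reactions", frozenset(self.reactions))
        for name, mapping in (("subsystems", self.subsystems), ("gprs", self.gprs)):
            extra = set(mapping) - self.reactions
            if extra:
                raise ValueError(
                    f"model {self.model_id!r}: {name} keys not in reactions: {sorted(extra)[:5]}"
                )


@dataclass
class SubsystemMap:
    """Reaction id -> subsystem name, with a pooled label for gaps."""

    assignment: dict[str, str]
    unassigned_label: str = UNASSIGNED

    def subsystem_of(self, reaction_id: str) -> str:
        return self.assignment.get(reaction_id, self.unassigned_label)

    def groups(self, reaction_ids: Sequence[str]) -> dict[str, list[str]]:
        """Partition ``reaction_ids`` into per-subsystem lists (total)."""
        out: dict[str, list[str]] = {}
        for rid in reaction_ids:
            out.setdefault(self.subsystem_of(rid), []).append(rid)
        return out

    def remapped(self, overrides: Mapping[str, str]) -> "SubsystemMap":
        """Return a copy with explicit reaction -> subsystem overrides applied."""
        merged = dict(self.assignment)
        merged.update(overrides)
        return SubsystemMap(merged, self.unassigned_label)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.assignment.items()), columns=["reaction_id", "subsystem"]
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubsystemMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


@dataclass
class BinaryReactionMatrix:
    """``N x R`` presence/absence matrix with model and reaction labels."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    is_differential: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be exactly 0 or 1")
        self.values = self.values.astype(np.int8)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("shape does not match row/column labels")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("duplicate column ids")
        if self.is_differential:
            colsum = self.values.sum(axis=0)
            bad = (colsum == 0) | (colsum == self.values.shape[0])
            if bad.any():
                raise ValueError("differential matrix contains constant columns")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def row_support(self, i: int) -> set[str]:
        """Reaction ids present in row ``i``."""
        mask = self.values[i].astype(bool)
        return {rid for rid, m in zip(self.col_ids, mask) if m}

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="model_id")

    def to_triplets_tsv(self, path: str | Path) -> None:
        """Sparse triplet export: one ``model_id <tab> reaction_id`` line per 1."""
        rows, cols = np.nonzero(self.values)
        df = pd.DataFrame(
            {
                "model_id": [self.row_ids[i] for i in rows],
                "reaction_id": [self.col_ids[j] for j in cols],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, is_differential: bool = False) -> "BinaryReactionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            df.to_numpy(),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            is_differential=is_differential,
        )


@dataclass(frozen=True)
class DifferentialReport:
    """Column bookkeeping from :func:`differentialize`."""

    kept: int
    dropped_all_ones: int
    dropped_all_zeros: int


def build_pan_matrix(
    models: Sequence[ModelDescriptor],
    subsystem_overrides: Mapping[str, str] | None = None,
) -> tuple[BinaryReactionMatrix, SubsystemMap]:
    """Assemble the pan-reaction matrix of a model collection.

    Columns are the lexicographically sorted union of all reaction sets;
    entry ``(n, r)`` is 1 iff reaction ``r`` is present in model ``n``.
    Subsystem annotations are merged across models; conflicting annotations
    are resolved by majority vote with lexicographic tie-breaking, and
    ``subsystem_overrides`` (e.g. a manual re-annotation table) wins over
    any merged assignment.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to build a pan matrix")
    seen: set[str] = set()
    for m in models:
        if m.model_id in seen:
            raise ValueError(f"duplicate model_id: {m.model_id!r}")
        seen.add(m.model_id)

    union: set[str] = set()
    for m in models:
        union |= m.reactions
    if not union:
        raise ValueError("no reactions in any model")
    col_ids = sorted(union)
    col_index = {rid: j for j, rid in enumerate(col_ids)}

    values = np.zeros((len(models), len(col_ids)), dtype=np.int8)
    for i, m in enumerate(models):
        for rid in m.reactions:
            values[i, col_index[rid]] = 1

    votes: dict[str, Counter] = {}
    for m in models:
        for rid, sub in m.subsystems.items():
            votes.setdefault(rid, Counter())[sub] += 1
    assignment: dict[str, str] = {}
    for rid, counter in votes.items():
        if len(counter) > 1:
            logger.info("subsystem conflict for %s: %s", rid, dict(counter))
        # majority vote; ties broken by lexicographically first name
        top_count = counter.most_common(1)[0][1]
        assignment[rid] = min(name for name, c in counter.items() if c == top_count)
    smap = SubsystemMap(assignment)
    if subsystem_overrides:
        smap = smap.remapped(dict(subsystem_overrides))

    matrix = BinaryReactionMatrix(values, [m.model_id for m in models], col_ids)
    return matrix, smap


def differentialize(
    X: BinaryReactionMatrix,
) -> tuple[BinaryReactionMatrix, DifferentialReport]:
    """Drop all-0 and all-1 columns, keeping the original column order."""
    if X.is_differential:
        raise ValueError("matrix is already differential")
    colsum = X.values.sum(axis=0)
    n = X.shape[0]
    all_ones = colsum == n
    all_zeros = colsum == 0
    keep = ~(all_ones | all_zeros)
    report = DifferentialReport(
        kept=int(keep.sum()),
        dropped_all_ones=int(all_ones.sum()),
        dropped_all_zeros=int(all_zeros.sum()),
    )
    if report.kept == 0:
        logger.warning("differential matrix has zero columns (all columns constant)")
    out = BinaryReactionMatrix(
        X.values[:, keep],
        list(X.row_ids),
        [c for c, k in zip(X.col_ids, keep) if k],
        is_differential=True,
    )
    return out, report


# ---------------------------------------------------------------------------
# Gene-reaction rules and expression-based presence calls
# ---------------------------------------------------------------------------

def _eval_gpr(rule: str, expressed: set[str], reaction_id: str) -> bool:
    """Evaluate a boolean gene rule under an expressed-gene assignment."""
    from cobra.core.gene import GPR

    try:
        gpr = GPR.from_string(rule)
    except Exception as exc:  # cobra raises various parse errors
        raise ValueError(f"malformed gene rule for reaction {reaction_id!r}: {rule!r}") from exc
    if gpr.body is None:
        raise ValueError(f"malformed gene rule for reaction {reaction_id!r}: {rule!r}")
    knockouts = gpr.genes - expressed
    return bool(gpr.eval(knockouts))


def reactions_from_expression(
    expression: Mapping[str, float],
    gprs: Mapping[str, str],
    threshold: float = 0.2,
) -> set[str]:
    """Context-specific presence calls from a gene-expression table.

    A gene counts as expressed iff its nTPM value is strictly above
    ``threshold``.  A reaction is present iff it has a gene rule and the rule
    evaluates true with ``and`` = conjunction and ``or`` = disjunction.
    Reactions without a rule are never returned (gap-filled content carries
    no genetic evidence).  Genes appearing in a rule but missing from the
    expression table are treated as not expressed and logged.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    expressed = {g for g, v in expression.items() if v > threshold}
    present: set[str] = set()
    for rid, rule in gprs.items():
        if not rule or not rule.strip():
            continue
        from cobra.core.gene import GPR

        try:
            gpr = GPR.from_string(rule)
        except Exception as exc:
            raise ValueError(f"malformed gene rule for reaction {rid!r}: {rule!r}") from exc
        missing = gpr.genes - set(expression)
        if missing:
            logger.info("reaction %s: genes absent from expression table: %s", rid, sorted(missing))
        if _eval_gpr(rule, expressed, rid):
            present.add(rid)
    return present


# ---------------------------------------------------------------------------
# Model file readers (SBML Level 3 + fbc/groups, COBRA JSON)
# ---------------------------------------------------------------------------

def read_model_file(path: str | Path, format: str | None = None) -> ModelDescriptor:
    """Read one SBML or COBRA-JSON model into a :class:`ModelDescriptor`.

    ``format`` is ``"sbml"`` or ``"json"``; when omitted it is inferred from
    the file suffix.  Subsystems come from SBML groups (or the JSON
    ``subsystem`` field), gene rules from fbc gene-product associations (or
    the JSON ``gene_reaction_rule`` field).
    """
    import cobra.io

    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format not in ("sbml", "json", "cobra-json"):
        raise ValueError(f"unknown model format: {format!r}")
    try:
        if format == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            model = cobra.io.load_json_model(str(path))
    except Exception as exc:
        raise ValueError(f"could not parse model file {path}: {exc}") from exc

    reactions = frozenset(r.id for r in model.reactions)
    subsystems: dict[str, str] = {}
    for r in model.reactions:
        if r.subsystem:
            subsystems[r.id] = str(r.subsystem)
    # SBML groups take precedence over any per-reaction annotation
    for group in getattr(model, "groups", []):
        for member in group.members:
            if member.id in reactions:
                subsystems[member.id] = group.name or group.id
    gprs = {
        r.id: r.gene_reaction_rule
        for r in model.reactions
        if r.gene_reaction_rule and r.gene_reaction_rule.strip()
    }
    return ModelDescriptor(model.id or path.stem, reactions, subsystems, gprs)


def read_model_collection(
    directory: str | Path, format: str | None = None, pattern: str = "*"
) -> list[ModelDescriptor]:
    """Read every model file in ``directory`` (sorted by filename)."""
    directory = Path(directory)
    suffixes = {".xml", ".sbml", ".json"}
    paths = sorted(
        p for p in directory.glob(pattern) if p.suffix.lower() in suffixes
    )
    if not paths:
        raise ValueError(f"no model files found in {directory}")
    return [read_model_file(p, format) for p in paths]


def read_subsystem_overrides(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV of reaction id -> replacement subsystem."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_expression_table(path: str | Path) -> dict[str, float]:
    """Read a 2-column TSV of gene id -> nTPM."""
    df = pd.read_csv(path, sep="\t")
    return {str(g): float(v) for g, v in zip(df.iloc[:, 0], df.iloc[:, 1])}
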