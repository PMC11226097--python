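"""Reaction- and subsystem-centric loading analysis.

Each reaction has a loading vector over the leading principal components
(default: the first two).  Subsystem-centric loading vectors are the
per-subsystem averages of those reaction vectors; two scalar statistics
rank how strongly a subsystem drives the separation of models:

* ``norm_of_avg`` — the Euclidean norm of the average loading vector.
  Reactions pointing in opposite directions cancel, so this statistic
  rewards subsystems whose reactions act coherently.
* ``avg_of_norms`` — the average of the per-reaction loading norms, which
  ignores direction and rewards any subsystem of high-loading reactions.

By the triangle inequality ``norm_of_avg <= avg_of_norms`` always, with
equality for single-reaction subsystems.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lpca import LPCAModel
from .reaction_matrix import SubsystemMap


def reaction_loadings(model: LPCAModel, n_comp: int = 2) -> pd.DataFrame:
    """Per-reaction loading vectors over the first ``n_comp`` components."""
    if n_comp < 1 or n_comp > model.k:
        raise ValueError(f"n_comp must be in 1..{model.k}")
    return model.loadings_frame().iloc[:, :n_comp]


def subsystem_average_loadings(
    table: pd.DataFrame, smap: SubsystemMap
) -> pd.DataFrame:
    """Average the reaction loading vectors within each subsystem.

    Reactions absent from the map are pooled under the map's unassigned
    label.  The returned frame carries the component averages plus an
    ``R_j`` column with the per-subsystem reaction count.
    """
    subsystem = pd.Series(
        [smap.subsystem_of(rid) for rid in table.index], index=table.index, name="subsystem"
    )
    grouped = table.groupby(subsystem)
    avg = grouped.mean()
    avg["R_j"] = grouped.size()
    return avg


def _norm_of_avg(avg: pd.DataFrame) -> pd.Series:
    comp = avg.drop(columns=["R_j"], errors="ignore")
    return np.sqrt((comp**2).sum(axis=1))


def rank_norm_of_average(avg: pd.DataFrame) -> pd.DataFrame:
    """Rank subsystems by the norm of their average loading vector."""
    out = avg.copy()
    out["norm_of_avg"] = _norm_of_avg(avg)
    return _sorted_with_normalised(out, "norm_of_avg")


def rank_average_of_norms(table: pd.DataFrame, smap: SubsystemMap) -> pd.DataFrame:
    """Rank subsystems by the average per-reaction loading norm."""
    norms = pd.Series(
        np.sqrt((table**2).sum(axis=1)), index=table.index, name="reaction_norm"
    )
    subsystem = pd.Series(
        [smap.subsystem_of(rid) for rid in table.index], index=table.index
    )
    grouped = norms.groupby(subsystem)
    out = pd.DataFrame({"avg_of_norms": grouped.mean(), "R_j": grouped.size()})
    return _sorted_with_normalised(out, "avg_of_norms")


def _sorted_with_normalised(df: pd.DataFrame, col: str) -> pd.DataFrame:
    # descending by statistic, ties broken lexicographically by name
    df = df.iloc[np.lexsort((df.index.to_numpy(), -df[col].to_numpy()))].copy()
    peak = df[col].max()
    df[f"{col}_normalized"] = df[col] / peak if peak > 0 else np.nan
    return df


def subsystem_ranking(
    model: LPCAModel, smap: SubsystemMap, n_comp: int = 2
) -> pd.DataFrame:
    """Full per-subsystem table: average vectors and both ranking statistics.

    Rows are ordered by ``norm_of_avg`` descending (ties broken
    lexicographically by subsystem name); normalised columns divide each
    statistic by its own maximum so the top subsystem scores exactly 1.
    """
    table = reaction_loadings(model, n_comp)
    avg = subsystem_average_loadings(table, smap)
    by_avg = rank_norm_of_average(avg)
    by_norms = rank_average_of_norms(table, smap)
    out = by_avg.join(by_norms[["avg_of_norms", "avg_of_norms_normalized"]])
    # numerical guard, not a correction: averaging can only shrink norms
    assert (out["norm_of_avg"] <= out["avg_of_norms"] + 1e-12).all()
    return out


def top_drivers(
    ranking: pd.DataFrame,
    table: pd.DataFrame,
    smap: SubsystemMap,
    n: int = 5,
    statistic: str = "norm_of_avg",
    include_unassigned: bool = False,
) -> dict[str, list[str]]:
    """Top-``n`` driver subsystems with their reactions ordered by loading norm.

    The unassigned pool is excluded by default: it aggregates reactions with
    no pathway annotation and its average is rarely interpretable.
    """
    if statistic not in ("norm_of_avg", "avg_of_norms"):
        raise ValueError("statistic must be 'norm_of_avg' or 'avg_of_norms'")
    df = ranking.iloc[np.lexsort((ranking.index.to_numpy(), -ranking[statistic].to_numpy()))]
    if not include_unassigned:
        df = df[df.index != smap.unassigned_label]
    chosen = list(df.index[:n])
    norms = np.sqrt((table**2).sum(axis=1))
    groups = smap.groups(list(table.index))
    out: dict[str, list[str]] = {}
    for sub in chosen:
        rids = groups.get(sub, [])
        rids = sorted(rids, key=lambda rid: (-norms[rid], rid))
        out[sub] = rids
    return out
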