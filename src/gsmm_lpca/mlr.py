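"""Multinomial-logistic-regression subsystem importance.

Given pre-defined classes of models (phylogenetic clades, tissue types, or
planted clusters), each reaction's presence/absence is related to class
membership through a multinomial logistic model with an intercept and one
binary predictor, fitted per reaction by penalised maximum likelihood
(L2 ridge on the slopes only; the lexicographically first class is the
reference with coefficients fixed at zero).

A reaction's importance is the Euclidean norm of its slope coefficients
across the non-reference classes; subsystem importance averages those norms
within each subsystem and is max-normalised for comparison against the
logistic-PCA subsystem rankings.

With a single binary predictor the likelihood depends on the data only
through the 2 x C table of (presence, class) counts, so each fit is a small
smooth convex problem solved by a damped Newton iteration on the count
sufficient statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .reaction_matrix import BinaryReactionMatrix, SubsystemMap

logger = logging.getLogger(__name__)


@dataclass
class ClusterLabels:
    """Model id -> class label, validated against a matrix's rows."""

    labels: dict[str, str]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def vector(self, row_ids: list[str]) -> np.ndarray:
        missing = [r for r in row_ids if r not in self.labels]
        if missing:
            raise ValueError(f"unlabelled model rows: {missing[:5]}")
        classes = self.classes
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        index = {c: i for i, c in enumerate(classes)}
        y = np.array([index[self.labels[r]] for r in row_ids])
        counts = np.bincount(y, minlength=len(classes))
        small = [classes[i] for i in np.nonzero(counts < 2)[0]]
        if small:
            raise ValueError(f"classes with fewer than 2 members: {small}")
        return y

    @classmethod
    def from_tsv(cls, path) -> "ClusterLabels":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(sorted(self.labels.items()), columns=["model_id", "label"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class MLRCoefficients:
    """Per-reaction multinomial coefficients (reference class omitted).

    ``intercepts`` and ``slopes`` are (R x (C-1)) frames indexed by reaction
    id with non-reference class columns; the reference class's coefficients
    are identically zero by convention.
    """

    intercepts: pd.DataFrame
    slopes: pd.DataFrame
    reference_class: str
    ridge: float
    converged: pd.Series
    log_likelihood: pd.Series

    def slope_norms(self) -> pd.Series:
        """Euclidean norm of each reaction's class-centered slope vector.

        The full slope vector over all C classes (reference entry 0) is
        centered to mean zero before taking the norm, so the statistic does
        not depend on which class serves as the reference — renaming
        classes leaves it unchanged.
        """
        b = self.slopes.to_numpy()
        c = b.shape[1] + 1
        sq = (b**2).sum(axis=1) - b.sum(axis=1) ** 2 / c
        return pd.Series(np.sqrt(np.maximum(sq, 0.0)), index=self.slopes.index)


def _negloglik_grad_hess(
    counts: np.ndarray, a: np.ndarray, b: np.ndarray, ridge: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Penalised NLL, gradient and Hessian from the 2 x C count table.

    ``counts[x, c]`` is the number of models with predictor value ``x`` in
    class ``c`` (class 0 = reference).  Parameters ``a``/``b`` are the
    intercepts/slopes of the C-1 non-reference classes.  The ridge penalty
    acts on the class-centered slope vector (reference entry 0 included in
    the centering), which keeps the fitted distribution independent of the
    reference-class choice.
    """
    cm1 = a.size
    c = cm1 + 1
    s = float(b.sum())
    nll = 0.5 * ridge * (float(b @ b) - s * s / c)
    grad = np.zeros(2 * cm1)
    hess = np.zeros((2 * cm1, 2 * cm1))
    grad[cm1:] = ridge * (b - s / c)
    hess[cm1:, cm1:] = ridge * (np.eye(cm1) - np.ones((cm1, cm1)) / c)
    for x in (0, 1):
        n_x = counts[x].sum()
        if n_x == 0:
            continue
        eta = a + b * x  # non-reference linear predictors; reference eta = 0
        zmax = max(0.0, float(eta.max()))
        logz = zmax + np.log(np.exp(-zmax) + np.exp(eta - zmax).sum())
        p = np.exp(eta - logz)  # probabilities of non-reference classes
        nll -= float(counts[x, 1:] @ eta) - n_x * logz
        g = n_x * p - counts[x, 1:]
        grad[:cm1] += g
        if x == 1:
            grad[cm1:] += g
        W = n_x * (np.diag(p) - np.outer(p, p))
        hess[:cm1, :cm1] += W
        if x == 1:
            hess[:cm1, cm1:] += W
            hess[cm1:, :cm1] += W
            hess[cm1:, cm1:] += W
    return nll, grad, hess


def _fit_one_reaction(
    counts: np.ndarray, ridge: float, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, bool, float]:
    """Damped Newton minimisation of the penalised multinomial NLL."""
    cm1 = counts.shape[1] - 1
    a = np.zeros(cm1)
    b = np.zeros(cm1)
    nll, grad, hess = _negloglik_grad_hess(counts, a, b, ridge)
    converged = False
    for _ in range(max_iter):
        step = np.linalg.solve(hess + 1e-12 * np.eye(2 * cm1), grad)
        t = 1.0
        for _ in range(30):
            a_new, b_new = a - t * step[:cm1], b - t * step[cm1:]
            nll_new, grad_new, hess_new = _negloglik_grad_hess(counts, a_new, b_new, ridge)
            if nll_new <= nll + 1e-12:
                break
            t /= 2.0
        a, b, nll, grad, hess = a_new, b_new, nll_new, grad_new, hess_new
        if np.max(np.abs(grad)) < tol * (1.0 + counts.sum()):
            converged = True
            break
    return a, b, converged, -nll


def fit_mlr(
    X: BinaryReactionMatrix,
    labels: ClusterLabels | Mapping[str, str],
    ridge: float = 1e-4,
    joint: bool = False,
) -> MLRCoefficients:
    """Fit multinomial logistic models relating reactions to class labels.

    By default each reaction is fitted separately (intercept + one binary
    presence indicator), maximising the L2-penalised likelihood.  With many
    more reactions than models a joint all-reaction fit is non-identifiable
    without heavy regularisation, which is why per-reaction fits are the
    default; ``joint=True`` fits a single ridge-penalised model over all
    reaction columns at once for sensitivity analysis.

    With binary predictors and several classes, perfect separation is
    common; an unpenalised per-reaction fit that fails to converge is
    automatically refitted at ``ridge = 1e-4`` with a logged notice.
    """
    if not isinstance(labels, ClusterLabels):
        labels = ClusterLabels(dict(labels))
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    y = labels.vector(list(X.row_ids))
    classes = labels.classes
    c = len(classes)
    noref = classes[1:]
    if joint:
        return _fit_joint(X, y, classes, ridge)

    intercepts = np.zeros((len(X.col_ids), c - 1))
    slopes = np.zeros((len(X.col_ids), c - 1))
    conv = np.zeros(len(X.col_ids), dtype=bool)
    ll = np.zeros(len(X.col_ids))
    v = X.values
    for j in range(v.shape[1]):
        counts = np.zeros((2, c))
        np.add.at(counts, (v[:, j], y), 1)
        a, b, ok, loglik = _fit_one_reaction(counts, ridge)
        if not ok and ridge == 0:
            logger.info(
                "reaction %s: unpenalised fit did not converge (separation); "
                "refitting with ridge=1e-4",
                X.col_ids[j],
            )
            a, b, ok, loglik = _fit_one_reaction(counts, 1e-4)
        intercepts[j], slopes[j], conv[j], ll[j] = a, b, ok, loglik

    return MLRCoefficients(
        intercepts=pd.DataFrame(intercepts, index=X.col_ids, columns=noref),
        slopes=pd.DataFrame(slopes, index=X.col_ids, columns=noref),
        reference_class=classes[0],
        ridge=ridge,
        converged=pd.Series(conv, index=X.col_ids),
        log_likelihood=pd.Series(ll, index=X.col_ids),
    )


def _fit_joint(
    X: BinaryReactionMatrix, y: np.ndarray, classes: list[str], ridge: float
) -> MLRCoefficients:
    """Single ridge-penalised multinomial fit over all reaction columns."""
    from sklearn.linear_model import LogisticRegression

    if ridge <= 0:
        raise ValueError("joint fit requires ridge > 0 (it is non-identifiable at 0)")
    clf = LogisticRegression(C=1.0 / ridge, max_iter=5000, tol=1e-10)
    clf.fit(X.values.astype(float), y)
    # sklearn's symmetric softmax coefficients, re-expressed against the
    # lexicographically first class as reference
    if len(classes) == 2:  # sklearn collapses the binary case to one row
        coef = np.vstack([np.zeros_like(clf.coef_[0]), clf.coef_[0]])
        intercept = np.array([0.0, clf.intercept_[0]])
    else:
        coef = clf.coef_ - clf.coef_[0]
        intercept = clf.intercept_ - clf.intercept_[0]
    noref = classes[1:]
    return MLRCoefficients(
        intercepts=pd.DataFrame(
            np.tile(intercept[1:], (len(X.col_ids), 1)), index=X.col_ids, columns=noref
        ),
        slopes=pd.DataFrame(coef[1:].T, index=X.col_ids, columns=noref),
        reference_class=classes[0],
        ridge=ridge,
        converged=pd.Series(clf.n_iter_[0] < 5000, index=X.col_ids),
        log_likelihood=pd.Series(np.nan, index=X.col_ids),
    )


def subsystem_mlr_importance(
    coef: MLRCoefficients, smap: SubsystemMap
) -> pd.DataFrame:
    """Average per-reaction slope norms within subsystems, max-normalised.

    Returns a frame indexed by subsystem with ``avg_beta_norm``, ``R_j``
    and ``avg_beta_norm_normalized`` columns, sorted descending (ties
    lexicographic).  If every coefficient is zero the normalised column is
    undefined (NaN) and a warning is logged.
    """
    norms = coef.slope_norms()
    subsystem = pd.Series([smap.subsystem_of(r) for r in norms.index], index=norms.index)
    grouped = norms.groupby(subsystem)
    out = pd.DataFrame({"avg_beta_norm": grouped.mean(), "R_j": grouped.size()})
    out = out.iloc[np.lexsort((out.index.to_numpy(), -out["avg_beta_norm"].to_numpy()))]
    peak = out["avg_beta_norm"].max()
    if peak > 0:
        out["avg_beta_norm_normalized"] = out["avg_beta_norm"] / peak
    else:
        logger.warning("all MLR coefficients are zero; normalisation undefined")
        out["avg_beta_norm_normalized"] = np.nan
    return out


def compare_rankings(
    lpca_ranking: pd.DataFrame,
    mlr_importance: pd.DataFrame,
    n: int = 5,
    lpca_column: str = "norm_of_avg",
) -> dict:
    """Agreement report between LPCA and MLR subsystem rankings.

    Reports the top-``n`` overlap, the Spearman rank correlation over the
    shared subsystems, and — per method — how many subsystems exceed 0.5
    after max-normalisation (a coarse count of how concentrated the signal
    is).
    """
    top_lpca = list(
        lpca_ranking.sort_values(lpca_column, ascending=False, kind="stable").index[:n]
    )
    top_mlr = list(
        mlr_importance.sort_values("avg_beta_norm", ascending=False, kind="stable").index[:n]
    )
    shared = sorted(set(lpca_ranking.index) & set(mlr_importance.index))
    corr = np.nan
    if len(shared) >= 2:
        a = lpca_ranking.loc[shared, lpca_column]
        b = mlr_importance.loc[shared, "avg_beta_norm"]
        corr = float(spearmanr(a, b).statistic)
    return {
        "top_n": n,
        "top_lpca": top_lpca,
        "top_mlr": top_mlr,
        "overlap": sorted(set(top_lpca) & set(top_mlr)),
        "overlap_count": len(set(top_lpca) & set(top_mlr)),
        "spearman_shared": corr,
        "n_above_half_lpca": int(
            (lpca_ranking[f"{lpca_column}_normalized"] > 0.5).sum()
        ),
        "n_above_half_mlr": int(
            (mlr_importance["avg_beta_norm_normalized"] > 0.5).sum()
        ),
    }
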