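"""Scikit-learn style estimators wrapping the grey relational pipeline.

:class:`GreyRelationalRanker` plays the role of a univariate feature
scorer: ``fit(X, y)`` takes the comparative series as columns of ``X``
and the reference (burden) series as ``y``, computes Deng, absolute and
second-synthetic grades plus a Pearson cross-check per column, and ranks
the columns.  ``transform`` reorders (and optionally truncates) the
columns by rank, so the ranker composes with sklearn pipelines.

:class:`HurwiczCriterion` scores a payoff matrix of alternatives x
criteria with the Hurwicz realism rule and selects an alternative.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import gra
from .panel import EpochSeries, GreyPanel, NormalizationMethod, normalize_panel

__all__ = ["GreyRelationalRanker", "HurwiczCriterion"]

logger = logging.getLogger("greyrank.estimators")

METRICS = ("gamma", "epsilon", "p", "pearson_r")


def _tied_groups(labels, values) -> list:
    """Groups of labels sharing an identical metric value (size >= 2)."""
    by_value: dict = {}
    for lab, val in zip(labels, values):
        by_value.setdefault(float(val), []).append(lab)
    return [sorted(group) for group in by_value.values() if len(group) > 1]


def rank_labels(labels, values, return_ties: bool = False):
    """Labels in strictly descending value order; ties broken lexicographically.

    Returns the ordered label list, and with ``return_ties=True`` also the
    tied groups (each a sorted list of labels sharing one value).
    """
    labels = list(labels)
    values = np.asarray(values, dtype=float)
    if len(labels) != values.size:
        raise ValueError("labels and values must have equal length")
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot rank non-finite values")
    order = sorted(range(len(labels)), key=lambda i: (-values[i], labels[i]))
    ranked = [labels[i] for i in order]
    if return_ties:
        return ranked, _tied_groups(labels, values)
    return ranked


class GreyRelationalRanker(TransformerMixin, BaseEstimator):
    """Rank comparative series against a reference by grey relational grade.

    Parameters
    ----------
    normalization : str, default "mean_image"
        Per-series operator applied to the reference and every comparative
        before grading (see :class:`~greyrank.panel.NormalizationMethod`).
        ``"none"`` grades the raw series.
    zeta : float, default 0.5
        Deng distinguishing coefficient, in (0, 1).
    extremes_scope : {"panel_wide", "per_pair"}, default "panel_wide"
        Scope of the min/max deviations in Deng's coefficient.
    theta : float, default 0.5
        Blend weight of the second synthetic grade.
    compute_pearson : bool, default True
        Also compute the product-moment correlation on the same
        (normalized) series, as a conventional cross-check of the
        grey ordering.
    n_select : int or None, default None
        If set, ``transform`` keeps only the top ``n_select`` columns by
        second-synthetic rank; otherwise all columns, reordered.

    Attributes
    ----------
    labels_ : list of str
        Comparative labels in input column order.
    gamma_, epsilon_, p_, pearson_r_ : ndarray
        Grades per comparative, aligned with ``labels_``.
    grades_ : pandas.DataFrame
        One row per comparative: the four metrics and a ``rank_<metric>``
        column each (1 = strongest association).
    ranking_ : dict
        Metric name -> labels in descending-grade order.
    ties_ : dict
        Metric name -> groups of labels with exactly equal grades.
    panel_extremes_ : tuple of float
        Global (min, max) absolute deviation used by panel-wide Deng.
    """

    def __init__(
        self,
        normalization: str = "mean_image",
        zeta: float = 0.5,
        extremes_scope: str = "panel_wide",
        theta: float = 0.5,
        compute_pearson: bool = True,
        n_select: int | None = None,
    ):
        self.normalization = normalization
        self.zeta = zeta
        self.extremes_scope = extremes_scope
        self.theta = theta
        self.compute_pearson = compute_pearson
        self.n_select = n_select

    # ------------------------------------------------------------------
    def _as_panel(self, X, y) -> GreyPanel:
        if isinstance(X, pd.DataFrame):
            labels = [str(c) for c in X.columns]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2:
                raise ValueError("X must be 2-D (n_epochs, n_comparatives)")
            labels = [f"x{j}" for j in range(values.shape[1])]
        yv = np.asarray(
            y.values if isinstance(y, EpochSeries) else y, dtype=float
        ).ravel()
        if yv.size != values.shape[0]:
            raise ValueError(
                f"y has {yv.size} epochs but X has {values.shape[0]} rows"
            )
        epochs = tuple(range(values.shape[0]))
        ref_label = y.label if isinstance(y, EpochSeries) else "reference"
        reference = EpochSeries(ref_label, epochs, yv)
        comparatives = tuple(
            EpochSeries(lab, epochs, values[:, j]) for j, lab in enumerate(labels)
        )
        return GreyPanel(reference=reference, comparatives=comparatives)

    def fit(self, X, y):
        """Compute all grades and ranks for the columns of X against y."""
        panel = self._as_panel(X, y)
        return self._fit_panel(panel)

    def fit_panel(self, panel: GreyPanel) -> "GreyRelationalRanker":
        """Fit directly from a :class:`GreyPanel` (labels preserved)."""
        # re-validate dataclass invariants hold for externally built panels
        return self._fit_panel(panel)

    def _fit_panel(self, panel: GreyPanel) -> "GreyRelationalRanker":
        if not panel.comparatives:
            raise ValueError("panel must contain at least one comparative")
        method = NormalizationMethod.coerce(self.normalization)
        deng_params = gra.DengParams(zeta=self.zeta, extremes_scope=self.extremes_scope)
        synth_params = gra.SyntheticParams(theta=self.theta)

        normalized = normalize_panel(panel, method)
        extremes = gra.panel_deviation_extremes(normalized)
        logger.info(
            "fit: %d comparatives, %d epochs, normalization=%s, "
            "panel deviation extremes=(%.6g, %.6g)",
            len(panel.comparatives), panel.n_epochs, method.value, *extremes,
        )

        labels = [c.label for c in normalized.comparatives]
        gammas, epsilons, ps, rs = [], [], [], []
        for cmp in normalized.comparatives:
            g = gra.deng_grade(normalized.reference, cmp, deng_params, extremes)
            e = gra.absolute_grade(normalized.reference, cmp)
            gammas.append(g)
            epsilons.append(e)
            ps.append(gra.synthetic_grade(g, e, synth_params))
            if self.compute_pearson:
                from .decision import pearson_r

                rs.append(pearson_r(normalized.reference, cmp))

        self.labels_ = labels
        self.gamma_ = np.asarray(gammas)
        self.epsilon_ = np.asarray(epsilons)
        self.p_ = np.asarray(ps)
        self.pearson_r_ = np.asarray(rs) if self.compute_pearson else None
        self.panel_extremes_ = extremes
        self.n_features_in_ = len(labels)
        self.feature_names_in_ = np.asarray(labels, dtype=object)

        metric_values = {"gamma": self.gamma_, "epsilon": self.epsilon_, "p": self.p_}
        if self.compute_pearson:
            metric_values["pearson_r"] = self.pearson_r_

        table = pd.DataFrame(metric_values, index=pd.Index(labels, name="factor"))
        self.ranking_ = {}
        self.ties_ = {}
        for metric, values in metric_values.items():
            ranked, ties = rank_labels(labels, values, return_ties=True)
            self.ranking_[metric] = ranked
            self.ties_[metric] = ties
            table[f"rank_{metric}"] = [ranked.index(lab) + 1 for lab in labels]
        self.grades_ = table
        return self

    def transform(self, X):
        """Reorder columns by second-synthetic rank, keeping the top n_select."""
        if not hasattr(self, "labels_"):
            raise ValueError("GreyRelationalRanker is not fitted yet")
        keep = self.ranking_["p"]
        if self.n_select is not None:
            if not (1 <= self.n_select <= len(keep)):
                raise ValueError(
                    f"n_select must be in [1, {len(keep)}], got {self.n_select}"
                )
            keep = keep[: self.n_select]
        if isinstance(X, pd.DataFrame):
            return X[keep]
        X = np.asarray(X, dtype=float)
        idx = [self.labels_.index(lab) for lab in keep]
        return X[:, idx]

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "labels_"):
            raise ValueError("GreyRelationalRanker is not fitted yet")
        keep = self.ranking_["p"]
        if self.n_select is not None:
            keep = keep[: self.n_select]
        return np.asarray(keep, dtype=object)


class HurwiczCriterion(BaseEstimator):
    """Hurwicz (realism) criterion over an alternatives x criteria payoff grid.

    Each alternative A_k receives
    ``h(A_k) = alpha * max_p v(A_k, N_p) + (1 - alpha) * min_p v(A_k, N_p)``,
    a convex blend of its best and worst payoff governed by the optimism
    index ``alpha``; the selected alternative minimizes (default) or
    maximizes h.  Ties go to the earliest alternative and are flagged.

    Attributes
    ----------
    h_values_ : pandas.Series
        Hurwicz value per alternative, in input order.
    selected_ : label of the optimizing alternative.
    selected_index_ : its positional index.
    tie_ : bool, True when another alternative attains the same optimum.
    """

    def __init__(self, alpha: float = 0.8, objective: str = "minimize"):
        self.alpha = alpha
        self.objective = objective

    def fit(self, X, y=None):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.objective not in ("minimize", "maximize"):
            raise ValueError(
                f"objective must be 'minimize' or 'maximize', got {self.objective!r}"
            )
        if isinstance(X, pd.DataFrame):
            payoffs = X.to_numpy(dtype=float)
            alternatives = [str(i) for i in X.index]
        else:
            payoffs = np.asarray(X, dtype=float)
            if payoffs.ndim != 2:
                raise ValueError("payoff matrix must be 2-D (alternatives x criteria)")
            alternatives = [f"A{k + 1}" for k in range(payoffs.shape[0])]
        if payoffs.size == 0:
            raise ValueError("payoff matrix is empty")
        if not np.all(np.isfinite(payoffs)):
            raise ValueError("payoff matrix must be finite and complete")

        h = self.alpha * payoffs.max(axis=1) + (1.0 - self.alpha) * payoffs.min(axis=1)
        self.alternatives_ = alternatives
        self.h_values_ = pd.Series(h, index=alternatives, name="h_value")
        best = float(h.min() if self.objective == "minimize" else h.max())
        hits = np.flatnonzero(h == best)
        self.selected_index_ = int(hits[0])
        self.selected_ = alternatives[self.selected_index_]
        self.tie_ = len(hits) > 1
        return self
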