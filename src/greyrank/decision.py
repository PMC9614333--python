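"""Factor ranking, Pearson cross-check, Hurwicz criterion, and the pipeline.

The end-to-end analysis takes one grey panel per disease, grades every
risk factor against the disease burden with the three grey relational
models, ranks factors per metric, assembles the second-synthetic grades
into a diseases x factors decision matrix, and applies the Hurwicz
criterion to single out one disease.  Functions here are thin wrappers
over the estimators in :mod:`greyrank.estimators`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .estimators import GreyRelationalRanker, HurwiczCriterion, rank_labels
from .gra import DengParams, GradeError, SyntheticParams
from .panel import EpochSeries, GreyPanel

__all__ = [
    "RelationalGrades",
    "DecisionMatrix",
    "HurwiczParams",
    "HurwiczResult",
    "PipelineResult",
    "rank_factors",
    "pearson_r",
    "hurwicz_values",
    "run_pipeline",
]

METRICS = ("gamma", "epsilon", "p", "pearson_r")


@dataclass(frozen=True)
class RelationalGrades:
    """Per-factor grades and ranks for one disease panel.

    ``table`` has one row per factor with columns ``gamma``, ``epsilon``,
    ``p`` (and ``pearson_r`` when computed) plus ``rank_<metric>`` columns
    where rank 1 marks the strongest association.  ``ties`` lists, per
    metric, groups of factors whose grades are exactly equal (those ranks
    were broken lexicographically).
    """

    table: pd.DataFrame
    ties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for metric in ("gamma", "epsilon", "p"):
            if metric not in self.table.columns:
                raise ValueError(f"grades table lacks required column '{metric}'")
        n = len(self.table)
        for col in self.table.columns:
            if col.startswith("rank_"):
                ranks = sorted(int(r) for r in self.table[col])
                if ranks != list(range(1, n + 1)):
                    raise ValueError(
                        f"column '{col}' is not a permutation of 1..{n}"
                    )

    @property
    def factors(self) -> list:
        return list(self.table.index)

    def ranking(self, metric: str = "p") -> list:
        """Factor labels in descending-grade order for one metric."""
        return rank_factors(self, metric)


def rank_factors(grades, metric: str = "p", return_ties: bool = False):
    """Order factor labels by descending grade under one metric.

    ``grades`` may be a :class:`RelationalGrades`, a pandas Series
    (label -> value), or a mapping.  Ties are broken lexicographically by
    label; pass ``return_ties=True`` to also receive the tied groups.
    """
    if isinstance(grades, RelationalGrades):
        if metric not in grades.table.columns:
            raise ValueError(
                f"unknown metric {metric!r}; available: "
                f"{[c for c in grades.table.columns if not c.startswith('rank_')]}"
            )
        series = grades.table[metric]
    elif isinstance(grades, pd.Series):
        series = grades
    elif isinstance(grades, Mapping):
        series = pd.Series(grades)
    else:
        raise TypeError(
            "grades must be RelationalGrades, a pandas Series, or a mapping"
        )
    return rank_labels(list(series.index), series.to_numpy(dtype=float), return_ties)


def pearson_r(ref, cmp) -> float:
    """Product-moment correlation between two series of equal length >= 3.

    Raises :class:`~greyrank.gra.GradeError` when either series is
    constant (the coefficient is undefined).
    """
    r = ref.values if isinstance(ref, EpochSeries) else np.asarray(ref, dtype=float)
    c = cmp.values if isinstance(cmp, EpochSeries) else np.asarray(cmp, dtype=float)
    if r.size != c.size:
        raise GradeError(f"length mismatch: {r.size} vs {c.size}")
    if r.size < 3:
        raise GradeError("Pearson correlation needs at least 3 epochs")
    for name, v, obj in (("ref", r, ref), ("cmp", c, cmp)):
        if np.ptp(v) == 0.0:
            label = obj.label if isinstance(obj, EpochSeries) else name
            raise GradeError(
                f"Pearson correlation undefined for constant series '{label}'"
            )
    return float(stats.pearsonr(r, c).statistic)


@dataclass(frozen=True)
class HurwiczParams:
    """Optimism index and optimization direction of the Hurwicz criterion."""

    alpha: float = 0.8
    objective: str = "minimize"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.objective not in ("minimize", "maximize"):
            raise ValueError(
                f"objective must be 'minimize' or 'maximize', got {self.objective!r}"
            )


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives (diseases) x criteria (risk factors) payoff grid."""

    payoffs: pd.DataFrame

    def __post_init__(self) -> None:
        if self.payoffs.size == 0:
            raise ValueError("decision matrix is empty")
        values = self.payoffs.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("decision matrix must be complete and finite")

    @property
    def alternatives(self) -> list:
        return list(self.payoffs.index)

    @property
    def criteria(self) -> list:
        return list(self.payoffs.columns)


@dataclass(frozen=True)
class HurwiczResult:
    """Hurwicz values per alternative and the selected alternative."""

    h_values: pd.Series
    selected: str
    alpha: float
    objective: str
    tie: bool = False


def hurwicz_values(matrix, params: HurwiczParams | None = None) -> HurwiczResult:
    """Apply the Hurwicz criterion to a decision matrix.

    ``matrix`` may be a :class:`DecisionMatrix`, a DataFrame (index =
    alternatives) or a 2-D array.  Each alternative scores
    ``alpha * row_max + (1 - alpha) * row_min``; the selected alternative
    optimizes that score in the requested direction.
    """
    params = params or HurwiczParams()
    payoffs = matrix.payoffs if isinstance(matrix, DecisionMatrix) else matrix
    crit = HurwiczCriterion(alpha=params.alpha, objective=params.objective).fit(payoffs)
    return HurwiczResult(
        h_values=crit.h_values_,
        selected=crit.selected_,
        alpha=params.alpha,
        objective=params.objective,
        tie=crit.tie_,
    )


@dataclass(frozen=True)
class PipelineResult:
    """Full results bundle: per-disease grades, decision matrix, Hurwicz."""

    per_disease: dict
    decision_matrix: DecisionMatrix
    hurwicz: HurwiczResult
    metadata: dict

    def grades_frame(self) -> pd.DataFrame:
        """Flat table: one row per (disease, factor) with grades and ranks."""
        rows = []
        for disease, grades in self.per_disease.items():
            frame = grades.table.reset_index()
            frame.insert(0, "disease", disease)
            rows.append(frame)
        return pd.concat(rows, ignore_index=True)

    def to_dict(self) -> dict:
        out = {
            "metadata": dict(self.metadata),
            "diseases": {},
            "decision": {
                "alternatives": self.decision_matrix.alternatives,
                "criteria": self.decision_matrix.criteria,
                "payoffs": self.decision_matrix.payoffs.to_numpy().tolist(),
                "hurwicz": {
                    "alpha": self.hurwicz.alpha,
                    "objective": self.hurwicz.objective,
                    "h_values": {
                        str(k): float(v) for k, v in self.hurwicz.h_values.items()
                    },
                    "selected": self.hurwicz.selected,
                    "tie": self.hurwicz.tie,
                },
            },
        }
        for disease, grades in self.per_disease.items():
            metric_cols = [c for c in grades.table.columns if not c.startswith("rank_")]
            out["diseases"][disease] = {
                "grades": {
                    str(factor): {
                        col: float(row[col]) for col in grades.table.columns
                    }
                    for factor, row in grades.table.iterrows()
                },
                "rankings": {m: rank_factors(grades, m) for m in metric_cols},
                "ties": {m: grades.ties.get(m, []) for m in metric_cols},
            }
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def run_pipeline(
    panels: Mapping[str, GreyPanel],
    normalization: str = "mean_image",
    deng: DengParams | None = None,
    synth: SyntheticParams | None = None,
    hurwicz: HurwiczParams | None = None,
    compute_pearson: bool = True,
) -> PipelineResult:
    """Grade, rank, and decide over one grey panel per disease.

    All panels must share the same comparative (risk-factor) labels so
    the second-synthetic grades form a complete decision matrix.
    """
    if not panels:
        raise ValueError("need at least one panel")
    deng = deng or DengParams()
    synth = synth or SyntheticParams()
    hparams = hurwicz or HurwiczParams()

    diseases = list(panels)
    factor_sets = {d: panels[d].comparative_labels for d in diseases}
    first = factor_sets[diseases[0]]
    for d in diseases[1:]:
        if set(factor_sets[d]) != set(first):
            missing = sorted(set(first) ^ set(factor_sets[d]))
            raise ValueError(
                f"panels disagree on comparative labels; '{diseases[0]}' vs "
                f"'{d}' differ on: {missing}"
            )

    per_disease: dict = {}
    payoff_rows = []
    for disease in diseases:
        ranker = GreyRelationalRanker(
            normalization=normalization,
            zeta=deng.zeta,
            extremes_scope=deng.extremes_scope,
            theta=synth.theta,
            compute_pearson=compute_pearson,
        ).fit_panel(panels[disease])
        per_disease[disease] = RelationalGrades(
            table=ranker.grades_, ties=ranker.ties_
        )
        payoff_rows.append(
            ranker.grades_["p"].reindex(first).to_numpy(dtype=float)
        )

    matrix = DecisionMatrix(
        payoffs=pd.DataFrame(payoff_rows, index=diseases, columns=first)
    )
    result = hurwicz_values(matrix, hparams)
    metadata = {
        "version": __version__,
        "normalization": str(
            normalization.value if hasattr(normalization, "value") else normalization
        ),
        "zeta": deng.zeta,
        "extremes_scope": deng.extremes_scope,
        "theta": synth.theta,
        "alpha": hparams.alpha,
        "objective": hparams.objective,
        "diseases": diseases,
        "factors": first,
        "n_epochs": {d: panels[d].n_epochs for d in diseases},
    }
    return PipelineResult(
        per_disease=per_disease,
        decision_matrix=matrix,
        hurwicz=result,
        metadata=metadata,
    )
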