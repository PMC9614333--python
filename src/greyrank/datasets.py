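"""Published reference grades: diet and nutrition versus cardiac burden in Spain.

A published grey-relational assessment scored six dietary and
nutritional risk factors against annual DALY series (2010-2019, both
sexes, percent of total population, Global Burden of Disease 2019) for
ischemic heart disease (IHD) and stroke in Spain, reporting for each
factor the Deng grade, the absolute grade, the second-synthetic grade
(theta = 0.5), and a correlation-based index used as an ordering
cross-check.  Those reported grade tables — not the underlying annual
series, which are not redistributed here — are bundled as inputs for
recombination checks, ranking concordance checks, and the worked
Hurwicz example (alpha = 0.8).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_reference_grades",
    "reference_decision_matrix",
    "REFERENCE_RANKINGS",
    "FACTORS",
]

FACTORS = [
    "Vitamin A deficiency",
    "Diet low in vegetables",
    "Diet high in sodium",
    "Zinc deficiency",
    "Iron deficiency",
    "Diet low in fruits",
]

_COLUMNS = ["gamma", "epsilon", "p", "r"]

# rows: (Deng gamma, absolute epsilon, second-synthetic p, correlation index)
_IHD = [
    (0.9287, 0.9321, 0.9304, 7.62),
    (0.9889, 0.9935, 0.9912, 18.04),
    (0.8472, 0.8658, 0.8565, 6.50),
    (0.7806, 0.8014, 0.7910, 3.11),
    (0.6931, 0.7083, 0.7007, 2.49),
    (0.9799, 0.9947, 0.9873, 17.01),
]

_STROKE = [
    (0.8951, 0.9001, 0.8976, 7.01),
    (0.9509, 0.9701, 0.9605, 23.00),
    (0.8908, 0.9110, 0.9009, 10.65),
    (0.8090, 0.8112, 0.8101, 4.21),
    (0.7192, 0.7212, 0.7202, 1.22),
    (0.9848, 0.9904, 0.9876, 23.68),
]

# "Ranking sequence based on GRA" as reported alongside the grade tables;
# the correlation-index ordering was reported as identical.
REFERENCE_RANKINGS = {
    "IHD": [
        "Diet low in vegetables",
        "Diet low in fruits",
        "Vitamin A deficiency",
        "Diet high in sodium",
        "Zinc deficiency",
        "Iron deficiency",
    ],
    "Stroke": [
        "Diet low in fruits",
        "Diet low in vegetables",
        "Diet high in sodium",
        "Vitamin A deficiency",
        "Zinc deficiency",
        "Iron deficiency",
    ],
}


def load_reference_grades() -> dict:
    """Reported grade tables per disease.

    Returns a dict mapping disease name ("IHD", "Stroke") to a DataFrame
    indexed by risk factor with columns ``gamma`` (Deng), ``epsilon``
    (absolute), ``p`` (second synthetic) and ``r`` (the reported
    correlation index, used only for its ordering).
    """
    return {
        "IHD": pd.DataFrame(_IHD, index=pd.Index(FACTORS, name="factor"), columns=_COLUMNS),
        "Stroke": pd.DataFrame(_STROKE, index=pd.Index(FACTORS, name="factor"), columns=_COLUMNS),
    }


def reference_decision_matrix() -> pd.DataFrame:
    """Diseases x factors payoff grid of reported second-synthetic grades."""
    tables = load_reference_grades()
    return pd.DataFrame(
        {disease: tables[disease]["p"] for disease in ("IHD", "Stroke")}
    ).T
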