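"""Grey relational engines: Deng's grade, the absolute grade, and their blend.

Grey relational analysis (GRA) scores the association between a reference
series Y_i and a comparative series Y_j by the geometric similarity of
their curves, yielding a grade in (0, 1] — higher means closer.  Three
models are implemented:

* **Deng's grade** (gamma): mean over epochs of a point coefficient built
  from absolute deviations ``|Y_i(l) - Y_j(l)|`` contrasted against the
  global minimum and maximum deviation, with a distinguishing
  coefficient ``zeta`` (conventionally 0.5).  Captures *pointwise*
  (partial) proximity.
* **Absolute grade** (epsilon): built from signed integrals of the
  zero-start images (series shifted to start at 0), so it captures
  *integral* proximity and is invariant to constant level shifts.
* **Second synthetic grade** (p): the convex blend
  ``p = theta * epsilon + (1 - theta) * gamma``, combining both notions
  of closeness; ``theta = 0.5`` weighs them equally.

All grades equal exactly 1 for pairs with identical shape in the sense
each model measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .panel import EpochSeries, GreyPanel

__all__ = [
    "DengParams",
    "SyntheticParams",
    "IncidenceComponents",
    "GradeError",
    "panel_deviation_extremes",
    "deng_point_coefficients",
    "deng_grade",
    "zero_start_image",
    "series_integral",
    "absolute_grade",
    "synthetic_grade",
]

logger = logging.getLogger("greyrank.gra")

EXTREMES_SCOPES = ("panel_wide", "per_pair")


class GradeError(ValueError):
    """Invalid input to a grey relational computation."""


@dataclass(frozen=True)
class DengParams:
    """Parameters of Deng's model.

    zeta : distinguishing coefficient in (0, 1); larger values flatten the
        contrast between small and large deviations.  0.5 is the
        near-universal convention.
    extremes_scope : where the min/max deviations in the point coefficient
        come from.  ``panel_wide`` (classical Deng) takes them over all
        comparatives in the panel; ``per_pair`` over the single pair.
    """

    zeta: float = 0.5
    extremes_scope: str = "panel_wide"

    def __post_init__(self) -> None:
        if not (0.0 < self.zeta < 1.0):
            raise GradeError(f"zeta must lie in (0, 1), got {self.zeta}")
        if self.extremes_scope not in EXTREMES_SCOPES:
            raise GradeError(
                f"extremes_scope must be one of {EXTREMES_SCOPES}, "
                f"got {self.extremes_scope!r}"
            )


@dataclass(frozen=True)
class SyntheticParams:
    """Blend weight for the second synthetic grade: p = theta*eps + (1-theta)*gamma."""

    theta: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise GradeError(f"theta must lie in [0, 1], got {self.theta}")


@dataclass(frozen=True)
class IncidenceComponents:
    """Signed integrals underlying the absolute grade.

    s_ref and s_cmp integrate the zero-start images of the reference and
    comparative; s_diff integrates their pointwise difference.  Identical
    series give s_diff == 0 and hence a grade of exactly 1.
    """

    s_ref: float
    s_cmp: float
    s_diff: float


def _values(x, name: str = "series") -> np.ndarray:
    if isinstance(x, EpochSeries):
        return x.values
    v = np.asarray(x, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise GradeError(f"{name} must be 1-D with at least 2 epochs")
    if not np.all(np.isfinite(v)):
        raise GradeError(f"{name} must be finite")
    return v


def _label(x, fallback: str) -> str:
    return x.label if isinstance(x, EpochSeries) else fallback


def panel_deviation_extremes(panel: GreyPanel) -> tuple[float, float]:
    """Global (min, max) absolute deviation |ref - cmp| over all comparatives.

    These are the ``min_k min_l`` / ``max_k max_l`` extremes entering
    Deng's point coefficient under ``panel_wide`` scope.
    """
    if not panel.comparatives:
        raise GradeError("panel has no comparatives")
    ref = panel.reference.values
    devs = np.abs(np.stack([c.values for c in panel.comparatives]) - ref)
    return float(devs.min()), float(devs.max())


def deng_point_coefficients(
    ref,
    cmp,
    params: DengParams | None = None,
    panel_extremes: tuple[float, float] | None = None,
) -> np.ndarray:
    """Deng's point relational coefficient at every epoch.

    coefficient(l) = (d_min + zeta*d_max) / (d(l) + zeta*d_max), where
    d(l) = |ref(l) - cmp(l)| and (d_min, d_max) are the extreme deviations
    under the chosen scope.  When every deviation is zero the ratio is
    0/0; the limit (and the grey-systems convention) is 1, which keeps
    identical pairs at a perfect score.
    """
    params = params or DengParams()
    r = _values(ref, "ref")
    c = _values(cmp, "cmp")
    if r.size != c.size:
        raise GradeError(
            f"length mismatch: ref has {r.size} epochs, cmp has {c.size}"
        )
    dev = np.abs(r - c)
    if params.extremes_scope == "panel_wide":
        if panel_extremes is None:
            raise GradeError(
                "extremes_scope='panel_wide' requires panel_extremes "
                "(see panel_deviation_extremes)"
            )
        d_min, d_max = map(float, panel_extremes)
    else:
        d_min, d_max = float(dev.min()), float(dev.max())
    if d_max == 0.0:
        return np.ones_like(dev)
    coeff = (d_min + params.zeta * d_max) / (dev + params.zeta * d_max)
    logger.debug(
        "Deng coefficients %s~%s (scope=%s, d_min=%g, d_max=%g): %s",
        _label(ref, "ref"), _label(cmp, "cmp"),
        params.extremes_scope, d_min, d_max, coeff,
    )
    return coeff


def deng_grade(
    ref,
    cmp,
    params: DengParams | None = None,
    panel_extremes: tuple[float, float] | None = None,
) -> float:
    """Deng's grey relational grade: the mean point coefficient, in (0, 1]."""
    grade = float(np.mean(deng_point_coefficients(ref, cmp, params, panel_extremes)))
    logger.info("Deng grade %s~%s = %.6f", _label(ref, "ref"), _label(cmp, "cmp"), grade)
    return grade


def zero_start_image(series):
    """Shift a series so it starts at zero: x0(l) = x(l) - x(1).

    Accepts an :class:`EpochSeries` (returned as such) or a plain array.
    Idempotent; a constant series maps to all zeros.
    """
    if isinstance(series, EpochSeries):
        return series.with_values(series.values - series.values[0])
    v = _values(series)
    return v - v[0]


def series_integral(zero_start) -> float:
    """Signed area under a zero-start image, trapezoid rule on unit spacing.

    With x0(1) = 0 this equals sum(x0(2..h-1)) + x0(h)/2, the classical
    discrete grey-incidence quantity.
    """
    v = _values(zero_start, "zero_start")
    if v[0] != 0.0:
        raise GradeError(
            f"series_integral expects a zero-start image; first value is {v[0]}"
        )
    return float(np.trapezoid(v))


def absolute_grade(ref, cmp, return_components: bool = False):
    """Absolute grey relational grade epsilon in (0, 1].

    epsilon = (1 + |s_ref| + |s_cmp|) / (1 + |s_ref| + |s_cmp| + |s_diff|)
    with s_* the signed integrals of the zero-start images (see
    :class:`IncidenceComponents`).  Invariant under adding a constant to
    either series; equals 1 iff s_diff == 0.
    """
    r = _values(ref, "ref")
    c = _values(cmp, "cmp")
    if r.size != c.size:
        raise GradeError(
            f"length mismatch: ref has {r.size} epochs, cmp has {c.size}"
        )
    r0 = r - r[0]
    c0 = c - c[0]
    comps = IncidenceComponents(
        s_ref=float(np.trapezoid(r0)),
        s_cmp=float(np.trapezoid(c0)),
        s_diff=float(np.trapezoid(r0 - c0)),
    )
    shared = 1.0 + abs(comps.s_ref) + abs(comps.s_cmp)
    eps = shared / (shared + abs(comps.s_diff))
    logger.info("absolute grade %s~%s = %.6f", _label(ref, "ref"), _label(cmp, "cmp"), eps)
    if return_components:
        return eps, comps
    return eps


def synthetic_grade(gamma: float, epsilon: float, params: SyntheticParams | None = None) -> float:
    """Second synthetic grade: p = theta*epsilon + (1-theta)*gamma.

    A convex combination, hence always between min(gamma, epsilon) and
    max(gamma, epsilon); theta=0 returns gamma, theta=1 returns epsilon.
    """
    params = params or SyntheticParams()
    for name, g in (("gamma", gamma), ("epsilon", epsilon)):
        if not (0.0 < g <= 1.0):
            raise GradeError(f"{name} must lie in (0, 1], got {g}")
    return params.theta * epsilon + (1.0 - params.theta) * gamma
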