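"""Panel data model: labelled epoch series, grey panels, normalization, CSV I/O.

A :class:`GreyPanel` bundles one *reference* series (the outcome whose
drivers are sought, e.g. annual ischemic-heart-disease DALYs expressed as
a percentage of the population) with an ordered set of *comparative*
series (candidate risk-factor exposures observed over the same epochs).
Grey relational models measure similarity of curve shape, so panels are
normalized before analysis; which operator to use is an explicit,
logged parameter of every pipeline run.  The default is the classical
grey-systems averaging operator (``mean_image``: divide each series by
its own mean), a convention rather than a universal prescription.
"""

from __future__ import annotations

import csv
import enum
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "GreyPanel",
    "NormalizationMethod",
    "PanelError",
    "PanelFormatError",
    "NormalizationError",
    "normalize_series",
    "normalize_panel",
    "read_panel",
    "write_panel",
]


class PanelError(ValueError):
    """Invalid panel or series construction."""


class PanelFormatError(PanelError):
    """Malformed panel file (structure, missing or non-numeric cells)."""


class NormalizationError(PanelError):
    """Normalization cannot be applied (zero divisor, constant series)."""


@dataclass(frozen=True)
class EpochSeries:
    """One labelled time series over equally spaced epochs.

    Parameters
    ----------
    label : str
        Series identifier, unique within a panel.
    epochs : sequence
        Ordered epoch labels (typically calendar years).  Numeric epochs
        must be strictly increasing; the models themselves index by
        position, treating epochs as equally spaced.
    values : sequence of float
        One finite measurement per epoch; at least two epochs.
    """

    label: str
    epochs: tuple = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        epochs = tuple(self.epochs)
        if values.ndim != 1:
            raise PanelError(f"series '{self.label}': values must be 1-D")
        if len(epochs) != values.size:
            raise PanelError(
                f"series '{self.label}': {len(epochs)} epochs but "
                f"{values.size} values"
            )
        if values.size < 2:
            raise PanelError(f"series '{self.label}': need at least 2 epochs")
        if not np.all(np.isfinite(values)):
            raise PanelError(f"series '{self.label}': values must be finite")
        if all(isinstance(e, numbers.Real) for e in epochs):
            if not all(a < b for a, b in zip(epochs, epochs[1:])):
                raise PanelError(
                    f"series '{self.label}': epochs must be strictly increasing"
                )
        elif len(set(epochs)) != len(epochs):
            raise PanelError(f"series '{self.label}': duplicate epoch labels")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "epochs", epochs)

    def __len__(self) -> int:
        return self.values.size

    def to_numpy(self) -> np.ndarray:
        return np.array(self.values, dtype=float)

    def with_values(self, values: Sequence[float], label: str | None = None) -> "EpochSeries":
        """Return a copy with new values (and optionally a new label)."""
        return EpochSeries(label if label is not None else self.label, self.epochs, np.asarray(values, dtype=float))


@dataclass(frozen=True)
class GreyPanel:
    """A reference series plus ordered comparative series of equal length."""

    reference: EpochSeries
    comparatives: tuple = ()

    def __post_init__(self) -> None:
        comparatives = tuple(self.comparatives)
        n = len(self.reference)
        labels = [self.reference.label] + [c.label for c in comparatives]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise PanelError(f"duplicate series labels in panel: {dupes}")
        for c in comparatives:
            if len(c) != n:
                raise PanelError(
                    f"comparative '{c.label}' has length {len(c)} but the "
                    f"reference '{self.reference.label}' has length {n}"
                )
            if c.epochs != self.reference.epochs:
                raise PanelError(
                    f"comparative '{c.label}' has different epochs than "
                    f"reference '{self.reference.label}'"
                )
        object.__setattr__(self, "comparatives", comparatives)

    @property
    def n_epochs(self) -> int:
        return len(self.reference)

    @property
    def comparative_labels(self) -> list:
        return [c.label for c in self.comparatives]

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: epoch index, one column per series (reference first)."""
        data = {self.reference.label: self.reference.values}
        for c in self.comparatives:
            data[c.label] = c.values
        return pd.DataFrame(data, index=pd.Index(self.reference.epochs, name="epoch"))


class NormalizationMethod(str, enum.Enum):
    """Per-series normalization operators used ahead of grey modelling.

    ``none``           leave values unchanged.
    ``initial_value``  divide by the first value (grey "initialling" operator).
    ``mean_image``     divide by the series mean (grey "averaging" operator).
    ``min_max``        affine map onto [0, 1].
    """

    NONE = "none"
    INITIAL_VALUE = "initial_value"
    MEAN_IMAGE = "mean_image"
    MIN_MAX = "min_max"

    @classmethod
    def coerce(cls, method: "NormalizationMethod | str") -> "NormalizationMethod":
        if isinstance(method, cls):
            return method
        try:
            return cls(str(method))
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise PanelError(
                f"unknown normalization method {method!r}; expected one of: {valid}"
            ) from None


def normalize_series(series: EpochSeries, method: NormalizationMethod | str) -> EpochSeries:
    """Normalize one series.  ``none`` returns the input unchanged.

    Raises
    ------
    NormalizationError
        If the divisor is zero (``initial_value`` on a zero-start series,
        ``mean_image`` on a zero-mean series) or the series is constant
        under ``min_max``.  The message names the offending series.
    """
    method = NormalizationMethod.coerce(method)
    v = series.values
    if method is NormalizationMethod.NONE:
        return series
    if method is NormalizationMethod.INITIAL_VALUE:
        if v[0] == 0.0:
            raise NormalizationError(
                f"cannot apply initial_value normalization to series "
                f"'{series.label}': first value is zero"
            )
        return series.with_values(v / v[0])
    if method is NormalizationMethod.MEAN_IMAGE:
        mean = float(np.mean(v))
        if mean == 0.0:
            raise NormalizationError(
                f"cannot apply mean_image normalization to series "
                f"'{series.label}': mean is zero"
            )
        return series.with_values(v / mean)
    # min_max
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        raise NormalizationError(
            f"cannot apply min_max normalization to constant series "
            f"'{series.label}'"
        )
    return series.with_values((v - lo) / (hi - lo))


def normalize_panel(panel: GreyPanel, method: NormalizationMethod | str) -> GreyPanel:
    """Normalize the reference and every comparative independently."""
    method = NormalizationMethod.coerce(method)
    if method is NormalizationMethod.NONE:
        return panel
    return GreyPanel(
        reference=normalize_series(panel.reference, method),
        comparatives=tuple(normalize_series(c, method) for c in panel.comparatives),
    )


def read_panel(path: str | Path, reference_label: str) -> GreyPanel:
    """Read a wide-format CSV panel.

    Expects a UTF-8 CSV with a header row, a leading epoch column and one
    column per series; ``reference_label`` names the reference column and
    the remaining columns become comparatives in file order.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        try:
            header = next(csv.reader(fh))
        except StopIteration:
            raise PanelFormatError(f"{path}: empty file") from None
    header = [str(h) for h in header]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise PanelFormatError(f"{path}: duplicate column names: {dupes}")
    if len(header) < 2:
        raise PanelFormatError(f"{path}: need an epoch column and at least one series column")

    df = pd.read_csv(path, encoding="utf-8")
    if reference_label not in df.columns[1:]:
        raise PanelFormatError(
            f"{path}: reference column '{reference_label}' not found; "
            f"series columns are {list(df.columns[1:])}"
        )
    epoch_col = df.columns[0]
    epochs_raw = df[epoch_col].tolist()
    epochs = []
    for e in epochs_raw:
        if isinstance(e, numbers.Real) and not isinstance(e, bool):
            e = float(e)
            epochs.append(int(e) if float(e).is_integer() else e)
        else:
            epochs.append(str(e))
    epochs = tuple(epochs)

    series = {}
    for col in df.columns[1:]:
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            cell = raw.iloc[row]
            what = "blank cell" if pd.isna(cell) else f"non-numeric cell {cell!r}"
            # +2: header line plus 1-based counting
            raise PanelFormatError(
                f"{path}: {what} in column '{col}', row {row + 2}"
            )
        series[col] = EpochSeries(str(col), epochs, numeric.to_numpy(dtype=float))

    reference = series.pop(reference_label)
    return GreyPanel(reference=reference, comparatives=tuple(series.values()))


def write_panel(panel: GreyPanel, path: str | Path, reference_first: bool = True) -> None:
    """Write a panel as wide CSV with fixed float formatting (%.12g).

    A file produced here reads back via :func:`read_panel` and rewrites
    byte-identically, which makes panels usable as stable text fixtures.
    """
    path = Path(path)
    frame = panel.to_frame()
    if not reference_first:
        cols = panel.comparative_labels + [panel.reference.label]
        frame = frame[cols]
    frame = frame.reset_index()
    frame.to_csv(path, index=False, float_format="%.12g")
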