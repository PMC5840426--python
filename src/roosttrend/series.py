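"""Time axis and series containers shared across the package.

Month indices are 0-based ("months since series start") everywhere in the
library.  A :class:`TimeAxis` pins the calendar: it records the calendar
month (1-12) and optionally the calendar year of index 0, from which the
calendar month of any index -- including indices beyond the observed series,
as needed for projections -- is derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeAxis", "CountSeries", "LatentTrajectory"]


@dataclass(frozen=True)
class TimeAxis:
    """Contiguous monthly time axis.

    Parameters
    ----------
    n_months : int
        Number of months on the axis.
    start_month : int
        Calendar month (1-12) of index 0.  Default 5 (May), the start of the
        monitoring programme the default scenario emulates.
    start_year : int, optional
        Calendar year of index 0; only needed for labelling (e.g. November
        summaries) and for converting dates to indices.
    """

    n_months: int
    start_month: int = 5
    start_year: int | None = 2004

    def __post_init__(self) -> None:
        if self.n_months < 1:
            raise ValueError("n_months must be >= 1")
        if not 1 <= self.start_month <= 12:
            raise ValueError("start_month must be in 1..12")

    def calendar_month(self, t) -> np.ndarray | int:
        """Calendar month (1-12) of month index ``t`` (scalar or array).

        Valid for any integer ``t``, including beyond ``n_months`` (used by
        forward projections).
        """
        return (self.start_month - 1 + np.asarray(t)) % 12 + 1

    @property
    def cal(self) -> np.ndarray:
        """Calendar months of indices ``0 .. n_months-1``."""
        return self.calendar_month(np.arange(self.n_months))

    def year_of(self, t) -> np.ndarray | int:
        if self.start_year is None:
            raise ValueError("axis has no start_year")
        return self.start_year + (self.start_month - 1 + np.asarray(t)) // 12

    def index_of(self, year: int, month: int) -> int:
        """Month index of a calendar (year, month); may be out of range."""
        if self.start_year is None:
            raise ValueError("axis has no start_year")
        return (year - self.start_year) * 12 + (month - self.start_month)

    def extended(self, extra_months: int) -> "TimeAxis":
        return TimeAxis(self.n_months + extra_months, self.start_month, self.start_year)


@dataclass
class CountSeries:
    """Observed monthly roost-count totals ``Y_t`` with missingness.

    ``y`` is float with NaN at unsurveyed months; ``observed`` mirrors the
    non-NaN pattern.
    """

    y: np.ndarray
    axis: TimeAxis

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1:
            raise ValueError("y must be 1-D")
        if len(self.y) != self.axis.n_months:
            raise ValueError("y length does not match axis")
        with np.errstate(invalid="ignore"):
            if np.any(self.y < 0):
                raise ValueError("counts must be non-negative")

    @property
    def n_months(self) -> int:
        return self.axis.n_months

    @property
    def month_index(self) -> np.ndarray:
        return np.arange(self.n_months)

    @property
    def calendar_month(self) -> np.ndarray:
        return self.axis.cal

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.y)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())


@dataclass
class LatentTrajectory:
    """Latent monthly states: total population ``X_t`` and in-camp ``X_t^C``."""

    total: np.ndarray
    in_camp: np.ndarray

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=float)
        self.in_camp = np.asarray(self.in_camp, dtype=float)
        if self.total.shape != self.in_camp.shape or self.total.ndim != 1:
            raise ValueError("total and in_camp must be 1-D with equal length")

    def __len__(self) -> int:
        return len(self.total)
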