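"""Daily multivariate rating series: container, readers, writers, coverage.

A single person's daily symptom diary is represented as a calendar-complete
day × item matrix with an explicit observedness mask: every calendar day
between the first and last observed date is materialized, whether or not a
questionnaire was completed that day.  This makes day-to-day (lag-1) logic
downstream unambiguous — a 90-of-122-days diary has at most 89 usable
day-pairs, and fewer once the gaps break consecutive runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RatingMatrix",
    "read_ratings",
    "write_ratings",
    "coverage_summary",
]


@dataclass
class RatingMatrix:
    """Calendar-complete day × item rating matrix with a missingness mask.

    Parameters
    ----------
    days : pandas.DatetimeIndex
        Strictly increasing, gap-free daily index spanning first to last
        observed date.
    items : list of str
        Ordered item labels.
    values : ndarray of shape (n_days, n_items)
        Numeric severity ratings; entries where ``observed`` is False are
        ignored (stored as NaN).
    observed : ndarray of bool, shape (n_days, n_items)
        True where a rating was actually recorded.
    scales : dict, optional
        Optional item → scale-tag mapping (e.g. ``{"Sad": "Depression"}``).
    """

    days: pd.DatetimeIndex
    items: list[str]
    values: np.ndarray
    observed: np.ndarray
    scales: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.days = pd.DatetimeIndex(self.days)
        self.items = list(self.items)
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != (len(self.days), len(self.items)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.days)} days × {len(self.items)} items"
            )
        if self.observed.shape != self.values.shape:
            raise ValueError("observed mask shape must match values shape")
        if len(self.days) >= 2:
            deltas = np.diff(self.days.values).astype("timedelta64[D]")
            if (deltas <= np.timedelta64(0, "D")).any():
                raise ValueError("days must be strictly increasing with no duplicates")
        if not np.isfinite(self.values[self.observed]).all():
            raise ValueError("values must be finite wherever observed")
        if self.n_items < 1:
            raise ValueError("at least one item required")
        if self.observed.any(axis=1).sum() < 2:
            raise ValueError("at least 2 observed days required")

    # -- basic geometry -------------------------------------------------
    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def day_observed(self) -> np.ndarray:
        """Boolean per-day vector: day has at least one observed item."""
        return self.observed.any(axis=1)

    @property
    def day_complete(self) -> np.ndarray:
        """Boolean per-day vector: every item observed that day."""
        return self.observed.all(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame (days × items) with NaN for unobserved cells."""
        vals = np.where(self.observed, self.values, np.nan)
        return pd.DataFrame(vals, index=self.days, columns=self.items)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatingMatrix):
            return NotImplemented
        return (
            self.days.equals(other.days)
            and self.items == other.items
            and np.array_equal(self.observed, other.observed)
            and np.array_equal(
                self.values[self.observed], other.values[other.observed]
            )
        )


def _calendar_complete(frame: pd.DataFrame) -> RatingMatrix:
    """Reindex a wide frame onto every calendar day in its span."""
    frame = frame.sort_index()
    full = pd.date_range(frame.index.min(), frame.index.max(), freq="D")
    frame = frame.reindex(full)
    observed = frame.notna().to_numpy()
    return RatingMatrix(
        days=full,
        items=list(frame.columns),
        values=frame.to_numpy(dtype=float),
        observed=observed,
    )


def read_ratings(path, layout: str = "wide") -> RatingMatrix:
    """Read a daily ratings CSV into a :class:`RatingMatrix`.

    Parameters
    ----------
    path : str or path-like
        CSV file.  Wide layout: a ``date`` column plus one column per item.
        Long layout: columns ``date,item,value``.
    layout : {"wide", "long"}

    Returns
    -------
    RatingMatrix
        Spanning the full calendar range from first to last observed date,
        with unobserved days masked.

    Raises
    ------
    ValueError
        On duplicate (date, item) cells, non-numeric values, or fewer than
        2 observed days.
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    raw = pd.read_csv(path)
    if layout == "wide":
        date_col = raw.columns[0]
        dates = pd.to_datetime(raw[date_col])
        if dates.duplicated().any():
            dup = dates[dates.duplicated()].iloc[0]
            raise ValueError(f"duplicate date {dup.date()} in wide CSV")
        wide = raw.drop(columns=[date_col])
        for col in wide.columns:
            try:
                wide[col] = pd.to_numeric(wide[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"non-numeric value in column {col!r}: {exc}") from exc
        wide.index = pd.DatetimeIndex(dates)
    else:
        required = {"date", "item", "value"}
        if not required.issubset(raw.columns):
            raise ValueError(f"long CSV must have columns {sorted(required)}")
        raw = raw.copy()
        raw["date"] = pd.to_datetime(raw["date"])
        dup_mask = raw.duplicated(subset=["date", "item"], keep=False)
        if dup_mask.any():
            row = raw[dup_mask].iloc[0]
            raise ValueError(
                f"duplicate cell for date {row['date'].date()}, item {row['item']!r}"
            )
        try:
            raw["value"] = pd.to_numeric(raw["value"])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in long CSV: {exc}") from exc
        wide = raw.pivot(index="date", columns="item", values="value")
        # preserve first-appearance item order rather than alphabetical
        order = list(dict.fromkeys(raw["item"]))
        wide = wide[order]
        wide.columns.name = None
    # drop fully-empty rows before establishing the span
    wide = wide.loc[wide.notna().any(axis=1)]
    if len(wide) < 2:
        raise ValueError(f"need at least 2 observed days, found {len(wide)}")
    return _calendar_complete(wide)


def write_ratings(rm: RatingMatrix, path, layout: str = "wide") -> None:
    """Write a RatingMatrix to CSV; unobserved cells/days are omitted."""
    frame = rm.to_frame()
    frame = frame.loc[frame.notna().any(axis=1)]
    if layout == "wide":
        out = frame.reset_index(names="date")
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
    elif layout == "long":
        long = frame.stack().reset_index()
        long.columns = ["date", "item", "value"]
        long["date"] = long["date"].dt.strftime("%Y-%m-%d")
        long.to_csv(path, index=False)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def coverage_summary(rm: RatingMatrix) -> dict:
    """Observedness summary: per-item and overall counts, span, longest gap.

    The overall observed-day count is the number of calendar days with at
    least one observed item; the longest gap is the longest run of fully
    unobserved calendar days strictly inside the span.
    """
    day_obs = rm.day_observed
    gaps = _longest_run(~day_obs)
    per_item = {
        item: int(rm.observed[:, i].sum()) for i, item in enumerate(rm.items)
    }
    return {
        "observed_days": int(day_obs.sum()),
        "span_days": rm.n_days,
        "longest_gap": gaps,
        "complete_days": int(rm.day_complete.sum()),
        "per_item_observed": per_item,
    }


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for flag in mask:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best
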