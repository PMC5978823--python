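"""Polynomial detrending of daily diary items.

Before estimating day-to-day dynamics, each item's slow trend (linear,
curvilinear, or monthly cyclicity) is removed by fitting polynomials in
week-time — weeks since the first day in the span, i.e. ``day_index / 7`` —
of orders 0..max_order on an orthogonalized basis, choosing the order by
corrected AIC.  Default max_order is 10, enough to absorb monthly cyclicity
over a ~4-month diary.  Residuals are mean-zero over observed days and keep
the item's original scale; z-scaling happens later in the network stage.

Lag-1 autocorrelation of the residuals is tested as a diagnostic only: the
network's autoregressive self-loops model it explicitly, so it is not
removed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .ratings import RatingMatrix

__all__ = [
    "DetrendResult",
    "PolynomialDetrender",
    "detrend_item",
    "detrend_all",
    "test_ar1",
]

logger = logging.getLogger(__name__)

_REPORT_COLUMNS = [
    "Item", "Mean", "Detrending", "Minimum", "Maximum", "SD",
    "Skewness", "Kurtosis",
]


@dataclass
class DetrendResult:
    """Outcome of detrending one item."""

    item: str
    chosen_order: int
    coefficients: np.ndarray        # on the orthonormal basis, chosen order
    residuals: pd.Series            # indexed by observed days only
    criterion_table: dict[int, float]
    mean_before: float
    error_model: str = "iid"
    ar1_coefficient: float = float("nan")
    ar1_significant: bool = False
    time_unit: str = "weeks"
    _extra: dict = field(default_factory=dict, repr=False)


def aicc(n: int, rss: float, k: int) -> float:
    """Corrected AIC for a least-squares fit with k parameters.

    AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1); infinite when the
    small-sample correction's denominator is non-positive.
    """
    if n - k - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-300)  # guard log of an exact fit
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def bic(n: int, rss: float, k: int) -> float:
    """Bayesian information criterion: n·ln(RSS/n) + k·ln(n)."""
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + k * np.log(n)


_CRITERIA = {"aicc": aicc, "bic": bic}


def _orthonormal_basis(t: np.ndarray, order: int) -> np.ndarray:
    """Orthonormal polynomial basis (QR of the Vandermonde) over points t."""
    v = np.vander(t, N=order + 1, increasing=True)
    q, r = np.linalg.qr(v)
    # fix signs so the basis is deterministic
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q * signs


class PolynomialDetrender(BaseEstimator, TransformerMixin):
    """Per-item polynomial detrender with AICc order selection.

    Fits, for every item of a :class:`RatingMatrix`, least-squares
    polynomials in week-time of orders ``0..max_order`` on an orthonormal
    basis and keeps the order minimizing the corrected AIC.  ``transform``
    returns a residual RatingMatrix on the same calendar.

    Parameters
    ----------
    max_order : int, default 10
        Highest candidate polynomial order; reduced per item to
        ``n_observed − 2`` when the series is short.
    alpha_ar1 : float, default 0.05
        Significance level for the diagnostic lag-1 autocorrelation test.
    criterion : {"bic", "aicc"}, default "bic"
        Order-selection criterion.  BIC is the default: with ~90 daily
        observations the AICc penalty (≈2 per extra order) lets pure noise
        masquerade as trend far too often, whereas BIC's ln(n) penalty
        keeps the false-trend rate low while still recovering genuine
        polynomial trend.

    Attributes
    ----------
    results_ : list of DetrendResult
        One per item, in item order.
    report_ : pandas.DataFrame
        Descriptive table: pre-detrending mean, chosen order, and residual
        min/max/SD/skewness/kurtosis per item.
    """

    def __init__(self, max_order: int = 10, alpha_ar1: float = 0.05,
                 criterion: str = "bic"):
        self.max_order = max_order
        self.alpha_ar1 = alpha_ar1
        self.criterion = criterion

    def fit(self, rm: RatingMatrix, y=None):
        if not isinstance(rm, RatingMatrix):
            raise TypeError("PolynomialDetrender expects a RatingMatrix")
        if self.max_order < 0:
            raise ValueError("max_order must be >= 0")
        if self.criterion not in _CRITERIA:
            raise ValueError(f"criterion must be one of {sorted(_CRITERIA)}")
        self.results_ = []
        for i, item in enumerate(rm.items):
            obs = rm.observed[:, i]
            series = pd.Series(rm.values[obs, i], index=rm.days[obs])
            day_index = np.flatnonzero(obs).astype(float)
            res = _detrend_series(series, day_index, self.max_order, item,
                                  criterion=self.criterion)
            try:
                ar = test_ar1(res.residuals, alpha=self.alpha_ar1)
                res.ar1_coefficient = ar["ar1_coefficient"]
                res.ar1_significant = ar["significant"]
                res.error_model = "ar1" if ar["significant"] else "iid"
            except ValueError:
                pass  # too few consecutive pairs: leave diagnostic as NaN
            self.results_.append(res)
        self.report_ = _build_report(self.results_)
        self._rm_shape = (rm.n_days, rm.n_items)
        return self

    def transform(self, rm: RatingMatrix) -> RatingMatrix:
        """Residual RatingMatrix (same calendar and mask, detrended values)."""
        if not hasattr(self, "results_"):
            raise RuntimeError("PolynomialDetrender is not fitted")
        values = np.full((rm.n_days, rm.n_items), np.nan)
        for i, res in enumerate(self.results_):
            obs = rm.observed[:, i]
            values[obs, i] = res.residuals.to_numpy()
        return RatingMatrix(
            days=rm.days, items=rm.items, values=values,
            observed=rm.observed.copy(), scales=dict(rm.scales),
        )


def _detrend_series(
    series: pd.Series, day_index: np.ndarray, max_order: int, item: str,
    criterion: str = "bic",
) -> DetrendResult:
    y = series.to_numpy(dtype=float)
    n = len(y)
    crit_fn = _CRITERIA[criterion]
    if n < 2:
        raise ValueError(f"item {item!r}: need at least 2 observed points")
    max_order = min(max_order, n - 2)
    mean_before = float(np.mean(y))

    if np.ptp(y) == 0.0:
        logger.warning("item %r is constant; no detrending applied", item)
        return DetrendResult(
            item=item, chosen_order=0, coefficients=np.array([mean_before]),
            residuals=pd.Series(np.zeros(n), index=series.index),
            criterion_table={0: crit_fn(n, 0.0, 1)}, mean_before=mean_before,
        )

    weeks = (day_index - day_index[0]) / 7.0
    basis_full = _orthonormal_basis(weeks, max_order)
    criterion: dict[int, float] = {}
    best = None
    for order in range(max_order + 1):
        q = basis_full[:, : order + 1]
        coef = q.T @ y
        resid = y - q @ coef
        rss = float(resid @ resid)
        crit = crit_fn(n, rss, k=order + 1)
        criterion[order] = crit
        if best is None or crit < best[0] - 1e-12:
            best = (crit, order, coef, resid)

    _, order, coef, resid = best
    resid = resid - resid.mean()  # numerically exact mean zero
    return DetrendResult(
        item=item, chosen_order=order, coefficients=coef,
        residuals=pd.Series(resid, index=series.index),
        criterion_table=criterion, mean_before=mean_before,
    )


def detrend_item(series: pd.Series, max_order: int = 10,
                 criterion: str = "bic") -> DetrendResult:
    """Detrend a single day-indexed observed series.

    The index must be datetime-like; week-time is computed from calendar
    offsets of the observed days.  See :class:`PolynomialDetrender`.
    """
    idx = pd.DatetimeIndex(series.index)
    day_index = (idx - idx[0]).days.to_numpy(dtype=float)
    return _detrend_series(series, day_index, max_order,
                           item=str(series.name or "item"), criterion=criterion)


def test_ar1(residuals: pd.Series, alpha: float = 0.05) -> dict:
    """Lag-1 autocorrelation over calendar-consecutive observed pairs.

    Estimates r1 from pairs of residuals on adjacent calendar days and
    tests H0: rho = 0 with the t statistic r·sqrt((m−2)/(1−r²)) on m−2
    degrees of freedom, where m is the number of consecutive pairs.
    """
    idx = pd.DatetimeIndex(residuals.index)
    vals = residuals.to_numpy(dtype=float)
    deltas = (idx[1:] - idx[:-1]).days
    mask = deltas == 1
    x, ynext = vals[:-1][mask], vals[1:][mask]
    m = len(x)
    if m < 3:
        raise ValueError(f"need >= 3 consecutive-day pairs, found {m}")
    sx, sy = x.std(), ynext.std()
    if sx == 0 or sy == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(x, ynext)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        significant = True
    else:
        tstat = r * np.sqrt((m - 2) / (1 - r * r))
        significant = bool(2 * stats.t.sf(abs(tstat), m - 2) < alpha)
    return {"ar1_coefficient": r, "significant": significant, "n_pairs": m}


def detrend_all(
    rm: RatingMatrix, max_order: int = 10, criterion: str = "bic"
) -> tuple[RatingMatrix, list[DetrendResult]]:
    """Detrend every item of a RatingMatrix.

    Returns the residual matrix (same calendar/mask) and the per-item
    results; the descriptive report is available as ``DetrendResult`` data
    or via :attr:`PolynomialDetrender.report_`.
    """
    det = PolynomialDetrender(max_order=max_order, criterion=criterion).fit(rm)
    return det.transform(rm), det.results_


def _build_report(results: list[DetrendResult]) -> pd.DataFrame:
    rows = []
    _ORDINAL = {1: "1st", 2: "2nd", 3: "3rd"}
    for res in results:
        r = res.residuals.to_numpy()
        order = res.chosen_order
        label = "None" if order == 0 else _ORDINAL.get(order, f"{order}th")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # constant residuals
            rows.append({
                "Item": res.item,
                "Mean": res.mean_before,
                "Detrending": label,
                "Minimum": float(np.min(r)),
                "Maximum": float(np.max(r)),
                "SD": float(np.std(r, ddof=1)),
                "Skewness": float(stats.skew(r, bias=False)) if np.ptp(r) > 0 else 0.0,
                "Kurtosis": float(stats.kurtosis(r, bias=False)) if np.ptp(r) > 0 else 0.0,
            })
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)
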