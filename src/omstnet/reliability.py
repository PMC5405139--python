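"""Test-retest reliability of network metrics across repeated scans.

The intraclass correlation coefficient (ICC) measures how consistently a
nodal metric (e.g. nodal global efficiency) is reproduced across scans of
the same subject.  Nodes act as targets and scans as raters; the default
form is ICC(2,1) — two-way random effects, single measure, absolute
agreement — computed from the two-way ANOVA mean squares:

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n)

with n targets, k raters, MSR the between-target, MSC the between-rater and
MSE the residual mean square.  ICC(3,1) (consistency, fixed raters) is also
available.  A companion optimizer scans an arbitrary-threshold grid and
returns the parameter maximizing ICC(GE) + ICC(LE) across scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .filters import arbitrary_filter, _scheme_filter
from .graph import as_weights, local_efficiency, nodal_global_efficiency

__all__ = ["ICCReport", "icc", "optimize_threshold_icc"]


@dataclass
class ICCReport:
    """An ICC estimate with its context and qualitative category."""

    icc: float
    metric: str
    scheme: str
    n_nodes: int
    n_scans: int

    @property
    def category(self) -> str:
        if self.icc > 0.85:
            return "excellent"
        if self.icc > 0.75:
            return "good"
        if self.icc > 0.5:
            return "fair"
        return "poor"


def icc(
    values: np.ndarray,
    *,
    form: Literal["icc2", "icc3"] = "icc2",
    metric: str = "",
    scheme: str = "",
) -> ICCReport:
    """ICC of a (targets × raters) value matrix.

    ``values`` holds one nodal metric: rows are nodes (targets), columns are
    scans (raters).  Requires at least 2 of each and non-zero between-target
    variance.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a (>=2 targets) x (>=2 raters) matrix")
    if not np.isfinite(X).all():
        raise ValueError("non-finite metric values")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise ValueError("zero variance across targets: ICC undefined")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "icc2":
        val = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    elif form == "icc3":
        val = (msr - mse) / (msr + (k - 1) * mse)
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    return ICCReport(float(val), metric, scheme, n, k)


def scan_metrics(
    scans: Sequence[np.ndarray],
    scheme: str | None,
    param: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(nodes × scans) nodal GE and LE after filtering each scan."""
    ge_cols, le_cols = [], []
    for W in scans:
        W = as_weights(W)
        if scheme is not None:
            W = _scheme_filter(W, scheme, param).weights
        ge_cols.append(nodal_global_efficiency(W))
        le_cols.append(local_efficiency(W))
    return np.column_stack(ge_cols), np.column_stack(le_cols)


def optimize_threshold_icc(
    scans: Sequence[np.ndarray],
    scheme: Literal["absolute", "proportional", "mean_degree"],
    grid: Sequence[float],
    *,
    form: Literal["icc2", "icc3"] = "icc2",
) -> tuple[float, tuple[ICCReport, ICCReport]]:
    """Grid value of an arbitrary scheme maximizing ICC(GE) + ICC(LE).

    Every scan is filtered at each grid value, nodal global and local
    efficiency are computed per scan, each metric's ICC across scans is
    estimated and the grid value with the largest sum wins (first on ties).
    """
    grid = list(grid)
    if len(grid) == 0:
        raise ValueError("empty parameter grid")
    if len(scans) < 2:
        raise ValueError("need at least 2 scans")
    best = None
    for param in grid:
        ge, le = scan_metrics(scans, scheme, float(param))
        try:
            r_ge = icc(ge, form=form, metric="global_efficiency", scheme=scheme)
            r_le = icc(le, form=form, metric="local_efficiency", scheme=scheme)
        except ValueError:
            continue
        total = r_ge.icc + r_le.icc
        if best is None or total > best[0] + 1e-15:
            best = (total, float(param), (r_ge, r_le))
    if best is None:
        raise ValueError("ICC undefined on every grid value")
    return best[1], best[2]
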