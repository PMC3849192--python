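"""Paired-ratio concordance: squared Pearson correlation and fold agreement.

Compares two sets of unbound brain/plasma ratios for the same compounds —
in vitro predictions against in vivo references, or two in vivo methods
against each other — with the squared Pearson correlation on untransformed
ratios and boundary-inclusive within-k-fold counts (default k = 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, SchemaError


@dataclass(frozen=True)
class RatioPairSet:
    """Paired positive ratios for a set of compounds.

    ``x`` is the predicted / method-A ratio, ``y`` the reference / method-B
    ratio.  Nonpositive pairs are retained here and excluded (with a
    warning) by the fold statistics.
    """

    labels: List[str]
    x: np.ndarray
    y: np.ndarray
    x_name: str = "x"
    y_name: str = "y"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(self.labels) == x.size == y.size):
            raise InvalidParameterError("labels, x and y must have equal length")
        if x.size < 2:
            raise InvalidParameterError("need at least two pairs")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, x_col: str, y_col: str, label_col: str = "compound"
    ) -> "RatioPairSet":
        for col in (label_col, x_col, y_col):
            if col not in df.columns:
                raise SchemaError(f"column {col!r} not found in table")
        sub = df[[label_col, x_col, y_col]].dropna()
        return cls(
            labels=list(sub[label_col].astype(str)),
            x=sub[x_col].to_numpy(float),
            y=sub[y_col].to_numpy(float),
            x_name=x_col,
            y_name=y_col,
        )


@dataclass(frozen=True)
class ConcordanceResult:
    """Concordance summary for one pair of ratio columns."""

    n: int
    r2: float
    k: float
    within_k_count: int
    within_k_fraction: float
    over_k_count: int
    discordant_labels: List[str] = field(default_factory=list)
    excluded_labels: List[str] = field(default_factory=list)
    #: labels whose fold falls within 5 % of the threshold: counts near the
    #: boundary are sensitive to the two-decimal rounding of tabulated ratios
    near_boundary_labels: List[str] = field(default_factory=list)
    comparison: str = ""


def pearson_r2(pairs: RatioPairSet, log_scale: bool = False) -> float:
    """Squared Pearson correlation of the paired ratios.

    Computed on untransformed values by default; ``log_scale=True`` applies
    a natural log to both axes first (positive pairs only).
    """
    x, y = pairs.x, pairs.y
    if log_scale:
        keep = (x > 0) & (y > 0)
        x, y = np.log(x[keep]), np.log(y[keep])
    if x.size < 3:
        raise InvalidParameterError("need at least three pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidParameterError(
            "correlation undefined: zero variance in one of the axes"
        )
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


def fold_errors(pairs: RatioPairSet) -> Tuple[np.ndarray, np.ndarray]:
    """Symmetric fold error max(x/y, y/x) per pair; mask of valid pairs."""
    valid = (pairs.x > 0) & (pairs.y > 0)
    fold = np.full(pairs.x.shape, np.nan)
    fold[valid] = np.maximum(
        pairs.x[valid] / pairs.y[valid], pairs.y[valid] / pairs.x[valid]
    )
    return fold, valid


def within_fold_stats(
    pairs: RatioPairSet, k: float = 2.0, comparison: str = ""
) -> ConcordanceResult:
    """Within-k-fold concordance summary (boundary inclusive).

    A pair agrees within k-fold when max(x/y, y/x) ≤ k.  Nonpositive pairs
    cannot enter a fold ratio and are excluded with a warning; they are
    listed in ``excluded_labels``.
    """
    if k < 1:
        raise InvalidParameterError("fold threshold k must be >= 1")
    fold, valid = fold_errors(pairs)
    labels = np.asarray(pairs.labels, dtype=object)
    if not np.all(valid):
        warnings.warn(
            f"{int((~valid).sum())} nonpositive pair(s) excluded from the "
            "fold statistics",
            stacklevel=2,
        )
    f = fold[valid]
    lab = labels[valid]
    within = f <= k
    near = np.abs(f - k) <= 0.05 * k
    n = int(valid.sum())
    try:
        r2 = pearson_r2(pairs)
    except InvalidParameterError:
        r2 = float("nan")
    return ConcordanceResult(
        n=n,
        r2=r2,
        k=k,
        within_k_count=int(within.sum()),
        within_k_fraction=float(within.sum() / n) if n else float("nan"),
        over_k_count=int((~within).sum()),
        discordant_labels=sorted(lab[~within]),
        excluded_labels=list(labels[~valid]),
        near_boundary_labels=sorted(lab[near]),
        comparison=comparison,
    )


def concordance_report(
    dataset: pd.DataFrame,
    comparisons: Dict[str, Tuple[str, str]],
    k: float = 2.0,
    label_col: str = "compound",
) -> Dict[str, ConcordanceResult]:
    """Run several named column-pair concordance analyses on one table.

    ``comparisons`` maps a report name to an (x_column, y_column) pair.
    Missing columns raise a schema error naming the column.
    """
    out: Dict[str, ConcordanceResult] = {}
    for name, (x_col, y_col) in comparisons.items():
        pairs = RatioPairSet.from_frame(dataset, x_col, y_col, label_col=label_col)
        out[name] = within_fold_stats(pairs, k=k, comparison=name)
    return out


def plot_concordance(
    pairs: RatioPairSet, k: float = 2.0, ax: Optional["object"] = None
):
    """Scatter of paired ratios with identity and k-fold guide lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    lo = min(pairs.x[pairs.x > 0].min(), pairs.y[pairs.y > 0].min()) / 2
    hi = max(pairs.x.max(), pairs.y.max()) * 2
    grid = np.array([lo, hi])
    ax.plot(grid, grid, "k-", lw=1)
    ax.plot(grid, k * grid, "k--", lw=0.8)
    ax.plot(grid, grid / k, "k--", lw=0.8)
    ax.plot(pairs.x, pairs.y, "o", ms=4)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(pairs.x_name)
    ax.set_ylabel(pairs.y_name)
    return ax
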