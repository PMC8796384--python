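"""Descriptor reduction: variance/correlation prefilters and bootstrap-Lasso.

Two deterministic prefilters run first: constant columns are dropped, then
for every pair of descriptors with |Pearson r| >= 0.95 the member less
correlated with the clamped %PPB target is removed.  The survivors feed a
Bolasso-style selection: L1-penalized linear fits on bootstrap resamples of
the rows, a descriptor being *selected* only if its coefficient is nonzero
in at least ``threshold`` of the resamples at every penalty in the stable
window of the alpha grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_STABLE_WINDOW",
    "SelectionResult",
    "prefilter_constant",
    "prefilter_correlated",
    "bolasso_select",
]

#: Lasso penalty grid, 0.5 to 4.9 in steps of 0.2
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.5, 5.0, 0.2), 1))
#: upper grid region over which selection must be stable
DEFAULT_STABLE_WINDOW: tuple[float, float] = (4.3, 4.9)


def prefilter_constant(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop zero-variance columns, preserving the order of survivors."""
    if matrix.shape[1] < 1:
        raise ValueError("matrix has no columns")
    n_unique = matrix.nunique(dropna=False)
    keep = [c for c in matrix.columns if n_unique[c] > 1]
    if not keep:
        raise ValueError("all columns are constant")
    return matrix[keep]


def prefilter_correlated(
    matrix: pd.DataFrame, target, threshold: float = 0.95
) -> pd.DataFrame:
    """For each descriptor pair with |r| >= threshold drop the member with
    the lower |correlation| with the target.

    Columns are visited sorted by descending |corr(descriptor, target)| (ties
    broken by original column order), pairs lexicographically within that
    order, so removal is deterministic and, for a clique of mutually
    correlated columns, exactly the most target-correlated member survives.
    """
    y = np.asarray(target, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to compute correlations")
    if matrix.shape[0] != y.shape[0]:
        raise ValueError("matrix and target are not aligned")

    cols = list(matrix.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        target_corr = {
            c: abs(_pearson(matrix[c].to_numpy(dtype=float), y)) for c in cols
        }
    order = sorted(
        range(len(cols)), key=lambda i: (-target_corr[cols[i]], i)
    )
    corr = matrix.corr().abs().to_numpy()
    col_pos = {c: i for i, c in enumerate(cols)}

    alive = set(cols)
    for a_idx in range(len(order)):
        ca = cols[order[a_idx]]
        if ca not in alive:
            continue
        for b_idx in range(a_idx + 1, len(order)):
            cb = cols[order[b_idx]]
            if cb not in alive:
                continue
            if corr[col_pos[ca], col_pos[cb]] >= threshold:
                alive.discard(cb)  # cb has the lower |corr with target|
    return matrix[[c for c in cols if c in alive]]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class SelectionResult:
    """Outcome of bootstrap-Lasso selection."""

    selected: list[str]
    alpha_grid: list[float]
    frequency: pd.DataFrame  # index: alpha, columns: descriptor names
    threshold: float
    stable_window: tuple[float, float]
    notes: list[str] = field(default_factory=list)

    def frequency_report(self) -> dict:
        """JSON-serializable per-alpha selection frequencies."""
        return {
            "alpha_grid": self.alpha_grid,
            "threshold": self.threshold,
            "stable_window": list(self.stable_window),
            "selected": self.selected,
            "frequency": {
                f"{a:g}": self.frequency.loc[a].to_dict() for a in self.frequency.index
            },
            "notes": self.notes,
        }


def bolasso_select(
    matrix: pd.DataFrame,
    target,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_bootstrap: int = 100,
    threshold: float = 1.0,
    stable_window: tuple[float, float] | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Bootstrap-Lasso descriptor selection.

    For each penalty ``alpha`` and each of ``n_bootstrap`` row resamples
    (with replacement), an L1-penalized least-squares fit is performed and
    nonzero coefficients recorded.  A descriptor is selected when its nonzero
    frequency is >= ``threshold`` at *every* alpha inside ``stable_window``
    (by default the upper region of the grid).  An all-zero selection is
    reported with a warning rather than raised.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    y = np.asarray(target, dtype=float)
    x = matrix.to_numpy(dtype=float)
    n, _ = x.shape
    alphas = [float(a) for a in alpha_grid]
    if stable_window is None:
        lo = float(np.quantile(alphas, 0.8))
        stable_window = (min(a for a in alphas if a >= lo), max(alphas))
    rng = np.random.default_rng(seed)

    freq = pd.DataFrame(0.0, index=alphas, columns=matrix.columns)
    notes: list[str] = []
    for alpha in alphas:
        hits = np.zeros(x.shape[1])
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            model = Lasso(alpha=alpha, max_iter=5000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(x[idx], y[idx])
            hits += np.abs(model.coef_) > 1e-12
        freq.loc[alpha] = hits / n_bootstrap

    window_alphas = [a for a in alphas if stable_window[0] <= a <= stable_window[1]]
    stable = freq.loc[window_alphas]
    selected = [c for c in matrix.columns if (stable[c] >= threshold).all()]

    if not selected:
        if (freq.loc[window_alphas].to_numpy() == 0).all():
            warnings.warn(
                "bolasso: every bootstrap fit was all-zero in the stable "
                "window; empty selection",
                stacklevel=2,
            )
            notes.append("all-zero fits in stable window")
        else:
            # near-duplicate informative columns can split the votes below
            # threshold; surface the instability instead of failing silently
            splitters = [
                c
                for c in matrix.columns
                if (stable[c] > 0).any() and not (stable[c] >= threshold).all()
            ]
            if splitters:
                notes.append(
                    "unstable selection: nonzero but sub-threshold frequency "
                    f"for {splitters}"
                )
    return SelectionResult(
        selected=selected,
        alpha_grid=alphas,
        frequency=freq,
        threshold=threshold,
        stable_window=stable_window,
        notes=notes,
    )
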