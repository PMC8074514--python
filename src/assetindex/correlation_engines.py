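"""Correlation matrices for index extraction.

Two families are supported.  Pearson product-moment correlations of the
(standardized) design columns are the benchmark input.  Tetrachoric and
polychoric correlations estimate the correlation of latent bivariate-normal
variables underlying observed binary / ordinal items, by two-step maximum
likelihood: thresholds are fixed at normal quantiles of the marginal
proportions, then the single correlation parameter maximizes the multinomial
likelihood whose cell probabilities are bivariate-normal rectangle
probabilities.  Rectangle probabilities use scipy's bivariate normal CDF
(Genz algorithm, absolute error well below 1e-7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "CorrelationMatrix",
    "bvn_cdf",
    "pearson_matrix",
    "tetrachoric_rho",
    "polychoric_rho",
    "polychoric_matrix",
]

RHO_CAP = 0.999  # keeps downstream eigendecompositions stable
_EIG_FLOOR = 1e-8


class DegenerateTableError(ValueError):
    """A margin or cell of the contingency table is empty."""


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation matrix with provenance flags."""

    items: list[str]
    matrix: np.ndarray
    kind: str  # pearson | polychoric
    thresholds: dict[str, np.ndarray] | None = None
    smoothed: bool = False
    corrected_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.items), len(self.items)):
            raise ValueError("matrix shape does not match item list")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("matrix diagonal must be 1")
        if np.any(np.abs(m) > 1 + 1e-10):
            raise ValueError("entries must lie in [-1, 1]")
        self.matrix = m

    @property
    def p(self) -> int:
        return len(self.items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.items, columns=self.items)


def pearson_matrix(design) -> CorrelationMatrix:
    """Product-moment correlations of the design's columns."""
    z = design.z if hasattr(design, "z") else pd.DataFrame(design)
    if z.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    sds = z.std(ddof=1)
    if (sds == 0).any():
        raise ValueError(f"constant columns present: {list(sds.index[sds == 0])}")
    r = np.corrcoef(z.to_numpy(), rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    return CorrelationMatrix(items=list(z.columns), matrix=r, kind="pearson")


# ---------------------------------------------------------------------------
# latent-normal correlations


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X ≤ h, Y ≤ k) for standard bivariate normal with correlation rho.

    Owen (1956): Φ₂(h, k; ρ) = ½Φ(h) + ½Φ(k) − T(h, a_h) − T(k, a_k) − β with
    a_h = (k − ρh)/(h√(1−ρ²)), a_k symmetric, β = ½ iff hk < 0.  Owen's T
    function is evaluated by scipy.special.owens_t; the identity is exact, so
    accuracy is that of owens_t (absolute error far below 1e-7).  Zero
    arguments are treated as +0 via a 1e-15 offset, which realizes the
    arctan limit of Owen's T.
    """
    if rho >= 1.0:
        return float(stats.norm.cdf(min(h, k)))
    if rho <= -1.0:
        return float(max(0.0, stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0))
    if np.isinf(h) or np.isinf(k):
        if h == -np.inf or k == -np.inf:
            return 0.0
        if h == np.inf and k == np.inf:
            return 1.0
        return float(stats.norm.cdf(k if h == np.inf else h))
    hh = h if h != 0.0 else 1e-15
    kk = k if k != 0.0 else 1e-15
    s = np.sqrt(1.0 - rho * rho)
    a_h = (kk - rho * hh) / (hh * s)
    a_k = (hh - rho * kk) / (kk * s)
    beta = 0.5 if hh * kk < 0 else 0.0
    val = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - float(special.owens_t(hh, a_h))
        - float(special.owens_t(kk, a_k))
        - beta
    )
    return float(np.clip(val, 0.0, 1.0))


def _rectangle_probs(cuts_x: np.ndarray, cuts_y: np.ndarray, rho: float) -> np.ndarray:
    """Cell probabilities of a discretized bivariate normal.

    ``cuts_x``/``cuts_y`` are interior thresholds; cell (i, j) is the
    probability mass of the rectangle between consecutive thresholds
    (padded with ±inf).
    """
    ax = np.concatenate(([-np.inf], cuts_x, [np.inf]))
    ay = np.concatenate(([-np.inf], cuts_y, [np.inf]))
    grid = np.empty((len(ax), len(ay)))
    for i, a in enumerate(ax):
        for j, b in enumerate(ay):
            grid[i, j] = bvn_cdf(a, b, rho)
    probs = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    return np.clip(probs, 1e-12, 1.0)


def _thresholds_from_margin(margin: np.ndarray) -> np.ndarray:
    """Interior normal quantiles of the cumulative marginal proportions."""
    cum = np.cumsum(margin)[:-1] / margin.sum()
    return stats.norm.ppf(cum)


def _fit_rho(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    cuts_x = _thresholds_from_margin(table.sum(axis=1))
    cuts_y = _thresholds_from_margin(table.sum(axis=0))

    def negloglik(rho: float) -> float:
        probs = _rectangle_probs(cuts_x, cuts_y, rho)
        return -float(np.sum(table * np.log(probs)))

    res = optimize.minimize_scalar(
        negloglik,
        bounds=(-RHO_CAP, RHO_CAP),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.clip(res.x, -RHO_CAP, RHO_CAP))


def tetrachoric_rho(table, correct: bool = False) -> float:
    """Tetrachoric correlation of a 2×2 contingency table by two-step ML.

    ``table[i, j]`` counts observations with X = i, Y = j (i, j ∈ {0, 1}).
    Zero cells make the MLE diverge; pass ``correct=True`` to apply the
    +0.5 continuity correction to every cell.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 non-negative counts")
    if (table == 0).any():
        if not correct:
            raise DegenerateTableError(
                "empty cell(s); re-run with correct=True for a +0.5 continuity correction"
            )
        table = table + 0.5
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero margin even after continuity correction")
    return _fit_rho(table)


def polychoric_rho(table, correct: bool = False) -> float:
    """Polychoric correlation of an R×C table (R, C ≤ 3) by two-step ML.

    Empty marginal categories are dropped (mass merges into the neighbouring
    category) with a warning.  Reduces to ``tetrachoric_rho`` for 2×2 input.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("table must be a non-negative count matrix")
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        warnings.warn("dropping empty marginal categories", stacklevel=2)
        table = table[rows][:, cols]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTableError("fewer than 2 non-empty categories on a margin")
    if (table == 0).any():
        if not correct:
            raise DegenerateTableError(
                "empty cell(s); re-run with correct=True for a +0.5 continuity correction"
            )
        table = table + 0.5
    return _fit_rho(table)


def smooth_to_psd(matrix: np.ndarray, floor: float = _EIG_FLOOR) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues and renormalize to unit diagonal if needed."""
    vals = np.linalg.eigvalsh(matrix)
    if vals.min() >= -floor:
        return matrix, False
    w, v = np.linalg.eigh(matrix)
    w = np.clip(w, floor, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return (m + m.T) / 2, True


def polychoric_matrix(design: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise polychoric correlations of categorical (binary/3-level) columns.

    Pairs with empty cells receive a per-pair continuity correction and are
    flagged; an indefinite assembled matrix is eigenvalue-smoothed.
    """
    df = pd.DataFrame(design)
    items = list(df.columns)
    p = len(items)
    codes = {}
    thresholds = {}
    for c in items:
        col = df[c].to_numpy()
        levels = np.unique(col)
        if len(levels) < 2:
            raise ValueError(f"column {c!r} is constant")
        if len(levels) > 3:
            raise ValueError(f"column {c!r} has >3 levels; binarize or recode upstream")
        codes[c] = np.searchsorted(levels, col)
        counts = np.bincount(codes[c], minlength=len(levels)).astype(float)
        thresholds[c] = _thresholds_from_margin(counts)
    m = np.eye(p)
    corrected = []
    for i in range(p):
        for j in range(i + 1, p):
            k_i = codes[items[i]].max() + 1
            k_j = codes[items[j]].max() + 1
            table = np.zeros((k_i, k_j))
            np.add.at(table, (codes[items[i]], codes[items[j]]), 1.0)
            try:
                rho = polychoric_rho(table)
            except DegenerateTableError:
                rho = polychoric_rho(table, correct=True)
                corrected.append((items[i], items[j]))
            m[i, j] = m[j, i] = rho
    m, smoothed = smooth_to_psd(m)
    return CorrelationMatrix(
        items=items,
        matrix=m,
        kind="polychoric",
        thresholds=thresholds,
        smoothed=smoothed,
        corrected_pairs=corrected,
    )
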