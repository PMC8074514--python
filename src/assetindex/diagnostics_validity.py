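"""Internal-consistency, adequacy, distribution-shape and validity checks.

Clumping and truncation are assessed in the source literature by eye, from
per-wave histograms; here they are operationalized quantitatively — the modal
share and distinct-value ratio for clumping, and the share of a wave's
households within 1% of the pooled range of the pooled minimum/maximum for
truncation.  Outputs label these as quantitative proxies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation_engines import CorrelationMatrix, pearson_matrix

__all__ = [
    "DiagnosticsReport",
    "WaveSummary",
    "cronbach_alpha",
    "kmo",
    "clumping",
    "truncation",
    "wave_summaries",
    "external_validity",
]


@dataclass
class WaveSummary:
    wave: str
    n: int
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    min: float
    max: float

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("empty wave summary")
        if not (self.min <= self.q25 <= self.median <= self.q75 <= self.max):
            raise ValueError("order statistics out of order")


@dataclass
class DiagnosticsReport:
    cronbach_alpha: float
    kmo: float
    variance_explained_pc1: float
    clumping: dict[str, dict[str, float]] = field(default_factory=dict)
    truncation: dict[str, dict[str, float]] = field(default_factory=dict)
    notes: str = (
        "clumping/truncation statistics are quantitative proxies for the "
        "visual histogram assessment (modal share, distinct-value ratio, "
        "share within 1% of the pooled range of the pooled extremes)"
    )

    def to_dict(self) -> dict:
        return {
            "cronbach_alpha": self.cronbach_alpha,
            "kmo": self.kmo,
            "variance_explained_pc1": self.variance_explained_pc1,
            "clumping": self.clumping,
            "truncation": self.truncation,
            "notes": self.notes,
        }


def cronbach_alpha(design) -> float:
    """Standardized Cronbach's alpha: k·r̄ / (1 + (k−1)·r̄).

    r̄ is the mean off-diagonal Pearson correlation of the design columns;
    on z-scored items this equals the usual raw-score alpha.
    """
    corr = design if isinstance(design, CorrelationMatrix) else pearson_matrix(design)
    k = corr.p
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    off = corr.matrix[~np.eye(k, dtype=bool)]
    rbar = float(off.mean())
    return k * rbar / (1.0 + (k - 1) * rbar)


def kmo(corr: CorrelationMatrix) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy.

    KMO = Σr² / (Σr² + Σq²) over off-diagonal entries, where q are the
    anti-image partial correlations q_ij = −s_ij/√(s_ii s_jj) with S = R⁻¹.
    A singular matrix gets a 1e-8 ridge (flagged by warning).
    """
    r = corr.matrix
    k = corr.p
    try:
        s = np.linalg.inv(r)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix; adding 1e-8 ridge", stacklevel=2)
        s = np.linalg.inv(r + 1e-8 * np.eye(k))
    d = np.sqrt(np.diag(s))
    q = -s / np.outer(d, d)
    off = ~np.eye(k, dtype=bool)
    r2 = float((r[off] ** 2).sum())
    q2 = float((q[off] ** 2).sum())
    return r2 / (r2 + q2)


def clumping(scores: pd.Series | np.ndarray, decimals: int = 9) -> dict[str, float]:
    """Modal share and distinct-value ratio of one wave's scores."""
    vals = np.round(np.asarray(scores, dtype=float), decimals)
    if vals.size == 0:
        raise ValueError("no scores")
    _, counts = np.unique(vals, return_counts=True)
    return {
        "modal_share": float(counts.max()) / vals.size,
        "distinct_ratio": float(len(counts)) / vals.size,
    }


def truncation(
    scores: pd.Series | np.ndarray,
    pooled_min: float,
    pooled_max: float,
    eps_frac: float = 0.01,
) -> dict[str, float]:
    """Share of a wave's scores within eps·range of the pooled extremes."""
    vals = np.asarray(scores, dtype=float)
    rng = pooled_max - pooled_min
    if not np.isfinite(rng) or rng <= 0:
        raise ValueError("pooled range must be positive and finite")
    eps = eps_frac * rng
    return {
        "lower_share": float(np.mean(vals <= pooled_min + eps)),
        "upper_share": float(np.mean(vals >= pooled_max - eps)),
    }


def wave_summaries(scores: pd.Series, waves: list[str] | None = None) -> list[WaveSummary]:
    """Per-wave order statistics of (household, wave)-indexed scores.

    Quartiles use linear interpolation (numpy default, R type-7).  Empty
    waves are skipped with a warning.
    """
    wave_level = scores.index.get_level_values(1)
    if waves is None:
        waves = list(pd.unique(wave_level))
    out = []
    for w in waves:
        vals = scores[wave_level == w].to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"no scores in wave {w!r}; skipped", stacklevel=2)
            continue
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        out.append(
            WaveSummary(
                wave=w,
                n=int(vals.size),
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                median=float(med),
                q25=float(q25),
                q75=float(q75),
                min=float(vals.min()),
                max=float(vals.max()),
            )
        )
    return out


def summaries_frame(summaries: list[WaveSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries]).set_index("wave")


def external_validity(
    scores: pd.Series,
    external: pd.Series,
    pairing: str = "earliest",
    wave_order: list[str] | None = None,
) -> tuple[float, int]:
    """Pearson r between an external household measure and the index score
    at the earliest (or latest) wave in which each household is observed.

    ``external`` is indexed by household_id.  Returns (r, n complete pairs).
    """
    if pairing not in {"earliest", "latest"}:
        raise ValueError("pairing must be 'earliest' or 'latest'")
    df = scores.rename("score").reset_index()
    df.columns = ["household_id", "wave", "score"]
    if wave_order is None:
        wave_order = list(pd.unique(df["wave"]))
    rank = {w: i for i, w in enumerate(wave_order)}
    df["order"] = df["wave"].map(rank)
    pick = df.sort_values("order").groupby("household_id", sort=False)
    chosen = pick.first() if pairing == "earliest" else pick.last()
    paired = chosen.join(external.rename("external"), how="inner").dropna(
        subset=["score", "external"]
    )
    n = len(paired)
    if n < 3:
        raise ValueError(f"only {n} complete pairs")
    r = float(np.corrcoef(paired["score"], paired["external"])[0, 1])
    return r, n
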