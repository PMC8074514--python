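"""The S1–S5 robustness protocol for the harmonized index.

Each variant refits an index under an alternative specification and compares
it to the benchmark by Spearman rank correlation on the common households:

* S1 — cross-sectional indices per wave, optionally stratified urban/rural
  in the final two waves;
* S2 — extended index adding the newer assets (video player, sound system,
  computer, telephone, washing machine, improved sewage), zero-imputed for
  the waves before their introduction;
* S3 — leave-out sweeps over items and/or waves;
* S4 — alternative correlation structure (Pearson, polychoric) × extraction
  method (PCA, one-factor minres EFA, MCA);
* S5 — three-level ordinal recoding of housing characteristics with a
  polychoric matrix.

Comparisons after wave omission are computed on the households of the
remaining waves; all other comparisons use every household scored by both
indices.  The comparison population is recorded in each report row.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .asset_panel import AssetPanel, PanelError
from .factor_extraction import DEFAULT_REFERENCE_ITEM, IndexModel, score
from .harmonize import HARMONIZED_ITEMS, NEWER_ITEMS, harmonized_item_set, pool
from .pipeline import build_index

__all__ = [
    "spearman",
    "SensitivityReport",
    "s1_cross_sectional",
    "s2_extended",
    "s3_leave_out",
    "s4_alternate",
    "s5_ordinal",
    "full_report",
]


def spearman(x: pd.Series, y: pd.Series) -> tuple[float, int]:
    """Spearman rank correlation on the common (household, wave) keys.

    Mid-ranks for ties; returns (r, n).  Constant vectors are an error.
    """
    common = x.index.intersection(y.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common keys")
    xv = x.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("Spearman undefined for a constant score vector")
    r = stats.spearmanr(xv, yv).statistic
    return float(r), len(common)


@dataclass
class SensitivityReport:
    """Rows of (variant, n common households, Spearman r) plus metadata."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["block", "variant", "population", "n", "spearman_r", "status"]
        )
    )

    def add(self, block, variant, population, n, r, status="ok"):
        self.rows.loc[len(self.rows)] = [block, variant, population, n, r, status]

    def min_r(self, block: str | None = None) -> float:
        sub = self.rows if block is None else self.rows[self.rows["block"] == block]
        return float(sub.loc[sub["status"] == "ok", "spearman_r"].min())

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


# ---------------------------------------------------------------------------


def s1_cross_sectional(
    panel: AssetPanel,
    benchmark_scores: pd.Series,
    wave: str,
    stratum: str | None = None,
    reference: str = DEFAULT_REFERENCE_ITEM,
) -> tuple[IndexModel, float, int]:
    """Refit within one wave (optionally one stratum) and compare to benchmark.

    Items that were not asked in the wave, or are constant there (e.g. after
    zero-imputation), drop out of the cross-sectional fit.
    """
    if wave not in panel.codebook.waves:
        raise PanelError(f"unknown wave {wave!r}")
    model, scores, _ = build_index(
        panel, waves=[wave], stratum=stratum, reference=reference
    )
    r, n = spearman(scores, benchmark_scores)
    return model, r, n


def s2_extended(
    panel: AssetPanel,
    benchmark_scores: pd.Series,
    reference: str = DEFAULT_REFERENCE_ITEM,
) -> tuple[IndexModel, dict[str, tuple[float, int]]]:
    """Extended 25-item index; per-wave comparison in the waves that actually
    asked at least one newer item."""
    cb = panel.codebook
    missing = [n for n in NEWER_ITEMS if n not in cb.item_names]
    if missing:
        raise PanelError(f"codebook lacks newer items: {missing}")
    items = harmonized_item_set(cb) + list(NEWER_ITEMS)
    model, scores, _ = build_index(panel, items=items, reference=reference)
    newer_waves = [
        w
        for w in cb.waves
        if any(cb.item(n).asked_in(w) for n in NEWER_ITEMS)
    ]
    by_wave = {}
    wave_level = scores.index.get_level_values(1)
    bm_level = benchmark_scores.index.get_level_values(1)
    for w in newer_waves:
        by_wave[w] = spearman(
            scores[wave_level == w], benchmark_scores[bm_level == w]
        )
    return model, by_wave


def s3_leave_out(
    panel: AssetPanel,
    benchmark_scores: pd.Series,
    omit_items: int = 0,
    omit_waves: int = 0,
    reference: str = DEFAULT_REFERENCE_ITEM,
) -> SensitivityReport:
    """Sweep all omissions of exactly ``omit_items`` items and ``omit_waves``
    waves; Spearman vs benchmark on the common scored households.

    After wave omission the comparison population is the households of the
    remaining waves.  Degenerate refits are recorded with a non-ok status and
    skipped.
    """
    if not (0 <= omit_items <= 2 and 0 <= omit_waves <= 2):
        raise ValueError("omit_items and omit_waves must each be 0, 1 or 2")
    items = harmonized_item_set(panel.codebook)
    waves = [w for w in panel.codebook.waves if w in panel.waves_present]
    if len(items) - omit_items < 2 or len(waves) - omit_waves < 1:
        raise ValueError("omission leaves too little data")
    report = SensitivityReport()
    for drop_items in itertools.combinations(items, omit_items):
        keep_items = [i for i in items if i not in drop_items]
        for drop_waves in itertools.combinations(waves, omit_waves):
            keep_waves = [w for w in waves if w not in drop_waves]
            label = f"omit_items={list(drop_items)};omit_waves={list(drop_waves)}"
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, scores, _ = build_index(
                        panel, items=keep_items, waves=keep_waves, reference=reference
                    )
                r, n = spearman(scores, benchmark_scores)
            except (PanelError, ValueError) as exc:
                report.add("S3", label, "remaining-waves households", 0, np.nan, f"skipped: {exc}")
                continue
            report.add("S3", label, "remaining-waves households", n, r)
    return report


_S4_GRID = [("pearson", "pca"), ("pearson", "efa"), ("polychoric", "pca"),
            ("polychoric", "efa"), (None, "mca")]


def s4_alternate(
    panel: AssetPanel,
    benchmark_scores: pd.Series,
    corr: str | None,
    method: str,
    reference: str = DEFAULT_REFERENCE_ITEM,
) -> tuple[IndexModel, float, int]:
    """Pooled refit under an alternative correlation/extraction choice."""
    if method == "mca":
        corr = None
    if (corr, method) not in _S4_GRID:
        raise ValueError(f"unsupported combination {(corr, method)}; grid: {_S4_GRID}")
    model, scores, _ = build_index(
        panel, corr=corr or "pearson", method=method, reference=reference
    )
    r, n = spearman(scores, benchmark_scores)
    return model, r, n


def s5_ordinal(
    panel: AssetPanel,
    benchmark_scores: pd.Series,
    method: str = "pca",
    reference: str = DEFAULT_REFERENCE_ITEM,
) -> tuple[IndexModel, float, int]:
    """Three-level housing recode with a polychoric matrix (PCA or EFA)."""
    if method not in {"pca", "efa"}:
        raise ValueError("S5 supports method 'pca' or 'efa'")
    have = [it.name for it in panel.codebook.items if it.ordinal_recode is not None]
    if not have:
        raise PanelError("no items declare an ordinal recode")
    model, scores, _ = build_index(
        panel, corr="polychoric", method=method, ordinal=True, reference=reference
    )
    r, n = spearman(scores, benchmark_scores)
    return model, r, n


# ---------------------------------------------------------------------------


def full_report(
    panel: AssetPanel,
    benchmark_scores: pd.Series,
    grid: tuple[str, ...] = ("s1", "s2", "s3", "s4", "s5"),
    reference: str = DEFAULT_REFERENCE_ITEM,
) -> SensitivityReport:
    """Run the requested S-blocks and assemble one report table.

    The S3 block covers all item pairs, all single and double wave omissions,
    and joint single-item × single-wave omissions.
    """
    report = SensitivityReport()
    cb = panel.codebook
    final_two = cb.waves[-2:]

    def _try(block, variant, population, fn):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, n = fn()
            report.add(block, variant, population, n, r)
        except (PanelError, ValueError) as exc:
            report.add(block, variant, population, 0, np.nan, f"failed: {exc}")

    if "s1" in grid:
        for w in panel.waves_present:
            _try("S1", f"cross-sectional {w}", f"wave {w}",
                 lambda w=w: s1_cross_sectional(panel, benchmark_scores, w, reference=reference)[1:])
        if panel.stratum is not None:
            for w in final_two:
                for s in sorted(panel.stratum.dropna().unique()):
                    _try("S1", f"cross-sectional {w} {s}", f"wave {w}, {s}",
                         lambda w=w, s=s: s1_cross_sectional(
                             panel, benchmark_scores, w, stratum=s, reference=reference)[1:])
    if "s2" in grid:
        try:
            _, by_wave = s2_extended(panel, benchmark_scores, reference=reference)
            for w, (r, n) in by_wave.items():
                report.add("S2", f"extended assets, {w}", f"wave {w}", n, r)
        except (PanelError, ValueError) as exc:
            report.add("S2", "extended assets", "per wave", 0, np.nan, f"failed: {exc}")
    if "s3" in grid:
        for oi, ow in [(2, 0), (0, 1), (0, 2), (1, 1)]:
            sub = s3_leave_out(panel, benchmark_scores, oi, ow, reference=reference)
            report.rows = pd.concat([report.rows, sub.rows], ignore_index=True)
    if "s4" in grid:
        for corr, method in _S4_GRID:
            _try("S4", f"{method}/{corr or 'categorical'}", "pooled households",
                 lambda corr=corr, method=method: s4_alternate(
                     panel, benchmark_scores, corr, method, reference=reference)[1:])
    if "s5" in grid:
        for method in ("pca", "efa"):
            _try("S5", f"ordinal housing, {method}/polychoric", "pooled households",
                 lambda method=method: s5_ordinal(
                     panel, benchmark_scores, method, reference=reference)[1:])
    return report
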