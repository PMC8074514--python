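"""End-to-end builders: impute → pool → correlate → extract → score.

These glue functions define the canonical pipelines used by the CLI, the
sensitivity suite and the tests.  The benchmark index is PCA on the Pearson
correlation matrix of the pooled, zero-imputed 19-item design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .asset_panel import AssetPanel, CROWDING_BINARY_CUTOFF
from .correlation_engines import pearson_matrix, polychoric_matrix
from .diagnostics_validity import (
    DiagnosticsReport,
    clumping,
    cronbach_alpha,
    kmo,
    truncation,
    wave_summaries,
)
from .factor_extraction import (
    DEFAULT_REFERENCE_ITEM,
    IndexModel,
    fit_efa_minres,
    fit_mca,
    fit_pca,
    score,
)
from .harmonize import (
    PooledDesign,
    design_from_values,
    harmonized_item_set,
    impute_not_asked_as_zero,
    pool,
)

__all__ = ["BenchmarkResult", "build_benchmark", "build_index", "run_diagnostics"]


@dataclass
class BenchmarkResult:
    model: IndexModel
    scores: pd.Series
    design: PooledDesign
    panel: AssetPanel  # the imputed panel the fit used


def categorical_design(
    panel: AssetPanel,
    items: Sequence[str],
    waves: Sequence[str] | None = None,
    stratum: str | None = None,
    ordinal: bool = False,
) -> PooledDesign:
    """Design of categorical codes: crowding binarized at the 0.75 cutoff,
    and (optionally) three-level ordinal codes for items that declare them."""
    values = panel.values[list(items)].copy()
    crowd = panel.codebook.crowding_item.name
    if crowd in values.columns:
        c = values[crowd]
        values[crowd] = (c > CROWDING_BINARY_CUTOFF).astype(float).where(c.notna())
    if ordinal:
        if panel.ordinal is None:
            raise ValueError("panel carries no ordinal codes")
        for it in panel.codebook.items:
            if it.name in values.columns and it.ordinal_recode is not None:
                values[it.name] = panel.ordinal[it.name]
    if waves is not None:
        values = values[values.index.get_level_values(1).isin(list(waves))]
    if stratum is not None:
        if panel.stratum is None:
            raise ValueError("panel has no stratum labels")
        values = values[panel.stratum.reindex(values.index) == stratum]
    return design_from_values(values)


def build_index(
    panel: AssetPanel,
    items: Sequence[str] | None = None,
    waves: Sequence[str] | None = None,
    stratum: str | None = None,
    corr: str = "pearson",
    method: str = "pca",
    ordinal: bool = False,
    reference: str = DEFAULT_REFERENCE_ITEM,
) -> tuple[IndexModel, pd.Series, PooledDesign]:
    """Fit one index variant on an (already imputed) panel and score its rows.

    Supported grid: corr ∈ {pearson, polychoric} × method ∈ {pca, efa}, plus
    method='mca' (which ignores ``corr`` and binarizes crowding).  Ordinal
    three-level coding requires a polychoric matrix.
    """
    if method not in {"pca", "efa", "mca"}:
        raise ValueError(f"unknown method {method!r}; supported: pca, efa, mca")
    if corr not in {"pearson", "polychoric"}:
        raise ValueError(f"unknown correlation kind {corr!r}; supported: pearson, polychoric")
    if ordinal and corr != "polychoric" and method != "mca":
        raise ValueError("ordinal coding requires corr='polychoric'")
    if items is None:
        items = harmonized_item_set(panel.codebook)

    if method == "mca":
        design = categorical_design(panel, items, waves, stratum, ordinal=False)
        model = fit_mca(design.raw, reference=reference)
        return model, score(model, design), design
    if corr == "polychoric" or ordinal:
        design = categorical_design(panel, items, waves, stratum, ordinal=ordinal)
        cm = polychoric_matrix(design.raw)
    else:
        design = pool(panel, items, waves, stratum)
        cm = pearson_matrix(design)
    fitter = fit_pca if method == "pca" else fit_efa_minres
    model = fitter(cm, design, reference=reference)
    return model, score(model, design), design


def build_benchmark(
    panel: AssetPanel, reference: str = DEFAULT_REFERENCE_ITEM
) -> BenchmarkResult:
    """The harmonized benchmark: zero-impute, pool all waves, Pearson PCA."""
    imputed = impute_not_asked_as_zero(panel)
    items = harmonized_item_set(panel.codebook)
    model, scores, design = build_index(
        imputed, items=items, corr="pearson", method="pca", reference=reference
    )
    return BenchmarkResult(model=model, scores=scores, design=design, panel=imputed)


def run_diagnostics(result: BenchmarkResult) -> tuple[DiagnosticsReport, pd.DataFrame]:
    """Alpha, KMO, PC1 share plus per-wave clumping/truncation and summaries."""
    design, model, scores = result.design, result.model, result.scores
    cm = pearson_matrix(design)
    waves = [w for w in result.panel.codebook.waves]
    pooled_min, pooled_max = float(scores.min()), float(scores.max())
    clump, trunc = {}, {}
    wave_level = scores.index.get_level_values(1)
    for w in waves:
        vals = scores[wave_level == w]
        if len(vals) == 0:
            continue
        clump[w] = clumping(vals)
        trunc[w] = truncation(vals, pooled_min, pooled_max)
    report = DiagnosticsReport(
        cronbach_alpha=cronbach_alpha(cm),
        kmo=kmo(cm),
        variance_explained_pc1=model.variance_explained,
        clumping=clump,
        truncation=trunc,
    )
    from .diagnostics_validity import summaries_frame

    summaries = summaries_frame(wave_summaries(scores, waves))
    return report, summaries
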