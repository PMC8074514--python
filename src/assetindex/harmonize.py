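"""Wave-aware zero-imputation, pooling and standardization.

Harmonization turns a multi-wave panel into a single pooled design matrix on
which one index is fit.  The only imputation is deterministic: items absent
from a wave's instrument may be coded "not owned" (0) for that wave when that
is the historically defensible reading (e.g. automobiles in a 1967 village
census).  Household nonresponse is never imputed; those records are excluded
listwise from fits.  Standardization always uses pooled means and SDs so that
scores are comparable across waves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .asset_panel import AssetPanel, Codebook, PanelError

__all__ = [
    "HARMONIZED_ITEMS",
    "NEWER_ITEMS",
    "PooledDesign",
    "harmonized_item_set",
    "impute_not_asked_as_zero",
    "pool",
    "design_from_values",
]

# The 19-item benchmark set: 8 durable assets + 11 housing characteristics
# (rooms-per-member crowding counts among the housing block).
HARMONIZED_ITEMS: tuple[str, ...] = (
    "radio",
    "record_player",
    "sewing_machine",
    "refrigerator",
    "television",
    "bicycle",
    "motorcycle",
    "automobile",
    "owns_land",
    "owns_house",
    "rooms_per_member",
    "floor",
    "roof",
    "walls",
    "separate_kitchen",
    "cooking_medium",
    "sanitary_installation",
    "electricity",
    "improved_water_source",
)

# Newer assets introduced from 2002 on, used by the extended-index variant.
NEWER_ITEMS: tuple[str, ...] = (
    "video_player",
    "sound_system",
    "computer",
    "telephone",
    "washing_machine",
    "improved_sewage",
)


def harmonized_item_set(codebook: Codebook) -> list[str]:
    """The 19-item benchmark set, verified present in the codebook."""
    missing = [n for n in HARMONIZED_ITEMS if n not in codebook.item_names]
    if missing:
        raise PanelError(f"codebook lacks benchmark items: {missing}")
    return list(HARMONIZED_ITEMS)


def impute_not_asked_as_zero(
    panel: AssetPanel,
    rules: Sequence[tuple[str, Iterable[str]]] | None = None,
) -> AssetPanel:
    """Set NOT_ASKED cells to 0 per the harmonization rules.

    ``rules`` is a list of (item, waves); by default every item's
    ``impute_zero_waves`` from the codebook is applied.  A rule that targets a
    wave in which the item *was* asked is rejected: zero-imputation must never
    overwrite real data.  NONRESPONSE cells are untouched.
    """
    if rules is None:
        rules = [
            (it.name, it.impute_zero_waves)
            for it in panel.codebook.items
            if it.impute_zero_waves
        ]
    out = panel.copy()
    wave_level = out.values.index.get_level_values(1)
    for name, waves in rules:
        item = panel.codebook.item(name)
        for wave in waves:
            if item.asked_in(wave):
                raise PanelError(
                    f"refusing to zero-impute {name!r} in wave {wave!r}: item was asked"
                )
            mask = np.asarray(wave_level == wave)
            if item.name in out.values.columns:
                col = out.values[name].to_numpy()
                col[mask & np.isnan(col)] = 0.0
                out.values[name] = col
                if out.ordinal is not None and item.ordinal_recode is not None:
                    ocol = out.ordinal[name].to_numpy()
                    ocol[mask & np.isnan(ocol)] = 0.0
                    out.ordinal[name] = ocol
    return out


@dataclass
class PooledDesign:
    """Complete-case pooled design: standardized and raw matrices plus scaling.

    ``z`` holds columns standardized on the pooled sample (mean 0, SD 1,
    ddof=1); ``raw`` the untransformed values on the same rows/columns.
    ``dropped`` lists items excluded because they were entirely NOT_ASKED in
    the pooled selection or had zero variance.
    """

    z: pd.DataFrame
    raw: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    dropped: list[str]
    n_excluded: int

    @property
    def items(self) -> list[str]:
        return list(self.z.columns)

    @property
    def n(self) -> int:
        return len(self.z)


def pool(
    panel: AssetPanel,
    items: Sequence[str],
    waves: Sequence[str] | None = None,
    stratum: str | None = None,
) -> PooledDesign:
    """Pool waves into one complete-case design standardized on pooled moments.

    Items that are entirely missing in the selection (not asked anywhere in
    the chosen waves) are dropped, as are zero-variance items; both are
    recorded in ``dropped`` with a warning.  Remaining records with any
    missing value (nonresponse) are excluded listwise.
    """
    unknown = [c for c in items if c not in panel.values.columns]
    if unknown:
        raise PanelError(f"items not in panel: {unknown}")
    sub = panel.values[list(items)]
    if waves is not None:
        sub = sub[sub.index.get_level_values(1).isin(list(waves))]
    if stratum is not None:
        if panel.stratum is None:
            raise PanelError("panel has no stratum labels")
        sub = sub[panel.stratum.reindex(sub.index) == stratum]
    if sub.empty:
        raise PanelError("empty selection")
    return design_from_values(sub)


def design_from_values(sub: pd.DataFrame) -> PooledDesign:
    """Complete-case standardized design from an already-selected value frame."""
    dropped = [c for c in sub.columns if sub[c].isna().all()]
    sub = sub.drop(columns=dropped)
    n_before = len(sub)
    sub = sub.dropna(axis=0, how="any")
    n_excluded = n_before - len(sub)
    if len(sub) < 3:
        raise PanelError(f"only {len(sub)} complete records after exclusions")

    sds = sub.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warnings.warn(
            f"dropping zero-variance items from fit: {constant}", stacklevel=2
        )
        dropped += constant
        sub = sub.drop(columns=constant)
        sds = sds.drop(constant)
    if sub.shape[1] < 2:
        raise PanelError("fewer than 2 non-constant items remain")
    means = sub.mean()
    z = (sub - means) / sds
    return PooledDesign(
        z=z, raw=sub, means=means, sds=sds, dropped=dropped, n_excluded=n_excluded
    )
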