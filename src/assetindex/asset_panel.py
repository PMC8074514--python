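"""Data model, codebook-driven recoding and I/O for multi-wave asset panels.

A panel holds one record per (household, wave).  Columns are survey items:
binary ownership/quality indicators, optionally a three-level ordinal version
of the housing-quality items, and exactly one continuous "crowding" item
(rooms per household member).  Two kinds of missingness are kept distinct:

* ``NOT_ASKED`` — the item was absent from that wave's instrument.  This is a
  property of the (item, wave) pair, declared in the codebook's availability
  sets, and is the only missingness that wave-aware zero-imputation may fill.
* ``NONRESPONSE`` — the item was on the instrument but the household has no
  value.  Such records are excluded listwise from index fits.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelError",
    "MissingKind",
    "ItemDef",
    "Codebook",
    "AssetPanel",
    "compute_crowding",
    "binarize_crowding",
    "read_panel",
    "read_panel_wide",
    "write_panel",
]

CROWDING_BINARY_CUTOFF = 0.75  # rooms per member above which a household counts as uncrowded


class PanelError(ValueError):
    """Raised on codebook violations, unknown raw levels or malformed files."""


class MissingKind(enum.Enum):
    NOT_ASKED = "not_asked"
    NONRESPONSE = "nonresponse"


@dataclass(frozen=True)
class ItemDef:
    """One survey item: its kind, level recodings and per-wave availability.

    ``binary_recode`` maps raw instrument levels (strings) to {0, 1};
    ``ordinal_recode`` optionally maps the same levels to {0, 1, 2}
    (low / medium / high quality).  ``impute_zero_waves`` lists waves in which
    the item, although not asked, is treated as not owned (coded 0) during
    harmonization.
    """

    name: str
    kind: str  # asset | housing | crowding
    binary_recode: Mapping[str, int] = field(default_factory=dict)
    ordinal_recode: Mapping[str, int] | None = None
    availability: frozenset[str] = frozenset()
    impute_zero_waves: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in {"asset", "housing", "crowding"}:
            raise PanelError(f"item {self.name!r}: unknown kind {self.kind!r}")
        if self.kind != "crowding":
            if not self.binary_recode:
                raise PanelError(f"item {self.name!r}: binary_recode required")
            if any(v not in (0, 1) for v in self.binary_recode.values()):
                raise PanelError(f"item {self.name!r}: binary codes must be 0/1")
        if self.ordinal_recode is not None:
            if set(self.ordinal_recode) != set(self.binary_recode):
                raise PanelError(
                    f"item {self.name!r}: ordinal_recode must cover the same raw levels"
                )
            for lvl, o in self.ordinal_recode.items():
                if o not in (0, 1, 2):
                    raise PanelError(f"item {self.name!r}: ordinal codes must be 0/1/2")
                b = self.binary_recode[lvl]
                # the two recodes must agree at the extremes
                if (o == 0 and b != 0) or (o == 2 and b != 1):
                    raise PanelError(
                        f"item {self.name!r}: ordinal level {lvl!r}={o} conflicts "
                        f"with binary code {b}"
                    )

    def asked_in(self, wave: str) -> bool:
        return wave in self.availability


@dataclass(frozen=True)
class Codebook:
    """Declarative description of the instrument: items and chronological waves."""

    items: tuple[ItemDef, ...]
    waves: tuple[str, ...]

    def __post_init__(self):
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise PanelError("duplicate item names in codebook")
        if len(set(self.waves)) != len(self.waves) or not self.waves:
            raise PanelError("waves must be a non-empty list of unique labels")
        wave_set = set(self.waves)
        n_crowd = 0
        for it in self.items:
            if not it.availability:
                raise PanelError(f"item {it.name!r}: empty availability")
            if not set(it.availability) <= wave_set:
                raise PanelError(f"item {it.name!r}: availability outside declared waves")
            if not set(it.impute_zero_waves) <= wave_set:
                raise PanelError(f"item {it.name!r}: impute_zero_waves outside declared waves")
            if it.kind == "crowding":
                n_crowd += 1
        if n_crowd != 1:
            raise PanelError(f"codebook must declare exactly one crowding item, got {n_crowd}")

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    @property
    def crowding_item(self) -> ItemDef:
        return next(it for it in self.items if it.kind == "crowding")

    def item(self, name: str) -> ItemDef:
        for it in self.items:
            if it.name == name:
                return it
        raise PanelError(f"unknown item {name!r}")

    def wave_order(self, wave: str) -> int:
        try:
            return self.waves.index(wave)
        except ValueError:
            raise PanelError(f"unknown wave {wave!r}") from None

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "waves": list(self.waves),
            "items": [
                {
                    "name": it.name,
                    "kind": it.kind,
                    "binary_recode": dict(it.binary_recode),
                    "ordinal_recode": dict(it.ordinal_recode) if it.ordinal_recode else None,
                    "availability": sorted(it.availability, key=self.wave_order),
                    "impute_zero_waves": list(it.impute_zero_waves),
                }
                for it in self.items
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Codebook":
        payload = json.loads(Path(path).read_text())
        items = tuple(
            ItemDef(
                name=d["name"],
                kind=d["kind"],
                binary_recode={str(k): int(v) for k, v in (d.get("binary_recode") or {}).items()},
                ordinal_recode=(
                    {str(k): int(v) for k, v in d["ordinal_recode"].items()}
                    if d.get("ordinal_recode")
                    else None
                ),
                availability=frozenset(d["availability"]),
                impute_zero_waves=tuple(d.get("impute_zero_waves") or ()),
            )
            for d in payload["items"]
        )
        return cls(items=items, waves=tuple(payload["waves"]))


def compute_crowding(rooms: int | float, members: int | float) -> float:
    """Rooms per household member; higher means wealthier (less crowded)."""
    if members is None or members < 1:
        raise PanelError(f"members must be >= 1, got {members!r}")
    if rooms is None or rooms < 1:
        raise PanelError(f"rooms must be >= 1, got {rooms!r}")
    return rooms / members


def binarize_crowding(value: float, cutoff: float = CROWDING_BINARY_CUTOFF) -> int:
    """1 iff rooms-per-member strictly exceeds the cutoff (default 0.75)."""
    if not math.isfinite(value) or value <= 0:
        raise PanelError(f"crowding value must be finite and positive, got {value!r}")
    return int(value > cutoff)


@dataclass
class AssetPanel:
    """Recoded household × wave table plus codebook and optional strata.

    ``values`` is indexed by (household_id, wave) with one float column per
    codebook item: 0/1 for binary items, positive reals for crowding, NaN for
    missing.  ``ordinal`` carries the 0/1/2 coding for items that declare an
    ordinal recode (NaN elsewhere).  The kind of a missing cell is recovered
    from the codebook: an item is NOT_ASKED wherever the wave is outside its
    availability set, otherwise an empty cell is household NONRESPONSE.
    """

    values: pd.DataFrame
    codebook: Codebook
    ordinal: pd.DataFrame | None = None
    stratum: pd.Series | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        if idx.nlevels != 2:
            raise PanelError("values must be indexed by (household_id, wave)")
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].tolist()[:3]
            raise PanelError(f"duplicate (household, wave) keys, e.g. {dupes}")
        unknown = set(self.values.columns) - set(self.codebook.item_names)
        if unknown:
            raise PanelError(f"columns not in codebook: {sorted(unknown)}")
        crowd = self.codebook.crowding_item.name
        for it in self.codebook.items:
            if it.name not in self.values.columns:
                continue
            col = self.values[it.name]
            obs = col.dropna()
            if it.name == crowd:
                if ((obs <= 0) | ~np.isfinite(obs)).any():
                    raise PanelError(f"{it.name}: crowding values must be finite and > 0")
            else:
                bad = ~obs.isin([0.0, 1.0])
                if bad.any():
                    raise PanelError(f"{it.name}: non-binary values {obs[bad].unique()[:3]}")
        if self.stratum is not None and not self.stratum.index.equals(idx):
            raise PanelError("stratum must share the panel index")

    # -- introspection ---------------------------------------------------

    @property
    def waves_present(self) -> list[str]:
        present = set(self.values.index.get_level_values(1))
        return [w for w in self.codebook.waves if w in present]

    def missing_kind(self, item: str, wave: str) -> MissingKind:
        """Kind of missingness a NaN cell for (item, wave) represents."""
        return (
            MissingKind.NONRESPONSE
            if self.codebook.item(item).asked_in(wave)
            else MissingKind.NOT_ASKED
        )

    def select_waves(self, waves: Iterable[str]) -> "AssetPanel":
        waves = list(waves)
        mask = self.values.index.get_level_values(1).isin(waves)
        return AssetPanel(
            values=self.values.loc[mask],
            codebook=self.codebook,
            ordinal=self.ordinal.loc[mask] if self.ordinal is not None else None,
            stratum=self.stratum.loc[mask] if self.stratum is not None else None,
        )

    def copy(self) -> "AssetPanel":
        return AssetPanel(
            values=self.values.copy(),
            codebook=self.codebook,
            ordinal=self.ordinal.copy() if self.ordinal is not None else None,
            stratum=self.stratum.copy() if self.stratum is not None else None,
        )

    def equals(self, other: "AssetPanel") -> bool:
        if not self.values.sort_index().equals(other.values.sort_index()):
            return False
        a, b = self.ordinal, other.ordinal
        if (a is None) != (b is None) or (a is not None and not a.sort_index().equals(b.sort_index())):
            return False
        a, b = self.stratum, other.stratum
        if (a is None) != (b is None) or (a is not None and not a.sort_index().equals(b.sort_index())):
            return False
        return True


# ---------------------------------------------------------------------------
# recoding


def _recode_cell(token, item: ItemDef, where: str) -> tuple[float, float]:
    """Map one raw cell to (binary_value, ordinal_value); NaN-safe."""
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return math.nan, math.nan
    s = str(token).strip()
    if s == "" or s.lower() in {"na", "n.a.", "nan"}:
        return math.nan, math.nan
    if item.kind == "crowding":
        try:
            v = float(s)
        except ValueError:
            raise PanelError(f"{where}: crowding value {s!r} is not numeric") from None
        return v, math.nan
    if s in item.binary_recode:
        b = float(item.binary_recode[s])
        o = float(item.ordinal_recode[s]) if item.ordinal_recode else math.nan
        return b, o
    # already-recoded numerics pass through (recoding is idempotent)
    try:
        v = float(s)
    except ValueError:
        raise PanelError(f"{where}: unknown raw level {s!r} for item {item.name!r}") from None
    if item.ordinal_recode is not None and v in (0.0, 1.0, 2.0):
        return (1.0 if v == 2.0 else 0.0) if v in (0.0, 2.0) else 0.0, v
    if v in (0.0, 1.0):
        return v, math.nan
    raise PanelError(f"{where}: value {v!r} out of range for item {item.name!r}")


def _recode_frame(
    raw: pd.DataFrame, codebook: Codebook
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recode a raw (household, wave)-indexed frame of tokens."""
    values = pd.DataFrame(index=raw.index, columns=codebook.item_names, dtype=float)
    ordinal = pd.DataFrame(index=raw.index, columns=codebook.item_names, dtype=float)
    waves = raw.index.get_level_values(1)
    for it in codebook.items:
        if it.name not in raw.columns:
            # column absent => NOT_ASKED everywhere it is unavailable; an
            # available wave with no column is unrecoverable
            asked = waves.isin(list(it.availability))
            if asked.any():
                raise PanelError(
                    f"column {it.name!r} missing but item is asked in "
                    f"{sorted(set(waves[asked]))}"
                )
            continue
        col = raw[it.name]
        pairs = [
            _recode_cell(tok, it, f"row {key}") for key, tok in zip(raw.index, col)
        ]
        values[it.name] = [p[0] for p in pairs]
        ordinal[it.name] = [p[1] for p in pairs]
        # enforce NOT_ASKED where unavailable: observed values there are an error
        not_asked = ~waves.isin(list(it.availability))
        observed = values[it.name].notna().to_numpy()
        clash = not_asked & observed
        if clash.any():
            bad = raw.index[clash][:3].tolist()
            raise PanelError(
                f"item {it.name!r} has values in waves where it was not asked, e.g. {bad}"
            )
    if not any(it.ordinal_recode for it in codebook.items):
        return values, None
    return values, ordinal


# ---------------------------------------------------------------------------
# file I/O


def read_panel(path: str | Path, codebook: Codebook) -> AssetPanel:
    """Read the long CSV dialect: household_id, wave[, stratum], item columns.

    Raw levels are recoded per the codebook; already-recoded numerics pass
    through unchanged.  Empty cells for an asked item become NONRESPONSE;
    cells in waves outside the item's availability must be empty (NOT_ASKED).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for req in ("household_id", "wave"):
        if req not in df.columns:
            raise PanelError(f"{path}: missing required column {req!r}")
    df = df.set_index(["household_id", "wave"])
    if df.index.has_duplicates:
        raise PanelError(f"{path}: duplicate (household_id, wave) rows")
    stratum = None
    if "stratum" in df.columns:
        s = df.pop("stratum").replace("", np.nan)
        if s.notna().any():
            stratum = s
    values, ordinal = _recode_frame(df, codebook)
    return AssetPanel(values=values, codebook=codebook, ordinal=ordinal, stratum=stratum)


def read_panel_wide(paths: Mapping[str, str | Path], codebook: Codebook) -> AssetPanel:
    """Read the wide dialect: one CSV per wave, columns household_id[, stratum] + items.

    An item column absent from a wave's file is NOT_ASKED for that wave (and
    must be absent from the item's availability set).
    """
    frames = []
    for wave, p in paths.items():
        if wave not in codebook.waves:
            raise PanelError(f"unknown wave {wave!r}")
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
        if "household_id" not in df.columns:
            raise PanelError(f"{p}: missing household_id column")
        df["wave"] = wave
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True).set_index(["household_id", "wave"])
    if combined.index.has_duplicates:
        raise PanelError("duplicate (household_id, wave) rows across wave files")
    stratum = None
    if "stratum" in combined.columns:
        s = combined.pop("stratum").replace("", np.nan)
        if s.notna().any():
            stratum = s
    combined = combined.fillna("")  # items absent from some wave files
    values, ordinal = _recode_frame(combined, codebook)
    return AssetPanel(values=values, codebook=codebook, ordinal=ordinal, stratum=stratum)


def _raw_token(item: ItemDef, b: float, o: float) -> str:
    """Inverse recode: pick the canonical raw level for stored codes."""
    if math.isnan(b):
        return ""
    if item.kind == "crowding":
        return repr(float(b))
    if item.ordinal_recode is not None and not math.isnan(o):
        for lvl, code in item.ordinal_recode.items():
            if code == int(o) and item.binary_recode[lvl] == int(b):
                return lvl
    for lvl, code in item.binary_recode.items():
        if code == int(b):
            return lvl
    raise PanelError(f"item {item.name!r}: no raw level for code {b}")


def write_panel(panel: AssetPanel, path: str | Path) -> None:
    """Write the long CSV dialect; round-trips losslessly through read_panel."""
    out = pd.DataFrame(index=panel.values.index)
    if panel.stratum is not None:
        out["stratum"] = panel.stratum.fillna("")
    for it in panel.codebook.items:
        if it.name not in panel.values.columns:
            continue
        b = panel.values[it.name]
        o = (
            panel.ordinal[it.name]
            if panel.ordinal is not None and it.name in panel.ordinal.columns
            else pd.Series(math.nan, index=b.index)
        )
        out[it.name] = [_raw_token(it, bb, oo) for bb, oo in zip(b, o)]
    out = out.reset_index()
    out.to_csv(path, index=False)
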