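"""Panel data model: recoding, crowding, missingness kinds, file round trips."""

import math

import numpy as np
import pandas as pd
import pytest

from assetindex import (
    AssetPanel,
    Codebook,
    ItemDef,
    MissingKind,
    PanelError,
    binarize_crowding,
    compute_crowding,
    read_panel,
    read_panel_wide,
    write_panel,
)
from assetindex.synth_cohort import default_codebook


@pytest.fixture
def tiny_codebook():
    return Codebook(
        waves=("w1", "w2"),
        items=(
            ItemDef(
                name="floor",
                kind="housing",
                binary_recode={"dirt": 0, "cement": 1, "tile": 1},
                availability=frozenset({"w1", "w2"}),
            ),
            ItemDef(
                name="automobile",
                kind="asset",
                binary_recode={"no": 0, "yes": 1},
                availability=frozenset({"w2"}),
                impute_zero_waves=("w1",),
            ),
            ItemDef(name="crowding", kind="crowding", availability=frozenset({"w1", "w2"})),
        ),
    )


class TestCrowding:
    @pytest.mark.parametrize(
        "rooms,members,expected", [(3, 4, 0.75), (2, 2, 1.0), (1, 15, 1 / 15)]
    )
    def test_quotient(self, rooms, members, expected):
        assert compute_crowding(rooms, members) == pytest.approx(expected)

    @pytest.mark.parametrize("rooms,members", [(1, 0), (0, 4), (2, -1)])
    def test_degenerate_inputs_rejected(self, rooms, members):
        with pytest.raises(PanelError):
            compute_crowding(rooms, members)

    @pytest.mark.parametrize(
        "value,expected", [(0.75, 0), (1.13, 1), (0.61, 0), (0.7500001, 1)]
    )
    def test_binarize_strict_cutoff(self, value, expected):
        # households exactly at 0.75 rooms per member count as crowded
        assert binarize_crowding(value) == expected

    @pytest.mark.parametrize("bad", [math.nan, math.inf, 0.0, -1.0])
    def test_binarize_rejects_nonpositive_or_nonfinite(self, bad):
        with pytest.raises(PanelError):
            binarize_crowding(bad)


class TestCodebookInvariants:
    def test_duplicate_item_names_rejected(self, tiny_codebook):
        items = tiny_codebook.items + (tiny_codebook.items[0],)
        with pytest.raises(PanelError, match="duplicate"):
            Codebook(items=items, waves=tiny_codebook.waves)

    def test_exactly_one_crowding_item(self, tiny_codebook):
        items = tuple(it for it in tiny_codebook.items if it.kind != "crowding")
        with pytest.raises(PanelError, match="crowding"):
            Codebook(items=items, waves=tiny_codebook.waves)

    def test_availability_must_be_declared_waves(self, tiny_codebook):
        with pytest.raises(PanelError, match="availability"):
            Codebook(
                items=tiny_codebook.items[:2]
                + (
                    ItemDef(
                        name="crowding",
                        kind="crowding",
                        availability=frozenset({"w99"}),
                    ),
                ),
                waves=tiny_codebook.waves,
            )

    def test_ordinal_binary_recode_must_agree_at_extremes(self):
        with pytest.raises(PanelError, match="conflicts"):
            ItemDef(
                name="roof",
                kind="housing",
                binary_recode={"low": 1, "medium": 0, "high": 1},
                ordinal_recode={"low": 0, "medium": 1, "high": 2},
                availability=frozenset({"w1"}),
            )

    def test_json_round_trip(self, tiny_codebook, tmp_path):
        p = tmp_path / "cb.json"
        tiny_codebook.to_json(p)
        again = Codebook.from_json(p)
        assert again == tiny_codebook


class TestReadPanel:
    def _write(self, tmp_path, text):
        p = tmp_path / "panel.csv"
        p.write_text(text)
        return p

    def test_raw_level_recoded(self, tiny_codebook, tmp_path):
        p = self._write(
            tmp_path,
            "household_id,wave,floor,automobile,crowding\n"
            "h1,w1,dirt,,0.5\n"
            "h2,w2,tile,yes,1.5\n",
        )
        panel = read_panel(p, tiny_codebook)
        assert panel.values.loc[("h1", "w1"), "floor"] == 0.0
        assert panel.values.loc[("h2", "w2"), "floor"] == 1.0
        assert panel.values.loc[("h2", "w2"), "automobile"] == 1.0

    def test_not_asked_vs_nonresponse(self, tiny_codebook, tmp_path):
        p = self._write(
            tmp_path,
            "household_id,wave,floor,automobile,crowding\n"
            "h1,w1,dirt,,0.5\n"
            "h2,w2,,yes,1.5\n",
        )
        panel = read_panel(p, tiny_codebook)
        # automobile was not on the w1 instrument; floor blank in w2 is a gap
        assert np.isnan(panel.values.loc[("h1", "w1"), "automobile"])
        assert panel.missing_kind("automobile", "w1") is MissingKind.NOT_ASKED
        assert np.isnan(panel.values.loc[("h2", "w2"), "floor"])
        assert panel.missing_kind("floor", "w2") is MissingKind.NONRESPONSE

    def test_unknown_raw_level_rejected_with_context(self, tiny_codebook, tmp_path):
        p = self._write(
            tmp_path,
            "household_id,wave,floor,automobile,crowding\nh1,w1,marble,,0.5\n",
        )
        with pytest.raises(PanelError, match="marble"):
            read_panel(p, tiny_codebook)

    def test_duplicate_key_rejected(self, tiny_codebook, tmp_path):
        p = self._write(
            tmp_path,
            "household_id,wave,floor,automobile,crowding\n"
            "h1,w1,dirt,,0.5\nh1,w1,dirt,,0.5\n",
        )
        with pytest.raises(PanelError, match="duplicate"):
            read_panel(p, tiny_codebook)

    def test_value_in_not_asked_wave_rejected(self, tiny_codebook, tmp_path):
        p = self._write(
            tmp_path,
            "household_id,wave,floor,automobile,crowding\nh1,w1,dirt,yes,0.5\n",
        )
        with pytest.raises(PanelError, match="not asked"):
            read_panel(p, tiny_codebook)

    def test_wide_dialect_missing_column_is_not_asked(self, tiny_codebook, tmp_path):
        (tmp_path / "w1.csv").write_text("household_id,floor,crowding\nh1,dirt,0.5\n")
        (tmp_path / "w2.csv").write_text(
            "household_id,floor,automobile,crowding\nh1,tile,no,1.2\n"
        )
        panel = read_panel_wide(
            {"w1": tmp_path / "w1.csv", "w2": tmp_path / "w2.csv"}, tiny_codebook
        )
        assert np.isnan(panel.values.loc[("h1", "w1"), "automobile"])
        assert panel.values.loc[("h1", "w2"), "automobile"] == 0.0


class TestRoundTrip:
    def test_write_read_identity_small(self, tiny_codebook, tmp_path):
        idx = pd.MultiIndex.from_tuples(
            [("h1", "w1"), ("h1", "w2"), ("h2", "w2")], names=["household_id", "wave"]
        )
        values = pd.DataFrame(
            {
                "floor": [0.0, 1.0, np.nan],
                "automobile": [np.nan, 1.0, 0.0],
                "crowding": [0.5, 0.75, 2.0 / 3.0],
            },
            index=idx,
        )
        panel = AssetPanel(values=values, codebook=tiny_codebook)
        path = tmp_path / "out.csv"
        write_panel(panel, path)
        again = read_panel(path, tiny_codebook)
        assert panel.equals(again)

    def test_round_trip_of_simulated_panels(self, tmp_path, small_panel):
        """Simulated panels (strata, ordinal codes, NOT_ASKED blocks) survive I/O."""
        path = tmp_path / "panel.csv"
        write_panel(small_panel, path)
        again = read_panel(path, small_panel.codebook)
        assert small_panel.equals(again)
        assert again.stratum is not None

    def test_recoding_is_idempotent(self, tmp_path, small_panel):
        path1, path2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_panel(small_panel, path1)
        once = read_panel(path1, small_panel.codebook)
        write_panel(once, path2)
        twice = read_panel(path2, small_panel.codebook)
        assert once.equals(twice)


class TestPanelInvariants:
    def test_not_asked_is_all_or_none(self, small_panel):
        cb = small_panel.codebook
        waves = small_panel.values.index.get_level_values(1)
        for it in cb.items:
            for w in cb.waves:
                col = small_panel.values.loc[waves == w, it.name]
                if not it.asked_in(w):
                    assert col.isna().all()

    def test_duplicate_index_rejected(self, small_panel):
        doubled = pd.concat([small_panel.values, small_panel.values])
        with pytest.raises(PanelError, match="duplicate"):
            AssetPanel(values=doubled, codebook=small_panel.codebook)

    def test_nonbinary_value_rejected(self, tiny_codebook):
        idx = pd.MultiIndex.from_tuples([("h1", "w1")], names=["household_id", "wave"])
        values = pd.DataFrame({"floor": [2.5], "crowding": [1.0]}, index=idx)
        with pytest.raises(PanelError, match="non-binary"):
            AssetPanel(values=values, codebook=tiny_codebook)

    def test_default_codebook_satisfies_invariants(self):
        cb = default_codebook()
        assert len(cb.waves) == 6
        assert sum(it.kind == "crowding" for it in cb.items) == 1
        rp = cb.item("record_player")
        assert rp.availability == frozenset({"1975", "1987"})
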