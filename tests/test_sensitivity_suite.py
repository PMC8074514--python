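"""S1-S5 robustness protocol and the Spearman comparison primitive."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from assetindex import (
    build_benchmark,
    full_report,
    s1_cross_sectional,
    s2_extended,
    s3_leave_out,
    s4_alternate,
    s5_ordinal,
    spearman,
)


def series(vals, prefix="h"):
    idx = pd.MultiIndex.from_tuples(
        [(f"{prefix}{i}", "w") for i in range(len(vals))],
        names=["household_id", "wave"],
    )
    return pd.Series(vals, index=idx, dtype=float)


def brute_force_spearman(x, y):
    """Rank-then-Pearson with mid-ranks computed by explicit counting."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        out = np.empty(len(v))
        for i, xi in enumerate(v):
            less = np.sum(v < xi)
            equal = np.sum(v == xi)
            out[i] = less + (equal + 1) / 2.0
        return out

    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = series([0.1, 0.5, 2.0, 3.0, 9.0])
        y = series(np.exp([0.1, 0.5, 2.0, 3.0, 9.0]))
        r, n = spearman(x, y)
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_negation_gives_minus_one(self):
        x = series([1.0, 2.0, 3.0, 4.0])
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_brute_force_rank_oracle(self):
        x = series([1, 2, 3, 4, 5])
        y = series([1, 3, 2, 5, 4])
        r, _ = spearman(x, y)
        assert r == pytest.approx(0.8, abs=1e-12)
        assert r == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_ties_use_midranks(self):
        x = series([1, 1, 2, 3, 3, 4.0])
        y = series([2, 1, 2, 5, 4, 4.0])
        r, _ = spearman(x, y)
        assert r == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(series([1, 1, 1, 1.0]), series([1, 2, 3, 4.0]))

    def test_restricted_to_common_keys(self):
        x = series(np.arange(10.0))
        y = series(np.arange(6.0))  # only h0..h5 overlap
        _, n = spearman(x, y)
        assert n == 6


@pytest.fixture(scope="module")
def bench(small_panel):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_benchmark(small_panel)


class TestS1:
    def test_single_wave_panel_reproduces_itself(self, small_panel):
        single = small_panel.select_waves(["2002"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = build_benchmark(single)
            _, r, n = s1_cross_sectional(res.panel, res.scores, "2002")
        assert r == pytest.approx(1.0, abs=1e-12)
        assert n == len(res.scores)

    def test_1967_fit_excludes_imputed_constant_items(self, bench):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, r, _ = s1_cross_sectional(bench.panel, bench.scores, "1967")
        for item in ("record_player", "television", "automobile", "motorcycle",
                     "sewing_machine", "owns_land", "electricity"):
            assert item not in model.items
        assert r > 0.5

    def test_stratified_fit_restricted_to_stratum(self, bench):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, r, n = s1_cross_sectional(bench.panel, bench.scores, "2017-18", stratum="urban")
        urban = (bench.panel.stratum == "urban") & (
            bench.panel.values.index.get_level_values(1) == "2017-18"
        )
        assert n == int(urban.sum())
        assert 0 < r <= 1

    def test_unknown_wave_rejected(self, bench):
        with pytest.raises(Exception, match="wave"):
            s1_cross_sectional(bench.panel, bench.scores, "1900")


class TestS2:
    def test_washing_machine_imputed_in_2002(self, bench):
        waves = bench.panel.values.index.get_level_values(1)
        col = bench.panel.values.loc[waves == "2002", "washing_machine"]
        assert (col == 0.0).all()

    def test_per_wave_correlations_high(self, bench):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, by_wave = s2_extended(bench.panel, bench.scores)
        assert set(by_wave) == {"2002", "2015-16", "2017-18"}
        assert len(model.items) == 25
        for r, n in by_wave.values():
            assert r >= 0.85

    def test_benchmark_loadings_preserved_in_rank(self, bench):
        from scipy.stats import spearmanr

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, _ = s2_extended(bench.panel, bench.scores)
        common = [i for i in bench.model.items if i in model.items]
        a = [bench.model.loading(i) for i in common]
        b = [model.loading(i) for i in common]
        assert spearmanr(a, b).statistic > 0.8


class TestS3:
    def test_identity_variant_is_unity(self, bench):
        rep = s3_leave_out(bench.panel, bench.scores, 0, 0)
        assert len(rep.rows) == 1
        assert rep.rows["spearman_r"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_pair_sweep_enumerates_all_combinations(self, bench):
        rep = s3_leave_out(bench.panel, bench.scores, 2, 0)
        assert len(rep.rows) == 171  # C(19, 2)

    def test_sweep_invariant_to_enumeration_order(self, bench):
        rep = s3_leave_out(bench.panel, bench.scores, 1, 0)
        r_by_label = dict(zip(rep.rows["variant"], rep.rows["spearman_r"]))
        # recompute two variants directly; results must match the sweep rows
        from assetindex import build_index, harmonized_item_set
        from assetindex.sensitivity_suite import spearman as sp

        items = harmonized_item_set(bench.panel.codebook)
        for drop in (items[0], items[7]):
            keep = [i for i in items if i != drop]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, scores, _ = build_index(bench.panel, items=keep)
            r, _ = sp(scores, bench.scores)
            assert r == pytest.approx(
                r_by_label[f"omit_items=['{drop}'];omit_waves=[]"], abs=1e-12
            )

    def test_wave_omission_compared_on_remaining_households(self, bench):
        rep = s3_leave_out(bench.panel, bench.scores, 0, 1, )
        assert len(rep.rows) == 6
        total = len(bench.scores)
        waves = bench.scores.index.get_level_values(1)
        for _, row in rep.rows.iterrows():
            omitted = row["variant"].split("omit_waves=['")[1].rstrip("']")
            expected_n = total - int((waves == omitted).sum())
            assert row["n"] == expected_n

    def test_invalid_counts_rejected(self, bench):
        with pytest.raises(ValueError):
            s3_leave_out(bench.panel, bench.scores, 3, 0)


class TestS4:
    def test_pearson_pca_is_benchmark_itself(self, bench):
        _, r, n = s4_alternate(bench.panel, bench.scores, "pearson", "pca")
        assert r == pytest.approx(1.0, abs=1e-12)
        assert n == len(bench.scores)

    def test_unsupported_combination_lists_grid(self, bench):
        with pytest.raises(ValueError, match="grid"):
            s4_alternate(bench.panel, bench.scores, "polychoric", "nmf")

    @pytest.mark.parametrize("corr,method,floor", [
        ("pearson", "efa", 0.99),
        (None, "mca", 0.99),
        ("polychoric", "pca", 0.95),
        ("polychoric", "efa", 0.9),
    ])
    def test_alternative_methods_track_benchmark(self, bench, corr, method, floor):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, r, _ = s4_alternate(bench.panel, bench.scores, corr, method)
        assert r >= floor


class TestS5:
    def test_ordinal_variants_track_benchmark(self, bench):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, r_pca, _ = s5_ordinal(bench.panel, bench.scores, "pca")
            _, r_efa, _ = s5_ordinal(bench.panel, bench.scores, "efa")
        assert r_pca >= 0.9
        assert r_efa >= 0.85

    def test_degenerate_ordinal_recode_equals_binary_variant(self, bench):
        """If the middle category is never used, the three-level polychoric
        index coincides with the binary polychoric index."""
        panel = bench.panel.copy()
        for it in panel.codebook.items:
            if it.ordinal_recode is not None:
                panel.ordinal[it.name] = panel.values[it.name] * 2.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, r_ord, _ = s5_ordinal(panel, bench.scores, "pca")
            _, r_bin, _ = s4_alternate(panel, bench.scores, "polychoric", "pca")
        assert r_ord == pytest.approx(r_bin, abs=1e-9)

    def test_missing_ordinal_recode_rejected(self, bench):
        cb = bench.panel.codebook
        from assetindex import AssetPanel, Codebook, ItemDef, PanelError

        stripped = Codebook(
            items=tuple(
                ItemDef(
                    name=it.name, kind=it.kind, binary_recode=it.binary_recode,
                    ordinal_recode=None, availability=it.availability,
                    impute_zero_waves=it.impute_zero_waves,
                )
                for it in cb.items
            ),
            waves=cb.waves,
        )
        panel = AssetPanel(
            values=bench.panel.values.copy(), codebook=stripped,
            ordinal=None, stratum=bench.panel.stratum,
        )
        with pytest.raises(PanelError, match="ordinal"):
            s5_ordinal(panel, bench.scores, "pca")


class TestFullReport:
    def test_blocks_present_and_pearson_pca_unity(self, bench):
        rep = full_report(bench.panel, bench.scores, grid=("s1", "s4"))
        blocks = set(rep.rows["block"])
        assert blocks == {"S1", "S4"}
        row = rep.rows[rep.rows["variant"] == "pca/pearson"]
        assert row["spearman_r"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert rep.min_r("S1") > 0.8
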