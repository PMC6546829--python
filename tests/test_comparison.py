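"""Differential methylation: Fisher exact, BH adjustment, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import bh_oracle, exact_fisher_two_sided
from wgbstiles.comparison import (
    ComparisonConfig,
    call_dmrs,
    classify_changing,
    common_and_unique_sets,
    common_tiles,
    compare_methylomes,
    fdr_bh,
    fisher_exact_2x2,
    hyper_hypo_label,
)
from wgbstiles.tiling import StageMethylome, Tile


def methylome(stage, tile_data):
    """tile_data: {start: (level, n_meth, n_unmeth)} on chr1."""
    tiles = {
        ("chr1", s): Tile("chr1", s, s + 300, 4, m, u, lv, 2.0)
        for s, (lv, m, u) in tile_data.items()
    }
    return StageMethylome(stage, tiles, 300)


class TestFisher:
    def test_extreme_table_enumeration_value(self):
        # p = 2 / C(20,10)
        assert fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(
            2 / 184756, rel=1e-9)

    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_moderate_table_hand_value(self):
        assert fisher_exact_2x2(4, 1, 1, 4) == pytest.approx(
            0.2063492063492063, rel=1e-9)

    def test_row_and_column_swaps_leave_p_unchanged(self):
        base = fisher_exact_2x2(7, 2, 3, 9)
        assert fisher_exact_2x2(3, 9, 7, 2) == pytest.approx(base, rel=1e-12)
        assert fisher_exact_2x2(2, 7, 9, 3) == pytest.approx(base, rel=1e-12)

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2(0, 0, 0, 0) == 1.0
        assert fisher_exact_2x2(0, 0, 3, 4) == 1.0
        assert fisher_exact_2x2(0, 3, 0, 4) == 1.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_matches_exact_enumeration_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 40, size=4)
            p = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            oracle = float(exact_fisher_two_sided(int(a), int(b), int(c),
                                                  int(d)))
            assert p == pytest.approx(oracle, abs=1e-9)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 60, size=4))
            p = fisher_exact_2x2(a, b, c, d)
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert p == pytest.approx(ref, abs=1e-9)

    def test_scaling_counts_never_increases_p(self):
        # same unequal proportions, more reads: evidence only accumulates
        for factor in (2, 3, 5):
            p1 = fisher_exact_2x2(8, 2, 3, 7)
            pk = fisher_exact_2x2(8 * factor, 2 * factor, 3 * factor,
                                  7 * factor)
            assert pk <= p1 + 1e-12


class TestBH:
    def test_hand_stepped_example(self):
        q = fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert fdr_bh([0.37]) == pytest.approx([0.37])

    def test_q_at_least_p_elementwise(self):
        rng = np.random.default_rng(5)
        p = rng.random(200)
        q = fdr_bh(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(6)
        p = rng.random(100)
        q = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_definitional_oracle_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            m = int(rng.integers(1, 120))
            p = np.round(rng.random(m), 2)  # heavy ties
            assert fdr_bh(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.1, 1.5])


class TestUniverses:
    def test_intersection_and_symmetry(self):
        a = methylome("a", {0: (0.5, 10, 10), 300: (0.5, 10, 10),
                            600: (0.5, 10, 10)})
        b = methylome("b", {300: (0.5, 10, 10), 600: (0.5, 10, 10),
                            900: (0.5, 10, 10)})
        assert common_tiles(a, b) == {("chr1", 300), ("chr1", 600)}
        assert len(common_tiles(a, b)) == len(common_tiles(b, a))

    def test_disjoint_methylomes_give_empty_report(self):
        a = methylome("a", {0: (0.5, 10, 10)})
        b = methylome("b", {600: (0.5, 10, 10)})
        comp = compare_methylomes(a, b)
        assert len(comp) == 0

    def test_common_and_unique_set_algebra(self):
        ms = [methylome("s1", {0: (0.5, 5, 5), 300: (0.5, 5, 5)}),
              methylome("s2", {300: (0.5, 5, 5), 600: (0.5, 5, 5)}),
              methylome("s3", {300: (0.5, 5, 5)})]
        common, unique = common_and_unique_sets(ms)
        assert common == {("chr1", 300)}
        assert unique == {"s1": {("chr1", 0)}, "s2": {("chr1", 600)},
                          "s3": set()}

    def test_identical_methylomes_all_common(self):
        tile_data = {0: (0.5, 5, 5), 300: (0.2, 2, 8)}
        ms = [methylome("a", tile_data), methylome("b", tile_data)]
        common, unique = common_and_unique_sets(ms)
        assert len(common) == 2
        assert all(not u for u in unique.values())

    def test_unique_disjoint_from_common_and_bounded(self):
        ms = [methylome("a", {0: (0.5, 5, 5), 300: (0.5, 5, 5)}),
              methylome("b", {300: (0.5, 5, 5), 900: (0.5, 5, 5)})]
        common, unique = common_and_unique_sets(ms)
        total_unique = sum(len(u) for u in unique.values())
        for u in unique.values():
            assert not (u & common)
        assert total_unique + len(common) <= sum(len(m) for m in ms)


class TestClassification:
    def test_strong_change_labelled_increasing(self):
        a = methylome("a", {0: (0.1, 2, 18)})
        b = methylome("b", {0: (0.9, 18, 2)})
        comp = compare_methylomes(a, b)
        row = comp.iloc[0]
        assert row["delta"] == pytest.approx(0.8)
        assert row["p"] == pytest.approx(
            float(exact_fisher_two_sided(2, 18, 18, 2)), rel=1e-9)
        assert row["label"] == "increasing"

    def test_delta_gate_is_strict(self):
        df = pd.DataFrame({
            "delta": [0.39, 0.41], "p": [1e-10, 1e-10], "q": [1e-10, 1e-10],
        })
        out = classify_changing(df)
        assert list(out["label"]) == ["stable", "increasing"]

    def test_significance_gate_fails_despite_big_delta(self):
        # counts (4,1) vs (1,4): p = 0.2063 > 0.05 -> stable
        a = methylome("a", {0: (0.8, 4, 1)})
        b = methylome("b", {0: (0.2, 1, 4)})
        comp = compare_methylomes(a, b)
        assert comp.iloc[0]["p"] == pytest.approx(0.2063492063492063, rel=1e-6)
        assert comp.iloc[0]["label"] == "stable"

    def test_dmr_call_and_threshold_rule(self):
        a = methylome("a", {0: (0.80, 40, 10), 300: (0.80, 40, 10)})
        b = methylome("b", {0: (0.20, 10, 40), 300: (0.30, 15, 35)})
        comp = compare_methylomes(a, b)
        dmrs = call_dmrs(comp)
        assert len(dmrs) == 1
        assert dmrs.iloc[0]["start"] == 0
        assert dmrs.iloc[0]["dmr_label"] == "dmr_high_in_a"
        # level_b = 0.30 > dmr_low: never a DMR regardless of p
        assert comp.set_index("start").loc[300, "dmr_label"] == "none"

    def test_dmr_subset_of_changing(self):
        rng = np.random.default_rng(12)
        spec_a, spec_b = {}, {}
        for i in range(60):
            la, lb = rng.random(), rng.random()
            na, nb = int(rng.integers(20, 80)), int(rng.integers(20, 80))
            spec_a[i * 300] = (la, int(la * na), na - int(la * na))
            spec_b[i * 300] = (lb, int(lb * nb), nb - int(lb * nb))
        comp = compare_methylomes(methylome("a", spec_a),
                                  methylome("b", spec_b))
        dmr_rows = comp["dmr_label"] != "none"
        changing_rows = comp["label"] != "stable"
        assert (dmr_rows & ~changing_rows).sum() == 0

    def test_swapping_arguments_mirrors_labels(self):
        rng = np.random.default_rng(13)
        spec_a, spec_b = {}, {}
        for i in range(40):
            la, lb = rng.random(), rng.random()
            spec_a[i * 300] = (la, int(la * 60), 60 - int(la * 60))
            spec_b[i * 300] = (lb, int(lb * 60), 60 - int(lb * 60))
        ab = compare_methylomes(methylome("a", spec_a), methylome("b", spec_b))
        ba = compare_methylomes(methylome("b", spec_b), methylome("a", spec_a))
        flip = {"increasing": "decreasing", "decreasing": "increasing",
                "stable": "stable"}
        flip_dmr = {"dmr_high_in_a": "dmr_high_in_b",
                    "dmr_high_in_b": "dmr_high_in_a", "none": "none"}
        assert list(ba["label"]) == [flip[x] for x in ab["label"]]
        assert list(ba["dmr_label"]) == [flip_dmr[x] for x in ab["dmr_label"]]
        assert ba["p"].to_numpy() == pytest.approx(ab["p"].to_numpy())
        assert ba["q"].to_numpy() == pytest.approx(ab["q"].to_numpy())


class TestHyperHypo:
    @pytest.mark.parametrize("level,expected", [
        (0.75, "hyper"), (0.25, "hypo"), (0.50, "intermediate"),
        (1.0, "hyper"), (0.0, "hypo"),
    ])
    def test_boundaries_inclusive(self, level, expected):
        assert hyper_hypo_label(level) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hyper_hypo_label(1.2)


class TestConfig:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ComparisonConfig(dmr_low=0.8, dmr_high=0.2)
        with pytest.raises(ValueError):
            ComparisonConfig(change_delta=1.5)
        with pytest.raises(ValueError):
            ComparisonConfig(alpha_p=0.0)
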