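"""Feature assignment, metagene profiles, region summaries, density, CpH."""

import numpy as np
import pandas as pd
import pytest

from wgbstiles.annotation import (
    assign_features,
    cph_level,
    density_methylation_relation,
    feature_profile,
    metagene_profile,
    region_summary,
    replicate_correlation,
    site_region_summary,
)
from wgbstiles.coverage_io import GenomicFeature
from wgbstiles.tiling import StageMethylome, Tile


def make_methylome(stage, levels_by_start, chrom="chr1"):
    tiles = {
        (chrom, s): Tile(chrom, s, s + 300, 4, 10, 10, lv, 2.0)
        for s, lv in levels_by_start.items()
    }
    return StageMethylome(stage, tiles, 300)


class TestAssignFeatures:
    def test_precedence_promoter_over_exon(self):
        feats = [GenomicFeature("chr1", 0, 100, "exon"),
                 GenomicFeature("chr1", 200, 290, "promoter")]
        asg = assign_features({("chr1", 0)}, feats)
        assert asg[("chr1", 0)].feature_class == "promoter"

    def test_no_overlap_is_intergenic(self):
        feats = [GenomicFeature("chr2", 0, 100, "exon")]
        asg = assign_features({("chr1", 0)}, feats)
        assert asg[("chr1", 0)].feature_class == "intergenic"

    def test_one_bp_overlap_counts(self):
        feats = [GenomicFeature("chr1", 299, 400, "CGI")]
        asg = assign_features({("chr1", 0), ("chr1", 300)}, feats)
        assert asg[("chr1", 0)].feature_class == "CGI"
        assert asg[("chr1", 300)].feature_class == "CGI"

    def test_assignment_is_a_partition(self):
        rng = np.random.default_rng(3)
        universe = {("chr1", int(s) * 300) for s in rng.integers(0, 200, 80)}
        feats = [GenomicFeature("chr1", int(a), int(a) + int(w), cls)
                 for a, w, cls in zip(rng.integers(0, 60_000, 40),
                                      rng.integers(50, 2000, 40),
                                      rng.choice(["promoter", "CGI", "exon",
                                                  "intron", "SINE", "LINE",
                                                  "LTR"], 40))]
        asg = assign_features(universe, feats)
        assert set(asg) == universe  # exactly one class per tile
        fractions = pd.Series(
            [a.feature_class for a in asg.values()]).value_counts(
            normalize=True)
        assert fractions.sum() == pytest.approx(1.0)

    def test_unknown_precedence_class_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            assign_features(set(), [], precedence=["promoter", "mystery"])


class TestFeatureProfile:
    def test_single_class_mean(self):
        m = make_methylome("s", {0: 0.1, 300: 0.1, 600: 0.7})
        feats = [GenomicFeature("chr1", 0, 600, "promoter")]
        asg = assign_features(m.keys(), feats)
        prof = feature_profile([m], asg).set_index("feature_class")
        assert prof.loc["promoter", "mean_level"] == pytest.approx(0.1)
        assert prof.loc["intergenic", "mean_level"] == pytest.approx(0.7)

    def test_missing_class_absent_not_zero(self):
        m = make_methylome("s", {0: 0.5})
        asg = assign_features(m.keys(), [])
        prof = feature_profile([m], asg)
        assert set(prof["feature_class"]) == {"intergenic"}

    def test_single_tile_identity(self):
        m = make_methylome("s", {0: 0.42})
        feats = [GenomicFeature("chr1", 0, 300, "CGI")]
        prof = feature_profile([m], assign_features(m.keys(), feats))
        assert prof.iloc[0]["mean_level"] == pytest.approx(0.42)


def uniform_sites(chrom, lo, hi, step, level):
    pos = np.arange(lo, hi, step)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "level": level})


class TestMetagene:
    GENES = pd.DataFrame({
        "gene_id": ["g1"], "chrom": ["chr1"], "start": [30_000],
        "end": [40_000], "strand": ["+"],
    })

    def test_constant_field_gives_flat_profile(self):
        sites = uniform_sites("chr1", 10_001, 60_000, 37, 0.5)
        prof = metagene_profile(self.GENES, sites)
        filled = prof.dropna(subset=["mean_level"])
        assert len(filled) > 200
        assert np.allclose(filled["mean_level"], 0.5, atol=1e-12)

    def test_promoter_dip_minimum_lands_at_tss(self):
        sites = uniform_sites("chr1", 10_001, 60_000, 23, 0.6)
        promoter = (sites["pos"] - 1 >= 29_000) & (sites["pos"] - 1 < 30_000)
        sites.loc[promoter, "level"] = 0.05
        prof = metagene_profile(self.GENES, sites)
        argmin = prof.loc[prof["mean_level"].idxmin()]
        # the dip is inside the last upstream kilobase, adjacent to the TSS
        assert argmin["zone"] == "upstream"
        assert argmin["axis"] >= -1000

    def test_minus_strand_mirrors_plus(self):
        plus = self.GENES
        minus = plus.assign(strand="-")
        # ramp along the genome; reflect it for the minus-strand version
        sites = uniform_sites("chr1", 10_001, 60_000, 41, 0.0)
        x = sites["pos"].to_numpy()
        sites["level"] = (x - x.min()) / (x.max() - x.min())
        p_plus = metagene_profile(plus, sites)
        mirrored = sites.copy()
        mirrored["pos"] = (30_000 + 40_000 - 1) - (sites["pos"] - 1) + 1
        mirrored = mirrored.sort_values("pos").reset_index(drop=True)
        p_minus = metagene_profile(minus, mirrored)
        a = p_plus["mean_level"].to_numpy()
        b = p_minus["mean_level"].to_numpy()
        mask = ~np.isnan(a) & ~np.isnan(b)
        assert mask.sum() > 150
        assert np.allclose(a[mask], b[mask], atol=1e-12)

    def test_short_gene_proportional_binning(self):
        genes = pd.DataFrame({
            "gene_id": ["tiny"], "chrom": ["chr1"], "start": [1000],
            "end": [1030], "strand": ["+"],
        })
        sites = uniform_sites("chr1", 990, 1050, 3, 0.5)
        prof = metagene_profile(genes, sites)  # no error, bins in range
        assert prof["bin"].max() == 219


class TestRegionSummary:
    def test_fully_unmethylated_contig(self):
        m = make_methylome("s", {0: 0.0, 300: 0.0}, chrom="chrM")
        out = region_summary(m, [("mito", "chrM", 0, 16_000)])
        assert out.iloc[0]["mean_level"] == pytest.approx(0.0)

    def test_unknown_chrom_warning_row(self):
        m = make_methylome("s", {0: 0.5})
        out = region_summary(m, [("ghost", "chr9", 0, 1000)])
        assert out.iloc[0]["n_tiles"] == 0
        assert np.isnan(out.iloc[0]["mean_level"])

    def test_whole_chromosome_equals_global_level(self):
        from wgbstiles.tiling import global_level

        m = make_methylome("s", {0: 0.2, 300: 0.4, 900: 0.9})
        out = region_summary(m, [("chr1", "chr1", 0, 10_000)])
        assert out.iloc[0]["mean_level"] == pytest.approx(global_level(m))

    def test_site_weighted_consistency_of_subregions(self):
        # mean over a region equals the site-count-weighted mean of halves
        sites = pd.DataFrame({
            "chrom": "chr1",
            "pos": [10, 20, 30, 510, 520],
            "level": [0.1, 0.2, 0.3, 0.8, 1.0],
        })
        whole = site_region_summary(sites, [("w", "chr1", 0, 1000)], "s")
        left = site_region_summary(sites, [("l", "chr1", 0, 500)], "s")
        right = site_region_summary(sites, [("r", "chr1", 500, 1000)], "s")
        nl, nr = left.iloc[0]["n_sites"], right.iloc[0]["n_sites"]
        weighted = (left.iloc[0]["mean_site_level"] * nl
                    + right.iloc[0]["mean_site_level"] * nr) / (nl + nr)
        assert whole.iloc[0]["mean_site_level"] == pytest.approx(weighted)


class TestCpH:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "context",
                                           "n_meth", "n_unmeth"])

    def test_all_unmethylated_is_zero(self):
        df = self.frame([("chr1", i, "CHH", 0, 10) for i in range(1, 6)])
        assert cph_level(df) == 0.0

    def test_no_cph_records_is_nan_not_zero(self):
        df = self.frame([("chr1", 1, "CpG", 5, 5)])
        assert np.isnan(cph_level(df))

    def test_cpg_records_never_contribute(self):
        df = self.frame([("chr1", 1, "CpG", 10, 0),
                         ("chr1", 2, "CHG", 0, 10),
                         ("chr1", 3, "CHH", 1, 9)])
        assert cph_level(df) == pytest.approx(0.05)

    def test_coverage_filter_applies(self):
        df = self.frame([("chr1", 1, "CHH", 4, 0),      # 4x, filtered
                         ("chr1", 2, "CHH", 0, 10)])
        assert cph_level(df, min_site_coverage=5) == 0.0


class TestDensityRelation:
    def tiles(self, dens, lev):
        return [Tile("chr1", i * 300, i * 300 + 300, 4, 1, 1, l, d)
                for i, (d, l) in enumerate(zip(dens, lev))]

    def test_perfect_linear_gives_minus_one(self):
        dens = np.linspace(1, 20, 200)
        lev = 1 - dens / 20
        _, r_buckets, r_raw = density_methylation_relation(
            self.tiles(dens, lev))
        assert r_buckets == pytest.approx(-1.0, abs=1e-9)
        assert r_raw == pytest.approx(-1.0, abs=1e-9)

    def test_independent_gives_small_r(self):
        rng = np.random.default_rng(21)
        dens = rng.uniform(1, 30, 10_000)
        lev = rng.uniform(0, 1, 10_000)
        _, r_buckets, r_raw = density_methylation_relation(
            self.tiles(dens, lev))
        assert abs(r_raw) < 0.2

    def test_constant_level_is_degenerate(self):
        dens = np.linspace(1, 20, 50)
        _, r_buckets, r_raw = density_methylation_relation(
            self.tiles(dens, np.full(50, 0.5)))
        assert np.isnan(r_raw) and np.isnan(r_buckets)

    def test_too_few_buckets_missing(self):
        _, r_buckets, _ = density_methylation_relation(
            self.tiles([2.0, 2.0], [0.1, 0.9]))
        assert np.isnan(r_buckets)


class TestReplicateCorrelation:
    def tiles_from(self, levels):
        return {("chr1", i * 300): Tile("chr1", i * 300, i * 300 + 300, 4,
                                        1, 1, lv, 2.0)
                for i, lv in enumerate(levels)}

    def test_self_correlation_unity_and_symmetry(self):
        rng = np.random.default_rng(2)
        a = self.tiles_from(rng.random(30))
        b = self.tiles_from(rng.random(30))
        mat = replicate_correlation({"a": a, "b": b, "a2": a})
        assert mat.loc["a", "a"] == 1.0
        assert mat.loc["a", "a2"] == pytest.approx(1.0)
        assert mat.loc["a", "b"] == pytest.approx(mat.loc["b", "a"])

    def test_too_few_shared_tiles_missing(self):
        a = self.tiles_from([0.5])
        b = {("chr2", 0): Tile("chr2", 0, 300, 4, 1, 1, 0.5, 2.0)}
        mat = replicate_correlation({"a": a, "b": b})
        assert np.isnan(mat.loc["a", "b"])

    def test_within_stage_exceeds_between_stage(self, tiny_config,
                                                tiny_genome):
        from wgbstiles.simulate import simulate_stage_coverage
        from wgbstiles.tiling import TilingConfig, build_tiles, \
            filter_sites_frame

        config = TilingConfig()
        tiles = {}
        for stage, rep in [("sperm", 1), ("sperm", 2), ("8cell", 1)]:
            df = simulate_stage_coverage(tiny_genome, tiny_config, stage, rep)
            cpg = filter_sites_frame(df[df["context"] == "CpG"],
                                     config.min_site_coverage)
            tiles[f"{stage}_r{rep}"] = build_tiles(cpg, config)
        mat = replicate_correlation(tiles)
        assert mat.loc["sperm_r1", "sperm_r2"] > mat.loc["sperm_r1",
                                                         "8cell_r1"]
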