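"""Feature annotation of tiles and methylation profiles.

Tiles are assigned to a single genomic feature class by a precedence rule
(promoter > CGI > exon > intron > SINE > LINE > LTR by default, configurable):
a tile takes the first class in precedence order with at least 1 bp of
overlap, and falls back to ``intergenic``.  The single label makes class
fractions a partition of any tile universe, which is how pie-chart style
distributions are reported.

Also here: per-feature methylation profiles by stage, metagene trend
profiles (length-normalised gene body with 15 kb fixed flanks), named-region
summaries (chromosomes, ICRs, mitochondria), CpH (= CHG + CHH) levels,
the CpG-density/methylation relation, and replicate correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .coverage_io import GenomicFeature
from .tiling import StageMethylome, Tile, TileKey

DEFAULT_PRECEDENCE = ("promoter", "CGI", "exon", "intron", "SINE", "LINE", "LTR")

KNOWN_CLASSES = set(DEFAULT_PRECEDENCE) | {"gene_body", "intergenic"}


@dataclass(frozen=True, slots=True)
class FeatureAssignment:
    tile_key: TileKey
    feature_class: str
    gene_id: Optional[str] = None


# ---------------------------------------------------------------------------
# Tile -> feature class assignment
# ---------------------------------------------------------------------------


def _tile_span(start: int, end: int, tile_size: int) -> range:
    """Tile start coordinates whose [t, t+size) window overlaps [start, end)."""
    first = (start // tile_size) * tile_size
    return range(first, end, tile_size)


def assign_features(
    tile_keys: Iterable[TileKey],
    features: Sequence[GenomicFeature],
    tile_size: int = 300,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> dict[TileKey, FeatureAssignment]:
    """Assign each tile exactly one feature class under the precedence rule.

    A tile gets the highest-precedence class among features it overlaps by
    >= 1 bp; tiles overlapping nothing are ``intergenic``.
    """
    for cls in precedence:
        if cls not in KNOWN_CLASSES:
            raise ValueError(f"unknown feature class in precedence: {cls!r}")
    rank = {cls: i for i, cls in enumerate(precedence)}
    universe = set(tile_keys)
    best: dict[TileKey, tuple[int, Optional[str]]] = {}
    for f in features:
        r = rank.get(f.feature_class)
        if r is None:
            continue  # classes outside the precedence list never label a tile
        for tstart in _tile_span(f.start, f.end, tile_size):
            key = (f.chrom, tstart)
            if key not in universe:
                continue
            cur = best.get(key)
            if cur is None or r < cur[0]:
                best[key] = (r, f.gene_id)
    out: dict[TileKey, FeatureAssignment] = {}
    for key in universe:
        if key in best:
            r, gene_id = best[key]
            out[key] = FeatureAssignment(key, precedence[r], gene_id)
        else:
            out[key] = FeatureAssignment(key, "intergenic")
    return out


def feature_profile(
    methylomes: Sequence[StageMethylome],
    assignments: Mapping[TileKey, FeatureAssignment],
) -> pd.DataFrame:
    """Mean tile methylation per (stage, feature class).

    Unweighted over tiles, the same convention as the stage-scale global
    level.  Classes with no tiles in a stage are absent rows, not zeros.
    """
    rows = []
    for m in methylomes:
        by_class: dict[str, list[float]] = {}
        for key, tile in m.tiles.items():
            asg = assignments.get(key)
            if asg is None:
                raise KeyError(f"tile {key} has no feature assignment")
            by_class.setdefault(asg.feature_class, []).append(tile.level)
        for cls, levels in sorted(by_class.items()):
            rows.append((m.stage, cls, float(np.mean(levels)), len(levels)))
    return pd.DataFrame(rows, columns=["stage", "feature_class", "mean_level",
                                       "n_tiles"])


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------


def metagene_profile(
    genes: pd.DataFrame,
    sites: pd.DataFrame,
    flank: int = 15_000,
    body_bins: int = 100,
    flank_bins: int = 60,
) -> pd.DataFrame:
    """Average site methylation along gene bodies with fixed flanks.

    ``sites`` needs columns chrom, pos (1-based), level, already
    coverage-filtered.  Gene bodies (TSS to TES) are scaled to
    ``body_bins`` proportional bins; each flank covers ``flank`` bp in
    ``flank_bins`` fixed-width bins.  Minus-strand genes are reflected so
    bin 0 is always the 5'-most upstream bin.  Each site contributes once
    per overlapping gene window; bin values are means over all contributing
    sites; empty bins are NaN.

    Returns a frame with bin index, zone (upstream/body/downstream), axis
    position (bp offset in flanks, body fraction inside) and mean level.
    """
    n_bins = 2 * flank_bins + body_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in sites.groupby("chrom"):
        order = np.argsort(grp["pos"].to_numpy(), kind="mergesort")
        by_chrom[str(chrom)] = (
            grp["pos"].to_numpy()[order],
            grp["level"].to_numpy(dtype=float)[order],
        )

    flank_width = flank / flank_bins
    for gene in genes.itertuples(index=False):
        data = by_chrom.get(gene.chrom)
        if data is None:
            continue
        pos, lev = data
        lo = np.searchsorted(pos, gene.start - flank + 1)  # 1-based pos
        hi = np.searchsorted(pos, gene.end + flank, side="right")
        if lo == hi:
            continue
        x = pos[lo:hi] - 1  # 0-based coordinates
        y = lev[lo:hi]
        if gene.strand == "-":
            x = (gene.start + gene.end - 1) - x  # reflect about the gene centre
        body_len = gene.end - gene.start
        bins = np.empty(x.size, dtype=np.int64)
        up = x < gene.start
        down = x >= gene.end
        body = ~(up | down)
        bins[up] = ((x[up] - (gene.start - flank)) / flank_width).astype(np.int64)
        frac = (x[body] - gene.start) / body_len
        bins[body] = flank_bins + np.minimum(
            (frac * body_bins).astype(np.int64), body_bins - 1
        )
        bins[down] = (
            flank_bins + body_bins
            + ((x[down] - gene.end) / flank_width).astype(np.int64)
        )
        keep = (bins >= 0) & (bins < n_bins)
        np.add.at(sums, bins[keep], y[keep])
        np.add.at(counts, bins[keep], 1)

    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    zone = (["upstream"] * flank_bins + ["body"] * body_bins
            + ["downstream"] * flank_bins)
    axis = np.concatenate([
        (np.arange(flank_bins) + 0.5) * flank_width - flank,     # bp before TSS
        (np.arange(body_bins) + 0.5) / body_bins,                # body fraction
        (np.arange(flank_bins) + 0.5) * flank_width,             # bp after TES
    ])
    return pd.DataFrame({
        "bin": np.arange(n_bins),
        "zone": zone,
        "axis": axis,
        "mean_level": means,
        "n_sites": counts,
    })


# ---------------------------------------------------------------------------
# Region summaries and CpH
# ---------------------------------------------------------------------------


def region_summary(
    methylome: StageMethylome,
    regions: Sequence[tuple[str, str, int, int]],
) -> pd.DataFrame:
    """Mean tile methylation over named regions (chromosome spans, ICRs, ...).

    ``regions`` rows are (name, chrom, start, end) with 0-based half-open
    coordinates.  A region with no covered tiles (including one on an
    unknown chromosome) yields n_tiles = 0 and a NaN mean.
    """
    rows = []
    for name, chrom, start, end in regions:
        levels = []
        for tstart in _tile_span(start, end, methylome.tile_size):
            tile = methylome.tiles.get((chrom, tstart))
            if tile is not None:
                levels.append(tile.level)
        mean = float(np.mean(levels)) if levels else float("nan")
        rows.append((name, methylome.stage, mean, len(levels)))
    return pd.DataFrame(rows, columns=["region", "stage", "mean_level",
                                       "n_tiles"])


def site_region_summary(
    sites: pd.DataFrame,
    regions: Sequence[tuple[str, str, int, int]],
    stage: str,
) -> pd.DataFrame:
    """Site-level variant of :func:`region_summary` (flagged by column name)."""
    rows = []
    for name, chrom, start, end in regions:
        sel = sites[(sites["chrom"] == chrom)
                    & (sites["pos"] - 1 >= start) & (sites["pos"] - 1 < end)]
        mean = float(sel["level"].mean()) if len(sel) else float("nan")
        rows.append((name, stage, mean, len(sel)))
    return pd.DataFrame(rows, columns=["region", "stage", "mean_site_level",
                                       "n_sites"])


def cph_level(records: pd.DataFrame, min_site_coverage: int = 5) -> float:
    """Mean CpH (CHG + CHH) site methylation after coverage filtering.

    Returns NaN when no CpH site passes the filter (absent, not zero).
    CpG records never contribute.
    """
    cph = records[records["context"].isin(["CHG", "CHH"])]
    total = cph["n_meth"] + cph["n_unmeth"]
    cph = cph[total >= min_site_coverage]
    if cph.empty:
        return float("nan")
    levels = cph["n_meth"] / (cph["n_meth"] + cph["n_unmeth"])
    return float(levels.mean())


# ---------------------------------------------------------------------------
# CpG density vs methylation
# ---------------------------------------------------------------------------


def density_methylation_relation(
    tiles: Union[Mapping[TileKey, Tile], Iterable[Tile]],
    n_buckets: int = 10,
    scheme: str = "quantile",
) -> tuple[pd.DataFrame, float, float]:
    """Bucketed density/methylation summary and Pearson correlations.

    Tiles are bucketed by CpG density — by equal-count quantiles (default)
    or equal-width bins — and the per-bucket mean level is correlated with
    the bucket's mean density (the figure-style summary r).  The raw
    tile-level r is returned alongside for transparency.  Fewer than three
    populated buckets, or a degenerate (constant) variable, gives NaN.
    """
    items = tiles.values() if isinstance(tiles, Mapping) else list(tiles)
    dens = np.array([t.density for t in items], dtype=float)
    lev = np.array([t.level for t in items], dtype=float)
    if dens.size == 0:
        return (pd.DataFrame(columns=["bucket", "mean_density", "mean_level",
                                      "n_tiles"]),
                float("nan"), float("nan"))
    if scheme == "quantile":
        edges = np.unique(np.quantile(dens, np.linspace(0, 1, n_buckets + 1)))
    elif scheme == "width":
        edges = np.linspace(dens.min(), dens.max(), n_buckets + 1)
    else:
        raise ValueError(f"unknown bucket scheme {scheme!r}")
    if edges.size < 2:
        edges = np.array([dens.min(), dens.min() + 1.0])
    idx = np.clip(np.searchsorted(edges, dens, side="right") - 1,
                  0, edges.size - 2)
    rows = []
    for b in range(edges.size - 1):
        mask = idx == b
        if not mask.any():
            continue
        rows.append((b, float(dens[mask].mean()), float(lev[mask].mean()),
                     int(mask.sum())))
    table = pd.DataFrame(rows, columns=["bucket", "mean_density", "mean_level",
                                        "n_tiles"])

    def _safe_r(x: np.ndarray, y: np.ndarray) -> float:
        if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
            return float("nan")
        return float(stats.pearsonr(x, y)[0])

    r_buckets = _safe_r(table["mean_density"].to_numpy(),
                        table["mean_level"].to_numpy())
    r_raw = _safe_r(dens, lev)
    return table, r_buckets, r_raw


# ---------------------------------------------------------------------------
# Replicate correlation
# ---------------------------------------------------------------------------


def replicate_correlation(
    sample_tiles: Mapping[str, Mapping[TileKey, Tile]],
) -> pd.DataFrame:
    """Pairwise Pearson r of tile levels over each sample pair's shared tiles.

    Symmetric with unit diagonal; pairs with fewer than two shared tiles
    (or a constant level vector) are NaN.
    """
    samples = sorted(sample_tiles)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    mat = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for i, si in enumerate(samples):
        for sj in samples[i + 1:]:
            shared = set(sample_tiles[si]) & set(sample_tiles[sj])
            if len(shared) < 2:
                r = float("nan")
            else:
                keys = sorted(shared)
                x = np.array([sample_tiles[si][k].level for k in keys])
                y = np.array([sample_tiles[sj][k].level for k in keys])
                if np.all(x == x[0]) or np.all(y == y[0]):
                    r = float("nan")
                else:
                    r = float(stats.pearsonr(x, y)[0])
            mat.loc[si, sj] = mat.loc[sj, si] = r
    return mat
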