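"""Fixed-width tiling of per-cytosine methylation calls.

The genome is binned into consecutive non-overlapping windows (300 bp by
default, grid anchored at coordinate 0 on every chromosome).  CpG sites with
fewer than ``min_site_coverage`` reads are discarded first; a tile is kept
only if it holds at least ``min_cpgs_per_tile`` surviving CpGs.  Replicates
of the same developmental stage are pooled after per-sample tiling: the
stage's tile universe is the union of the replicates' tile keys, with read
counts summed and site-mean levels pooled weighted by CpG count.

Two tile-level conventions are provided:

* ``mean_of_sites`` (default) — the unweighted mean of per-site methylation
  levels, matching how sample-scale levels are computed by averaging tiles.
* ``pooled_counts`` — methylated reads over total reads, the convention the
  count-based Fisher test operates on.

CpG density is the number of CpG sites within ±``density_window`` bp of a
focal site, self included (closed interval, so the minimum is 1); a tile's
density is the mean over its member sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .coverage_io import CytosineRecord

TileKey = tuple[str, int]

LEVEL_METHODS = ("mean_of_sites", "pooled_counts")


@dataclass(frozen=True, slots=True)
class TilingConfig:
    tile_size: int = 300
    min_site_coverage: int = 5
    min_cpgs_per_tile: int = 4
    density_window: int = 150
    level_method: str = "mean_of_sites"

    def __post_init__(self) -> None:
        for name in ("tile_size", "min_site_coverage", "min_cpgs_per_tile",
                     "density_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.level_method not in LEVEL_METHODS:
            raise ValueError(
                f"level_method must be one of {LEVEL_METHODS}, "
                f"got {self.level_method!r}"
            )


@dataclass(slots=True)
class Tile:
    """A fixed-width genomic window with pooled methylation evidence."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive; end - start == tile_size
    n_cpgs: int
    n_meth: int
    n_unmeth: int
    level: float
    density: float = float("nan")

    @property
    def key(self) -> TileKey:
        return (self.chrom, self.start)

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass(slots=True)
class StageMethylome:
    """The pooled tile set of one developmental stage."""

    stage: str
    tiles: dict[TileKey, Tile]
    tile_size: int
    sample_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tiles)

    def keys(self) -> set[TileKey]:
        return set(self.tiles)

    def levels(self, keys: Optional[Iterable[TileKey]] = None) -> np.ndarray:
        ks = self.tiles.keys() if keys is None else keys
        return np.array([self.tiles[k].level for k in ks], dtype=float)


# ---------------------------------------------------------------------------
# Per-site operations
# ---------------------------------------------------------------------------


def site_level(n_meth: int, n_unmeth: int) -> float:
    """Methylation level of one cytosine: methylated reads over total reads."""
    total = n_meth + n_unmeth
    if total <= 0:
        raise ValueError("site has zero coverage; filter before computing levels")
    return n_meth / total


def filter_sites(
    records: Iterable[CytosineRecord], min_site_coverage: int = 5
) -> list[CytosineRecord]:
    """Keep records with total coverage >= min_site_coverage (inclusive)."""
    return [r for r in records if r.n_meth + r.n_unmeth >= min_site_coverage]


def filter_sites_frame(df: pd.DataFrame, min_site_coverage: int = 5) -> pd.DataFrame:
    total = df["n_meth"] + df["n_unmeth"]
    return df.loc[total >= min_site_coverage].reset_index(drop=True)


# ---------------------------------------------------------------------------
# CpG density
# ---------------------------------------------------------------------------


def cpg_density(positions: np.ndarray, window: int = 150) -> np.ndarray:
    """Per-site CpG neighbourhood counts on one chromosome.

    ``positions`` must be sorted.  The count for a site at ``p`` is the
    number of positions ``p'`` with ``|p' - p| <= window``, the focal site
    included, computed with a vectorised sliding-window scan.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    positions = np.asarray(positions)
    if positions.size == 0:
        return np.zeros(0, dtype=np.int64)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    right = np.searchsorted(positions, positions + window, side="right")
    left = np.searchsorted(positions, positions - window, side="left")
    return (right - left).astype(np.int64)


def tile_density(site_counts: Sequence[float]) -> float:
    """Tile CpG density: the mean neighbourhood count over member sites."""
    counts = np.asarray(site_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("tile has no member sites")
    return float(counts.mean())


# ---------------------------------------------------------------------------
# Tile construction
# ---------------------------------------------------------------------------


def _records_to_frame(records: Iterable[CytosineRecord]) -> pd.DataFrame:
    rows = [(r.chrom, r.pos, r.context, r.n_meth, r.n_unmeth) for r in records]
    return pd.DataFrame(rows, columns=["chrom", "pos", "context", "n_meth",
                                       "n_unmeth"])


def build_tiles(
    records: Union[Iterable[CytosineRecord], pd.DataFrame],
    config: TilingConfig = TilingConfig(),
) -> dict[TileKey, Tile]:
    """Bin filtered CpG records into fixed-width tiles for one sample.

    Each CpG at 1-based position ``pos`` falls in the tile starting at
    ``floor((pos - 1) / tile_size) * tile_size``.  Tiles with fewer than
    ``min_cpgs_per_tile`` member CpGs are dropped.  Records must already be
    coverage-filtered and in CpG context.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = _records_to_frame(records)
    if df.empty:
        return {}
    if "context" in df.columns and (df["context"] != "CpG").any():
        bad = df.loc[df["context"] != "CpG", "context"].iloc[0]
        raise ValueError(f"build_tiles expects CpG records only, found {bad!r}")

    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    total = (df["n_meth"] + df["n_unmeth"]).to_numpy()
    if np.any(total <= 0):
        raise ValueError("zero-coverage record; filter sites first")
    levels = df["n_meth"].to_numpy() / total

    # per-chromosome neighbourhood counts over this sample's covered CpGs
    dens = np.empty(len(df), dtype=np.int64)
    chroms = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        dens[mask] = cpg_density(pos[mask], config.density_window)

    tile_start = ((pos - 1) // config.tile_size) * config.tile_size
    grp = pd.DataFrame(
        {
            "chrom": chroms,
            "tstart": tile_start,
            "level": levels,
            "n_meth": df["n_meth"].to_numpy(),
            "n_unmeth": df["n_unmeth"].to_numpy(),
            "density": dens,
        }
    ).groupby(["chrom", "tstart"], sort=True)
    agg = grp.agg(
        n_cpgs=("level", "size"),
        level_mean=("level", "mean"),
        n_meth=("n_meth", "sum"),
        n_unmeth=("n_unmeth", "sum"),
        density=("density", "mean"),
    ).reset_index()
    agg = agg[agg["n_cpgs"] >= config.min_cpgs_per_tile]

    tiles: dict[TileKey, Tile] = {}
    for row in agg.itertuples(index=False):
        if config.level_method == "mean_of_sites":
            level = float(row.level_mean)
        else:
            level = row.n_meth / (row.n_meth + row.n_unmeth)
        start = int(row.tstart)
        tiles[(row.chrom, start)] = Tile(
            chrom=row.chrom,
            start=start,
            end=start + config.tile_size,
            n_cpgs=int(row.n_cpgs),
            n_meth=int(row.n_meth),
            n_unmeth=int(row.n_unmeth),
            level=level,
            density=float(row.density),
        )
    return tiles


def pool_replicates(
    sample_tiles: Mapping[str, Mapping[TileKey, Tile]],
    stage: str,
    level_method: str = "mean_of_sites",
) -> StageMethylome:
    """Pool per-sample tile sets of one stage into a stage methylome.

    The stage universe is the union of replicate tile keys.  Read counts and
    CpG counts are summed; under ``mean_of_sites`` the pooled level is the
    CpG-count-weighted mean of replicate levels (i.e. the mean over all site
    observations), under ``pooled_counts`` it is recomputed from the summed
    reads.  Pooling is order-invariant.
    """
    if not sample_tiles:
        raise ValueError("need at least one sample tile set")
    if level_method not in LEVEL_METHODS:
        raise ValueError(f"unknown level_method {level_method!r}")

    sizes = set()
    for tiles in sample_tiles.values():
        for t in tiles.values():
            sizes.add(t.end - t.start)
    if len(sizes) > 1:
        raise ValueError(f"mixed tile sizes in replicates: {sorted(sizes)}")
    tile_size = sizes.pop() if sizes else 300

    pooled: dict[TileKey, Tile] = {}
    weights: dict[TileKey, tuple[float, float]] = {}  # (sum w*level, sum w*dens)
    for sample_id in sorted(sample_tiles):
        for key, t in sample_tiles[sample_id].items():
            if key not in pooled:
                pooled[key] = Tile(
                    chrom=t.chrom, start=t.start, end=t.end,
                    n_cpgs=t.n_cpgs, n_meth=t.n_meth, n_unmeth=t.n_unmeth,
                    level=t.level, density=t.density,
                )
                weights[key] = (t.n_cpgs * t.level, t.n_cpgs * t.density)
            else:
                p = pooled[key]
                wl, wd = weights[key]
                weights[key] = (wl + t.n_cpgs * t.level,
                                wd + t.n_cpgs * t.density)
                p.n_cpgs += t.n_cpgs
                p.n_meth += t.n_meth
                p.n_unmeth += t.n_unmeth
    for key, p in pooled.items():
        wl, wd = weights[key]
        if level_method == "mean_of_sites":
            p.level = wl / p.n_cpgs
        else:
            p.level = p.n_meth / (p.n_meth + p.n_unmeth)
        p.density = wd / p.n_cpgs

    return StageMethylome(
        stage=stage,
        tiles=pooled,
        tile_size=tile_size,
        sample_ids=sorted(sample_tiles),
    )


def global_level(methylome: StageMethylome) -> float:
    """Sample-scale methylation: the unweighted mean of tile levels."""
    if not methylome.tiles:
        raise ValueError(f"stage {methylome.stage!r} has no tiles")
    return float(np.mean([t.level for t in methylome.tiles.values()]))
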