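"""Pairwise tile comparisons between stages or gametes.

For a pair of stage methylomes the comparison universe is the set of tiles
covered in both.  For each shared tile, a 2x2 Fisher exact test on the
pooled methylated/unmethylated read counts gives a two-sided p-value, and
Benjamini-Hochberg adjustment over the whole universe gives q.  Tiles are

* **changing** when |level_b - level_a| > 40% (strict) and p <= 0.05 and
  q <= 0.05, split into increasing/decreasing by the sign of the change;
  everything else is **stable**;
* **DMRs** when one side is >= 75% methylated and the other <= 25%
  (inclusive at both boundaries) with the same significance gates.

Because 75% - 25% = 50% > 40%, every DMR is also a changing tile when both
rules are evaluated on the same p and q values.

The two-sided Fisher p is defined by hypergeometric enumeration: the sum of
the probabilities of all tables with the observed margins whose point
probability does not exceed the observed one (within relative tolerance
1e-12).  A table with an all-zero margin has p = 1 by convention; it cannot
arise from covered tiles but is handled defensively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tiling import StageMethylome, TileKey

_REL_TOL = 1 + 1e-12


@dataclass(frozen=True, slots=True)
class ComparisonConfig:
    change_delta: float = 0.40
    dmr_high: float = 0.75
    dmr_low: float = 0.25
    alpha_p: float = 0.05
    alpha_fdr: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.dmr_low < self.dmr_high < 1:
            raise ValueError("need 0 < dmr_low < dmr_high < 1")
        if not 0 < self.change_delta < 1:
            raise ValueError("change_delta must be in (0, 1)")
        for name in ("alpha_p", "alpha_fdr"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1)")


# ---------------------------------------------------------------------------
# Fisher exact test (two-sided, by hypergeometric enumeration)
# ---------------------------------------------------------------------------


def fisher_pvalues_for_margins(n: int, r1: int, c1: int
                               ) -> tuple[int, np.ndarray]:
    """Two-sided Fisher p for every table with margins (r1, n-r1; c1, n-c1).

    Returns (k_lo, p) where p[i] is the p-value of the table whose top-left
    cell is ``k_lo + i``.  All tables with these margins are scored in one
    vectorised pass (sorted pmf + cumulative sums), which the tile-scale
    test loop and exhaustive verification both rely on.
    """
    k_lo = max(0, r1 + c1 - n)
    k_hi = min(r1, c1)
    support = np.arange(k_lo, k_hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    order = np.argsort(pmf, kind="mergesort")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    idx = np.searchsorted(sorted_pmf, pmf * _REL_TOL, side="right")
    p = np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)
    return k_lo, np.minimum(p, 1.0)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric point probabilities over all tables with the
    observed margins whose probability is <= that of the observed table
    (within relative tolerance 1e-12).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    k_lo, p = fisher_pvalues_for_margins(n, r1, c1)
    return float(p[a - k_lo])


def fisher_exact_many(tables: np.ndarray) -> np.ndarray:
    """Two-sided Fisher p for an (n, 4) array of [a, b, c, d] tables."""
    tables = np.asarray(tables, dtype=np.int64)
    if tables.ndim != 2 or tables.shape[1] != 4:
        raise ValueError("tables must be an (n, 4) array")
    return np.array([fisher_exact_2x2(*row) for row in tables])


def fdr_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Tile universes
# ---------------------------------------------------------------------------


def common_tiles(a: StageMethylome, b: StageMethylome) -> set[TileKey]:
    """Tiles covered in both methylomes (the comparison universe)."""
    if a.tile_size != b.tile_size:
        raise ValueError("methylomes have different tile sizes")
    return a.keys() & b.keys()


def common_and_unique_sets(
    methylomes: Sequence[StageMethylome],
) -> tuple[set[TileKey], dict[str, set[TileKey]]]:
    """Commonly methylated tiles (in every stage) and per-stage unique tiles.

    A stage's unique tiles are covered in that stage and in no other; unique
    sets are pairwise disjoint and disjoint from the common set.
    """
    if len(methylomes) < 2:
        raise ValueError("need at least two methylomes")
    keysets = [m.keys() for m in methylomes]
    common = set.intersection(*keysets)
    unique: dict[str, set[TileKey]] = {}
    for i, m in enumerate(methylomes):
        others: set[TileKey] = set()
        for j, ks in enumerate(keysets):
            if j != i:
                others |= ks
        unique[m.stage] = keysets[i] - others
    return common, unique


# ---------------------------------------------------------------------------
# Comparison table and classification
# ---------------------------------------------------------------------------

COMPARISON_COLUMNS = [
    "chrom", "start", "end", "level_a", "level_b", "delta",
    "n_meth_a", "n_unmeth_a", "n_meth_b", "n_unmeth_b", "p", "q",
    "label", "dmr_label",
]


def compare_methylomes(
    a: StageMethylome,
    b: StageMethylome,
    config: ComparisonConfig = ComparisonConfig(),
) -> pd.DataFrame:
    """Full pairwise comparison over the common-tile universe.

    Returns one row per shared tile with levels, delta = level_b - level_a,
    Fisher p, BH q (adjusted over this comparison's universe), a
    stable/increasing/decreasing label and a DMR label
    (none/dmr_high_in_a/dmr_high_in_b).
    """
    keys = sorted(common_tiles(a, b))
    rows = []
    for key in keys:
        ta, tb = a.tiles[key], b.tiles[key]
        rows.append(
            (
                ta.chrom, ta.start, ta.end, ta.level, tb.level,
                tb.level - ta.level,
                ta.n_meth, ta.n_unmeth, tb.n_meth, tb.n_unmeth,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "level_a", "level_b", "delta",
                 "n_meth_a", "n_unmeth_a", "n_meth_b", "n_unmeth_b"],
    )
    if df.empty:
        df["p"] = df["q"] = pd.Series(dtype=float)
        df["label"] = df["dmr_label"] = pd.Series(dtype=str)
        return df
    tables = df[["n_meth_a", "n_unmeth_a", "n_meth_b", "n_unmeth_b"]].to_numpy()
    df["p"] = fisher_exact_many(tables)
    df["q"] = fdr_bh(df["p"].to_numpy())
    df = classify_changing(df, config)
    df["dmr_label"] = _dmr_labels(df, config)
    return df


def classify_changing(
    comparisons: pd.DataFrame, config: ComparisonConfig = ComparisonConfig()
) -> pd.DataFrame:
    """Attach stable/increasing/decreasing labels (p and q must be present)."""
    df = comparisons.copy()
    sig = (df["p"] <= config.alpha_p) & (df["q"] <= config.alpha_fdr)
    changing = sig & (df["delta"].abs() > config.change_delta)
    label = np.where(
        changing & (df["delta"] > 0), "increasing",
        np.where(changing & (df["delta"] < 0), "decreasing", "stable"),
    )
    df["label"] = label
    return df


def _dmr_labels(df: pd.DataFrame, config: ComparisonConfig) -> np.ndarray:
    sig = (df["p"] <= config.alpha_p) & (df["q"] <= config.alpha_fdr)
    high_a = (df["level_a"] >= config.dmr_high) & (df["level_b"] <= config.dmr_low)
    high_b = (df["level_b"] >= config.dmr_high) & (df["level_a"] <= config.dmr_low)
    return np.where(
        sig & high_a, "dmr_high_in_a",
        np.where(sig & high_b, "dmr_high_in_b", "none"),
    )


def call_dmrs(
    comparisons: pd.DataFrame, config: ComparisonConfig = ComparisonConfig()
) -> pd.DataFrame:
    """The DMR subset of a comparison table (>=75% vs <=25%, significant)."""
    df = comparisons
    if "dmr_label" not in df.columns:
        df = df.copy()
        df["dmr_label"] = _dmr_labels(df, config)
    return df[df["dmr_label"] != "none"].reset_index(drop=True)


def hyper_hypo_label(
    level: float, config: ComparisonConfig = ComparisonConfig()
) -> str:
    """Classify a single tile level: hyper (>=75%), hypo (<=25%), else intermediate."""
    if not 0 <= level <= 1:
        raise ValueError("level must lie in [0, 1]")
    if level >= config.dmr_high:
        return "hyper"
    if level <= config.dmr_low:
        return "hypo"
    return "intermediate"


def write_comparison(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_dmr_bed(dmrs: pd.DataFrame, path, name_a: str = "a", name_b: str = "b") -> None:
    """Write DMRs as BED with the high-methylation side in the name column."""
    with open(path, "w") as fh:
        for row in dmrs.itertuples(index=False):
            side = name_a if row.dmr_label == "dmr_high_in_a" else name_b
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\thigh_in_{side}\n")
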