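"""Methylation-expression correlation and repeat-element expression.

Per-gene methylation is the mean tile level over a gene-linked region —
promoter (upstream flank of the TSS), gene body, exons, introns, or the
CGI/LINE/SINE/LTR features overlapping the gene span.  Expression arrives
as FPKM per (gene, stage); correlation is Spearman's rho between
log2(FPKM + pseudocount) and methylation over genes carrying both values.
Spearman is rank-based, so for strictly positive FPKM the log transform and
pseudocount leave rho unchanged; the pseudocount only admits zeros.

Repeat-element expression is multi-label: a transcript overlapping both a
SINE and a LINE counts in both class summaries, unlike the single-label
tile assignment.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage_io import GenomicFeature, derive_promoters
from .tiling import StageMethylome
from .annotation import _tile_span

REGION_KINDS = ("promoter", "gene_body", "exon", "intron", "CGI", "LINE",
                "SINE", "LTR")


def _parse_exons(row) -> list[tuple[int, int]]:
    starts = getattr(row, "exon_starts", None)
    ends = getattr(row, "exon_ends", None)
    if starts is None or ends is None or pd.isna(starts) or pd.isna(ends):
        return []
    s = [int(v) for v in str(starts).rstrip(",").split(",") if v]
    e = [int(v) for v in str(ends).rstrip(",").split(",") if v]
    if len(s) != len(e):
        raise ValueError(f"gene {row.gene_id}: exon start/end lists differ")
    return list(zip(s, e))


def _mean_tile_level(
    methylome: StageMethylome, intervals: Sequence[tuple[str, int, int]]
) -> float:
    levels = []
    seen = set()
    for chrom, start, end in intervals:
        for tstart in _tile_span(start, end, methylome.tile_size):
            key = (chrom, tstart)
            if key in seen:
                continue
            seen.add(key)
            tile = methylome.tiles.get(key)
            if tile is not None:
                levels.append(tile.level)
    return float(np.mean(levels)) if levels else float("nan")


def gene_region_methylation(
    genes: pd.DataFrame,
    methylome: StageMethylome,
    region_kind: str,
    features: Optional[Sequence[GenomicFeature]] = None,
    promoter_flank: int = 1000,
) -> pd.Series:
    """Per-gene mean methylation of one region kind, NaN when uncovered.

    ``promoter`` uses the upstream flank of the TSS; ``gene_body`` the full
    span; ``exon``/``intron`` need exon structure on the gene models; the
    repeat/CGI kinds average tiles of matching features that overlap the
    gene span (``features`` required).
    """
    if region_kind not in REGION_KINDS:
        raise ValueError(f"unknown region kind {region_kind!r}")
    values: dict[str, float] = {}
    if region_kind == "promoter":
        promoters = derive_promoters(genes, flank=promoter_flank)
        by_gene: dict[str, list[tuple[str, int, int]]] = {}
        for p in promoters:
            by_gene.setdefault(p.gene_id, []).append((p.chrom, p.start, p.end))
        for row in genes.itertuples(index=False):
            ivs = by_gene.get(row.gene_id, [])
            values[row.gene_id] = _mean_tile_level(methylome, ivs)
    elif region_kind == "gene_body":
        for row in genes.itertuples(index=False):
            values[row.gene_id] = _mean_tile_level(
                methylome, [(row.chrom, row.start, row.end)]
            )
    elif region_kind in ("exon", "intron"):
        for row in genes.itertuples(index=False):
            exons = _parse_exons(row)
            if not exons:
                values[row.gene_id] = float("nan")
                continue
            exons = sorted(exons)
            if region_kind == "exon":
                ivs = [(row.chrom, s, e) for s, e in exons]
            else:
                ivs = [
                    (row.chrom, e0, s1)
                    for (_, e0), (s1, _) in zip(exons[:-1], exons[1:])
                    if e0 < s1
                ]
            values[row.gene_id] = _mean_tile_level(methylome, ivs)
    else:  # CGI / LINE / SINE / LTR overlapping the gene span
        if features is None:
            raise ValueError(f"region kind {region_kind!r} requires features")
        matching = [f for f in features if f.feature_class == region_kind]
        by_chrom: dict[str, list[GenomicFeature]] = {}
        for f in matching:
            by_chrom.setdefault(f.chrom, []).append(f)
        for row in genes.itertuples(index=False):
            ivs = [
                (f.chrom, f.start, f.end)
                for f in by_chrom.get(row.chrom, [])
                if f.start < row.end and row.start < f.end
            ]
            values[row.gene_id] = _mean_tile_level(methylome, ivs)
    return pd.Series(values, name=region_kind)


def meth_expr_correlation(
    methylation: pd.Series,
    expression: pd.Series,
    pseudocount: float = 1.0,
) -> tuple[float, int]:
    """Spearman rho between log2(FPKM + pseudocount) and methylation.

    Genes lacking either value are dropped; returns (rho, n).  Fewer than
    three complete pairs, or a constant vector, gives (NaN, n).
    """
    joined = pd.concat(
        [methylation.rename("meth"), expression.rename("fpkm")], axis=1
    ).dropna()
    n = len(joined)
    if n < 3:
        return float("nan"), n
    log_expr = np.log2(joined["fpkm"].to_numpy(dtype=float) + pseudocount)
    meth = joined["meth"].to_numpy(dtype=float)
    if np.all(meth == meth[0]) or np.all(log_expr == log_expr[0]):
        return float("nan"), n
    rho = stats.spearmanr(log_expr, meth).statistic
    return float(rho), n


def correlation_table(
    genes: pd.DataFrame,
    methylomes: Mapping[str, StageMethylome],
    expression: pd.DataFrame,
    region_kinds: Sequence[str] = REGION_KINDS,
    features: Optional[Sequence[GenomicFeature]] = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Spearman rho per (stage, region kind): the pipeline's correlation sweep."""
    rows = []
    for stage, methylome in methylomes.items():
        expr = expression[expression["stage"] == stage].set_index("gene_id")["fpkm"]
        if expr.empty:
            continue
        for kind in region_kinds:
            try:
                meth = gene_region_methylation(genes, methylome, kind,
                                               features=features)
            except ValueError:
                continue
            rho, n = meth_expr_correlation(meth, expr, pseudocount)
            rows.append((stage, kind, rho, n))
    return pd.DataFrame(rows, columns=["stage", "region_kind", "rho", "n"])


def repeat_expression(
    transcripts: pd.DataFrame,
    repeat_features: Sequence[GenomicFeature],
    expression: pd.DataFrame,
    classes: Sequence[str] = ("LINE", "SINE", "LTR"),
) -> pd.DataFrame:
    """Mean FPKM of repeat-annotated transcripts per class and stage.

    A transcript is annotated to a repeat class when its span overlaps a
    feature of that class by >= 1 bp; a transcript may count in several
    classes.  Classes with no annotated transcript are absent rows.
    """
    by_class: dict[str, set[str]] = {cls: set() for cls in classes}
    feats = [f for f in repeat_features if f.feature_class in classes]
    for row in transcripts.itertuples(index=False):
        for f in feats:
            if f.chrom == row.chrom and f.start < row.end and row.start < f.end:
                by_class[f.feature_class].add(row.gene_id)
    rows = []
    for cls in classes:
        ids = by_class[cls]
        if not ids:
            continue
        sub = expression[expression["gene_id"].isin(ids)]
        for stage, grp in sub.groupby("stage"):
            rows.append((cls, stage, float(grp["fpkm"].mean()), len(grp)))
    return pd.DataFrame(rows, columns=["repeat_class", "stage", "mean_fpkm",
                                       "n_transcripts"])
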