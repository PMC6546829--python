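"""Readers and writers for the on-disk formats of a WGBS tile analysis.

Per-cytosine methylation calls arrive in one of two Bismark dialects:

* ``bismark_cov`` — six tab-separated columns
  ``chrom  start  end  pct_methylated  n_meth  n_unmeth`` with 1-based
  inclusive coordinates.  These files are conventionally CpG-only and carry
  no strand or context, so records default to ``context='CpG'`` and
  ``strand='unknown'``.
* ``cytosine_report`` — seven columns
  ``chrom  pos  strand  n_meth  n_unmeth  context  trinucleotide`` with
  1-based positions and explicit CpG/CHG/CHH context.

Internally, cytosine positions are 1-based (as in Bismark reports) and all
intervals — features, tiles, gene bodies — are 0-based half-open (as in
BED).  Conversions happen only here, at the I/O boundary.

Gzip-compressed inputs (``.gz``) are accepted transparently.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd
import yaml

PathLike = Union[str, Path]

CONTEXTS = ("CpG", "CHG", "CHH")
STRANDS = ("+", "-", "unknown")

FEATURE_CLASSES = (
    "promoter",
    "exon",
    "intron",
    "CGI",
    "LINE",
    "SINE",
    "LTR",
    "gene_body",
    "intergenic",
)


class CoverageFormatError(ValueError):
    """A coverage, feature or table file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class CytosineRecord:
    """One cytosine's position, strand, context and read counts.

    ``pos`` is 1-based, matching Bismark reports.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("read counts must be non-negative")
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}, got {self.context!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass(frozen=True, slots=True)
class GenomicFeature:
    """A genomic interval with a feature class label (BED convention).

    ``start``/``end`` are 0-based half-open.
    """

    chrom: str
    start: int
    end: int
    feature_class: str
    gene_id: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class ManifestEntry:
    sample_id: str
    stage: str
    replicate: int
    path: str


@dataclass(slots=True)
class SampleManifest:
    """Maps coverage files to stages/replicates, with an ordered stage list."""

    entries: list[ManifestEntry]
    stage_order: list[str]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        stages_seen = {e.stage for e in self.entries}
        for stage in self.stage_order:
            if stage not in stages_seen:
                raise ValueError(f"stage {stage!r} in stage_order has no samples")

    def samples_for(self, stage: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.stage == stage]


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------


def open_text(path: PathLike, mode: str = "rt") -> io.TextIOBase:
    """Open plain or gzip-compressed text transparently."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _detect_dialect(fields: Sequence[str]) -> str:
    if len(fields) == 6:
        return "bismark_cov"
    if len(fields) == 7:
        return "cytosine_report"
    raise CoverageFormatError(
        f"cannot detect coverage dialect from {len(fields)} columns"
    )


# ---------------------------------------------------------------------------
# Coverage readers
# ---------------------------------------------------------------------------


def read_coverage(
    path: PathLike, dialect: Optional[str] = None
) -> Iterator[CytosineRecord]:
    """Stream per-cytosine records from a Bismark coverage or cytosine report.

    Parameters
    ----------
    path
        Plain or gzipped text file.
    dialect
        ``"bismark_cov"`` or ``"cytosine_report"``; auto-detected from the
        column count of the first data line when omitted.

    Yields records in file order.  Cytosine-report lines with zero coverage
    are still emitted (filtering is the caller's job).
    """
    if dialect is not None and dialect not in ("bismark_cov", "cytosine_report"):
        raise CoverageFormatError(f"unknown coverage dialect {dialect!r}")
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect is None:
                dialect = _detect_dialect(fields)
            try:
                if dialect == "bismark_cov":
                    if len(fields) != 6:
                        raise ValueError(f"expected 6 columns, got {len(fields)}")
                    chrom, start, _end, _pct, n_meth, n_unmeth = fields
                    yield CytosineRecord(
                        chrom=chrom,
                        pos=int(start),
                        strand="unknown",
                        context="CpG",
                        n_meth=int(n_meth),
                        n_unmeth=int(n_unmeth),
                    )
                else:
                    if len(fields) != 7:
                        raise ValueError(f"expected 7 columns, got {len(fields)}")
                    chrom, pos, strand, n_meth, n_unmeth, context, _tri = fields
                    yield CytosineRecord(
                        chrom=chrom,
                        pos=int(pos),
                        strand=strand,
                        context="CpG" if context == "CG" else context,
                        n_meth=int(n_meth),
                        n_unmeth=int(n_unmeth),
                    )
            except ValueError as exc:
                raise CoverageFormatError(
                    f"{path}: malformed line {lineno}: {exc}"
                ) from exc


def read_coverage_frame(path: PathLike, dialect: Optional[str] = None) -> pd.DataFrame:
    """Read a whole coverage file into a DataFrame.

    Columns: ``chrom, pos, strand, context, n_meth, n_unmeth``.  Equivalent
    to materialising :func:`read_coverage` but vectorised for large files.
    """
    with open_text(path) as fh:
        first = fh.readline()
    if not first.strip():
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
        )
    if dialect is None:
        dialect = _detect_dialect(first.rstrip("\n").split("\t"))
    if dialect == "bismark_cov":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "end", "pct", "n_meth", "n_unmeth"],
            dtype={"chrom": str},
            comment="#",
        )
        df["strand"] = "unknown"
        df["context"] = "CpG"
    elif dialect == "cytosine_report":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"],
            dtype={"chrom": str, "strand": str, "context": str},
            comment="#",
        )
        df["context"] = df["context"].replace({"CG": "CpG"})
    else:
        raise CoverageFormatError(f"unknown coverage dialect {dialect!r}")
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        raise CoverageFormatError(f"{path}: negative read counts")
    return df[["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]]


def merge_cpg_dyads(records: Iterable[CytosineRecord]) -> list[CytosineRecord]:
    """Sum the counts of the two strands of each CpG dyad onto the + position.

    A minus-strand CpG call at position ``p`` belongs to the dyad whose plus
    strand cytosine sits at ``p - 1``.  Off by default in the pipeline; the
    extractor output keeps both strands separate.
    """
    merged: dict[tuple[str, int], list[int]] = {}
    order: list[tuple[str, int]] = []
    for rec in records:
        if rec.context != "CpG":
            raise ValueError("dyad merging applies to CpG records only")
        pos = rec.pos - 1 if rec.strand == "-" else rec.pos
        key = (rec.chrom, pos)
        if key not in merged:
            merged[key] = [0, 0]
            order.append(key)
        merged[key][0] += rec.n_meth
        merged[key][1] += rec.n_unmeth
    return [
        CytosineRecord(chrom=c, pos=p, strand="+", context="CpG",
                       n_meth=m, n_unmeth=u)
        for (c, p), (m, u) in ((k, merged[k]) for k in order)
    ]


# ---------------------------------------------------------------------------
# Features and gene models
# ---------------------------------------------------------------------------


def read_features(
    path: PathLike,
    default_class: Optional[str] = None,
    name_column: str = "feature_class",
) -> list[GenomicFeature]:
    """Read a BED3+ file of genomic features.

    The optional 4th column is interpreted per ``name_column``: either the
    feature class (default) or a gene id (with ``default_class`` supplying
    the class).  Intervals are returned 0-based half-open, exactly as read —
    overlaps are retained, nothing is merged.
    """
    features: list[GenomicFeature] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CoverageFormatError(
                    f"{path}: line {lineno}: BED needs >=3 columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise CoverageFormatError(
                    f"{path}: line {lineno}: non-numeric coordinates"
                ) from exc
            if start >= end:
                raise CoverageFormatError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 else None
            if name_column == "feature_class":
                fclass = name or default_class
                gene_id = None
            else:
                fclass = default_class
                gene_id = name
            if fclass is None:
                raise CoverageFormatError(
                    f"{path}: line {lineno}: no feature class (supply default_class)"
                )
            features.append(
                GenomicFeature(chrom, start, end, fclass, gene_id=gene_id,
                               strand=strand)
            )
    return features


def write_features(features: Iterable[GenomicFeature], path: PathLike) -> None:
    with open(path, "w") as fh:
        for f in features:
            name = f.gene_id if f.gene_id is not None else f.feature_class
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\n")


GENE_MODEL_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gene_models(path: PathLike) -> pd.DataFrame:
    """Read a gene-model TSV: gene_id, chrom, start, end, strand[, exons].

    Coordinates are 0-based half-open gene spans; the TSS is ``start`` for
    + strand genes and ``end`` for - strand genes.  Optional ``exon_starts``
    and ``exon_ends`` columns hold comma-separated coordinate lists.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = [c for c in GENE_MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise CoverageFormatError(f"{path}: gene models missing columns {missing}")
    if (df["start"] >= df["end"]).any():
        raise CoverageFormatError(f"{path}: gene with start >= end")
    return df


def write_gene_models(genes: pd.DataFrame, path: PathLike) -> None:
    genes.to_csv(path, sep="\t", index=False)


def derive_promoters(
    genes: pd.DataFrame,
    flank: int = 1000,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> list[GenomicFeature]:
    """Promoters as the ``flank`` bp immediately upstream of each TSS.

    + strand: ``[TSS - flank, TSS)``; - strand: ``[TSS, TSS + flank)``,
    clipped to chromosome bounds when sizes are provided.  Genes whose
    promoter is entirely off-chromosome are skipped.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    promoters: list[GenomicFeature] = []
    for row in genes.itertuples(index=False):
        strand = getattr(row, "strand", None)
        if strand not in ("+", "-"):
            raise ValueError(f"gene {row.gene_id}: missing or invalid strand")
        if strand == "+":
            start, end = row.start - flank, row.start
        else:
            start, end = row.end, row.end + flank
        start = max(start, 0)
        if chrom_sizes is not None and row.chrom in chrom_sizes:
            end = min(end, chrom_sizes[row.chrom])
        if start >= end:
            continue
        promoters.append(
            GenomicFeature(row.chrom, start, end, "promoter",
                           gene_id=row.gene_id, strand=strand)
        )
    return promoters


# ---------------------------------------------------------------------------
# Tile serialization (BED-like TSV with header)
# ---------------------------------------------------------------------------

TILE_COLUMNS = ["chrom", "start", "end", "level", "n_cpgs", "n_meth", "n_unmeth",
                "density"]


def write_tiles(tiles, path: PathLike) -> None:
    """Write tiles as a headered BED-like TSV.

    Levels and densities are serialized with 6 decimal places so that a
    write/read round trip is stable at that precision.
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(TILE_COLUMNS) + "\n")
        items = tiles.values() if isinstance(tiles, dict) else tiles
        for t in sorted(items, key=lambda t: (t.chrom, t.start)):
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.level:.6f}\t{t.n_cpgs}\t"
                f"{t.n_meth}\t{t.n_unmeth}\t{t.density:.6f}\n"
            )


def read_tiles(path: PathLike):
    """Read tiles written by :func:`write_tiles` back into a keyed dict."""
    from .tiling import Tile  # local import to avoid a module cycle

    tiles = {}
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(TILE_COLUMNS):
                raise CoverageFormatError(
                    f"{path}: line {lineno}: expected {len(TILE_COLUMNS)} columns"
                )
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            tiles[(chrom, start)] = Tile(
                chrom=chrom,
                start=start,
                end=end,
                n_cpgs=int(fields[4]),
                n_meth=int(fields[5]),
                n_unmeth=int(fields[6]),
                level=float(fields[3]),
                density=float(fields[7]),
            )
    return tiles


# ---------------------------------------------------------------------------
# Expression tables and manifests
# ---------------------------------------------------------------------------


def read_expression(path: PathLike) -> pd.DataFrame:
    """Read a gene expression TSV with columns gene_id, stage, fpkm."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "stage": str})
    for col in ("gene_id", "stage", "fpkm"):
        if col not in df.columns:
            raise CoverageFormatError(f"{path}: expression table missing {col!r}")
    if (df["fpkm"] < 0).any():
        raise CoverageFormatError(f"{path}: negative FPKM")
    if df.duplicated(subset=["gene_id", "stage"]).any():
        raise CoverageFormatError(f"{path}: duplicate (gene_id, stage) rows")
    return df


def write_expression(expr: pd.DataFrame, path: PathLike) -> None:
    expr.to_csv(path, sep="\t", index=False)


def read_manifest(path: PathLike) -> SampleManifest:
    """Read a YAML sample manifest.

    Expected shape::

        stage_order: [sperm, GV, ...]
        samples:
          - {sample_id: sperm_r1, stage: sperm, replicate: 1, path: sperm_r1.tsv}

    Relative sample paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "samples" not in doc:
        raise CoverageFormatError(f"{path}: manifest must map 'samples'")
    entries = []
    for item in doc["samples"]:
        p = Path(item["path"])
        if not p.is_absolute():
            p = path.parent / p
        entries.append(
            ManifestEntry(
                sample_id=str(item["sample_id"]),
                stage=str(item["stage"]),
                replicate=int(item.get("replicate", 1)),
                path=str(p),
            )
        )
    stage_order = [str(s) for s in doc.get("stage_order", [])]
    if not stage_order:
        seen: list[str] = []
        for e in entries:
            if e.stage not in seen:
                seen.append(e.stage)
        stage_order = seen
    return SampleManifest(entries=entries, stage_order=stage_order)


def write_manifest(manifest: SampleManifest, path: PathLike) -> None:
    doc = {
        "stage_order": list(manifest.stage_order),
        "samples": [
            {
                "sample_id": e.sample_id,
                "stage": e.stage,
                "replicate": e.replicate,
                "path": e.path,
            }
            for e in manifest.entries
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
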