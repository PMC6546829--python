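"""End-to-end orchestration: config file in, TSV/BED report bundle out.

The pipeline sequences the analysis stages — read coverage, filter sites,
build per-sample tiles, pool replicates, pairwise comparisons (consecutive
stages plus declared gamete pairs), common/unique tile sets, feature and
metagene profiles, region summaries, CpH levels, density relation,
replicate correlations, and methylation-expression correlations — writing
every intermediate as plain TSV/BED so each stage is independently
inspectable and diffable.  Rerunning on identical inputs reproduces
identical outputs; a run log records the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import coverage_io as cio
from .annotation import (
    DEFAULT_PRECEDENCE,
    assign_features,
    cph_level,
    density_methylation_relation,
    feature_profile,
    metagene_profile,
    region_summary,
    replicate_correlation,
)
from .comparison import (
    ComparisonConfig,
    call_dmrs,
    common_and_unique_sets,
    compare_methylomes,
    write_comparison,
    write_dmr_bed,
)
from .expression import correlation_table, repeat_expression
from .tiling import (
    StageMethylome,
    TilingConfig,
    build_tiles,
    filter_sites_frame,
    global_level,
    pool_replicates,
)

logger = logging.getLogger("wgbstiles")


@dataclass(slots=True)
class PipelineConfig:
    manifest: str
    outdir: str = "wgbstiles_out"
    features: Optional[str] = None
    gene_models: Optional[str] = None
    expression: Optional[str] = None
    repeat_transcripts: Optional[str] = None
    repeat_expression: Optional[str] = None
    chrom_sizes: Optional[str] = None
    regions: Optional[str] = None  # TSV: name, chrom, start, end
    stage_order: Optional[list[str]] = None
    gamete_pairs: list[list[str]] = field(default_factory=list)
    tiling: TilingConfig = field(default_factory=TilingConfig)
    comparison: ComparisonConfig = field(default_factory=ComparisonConfig)
    precedence: list[str] = field(default_factory=lambda: list(DEFAULT_PRECEDENCE))
    metagene_flank: int = 15_000
    seed: int = 0
    log_level: str = "INFO"


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config, resolving paths against its directory."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "manifest" not in doc:
        raise ValueError(f"{path}: config must name a manifest")

    def _resolve(key):
        if doc.get(key):
            p = Path(doc[key])
            doc[key] = str(p if p.is_absolute() else path.parent / p)

    for key in ("manifest", "features", "gene_models", "expression",
                "repeat_transcripts", "repeat_expression", "chrom_sizes",
                "regions"):
        _resolve(key)
    tiling = TilingConfig(**doc.pop("tiling", {}) or {})
    comparison = ComparisonConfig(**doc.pop("comparison", {}) or {})
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(tiling=tiling, comparison=comparison, **doc)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every config problem (paths, thresholds, stage consistency)."""
    errors: list[str] = []
    manifest = None
    if not Path(config.manifest).exists():
        errors.append(f"manifest not found: {config.manifest}")
    else:
        try:
            manifest = cio.read_manifest(config.manifest)
        except Exception as exc:
            errors.append(f"manifest unreadable: {exc}")
    for key in ("features", "gene_models", "expression", "repeat_transcripts",
                "repeat_expression", "chrom_sizes", "regions"):
        p = getattr(config, key)
        if p and not Path(p).exists():
            errors.append(f"{key} not found: {p}")
    if manifest is not None:
        stages = {e.stage for e in manifest.entries}
        order = config.stage_order or manifest.stage_order
        missing = stages - set(order)
        if missing:
            errors.append(f"stage_order missing manifest stages: {sorted(missing)}")
        for e in manifest.entries:
            if not Path(e.path).exists():
                errors.append(f"coverage file missing for {e.sample_id}: {e.path}")
        for pair in config.gamete_pairs:
            if len(pair) != 2 or any(s not in stages for s in pair):
                errors.append(f"invalid gamete pair {pair!r}")
    for cls in config.precedence:
        from .annotation import KNOWN_CLASSES

        if cls not in KNOWN_CLASSES:
            errors.append(f"unknown feature class in precedence: {cls!r}")
    return errors


def _config_hash(config: PipelineConfig) -> str:
    doc = asdict(config)
    doc.pop("outdir", None)  # the output location is not an analysis input
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _pool_site_counts(frames: list[pd.DataFrame],
                      min_cov: int) -> pd.DataFrame:
    """Pool CpG site counts across replicates, filter, and attach levels."""
    allc = pd.concat(frames, ignore_index=True)
    grp = allc.groupby(["chrom", "pos"], as_index=False)[["n_meth", "n_unmeth"]
                                                         ].sum()
    total = grp["n_meth"] + grp["n_unmeth"]
    grp = grp[total >= min_cov].reset_index(drop=True)
    grp["level"] = grp["n_meth"] / (grp["n_meth"] + grp["n_unmeth"])
    return grp


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute the full analysis; returns key results and output paths.

    Any stage failure raises a RuntimeError naming the stage.
    """
    logging.basicConfig(level=config.log_level)
    errors = validate_config(config)
    if errors:
        raise RuntimeError("config validation failed: " + "; ".join(errors))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {"outdir": str(outdir)}

    def stage_guard(name):
        class _Guard:
            def __enter__(self):
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}"
                                       ) from exc
                logger.info("stage %s: done", name)

        return _Guard()

    manifest = cio.read_manifest(config.manifest)
    stage_order = config.stage_order or manifest.stage_order

    # --- read, filter, tile per sample -----------------------------------
    sample_tiles: dict[str, dict] = {}
    cpg_frames: dict[str, list[pd.DataFrame]] = {s: [] for s in stage_order}
    cph_means: dict[str, list[pd.DataFrame]] = {s: [] for s in stage_order}
    with stage_guard("tiling"):
        for entry in manifest.entries:
            df = cio.read_coverage_frame(entry.path)
            cpg = df[df["context"] == "CpG"]
            cph = df[df["context"] != "CpG"]
            filtered = filter_sites_frame(cpg, config.tiling.min_site_coverage)
            tiles = build_tiles(filtered, config.tiling)
            sample_tiles[entry.sample_id] = tiles
            cio.write_tiles(tiles, outdir / f"tiles_{entry.sample_id}.tsv")
            cpg_frames[entry.stage].append(filtered)
            cph_means[entry.stage].append(cph)

    # --- pool replicates into stage methylomes ---------------------------
    methylomes: dict[str, StageMethylome] = {}
    with stage_guard("pooling"):
        for stage in stage_order:
            per_sample = {e.sample_id: sample_tiles[e.sample_id]
                          for e in manifest.samples_for(stage)}
            methylomes[stage] = pool_replicates(
                per_sample, stage, config.tiling.level_method)
            cio.write_tiles(methylomes[stage].tiles,
                            outdir / f"tiles_stage_{stage}.tsv")
        globals_ = {s: global_level(m) for s, m in methylomes.items()
                    if len(m)}
        pd.DataFrame(
            {"stage": list(globals_), "global_level": list(globals_.values())}
        ).to_csv(outdir / "global_levels.tsv", sep="\t", index=False)
        results["global_levels"] = globals_

    # --- pairwise comparisons --------------------------------------------
    with stage_guard("comparison"):
        pairs = [(stage_order[i], stage_order[i + 1])
                 for i in range(len(stage_order) - 1)]
        pairs += [tuple(p) for p in config.gamete_pairs
                  if tuple(p) not in pairs]
        comparisons = {}
        for a, b in pairs:
            comp = compare_methylomes(methylomes[a], methylomes[b],
                                      config.comparison)
            comparisons[(a, b)] = comp
            write_comparison(comp, outdir / f"comparison_{a}_vs_{b}.tsv")
            dmrs = call_dmrs(comp, config.comparison)
            write_dmr_bed(dmrs, outdir / f"dmrs_{a}_vs_{b}.bed", a, b)
        results["comparisons"] = comparisons

    # --- common / unique tile sets ---------------------------------------
    with stage_guard("common_unique"):
        common, unique = common_and_unique_sets(
            [methylomes[s] for s in stage_order])
        with open(outdir / "common_tiles.bed", "w") as fh:
            for chrom, start in sorted(common):
                fh.write(f"{chrom}\t{start}\t{start + config.tiling.tile_size}"
                         f"\tcommon\n")
        rows = [(s, len(unique[s])) for s in stage_order]
        pd.DataFrame(rows, columns=["stage", "n_unique_tiles"]).to_csv(
            outdir / "unique_tile_counts.tsv", sep="\t", index=False)
        results["n_common_tiles"] = len(common)
        results["unique_counts"] = {s: len(unique[s]) for s in stage_order}

    # --- feature annotation and profiles ---------------------------------
    features = cio.read_features(config.features) if config.features else None
    genes = (cio.read_gene_models(config.gene_models)
             if config.gene_models else None)
    if features is not None:
        with stage_guard("feature_profile"):
            feats = list(features)
            if genes is not None:
                feats += cio.derive_promoters(genes)
            universe = set()
            for m in methylomes.values():
                universe |= m.keys()
            assignments = assign_features(universe, feats,
                                          config.tiling.tile_size,
                                          config.precedence)
            profile = feature_profile(list(methylomes.values()), assignments)
            profile.to_csv(outdir / "feature_profile.tsv", sep="\t",
                           index=False)
            results["feature_profile"] = profile

    # --- metagene profiles ------------------------------------------------
    if genes is not None:
        with stage_guard("metagene"):
            for stage in stage_order:
                sites = _pool_site_counts(cpg_frames[stage],
                                          config.tiling.min_site_coverage)
                prof = metagene_profile(genes, sites,
                                        flank=config.metagene_flank)
                prof.to_csv(outdir / f"metagene_{stage}.tsv", sep="\t",
                            index=False)

    # --- region summaries --------------------------------------------------
    with stage_guard("regions"):
        regions = []
        if config.chrom_sizes:
            cs = pd.read_csv(config.chrom_sizes, sep="\t")
            regions += [(str(r.chrom), str(r.chrom), 0, int(r.size))
                        for r in cs.itertuples(index=False)]
        if config.regions:
            rg = pd.read_csv(config.regions, sep="\t")
            regions += [(str(r.name), str(r.chrom), int(r.start), int(r.end))
                        for r in rg.itertuples(index=False)]
        if regions:
            tables = [region_summary(methylomes[s], regions)
                      for s in stage_order]
            summary = pd.concat(tables, ignore_index=True)
            summary.to_csv(outdir / "region_summary.tsv", sep="\t",
                           index=False)
            results["region_summary"] = summary

    # --- CpH levels ---------------------------------------------------------
    with stage_guard("cph"):
        rows = []
        for stage in stage_order:
            merged = pd.concat(cph_means[stage], ignore_index=True)
            rows.append((stage, cph_level(merged,
                                          config.tiling.min_site_coverage)))
        cph = pd.DataFrame(rows, columns=["stage", "mean_cph_level"])
        cph.to_csv(outdir / "cph_levels.tsv", sep="\t", index=False)
        results["cph_levels"] = dict(zip(cph["stage"], cph["mean_cph_level"]))

    # --- density relation and replicate correlation -------------------------
    with stage_guard("density"):
        rows = []
        for stage in stage_order:
            table, r_buckets, r_raw = density_methylation_relation(
                methylomes[stage].tiles)
            table.insert(0, "stage", stage)
            rows.append(table)
            results.setdefault("density_r", {})[stage] = r_buckets
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "density_relation.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"stage": list(results["density_r"]),
             "r_buckets": list(results["density_r"].values())}
        ).to_csv(outdir / "density_r.tsv", sep="\t", index=False)

    with stage_guard("replicate_correlation"):
        mat = replicate_correlation(sample_tiles)
        mat.to_csv(outdir / "replicate_correlation.tsv", sep="\t")
        results["replicate_correlation"] = mat

    # --- expression links ----------------------------------------------------
    if genes is not None and config.expression:
        with stage_guard("expression"):
            expr = cio.read_expression(config.expression)
            corr = correlation_table(genes, methylomes, expr,
                                     features=features)
            corr.to_csv(outdir / "meth_expr_correlation.tsv", sep="\t",
                        index=False)
            results["meth_expr_correlation"] = corr
    if config.repeat_transcripts and config.repeat_expression:
        with stage_guard("repeat_expression"):
            tx = cio.read_gene_models(config.repeat_transcripts)
            rexpr = cio.read_expression(config.repeat_expression)
            rsum = repeat_expression(tx, features or [], rexpr)
            rsum.to_csv(outdir / "repeat_expression_summary.tsv", sep="\t",
                        index=False)
            results["repeat_expression"] = rsum

    # --- run log -------------------------------------------------------------
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"config_hash\t{_config_hash(config)}\n")
        fh.write(f"n_samples\t{len(manifest.entries)}\n")
        fh.write(f"stages\t{','.join(stage_order)}\n")
        for name in sorted(p.name for p in outdir.iterdir()
                           if p.name != "run_log.txt"):
            digest = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            fh.write(f"output\t{name}\t{digest[:16]}\n")
    return results
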