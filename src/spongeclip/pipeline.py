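"""End-to-end orchestration: simulate -> call -> regions -> quantify -> scan.

``run_pipeline`` consumes a :class:`PipelineConfig` pointing at annotation,
sequences, a tag table and a miRNA file (real or simulator-written), and
writes the full report bundle atomically: outputs accumulate in a staging
directory and are moved into the output directory only when every stage has
succeeded, so a failed run leaves no partial outputs behind.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from . import __version__
from .binding_regions import (
    regions_for_condition,
    select_condition_specific,
    write_regions_tsv,
)
from .crosslink_calling import (
    CallerConfig,
    call_sites_for_condition,
    count_sites_per_gene,
    merge_replicates,
    write_sites_bed,
)
from .risc_quant import (
    compute_gene_stats,
    rank_by_enrichment,
    replicate_concordance,
    write_gene_stats,
)
from .seed_search import (
    filter_expressed_mirnas,
    load_mirnas,
    map_matches_to_features,
    matches_in_regions,
    seed_density_per_kb,
    write_matches_tsv,
)
from .synthetic_data import CONTROL, read_tags_bed
from .transcript_model import (
    classify_tag_locations,
    load_annotation,
    select_longest_per_gene,
    write_feature_table,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    gtf: Path
    fasta: Path
    tags: Path
    mirnas: Path
    out_dir: Path
    expressed: Path | None = None  # optional expressed-miRNA name list
    caller: CallerConfig = field(default_factory=CallerConfig)
    flank: int = 20
    seed_span: tuple[int, int] = (2, 8)
    pseudocount: float = 0.0
    control_label: str = CONTROL
    treated_label: str = "tgfb4h"


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every analysis stage and return the paths of the written outputs."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    staging = out_dir / "_staging"
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir()
    try:
        outputs = _run_stages(cfg, staging)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    final = {}
    for key, path in outputs.items():
        target = out_dir / path.name
        path.replace(target)
        final[key] = target
    staging.rmdir()
    return final


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def _run_stages(cfg: PipelineConfig, staging: Path) -> dict[str, Path]:
    outputs: dict[str, Path] = {}
    log_lines: list[str] = [f"spongeclip {__version__}"]

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    ts = _stage("load_annotation")(load_annotation, cfg.gtf, cfg.fasta)
    log(f"load_annotation: {len(ts)} transcripts, {len(ts.gene_ids)} genes")
    ts = _stage("select_longest")(select_longest_per_gene, ts)
    log(f"select_longest_per_gene: {len(ts)} transcripts retained")

    tags = _stage("load_tags")(read_tags_bed, cfg.tags)
    log(f"load_tags: {len(tags)} tags, conditions {sorted(tags['condition'].unique())}")

    locations = _stage("classify_tags")(classify_tag_locations, tags, ts)
    outputs["tag_locations"] = staging / "tag_locations.tsv"
    write_feature_table(locations, outputs["tag_locations"])

    concordance = _stage("replicate_concordance")(replicate_concordance, tags, ts)
    pooled = _stage("merge_replicates")(merge_replicates, tags)
    log(f"merge_replicates: {len(pooled)} pooled tags")

    conditions = sorted(pooled["condition"].unique())
    sites_by_cond = {}
    for cond in conditions:
        sites = _stage("call_sites")(call_sites_for_condition, pooled, ts, cfg.caller, cond)
        sites_by_cond[cond] = sites
        outputs[f"sites_{cond}"] = staging / f"sites_{cond}.bed"
        write_sites_bed(sites, outputs[f"sites_{cond}"])
        log(f"call_sites[{cond}]: {len(sites)} crosslink sites")

    control, treated = cfg.control_label, cfg.treated_label
    if treated not in sites_by_cond or control not in sites_by_cond:
        raise StageError(
            f"stage 'pairing' failed: need conditions {control!r} and {treated!r}, "
            f"tag table has {conditions}"
        )
    regions_c = regions_for_condition(sites_by_cond[control], ts, cfg.flank)
    regions_t = regions_for_condition(sites_by_cond[treated], ts, cfg.flank)
    regions_t = _stage("select_specific")(select_condition_specific, regions_t, regions_c)
    n_specific = sum(r.treatment_specific for r in regions_t)
    log(f"binding_regions: {len(regions_c)} control, {len(regions_t)} treated "
        f"({n_specific} treatment-specific)")
    outputs["regions"] = staging / f"regions_{treated}.tsv"
    write_regions_tsv(regions_t, outputs["regions"])

    tags_c = pooled[pooled["condition"] == control]
    tags_t = pooled[pooled["condition"] == treated]
    stats = _stage("gene_stats")(
        compute_gene_stats, tags_c, tags_t, regions_c, regions_t,
        sites_by_cond[control], sites_by_cond[treated], ts, cfg.pseudocount,
    )
    ranked = rank_by_enrichment(stats)
    outputs["gene_stats"] = staging / "gene_stats.tsv"
    write_gene_stats(ranked, outputs["gene_stats"])
    log(f"gene_stats: {len(ranked)} genes ranked by fold enrichment")

    mirnas = _stage("load_mirnas")(load_mirnas, cfg.mirnas, cfg.seed_span)
    if cfg.expressed is not None:
        expressed = [l.strip() for l in Path(cfg.expressed).read_text().splitlines() if l.strip()]
        mirnas = filter_expressed_mirnas(mirnas, expressed)
    log(f"load_mirnas: {len(mirnas)} seed records")
    specific = [r for r in regions_t if r.treatment_specific]
    matches = _stage("seed_scan")(matches_in_regions, mirnas, specific, ts)
    log(f"seed_scan: {len(matches)} seed matches in {len(specific)} specific regions")
    outputs["seed_matches"] = staging / "seed_matches.tsv"
    write_matches_tsv(matches, outputs["seed_matches"])

    report = map_matches_to_features(matches, ts)
    outputs["feature_report"] = staging / "seed_feature_report.tsv"
    report.to_csv(outputs["feature_report"], sep="\t", index=False)

    density = seed_density_per_kb(matches, ts)
    outputs["density_ranking"] = staging / "seed_density_ranking.tsv"
    density.to_csv(outputs["density_ranking"], sep="\t", index=False, float_format="%.6g")
    log(f"seed_density: top transcript {density.iloc[0]['transcript_id']} "
        f"({density.iloc[0]['density_per_kb']:.3g} matches/kb)")

    for cond, mat in sorted(concordance.items()):
        if not mat.empty:
            vals = mat.to_numpy()[~(mat.to_numpy() == 1.0)]
            log(f"replicate_concordance[{cond}]: min pairwise r = {mat.min().min():.3f}"
                if len(vals) else f"replicate_concordance[{cond}]: single replicate")

    outputs["run_log"] = staging / "run_log.txt"
    with open(outputs["run_log"], "w") as fh:
        fh.write(f"config: {cfg}\n")
        fh.write("\n".join(log_lines) + "\n")
    return outputs
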