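"""Per-gene RISC-association quantification.

Tags falling inside a gene's binding regions are counted (each tag once,
however many overlapping regions contain it), normalised to RPKM — reads per
kilobase of the gene's transcript per million mapped tags of the condition —
and treated/control RPKM ratios give the fold enrichment used to rank
candidate sponge transcripts. Genes with zero control signal are flagged
treated-only instead of being assigned an infinite ratio (a pseudocount can
be requested to force a ratio).
"""

from __future__ import annotations

import itertools
import math
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .binding_regions import BindingRegion
from .crosslink_calling import CrosslinkSite
from .transcript_model import TranscriptSet


def count_tags_in_regions(
    tags: pd.DataFrame, regions: list[BindingRegion], ts: TranscriptSet
) -> pd.Series:
    """Per-gene counts of tags whose truncation position lies in any of the
    gene's binding regions (half-open; multiply-covered tags count once)."""
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.transcript_id, IntervalTree()).addi(r.start, r.end)
    counts = pd.Series(0, index=pd.Index(ts.gene_ids, name="gene_id"), dtype=int)
    for tid, group in tags.groupby("transcript_id"):
        tree = trees.get(tid)
        if tree is None:
            continue
        gene = ts.gene_of(tid)
        counts[gene] += int(sum(bool(tree[pos]) for pos in group["position"]))
    return counts


def rpkm(count: int, transcript_length: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped tags."""
    if transcript_length <= 0:
        raise ValueError("transcript_length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count / (transcript_length / 1000) / (total_mapped / 1e6)


def fold_enrichment(
    rpkm_control: float, rpkm_treated: float, pseudocount: float = 0.0
) -> float | None:
    """Treated/control RPKM ratio; ``None`` (treated-only) when the control
    RPKM is zero and no pseudocount is given."""
    denom = rpkm_control + pseudocount
    if denom == 0:
        return None
    return (rpkm_treated + pseudocount) / denom


def compute_gene_stats(
    tags_control: pd.DataFrame,
    tags_treated: pd.DataFrame,
    regions_control: list[BindingRegion],
    regions_treated: list[BindingRegion],
    sites_control: list[CrosslinkSite],
    sites_treated: list[CrosslinkSite],
    ts: TranscriptSet,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Assemble the per-gene report: in-region reads, RPKM per condition,
    fold enrichment and crosslink-site counts."""
    total_control = len(tags_control)
    total_treated = len(tags_treated)
    reads_c = count_tags_in_regions(tags_control, regions_control, ts)
    reads_t = count_tags_in_regions(tags_treated, regions_treated, ts)
    lengths = pd.Series(
        {g: max(t.length for t in ts.transcripts_of_gene(g)) for g in ts.gene_ids}
    )
    site_counts_c = _sites_per_gene(sites_control, ts)
    site_counts_t = _sites_per_gene(sites_treated, ts)

    rows = []
    for gene in ts.gene_ids:
        rc = rpkm(int(reads_c[gene]), int(lengths[gene]), total_control) if total_control else 0.0
        rt = rpkm(int(reads_t[gene]), int(lengths[gene]), total_treated) if total_treated else 0.0
        enr = fold_enrichment(rc, rt, pseudocount)
        rows.append(
            {
                "gene_id": gene,
                "reads_control": int(reads_c[gene]),
                "rpkm_control": rc,
                "reads_treated": int(reads_t[gene]),
                "rpkm_treated": rt,
                "enrichment": math.nan if enr is None else enr,
                "enrichment_2dp": math.nan if enr is None else round(enr, 2),
                "treated_only": enr is None and rt > 0,
                "sites_control": int(site_counts_c[gene]),
                "sites_treated": int(site_counts_t[gene]),
            }
        )
    return pd.DataFrame(rows)


def _sites_per_gene(sites: list[CrosslinkSite], ts: TranscriptSet) -> pd.Series:
    counts = pd.Series(0, index=pd.Index(ts.gene_ids, name="gene_id"), dtype=int)
    for s in sites:
        counts[ts.gene_of(s.transcript_id)] += 1
    return counts


def rank_by_enrichment(stats: pd.DataFrame) -> pd.DataFrame:
    """Descending fold-enrichment ranking, gene_id breaking ties; treated-only
    genes (undefined ratio, nonzero treated RPKM) listed separately at the
    top, ordered by their treated RPKM."""
    treated_only = stats[stats["treated_only"]].sort_values(
        ["rpkm_treated", "gene_id"], ascending=[False, True]
    )
    ranked = stats[~stats["treated_only"] & stats["enrichment"].notna()].sort_values(
        ["enrichment", "gene_id"], ascending=[False, True]
    )
    silent = stats[~stats["treated_only"] & stats["enrichment"].isna()].sort_values("gene_id")
    return pd.concat([treated_only, ranked, silent], ignore_index=True)


def replicate_concordance(tags: pd.DataFrame, ts: TranscriptSet) -> dict[str, pd.DataFrame]:
    """Pearson correlation of log-transformed per-gene replicate counts for
    every replicate pair within each condition.

    A condition with a single replicate yields an empty matrix; a replicate
    with zero tags yields NaN for its pairs.
    """
    gene_of = {t.transcript_id: t.gene_id for t in ts}
    out: dict[str, pd.DataFrame] = {}
    for cond, cond_tags in tags.groupby("condition"):
        reps = sorted(cond_tags["replicate"].unique())
        if len(reps) < 2:
            out[cond] = pd.DataFrame()
            continue
        counts = (
            cond_tags.assign(gene_id=cond_tags["transcript_id"].map(gene_of))
            .groupby(["gene_id", "replicate"])
            .size()
            .unstack(fill_value=0)
            .reindex(index=ts.gene_ids, columns=reps, fill_value=0)
        )
        logged = np.log2(counts + 1)
        mat = pd.DataFrame(np.eye(len(reps)), index=reps, columns=reps)
        for r1, r2 in itertools.combinations(reps, 2):
            x, y = logged[r1].to_numpy(), logged[r2].to_numpy()
            if x.sum() == 0 or y.sum() == 0 or x.std() == 0 or y.std() == 0:
                rho = np.nan
            else:
                rho = float(np.corrcoef(x, y)[0, 1])
            mat.loc[r1, r2] = mat.loc[r2, r1] = rho
        out[cond] = mat
    return out


def write_gene_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, sep="\t", index=False, float_format="%.6g")
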