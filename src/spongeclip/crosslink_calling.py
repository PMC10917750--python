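"""Crosslink-site calling from truncation pileups.

Replicates of a condition are pooled first, then per-transcript truncation
pileups are thresholded: a position is a crosslink site iff its pooled
truncation count reaches ``min_count`` (default 4, the minimum-evidence
convention for point-like iCLIP sites) and it is a local maximum within
``merge_distance`` nucleotides, ties resolved toward the smaller coordinate.
This is a deliberately simple, fully specified caller — no HMM, no
covariates — whose behaviour is checkable against brute-force enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .transcript_model import TranscriptModel, TranscriptSet


@dataclass(frozen=True)
class CrosslinkSite:
    transcript_id: str
    position: int
    score: int  # pooled truncation count
    condition: str


@dataclass(frozen=True)
class CallerConfig:
    min_count: int = 4
    merge_distance: int = 8

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.merge_distance < 0:
            raise ValueError("merge_distance must be >= 0")


def merge_replicates(tags: pd.DataFrame) -> pd.DataFrame:
    """Pool replicates per condition: drop the replicate label, keep every tag."""
    return tags[["transcript_id", "position", "condition"]].reset_index(drop=True)


def pileup_truncations(tags: pd.DataFrame, t: TranscriptModel) -> np.ndarray:
    """Per-position truncation counts for one transcript's pooled tags."""
    positions = tags.loc[tags["transcript_id"] == t.transcript_id, "position"].to_numpy()
    if len(positions) and (positions.min() < 0 or positions.max() >= t.length):
        raise ValueError(
            f"tag positions outside [0, {t.length}) on {t.transcript_id}"
        )
    return np.bincount(positions, minlength=t.length)[: t.length]


def call_crosslink_sites(
    pileup: np.ndarray,
    cfg: CallerConfig,
    transcript_id: str = "",
    condition: str = "",
) -> list[CrosslinkSite]:
    """Threshold + local-maximum site calling.

    Position ``p`` is a site iff ``pileup[p] >= min_count`` and no position in
    ``[p - merge_distance, p + merge_distance]`` beats it: strictly greater
    anywhere suppresses ``p``, and an equal count at a smaller coordinate
    suppresses ``p`` (so of two tied peaks within range only the left one is
    called). Output is sorted by position.
    """
    d = cfg.merge_distance
    sites = []
    for p in np.flatnonzero(pileup >= cfg.min_count):
        lo, hi = max(0, p - d), min(len(pileup), p + d + 1)
        c = pileup[p]
        left_ok = p == lo or pileup[lo:p].max() < c
        right_ok = p + 1 == hi or pileup[p + 1 : hi].max() <= c
        if left_ok and right_ok:
            sites.append(
                CrosslinkSite(
                    transcript_id=transcript_id,
                    position=int(p),
                    score=int(c),
                    condition=condition,
                )
            )
    return sites


def call_sites_for_condition(
    pooled_tags: pd.DataFrame, ts: TranscriptSet, cfg: CallerConfig, condition: str
) -> list[CrosslinkSite]:
    """Call sites on every transcript for one condition's pooled tags."""
    cond_tags = pooled_tags[pooled_tags["condition"] == condition]
    sites: list[CrosslinkSite] = []
    for t in sorted(ts, key=lambda t: t.transcript_id):
        pileup = pileup_truncations(cond_tags, t)
        sites.extend(call_crosslink_sites(pileup, cfg, t.transcript_id, condition))
    return sites


def count_sites_per_gene(
    sites_by_condition: dict[str, list[CrosslinkSite]], ts: TranscriptSet
) -> pd.DataFrame:
    """Gene x condition table of crosslink-site counts (0 for siteless genes)."""
    conditions = list(sites_by_condition)
    table = pd.DataFrame(0, index=pd.Index(ts.gene_ids, name="gene_id"), columns=conditions)
    for cond, sites in sites_by_condition.items():
        for site in sites:
            table.loc[ts.gene_of(site.transcript_id), cond] += 1
    return table


def write_sites_bed(sites: list[CrosslinkSite], path: str | Path) -> None:
    """Sites as BED6 (single-nucleotide intervals, score = truncation count)."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites, start=1):
            fh.write(
                f"{s.transcript_id}\t{s.position}\t{s.position + 1}"
                f"\tsite_{i}\t{s.score}\t+\n"
            )
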