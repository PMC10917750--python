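"""Binding regions: 40-bp windows around crosslink sites and their
treatment-specific subset.

A site at position p widens to the half-open window [p - 20, p + 20),
clipped at transcript edges — 40 bp, containing the site, asymmetric by one
base on the right. Regions are kept individually (no merging). A treated
region is treatment-specific iff it shares no position with any control
region on the same transcript; abutting half-open intervals do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from .crosslink_calling import CrosslinkSite
from .transcript_model import TranscriptModel, TranscriptSet


@dataclass(frozen=True)
class BindingRegion:
    transcript_id: str
    start: int
    end: int  # half-open
    center_site: int
    condition: str
    treatment_specific: bool = False

    @property
    def name(self) -> str:
        return f"region_{self.transcript_id}_{self.center_site}_{self.condition}"


def extend_to_regions(
    sites: list[CrosslinkSite], t: TranscriptModel, flank: int = 20
) -> list[BindingRegion]:
    """Widen each site to ``[max(0, p - flank), min(length, p + flank))``."""
    regions = []
    for s in sites:
        if s.transcript_id != t.transcript_id:
            raise ValueError(f"site on {s.transcript_id}, transcript is {t.transcript_id}")
        if not 0 <= s.position < t.length:
            raise ValueError(f"site position {s.position} outside [0, {t.length})")
        regions.append(
            BindingRegion(
                transcript_id=t.transcript_id,
                start=max(0, s.position - flank),
                end=min(t.length, s.position + flank),
                center_site=s.position,
                condition=s.condition,
            )
        )
    return regions


def regions_for_condition(
    sites: list[CrosslinkSite], ts: TranscriptSet, flank: int = 20
) -> list[BindingRegion]:
    by_tid: dict[str, list[CrosslinkSite]] = {}
    for s in sites:
        by_tid.setdefault(s.transcript_id, []).append(s)
    regions: list[BindingRegion] = []
    for tid in sorted(by_tid):
        regions.extend(extend_to_regions(by_tid[tid], ts[tid], flank))
    return regions


def select_condition_specific(
    treated: list[BindingRegion], control: list[BindingRegion]
) -> list[BindingRegion]:
    """Flag each treated region treatment-specific iff it overlaps no control
    region on the same transcript. All treated regions are returned."""
    trees: dict[str, IntervalTree] = {}
    for r in control:
        trees.setdefault(r.transcript_id, IntervalTree()).addi(r.start, r.end)
    return [
        replace(
            r,
            treatment_specific=not (
                r.transcript_id in trees and trees[r.transcript_id].overlap(r.start, r.end)
            ),
        )
        for r in treated
    ]


def extract_region_sequences(
    regions: list[BindingRegion], ts: TranscriptSet
) -> list[SeqRecord]:
    """The exact substring [start, end) of each region's transcript sequence."""
    records = []
    for r in regions:
        t = ts[r.transcript_id]
        if not (0 <= r.start < r.end <= t.length):
            raise ValueError(f"region {r.name} outside transcript bounds")
        records.append(
            SeqRecord(
                Seq(t.sequence[r.start : r.end]),
                id=f"{r.transcript_id}:{r.start}-{r.end}",
                description=r.name,
            )
        )
    return records


def write_regions_tsv(regions: list[BindingRegion], path: str | Path) -> None:
    """BED6 + a 7th 0/1 column for the treatment-specific flag."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.transcript_id}\t{r.start}\t{r.end}\t{r.name}\t0\t+"
                f"\t{int(r.treatment_specific)}\n"
            )
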