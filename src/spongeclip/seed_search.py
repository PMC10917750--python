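"""miRNA seed extraction and seed-match scanning.

The seed of a mature miRNA is nucleotides 2-8 (a 7-mer; a 2-7 hexamer span
is available as an option). A RISC-bound target presents the seed's reverse
complement on the transcript strand, so that DNA pattern is what is scanned
for — exact matching, every occurrence reported including overlapping ones.
Matches are mapped to transcript features (5'UTR / CDS exon / 3'UTR, by
match start) and aggregated per miRNA, and transcripts are ranked by seed
matches per kilobase.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .binding_regions import BindingRegion
from .transcript_model import (
    FEATURE_3UTR,
    FEATURE_5UTR,
    TranscriptSet,
    feature_of_position,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedRecord:
    mirna_name: str
    mature_sequence: str  # RNA alphabet
    seed: str  # RNA alphabet, mature positions 2-8 by default
    match_pattern: str  # DNA reverse complement of the seed

    @classmethod
    def from_mature(
        cls, name: str, mature: str, seed_span: tuple[int, int] = (2, 8)
    ) -> "SeedRecord":
        rna = mature.strip().upper().replace("T", "U")
        if not set(rna) <= set("ACGU"):
            raise ValueError(f"{name}: non-nucleotide characters in mature sequence")
        lo, hi = seed_span
        if len(rna) < hi:
            raise ValueError(f"{name}: mature sequence shorter than {hi} nt")
        seed = rna[lo - 1 : hi]
        pattern = str(Seq(seed.replace("U", "T")).reverse_complement())
        return cls(mirna_name=name, mature_sequence=rna, seed=seed, match_pattern=pattern)


@dataclass(frozen=True)
class SeedMatch:
    mirna_name: str
    transcript_id: str
    position: int  # transcript coordinate of the match start
    feature: str
    exon: int
    region_id: str | None = None  # containing binding region, if scanned per region


def load_mirnas(path: str | Path, seed_span: tuple[int, int] = (2, 8)) -> list[SeedRecord]:
    """Read mature miRNAs from a FASTA or a 2-column name/sequence TSV.

    Sequences shorter than the seed span's end are skipped with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    entries: list[tuple[str, str]]
    if first.startswith(">"):
        entries = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["name", "mature"])
        entries = list(df.itertuples(index=False, name=None))
    records, skipped = [], 0
    for name, mature in entries:
        try:
            records.append(SeedRecord.from_mature(name, str(mature), seed_span))
        except ValueError as exc:
            skipped += 1
            logger.warning("skipping %s: %s", name, exc)
    if skipped:
        logger.warning("skipped %d miRNA(s) with unusable mature sequences", skipped)
    return records


def filter_expressed_mirnas(
    records: list[SeedRecord], expressed: Iterable[str]
) -> list[SeedRecord]:
    """Keep only miRNAs named in the expressed list (e.g. from a cell-line
    expression atlas); an empty intersection is a warning, not an error."""
    names = set(expressed)
    kept = [r for r in records if r.mirna_name in names]
    if not kept:
        logger.warning("no miRNA in the expressed list matched any record")
    return kept


def scan_sequences(
    patterns: Sequence[SeedRecord], targets: Sequence[tuple[str, str]]
) -> list[tuple[str, int, str]]:
    """Every exact occurrence of every match pattern in every target.

    Overlapping occurrences are all reported. Output is sorted by
    (target_id, position, mirna_name) and therefore deterministic.
    """
    hits = []
    for target_id, seq in targets:
        seq = seq.upper()
        for rec in patterns:
            for m in re.finditer(f"(?={re.escape(rec.match_pattern)})", seq):
                hits.append((target_id, m.start(), rec.mirna_name))
    hits.sort()
    return hits


def matches_in_regions(
    patterns: Sequence[SeedRecord], regions: list[BindingRegion], ts: TranscriptSet
) -> list[SeedMatch]:
    """Scan binding-region subsequences; match positions are reported in
    transcript coordinates (region offset added back)."""
    targets = [
        (r.name, ts[r.transcript_id].sequence[r.start : r.end]) for r in regions
    ]
    by_name = {r.name: r for r in regions}
    matches = []
    for region_id, local_pos, mirna in scan_sequences(patterns, targets):
        region = by_name[region_id]
        pos = region.start + local_pos
        feature, exon = feature_of_position(ts[region.transcript_id], pos)
        matches.append(
            SeedMatch(mirna, region.transcript_id, pos, feature, exon, region_id)
        )
    matches.sort(key=lambda m: (m.transcript_id, m.position, m.mirna_name))
    return matches


def matches_in_transcripts(
    patterns: Sequence[SeedRecord], ts: TranscriptSet
) -> list[SeedMatch]:
    targets = [(t.transcript_id, t.sequence) for t in sorted(ts, key=lambda t: t.transcript_id)]
    matches = []
    for tid, pos, mirna in scan_sequences(patterns, targets):
        feature, exon = feature_of_position(ts[tid], pos)
        matches.append(SeedMatch(mirna, tid, pos, feature, exon, None))
    return matches


def _feature_display(match: SeedMatch) -> str:
    if match.feature == FEATURE_5UTR:
        return "5'UTR"
    if match.feature == FEATURE_3UTR:
        return "3'UTR"
    return f"Exon {match.exon}"


def map_matches_to_features(
    matches: list[SeedMatch], ts: TranscriptSet
) -> pd.DataFrame:
    """Aggregate matches per miRNA per transcript into a feature-location
    report, e.g. ``Exon 3 (1), 3'UTR (2)`` (a single match omits the count)."""
    rows: dict[tuple[str, str], list[SeedMatch]] = {}
    for m in matches:
        rows.setdefault((m.mirna_name, m.transcript_id), []).append(m)
    out = []
    for (mirna, tid), ms in sorted(rows.items()):
        labels = [_feature_display(m) for m in ms]
        ordered = sorted(set(labels), key=_label_sort_key)
        if len(ms) == 1:
            location = labels[0]
        else:
            location = ", ".join(f"{lab} ({labels.count(lab)})" for lab in ordered)
        out.append(
            {"mirna_name": mirna, "transcript_id": tid,
             "gene_name": ts[tid].gene_name, "n_matches": len(ms), "location": location}
        )
    return pd.DataFrame(
        out, columns=["mirna_name", "transcript_id", "gene_name", "n_matches", "location"]
    )


def _label_sort_key(label: str) -> tuple[int, int]:
    if label == "5'UTR":
        return (0, 0)
    if label.startswith("Exon"):
        return (1, int(label.split()[1]))
    return (2, 0)


def seed_density_per_kb(
    matches: list[SeedMatch],
    ts: TranscriptSet,
    mirnas: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Rank transcripts by seed matches per kilobase of transcript, descending
    (ties by gene_id); transcripts with no matches rank last with density 0."""
    names = set(mirnas) if mirnas is not None else None
    counts: dict[str, int] = {t.transcript_id: 0 for t in ts}
    for m in matches:
        if names is None or m.mirna_name in names:
            counts[m.transcript_id] += 1
    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "n_matches": counts[t.transcript_id],
            "length": t.length,
            "density_per_kb": counts[t.transcript_id] / (t.length / 1000),
        }
        for t in ts
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["density_per_kb", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)


def write_matches_tsv(matches: list[SeedMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\ttranscript\tposition\tfeature\texon\tregion_id\n")
        for m in matches:
            fh.write(
                f"{m.mirna_name}\t{m.transcript_id}\t{m.position}\t{m.feature}"
                f"\t{m.exon}\t{m.region_id or '.'}\n"
            )
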