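"""Transcript-space models of a transcriptome.

Everything downstream of alignment works in *transcript coordinates*:
0-based, half-open, one coordinate system per transcript. A transcript is
a tiling of exons over ``[0, length)`` plus a CDS interval
``[cds_start, cds_end)``; positions before the CDS are 5'UTR, positions at
or after ``cds_end`` are 3'UTR. Non-coding transcripts use the sentinel
``cds_start == cds_end == length`` and every position is labelled ``exon``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

FEATURE_5UTR = "5UTR"
FEATURE_CDS = "CDS"
FEATURE_3UTR = "3UTR"
FEATURE_EXON = "exon"  # non-coding transcripts: no UTR/CDS split


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript with its exon structure, CDS bounds and sequence."""

    transcript_id: str
    gene_id: str
    gene_name: str
    length: int
    exon_bounds: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.transcript_id}: non-positive length")
        if len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= annotated length {self.length}"
            )
        prev = 0
        for start, end in self.exon_bounds:
            if start != prev or end <= start:
                raise ValueError(
                    f"{self.transcript_id}: exons must tile [0, length) "
                    f"without gaps or overlaps, got {self.exon_bounds}"
                )
            prev = end
        if prev != self.length:
            raise ValueError(
                f"{self.transcript_id}: exons end at {prev}, length is {self.length}"
            )
        if self.is_coding:
            if not (0 <= self.cds_start < self.cds_end <= self.length):
                raise ValueError(f"{self.transcript_id}: invalid CDS bounds")
        elif not (self.cds_start == self.cds_end == self.length):
            raise ValueError(
                f"{self.transcript_id}: non-coding sentinel is "
                "cds_start == cds_end == length"
            )

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    def exon_index_of(self, pos: int) -> int:
        """1-based index of the exon containing ``pos``."""
        for i, (start, end) in enumerate(self.exon_bounds, start=1):
            if start <= pos < end:
                return i
        raise ValueError(f"position {pos} outside [0, {self.length})")


def feature_of_position(t: TranscriptModel, pos: int) -> tuple[str, int]:
    """Map a transcript position to its feature label and 1-based exon index.

    Half-open CDS: ``pos == cds_end`` is already 3'UTR. Non-coding
    transcripts yield the ``exon`` label for every position.
    """
    if not 0 <= pos < t.length:
        raise ValueError(
            f"position {pos} out of range [0, {t.length}) on {t.transcript_id}"
        )
    exon = t.exon_index_of(pos)
    if not t.is_coding:
        return FEATURE_EXON, exon
    if pos < t.cds_start:
        return FEATURE_5UTR, exon
    if pos >= t.cds_end:
        return FEATURE_3UTR, exon
    return FEATURE_CDS, exon


@dataclass
class TranscriptSet:
    """A collection of transcripts with a gene index."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._gene_index: dict[str, list[str]] = {}
        for tid, t in self.transcripts.items():
            if tid != t.transcript_id:
                raise ValueError(f"key {tid} != transcript_id {t.transcript_id}")
            self._gene_index.setdefault(t.gene_id, []).append(tid)

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptModel]) -> "TranscriptSet":
        models = list(transcripts)
        ids = [t.transcript_id for t in models]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript_ids")
        return cls({t.transcript_id: t for t in models})

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self._gene_index)

    def transcripts_of_gene(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[tid] for tid in self._gene_index[gene_id]]

    def gene_of(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].gene_id


def select_longest_per_gene(ts: TranscriptSet) -> TranscriptSet:
    """Keep the single longest isoform per gene.

    Length ties break to the lexicographically smallest transcript_id, so
    the filter is deterministic and idempotent.
    """
    if len(ts) == 0:
        raise ValueError("empty TranscriptSet")
    kept: list[TranscriptModel] = []
    for gene_id in ts.gene_ids:
        isoforms = ts.transcripts_of_gene(gene_id)
        kept.append(max(isoforms, key=lambda t: (t.length, _NegStr(t.transcript_id))))
    return TranscriptSet.from_transcripts(kept)


class _NegStr(str):
    """Inverts string ordering so max() prefers the smallest transcript_id on ties."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def load_annotation(gtf_path: str | Path, fasta_path: str | Path) -> TranscriptSet:
    """Load a transcript-space GTF plus a transcript FASTA into a TranscriptSet.

    The GTF's seqname column holds the transcript_id (transcripts are the
    coordinate system); exon rows define the tiling and CDS rows the coding
    interval. Every annotated transcript must have a FASTA sequence.
    """
    gtf_path, fasta_path = Path(gtf_path), Path(fasta_path)
    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes["gene_id"][0]
        gene_name = feat.attributes.get("gene_name", [gene_id])[0]
        meta[tid] = (gene_id, gene_name)
        interval = (feat.start - 1, feat.end)  # GTF is 1-based closed
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(interval)

    models = []
    for tid in sorted(meta):
        if tid not in sequences:
            raise ValueError(f"transcript {tid} annotated in GTF but absent from FASTA")
        gene_id, gene_name = meta[tid]
        exon_bounds = tuple(sorted(exons.get(tid, [])))
        length = exon_bounds[-1][1] if exon_bounds else 0
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        else:
            cds_start = cds_end = length
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                gene_name=gene_name,
                length=length,
                exon_bounds=exon_bounds,
                cds_start=cds_start,
                cds_end=cds_end,
                sequence=sequences[tid],
            )
        )
    return TranscriptSet.from_transcripts(models)


def _validate_gtf_lines(gtf_path: Path) -> None:
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise ValueError(f"malformed GTF line {lineno} in {gtf_path}")


def write_annotation(ts: TranscriptSet, gtf_path: str | Path, fasta_path: str | Path) -> None:
    """Write the transcript-space GTF and FASTA that :func:`load_annotation` reads."""
    with open(gtf_path, "w") as gtf:
        for t in sorted(ts, key=lambda t: t.transcript_id):
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_name "{t.gene_name}";'
            )
            for start, end in t.exon_bounds:
                gtf.write(
                    f"{t.transcript_id}\tspongeclip\texon\t{start + 1}\t{end}\t.\t+\t.\t{attrs}\n"
                )
            if t.is_coding:
                gtf.write(
                    f"{t.transcript_id}\tspongeclip\tCDS\t{t.cds_start + 1}\t{t.cds_end}"
                    f"\t.\t+\t0\t{attrs}\n"
                )
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in sorted(ts, key=lambda t: t.transcript_id)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


# ---------------------------------------------------------------------------
# Tag-location classification (exonic feature composition of iCLIP tags)
# ---------------------------------------------------------------------------

def classify_tag_locations(tags: pd.DataFrame, ts: TranscriptSet) -> pd.DataFrame:
    """Classify truncation tags into transcript features (5'UTR / CDS / 3'UTR).

    Returns a table with columns ``category``, ``count`` and ``fraction``
    (fractions sum to 1). An empty tag table yields an empty table so sparse
    conditions do not abort a pipeline run.
    """
    columns = ["category", "count", "fraction"]
    if len(tags) == 0:
        return pd.DataFrame(columns=columns)
    unknown = set(tags["transcript_id"]) - set(ts.transcripts)
    if unknown:
        raise KeyError(f"tags reference unknown transcripts: {sorted(unknown)[:5]}")
    labels = [
        feature_of_position(ts[tid], pos)[0]
        for tid, pos in zip(tags["transcript_id"], tags["position"])
    ]
    counts = pd.Series(labels).value_counts()
    order = [c for c in (FEATURE_5UTR, FEATURE_CDS, FEATURE_3UTR, FEATURE_EXON) if c in counts]
    out = pd.DataFrame(
        {
            "category": order,
            "count": [int(counts[c]) for c in order],
        }
    )
    out["fraction"] = out["count"] / out["count"].sum()
    return out


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def transcript_feature_lengths(t: TranscriptModel) -> Mapping[str, int]:
    """Total length of each feature class; values sum to the transcript length."""
    if not t.is_coding:
        return {FEATURE_EXON: t.length}
    return {
        FEATURE_5UTR: t.cds_start,
        FEATURE_CDS: t.cds_end - t.cds_start,
        FEATURE_3UTR: t.length - t.cds_end,
    }
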