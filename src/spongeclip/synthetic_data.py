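"""Synthetic transcriptomes and iCLIP truncation tags with known ground truth.

The generator emulates the structure of an AGO2 iCLIP experiment over a TGF-β
EMT time course: three replicates per condition, truncation tags concentrated
at crosslink sites over a low uniform background, one designated "sponge"
transcript whose RISC association is multiplicatively enriched under
treatment and which carries planted miRNA seed-match sites (the reverse
complement of each miRNA's seed written into the sequence). Background
sequence is rejection-sampled so no planted pattern occurs anywhere outside
its ground-truth positions, which makes recovery tests exact.

Counts are Poisson: the truncation count at a planted site is
``Poisson(peak_height)`` per replicate (per active condition) and each
background position contributes ``Poisson(background_rate)`` per replicate.
The sponge transcript's treated-condition expectations (sites and background
alike) are scaled by ``sponge_enrichment``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .transcript_model import (
    TranscriptModel,
    TranscriptSet,
    feature_of_position,
)

CONTROL = "control"
TGFB4H = "tgfb4h"
TGFB48H = "tgfb48h"
CONDITIONS = (CONTROL, TGFB4H, TGFB48H)

_MAX_REJECTION_ATTEMPTS = 1000
TAG_COLUMNS = ["transcript_id", "position", "condition", "replicate"]


@dataclass(frozen=True)
class PlantedSite:
    """A crosslink site planted at a fixed position, active in some conditions."""

    position: int
    conditions: tuple[str, ...]
    peak_height: float


@dataclass(frozen=True)
class PlantedSeed:
    """A miRNA whose seed match pattern is written into the sponge sequence."""

    mirna_name: str
    mature_sequence: str  # RNA alphabet
    insertions: tuple[int, ...]  # transcript positions of the 7-nt pattern


@dataclass
class SimulationConfig:
    n_genes: int = 20
    length_range: tuple[int, int] = (1000, 4000)
    sponge_gene: str = "gene01"
    planted_sites: dict[str, tuple[PlantedSite, ...]] = field(default_factory=dict)
    planted_seeds: tuple[PlantedSeed, ...] = ()
    background_rate: float = 0.005  # expected truncations / nt / replicate
    sponge_enrichment: float = 10.0
    n_replicates: int = 3
    conditions: tuple[str, ...] = (CONTROL, TGFB4H)
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if self.background_rate < 0 or self.sponge_enrichment <= 0:
            raise ValueError("rates must be positive")
        if self.n_replicates < 1 or self.n_genes < 1:
            raise ValueError("n_replicates and n_genes must be >= 1")
        for cond in self.conditions:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
        spans = sorted(
            (pos, pos + len(_seed_pattern(s.mature_sequence)))
            for s in self.planted_seeds
            for pos in s.insertions
        )
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("planted seed insertions overlap")

    @property
    def treated_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c != CONTROL)


@dataclass
class GroundTruth:
    """What was planted: site positions, seed matches and expected tag totals."""

    # (transcript_id, condition) -> sorted site positions
    sites: dict[tuple[str, str], tuple[int, ...]]
    # rows: mirna_name, transcript_id, position, feature, exon
    seed_matches: pd.DataFrame
    # (gene_id, condition) -> expected pooled tag total
    expected_totals: dict[tuple[str, str], float]


def _revcomp_dna(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _seed_pattern(mature_rna: str, span: tuple[int, int] = (2, 8)) -> str:
    """DNA match pattern (reverse complement of the seed) of a mature miRNA."""
    seed = mature_rna.upper().replace("T", "U")[span[0] - 1 : span[1]]
    return _revcomp_dna(seed.replace("U", "T"))


def default_config(rng_seed: int = 1) -> SimulationConfig:
    """The study-emulating default: 20 genes, 3 replicates x 2 conditions.

    The sponge (gene01/tx01, 3000 nt, CDS [150, 2300), 9 exons) carries 2
    sites active in both conditions and 32 treated-only sites (site counts
    2 control / 34 treated), a 10-fold treated-condition enrichment, and two
    planted miRNAs: one with matches in exon 3 of the CDS plus two in the
    3'UTR, one with a single 3'UTR match. Every other gene carries 3 sites
    shared between conditions (fold enrichment ~1), and gene02 additionally
    two treated-only sites, so specificity selection is non-trivial while the
    sponge still dominates both rankings.
    """
    site_positions = tuple(100 + 80 * i for i in range(34))  # 100 .. 2740
    shared = {site_positions[6], site_positions[31]}  # 580 (CDS), 2580 (3'UTR)
    sponge_sites = tuple(
        PlantedSite(
            position=p,
            conditions=(CONTROL, TGFB4H) if p in shared else (TGFB4H,),
            peak_height=10.0,
        )
        for p in site_positions
    )
    planted: dict[str, tuple[PlantedSite, ...]] = {"tx01": sponge_sites}
    # per-gene occupancy spans an order of magnitude, as in real RISC maps;
    # without between-gene dynamic range replicate correlations are undefined
    heights = (4.0, 8.0, 15.0, 30.0, 60.0)
    for i in range(2, 21):
        h = heights[i % len(heights)]
        # positions valid for any length >= 1000 (length_range minimum)
        sites = [PlantedSite(p, (CONTROL, TGFB4H), h) for p in (150, 500, 850)]
        if i == 2:
            sites += [PlantedSite(p, (TGFB4H,), h) for p in (300, 700)]
        planted[f"tx{i:02d}"] = tuple(sorted(sites, key=lambda s: s.position))
    seeds = (
        # mirrors a sponge architecture of one CDS (exon 3) + two 3'UTR sites
        PlantedSeed("miR-syn-1", "UCAGUGCAAUGUUAAAAGGGCAU", insertions=(662, 2422, 2742)),
        PlantedSeed("miR-syn-2", "UGGAGUGUGACAAUGGUGUUUG", insertions=(2502,)),
    )
    return SimulationConfig(
        planted_sites=planted,
        planted_seeds=seeds,
        rng_seed=rng_seed,
    )


_SPONGE_EXONS = ((0, 200), (200, 500), (500, 900), (900, 1300), (1300, 1700),
                 (1700, 2000), (2000, 2200), (2200, 2500), (2500, 3000))
_SPONGE_CDS = (150, 2300)


def generate_transcriptome(cfg: SimulationConfig) -> tuple[TranscriptSet, GroundTruth]:
    """Build the toy transcriptome with planted seed-match sites.

    Reproducible under ``cfg.rng_seed``. Raises if a sequence free of
    accidental planted-pattern occurrences cannot be drawn within the
    rejection-sampling budget.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    patterns = {s.mirna_name: _seed_pattern(s.mature_sequence) for s in cfg.planted_seeds}

    models: list[TranscriptModel] = []
    for i in range(cfg.n_genes):
        gene_id = f"gene{i + 1:02d}"
        tid = f"tx{i + 1:02d}"
        if gene_id == cfg.sponge_gene:
            length, exon_bounds, cds = 3000, _SPONGE_EXONS, _SPONGE_CDS
            insertions = [
                (pos, patterns[s.mirna_name])
                for s in cfg.planted_seeds
                for pos in s.insertions
            ]
        else:
            length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
            exon_bounds = _random_exon_bounds(rng, length)
            cds = _random_cds(rng, length)
            insertions = []
        seq = _draw_sequence(rng, length, list(patterns.values()), insertions)
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                gene_name=gene_id.upper(),
                length=length,
                exon_bounds=tuple(exon_bounds),
                cds_start=cds[0],
                cds_end=cds[1],
                sequence=seq,
            )
        )
    ts = TranscriptSet.from_transcripts(models)

    seed_rows = []
    for s in cfg.planted_seeds:
        sponge_tid = _sponge_transcript_id(cfg)
        for pos in s.insertions:
            feature, exon = feature_of_position(ts[sponge_tid], pos)
            seed_rows.append(
                {"mirna_name": s.mirna_name, "transcript_id": sponge_tid,
                 "position": pos, "feature": feature, "exon": exon}
            )
    gt = GroundTruth(
        sites=_ground_truth_sites(cfg),
        seed_matches=pd.DataFrame(
            seed_rows, columns=["mirna_name", "transcript_id", "position", "feature", "exon"]
        ),
        expected_totals=_expected_totals(cfg, ts),
    )
    return ts, gt


def _sponge_transcript_id(cfg: SimulationConfig) -> str:
    idx = int(cfg.sponge_gene.removeprefix("gene"))
    return f"tx{idx:02d}"


def _random_exon_bounds(rng: np.random.Generator, length: int) -> list[tuple[int, int]]:
    n_exons = int(rng.integers(3, 7))
    cuts = np.sort(rng.choice(np.arange(50, length - 50), size=n_exons - 1, replace=False))
    edges = [0, *cuts.tolist(), length]
    return list(zip(edges[:-1], edges[1:]))

def _random_cds(rng: np.random.Generator, length: int) -> tuple[int, int]:
    cds_start = int(rng.integers(30, max(31, length // 4)))
    cds_end = int(rng.integers(int(length * 0.6), length - 50))
    return cds_start, cds_end


def _draw_sequence(
    rng: np.random.Generator,
    length: int,
    forbidden: list[str],
    insertions: list[tuple[int, str]],
) -> str:
    """Random uniform-GC sequence with patterns written in and none elsewhere."""
    bases = np.array(list("ACGT"))
    expected = {pos: pat for pos, pat in insertions}
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        for pos, pat in insertions:
            if pos + len(pat) > length:
                raise ValueError(f"seed insertion at {pos} exceeds transcript length {length}")
            seq = seq[:pos] + pat + seq[pos + len(pat):]
        ok = True
        for pat in set(forbidden):
            hits = _find_all(seq, pat)
            planted = sorted(p for p, q in expected.items() if q == pat)
            if hits != planted:
                ok = False
                break
        if ok:
            return seq
    raise RuntimeError(
        f"could not draw a {length}-nt sequence free of accidental seed "
        f"patterns in {_MAX_REJECTION_ATTEMPTS} attempts"
    )


def _find_all(seq: str, pattern: str) -> list[int]:
    hits, start = [], seq.find(pattern)
    while start != -1:
        hits.append(start)
        start = seq.find(pattern, start + 1)  # overlapping occurrences too
    return hits


def _site_scale(cfg: SimulationConfig, gene_id: str, condition: str) -> float:
    if gene_id == cfg.sponge_gene and condition != CONTROL:
        return cfg.sponge_enrichment
    return 1.0


def _ground_truth_sites(cfg: SimulationConfig) -> dict[tuple[str, str], tuple[int, ...]]:
    out: dict[tuple[str, str], tuple[int, ...]] = {}
    for tid, sites in cfg.planted_sites.items():
        for cond in cfg.conditions:
            positions = tuple(sorted(s.position for s in sites if cond in s.conditions))
            if positions:
                out[(tid, cond)] = positions
    return out


def _expected_totals(cfg: SimulationConfig, ts: TranscriptSet) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for t in ts:
        for cond in cfg.conditions:
            scale = _site_scale(cfg, t.gene_id, cond) * cfg.n_replicates
            total = t.length * cfg.background_rate * scale
            for site in cfg.planted_sites.get(t.transcript_id, ()):
                if cond in site.conditions:
                    total += site.peak_height * scale
            out[(t.gene_id, cond)] = total
    return out


def simulate_iclip_tags(
    ts: TranscriptSet, cfg: SimulationConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw truncation tags for every replicate x condition.

    Returns one row per tag (transcript_id, position, condition, replicate)
    plus the ground truth. Reproducible under ``cfg.rng_seed`` (a stream
    independent of the sequence draw).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 1]))
    frames = []
    for cond in cfg.conditions:
        for rep in range(1, cfg.n_replicates + 1):
            for t in sorted(ts, key=lambda t: t.transcript_id):
                scale = _site_scale(cfg, t.gene_id, cond)
                counts = rng.poisson(cfg.background_rate * scale, size=t.length)
                for site in cfg.planted_sites.get(t.transcript_id, ()):
                    if cond in site.conditions:
                        counts[site.position] += rng.poisson(site.peak_height * scale)
                positions = np.repeat(np.arange(t.length), counts)
                if len(positions) == 0:
                    continue
                frames.append(
                    pd.DataFrame(
                        {
                            "transcript_id": t.transcript_id,
                            "position": positions,
                            "condition": cond,
                            "replicate": rep,
                        }
                    )
                )
    tags = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TAG_COLUMNS)
    )
    gt = GroundTruth(
        sites=_ground_truth_sites(cfg),
        seed_matches=pd.DataFrame(
            columns=["mirna_name", "transcript_id", "position", "feature", "exon"]
        ),
        expected_totals=_expected_totals(cfg, ts),
    )
    return tags, gt


# ---------------------------------------------------------------------------
# Writers / readers
# ---------------------------------------------------------------------------

def write_tags_bed(tags: pd.DataFrame, path: str | Path) -> None:
    """Tag table as a 6-column BED dialect, one row per tag.

    ``transcript_id  start  end  tag_id  1  +`` with start the truncation
    position and end = start + 1.
    """
    with open(path, "w") as fh:
        for i, row in enumerate(tags.itertuples(index=False), start=1):
            fh.write(
                f"{row.transcript_id}\t{row.position}\t{row.position + 1}"
                f"\ttag_{i:07d}|{row.condition}|{row.replicate}\t1\t+\n"
            )


def read_tags_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            tid, start, _end, name, _score, _strand = line.rstrip("\n").split("\t")
            _tag, condition, replicate = name.split("|")
            rows.append((tid, int(start), condition, int(replicate)))
    return pd.DataFrame(rows, columns=TAG_COLUMNS)


def write_mirnas_tsv(seeds: tuple[PlantedSeed, ...], path: str | Path,
                     decoys: dict[str, str] | None = None) -> None:
    """Two-column miRNA table (name, mature sequence), planted plus decoys."""
    with open(path, "w") as fh:
        for s in seeds:
            fh.write(f"{s.mirna_name}\t{s.mature_sequence}\n")
        for name, mature in (decoys or {}).items():
            fh.write(f"{name}\t{mature}\n")


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("record\ttranscript_id\tcondition\tpositions\n")
        for (tid, cond), positions in sorted(gt.sites.items()):
            fh.write(f"site\t{tid}\t{cond}\t{','.join(map(str, positions))}\n")
        for row in gt.seed_matches.itertuples(index=False):
            fh.write(
                f"seed\t{row.transcript_id}\t{row.mirna_name}\t"
                f"{row.position}:{row.feature}:exon{row.exon}\n"
            )


def write_config(cfg: SimulationConfig, path: str | Path) -> None:
    """Flat key-value echo of the simulation config for the run log."""
    d = asdict(cfg)
    with open(path, "w") as fh:
        for key, value in d.items():
            fh.write(f"{key} = {value!r}\n")
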