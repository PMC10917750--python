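import numpy as np
import pytest

from spongeclip import (
    TranscriptModel,
    TranscriptSet,
    default_config,
    generate_transcriptome,
    simulate_iclip_tags,
)


def make_transcript(
    transcript_id="tx1",
    gene_id="geneA",
    length=300,
    exon_bounds=None,
    cds=None,
    sequence=None,
    seed=0,
):
    """Small hand-configurable transcript for unit tests."""
    if cds is None:
        cds = (max(1, length // 6), length - max(1, length // 6))
    if exon_bounds is None:
        a, b = length // 3, 2 * length // 3
        exon_bounds = ((0, a), (a, b), (b, length))
    if sequence is None:
        rng = np.random.default_rng(seed)
        sequence = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        gene_name=gene_id.upper(),
        length=length,
        exon_bounds=tuple(exon_bounds),
        cds_start=cds[0],
        cds_end=cds[1],
        sequence=sequence,
    )


def random_transcript_set(rng, n_genes=5, max_isoforms=3):
    """Random multi-isoform TranscriptSet for brute-force oracle tests."""
    models = []
    k = 0
    for g in range(n_genes):
        for _ in range(int(rng.integers(1, max_isoforms + 1))):
            k += 1
            length = int(rng.integers(120, 600))
            cut1 = int(rng.integers(20, length // 2))
            cut2 = int(rng.integers(cut1 + 10, length - 10))
            models.append(
                make_transcript(
                    transcript_id=f"t{k:03d}",
                    gene_id=f"g{g}",
                    length=length,
                    exon_bounds=((0, cut1), (cut1, cut2), (cut2, length)),
                    cds=(min(15, cut1), length - 10),
                    seed=int(rng.integers(0, 2**31)),
                )
            )
    return TranscriptSet.from_transcripts(models)


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(rng_seed=1)


@pytest.fixture(scope="session")
def transcriptome(default_cfg):
    return generate_transcriptome(default_cfg)


@pytest.fixture(scope="session")
def simulated(default_cfg, transcriptome):
    ts, _ = transcriptome
    return simulate_iclip_tags(ts, default_cfg)
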