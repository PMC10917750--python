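import numpy as np
import pandas as pd
import pytest

from spongeclip import (
    TranscriptSet,
    classify_tag_locations,
    default_config,
    feature_of_position,
    generate_transcriptome,
    load_annotation,
    select_longest_per_gene,
)
from spongeclip.transcript_model import (
    transcript_feature_lengths,
    write_annotation,
)

from conftest import make_transcript, random_transcript_set


class TestAnnotationIO:
    def test_round_trip_preserves_models(self, transcriptome, tmp_path):
        ts, _ = transcriptome
        write_annotation(ts, tmp_path / "a.gtf", tmp_path / "a.fa")
        loaded = load_annotation(tmp_path / "a.gtf", tmp_path / "a.fa")
        assert set(loaded.transcripts) == set(ts.transcripts)
        for tid, t in ts.transcripts.items():
            assert loaded[tid] == t

    def test_missing_sequence_names_transcript(self, tmp_path):
        ts = TranscriptSet.from_transcripts([make_transcript("txA"), make_transcript("txB", gene_id="geneB")])
        write_annotation(ts, tmp_path / "a.gtf", tmp_path / "a.fa")
        # drop txB from the FASTA
        records = (tmp_path / "a.fa").read_text().split(">")
        (tmp_path / "a.fa").write_text(">" + records[1])
        with pytest.raises(ValueError, match="txB"):
            load_annotation(tmp_path / "a.gtf", tmp_path / "a.fa")

    def test_malformed_gtf_line_reports_line_number(self, tmp_path):
        ts = TranscriptSet.from_transcripts([make_transcript("txA")])
        write_annotation(ts, tmp_path / "a.gtf", tmp_path / "a.fa")
        with open(tmp_path / "a.gtf", "a") as fh:
            fh.write("broken line without tabs\n")
        n_lines = len((tmp_path / "a.gtf").read_text().splitlines())
        with pytest.raises(ValueError, match=f"line {n_lines}"):
            load_annotation(tmp_path / "a.gtf", tmp_path / "a.fa")


class TestLongestIsoform:
    def test_retains_maximal_length_isoform(self):
        short = make_transcript("tx_s", length=500, exon_bounds=((0, 500),), cds=(50, 450))
        long = make_transcript("tx_l", length=800, exon_bounds=((0, 800),), cds=(50, 450))
        ts = TranscriptSet.from_transcripts([short, long])
        assert list(select_longest_per_gene(ts).transcripts) == ["tx_l"]

    def test_tie_breaks_to_smallest_transcript_id(self):
        a = make_transcript("tx_b", length=500, exon_bounds=((0, 500),), cds=(50, 450))
        b = make_transcript("tx_a", length=500, exon_bounds=((0, 500),), cds=(50, 450))
        ts = TranscriptSet.from_transcripts([a, b])
        assert list(select_longest_per_gene(ts).transcripts) == ["tx_a"]

    def test_agrees_with_brute_force_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ts = random_transcript_set(rng)
            got = select_longest_per_gene(ts)
            for gene in ts.gene_ids:
                isoforms = ts.transcripts_of_gene(gene)
                best = sorted(isoforms, key=lambda t: (-t.length, t.transcript_id))[0]
                (kept,) = got.transcripts_of_gene(gene)
                assert kept == best

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        ts = random_transcript_set(rng)
        once = select_longest_per_gene(ts)
        twice = select_longest_per_gene(once)
        assert once.transcripts == twice.transcripts

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            select_longest_per_gene(TranscriptSet())


class TestFeatureOfPosition:
    def test_boundaries_follow_half_open_cds(self):
        t = make_transcript(cds=(50, 250))
        assert feature_of_position(t, 0) == ("5UTR", 1)
        assert feature_of_position(t, 49)[0] == "5UTR"
        assert feature_of_position(t, 50)[0] == "CDS"
        assert feature_of_position(t, 249)[0] == "CDS"
        assert feature_of_position(t, 250)[0] == "3UTR"  # pos == cds_end

    def test_out_of_range_rejected(self):
        t = make_transcript()
        for pos in (-1, t.length):
            with pytest.raises(ValueError):
                feature_of_position(t, pos)

    def test_exhaustive_scan_partitions_transcript(self):
        t = make_transcript(length=300, exon_bounds=((0, 90), (90, 210), (210, 300)), cds=(40, 260))
        labels = [feature_of_position(t, p)[0] for p in range(t.length)]
        counts = pd.Series(labels).value_counts().to_dict()
        assert counts == transcript_feature_lengths(t)
        assert sum(counts.values()) == t.length
        # exon indices partition too
        exons = [feature_of_position(t, p)[1] for p in range(t.length)]
        assert pd.Series(exons).value_counts().sort_index().tolist() == [90, 120, 90]

    def test_noncoding_transcript_labels_everything_exon(self):
        t = make_transcript(cds=(300, 300))  # sentinel: cds_start == cds_end == length
        assert feature_of_position(t, 0)[0] == "exon"
        assert feature_of_position(t, 299)[0] == "exon"


class TestClassifyTagLocations:
    def _ts(self):
        return TranscriptSet.from_transcripts([make_transcript(length=1000, exon_bounds=((0, 1000),), cds=(200, 700))])

    def test_all_tags_in_3utr(self):
        ts = self._ts()
        tags = pd.DataFrame({"transcript_id": "tx1", "position": [800, 900, 950]})
        table = classify_tag_locations(tags, ts)
        assert table.loc[table["category"] == "3UTR", "fraction"].item() == 1.0

    def test_empty_tag_set_gives_empty_table(self):
        table = classify_tag_locations(pd.DataFrame(columns=["transcript_id", "position"]), self._ts())
        assert table.empty

    def test_unknown_transcript_rejected(self):
        tags = pd.DataFrame({"transcript_id": ["nope"], "position": [1]})
        with pytest.raises(KeyError, match="nope"):
            classify_tag_locations(tags, self._ts())

    def test_permutation_invariant(self):
        ts = self._ts()
        rng = np.random.default_rng(3)
        tags = pd.DataFrame({"transcript_id": "tx1", "position": rng.integers(0, 1000, 200)})
        shuffled = tags.sample(frac=1, random_state=5).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            classify_tag_locations(tags, ts), classify_tag_locations(shuffled, ts)
        )

    def test_recovers_known_fractions_at_large_n(self):
        # 5'UTR [0,200), CDS [200,700), 3'UTR [700,1000): place tags with
        # probabilities 0.2/0.5/0.3 and expect recovery within binomial error
        ts = self._ts()
        rng = np.random.default_rng(42)
        n = 10_000
        choice = rng.choice(3, size=n, p=[0.2, 0.5, 0.3])
        lo = np.array([0, 200, 700])[choice]
        hi = np.array([200, 700, 1000])[choice]
        pos = rng.integers(lo, hi)
        table = classify_tag_locations(pd.DataFrame({"transcript_id": "tx1", "position": pos}), ts)
        fractions = table.set_index("category")["fraction"]
        assert abs(table["fraction"].sum() - 1) < 1e-9
        assert table["count"].sum() == n
        for category, p in [("5UTR", 0.2), ("CDS", 0.5), ("3UTR", 0.3)]:
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(fractions[category] - p) < 5 * sigma


def test_generated_default_transcriptome_is_one_isoform_per_gene(transcriptome):
    ts, _ = transcriptome
    assert select_longest_per_gene(ts).transcripts == ts.transcripts
    for gene in ts.gene_ids:
        assert len(ts.transcripts_of_gene(gene)) == 1
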