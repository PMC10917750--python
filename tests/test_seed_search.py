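import numpy as np
import pandas as pd
import pytest

from spongeclip import (
    BindingRegion,
    SeedRecord,
    TranscriptSet,
    filter_expressed_mirnas,
    map_matches_to_features,
    matches_in_regions,
    matches_in_transcripts,
    scan_sequences,
    seed_density_per_kb,
)
from spongeclip.seed_search import load_mirnas

from conftest import make_transcript


LET7A = "UGAGGUAGUAGGUUGUAUAGUU"


def naive_scan(patterns, targets):
    """O(n*m) sliding-window oracle, overlapping occurrences included."""
    hits = []
    for target_id, seq in targets:
        for rec in patterns:
            p = rec.match_pattern
            for i in range(len(seq) - len(p) + 1):
                if seq[i : i + len(p)] == p:
                    hits.append((target_id, i, rec.mirna_name))
    return sorted(hits)


class TestSeedRecord:
    def test_let7a_seed_and_pattern(self):
        rec = SeedRecord.from_mature("let-7a-5p", LET7A)
        assert rec.seed == "GAGGUAG"
        assert rec.match_pattern == "CTACCTC"

    def test_dna_input_normalised_to_rna(self):
        rna = SeedRecord.from_mature("x", LET7A)
        dna = SeedRecord.from_mature("x", LET7A.replace("U", "T"))
        assert rna == dna

    def test_hexamer_span_option(self):
        rec = SeedRecord.from_mature("let-7a-5p", LET7A, seed_span=(2, 7))
        assert rec.seed == "GAGGUA"
        assert len(rec.match_pattern) == 6

    def test_short_mature_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            SeedRecord.from_mature("tiny", "UGAGGUA")


class TestLoadMirnas:
    def test_fasta_and_tsv_agree(self, tmp_path):
        fasta = tmp_path / "m.fa"
        fasta.write_text(f">let-7a-5p\n{LET7A}\n")
        tsv = tmp_path / "m.tsv"
        tsv.write_text(f"let-7a-5p\t{LET7A}\n")
        assert load_mirnas(fasta) == load_mirnas(tsv)

    def test_short_sequence_skipped_with_warning(self, tmp_path, caplog):
        tsv = tmp_path / "m.tsv"
        tsv.write_text(f"ok\t{LET7A}\nshorty\tUGAGGUA\n")
        with caplog.at_level("WARNING"):
            records = load_mirnas(tsv)
        assert [r.mirna_name for r in records] == ["ok"]
        assert "shorty" in caplog.text

    def test_duplicate_seeds_kept_as_distinct_records(self, tmp_path):
        tsv = tmp_path / "m.tsv"
        tsv.write_text(f"fam-a\t{LET7A}\nfam-b\t{LET7A}GG\n")  # same 2-8 seed
        records = load_mirnas(tsv)
        assert len(records) == 2
        assert records[0].seed == records[1].seed


class TestScanSequences:
    def test_single_embedded_pattern(self):
        rec = SeedRecord.from_mature("let-7a-5p", LET7A)
        assert scan_sequences([rec], [("t", "AACTACCTCAA")]) == [("t", 2, "let-7a-5p")]

    def test_absent_pattern(self):
        rec = SeedRecord.from_mature("let-7a-5p", LET7A)
        assert scan_sequences([rec], [("t", "AAAAAAAAAAAA")]) == []

    def test_overlapping_occurrences_all_reported(self):
        rec = SeedRecord(mirna_name="m", mature_sequence="", seed="", match_pattern="AAAAAAA")
        hits = scan_sequences([rec], [("t", "A" * 10)])
        assert [h[1] for h in hits] == [0, 1, 2, 3]

    def test_matches_naive_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(13)
        bases = np.array(list("ACGT"))
        for _ in range(100):
            patterns = [
                SeedRecord("m%d" % i, "", "", "".join(bases[rng.integers(0, 4, size=7)]))
                for i in range(rng.integers(1, 4))
            ]
            targets = [
                ("t%d" % j, "".join(bases[rng.integers(0, 4, size=rng.integers(10, 120))]))
                for j in range(rng.integers(1, 4))
            ]
            assert scan_sequences(patterns, targets) == naive_scan(patterns, targets)

    def test_sentinel_separator_preserves_match_count(self):
        rng = np.random.default_rng(29)
        bases = np.array(list("ACGT"))
        rec = SeedRecord("m", "", "", "CTACCTC")
        s1 = "".join(bases[rng.integers(0, 4, size=200)]) + "CTACCTC"
        s2 = "CTACCTC" + "".join(bases[rng.integers(0, 4, size=200)])
        separate = scan_sequences([rec], [("a", s1), ("b", s2)])
        joined = scan_sequences([rec], [("ab", s1 + "N" + s2)])
        assert len(separate) == len(joined)


class TestFeatureMapping:
    def test_planted_sponge_reports_exon3_and_3utr(self, default_cfg, transcriptome):
        ts, _ = transcriptome
        mirnas = [
            SeedRecord.from_mature(s.mirna_name, s.mature_sequence)
            for s in default_cfg.planted_seeds
        ]
        matches = matches_in_transcripts(mirnas, ts)
        # every match re-verifies as a substring at its recorded position
        for m in matches:
            rec = next(r for r in mirnas if r.mirna_name == m.mirna_name)
            seq = ts[m.transcript_id].sequence
            assert seq[m.position : m.position + 7] == rec.match_pattern
        report = map_matches_to_features(matches, ts).set_index("mirna_name")
        assert report.loc["miR-syn-1", "location"] == "Exon 3 (1), 3'UTR (2)"
        assert report.loc["miR-syn-2", "location"] == "3'UTR"

    def test_no_matches_gives_empty_report(self, transcriptome):
        ts, _ = transcriptome
        assert map_matches_to_features([], ts).empty

    def test_boundary_straddling_match_labelled_by_start(self):
        # pattern starts 3 nt before cds_end: labelled CDS even though it
        # extends into the 3'UTR
        seq = "A" * 47 + "CTACCTC" + "A" * 46
        t = make_transcript(length=100, exon_bounds=((0, 100),), cds=(10, 50), sequence=seq)
        ts = TranscriptSet.from_transcripts([t])
        rec = SeedRecord("m", "", "", "CTACCTC")
        (match,) = matches_in_transcripts([rec], ts)
        assert match.position == 47
        assert match.feature == "CDS"

    def test_region_scan_reports_transcript_coordinates(self, default_cfg, transcriptome):
        ts, gt = transcriptome
        mirnas = [
            SeedRecord.from_mature(s.mirna_name, s.mature_sequence)
            for s in default_cfg.planted_seeds
        ]
        regions = [
            BindingRegion("tx01", pos - 20, pos + 20, pos, "tgfb4h")
            for pos in (664, 2424, 2504, 2744)
        ]
        matches = matches_in_regions(mirnas, regions, ts)
        assert sorted(m.position for m in matches) == [662, 2422, 2502, 2742]
        assert all(m.region_id is not None for m in matches)


class TestDensityRanking:
    def test_density_arithmetic(self, transcriptome):
        ts, _ = transcriptome
        t = ts["tx01"]  # 3000 nt
        matches = matches_in_transcripts(
            [SeedRecord("m", "", "", t.sequence[:7])], ts
        )  # at least the prefix occurrence
        df = seed_density_per_kb(matches, ts)
        row = df[df["transcript_id"] == "tx01"].iloc[0]
        assert row["density_per_kb"] == pytest.approx(row["n_matches"] / 3.0)

    def test_zero_match_transcripts_rank_last_with_zero_density(self, transcriptome):
        ts, _ = transcriptome
        df = seed_density_per_kb([], ts)
        assert (df["density_per_kb"] == 0).all()
        assert df["gene_id"].tolist() == sorted(df["gene_id"])  # tie-break order

    def test_density_scales_inversely_with_length(self):
        t1 = make_transcript("tx1", "gA", length=1000, exon_bounds=((0, 1000),), cds=(10, 900))
        t2 = make_transcript("tx2", "gB", length=2000, exon_bounds=((0, 2000),), cds=(10, 900))
        ts = TranscriptSet.from_transcripts([t1, t2])
        matches = [
            m for tid in ("tx1", "tx2")
            for m in matches_in_transcripts([SeedRecord("m", "", "", ts[tid].sequence[:7])], ts)
        ]
        # fabricate equal counts by taking one match per transcript
        one_each = {m.transcript_id: m for m in matches}
        df = seed_density_per_kb(list(one_each.values()), ts).set_index("transcript_id")
        assert df.loc["tx1", "density_per_kb"] == pytest.approx(
            2 * df.loc["tx2", "density_per_kb"]
        )


class TestFilterExpressed:
    def test_subset(self):
        records = [SeedRecord(f"m{i}", "", "", "AAAAAAA") for i in range(5)]
        kept = filter_expressed_mirnas(records, ["m1", "m3", "absent"])
        assert [r.mirna_name for r in kept] == ["m1", "m3"]

    def test_empty_list_warns_and_returns_nothing(self, caplog):
        with caplog.at_level("WARNING"):
            assert filter_expressed_mirnas([SeedRecord("m", "", "", "AAAAAAA")], []) == []
        assert "expressed" in caplog.text

    def test_filter_commutes_with_scanning(self):
        rng = np.random.default_rng(37)
        bases = np.array(list("ACGT"))
        records = [
            SeedRecord("m%d" % i, "", "", "".join(bases[rng.integers(0, 4, size=7)]))
            for i in range(6)
        ]
        targets = [("t", "".join(bases[rng.integers(0, 4, size=500)]))]
        expressed = ["m0", "m2", "m4"]
        filtered_first = scan_sequences(filter_expressed_mirnas(records, expressed), targets)
        scanned_first = [
            h for h in scan_sequences(records, targets) if h[2] in set(expressed)
        ]
        assert filtered_first == sorted(scanned_first)
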