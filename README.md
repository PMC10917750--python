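# spongeclip

AGO2 iCLIP analysis for competing-endogenous-RNA (miRNA sponge) discovery.

During TGF-β-induced epithelial–mesenchymal transition, some transcripts are
recruited into the RNA-induced silencing complex (RISC) far in excess of
their expression change, behaving as miRNA sponges: they sequester miRNAs
through seed-match sites and de-repress those miRNAs' targets. `spongeclip`
implements the transcript-space analysis that identifies such sponges from
AGO2 iCLIP truncation tags:

1. **Crosslink-site calling.** iCLIP reverse transcription truncates at the
   crosslinked nucleotide, so each tag's 5′ position marks an AGO2–RNA
   contact. Replicates are pooled per condition and a position *p* is called
   a crosslink site iff its pooled truncation count *c(p)* ≥ `min_count`
   (default 4) and *c(p)* is the local maximum over
   *[p − d, p + d]* (default *d* = 8 nt; ties resolve to the smaller
   coordinate).
2. **Binding regions.** Each site is widened to the half-open 40-bp window
   *[p − 20, p + 20)*, clipped at transcript edges. A treated-condition
   region is **treatment-specific** iff it shares no position with any
   control region on the same transcript.
3. **RISC-association quantification.** Tags inside a gene's binding regions
   are counted (once per tag) and normalised to RPKM
   (count / (L/10³) / (N/10⁶), with L the gene's transcript length and N the
   condition's total mapped tags). The sponge score is the fold enrichment
   RPKM_treated / RPKM_control; genes with zero control signal are reported
   as treated-only rather than given an infinite ratio.
4. **Seed scanning.** The seed of each mature miRNA (positions 2–8) is
   reverse-complemented into the DNA pattern a RISC-bound target presents;
   exact occurrences (including overlapping ones) are located inside the
   treatment-specific regions, mapped to transcript features
   (5′UTR / CDS exon *k* / 3′UTR by match start) and summarised as seed
   matches per kilobase of transcript.

A first-class synthetic-data module generates toy transcriptomes with a
planted sponge (condition-specific crosslink sites, multiplicative treated
enrichment, seed patterns written into the sequence and excluded from the
background by rejection sampling) so that every step is testable against
known ground truth.

## Worked example

```
spongeclip all -o run --seed 1
```

simulates the default study (20 genes, 3 replicates × control/TGF-β-4h, a
sponge gene with 2 control and 34 treated-condition crosslink sites and
10-fold treated enrichment) and runs the full analysis. The same steps are
available as narrative drivers `analysis/01_simulate_iclip.py` …
`analysis/05_scan_mirna_seeds.py`, which print:

```
control: 58 crosslink sites -> results/sites_control.bed
tgfb4h: 93 crosslink sites -> results/sites_tgfb4h.bed
sponge gene01 site counts: {'control': 2, 'tgfb4h': 34} (planted architecture: 2 control, 34 treated)
93 treated binding regions, 35 treatment-specific (32 on the sponge transcript tx01)
rank 1: gene01 (enrichment 46.12, sites 2 -> 34)
replicate concordance (log2 per-gene counts): min pairwise r = 0.955
seed-match locations per miRNA:
mirna_name transcript_id gene_name  n_matches              location
 miR-syn-1          tx01    GENE01          3 Exon 3 (1), 3'UTR (2)
 miR-syn-2          tx01    GENE01          1                 3'UTR
highest seed density: tx01 (gene01), 1.33 matches/kb
```

The planted sponge is recovered exactly: its site counts go from 2 (control)
to 34 (treated), it ranks first by RPKM fold enrichment and by seed density
per kb, and the planted miRNA's matches map to one CDS site in exon 3 plus
two 3′UTR sites. `spongeclip analyze` runs the same analysis on
user-supplied GTF/FASTA/tag-table/miRNA inputs; `--min-count`,
`--merge-distance`, `--flank`, `--seed-span {2-7,2-8}` and `--pseudocount`
expose the tunables.

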