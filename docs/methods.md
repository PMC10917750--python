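# Methods

## Coordinate model

All analysis is performed in transcript space: 0-based, half-open
coordinates on each transcript, with no genome projection or strand
arithmetic. A transcript is an exon tiling of `[0, length)` plus a CDS
interval `[cds_start, cds_end)`; `pos < cds_start` is 5′UTR,
`pos >= cds_end` is 3′UTR (half-open, so the position equal to `cds_end` is
already 3′UTR). Non-coding transcripts carry the sentinel
`cds_start == cds_end == length` and every position is labelled `exon`.
When annotation contains several isoforms per gene, only the longest is
retained (ties broken to the lexicographically smallest transcript id, which
makes the filter deterministic and idempotent).

## Crosslink-site caller

iCLIP tags are truncation-diagnostic: the tag's 5′ position marks the
protein–RNA crosslink. Replicates are pooled per condition before calling
(pooling preserves the tag multiset exactly), and sites are defined by a
threshold plus local-maximum rule:

* `min_count` (default **4** pooled truncations) — the minimum evidence for
  a point-like site;
* `merge_distance` (default **8 nt**) — within `[p − 8, p + 8]` only the
  highest pileup position is called; a tie is resolved to the smaller
  coordinate (which simultaneously suppresses the larger-coordinate tied
  peak). 8 nt is roughly a seed-match footprint, so near-adjacent truncation
  clusters collapse to one site.

This rule is a deliberate simplification of HMM-based callers: it keeps the
analysis logic (minimum truncation evidence, single-nucleotide sites) while
being fully specified and checkable against brute-force enumeration, which
the test suite does. Raising `min_count` can only remove sites
(monotonicity), and calling is a pure function of the pileup.

## Binding regions and treatment specificity

Sites widen to `[max(0, p − 20), min(L, p + 20))`: 40 bp in the interior,
clipped at edges, containing the site, asymmetric by one base on the right
(a symmetric ±20 window would span 41 nt; the 40-bp convention was kept and
the one-base asymmetry placed at the right boundary). Overlapping regions
are not merged, so region count always equals site count. A treated region
is treatment-specific iff it overlaps (shares ≥ 1 position with) no control
region of the same transcript; abutting half-open intervals do not overlap.
Specificity is evaluated per treated timepoint independently against the
control.

## RISC-association quantification

For each gene, tags whose truncation position falls inside any of the
gene's binding regions are counted, each tag once regardless of how many
regions cover it. RPKM uses the condition's **total** mapped tag count as
denominator (the standard definition — not only in-region tags) and the
gene's longest-transcript length. Fold enrichment is
`RPKM_treated / RPKM_control`, computed at full precision and displayed at
2 dp. Zero-control genes are flagged *treated-only* and listed separately at
the top of the ranking by treated RPKM instead of receiving an infinite or
pseudocounted ratio; `pseudocount > 0` (default 0) forces a ratio when
requested. Replicate concordance is the Pearson correlation of
log2(count + 1) per-gene vectors for every replicate pair within a
condition (a principal-component view of the same matrix adds nothing at
this scale and is not produced).

## Seed scanning

The seed is mature-miRNA positions 2–8 (7-mer; `--seed-span 2-7` selects
the hexamer convention). The match pattern is the reverse complement of the
seed written in DNA, i.e. the transcript-strand sequence a RISC-bound
target presents. Scanning is exact substring matching with all overlapping
occurrences reported — for a 7-nt single-sequence motif with zero
mismatches this coincides with profile-based motif scanning at default
thresholds, without a p-value model. A match is assigned the feature of its
start position; matches straddling a feature boundary are not split.
Feature reports aggregate per miRNA per transcript as e.g.
`Exon 3 (1), 3'UTR (2)`; seed density is matches per kilobase of transcript
length, ranked descending with gene-id tie-break.

## Synthetic data

The generator emulates the analyzed structure of an AGO2 iCLIP EMT time
course: 3 replicates per condition, truncation counts Poisson-distributed —
`Poisson(peak_height)` per replicate at planted sites (per active
condition), `Poisson(background_rate)` per nucleotide per replicate
elsewhere — with the sponge transcript's treated-condition expectations
(sites and background) multiplied by `sponge_enrichment`. Defaults, fixed
once as the study conditions:

* 20 genes, lengths 1–4 kb, uniform base composition (GC 0.5), one isoform
  per gene; the sponge is gene01/tx01 (3000 nt, 9 exons, CDS [150, 2300)).
* Sponge sites: 34 positions spaced 80 nt apart, 2 of them (one CDS, one
  3′UTR) active in both conditions and 32 treated-only — per-condition site
  counts 2 (control) and 34 (treated), so the control sites are a subset of
  treated binding and treatment-specific selection is non-trivial (32/34).
* `peak_height` 10 for the sponge; non-sponge genes carry 3 both-condition
  sites with heights cycling over (4, 8, 15, 30, 60). The order-of-magnitude
  occupancy spread mirrors real RISC maps and is what makes between-replicate
  correlation a meaningful statistic — with identical per-gene means the
  per-gene count vector has no signal variance and Pearson correlation
  degenerates to noise. One non-sponge gene (gene02) additionally carries
  two treated-only sites.
* `background_rate` 0.005 truncations/nt/replicate — planted peaks are
  three orders of magnitude above per-position background, and pooled
  background (expectation 0.015) essentially never reaches the calling
  threshold, keeping planted/called correspondence crisp.
* `sponge_enrichment` 10, after the ~11-fold RISC-association increase the
  screen is designed to detect.
* Two planted miRNAs with matches written into the sponge — one with a CDS
  (exon 3) site plus two 3′UTR sites, one with a single 3′UTR site — at
  positions inside treated-only binding regions. Background sequence is
  rejection-resampled (up to 1000 attempts) until no planted pattern occurs
  anywhere outside its ground-truth positions, so scan results are exact.
* Conditions default to control + one treated timepoint (a second treated
  label is supported throughout); 3 replicates; everything is reproducible
  bit-for-bit under `rng_seed` (sequence and tag draws use independent
  streams derived from it).

What the generator does **not** emulate: sequencing errors, adapter/barcode
structure and UMI collapsing (tags are emitted pre-deduplicated, as the
analyzed data are), overdispersion beyond Poisson, real sequencing depth
(millions of tags per condition), isoform mixtures, and genome-space
alignment artefacts. Passing recovery tests therefore demonstrates that the
analysis logic is correct on data satisfying its assumptions, not that the
caller matches an HMM-based caller on real, overdispersed libraries.

## Numerical and degenerate-input choices

* Empty tag tables classify to an empty feature table (sparse conditions do
  not abort a pipeline).
* A replicate with zero tags yields NaN concordance for its pairs; a
  single-replicate condition yields an empty matrix.
* Fold-enrichment display rounding is 2 dp; all tables also carry full
  precision.
* Pipeline outputs are staged and moved into place only on success, so a
  failed run leaves no partial outputs; identical config + seed reruns are
  byte-identical for all TSV/BED/FASTA outputs.

## Problem sizes

The default synthetic study (~20k tags, ~50 kb of transcriptome) runs the
full pipeline in about a second; oracle-equivalence suites use 100 random
small fixtures per operation. These sizes were chosen so the planted
architecture is recovered with wide statistical margin (site recall and
precision ≥ 0.9 with planted peaks ≥ 8× background expectation) while the
whole suite stays interactive.

## Known limitations

* The caller is not an HMM and reports no significance; site totals on real
  libraries will differ from model-based callers.
* Exact seed matching carries no thermodynamic or context scoring and no
  mismatch tolerance by default.
* RPKM fold enrichment is a composition-sensitive ratio: a gene whose
  association is unchanged can show enrichment < 1 when another gene's
  association grows sharply (visible in the worked example, where non-sponge
  genes sit near 0.4 because the sponge dominates the treated library).
* Tag-location classification covers exonic categories only; a
  transcript-space model has no introns or intergenic space.
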