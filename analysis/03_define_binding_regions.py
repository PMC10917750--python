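"""Widen crosslink sites to 40-bp binding regions and select the
treatment-specific subset (treated regions overlapping no control region).

Writes the flagged treated-condition region table and the region sequences
(FASTA) to results/. Run after 02_call_crosslink_sites.py.
"""

from pathlib import Path

from Bio import SeqIO

from spongeclip import (
    CallerConfig,
    load_annotation,
    merge_replicates,
    select_condition_specific,
    select_longest_per_gene,
)
from spongeclip.binding_regions import (
    extract_region_sequences,
    regions_for_condition,
    write_regions_tsv,
)
from spongeclip.crosslink_calling import call_sites_for_condition
from spongeclip.synthetic_data import read_tags_bed

SIM = Path("results/simulated")
OUT = Path("results")
CONTROL, TREATED = "control", "tgfb4h"


def main() -> None:
    ts = select_longest_per_gene(load_annotation(SIM / "transcripts.gtf", SIM / "transcripts.fa"))
    pooled = merge_replicates(read_tags_bed(SIM / "tags.bed"))
    caller = CallerConfig()
    regions_c = regions_for_condition(call_sites_for_condition(pooled, ts, caller, CONTROL), ts)
    regions_t = regions_for_condition(call_sites_for_condition(pooled, ts, caller, TREATED), ts)
    regions_t = select_condition_specific(regions_t, regions_c)

    write_regions_tsv(regions_t, OUT / f"regions_{TREATED}.tsv")
    specific = [r for r in regions_t if r.treatment_specific]
    SeqIO.write(extract_region_sequences(specific, ts), OUT / "specific_region_seqs.fa", "fasta")

    n_sponge = sum(r.transcript_id == "tx01" for r in specific)
    print(f"{len(regions_t)} treated binding regions, {len(specific)} treatment-specific "
          f"({n_sponge} on the sponge transcript tx01)")
    print(f"-> results/regions_{TREATED}.tsv, results/specific_region_seqs.fa")


if __name__ == "__main__":
    main()
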