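#!/usr/bin/env python
"""Clean the OTU table and build the phylum relative-abundance matrix.

Steps, in order: drop chloroplast/mitochondria OTUs, drop OTUs not reaching
10 reads in at least 3 samples, rarefy every sample to 39,680 reads
(seed 150517), and aggregate to phylum relative abundances.
"""

from pathlib import Path

from picong.io_tables import read_otu_table, write_otu_table
from picong.preprocess import (
    RarefactionSpec,
    aggregate_to_rank,
    filter_rare_otus,
    rarefy,
    remove_organelles,
)

REPO = Path(__file__).resolve().parents[1]
WORK = REPO / "scratch"  # bulky intermediates
DATA = WORK / "data"


def main() -> None:
    table = read_otu_table(DATA / "otu_counts.tsv", DATA / "taxonomy.tsv")
    n0 = len(table.otu_ids)
    table = remove_organelles(table)
    table = filter_rare_otus(table)
    n1 = len(table.otu_ids)
    table = rarefy(table, RarefactionSpec())
    community = aggregate_to_rank(table, "Phylum")

    write_otu_table(table, WORK / "otu_rarefied.tsv", WORK / "taxonomy_rarefied.tsv")
    community.values.to_csv(WORK / "phylum_matrix.tsv", sep="\t", index_label="sample_id")

    print(f"OTUs: {n0} -> {n1} after organelle + rare filters, "
          f"{len(table.otu_ids)} after rarefaction")
    print(f"rarefied to {int(table.sample_totals.iloc[0])} reads/sample; "
          f"grand total {int(table.counts.to_numpy().sum())}")
    print(f"phylum matrix: {community.values.shape[0]} samples x "
          f"{community.values.shape[1]} phyla -> {WORK / 'phylum_matrix.tsv'}")


if __name__ == "__main__":
    main()
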