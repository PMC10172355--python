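#!/usr/bin/env python
"""Generate the study-shaped synthetic inputs.

Writes an OTU count table with taxonomy, sample metadata, a CARD-FISH
proportion block and the planted ground-truth labels to results/data/.
The defaults emulate the study design: ~90 samples from 3 stations x 12
months x station-specific depth levels, library sizes averaging ~134k reads,
24 phyla with 4 planted phylum-composition clusters and 9 planted CARD-FISH
clusters.
"""

from pathlib import Path

from picong.io_tables import write_cardfish, write_metadata, write_otu_table
from picong.synthetic_data import SimulationSpec, simulate_cardfish, simulate_otu_table

OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"
SEED = 20260920


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SimulationSpec(seed=SEED)
    table, metadata, truth = simulate_otu_table(spec)
    cardfish = simulate_cardfish(spec)

    write_otu_table(table, OUT / "otu_counts.tsv", OUT / "taxonomy.tsv")
    write_metadata(metadata, OUT / "metadata.csv")
    write_cardfish(cardfish, OUT / "cardfish.tsv")
    truth.labels.to_frame().to_csv(OUT / "ground_truth_phylum_labels.tsv", sep="\t")
    cardfish.cluster_labels.to_frame().to_csv(
        OUT / "ground_truth_cardfish_labels.tsv", sep="\t"
    )
    truth.centroids.to_csv(OUT / "ground_truth_centroids.tsv", sep="\t")

    totals = table.sample_totals
    print(f"simulated {table.counts.shape[1]} samples x {table.counts.shape[0]} OTUs")
    print(f"library sizes: {totals.min()}-{totals.max()} (mean {totals.mean():.0f})")
    print(f"planted phylum clusters: {truth.labels.value_counts().sort_index().tolist()}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
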