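#!/usr/bin/env python
"""Train the two neural-gas models and assign best-match units.

Model 1 (CFBMU): 9 units on the 5-probe CARD-FISH block.
Model 2 (PHBMU): 4 units on the 24-phylum relative-abundance matrix.
Both use 1000 epochs, initial step size 0.5, initial neighbourhood range 4.5.
Recovery of the planted clusters is scored with the adjusted Rand index.
"""

from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from picong.io_tables import read_cardfish
from picong.neural_gas import NGConfig, assign_bmu, quantization_error, save_assignment, save_model, train_ng
from picong.preprocess import CommunityMatrix, build_ng_matrix, cardfish_matrix

REPO = Path(__file__).resolve().parents[1]
ROOT = REPO / "results"
WORK = REPO / "scratch"
DATA = WORK / "data"
SEED = 20260920


def train_one(name: str, X: CommunityMatrix, n_units: int, truth_path: Path) -> None:
    model = train_ng(X, NGConfig(n_units=n_units, seed=SEED))
    assignment = assign_bmu(model, X)
    save_model(model, ROOT / f"{name}_codebook.tsv", ROOT / f"{name}_config.json")
    save_assignment(assignment, ROOT / f"{name}_assignments.tsv")
    qe = quantization_error(model, X)

    truth = pd.read_csv(truth_path, sep="\t", index_col=0)["cluster"]
    ari = adjusted_rand_score(
        truth.reindex(assignment.sample_ids).to_numpy(), assignment.labels.to_numpy()
    )
    occ = assignment.labels.value_counts().sort_index()
    print(f"{name}: {n_units} units, QE {qe:.4f}, ARI vs planted {ari:.3f}, "
          f"occupancy {occ.tolist()}")


def main() -> None:
    cardfish = cardfish_matrix(read_cardfish(DATA / "cardfish.tsv"))
    train_one("cfbmu", build_ng_matrix(cardfish), 9,
              DATA / "ground_truth_cardfish_labels.tsv")

    ROOT.mkdir(exist_ok=True)
    phyla = pd.read_csv(WORK / "phylum_matrix.tsv", sep="\t", index_col=0)
    community = CommunityMatrix(phyla, "phylum_relative_abundance")
    train_one("phbmu", build_ng_matrix(community), 4,
              DATA / "ground_truth_phylum_labels.tsv")


if __name__ == "__main__":
    main()
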