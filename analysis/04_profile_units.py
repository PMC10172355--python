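#!/usr/bin/env python
"""Characterize each best-match unit: occupancy, dominant community features,
covariate averages, and station/month/depth cross-tabulations."""

from pathlib import Path

import pandas as pd

from picong.bmu_profile import cross_tabulate, dominant_features, occupancy_percent, profile_bmus
from picong.io_tables import read_cardfish, read_metadata, write_profile_report
from picong.neural_gas import load_assignment
from picong.preprocess import CommunityMatrix, cardfish_matrix

REPO = Path(__file__).resolve().parents[1]
ROOT = REPO / "results"
WORK = REPO / "scratch"
DATA = WORK / "data"


def profile_model(name: str, community: CommunityMatrix, metadata) -> None:
    assignment = load_assignment(ROOT / f"{name}_assignments.tsv")
    n_units = int(assignment.labels.max()) + 1
    profiles = profile_bmus(assignment, community, metadata, n_units=n_units)
    write_profile_report(profiles, ROOT / f"{name}_profiles.tsv")

    counts = [p.n_members for p in profiles]
    pct = occupancy_percent(counts, decimals=1)
    print(f"\n{name.upper()}: occupancy " +
          ", ".join(f"unit{p.unit + 1} {p.n_members} ({pct[i]}%)"
                    for i, p in enumerate(profiles)))
    for prof in profiles:
        top = dominant_features(prof, 2)
        if top:
            lead = prof.stats[top[0]]
            print(f"  unit {prof.unit + 1}: dominated by {top[0]} "
                  f"(mean {lead.mean:.3g}), then {top[1] if len(top) > 1 else '-'}")
    if metadata is not None:
        for factor in ("station", "month", "depth"):
            tab = cross_tabulate(assignment, metadata, factor, n_units=n_units)
            tab.to_csv(ROOT / f"{name}_crosstab_{factor}.tsv", sep="\t")


def main() -> None:
    metadata = read_metadata(DATA / "metadata.csv")

    cardfish = cardfish_matrix(read_cardfish(DATA / "cardfish.tsv"))
    # CARD-FISH samples carry their own IDs; covariates are profiled for the
    # phylum model where sample IDs are shared with the metadata
    profile_model("cfbmu", cardfish, None)

    phyla = pd.read_csv(WORK / "phylum_matrix.tsv", sep="\t", index_col=0)
    profile_model("phbmu", CommunityMatrix(phyla, "phylum_relative_abundance"), metadata)
    print(f"\nprofiles and cross-tabulations in {ROOT}")


if __name__ == "__main__":
    main()
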