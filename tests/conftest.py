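import numpy as np
import pandas as pd
import pytest

from picong.io_tables import RANKS, OtuTable, SampleMetadata


def make_otu_table(counts: dict[str, list[int]], sample_ids: list[str],
                   taxonomy: dict[str, dict[str, str]] | None = None) -> OtuTable:
    """Build a small OtuTable; taxonomy defaults to all-bacterial, one phylum."""
    frame = pd.DataFrame.from_dict(counts, orient="index", columns=sample_ids)
    tax_rows = {}
    for otu in frame.index:
        row = {r: "" for r in RANKS}
        row.update({"Kingdom": "Bacteria", "Phylum": "Proteobacteria"})
        if taxonomy and otu in taxonomy:
            row.update(taxonomy[otu])
        tax_rows[otu] = row
    return OtuTable(frame.astype(np.int64), pd.DataFrame.from_dict(tax_rows, orient="index"))


@pytest.fixture
def toy_table() -> OtuTable:
    return make_otu_table(
        {"OTU1": [30, 10, 5, 0], "OTU2": [10, 10, 10, 10], "OTU3": [0, 20, 25, 30]},
        ["S1", "S2", "S3", "S4"],
        taxonomy={
            "OTU2": {"Kingdom": "Archaea", "Phylum": "Thermoplasmatota"},
            "OTU3": {"Phylum": "Bacteroidota"},
        },
    )


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    frame = pd.DataFrame(
        {
            "station": ["ST101", "ST101", "CJ007", "CJ009"],
            "month": [1, 2, 1, 2],
            "depth": [0.0, 35.0, 30.0, 100.0],
            "Temp": [14.0, 15.0, 18.0, np.nan],
            "Sal": [38.0, 38.2, 38.4, 38.9],
            "NO3": [1.0, 0.8, 1.2, 0.9],
            "NO2": [0.2, 0.1, 0.15, 0.1],
            "NH4": [0.3, 0.2, 0.25, 0.3],
        },
        index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
    )
    return SampleMetadata(frame)
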