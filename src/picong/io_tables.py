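"""Tabular I/O for the pipeline: OTU count/taxonomy tables, sample metadata,
CARD-FISH proportion tables, and the formatted per-unit report.

On-disk conventions: tab-delimited UTF-8 with a header row for counts,
taxonomy and report outputs (OTUs as rows, samples as columns — the common
amplicon layout); comma-delimited for sample metadata. Taxonomy ranks are
separate columns ordered Kingdom → Genus, never a single semicolon string.
All tables are canonicalised to ID-sorted order on read, so row/column
permutations of the input files load to the same object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Taxonomic ranks carried with every OTU, in canonical order.
RANKS: tuple[str, ...] = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus")

#: CARD-FISH probes quantified as percent of DAPI-stained cells.
CARDFISH_GROUPS: tuple[str, ...] = (
    "ROS537", "SAR11_441R", "GAM42A", "CF319A", "ALF968",
)

#: Environmental + biological covariates attached to each sample.
#: Temp (degC), Sal (PSU), nutrients (umol/L), Chl_a (ug/L), cell
#: abundances (cells/mL), BP (bacterial production rate).
COVARIATES: tuple[str, ...] = (
    "Temp", "Sal", "NO3", "NO2", "NH4", "DIN", "NTOT", "SRP", "PTOT",
    "SiO4", "Chl_a", "UHB", "HIGH", "SYN", "PROCHL", "PE", "HNF", "AAP", "BP",
)

DESIGN_COLUMNS: tuple[str, ...] = ("station", "month", "depth")


class TableFormatError(ValueError):
    """Malformed input table (duplicate IDs, negative/non-integer counts...)."""


class TableConsistencyError(ValueError):
    """Cross-table inconsistency (e.g. an OTU missing from the taxonomy)."""


@dataclass
class OtuTable:
    """Integer OTU count matrix with linked taxonomy.

    ``counts``: OTUs (rows) x samples (columns), non-negative integers.
    ``taxonomy``: one row per OTU, columns = :data:`RANKS`; missing ranks
    are empty strings.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.sort_index(axis=0).sort_index(axis=1)
        self.taxonomy = self.taxonomy.reindex(columns=list(RANKS)).fillna("")
        self.taxonomy = self.taxonomy.loc[self.counts.index]
        self.validate()

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            raise TableFormatError("duplicate OTU IDs in count table")
        if self.counts.columns.has_duplicates:
            raise TableFormatError("duplicate sample IDs in count table")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise TableFormatError("counts must be integral")
            self.counts = self.counts.round().astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise TableFormatError("counts must be non-negative")
        missing = self.counts.index.difference(self.taxonomy.dropna(how="all").index)
        if len(missing):
            raise TableConsistencyError(
                f"OTUs missing from taxonomy: {', '.join(map(str, missing[:5]))}"
            )

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_otus(self, keep: Sequence[str] | pd.Index) -> "OtuTable":
        keep = pd.Index(keep)
        return OtuTable(self.counts.loc[keep].copy(), self.taxonomy.loc[keep].copy())

    def copy(self) -> "OtuTable":
        return OtuTable(self.counts.copy(), self.taxonomy.copy())


@dataclass
class SampleMetadata:
    """Per-sample design labels (station, month, depth) plus covariates.

    Backed by a DataFrame indexed by sample_id. Missing covariates stay
    missing (NaN); DIN is recomputed as NO3+NO2+NH4 when those three are
    present, and a recomputed value wins over an inconsistent stored one.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise TableFormatError(f"duplicate sample_id: {', '.join(map(str, dupes[:5]))}")
        self.data = self.data.sort_index()
        if "depth" in self.data.columns:
            depth = pd.to_numeric(self.data["depth"], errors="coerce")
            if (depth.dropna() < 0).any():
                raise TableFormatError("depth must be >= 0")
        self._reconcile_din()

    def _reconcile_din(self) -> None:
        cols = self.data.columns
        if not {"NO3", "NO2", "NH4"}.issubset(cols):
            return
        derived = self.data["NO3"] + self.data["NO2"] + self.data["NH4"]
        if "DIN" not in cols:
            self.data["DIN"] = derived
            return
        stored = self.data["DIN"]
        fill = stored.isna() & derived.notna()
        disagree = stored.notna() & derived.notna() & ((stored - derived).abs() > 1e-6)
        if disagree.any():
            logger.warning(
                "DIN disagrees with NO3+NO2+NH4 for %d sample(s); recomputed value kept",
                int(disagree.sum()),
            )
        self.data.loc[fill | disagree, "DIN"] = derived[fill | disagree]

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def covariate_frame(self) -> pd.DataFrame:
        """Numeric covariates (plus depth) available for unit profiling."""
        cols = [c for c in self.data.columns if c in COVARIATES]
        frame = self.data[cols].apply(pd.to_numeric, errors="coerce")
        if "depth" in self.data.columns:
            frame = frame.copy()
            frame.insert(0, "depth", pd.to_numeric(self.data["depth"], errors="coerce"))
        return frame


@dataclass
class CardFishTable:
    """CARD-FISH probe proportions (percent of DAPI counts) per sample.

    Probes overlap (ALF968 contains SAR11_441R and ROS537), so only the
    per-cell range [0, 100] is enforced, never a per-sample sum.
    """

    values: pd.DataFrame
    cluster_labels: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [g for g in CARDFISH_GROUPS if g not in self.values.columns]
        if missing:
            raise TableFormatError(f"missing CARD-FISH groups: {missing}")
        self.values = self.values[list(CARDFISH_GROUPS)].sort_index()
        if self.values.index.has_duplicates:
            raise TableFormatError("duplicate sample IDs in CARD-FISH table")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 100:
            raise TableFormatError("CARD-FISH proportions must lie in [0, 100]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(counts_path: str | Path, taxonomy_path: str | Path) -> OtuTable:
    """Load an OTU count TSV (first column = OTU ID) and its taxonomy TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        raise TableFormatError(f"duplicate OTU IDs in {counts_path}")
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
    if taxonomy.index.has_duplicates:
        raise TableFormatError(f"duplicate OTU IDs in {taxonomy_path}")
    taxonomy = taxonomy.fillna("")
    missing = counts.index.difference(taxonomy.index)
    if len(missing):
        raise TableConsistencyError(
            f"taxonomy lacks OTU(s): {', '.join(map(str, missing[:5]))}"
        )
    values = counts.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise TableFormatError("non-integer counts in count table")
    if (values < 0).any():
        raise TableFormatError("negative counts in count table")
    return OtuTable(counts.astype(np.int64), taxonomy.loc[counts.index])


def write_otu_table(table: OtuTable, counts_path: str | Path, taxonomy_path: str | Path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="otu_id")
    table.taxonomy.to_csv(taxonomy_path, sep="\t", index_label="otu_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Load the sample metadata CSV (must contain a sample_id column)."""
    frame = pd.read_csv(path)
    if "sample_id" not in frame.columns:
        raise TableFormatError(f"{path} lacks a sample_id column")
    frame = frame.set_index("sample_id")
    return SampleMetadata(frame)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.data.to_csv(path, index_label="sample_id")


def read_cardfish(path: str | Path) -> CardFishTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return CardFishTable(frame)


def write_cardfish(table: CardFishTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# formatted per-unit report
# ---------------------------------------------------------------------------

def format_stat_cell(
    mean: float, sd: float, vmin: float, vmax: float, decimals: int = 3
) -> str:
    """Render one summary cell as ``mean (± SD; min, max)``."""
    if any(pd.isna(v) for v in (mean, sd, vmin, vmax)):
        return "NA"
    fmt = f"{{:.{decimals}f}}"
    return (
        f"{fmt.format(mean)} (± {fmt.format(sd)}; "
        f"{fmt.format(vmin)}, {fmt.format(vmax)})"
    )


def write_profile_report(profiles, path: str | Path, decimals: int = 3) -> pd.DataFrame:
    """Write per-unit summaries as a TSV: one row per variable, one column
    per unit, cells formatted ``mean (± SD; min, max)``; empty units -> NA.

    Returns the formatted DataFrame that was written.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to report")
    variables: list[str] = []
    for prof in profiles:
        for var in prof.stats:
            if var not in variables:
                variables.append(var)
    columns = {}
    for prof in profiles:
        cells = []
        for var in variables:
            st = prof.stats.get(var)
            if st is None or st.n == 0:
                cells.append("NA")
            else:
                cells.append(format_stat_cell(st.mean, st.sd, st.min, st.max, decimals))
        columns[f"BMU{prof.unit + 1}"] = cells
    report = pd.DataFrame(columns, index=pd.Index(variables, name="variable"))
    report.to_csv(path, sep="\t")
    return report
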