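"""OTU-table cleanup and construction of the quantizer input matrix.

The fixed post-clustering order is: organelle removal -> rare-OTU
prevalence/abundance filter -> rarefaction to even depth -> aggregation to a
taxonomic rank as relative abundances. Rarefaction is exact multivariate
hypergeometric subsampling (without replacement), seeded, with samples
processed in sorted-ID order so a run is reproducible across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .io_tables import RANKS, CardFishTable, OtuTable

logger = logging.getLogger(__name__)

#: Rarefaction defaults: the study depth (the smallest retained library) and
#: the fixed reproducibility seed.
DEFAULT_RAREFACTION_DEPTH = 39_680
DEFAULT_RAREFACTION_SEED = 150_517

FeatureKind = Literal["cardfish_proportions", "phylum_relative_abundance", "rank_relative_abundance"]


@dataclass
class RarefactionSpec:
    depth: int = DEFAULT_RAREFACTION_DEPTH
    seed: int = DEFAULT_RAREFACTION_SEED

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("rarefaction depth must be >= 1")


@dataclass
class CommunityMatrix:
    """Samples (rows) x named community features (columns), non-negative.

    Rows of a relative-abundance matrix sum to 1; CARD-FISH proportions are
    percent-of-DAPI and carry no row-sum constraint.
    """

    values: pd.DataFrame
    feature_kind: str

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample IDs in community matrix")
        arr = self.values.to_numpy(dtype=float)
        raw_kind = self.feature_kind in (
            "cardfish_proportions",
            "phylum_relative_abundance",
            "rank_relative_abundance",
        )
        if raw_kind and arr.size and np.nanmin(arr) < -1e-12:
            raise ValueError("community matrix must be non-negative")
        if self.feature_kind.endswith("relative_abundance") and arr.size:
            sums = np.nansum(arr, axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative-abundance rows must sum to 1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> pd.Index:
        return self.values.columns


def remove_organelles(table: OtuTable) -> OtuTable:
    """Drop OTUs whose any taxonomy rank equals 'chloroplast' or
    'mitochondria' (case-insensitive); counts of retained OTUs unchanged."""
    tax = table.taxonomy.astype(str).apply(lambda col: col.str.strip().str.lower())
    organelle = tax.isin(["chloroplast", "mitochondria"]).any(axis=1)
    if organelle.any():
        logger.info("removed %d organelle OTU(s)", int(organelle.sum()))
    return table.subset_otus(table.otu_ids[~organelle.to_numpy()])


def filter_rare_otus(table: OtuTable, min_count: int = 10, min_samples: int = 3) -> OtuTable:
    """Prevalence/abundance filter: keep an OTU iff its count reaches
    ``min_count`` in at least ``min_samples`` samples."""
    if min_count < 1 or min_samples < 1:
        raise ValueError("min_count and min_samples must be >= 1")
    qualifying = (table.counts >= min_count).sum(axis=1)
    keep = qualifying >= min_samples
    return table.subset_otus(table.otu_ids[keep.to_numpy()])


def rarefy(table: OtuTable, spec: RarefactionSpec | None = None) -> OtuTable:
    """Subsample each sample without replacement to exactly ``spec.depth``
    reads (multivariate hypergeometric). Samples shallower than the depth are
    dropped with a warning; OTUs left with all-zero rows are dropped.
    Deterministic for a given seed.
    """
    spec = spec or RarefactionSpec()
    totals = table.sample_totals
    deep_enough = totals >= spec.depth
    if not deep_enough.any():
        raise ValueError(
            f"rarefaction depth {spec.depth} exceeds every sample total "
            f"(max {int(totals.max())})"
        )
    dropped = totals.index[~deep_enough]
    if len(dropped):
        logger.warning(
            "dropping %d sample(s) shallower than depth %d: %s",
            len(dropped), spec.depth, ", ".join(map(str, dropped[:5])),
        )
    rng = np.random.default_rng(spec.seed)
    kept_samples = sorted(totals.index[deep_enough])
    out = {}
    for sample in kept_samples:  # sorted order fixes the RNG stream
        col = table.counts[sample].to_numpy()
        if col.sum() == spec.depth:
            out[sample] = col
        else:
            out[sample] = rng.multivariate_hypergeometric(col, spec.depth)
    rare = pd.DataFrame(out, index=table.otu_ids)
    nonzero = rare.sum(axis=1) > 0
    rare = rare.loc[nonzero]
    return OtuTable(rare.astype(np.int64), table.taxonomy.loc[rare.index].copy())


def aggregate_to_rank(table: OtuTable, rank: str = "Phylum") -> CommunityMatrix:
    """Sum counts within each taxon at ``rank`` per sample and divide by the
    sample total: a relative-abundance matrix whose rows sum to 1. OTUs
    without a label at that rank pool into ``unclassified_<rank>``."""
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    totals = table.sample_totals
    if (totals == 0).any():
        zero = totals.index[totals == 0]
        raise ValueError(f"sample(s) with zero total counts: {', '.join(map(str, zero[:5]))}")
    labels = table.taxonomy[rank].astype(str).str.strip()
    labels = labels.where(labels != "", f"unclassified_{rank.lower()}")
    summed = table.counts.groupby(labels).sum()
    rel = (summed / totals).T.sort_index(axis=1)
    kind = "phylum_relative_abundance" if rank == "Phylum" else "rank_relative_abundance"
    return CommunityMatrix(rel, kind)


def cardfish_matrix(table: CardFishTable) -> CommunityMatrix:
    """View a CARD-FISH table as a quantizer-ready community matrix."""
    if table.values.isna().any().any():
        bad = table.values.index[table.values.isna().any(axis=1)]
        raise ValueError(f"missing CARD-FISH values for: {', '.join(map(str, bad[:5]))}")
    return CommunityMatrix(table.values.astype(float), "cardfish_proportions")


def build_ng_matrix(community: CommunityMatrix, standardize: bool = False) -> CommunityMatrix:
    """The quantizer training space: the community block only (covariates are
    never trained on). Optional per-feature z-scoring; constant columns map
    to zeros with a warning."""
    values = community.values
    if values.isna().any().any():
        bad = values.index[values.isna().any(axis=1)]
        raise ValueError(
            f"missing community values for sample(s): {', '.join(map(str, bad[:5]))}"
        )
    if not standardize:
        return CommunityMatrix(values.copy(), community.feature_kind)
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "constant feature(s) mapped to zeros under standardization: %s",
            ", ".join(values.columns[constant]),
        )
    safe_sd = np.where(constant, 1.0, sd)
    scaled = (arr - mean) / safe_sd
    scaled[:, constant] = 0.0
    frame = pd.DataFrame(scaled, index=values.index, columns=values.columns)
    return CommunityMatrix(frame, "standardized")
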