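"""Per-unit characterization: occupancy, member lists, covariate and
community-feature summaries, dominant features, and design cross-tabulations.

Each trained unit is described by the average of every ecological variable
over the samples it claims; missing covariates are excluded pairwise, so a
mean is always over the members that actually carry the value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_tables import SampleMetadata
from .neural_gas import BmuAssignment
from .preprocess import CommunityMatrix


@dataclass(frozen=True)
class VariableStats:
    mean: float
    sd: float
    min: float
    max: float
    n: int


@dataclass
class BmuProfile:
    unit: int
    n_members: int
    occupancy: float
    member_ids: tuple[str, ...]
    stats: dict[str, VariableStats] = field(default_factory=dict)
    community_features: tuple[str, ...] = ()


def _column_stats(values: pd.Series) -> VariableStats:
    clean = values.dropna()
    n = int(clean.size)
    if n == 0:
        return VariableStats(np.nan, np.nan, np.nan, np.nan, 0)
    sd = float(clean.std(ddof=1)) if n > 1 else 0.0
    return VariableStats(float(clean.mean()), sd, float(clean.min()), float(clean.max()), n)


def profile_bmus(
    assignment: BmuAssignment,
    community: CommunityMatrix | None = None,
    metadata: SampleMetadata | None = None,
    n_units: int | None = None,
) -> list[BmuProfile]:
    """One profile per unit (empty units included, occupancy 0).

    Occupancy is n_members / n_assigned_samples; summaries cover the
    community features and every numeric covariate in the metadata.
    """
    labels = assignment.labels
    n_samples = len(labels)
    if n_units is None:
        n_units = int(labels.max()) + 1 if n_samples else 0

    blocks: list[pd.DataFrame] = []
    community_features: tuple[str, ...] = ()
    if community is not None:
        comm = community.values.reindex(labels.index)
        missing = comm.index[comm.isna().all(axis=1)]
        if len(missing):
            raise KeyError(
                f"assigned sample(s) missing from community matrix: "
                f"{', '.join(map(str, missing[:5]))}"
            )
        community_features = tuple(comm.columns)
        blocks.append(comm)
    if metadata is not None:
        absent = labels.index.difference(metadata.sample_ids)
        if len(absent):
            raise KeyError(
                f"assigned sample(s) missing from metadata: "
                f"{', '.join(map(str, absent[:5]))}"
            )
        blocks.append(metadata.covariate_frame().reindex(labels.index))
    variables = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=labels.index)

    profiles = []
    for unit in range(n_units):
        members = labels.index[labels.to_numpy() == unit]
        sub = variables.loc[members]
        stats = {str(col): _column_stats(sub[col]) for col in variables.columns}
        profiles.append(
            BmuProfile(
                unit=unit,
                n_members=len(members),
                occupancy=len(members) / n_samples if n_samples else 0.0,
                member_ids=tuple(map(str, members)),
                stats=stats,
                community_features=tuple(map(str, community_features)),
            )
        )
    return profiles


def dominant_features(profile: BmuProfile, k: int = 1) -> list[str]:
    """Top-k community features by within-unit mean; ties broken
    alphabetically; empty unit -> empty list."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if profile.n_members == 0:
        return []
    feats = [f for f in profile.community_features if f in profile.stats]
    ordered = sorted(feats, key=lambda f: (-profile.stats[f].mean, f))
    return ordered[:k]


def occupancy_percent(
    counts: Iterable[int], total: int | None = None, decimals: int = 0
) -> np.ndarray:
    """Unit occupancies as percentages, rounded half-even to ``decimals``.

    ``total`` defaults to the sum of the counts; pass the study design size
    explicitly when the reporting denominator differs from the classified
    sample count.
    """
    counts = np.asarray(list(counts), dtype=float)
    denom = float(total) if total is not None else counts.sum()
    if denom <= 0:
        raise ValueError("total must be positive")
    return np.round(100.0 * counts / denom, decimals)


def cross_tabulate(
    assignment: BmuAssignment,
    metadata: SampleMetadata,
    factor: str,
    n_units: int | None = None,
) -> pd.DataFrame:
    """Units x factor-level contingency table for station, month or depth.

    Depth is tabulated on its sampled levels (a DCM label stays a label);
    marginals equal the unit occupancy counts and the factor totals.
    """
    if factor not in ("station", "month", "depth"):
        raise ValueError("factor must be one of station, month, depth")
    column = "depth_label" if factor == "depth" and "depth_label" in metadata.data.columns else factor
    if column not in metadata.data.columns:
        raise ValueError(f"metadata lacks a {factor} column")
    labels = assignment.labels
    absent = labels.index.difference(metadata.sample_ids)
    if len(absent):
        raise KeyError(f"sample(s) missing from metadata: {', '.join(map(str, absent[:5]))}")
    levels = metadata.data.loc[labels.index, column]
    table = pd.crosstab(labels, levels)
    table.index.name = "unit"
    if n_units is not None:
        table = table.reindex(pd.RangeIndex(n_units, name="unit"), fill_value=0)
    return table
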