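"""Alpha diversity on the rarefied, untransformed OTU table.

Shannon index H' = -sum p_i ln p_i (nats), Pielou evenness J' = H'/ln(S),
observed richness S, computed per sample and per kingdom (Archaea vs
Bacteria), then summarized per best-match unit as mean (± SD; min, max).
The rarefaction curve is the exact hypergeometric expectation of richness
at a subsampling depth (Hurlbert's E[S_d]), not a Monte-Carlo average.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_tables import OtuTable, format_stat_cell
from .neural_gas import BmuAssignment

logger = logging.getLogger(__name__)

KINGDOMS = ("Archaea", "Bacteria")
_METRICS = ("richness", "shannon", "pielou")
_METRIC_TITLES = {
    "richness": "species number",
    "shannon": "diversity (Shannon index)",
    "pielou": "evenness (Pielou's index)",
}


def shannon(counts: Iterable[float]) -> float:
    """Shannon index in nats over the positive entries of a count vector."""
    arr = np.asarray(list(counts), dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def evenness(h: float, richness: float) -> float:
    """Pielou's J' = H'/ln(S) for a given Shannon value and richness."""
    if richness <= 1:
        return float("nan")
    return float(h / np.log(richness))


def pielou(counts: Iterable[float]) -> float:
    """Pielou evenness of a count vector; NaN when fewer than 2 taxa occur."""
    arr = np.asarray(list(counts), dtype=float)
    s = int((arr > 0).sum())
    if s <= 1:
        return float("nan")
    return evenness(shannon(arr), s)


def diversity_by_kingdom(table: OtuTable) -> pd.DataFrame:
    """Per-(sample, kingdom) richness S, Shannon H' and Pielou J'.

    Kingdom labels other than Archaea/Bacteria are excluded with a logged
    count; a sample with zero counts in a kingdom yields no record.
    """
    kingdom = table.taxonomy["Kingdom"].astype(str).str.strip()
    known = kingdom.isin(KINGDOMS)
    if (~known).any():
        logger.warning(
            "excluding %d OTU(s) with unknown kingdom label(s)", int((~known).sum())
        )
    records = []
    for kd in KINGDOMS:
        sub = table.counts.loc[(kingdom == kd).to_numpy()]
        if sub.empty:
            continue
        for sample in sub.columns:
            col = sub[sample].to_numpy()
            s = int((col > 0).sum())
            if s == 0:
                continue
            h = shannon(col)
            records.append(
                {
                    "sample_id": sample,
                    "kingdom": kd,
                    "richness": s,
                    "shannon": h,
                    "pielou": evenness(h, s),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["sample_id", "kingdom", "richness", "shannon", "pielou"]
    )


def summarize_diversity_by_bmu(
    records: pd.DataFrame, assignment: BmuAssignment, n_units: int | None = None
) -> pd.DataFrame:
    """Tidy per-(unit, kingdom, metric) summary: mean, sd, min, max, n.

    Per-sample values are averaged within each unit (evenness is the mean of
    per-sample J', not J' of the mean composition).
    """
    unknown = set(records["sample_id"]) - set(assignment.sample_ids)
    if unknown:
        raise KeyError(f"records for unassigned sample(s): {sorted(unknown)[:5]}")
    if n_units is None:
        n_units = int(assignment.labels.max()) + 1
    merged = records.merge(
        assignment.labels.rename("unit"), left_on="sample_id", right_index=True
    )
    rows = []
    for unit in range(n_units):
        for kd in KINGDOMS:
            sub = merged[(merged["unit"] == unit) & (merged["kingdom"] == kd)]
            n_members = int(assignment.labels.eq(unit).sum())
            for metric in _METRICS:
                vals = sub[metric].dropna()
                n = int(vals.size)
                rows.append(
                    {
                        "unit": unit,
                        "kingdom": kd,
                        "metric": metric,
                        "mean": float(vals.mean()) if n else np.nan,
                        "sd": (float(vals.std(ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan)),
                        "min": float(vals.min()) if n else np.nan,
                        "max": float(vals.max()) if n else np.nan,
                        "n": n,
                        "n_members": n_members,
                    }
                )
    return pd.DataFrame(rows)


def format_diversity_table(summary: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    """Render the per-unit diversity summary in the publication layout:
    a sample-count row plus one ``mean (± SD; min, max)`` row per
    kingdom x metric, one column per unit."""
    units = sorted(summary["unit"].unique())
    columns = [f"PHBMU{u + 1}" for u in units]
    data: dict[str, list[str]] = {c: [] for c in columns}
    index = ["Number of samples"]
    for u, c in zip(units, columns):
        n_members = summary.loc[summary["unit"] == u, "n_members"].iloc[0]
        data[c].append(str(int(n_members)))
    for kd in KINGDOMS:
        for metric in _METRICS:
            adjective = {"Archaea": "archaeal", "Bacteria": "bacterial"}[kd]
            index.append(f"Average {adjective} {_METRIC_TITLES[metric]} (± S.D; min, max)")
            for u, c in zip(units, columns):
                row = summary[
                    (summary["unit"] == u)
                    & (summary["kingdom"] == kd)
                    & (summary["metric"] == metric)
                ].iloc[0]
                data[c].append(
                    format_stat_cell(row["mean"], row["sd"], row["min"], row["max"], decimals)
                )
    return pd.DataFrame(data, index=pd.Index(index, name="statistic"))


def rarefaction_curve(counts: Iterable[float], depths: Sequence[int]) -> np.ndarray:
    """Expected richness E[S_d] at each subsampling depth d (hypergeometric
    expectation): E[S_d] = sum_i (1 - C(N - N_i, d) / C(N, d)).

    Monotone non-decreasing and concave in d; depths above the sample total
    are rejected.
    """
    arr = np.asarray(list(counts), dtype=float)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("rarefaction curve undefined for an all-zero vector")
    total = arr.sum()
    depths = np.asarray(depths, dtype=int)
    if (depths < 1).any() or (depths > total).any():
        raise ValueError(f"depths must lie in [1, {int(total)}]")

    def log_choose(n: np.ndarray | float, k: float) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = np.empty(len(depths), dtype=float)
    for j, d in enumerate(depths):
        rest = total - arr  # reads not in taxon i
        term = np.zeros_like(arr)
        feasible = rest >= d  # else the taxon is always seen
        term[feasible] = np.exp(log_choose(rest[feasible], d) - log_choose(total, d))
        out[j] = float((1.0 - term).sum())
    return out
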