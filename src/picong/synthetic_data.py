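"""Study-shaped synthetic data with planted community structure.

Emulates a year of monthly picoplankton sampling at three Adriatic stations
(one coastal two-depth profile, one transitional three-depth profile, one
open-sea six-depth profile including a deep-chlorophyll-maximum level):

* an OTU count table: per sample, a planted cluster determines a phylum
  composition centroid; phylum proportions are drawn from a Dirichlet around
  that centroid, split into per-OTU proportions by fixed log-normal weights,
  and converted to counts by a multinomial at a library size drawn from a
  truncated log-normal (mean 134,328, SD 38,181, range 58,138-291,926);
* taxonomy over 24 phyla, ~10% of OTUs archaeal (Crenarchaeota,
  Thermoplasmatota), the rest bacterial with a Proteobacteria-dominated base;
* covariates whose means shift with the planted cluster (temperature,
  salinity, nitrate, ammonium, chlorophyll a) plus cluster-independent ones,
  all with Gaussian noise — clusters are independent of station/month/depth
  by construction;
* a 5-probe CARD-FISH block (percent of DAPI counts) from a logistic-normal
  around per-cluster centers, with the SAR11 probe never exceeding the
  Alphaproteobacteria probe that contains it.

The planted labels and centroids are returned as ground truth so the
quantization stage can be scored for cluster recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import expit, logit
from sklearn.metrics import adjusted_rand_score

from .io_tables import CARDFISH_GROUPS, RANKS, CardFishTable, OtuTable, SampleMetadata
from .neural_gas import BmuAssignment, NGConfig, assign_bmu, train_ng
from .preprocess import (
    RarefactionSpec,
    aggregate_to_rank,
    build_ng_matrix,
    filter_rare_otus,
    rarefy,
    remove_organelles,
)

#: 24 phyla; the two archaeal ones are listed first.
PHYLA: tuple[str, ...] = (
    "Thermoplasmatota", "Crenarchaeota",  # Archaea
    "Proteobacteria", "Cyanobacteria", "Bacteroidota", "Actinobacteriota",
    "Verrucomicrobiota", "Marinimicrobia", "Planctomycetota", "Chloroflexi",
    "Nitrospinota", "Gemmatimonadota", "Acidobacteriota", "Dadabacteria",
    "Desulfobacterota", "Firmicutes", "SAR324", "Myxococcota",
    "Bdellovibrionota", "Campilobacterota", "Fibrobacterota", "NB1-j",
    "PAUC34f", "Patescibacteria",
)
ARCHAEAL_PHYLA: tuple[str, ...] = ("Thermoplasmatota", "Crenarchaeota")

#: Oligotrophic-coastal base phylum composition (Proteobacteria-dominated,
#: Cyanobacteria ~ Bacteroidota next, archaea ~10% of reads).
_BASE_PHYLUM_PROPS: dict[str, float] = {
    "Thermoplasmatota": 0.06, "Crenarchaeota": 0.04,
    "Proteobacteria": 0.40, "Cyanobacteria": 0.12, "Bacteroidota": 0.10,
    "Actinobacteriota": 0.05, "Verrucomicrobiota": 0.04, "Marinimicrobia": 0.035,
    "Planctomycetota": 0.03, "Chloroflexi": 0.02, "Nitrospinota": 0.015,
    "Gemmatimonadota": 0.012, "Acidobacteriota": 0.012, "Dadabacteria": 0.01,
    "Desulfobacterota": 0.01, "Firmicutes": 0.008, "SAR324": 0.008,
    "Myxococcota": 0.007, "Bdellovibrionota": 0.006, "Campilobacterota": 0.005,
    "Fibrobacterota": 0.005, "NB1-j": 0.005, "PAUC34f": 0.004,
    "Patescibacteria": 0.003,
}

#: Baseline covariate levels (central Adriatic scales) and noise SDs.
_COVARIATE_BASE: dict[str, tuple[float, float]] = {
    # name: (mean, noise SD)
    "Temp": (16.0, 1.0), "Sal": (38.2, 0.15),
    "NO3": (1.0, 0.2), "NO2": (0.10, 0.03), "NH4": (0.30, 0.08),
    "NTOT": (6.0, 1.0), "SRP": (0.05, 0.015), "PTOT": (0.15, 0.04),
    "SiO4": (2.0, 0.5), "Chl_a": (0.20, 0.05),
    "UHB": (5e5, 1e5), "HIGH": (2e5, 5e4), "SYN": (1.2e4, 4e3),
    "PROCHL": (5e3, 2e3), "PE": (1.5e3, 5e2), "HNF": (6e2, 2e2),
    "AAP": (1.0e4, 3e3), "BP": (0.05, 0.02),
}

#: Cluster mean shifts (added to the base) cycling over planted clusters.
_COVARIATE_SHIFT_CYCLE: tuple[dict[str, float], ...] = (
    {"Temp": -3.0, "NH4": 0.25, "NTOT": 2.0},           # cold, ammonium-rich
    {"Sal": 0.6, "NO3": 0.8, "NO2": 0.08},              # saline, nitrate-rich
    {"Temp": 4.0, "Chl_a": 0.25, "NH4": 0.10},          # warm, productive
    {"Sal": -0.5, "NO3": 0.3, "Chl_a": 0.10},           # fresher coastal
    {"Temp": 2.0, "SRP": 0.03},
    {"Temp": -1.5, "Sal": 0.3},
    {"NO3": 0.5, "NH4": -0.1},
    {"Chl_a": 0.15, "Sal": -0.2},
    {"Temp": 1.0, "NO3": -0.3},
)

#: Per-cluster CARD-FISH centers (% of DAPI): ROS537, SAR11_441R, GAM42A,
#: CF319A, ALF968; SAR11 <= ALF968 (the alpha probe contains the SAR11 one).
DEFAULT_CARDFISH_CENTERS: np.ndarray = np.array(
    [
        [6.0, 38.0, 10.0, 10.0, 44.0],   # SAR11-dominated, productive
        [3.0, 20.0, 18.0, 15.0, 25.0],   # balanced "stand-by"
        [2.0, 12.0, 30.0, 18.0, 20.0],   # Gammaproteobacteria-dominated
        [7.0, 10.0, 12.0, 32.0, 18.0],   # Bacteroidetes-dominated
        [2.0, 22.0, 10.0, 8.0, 45.0],    # Alphaproteobacteria, deep saline
        [9.0, 12.0, 10.0, 35.0, 22.0],   # Bacteroidetes + Roseobacter
        [3.0, 25.0, 8.0, 6.0, 48.0],     # Alpha ~40% DAPI, open sea
        [3.0, 44.0, 10.0, 8.0, 50.0],    # SAR11 44%
        [2.0, 48.0, 6.0, 5.0, 55.0],     # SAR11 maximal, cold/fresh
    ]
)

DEFAULT_DEPTH_LEVELS: dict[str, tuple[object, ...]] = {
    "ST101": (0, 35),
    "CJ007": (0, 30, 50),
    "CJ009": (0, 30, 50, 75, 100, "DCM"),
}

#: Numeric stand-in (m) for the DCM label, for simulation only.
DCM_NUMERIC_DEPTH = 50.0


@dataclass
class SimulationSpec:
    """Generator settings; defaults reproduce the study's sampling design and
    sequencing-depth distribution."""

    n_samples: int = 90
    months: int = 12
    depth_levels: Mapping[str, Sequence[object]] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH_LEVELS)
    )
    n_otus: int = 900
    n_phyla: int = 24
    k_clusters: int = 4
    k_cardfish: int = 9
    dirichlet_concentration: float = 60.0
    signature_mix: float = 0.45  # mass moved onto cluster signature phyla
    library_mean: float = 134_328.0
    library_sd: float = 38_181.0
    library_min: float = 58_138.0
    library_max: float = 291_926.0
    archaea_fraction: float = 0.10
    otu_weight_sigma: float = 1.0  # log-normal spread of within-phylum OTU weights
    cardfish_centers: np.ndarray | None = None
    cardfish_noise: float = 0.25  # logit-scale SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_clusters > self.n_samples:
            raise ValueError("k_clusters cannot exceed n_samples")
        if self.k_clusters < 1 or self.k_cardfish < 1:
            raise ValueError("cluster counts must be positive")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        if not (0 < self.library_min <= self.library_max):
            raise ValueError("library-size truncation bounds must be positive")
        if self.n_phyla < 2 or self.n_phyla > len(PHYLA):
            raise ValueError(f"n_phyla must be in [2, {len(PHYLA)}]")
        if 2 * self.k_clusters > self.n_phyla:
            raise ValueError("need at least 2 signature phyla per cluster")
        centers = self.cardfish_centers
        if centers is None:
            centers = DEFAULT_CARDFISH_CENTERS[: self.k_cardfish]
            if len(centers) < self.k_cardfish:
                raise ValueError(
                    f"no default CARD-FISH centers beyond K={len(DEFAULT_CARDFISH_CENTERS)}"
                )
        centers = np.asarray(centers, dtype=float)
        if centers.shape != (self.k_cardfish, len(CARDFISH_GROUPS)):
            raise ValueError("cardfish_centers shape must be (k_cardfish, 5)")
        if (centers < 0).any() or (centers > 100).any():
            raise ValueError("CARD-FISH centers must lie in [0, 100]")
        sar11 = centers[:, CARDFISH_GROUPS.index("SAR11_441R")]
        alf = centers[:, CARDFISH_GROUPS.index("ALF968")]
        if (sar11 > alf).any():
            raise ValueError("SAR11_441R center exceeds ALF968 center (SAR11 is a subset)")
        self.cardfish_centers = centers


@dataclass
class GroundTruth:
    """Planted structure: per-sample cluster label, per-cluster phylum
    centroid (on the simplex) and per-cluster covariate means."""

    labels: pd.Series
    centroids: pd.DataFrame       # cluster x phylum
    covariate_means: pd.DataFrame  # cluster x covariate

    def __post_init__(self) -> None:
        sums = self.centroids.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("centroids must lie on the simplex")


def planted_centroids(spec: SimulationSpec) -> pd.DataFrame:
    """K phylum centroids: a common base mixed with disjoint two-phylum
    signatures, giving pairwise L1 separation of 2 * signature_mix."""
    phyla = list(PHYLA[: spec.n_phyla])
    base = np.array([_BASE_PHYLUM_PROPS[p] for p in phyla], dtype=float)
    base /= base.sum()
    # signature phyla: most-abundant bacterial phyla first, two per cluster
    order = [p for p in phyla if p not in ARCHAEAL_PHYLA]
    order = sorted(order, key=lambda p: -_BASE_PHYLUM_PROPS[p])
    centroids = np.empty((spec.k_clusters, len(phyla)))
    for j in range(spec.k_clusters):
        sig = np.zeros(len(phyla))
        for p in order[2 * j: 2 * j + 2]:
            sig[phyla.index(p)] = 0.5
        centroids[j] = (1 - spec.signature_mix) * base + spec.signature_mix * sig
    return pd.DataFrame(
        centroids, index=pd.RangeIndex(spec.k_clusters, name="cluster"), columns=phyla
    )


def _design_grid(spec: SimulationSpec) -> pd.DataFrame:
    rows = []
    for month in range(1, spec.months + 1):
        for station, depths in spec.depth_levels.items():
            for depth in depths:
                label = str(depth)
                numeric = DCM_NUMERIC_DEPTH if label == "DCM" else float(depth)
                rows.append(
                    {"station": station, "month": month, "depth": numeric, "depth_label": label}
                )
    return pd.DataFrame(rows)


def _library_sizes(spec: SimulationSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    # log-normal parameterized to the target arithmetic mean/SD, truncated
    sigma2 = np.log1p((spec.library_sd / spec.library_mean) ** 2)
    mu = np.log(spec.library_mean) - sigma2 / 2
    sizes = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, np.sqrt(sigma2), size=2 * (n - filled))
        ok = draw[(draw >= spec.library_min) & (draw <= spec.library_max)]
        take = min(len(ok), n - filled)
        sizes[filled: filled + take] = ok[:take]
        filled += take
    return np.round(sizes).astype(np.int64)


def _cluster_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    labels = rng.integers(0, k, size=n)
    # guarantee every planted cluster is populated: steal from the largest
    for j in range(k):
        if not (labels == j).any():
            largest = np.bincount(labels, minlength=k).argmax()
            labels[np.flatnonzero(labels == largest)[0]] = j
    return labels


def simulate_otu_table(spec: SimulationSpec | None = None):
    """Generate (OtuTable, SampleMetadata, GroundTruth) under ``spec``.

    Deterministic given ``spec.seed``; count column sums equal the drawn
    library sizes exactly.
    """
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    phyla = list(PHYLA[: spec.n_phyla])

    design = _design_grid(spec)
    if spec.n_samples > len(design):
        raise ValueError(
            f"n_samples ({spec.n_samples}) exceeds the design grid ({len(design)})"
        )
    design = design.iloc[rng.permutation(len(design))[: spec.n_samples]].reset_index(drop=True)
    sample_ids = [
        f"{r.station}_M{r.month:02d}_{r.depth_label}" for r in design.itertuples()
    ]
    design.index = pd.Index(sample_ids, name="sample_id")

    centroids = planted_centroids(spec)
    labels = _cluster_labels(spec.n_samples, spec.k_clusters, rng)

    # OTU -> phylum allocation: archaeal share split over archaeal phyla,
    # the rest proportional to the base composition (at least 1 OTU each).
    base = np.array([_BASE_PHYLUM_PROPS[p] for p in phyla])
    alloc_weights = base.copy()
    arch_idx = [phyla.index(p) for p in ARCHAEAL_PHYLA if p in phyla]
    bact_idx = [i for i in range(len(phyla)) if i not in arch_idx]
    alloc_weights[arch_idx] = spec.archaea_fraction * alloc_weights[arch_idx] / alloc_weights[arch_idx].sum()
    alloc_weights[bact_idx] = (1 - spec.archaea_fraction) * alloc_weights[bact_idx] / alloc_weights[bact_idx].sum()
    n_per_phylum = np.maximum(1, np.floor(alloc_weights * spec.n_otus).astype(int))
    while n_per_phylum.sum() > spec.n_otus:
        n_per_phylum[np.argmax(n_per_phylum)] -= 1
    while n_per_phylum.sum() < spec.n_otus:
        n_per_phylum[np.argmax(alloc_weights)] += 1

    otu_phylum: list[str] = []
    for p, m in zip(phyla, n_per_phylum):
        otu_phylum.extend([p] * int(m))
    otu_ids = [f"OTU{i + 1:04d}" for i in range(spec.n_otus)]
    otu_weights = rng.lognormal(0.0, spec.otu_weight_sigma, size=spec.n_otus)

    # within-phylum weight normalization, fixed across samples
    phylum_of = pd.Series(otu_phylum, index=otu_ids)
    weight = pd.Series(otu_weights, index=otu_ids)
    weight_norm = weight / weight.groupby(phylum_of).transform("sum")

    library_sizes = _library_sizes(spec, spec.n_samples, rng)
    alpha0 = spec.dirichlet_concentration
    counts = np.empty((spec.n_otus, spec.n_samples), dtype=np.int64)
    phylum_index = pd.Index(phyla)
    otu_to_phylum_pos = phylum_index.get_indexer(phylum_of.to_numpy())
    for s in range(spec.n_samples):
        centroid = centroids.iloc[labels[s]].to_numpy()
        alpha = np.maximum(alpha0 * centroid, 1e-3)
        phylum_props = rng.dirichlet(alpha)
        otu_props = phylum_props[otu_to_phylum_pos] * weight_norm.to_numpy()
        otu_props /= otu_props.sum()
        counts[:, s] = rng.multinomial(library_sizes[s], otu_props)

    taxonomy = pd.DataFrame(
        {
            "Kingdom": ["Archaea" if p in ARCHAEAL_PHYLA else "Bacteria" for p in otu_phylum],
            "Phylum": otu_phylum,
            "Class": "",
            "Order": "",
            "Family": "",
            "Genus": [f"{p}_gen{(i % 5) + 1}" for i, p in enumerate(otu_phylum)],
        },
        index=pd.Index(otu_ids, name="otu_id"),
    )
    table = OtuTable(
        pd.DataFrame(counts, index=pd.Index(otu_ids, name="otu_id"), columns=sample_ids),
        taxonomy,
    )

    # covariates: cluster mean shifts + Gaussian noise, missing none
    shifts = [
        _COVARIATE_SHIFT_CYCLE[j % len(_COVARIATE_SHIFT_CYCLE)] for j in range(spec.k_clusters)
    ]
    cov_names = list(_COVARIATE_BASE)
    cov_means = pd.DataFrame(
        [
            {c: _COVARIATE_BASE[c][0] + shifts[j].get(c, 0.0) for c in cov_names}
            for j in range(spec.k_clusters)
        ],
        index=pd.RangeIndex(spec.k_clusters, name="cluster"),
    )
    meta = design.copy()
    for c in cov_names:
        noise = rng.normal(0.0, _COVARIATE_BASE[c][1], size=spec.n_samples)
        vals = cov_means[c].to_numpy()[labels] + noise
        meta[c] = np.maximum(vals, 0.0) if c not in ("Temp",) else vals
    meta["DIN"] = meta["NO3"] + meta["NO2"] + meta["NH4"]
    metadata = SampleMetadata(meta)

    truth = GroundTruth(
        labels=pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"), name="cluster").sort_index(),
        centroids=centroids,
        covariate_means=cov_means,
    )
    return table, metadata, truth


def simulate_cardfish(spec: SimulationSpec | None = None) -> CardFishTable:
    """Generate a CARD-FISH proportion table (percent of DAPI) with planted
    cluster structure; the planted labels ride along as ``cluster_labels``."""
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed + 1)  # independent of the OTU stream
    centers = np.asarray(spec.cardfish_centers, dtype=float)
    labels = _cluster_labels(spec.n_samples, spec.k_cardfish, rng)
    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]

    frac = np.clip(centers / 100.0, 1e-6, 1 - 1e-6)
    values = np.empty((spec.n_samples, len(CARDFISH_GROUPS)))
    for s in range(spec.n_samples):
        mu = logit(frac[labels[s]])
        if spec.cardfish_noise > 0:
            mu = mu + rng.normal(0.0, spec.cardfish_noise, size=mu.shape)
        values[s] = 100.0 * expit(mu)
    sar11_i = CARDFISH_GROUPS.index("SAR11_441R")
    alf_i = CARDFISH_GROUPS.index("ALF968")
    values[:, sar11_i] = np.minimum(values[:, sar11_i], values[:, alf_i])
    frame = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                         columns=list(CARDFISH_GROUPS))
    return CardFishTable(
        frame, cluster_labels=pd.Series(labels, index=frame.index, name="cluster")
    )


@dataclass
class RecoveryReport:
    """Outcome of a plant-and-recover experiment."""

    ari: float
    centroid_error: float
    assignment: BmuAssignment
    truth: GroundTruth
    matching: tuple[tuple[int, int], ...]  # (unit, planted cluster) pairs


def recovery_experiment(
    spec: SimulationSpec | None = None,
    ng_config: NGConfig | None = None,
    rarefaction: RarefactionSpec | None = None,
) -> RecoveryReport:
    """Simulate -> preprocess -> train -> assign, scored against the plant.

    ARI compares BMU labels with planted labels (NaN when K = 1, where ARI is
    undefined); centroid error is the mean Euclidean distance between
    Hungarian-matched codebook rows and planted centroids.
    """
    spec = spec or SimulationSpec()
    ng_config = ng_config or NGConfig(n_units=spec.k_clusters, seed=spec.seed)
    if ng_config.n_units != spec.k_clusters:
        raise ValueError("ng_config.n_units must equal spec.k_clusters")
    table, metadata, truth = simulate_otu_table(spec)
    table = remove_organelles(table)
    table = filter_rare_otus(table)
    table = rarefy(table, rarefaction or RarefactionSpec())
    community = aggregate_to_rank(table, "Phylum")
    X = build_ng_matrix(community)
    model = train_ng(X, ng_config)
    assignment = assign_bmu(model, X)

    planted = truth.labels.reindex(assignment.sample_ids)
    ari = (
        float("nan")
        if spec.k_clusters == 1
        else float(adjusted_rand_score(planted.to_numpy(), assignment.labels.to_numpy()))
    )

    codebook = model.codebook.reindex(columns=truth.centroids.columns, fill_value=0.0)
    cost = np.linalg.norm(
        codebook.to_numpy()[:, None, :] - truth.centroids.to_numpy()[None, :, :], axis=2
    )
    rows, cols = linear_sum_assignment(cost)
    centroid_error = float(cost[rows, cols].mean())
    return RecoveryReport(
        ari=ari,
        centroid_error=centroid_error,
        assignment=assignment,
        truth=truth,
        matching=tuple(zip(rows.tolist(), cols.tolist())),
    )
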