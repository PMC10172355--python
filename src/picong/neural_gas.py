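"""Online neural-gas vector quantization.

Neural gas trains a free set of prototype vectors ("units") without any
lattice topology: for every presented sample all units are ranked by
Euclidean distance and each is pulled toward the sample with a strength that
decays exponentially in its rank,

    w_i <- w_i + eps(t) * exp(-k_i / lambda(t)) * (x - w_i),

where k_i is the rank of unit i (0 = closest), and both the step size
eps(t) and the neighbourhood range lambda(t) anneal exponentially from their
initial to their final value over t_max = epochs * n_samples presentations:

    eps(t)    = eps0 * (eps_f / eps0) ** (t / t_max)
    lambda(t) = lam0 * (lam_f / lam0) ** (t / t_max).

The unit closest to a sample is its Best Match Unit (BMU); after training,
each sample is classified by its BMU. As lambda -> 0 the update degenerates
to winner-take-all online k-means, which the tests exploit as an oracle.

One epoch is one (seeded) shuffled pass over the samples; the codebook is
initialized from distinct data points, which together with eps0 <= 1 keeps
every prototype coordinate inside the data's per-feature range. Everything
is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CommunityMatrix


@dataclass
class NGConfig:
    """Training hyperparameters (defaults follow the two-model study setup:
    1000 epochs, initial step 0.5, initial neighbourhood range 4.5)."""

    n_units: int
    epochs: int = 1000
    eps_init: float = 0.5
    eps_final: float = 0.005
    lambda_init: float = 4.5
    lambda_final: float = 0.01
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if not (0 < self.eps_final <= self.eps_init <= 1):
            raise ValueError("require 0 < eps_final <= eps_init <= 1")
        if not (0 < self.lambda_final <= self.lambda_init):
            raise ValueError("require 0 < lambda_final <= lambda_init")


@dataclass
class NGModel:
    """A trained codebook: one prototype vector per unit, plus the training
    configuration and the per-epoch mean quantization error."""

    codebook: pd.DataFrame  # units x features
    config: NGConfig
    qe_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_units(self) -> int:
        return len(self.codebook)

    @property
    def feature_names(self) -> pd.Index:
        return self.codebook.columns


@dataclass
class BmuAssignment:
    """Best-match-unit label and distance for every sample."""

    labels: pd.Series     # sample_id -> unit index
    distances: pd.Series  # sample_id -> Euclidean distance to its BMU

    @property
    def sample_ids(self) -> pd.Index:
        return self.labels.index

    def members(self, unit: int) -> pd.Index:
        return self.labels.index[self.labels.to_numpy() == unit]


def _as_array(X: CommunityMatrix | pd.DataFrame) -> tuple[np.ndarray, pd.Index, pd.Index]:
    frame = X.values if isinstance(X, CommunityMatrix) else X
    arr = frame.to_numpy(dtype=float)
    return arr, frame.index, frame.columns


def train_ng(
    X: CommunityMatrix | pd.DataFrame,
    config: NGConfig,
    init_codebook: np.ndarray | None = None,
) -> NGModel:
    """Train a neural-gas codebook on the rows of ``X``.

    ``init_codebook`` overrides the default data-point initialization (used
    for controlled comparisons); rank ties are broken by lowest unit index.
    """
    data, sample_ids, feature_names = _as_array(X)
    n_samples, n_features = data.shape
    if np.isnan(data).any():
        raise ValueError("training data contains NaN")
    if config.n_units > n_samples:
        raise ValueError(
            f"n_units ({config.n_units}) exceeds n_samples ({n_samples})"
        )
    rng = np.random.default_rng(config.seed)
    if init_codebook is not None:
        W = np.array(init_codebook, dtype=float, copy=True)
        if W.shape != (config.n_units, n_features):
            raise ValueError("init_codebook shape mismatch")
    else:
        W = data[rng.choice(n_samples, size=config.n_units, replace=False)].copy()

    k = config.n_units
    t_max = config.epochs * n_samples
    eps_ratio = config.eps_final / config.eps_init
    lam_ratio = config.lambda_final / config.lambda_init
    ranks = np.empty(k, dtype=np.intp)
    arange_k = np.arange(k)
    qe_history = np.empty(config.epochs)

    t = 0
    with np.errstate(under="ignore"):
        for epoch in range(config.epochs):
            order = rng.permutation(n_samples) if config.shuffle else np.arange(n_samples)
            qe_sum = 0.0
            for i in order:
                x = data[i]
                frac = t / t_max
                eps = config.eps_init * eps_ratio**frac
                lam = config.lambda_init * lam_ratio**frac
                diff = x - W
                d2 = np.einsum("ij,ij->i", diff, diff)
                # stable sort -> ties ranked by lowest unit index
                ranks[np.argsort(d2, kind="stable")] = arange_k
                W += (eps * np.exp(-ranks / lam))[:, None] * diff
                qe_sum += np.sqrt(d2.min())
                t += 1
            qe_history[epoch] = qe_sum / n_samples

    codebook = pd.DataFrame(W, index=pd.RangeIndex(k, name="unit"), columns=feature_names)
    return NGModel(codebook=codebook, config=config, qe_history=qe_history)


def assign_bmu(model: NGModel, X: CommunityMatrix | pd.DataFrame) -> BmuAssignment:
    """Map every sample to its nearest prototype (ties -> lowest unit index)."""
    data, sample_ids, feature_names = _as_array(X)
    if list(feature_names) != list(model.feature_names):
        raise ValueError(
            "feature mismatch between data and codebook: "
            f"{list(feature_names)} vs {list(model.feature_names)}"
        )
    if data.shape[0] == 0:
        raise ValueError("no samples to assign")
    W = model.codebook.to_numpy(dtype=float)
    d2 = ((data[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)  # argmin returns the first (lowest) index on ties
    dists = np.sqrt(d2[np.arange(len(labels)), labels])
    return BmuAssignment(
        labels=pd.Series(labels, index=sample_ids, name="bmu"),
        distances=pd.Series(dists, index=sample_ids, name="distance"),
    )


def quantization_error(model: NGModel, X: CommunityMatrix | pd.DataFrame) -> float:
    """Mean Euclidean distance from each sample to its BMU."""
    return float(assign_bmu(model, X).distances.mean())


# ---------------------------------------------------------------------------
# serialization: TSV codebook + JSON config sidecar
# ---------------------------------------------------------------------------

def save_model(model: NGModel, codebook_path: str | Path, config_path: str | Path) -> None:
    model.codebook.to_csv(codebook_path, sep="\t", index_label="unit")
    payload = {"config": asdict(model.config), "qe_history": model.qe_history.tolist()}
    Path(config_path).write_text(json.dumps(payload, indent=2))


def load_model(codebook_path: str | Path, config_path: str | Path) -> NGModel:
    codebook = pd.read_csv(codebook_path, sep="\t", index_col="unit")
    payload = json.loads(Path(config_path).read_text())
    return NGModel(
        codebook=codebook,
        config=NGConfig(**payload["config"]),
        qe_history=np.asarray(payload.get("qe_history", [])),
    )


def save_assignment(assignment: BmuAssignment, path: str | Path) -> None:
    frame = pd.DataFrame({"bmu": assignment.labels, "distance": assignment.distances})
    frame.to_csv(path, sep="\t", index_label="sample_id")


def load_assignment(path: str | Path) -> BmuAssignment:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    return BmuAssignment(labels=frame["bmu"], distances=frame["distance"])
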