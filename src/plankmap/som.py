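"""Self-organizing map community typing.

A Kohonen map is trained online on sample composition vectors: at each step a
sample is drawn (epoch-shuffled order), its Euclidean best-matching unit (BMU)
found, and every prototype pulled toward the sample with a Gaussian
neighborhood kernel on rectangular grid distance and a linearly decaying
learning rate.  Neurons are then cut into the two most distinct community
clusters by Ward hierarchical clustering of the prototype vectors; the
nearshore/offshore semantics of the two clusters are assigned downstream from
station geography, so everything here is invariant to swapping cluster ids.

Ties in BMU distance break toward the lowest neuron index; training is fully
deterministic for a fixed seed (prototype initialization and sample order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from plankmap.core_data import AsvTable


@dataclass
class SomConfig:
    epochs: int = 20
    learning_rate_start: float = 0.5
    learning_rate_end: float = 0.01
    radius_start: float | None = None  # default: grid diameter / 2
    radius_end: float = 0.5
    init: str = "sample"               # prototypes initialized from random samples


@dataclass
class SomModel:
    grid_rows: int
    grid_cols: int
    prototypes: np.ndarray                      # (n_neurons, n_features)
    config: SomConfig
    seed: int
    quantization_errors: list[float] = field(default_factory=list)
    neuron_cluster: np.ndarray | None = None    # values in {1, 2}
    cluster_labels: dict[int, str] | None = None  # {cluster: nearshore|offshore}

    @property
    def n_neurons(self) -> int:
        return self.grid_rows * self.grid_cols

    def grid_coords(self) -> np.ndarray:
        r, c = np.divmod(np.arange(self.n_neurons), self.grid_cols)
        return np.column_stack([r, c]).astype(float)

    def bmu(self, X: np.ndarray) -> np.ndarray:
        """Best-matching unit per row of X; ties -> lowest neuron index."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.prototypes[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def quantization_error(self, X: np.ndarray) -> float:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        bmus = self.bmu(X)
        return float(np.mean(np.linalg.norm(X - self.prototypes[bmus], axis=1)))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "grid_rows": self.grid_rows, "grid_cols": self.grid_cols,
            "prototypes": self.prototypes.tolist(),
            "config": asdict(self.config), "seed": self.seed,
            "quantization_errors": self.quantization_errors,
            "neuron_cluster": None if self.neuron_cluster is None
            else self.neuron_cluster.tolist(),
            "cluster_labels": None if self.cluster_labels is None
            else {str(k): v for k, v in self.cluster_labels.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SomModel":
        payload = json.loads(Path(path).read_text())
        return cls(grid_rows=payload["grid_rows"], grid_cols=payload["grid_cols"],
                   prototypes=np.asarray(payload["prototypes"], dtype=float),
                   config=SomConfig(**payload["config"]), seed=payload["seed"],
                   quantization_errors=payload["quantization_errors"],
                   neuron_cluster=None if payload["neuron_cluster"] is None
                   else np.asarray(payload["neuron_cluster"]),
                   cluster_labels=None if payload["cluster_labels"] is None
                   else {int(k): v for k, v in payload["cluster_labels"].items()})


def train_som(X: np.ndarray, grid: tuple[int, int] = (6, 6),
              config: SomConfig | None = None, seed: int = 0) -> SomModel:
    """Train a Kohonen map on a samples-by-features matrix.

    Learning rate and neighborhood radius decay linearly over the total step
    count; the neighborhood is a Gaussian on Euclidean grid distance (a zero
    radius updates the BMU only, reducing training to online k-means).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in SOM input")
    config = config or SomConfig()
    rows, cols = grid
    n_neurons = rows * cols
    n_samples = X.shape[0]
    rng = np.random.default_rng(seed)

    if config.init == "sample":
        protos = X[rng.integers(0, n_samples, n_neurons)].copy()
    else:
        lo, hi = X.min(axis=0), X.max(axis=0)
        protos = rng.uniform(lo, hi, size=(n_neurons, X.shape[1]))

    model = SomModel(grid_rows=rows, grid_cols=cols, prototypes=protos,
                     config=config, seed=seed)
    coords = model.grid_coords()
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)

    radius_start = (config.radius_start if config.radius_start is not None
                    else 0.5 * float(np.hypot(rows - 1, cols - 1)))
    total = config.epochs * n_samples
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(n_samples)
        for i in order:
            frac = step / max(total - 1, 1)
            lr = config.learning_rate_start + frac * (
                config.learning_rate_end - config.learning_rate_start)
            radius = radius_start + frac * (config.radius_end - radius_start)
            x = X[i]
            d2 = ((protos - x) ** 2).sum(axis=1)
            bmu = int(np.argmin(d2))
            if radius <= 0:
                protos[bmu] += lr * (x - protos[bmu])
            else:
                h = np.exp(-grid_d2[bmu] / (2.0 * radius * radius))
                protos += (lr * h)[:, None] * (x - protos)
            step += 1
        model.quantization_errors.append(model.quantization_error(X))
    return model


def cluster_neurons(model: SomModel, k: int = 2) -> np.ndarray:
    """Ward-linkage hierarchical clustering of prototypes, tree cut at ``k``.

    Stores and returns the neuron->cluster map (ids 1..k, arbitrary).
    """
    protos = model.prototypes
    if np.allclose(protos, protos[0]):
        raise ValueError("all prototypes identical: no community structure to cluster")
    Z = linkage(protos, method="ward", metric="euclidean")
    clusters = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(clusters)) < k:
        raise ValueError(f"could not separate {k} non-empty clusters")
    model.neuron_cluster = clusters.astype(int)
    return model.neuron_cluster


def classify_samples(model: SomModel, X: np.ndarray,
                     sample_ids: list[str] | None = None,
                     group: str = "all") -> pd.DataFrame:
    """Assign every sample its BMU's cluster (and label, once clusters are named)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.prototypes.shape[1]:
        raise ValueError(
            f"sample dimension {X.shape[1]} != training dimension "
            f"{model.prototypes.shape[1]}")
    if model.neuron_cluster is None:
        raise ValueError("cluster neurons before classifying samples")
    bmus = model.bmu(X)
    clusters = model.neuron_cluster[bmus]
    ids = sample_ids if sample_ids is not None else [f"sample{i}" for i in range(len(bmus))]
    out = pd.DataFrame({"sample_id": ids, "group": group,
                        "bmu": bmus, "cluster": clusters})
    if model.cluster_labels is not None:
        out["label"] = [model.cluster_labels[c] for c in clusters]
    return out


def differential_abundance(table: AsvTable, classifications: pd.DataFrame,
                           percentile: float = 99.0) -> pd.DataFrame:
    """Per-ASV mean relative-abundance difference between the two community types.

    For each ASV: mean within-sample relative abundance over nearshore-labeled
    samples minus over offshore-labeled samples; ASVs whose absolute
    difference strictly exceeds the given percentile of all absolute
    differences are flagged.
    """
    labels = classifications.set_index("sample_id")["label"]
    near_ids = [s for s in table.sample_ids if labels.get(s) == "nearshore"]
    off_ids = [s for s in table.sample_ids if labels.get(s) == "offshore"]
    if not near_ids or not off_ids:
        raise ValueError("both community types must be represented")
    sums = table.sample_sums().astype(float)
    props = table.counts / np.where(sums == 0, 1.0, sums)[np.newaxis, :]
    col = {s: j for j, s in enumerate(table.sample_ids)}
    near_mean = props[:, [col[s] for s in near_ids]].mean(axis=1)
    off_mean = props[:, [col[s] for s in off_ids]].mean(axis=1)
    diff = near_mean - off_mean
    cutoff = np.percentile(np.abs(diff), percentile)
    return pd.DataFrame({
        "asv_id": table.asv_ids,
        "mean_nearshore": near_mean,
        "mean_offshore": off_mean,
        "difference": diff,
        "flagged": np.abs(diff) > cutoff,
    })
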