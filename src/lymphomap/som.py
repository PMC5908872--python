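"""Kohonen self-organizing map on a hexagonal grid, written from scratch.

The map clusters pathway net-expression profiles (one row per pathway, one
coordinate per sample group) onto a small hexagonal grid of units, each with
a codebook vector of the same length. Training is the classic online rule:
for each row x presented, the best-matching unit (BMU) is the unit with the
nearest codebook (Euclidean), and every unit u moves toward x by

    w_u <- w_u + eta(t) * exp(-d(u, BMU)^2 / (2 r(t)^2)) * (x - w_u)

where d is the distance between unit centers on the hex grid and both the
learning rate eta and the neighborhood radius r decay linearly over epochs.
The codebook is initialized by sampling data rows, and row presentation
order is reshuffled every epoch; all randomness comes from one seeded
generator, so a seed fully determines the model.

Net expressions already live on a common [-1, 1] scale, so no input
standardization is applied.

Unit indexing is row-major: on a 4 x 4 grid, unit 1 is the top-left corner
and unit 16 the bottom-right (1-based, matching how units are usually
labelled on published SOM figures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathways import classify_band
from .types import ConfigError


def hex_grid(rows: int = 4, cols: int = 4) -> np.ndarray:
    """Unit centers of a rows x cols hexagonal grid (odd rows shifted right).

    Unit (r, c) sits at ``x = c + 0.5 * (r % 2), y = r * sqrt(3)/2``; nearest
    neighbors are exactly 1 apart. Returned as an (rows*cols, 2) array in
    row-major unit order.
    """
    if rows < 1 or cols < 1:
        raise ConfigError("grid must have at least one row and one column")
    centers = np.empty((rows * cols, 2), dtype=float)
    for r in range(rows):
        for c in range(cols):
            centers[r * cols + c] = (c + 0.5 * (r % 2), r * np.sqrt(3.0) / 2.0)
    return centers


@dataclass
class SOMModel:
    """Trained map: grid geometry, codebook, and the training trace."""

    centers: np.ndarray           # n_units x 2 grid coordinates
    codebook: np.ndarray          # n_units x n_features
    feature_names: list[str]
    qe_per_epoch: list[float] = field(default_factory=list)
    hyperparams: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.centers.shape[0]

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "codebook": self.codebook.tolist(),
            "feature_names": list(self.feature_names),
            "qe_per_epoch": [float(v) for v in self.qe_per_epoch],
            "hyperparams": self.hyperparams,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SOMModel":
        return cls(
            centers=np.asarray(d["centers"], dtype=float),
            codebook=np.asarray(d["codebook"], dtype=float),
            feature_names=list(d["feature_names"]),
            qe_per_epoch=list(d["qe_per_epoch"]),
            hyperparams=dict(d["hyperparams"]),
        )


def _bmu_indices(codebook: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Index of the nearest codebook per row; ties go to the lowest unit."""
    d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)  # argmin returns the first (lowest) minimizer


def train_som(
    data: pd.DataFrame,
    rows: int = 4,
    cols: int = 4,
    epochs: int = 100,
    radius: tuple[float, float] | None = None,
    rate: tuple[float, float] = (0.05, 0.01),
    seed: int = 0,
) -> SOMModel:
    """Train a rows x cols hexagonal SOM on the rows of ``data``.

    ``radius`` defaults to (half the grid diagonal, 1.0); both radius and
    learning rate decay linearly from first to last epoch. Identical seed
    and data give an identical model.
    """
    if data.shape[0] < 1:
        raise ConfigError("cannot train a SOM on an empty matrix")
    if data.isna().to_numpy().any():
        raise ConfigError("SOM input contains missing values")
    if epochs < 1:
        raise ConfigError("epochs must be >= 1")
    X = data.to_numpy(dtype=float)
    n, _ = X.shape
    centers = hex_grid(rows, cols)
    n_units = centers.shape[0]
    grid_d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    diag = np.sqrt(grid_d2.max())
    r0, r1 = radius if radius is not None else (max(diag / 2.0, 1.0), 1.0)
    eta0, eta1 = rate

    rng = np.random.default_rng(seed)
    init_idx = (
        rng.choice(n, size=n_units, replace=False)
        if n >= n_units
        else rng.choice(n, size=n_units, replace=True)
    )
    codebook = X[init_idx].copy()

    qe_trace: list[float] = []
    for t in range(epochs):
        frac = t / (epochs - 1) if epochs > 1 else 0.0
        r_t = r0 + (r1 - r0) * frac
        eta_t = eta0 + (eta1 - eta0) * frac
        order = rng.permutation(n)
        for i in order:
            x = X[i]
            bmu = int(((codebook - x) ** 2).sum(axis=1).argmin())
            h = np.exp(-grid_d2[bmu] / (2.0 * r_t * r_t))
            codebook += (eta_t * h)[:, None] * (x - codebook)
        bmus = _bmu_indices(codebook, X)
        qe_trace.append(float(np.sqrt(((X - codebook[bmus]) ** 2).sum(axis=1)).mean()))

    return SOMModel(
        centers=centers,
        codebook=codebook,
        feature_names=list(data.columns),
        qe_per_epoch=qe_trace,
        hyperparams={
            "rows": rows,
            "cols": cols,
            "epochs": epochs,
            "radius": [float(r0), float(r1)],
            "rate": [float(eta0), float(eta1)],
            "seed": int(seed),
        },
    )


@dataclass
class SOMAssignment:
    """Pathway -> unit mapping plus per-unit summaries.

    ``units`` is 1-based row-major; ``summary`` has one row per unit with
    the member count, per-group codebook-free means of member rows, the
    median over all member values, and the band of that median.
    """

    units: pd.Series
    summary: pd.DataFrame

    def counts(self) -> pd.Series:
        return self.summary["n_pathways"]


def assign_bmu(model: SOMModel, data: pd.DataFrame) -> SOMAssignment:
    """Assign every row to its best-matching unit and summarize units."""
    if data.shape[1] != model.codebook.shape[1]:
        raise ConfigError(
            f"data has {data.shape[1]} columns but the codebook expects "
            f"{model.codebook.shape[1]}"
        )
    X = data.to_numpy(dtype=float)
    bmus = _bmu_indices(model.codebook, X)
    units = pd.Series(bmus + 1, index=data.index, name="unit")
    rows = []
    for u in range(1, model.n_units + 1):
        members = data.loc[units == u]
        row: dict = {"unit": u, "n_pathways": int(members.shape[0])}
        for g in data.columns:
            row[f"mean_{g}"] = float(members[g].mean()) if len(members) else float("nan")
        if len(members):
            med = float(np.median(members.to_numpy()))
            row["median_NE"] = med
            row["band"] = classify_band(med)
        else:
            row["median_NE"] = float("nan")
            row["band"] = "empty"
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("unit")
    return SOMAssignment(units=units, summary=summary)


def quantization_error(model: SOMModel, data: pd.DataFrame) -> float:
    """Mean Euclidean distance from each row to its BMU codebook."""
    if data.shape[1] != model.codebook.shape[1]:
        raise ConfigError("dimension mismatch between data and codebook")
    X = data.to_numpy(dtype=float)
    bmus = _bmu_indices(model.codebook, X)
    return float(np.sqrt(((X - model.codebook[bmus]) ** 2).sum(axis=1)).mean())
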