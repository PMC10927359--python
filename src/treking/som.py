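"""Self-organizing map clustering of kinase temporal functionality profiles.

Each kinase's row of the functionality matrix (a {-1,0,+1} vector over time
windows) is a temporal profile; a small rectangular SOM (default 6x6, so at
most 36 occupied neurons) groups kinases with similar profiles onto the same
grid cell ("neuron") while keeping neurons with similar mean temporal
behavior nearby on the grid. Training is classical online SOM: random
sampling of inputs, best-matching-unit search by Euclidean distance, and a
Gaussian neighborhood whose width and learning rate decay asymptotically
over iterations. Distances operate on the raw {-1,0,+1} vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tkir import FunctionalityMatrix

logger = logging.getLogger("treking.som")


@dataclass
class SOMConfig:
    rows: int = 6
    cols: int = 6
    sigma: float = 1.0
    learning_rate: float = 0.5
    iterations_per_profile: int = 500
    init: str = "random"          # random codebooks drawn from the data range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols < 1:
            raise ValueError("grid must have at least one neuron")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.iterations_per_profile < 1:
            raise ValueError("need at least one iteration")


@dataclass
class TrainedSOM:
    codebook: np.ndarray          # (rows, cols, n_features)
    config: SOMConfig
    initial_qe: float
    final_qe: float

    @property
    def rows(self) -> int:
        return self.codebook.shape[0]

    @property
    def cols(self) -> int:
        return self.codebook.shape[1]

    def bmu(self, x: np.ndarray) -> tuple[int, int]:
        """Best-matching unit; ties break to the lowest (i, j) row-major."""
        d = np.linalg.norm(self.codebook - x, axis=2)
        flat = int(np.argmin(d))  # argmin is row-major first-minimum
        return flat // self.cols, flat % self.cols


@dataclass
class NeuronAssignment:
    kinase_to_neuron: dict[str, tuple[int, int]]
    members: dict[tuple[int, int], list[str]]
    som: TrainedSOM

    @property
    def occupied(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, i, j) for k, (i, j) in self.kinase_to_neuron.items()],
            columns=["kinase", "neuron_i", "neuron_j"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _quantization_error(codebook: np.ndarray, data: np.ndarray) -> float:
    d = np.linalg.norm(
        codebook.reshape(-1, codebook.shape[-1])[None, :, :] - data[:, None, :],
        axis=2,
    )
    return float(d.min(axis=1).mean())


def train_som(profiles: pd.DataFrame, config: SOMConfig | None = None) -> TrainedSOM:
    """Train the map on a kinase x window profile matrix.

    Deterministic given config.seed; the quantization error (mean distance
    of each profile to its best-matching codebook) is recorded before and
    after training.
    """
    config = config or SOMConfig()
    data = np.asarray(profiles, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("need at least one profile")
    rng = np.random.default_rng(config.seed)
    lo, hi = data.min(), data.max()
    if hi == lo:
        hi = lo + 1.0
    codebook = rng.uniform(lo, hi, size=(config.rows, config.cols, data.shape[1]))
    initial_qe = _quantization_error(codebook, data)

    n_iter = config.iterations_per_profile * data.shape[0]
    half_life = n_iter / 2
    gi, gj = np.meshgrid(np.arange(config.rows), np.arange(config.cols),
                         indexing="ij")
    for t in range(n_iter):
        x = data[rng.integers(data.shape[0])]
        decay = 1.0 / (1.0 + t / half_life)   # asymptotic decay
        sigma = config.sigma * decay
        lr = config.learning_rate * decay
        d = np.linalg.norm(codebook - x, axis=2)
        flat = int(np.argmin(d))
        bi, bj = flat // config.cols, flat % config.cols
        g2 = (gi - bi) ** 2 + (gj - bj) ** 2
        h = lr * np.exp(-g2 / (2.0 * sigma * sigma))
        codebook += h[:, :, None] * (x - codebook)

    final_qe = _quantization_error(codebook, data)
    logger.info("SOM trained: quantization error %.4g -> %.4g", initial_qe, final_qe)
    return TrainedSOM(codebook=codebook, config=config,
                      initial_qe=initial_qe, final_qe=final_qe)


def assign_neurons(som: TrainedSOM, profiles: pd.DataFrame) -> NeuronAssignment:
    """Map each kinase to its best-matching unit by Euclidean distance."""
    data = np.asarray(profiles, dtype=float)
    if data.shape[1] != som.codebook.shape[2]:
        raise ValueError("profile length does not match the trained map")
    kinase_to_neuron: dict[str, tuple[int, int]] = {}
    members: dict[tuple[int, int], list[str]] = {}
    for name, x in zip(profiles.index, data):
        ij = som.bmu(x)
        kinase_to_neuron[str(name)] = ij
        members.setdefault(ij, []).append(str(name))
    return NeuronAssignment(kinase_to_neuron=kinase_to_neuron,
                            members=members, som=som)


def neuron_mean_trace(
    assignment: NeuronAssignment, matrix: FunctionalityMatrix,
    neuron: tuple[int, int],
) -> pd.Series:
    """Per-window mean functionality of a neuron's member kinases.

    +1 iff every member is barrier-strengthening in that window, -1 iff all
    are weakening; intermediate values mean only a fraction of members are
    called (e.g. 2 of 4 at +1 gives 0.5).
    """
    members = assignment.members.get(tuple(neuron), [])
    if not members:
        raise ValueError(f"neuron {neuron} has no members")
    return matrix.calls.loc[members].mean(axis=0)


def all_neuron_traces(
    assignment: NeuronAssignment, matrix: FunctionalityMatrix
) -> dict[tuple[int, int], pd.Series]:
    return {
        ij: neuron_mean_trace(assignment, matrix, ij)
        for ij in sorted(assignment.members)
    }


def distance_map(som: TrainedSOM) -> np.ndarray:
    """U-matrix: per neuron, the sum of Euclidean distances from its codebook
    to its 8-connected neighbors' codebooks, normalized by the maximum sum
    (so the max cell is 1; an all-identical codebook maps to all zeros)."""
    rows, cols = som.rows, som.cols
    if rows * cols < 2:
        raise ValueError("distance map undefined on a 1x1 grid")
    out = np.zeros((rows, cols))
    for i in range(rows):
        for j in range(cols):
            s = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ni, nj = i + di, j + dj
                    if 0 <= ni < rows and 0 <= nj < cols:
                        s += float(np.linalg.norm(
                            som.codebook[i, j] - som.codebook[ni, nj]))
            out[i, j] = s
    mx = out.max()
    return out / mx if mx > 0 else out


def topographic_error(som: TrainedSOM, profiles: pd.DataFrame) -> float:
    """Fraction of profiles whose best and second-best units are not grid
    neighbors — a diagnostic of topographic ordering, not a hard contract."""
    data = np.asarray(profiles, dtype=float)
    errs = 0
    for x in data:
        d = np.linalg.norm(som.codebook - x, axis=2).ravel()
        order = np.argsort(d, kind="stable")
        b1, b2 = int(order[0]), int(order[1])
        i1, j1 = divmod(b1, som.cols)
        i2, j2 = divmod(b2, som.cols)
        if max(abs(i1 - i2), abs(j1 - j2)) > 1:
            errs += 1
    return errs / len(data)
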