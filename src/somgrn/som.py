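"""Self-organizing maps on a hexagonal lattice, best-of-trials training.

Rows of a (items x experiments) matrix are mapped onto a 2-D hexagonal
lattice of units, each carrying a weight vector in experiment space.
Training is the classic online Kohonen procedure: per presentation the
winning (nearest, Euclidean) unit and its lattice neighbourhood move toward
the presented row, with learning rate and neighbourhood radius decaying as
negative exponentials.  Several independent trials are run from different
seeds; the model whose mean quantization error on the full matrix is lowest
is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# odd-r offset hexagonal layout: odd rows are shifted right by half a cell


def _oddr_to_cube(row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = col - (row - (row & 1)) // 2
    z = row
    y = -x - z
    return x, y, z


def hex_distance_matrix(rows: int, cols: int) -> np.ndarray:
    """Pairwise hexagonal (cube-coordinate) lattice distances, unit spacing."""
    r, c = np.divmod(np.arange(rows * cols), cols)
    x, y, z = _oddr_to_cube(r, c)
    dx = np.abs(x[:, None] - x[None, :])
    dy = np.abs(y[:, None] - y[None, :])
    dz = np.abs(z[:, None] - z[None, :])
    return (dx + dy + dz) / 2.0


@dataclass
class HexLattice:
    """Hexagonal lattice of rows x cols units, row-major unit indexing."""

    rows: int
    cols: int
    _dist: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("lattice must have >=1 row and column")
        if self._dist is None:
            self._dist = hex_distance_matrix(self.rows, self.cols)

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    @property
    def distances(self) -> np.ndarray:
        return self._dist

    def adjacency(self) -> dict[int, set[int]]:
        """unit -> neighbouring units at lattice distance 1 (<=6 each)."""
        d = self._dist
        return {u: set(np.flatnonzero(d[u] == 1.0).tolist()) for u in range(self.n_units)}

    def unit_position(self, unit: int) -> tuple[int, int]:
        return divmod(unit, self.cols)


@dataclass
class TrainingConfig:
    rows: int = 40
    cols: int = 60
    epochs: int = 100
    trials: int = 100
    alpha0: float = 0.1
    sigma0: float | None = None  # default max(rows, cols)/2, at least 1
    sigma_min: float = 0.2  # final neighbourhood radius (lattice units)
    decay_constant: float | None = None  # default: sigma reaches sigma_min at the end
    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha0 <= 1):
            raise ValueError("alpha0 must be in (0, 1]")
        if self.sigma0 is None:
            self.sigma0 = max(max(self.rows, self.cols) / 2.0, 1.0)
        if self.sigma0 < 1:
            raise ValueError("sigma0 must be >= 1")
        if not (0 < self.sigma_min <= self.sigma0):
            raise ValueError("sigma_min must be in (0, sigma0]")
        if not (0 < self.train_fraction <= 1):
            raise ValueError("train_fraction must be in (0, 1]")


@dataclass
class SOMModel:
    """A trained SOM: lattice plus one weight vector per unit."""

    lattice: HexLattice
    weights: np.ndarray  # (n_units, d)
    config: TrainingConfig
    final_score: float
    trial_scores: list[float] = field(default_factory=list)
    columns: list[str] | None = None

    def slice_view(self, experiment: int | str) -> np.ndarray:
        """Per-unit value of one experiment dimension as a (rows, cols) grid."""
        if isinstance(experiment, str):
            if self.columns is None or experiment not in self.columns:
                raise IndexError(f"unknown experiment {experiment!r}")
            experiment = self.columns.index(experiment)
        if not (0 <= experiment < self.weights.shape[1]):
            raise IndexError(f"experiment index {experiment} out of range")
        return self.weights[:, experiment].reshape(self.lattice.rows, self.lattice.cols)


def preprocess_matrix(matrix: pd.DataFrame, transform: str = "log2p1") -> pd.DataFrame:
    """Prepare a nonnegative TPM/RPKM matrix for SOM training.

    transform: "log2p1" (default, x -> log2(x+1)), "identity", or
    "max" (per-row division by the row maximum; zero rows unchanged).
    """
    vals = matrix.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("matrix contains negative values")
    if transform == "identity":
        out = vals
    elif transform == "log2p1":
        out = np.log2(vals + 1.0)
    elif transform == "max":
        mx = vals.max(axis=1, keepdims=True)
        mx = np.where(mx == 0, 1.0, mx)
        out = vals / mx
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _as_array(matrix) -> np.ndarray:
    arr = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("matrix must be 2-D with >=1 row")
    if not np.all(np.isfinite(arr)):
        raise ValueError("matrix contains non-finite values")
    return arr


def _min_dists_and_bmus(weights: np.ndarray, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # direct squared distances (chunked) so exact ties stay exact;
    # ties -> lowest unit index (argmin default)
    n = len(data)
    bmu = np.empty(n, dtype=int)
    mind = np.empty(n)
    chunk = max(1, int(2_000_000 / max(weights.size, 1)))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d2 = ((data[lo:hi, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
        b = np.argmin(d2, axis=1)
        bmu[lo:hi] = b
        mind[lo:hi] = d2[np.arange(hi - lo), b]
    return np.sqrt(mind), bmu


def score_som(model: SOMModel, matrix) -> float:
    """Mean over rows of the distance to the nearest unit (quantization error)."""
    data = _as_array(matrix)
    if data.shape[1] != model.weights.shape[1]:
        raise ValueError("dimension mismatch between matrix and SOM weights")
    dists, _ = _min_dists_and_bmus(model.weights, data)
    return float(dists.mean())


def _train_single(
    data: np.ndarray,
    lattice: HexLattice,
    config: TrainingConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    n, d = data.shape
    n_units = lattice.n_units
    # initialize weights by sampling data rows (with replacement)
    init_rows = rng.integers(0, n, size=n_units)
    weights = data[init_rows].astype(float).copy()

    n_train = max(1, int(round(config.train_fraction * n)))
    train_idx = rng.permutation(n)[:n_train]

    total = config.epochs * n_train
    lam = config.decay_constant
    if lam is None:
        # sigma decays from sigma0 to sigma_min over the whole schedule
        ratio = config.sigma0 / config.sigma_min
        lam = total / np.log(ratio) if ratio > 1 else float(total)
    latd2 = lattice.distances**2
    t = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n_train)
        for i in order:
            x = data[train_idx[i]]
            diff = weights - x
            winner = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            alpha = config.alpha0 * np.exp(-t / lam)
            sigma = max(config.sigma0 * np.exp(-t / lam), config.sigma_min)
            h = np.exp(-latd2[winner] / (2.0 * sigma * sigma))
            weights -= (alpha * h)[:, None] * diff
            t += 1
    return weights


def train_som(matrix, config: TrainingConfig) -> SOMModel:
    """Best-of-trials SOM training.

    Runs ``config.trials`` independent trainings with per-trial seeds derived
    from ``config.seed``; each trains on a random ``train_fraction`` row split
    and is scored by mean quantization error on the FULL matrix; the
    lowest-scoring trial's model is returned, all trial scores recorded.
    """
    data = _as_array(matrix)
    columns = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else None
    lattice = HexLattice(config.rows, config.cols)
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.trials)
    best_weights = None
    best_score = np.inf
    trial_scores: list[float] = []
    for cs in child_seeds:
        rng = np.random.default_rng(cs)
        weights = _train_single(data, lattice, config, rng)
        dists, _ = _min_dists_and_bmus(weights, data)
        score = float(dists.mean())
        trial_scores.append(score)
        if score < best_score:
            best_score = score
            best_weights = weights
    return SOMModel(
        lattice=lattice,
        weights=best_weights,
        config=config,
        final_score=best_score,
        trial_scores=trial_scores,
        columns=columns,
    )


@dataclass
class AssignmentMap:
    """item id -> best-matching unit, plus the distance to that unit."""

    unit: pd.Series  # item id -> unit index
    distance: pd.Series

    def __len__(self) -> int:
        return len(self.unit)


def save_model(model: SOMModel, json_path, weights_path) -> None:
    """Serialize a SOMModel as JSON metadata plus a TSV weight table."""
    import json

    meta = {
        "rows": model.lattice.rows,
        "cols": model.lattice.cols,
        "final_score": model.final_score,
        "trial_scores": model.trial_scores,
        "columns": model.columns,
        "config": {
            "rows": model.config.rows, "cols": model.config.cols,
            "epochs": model.config.epochs, "trials": model.config.trials,
            "alpha0": model.config.alpha0, "sigma0": model.config.sigma0,
            "sigma_min": model.config.sigma_min, "seed": model.config.seed,
            "train_fraction": model.config.train_fraction,
        },
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2)
    cols = model.columns or [str(i) for i in range(model.weights.shape[1])]
    pd.DataFrame(model.weights, columns=cols).to_csv(weights_path, sep="\t", index=False)


def load_model(json_path, weights_path) -> SOMModel:
    """Load a SOMModel written by :func:`save_model`."""
    import json

    with open(json_path) as fh:
        meta = json.load(fh)
    weights = pd.read_csv(weights_path, sep="\t").to_numpy(dtype=float)
    return SOMModel(
        lattice=HexLattice(meta["rows"], meta["cols"]),
        weights=weights,
        config=TrainingConfig(**meta["config"]),
        final_score=meta["final_score"],
        trial_scores=meta.get("trial_scores", []),
        columns=meta.get("columns"),
    )


def assign_items(model: SOMModel, matrix) -> AssignmentMap:
    """Assign every row to its nearest unit (ties -> lowest unit index)."""
    data = _as_array(matrix)
    if data.shape[1] != model.weights.shape[1]:
        raise ValueError("dimension mismatch between matrix and SOM weights")
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(len(data))
    dists, bmu = _min_dists_and_bmus(model.weights, data)
    return AssignmentMap(
        unit=pd.Series(bmu, index=index),
        distance=pd.Series(dists, index=index),
    )
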