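"""Binary particle swarm optimization over a hybrid bit-string.

Each particle's position is a bit-string of length ``n_features + 10``:
the first segment is a feature-selection mask, the trailing 10 bits index
a (C, γ) point on the geometric SVM hyperparameter grid 2^−16 … 2^15
(common ratio 2, 32 values per parameter, 1024 combinations). Fitness is
the mean accuracy of stratified ten-fold cross-validation of an RBF-kernel
SVM trained on the masked columns with the decoded hyperparameters; the
fold partition is fixed once per run so fitness values are comparable
across particles and iterations.

The search runs in two phases. Phase 1 is canonical sigmoid-transfer
binary PSO with global-best bookkeeping. Phase 2 (after
``phase_switch_iteration``) switches to a convergence accelerator that
draws position bits toward the global best: bit i becomes the global-best
bit with probability s(|v_i|), otherwise it is kept. The phase-2 rule is
pluggable via ``BpsoConfig.phase2_update``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .encoders import FeatureMatrix

__all__ = [
    "HyperparamGrid",
    "BpsoConfig",
    "Particle",
    "SelectionResult",
    "FoldData",
    "decode_particle",
    "repair_mask",
    "init_swarm",
    "make_folds",
    "build_fold_data",
    "evaluate_fitness",
    "update_velocity",
    "update_position",
    "sigmoid",
    "run_bpso",
]

N_HYPER_BITS = 10


@dataclass(frozen=True)
class HyperparamGrid:
    """Geometric grid 2^exponent_min … 2^exponent_max for C and γ."""

    base: float = 2.0
    exponent_min: int = -16
    exponent_max: int = 15

    @property
    def n_values(self) -> int:
        return self.exponent_max - self.exponent_min + 1

    def values(self) -> np.ndarray:
        return self.base ** np.arange(self.exponent_min, self.exponent_max + 1)

    def value(self, index: int) -> float:
        if not 0 <= index < self.n_values:
            raise ValueError(f"grid index {index} out of range")
        return float(self.base ** (self.exponent_min + index))


def _bits_to_int(bits: np.ndarray) -> int:
    """Most-significant bit first."""
    out = 0
    for b in bits:
        out = (out << 1) | int(b)
    return out


def decode_particle(
    position: np.ndarray, n_features: int, grid: Optional[HyperparamGrid] = None
) -> tuple[np.ndarray, float, float]:
    """Split a hybrid position into (feature mask, C, γ).

    The 10 hyperparameter bits are read most-significant first, the
    C block before the γ block.
    """
    grid = grid or HyperparamGrid()
    position = np.asarray(position)
    if position.shape[0] != n_features + N_HYPER_BITS:
        raise ValueError(
            f"position length {position.shape[0]} != "
            f"{n_features} features + {N_HYPER_BITS} hyperparameter bits"
        )
    mask = position[:n_features].astype(bool)
    hyper = position[n_features:]
    c_index = _bits_to_int(hyper[:5])
    g_index = _bits_to_int(hyper[5:])
    return mask, grid.value(c_index), grid.value(g_index)


def repair_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """An all-zero mask has undefined fitness: flip one random bit to 1."""
    if mask.any():
        return mask
    repaired = mask.copy()
    repaired[rng.integers(len(mask))] = True
    return repaired


def sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


@dataclass
class BpsoConfig:
    """Swarm settings.

    Defaults follow the published full-scale search: 80 particles, 300
    iterations with the phase switch at 200, velocities clamped to
    (−6, 6), ten-fold cross-validation fitness. Inertia decreases
    linearly from 0.9 to 0.4 (standard PSO schedule) and c1 = c2 = 2.
    """

    n_particles: int = 80
    n_iterations: int = 300
    phase_switch_iteration: int = 200
    v_max: float = 6.0
    inertia: tuple[float, float] = (0.9, 0.4)
    c1: float = 2.0
    c2: float = 2.0
    cv_folds: int = 10
    random_seed: int = 0
    grid: HyperparamGrid = field(default_factory=HyperparamGrid)
    phase2_update: Optional[
        Callable[[np.ndarray, np.ndarray, np.ndarray, np.random.Generator], np.ndarray]
    ] = None

    def __post_init__(self) -> None:
        if self.phase_switch_iteration > self.n_iterations:
            raise ValueError(
                "phase_switch_iteration must not exceed n_iterations"
            )
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")

    def inertia_at(self, iteration: int) -> float:
        start, end = self.inertia
        if self.n_iterations <= 1:
            return start
        frac = iteration / (self.n_iterations - 1)
        return start + (end - start) * frac


@dataclass
class Particle:
    """One swarm member: binary position, real velocity, personal best."""

    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float = -np.inf


@dataclass
class SelectionResult:
    """Outcome of one BPSO run: winning mask, (C, γ) and fitness trace."""

    feature_mask: np.ndarray
    C: float
    gamma: float
    best_fitness: float
    fitness_history: np.ndarray

    def __post_init__(self) -> None:
        self.feature_mask = np.asarray(self.feature_mask, dtype=bool)
        self.fitness_history = np.asarray(self.fitness_history, dtype=float)
        if not self.feature_mask.any():
            raise ValueError("selection mask must have at least one bit set")

    @property
    def n_selected(self) -> int:
        return int(self.feature_mask.sum())

    def save(self, path: str | Path) -> None:
        path = Path(path)
        mask_str = "".join("1" if b else "0" for b in self.feature_mask)
        with open(path, "w") as out:
            out.write("schema_version\t1\n")
            out.write(f"mask\t{mask_str}\n")
            out.write(f"C\t{self.C:.10g}\n")
            out.write(f"gamma\t{self.gamma:.10g}\n")
            out.write(f"best_fitness\t{self.best_fitness:.10g}\n")
        history_path = path.with_suffix(path.suffix + ".history.tsv")
        with open(history_path, "w") as out:
            out.write("iteration\tfitness\n")
            for i, fit in enumerate(self.fitness_history):
                out.write(f"{i}\t{fit:.10g}\n")

    @classmethod
    def load(cls, path: str | Path) -> "SelectionResult":
        path = Path(path)
        fields = {}
        with open(path) as handle:
            for line in handle:
                key, value = line.rstrip("\n").split("\t")
                fields[key] = value
        history_path = path.with_suffix(path.suffix + ".history.tsv")
        history = []
        if history_path.exists():
            with open(history_path) as handle:
                next(handle)
                history = [float(line.split("\t")[1]) for line in handle]
        return cls(
            np.array([c == "1" for c in fields["mask"]]),
            float(fields["C"]),
            float(fields["gamma"]),
            float(fields["best_fitness"]),
            np.array(history),
        )


def init_swarm(n_features: int, config: BpsoConfig) -> list[Particle]:
    """Initialize particles: Bernoulli(0.5) bits, uniform velocities."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(config.random_seed)
    dim = n_features + N_HYPER_BITS
    swarm = []
    for _ in range(config.n_particles):
        position = rng.integers(0, 2, size=dim).astype(np.uint8)
        velocity = rng.uniform(-config.v_max, config.v_max, size=dim)
        swarm.append(Particle(position, velocity, position.copy()))
    return swarm


def make_folds(
    labels: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold partition, fixed for the whole run."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels are degenerate (single class)")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    return [
        (train, test)
        for train, test in skf.split(np.zeros(len(labels)), labels)
    ]


@dataclass
class FoldData:
    """Pre-split per-fold design matrices for fast repeated fitness.

    For label-derived encoders (PSKP) the training-fold matrix must be
    encoded with a table fitted on that fold only; callers supply the
    per-fold matrices directly in that case.
    """

    folds: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]

    @property
    def n_features(self) -> int:
        return self.folds[0][0].shape[1]


def build_fold_data(
    X: np.ndarray,
    labels: np.ndarray,
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
) -> FoldData:
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    return FoldData(
        [
            (X[train], labels[train], X[test], labels[test])
            for train, test in splits
        ]
    )


def _cv_accuracy(fold_data: FoldData, mask: np.ndarray, C: float, gamma: float) -> float:
    accs = []
    for X_tr, y_tr, X_te, y_te in fold_data.folds:
        model = SVC(C=C, gamma=gamma, kernel="rbf", cache_size=64)
        model.fit(X_tr[:, mask], y_tr)
        accs.append(float(np.mean(model.predict(X_te[:, mask]) == y_te)))
    return float(np.mean(accs))


def evaluate_fitness(
    position: np.ndarray,
    matrix: FeatureMatrix | np.ndarray,
    labels: Optional[np.ndarray] = None,
    config: Optional[BpsoConfig] = None,
    fold_data: Optional[FoldData] = None,
) -> float:
    """Ten-fold CV accuracy of the particle's decoded SVM configuration.

    The decoded mask must select at least one feature (apply
    :func:`repair_mask` first when needed).
    """
    config = config or BpsoConfig()
    if fold_data is None:
        if isinstance(matrix, FeatureMatrix):
            X = matrix.values
            labels = matrix.labels if labels is None else labels
        else:
            X = np.asarray(matrix, dtype=float)
        if labels is None:
            raise ValueError("labels required")
        splits = make_folds(labels, config.cv_folds, config.random_seed)
        fold_data = build_fold_data(X, labels, splits)
    mask, C, gamma = decode_particle(
        np.asarray(position), fold_data.n_features, config.grid
    )
    if not mask.any():
        raise ValueError("empty feature mask; repair before evaluation")
    return _cv_accuracy(fold_data, mask, C, gamma)


def update_velocity(
    particle: Particle,
    gbest_position: np.ndarray,
    config: BpsoConfig,
    rng: np.random.Generator,
    inertia: Optional[float] = None,
) -> np.ndarray:
    """v' = w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x), clamped to ±v_max."""
    w = config.inertia[0] if inertia is None else inertia
    x = particle.position.astype(float)
    r1 = rng.uniform(size=x.shape)
    r2 = rng.uniform(size=x.shape)
    v = (
        w * particle.velocity
        + config.c1 * r1 * (particle.pbest_position.astype(float) - x)
        + config.c2 * r2 * (gbest_position.astype(float) - x)
    )
    return np.clip(v, -config.v_max, config.v_max)


def update_position(velocity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sigmoid-transfer sampling: bit_i = 1 with probability s(v_i)."""
    return (rng.uniform(size=velocity.shape) < sigmoid(velocity)).astype(np.uint8)


def _phase2_pull_to_gbest(
    position: np.ndarray,
    velocity: np.ndarray,
    gbest_position: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Convergence accelerator: adopt the gbest bit with prob s(|v|)."""
    adopt = rng.uniform(size=velocity.shape) < sigmoid(np.abs(velocity))
    return np.where(adopt, gbest_position, position).astype(np.uint8)


def run_bpso(
    matrix: FeatureMatrix | np.ndarray,
    labels: Optional[np.ndarray] = None,
    config: Optional[BpsoConfig] = None,
    fold_data: Optional[FoldData] = None,
) -> SelectionResult:
    """Run the two-phase binary PSO search.

    Fully reproducible from ``config.random_seed``; the global-best
    fitness history is non-decreasing by construction. Fitness values are
    memoized on the exact bit pattern, which prunes the many re-visits a
    converging swarm produces.
    """
    config = config or BpsoConfig()
    if isinstance(matrix, FeatureMatrix):
        X = matrix.values
        labels = matrix.labels if labels is None else labels
    else:
        X = np.asarray(matrix, dtype=float) if matrix is not None else None
    if fold_data is None:
        if labels is None:
            raise ValueError("labels required")
        splits = make_folds(labels, config.cv_folds, config.random_seed)
        fold_data = build_fold_data(X, labels, splits)
    n_features = fold_data.n_features
    rng = np.random.default_rng(config.random_seed)
    swarm = init_swarm(n_features, config)
    phase2 = config.phase2_update or _phase2_pull_to_gbest

    cache: dict[bytes, float] = {}

    def fitness_of(position: np.ndarray) -> float:
        key = position.tobytes()
        if key not in cache:
            mask, C, gamma = decode_particle(position, n_features, config.grid)
            cache[key] = _cv_accuracy(fold_data, mask, C, gamma)
        return cache[key]

    def ensure_valid(position: np.ndarray) -> np.ndarray:
        if not position[:n_features].any():
            repaired = position.copy()
            repaired[rng.integers(n_features)] = 1
            return repaired
        return position

    gbest_position: Optional[np.ndarray] = None
    gbest_fitness = -np.inf
    history = np.empty(config.n_iterations)

    for iteration in range(config.n_iterations):
        for particle in swarm:
            particle.position = ensure_valid(particle.position)
            fit = fitness_of(particle.position)
            if fit > particle.pbest_fitness:
                particle.pbest_fitness = fit
                particle.pbest_position = particle.position.copy()
            if fit > gbest_fitness:
                gbest_fitness = fit
                gbest_position = particle.position.copy()
        history[iteration] = gbest_fitness
        if iteration == config.n_iterations - 1:
            break
        w = config.inertia_at(iteration)
        in_phase2 = iteration >= config.phase_switch_iteration
        for particle in swarm:
            particle.velocity = update_velocity(
                particle, gbest_position, config, rng, inertia=w
            )
            if in_phase2:
                particle.position = phase2(
                    particle.position, particle.velocity, gbest_position, rng
                )
            else:
                particle.position = update_position(particle.velocity, rng)

    mask, C, gamma = decode_particle(gbest_position, n_features, config.grid)
    return SelectionResult(mask, C, gamma, gbest_fitness, history)
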