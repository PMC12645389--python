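"""Multi-form evolutionary wrapper feature selection with an SVM fitness.

Two subpopulations co-evolve on the same subset-selection problem under
different formulations ("forms"):

* **Form A** treats it as a bi-objective problem — minimize the
  cross-validated SVM error and the fraction of selected features — with a
  Chebyshev-decomposition environmental selection over evenly spread weight
  vectors.
* **Form B** minimizes a single Chebyshev scalarization of the same two
  objectives with fixed weights (0.9, 0.1), selecting survivors by simple
  truncation.

Knowledge flows between the forms in two ways: *implicitly*, by drawing one
crossover parent from the partner population with some probability during
offspring generation, and *explicitly*, by periodically migrating each
population's elite solutions into the other. The final answer is the
minimum-error member of the first Pareto front of the merged populations.

Fitness is the stratified k-fold cross-validation error of an RBF-kernel
SVM (C = 1) on the selected columns, with per-fold standardization fitted
on the training folds only. The folds are fixed once per run, so fitness is
a deterministic function of the bitstring and results are cached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

#: Fixed Chebyshev weights of the single-objective form (error, fraction).
FORM_B_WEIGHTS: tuple[float, float] = (0.9, 0.1)


@dataclass
class FeatureTable:
    """Subjects × features matrix with binary group labels (MCS = 1, UWS = 0)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be subjects x features, one label per row")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("one name per feature required")
        if np.isnan(self.X).any():
            raise ValueError("feature table contains missing values")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       label_column: str = "label") -> "FeatureTable":
        y = df[label_column].to_numpy()
        X = df.drop(columns=[label_column])
        return cls(X=X.to_numpy(), y=y, feature_names=list(X.columns))


@dataclass
class MFFSConfig:
    subpop_size: int = 100
    n_subpops: int = 2
    iterations: int = 100
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # default 1/chromosome_length
    implicit_transfer_prob: float = 0.2
    transfer_interval: int = 5
    elite_count: int = 5
    cv_folds: int = 5
    svm_C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subpop_size % 2:
            raise ValueError("subpop_size must be even")
        if self.iterations < 1 or self.cv_folds < 2:
            raise ValueError("iterations >= 1 and cv_folds >= 2 required")


@dataclass
class Individual:
    bits: np.ndarray  # uint8 0/1 vector
    objectives: tuple[float, float] | None = None  # (cv_error, feature_frac)


@dataclass
class ParetoSolution:
    """The selected subset plus the final non-dominated front and run history."""

    bits: np.ndarray
    feature_names: list[str]
    cv_error: float
    feature_fraction: float
    front: list[tuple[np.ndarray, tuple[float, float]]] = field(
        default_factory=list)
    history: list[float] = field(default_factory=list)  # best error per gen

    @property
    def cv_accuracy(self) -> float:
        return 1.0 - self.cv_error


class FitnessEvaluator:
    """Deterministic, cached CV-error evaluation of feature subsets.

    Folds are stratified and fixed at construction from ``config.seed``;
    the empty subset scores error 1.0 by convention.
    """

    def __init__(self, table: FeatureTable, config: MFFSConfig):
        self.table = table
        self.config = config
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                              random_state=config.seed)
        self.folds = list(skf.split(table.X, table.y))
        for _tr, te in self.folds:
            if len(np.unique(table.y[te])) < 1:  # pragma: no cover
                raise ValueError("degenerate fold stratification")
        self._cache: dict[bytes, tuple[float, float]] = {}

    def __call__(self, bits: np.ndarray) -> tuple[float, float]:
        bits = np.asarray(bits, dtype=np.uint8)
        key = bits.tobytes()
        if key in self._cache:
            return self._cache[key]
        frac = float(bits.sum()) / bits.size
        if bits.sum() == 0:
            obj = (1.0, 0.0)
        else:
            cols = np.nonzero(bits)[0]
            X, y = self.table.X[:, cols], self.table.y
            accs = []
            for tr, te in self.folds:
                clf = make_pipeline(
                    StandardScaler(),
                    SVC(C=self.config.svm_C, kernel="rbf", gamma="scale"))
                clf.fit(X[tr], y[tr])
                accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
            obj = (1.0 - float(np.mean(accs)), frac)
        self._cache[key] = obj
        return obj


def fitness(bits: np.ndarray, table: FeatureTable,
            config: MFFSConfig) -> tuple[float, float]:
    """(cv_error, feature_fraction) of one subset under fixed seeded folds."""
    return FitnessEvaluator(table, config)(bits)


def scalarize(obj: tuple[float, float],
              weights: tuple[float, float] = FORM_B_WEIGHTS,
              ideal: tuple[float, float] = (0.0, 0.0)) -> float:
    """Chebyshev scalarization ``max_i w_i · |f_i − z*_i|``."""
    return max(weights[0] * abs(obj[0] - ideal[0]),
               weights[1] * abs(obj[1] - ideal[1]))


def _tournament(pop: list[Individual], rng: np.random.Generator) -> Individual:
    a, b = rng.integers(0, len(pop), size=2)
    fa, fb = scalarize(pop[a].objectives), scalarize(pop[b].objectives)
    return pop[a] if fa <= fb else pop[b]


def generate_offspring(parents: list[Individual],
                       partner_pop: list[Individual],
                       config: MFFSConfig,
                       rng: np.random.Generator) -> list[np.ndarray]:
    """Binary-tournament selection, uniform crossover, per-bit mutation.

    With probability ``implicit_transfer_prob`` the second parent of a pair
    is drawn from the partner population (implicit knowledge transfer).
    Returns ``subpop_size`` offspring bitstrings.
    """
    if not parents or not partner_pop:
        raise ValueError("both populations must be nonempty")
    L = parents[0].bits.size
    p_mut = config.mutation_prob if config.mutation_prob is not None else 1.0 / L
    out: list[np.ndarray] = []
    while len(out) < config.subpop_size:
        p1 = _tournament(parents, rng)
        pool = partner_pop if rng.uniform() < config.implicit_transfer_prob \
            else parents
        p2 = _tournament(pool, rng)
        c1, c2 = p1.bits.copy(), p2.bits.copy()
        if rng.uniform() < config.crossover_prob:
            swap = rng.uniform(size=L) < 0.5
            c1[swap], c2[swap] = p2.bits[swap], p1.bits[swap]
        for c in (c1, c2):
            flip = rng.uniform(size=L) < p_mut
            c[flip] ^= 1
        out.extend([c1, c2])
    return out[: config.subpop_size]


def explicit_transfer(pop_a: list[Individual], pop_b: list[Individual],
                      elite_count: int,
                      ) -> tuple[list[Individual], list[Individual]]:
    """Migrate each population's elites over the other's worst members.

    Ranking uses the fixed-weight Chebyshev scalarization; population sizes
    are conserved and the best scalarized fitness of each population cannot
    worsen.
    """
    if elite_count == 0:
        return list(pop_a), list(pop_b)
    if elite_count > min(len(pop_a), len(pop_b)):
        raise ValueError("elite_count exceeds population size")

    def sorted_pop(pop: list[Individual]) -> list[Individual]:
        return sorted(pop, key=lambda ind: scalarize(ind.objectives))

    sa, sb = sorted_pop(pop_a), sorted_pop(pop_b)
    elites_a = [Individual(i.bits.copy(), i.objectives)
                for i in sa[:elite_count]]
    elites_b = [Individual(i.bits.copy(), i.objectives)
                for i in sb[:elite_count]]
    new_a = sa[: len(sa) - elite_count] + elites_b
    new_b = sb[: len(sb) - elite_count] + elites_a
    return new_a, new_b


def environmental_selection(union: list[Individual],
                            config: MFFSConfig) -> list[Individual]:
    """Chebyshev-decomposition survival over evenly spread weight vectors.

    ``subpop_size`` weight vectors λ span (1,0)…(0,1); each keeps the union
    member minimizing ``max_i λ_i·|f_i − z*_i|`` with z* the ideal point of
    the union. A member already kept is replaced by the next-best for that
    weight vector.
    """
    H = config.subpop_size
    if len(union) < H:
        raise ValueError("union smaller than the target population size")
    objs = np.array([ind.objectives for ind in union])
    ideal = objs.min(axis=0)
    w1 = np.linspace(1.0, 0.0, H)
    lambdas = np.stack([w1, 1.0 - w1], axis=1)
    dev = np.abs(objs - ideal[None, :])  # (n, 2)
    g = np.maximum(lambdas[:, None, 0] * dev[None, :, 0],
                   lambdas[:, None, 1] * dev[None, :, 1])  # (H, n)
    chosen: list[int] = []
    taken = np.zeros(len(union), dtype=bool)
    for h in range(H):
        order = np.argsort(g[h], kind="stable")
        pick = next((i for i in order if not taken[i]), None)
        if pick is None:  # pragma: no cover - len(union) >= H guarantees a pick
            pick = int(order[0])
        taken[pick] = True
        chosen.append(int(pick))
    return [union[i] for i in chosen]


def pareto_front(pop: list[Individual]) -> list[Individual]:
    """Mutually non-dominated members (minimization on both objectives)."""
    front: list[Individual] = []
    for ind in pop:
        f = ind.objectives
        dominated = any(
            (o.objectives[0] <= f[0] and o.objectives[1] <= f[1]
             and o.objectives != f)
            for o in pop)
        if not dominated:
            front.append(ind)
    # Deduplicate identical objective pairs, keeping one representative each.
    seen: set[tuple[float, float]] = set()
    out = []
    for ind in front:
        if ind.objectives not in seen:
            seen.add(ind.objectives)
            out.append(ind)
    return out


def run_mffs(table: FeatureTable, config: MFFSConfig | None = None,
             ) -> ParetoSolution:
    """Run the full two-population search and return the selected subset.

    Both subpopulations are seeded with the all-features chromosome, so the
    search never returns a subset worse (under the shared folds) than the
    full feature set. The winner is the first-Pareto-front member of the
    merged final populations with minimum CV error; ties are broken toward
    fewer features, then the lexicographically smaller bitstring.
    """
    if config is None:
        config = MFFSConfig()
    rng = np.random.default_rng(config.seed)
    evaluator = FitnessEvaluator(table, config)
    L = table.n_features

    def make_pop() -> list[Individual]:
        bits = (rng.uniform(size=(config.subpop_size, L)) < 0.5).astype(np.uint8)
        bits[0] = 1  # seed the full feature set
        return [Individual(b, evaluator(b)) for b in bits]

    pops = [make_pop() for _ in range(2)]
    history: list[float] = []
    for gen in range(1, config.iterations + 1):
        new_pops = []
        for idx, pop in enumerate(pops):
            partner = pops[1 - idx]
            kids = generate_offspring(pop, partner, config, rng)
            union = pop + [Individual(b, evaluator(b)) for b in kids]
            if idx == 0:  # Form A: bi-objective decomposition selection
                new_pops.append(environmental_selection(union, config))
            else:  # Form B: truncation on the fixed-weight scalarization
                new_pops.append(sorted(
                    union, key=lambda ind: scalarize(ind.objectives)
                )[: config.subpop_size])
        pops = new_pops
        if config.transfer_interval and gen % config.transfer_interval == 0:
            pops = list(explicit_transfer(pops[0], pops[1],
                                          config.elite_count))
        history.append(min(ind.objectives[0] for p in pops for ind in p))

    merged = pops[0] + pops[1]
    front = pareto_front(merged)
    best = min(front, key=lambda ind: (ind.objectives[0],
                                       int(ind.bits.sum()),
                                       tuple(ind.bits)))
    names = [n for n, b in zip(table.feature_names, best.bits) if b]
    return ParetoSolution(
        bits=best.bits.copy(), feature_names=names,
        cv_error=best.objectives[0], feature_fraction=best.objectives[1],
        front=[(i.bits.copy(), i.objectives) for i in front],
        history=history)
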