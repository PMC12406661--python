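"""Model selection tool (MST): CART over GA-selected model subsets.

The MST is a shallow covariate-split decision tree whose leaves name a
population-PK model.  It is built in three stages:

1. every timeframe is labelled with the subset model achieving the lowest
   mean PAPE of its population predictions;
2. a depth-limited CART (Gini impurity) maps frozen covariates to that
   label;
3. a genetic algorithm searches over model subsets (bitmasks of the
   registry), scoring each subset by the mean over 10 cross-validation
   folds of the held-out mean PAPE obtained when the fold's timeframes use
   the models the tree assigns them.  Folds are grouped by treatment
   episode so concentrations of one course never appear on both sides.

The published reference tree routes patients by CKD-EPI eGFR and treatment
day among the Staatz, Kim and Zhou models.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.tree import DecisionTreeClassifier

from .covariates import CovariateVector, Timeframe
from .metrics import ErrorTable
from .pk import PKModelSpec

#: Covariate families offered to the tree by default.
DEFAULT_SPLIT_COVARIATES = (
    "egfr_ckd_epi",
    "crcl_cg",
    "creatinine",
    "treatment_day",
    "age",
    "weight",
    "bmi",
    "sex",
    "rrt_active",
)


class MSTError(ValueError):
    pass


# ---------------------------------------------------------------------------
# decision tree


@dataclass(frozen=True)
class TreeLeaf:
    model: str

    @property
    def depth(self) -> int:
        return 0


@dataclass(frozen=True)
class TreeNode:
    covariate: str
    threshold: float
    left: "TreeNode | TreeLeaf"  # taken when value < threshold
    right: "TreeNode | TreeLeaf"  # taken when value >= threshold

    @property
    def depth(self) -> int:
        return 1 + max(self.left.depth, self.right.depth)


DecisionTree = TreeNode | TreeLeaf


def apply_mst(tree: DecisionTree, covariates: CovariateVector) -> str:
    """Deterministic root-to-leaf descent; "<" goes left, "≥" goes right."""
    node = tree
    while isinstance(node, TreeNode):
        try:
            value = covariates[node.covariate]
        except KeyError:
            raise MSTError(f"missing split covariate {node.covariate!r}") from None
        node = node.left if value < node.threshold else node.right
    return node.model


def tree_models(tree: DecisionTree) -> set[str]:
    if isinstance(tree, TreeLeaf):
        return {tree.model}
    return tree_models(tree.left) | tree_models(tree.right)


def tree_thresholds(tree: DecisionTree, covariate: str | None = None) -> list[float]:
    """All split thresholds in the tree, optionally for one covariate."""
    if isinstance(tree, TreeLeaf):
        return []
    own = [tree.threshold] if covariate in (None, tree.covariate) else []
    return own + tree_thresholds(tree.left, covariate) + tree_thresholds(tree.right, covariate)


def tree_to_dict(tree: DecisionTree) -> dict:
    if isinstance(tree, TreeLeaf):
        return {"model": tree.model}
    return {
        "covariate": tree.covariate,
        "threshold": tree.threshold,
        "left": tree_to_dict(tree.left),
        "right": tree_to_dict(tree.right),
    }


def tree_from_dict(data: dict) -> DecisionTree:
    if "model" in data:
        return TreeLeaf(model=str(data["model"]))
    return TreeNode(
        covariate=str(data["covariate"]),
        threshold=float(data["threshold"]),
        left=tree_from_dict(data["left"]),
        right=tree_from_dict(data["right"]),
    )


def save_tree(tree: DecisionTree, path) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(tree), fh, indent=2)


def load_tree(path) -> DecisionTree:
    with open(path) as fh:
        return tree_from_dict(json.load(fh))


def reference_mst() -> DecisionTree:
    """The published depth-3 tree over CKD-EPI eGFR and treatment day.

    eGFR < 31 → Staatz; eGFR ≥ 31 on treatment day 1 → Kim;
    later days with eGFR ≥ 125 → Kim; otherwise (31 ≤ eGFR < 125) → Zhou.
    """
    return TreeNode(
        covariate="egfr_ckd_epi",
        threshold=31.0,
        left=TreeLeaf("Staatz"),
        right=TreeNode(
            covariate="treatment_day",
            threshold=2.0,
            left=TreeLeaf("Kim"),
            right=TreeNode(
                covariate="egfr_ckd_epi",
                threshold=125.0,
                left=TreeLeaf("Zhou"),
                right=TreeLeaf("Kim"),
            ),
        ),
    )


# ---------------------------------------------------------------------------
# labelling and CART


def label_best_model(
    timeframe_index: int, subset: Sequence[int], table: ErrorTable
) -> str:
    """Subset model with the lowest mean PAPE on the timeframe (ties: registry order)."""
    best_name, best_pape = None, math.inf
    for i in subset:
        value = table.timeframe_mean_pape(i, timeframe_index)
        if value < best_pape:
            best_name, best_pape = table.model_names[i], value
    if best_name is None or math.isinf(best_pape):
        raise MSTError(f"no subset model evaluable on timeframe {timeframe_index}")
    return best_name


def label_subset(table: ErrorTable, subset: Sequence[int]) -> np.ndarray:
    """Best-model registry index per timeframe, restricted to *subset*."""
    labels = np.empty(len(table.timeframes), dtype=int)
    for t in range(len(table.timeframes)):
        best_i, best_pape = -1, math.inf
        for i in subset:
            value = table.timeframe_mean_pape(i, t)
            if value < best_pape:
                best_i, best_pape = i, value
        if best_i < 0:
            raise MSTError(f"no subset model evaluable on timeframe {t}")
        labels[t] = best_i
    return labels


def _covariate_matrix(
    timeframes: Sequence[Timeframe], covariate_names: Sequence[str]
) -> np.ndarray:
    X = np.empty((len(timeframes), len(covariate_names)))
    for r, tf in enumerate(timeframes):
        for c, name in enumerate(covariate_names):
            X[r, c] = tf.frozen_covariates.get(name, np.nan)
    return X


def fit_cart(
    X: np.ndarray,
    labels: np.ndarray,
    covariate_names: Sequence[str],
    model_names: Sequence[str],
    max_depth: int = 3,
    min_leaf_fraction: float = 0.05,
) -> DecisionTree:
    """Greedy Gini CART on frozen covariates, exported as a DecisionTree.

    ``labels`` are registry indices; sklearn's lowest-class majority-tie rule
    therefore reproduces the registry-order tie-break.  Thresholds fall at
    midpoints between adjacent observed values, so "< threshold goes left"
    matches the fitted partition on the training data.
    """
    classes = np.unique(labels)
    if classes.size == 1:
        return TreeLeaf(model_names[int(classes[0])])
    min_leaf = max(1, math.ceil(min_leaf_fraction * len(labels)))
    clf = DecisionTreeClassifier(
        criterion="gini",
        max_depth=max_depth,
        min_samples_leaf=min_leaf,
        random_state=0,
    )
    clf.fit(X, labels)
    tree = clf.tree_

    def convert(node: int) -> DecisionTree:
        if tree.children_left[node] == -1:
            counts = tree.value[node][0]
            cls = clf.classes_[int(np.argmax(counts))]
            return TreeLeaf(model_names[int(cls)])
        return TreeNode(
            covariate=covariate_names[int(tree.feature[node])],
            threshold=float(tree.threshold[node]),
            left=convert(int(tree.children_left[node])),
            right=convert(int(tree.children_right[node])),
        )

    return convert(0)


# ---------------------------------------------------------------------------
# GA configuration and fitness


@dataclass
class GAConfig:
    """Hyperparameters of the subset search and tree fit."""

    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # default: 1 / registry size per bit
    elitism: int = 2
    tournament_size: int = 3
    cv_folds: int = 10
    max_depth: int = 3
    min_leaf_fraction: float = 0.05
    split_covariates: tuple[str, ...] = DEFAULT_SPLIT_COVARIATES
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.crossover_rate,) + (
            () if self.mutation_rate is None else (self.mutation_rate,)
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must be in [0, 1], got {rate}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")


@dataclass(frozen=True)
class SubsetEvaluation:
    subset: tuple[int, ...]  # registry indices, sorted
    subset_names: tuple[str, ...]
    fitness: float  # mean over folds of held-out mean PAPE, %
    tree: DecisionTree  # refitted on all timeframes


def episode_folds(
    timeframes: Sequence[Timeframe], n_folds: int, seed: int
) -> list[np.ndarray]:
    """Seeded episode-grouped fold assignment (timeframe indices per fold)."""
    episodes = sorted({tf.episode_id for tf in timeframes})
    if len(episodes) < n_folds:
        # fall back to timeframe-level folds when episodes are too few,
        # still deterministic
        indices = np.arange(len(timeframes))
        if indices.size < n_folds:
            raise MSTError(
                f"need at least {n_folds} timeframes for {n_folds}-fold CV, got {indices.size}"
            )
        rng = np.random.default_rng(seed)
        rng.shuffle(indices)
        return [np.sort(part) for part in np.array_split(indices, n_folds)]
    rng = np.random.default_rng(seed)
    order = list(episodes)
    rng.shuffle(order)
    fold_of_episode = {ep: i % n_folds for i, ep in enumerate(order)}
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for idx, tf in enumerate(timeframes):
        folds[fold_of_episode[tf.episode_id]].append(idx)
    return [np.array(f, dtype=int) for f in folds]


def cv_fitness(
    subset: Sequence[int],
    table: ErrorTable,
    config: GAConfig,
    folds: Sequence[np.ndarray] | None = None,
    X: np.ndarray | None = None,
) -> float:
    """Cross-validated fitness of a model subset (lower is better).

    Per fold: fit the CART on the other folds' labelled timeframes, assign a
    model to each held-out timeframe, and pool the held-out observations'
    PAPE; the fitness is the mean of the fold means.
    """
    if folds is None:
        folds = episode_folds(table.timeframes, config.cv_folds, config.seed)
    if X is None:
        X = _covariate_matrix(table.timeframes, config.split_covariates)
    labels = label_subset(table, subset)
    fold_means: list[float] = []
    for fold in folds:
        mask = np.ones(len(table.timeframes), dtype=bool)
        mask[fold] = False
        train_idx = np.flatnonzero(mask)
        tree = fit_cart(
            X[train_idx],
            labels[train_idx],
            config.split_covariates,
            table.model_names,
            max_depth=config.max_depth,
            min_leaf_fraction=config.min_leaf_fraction,
        )
        held_papes: list[np.ndarray] = []
        for t in fold:
            model = apply_mst(tree, table.timeframes[t].frozen_covariates)
            values = table.ppe_values(table.model_names.index(model), t)
            if values is not None:
                held_papes.append(np.abs(values))
        if held_papes:
            fold_means.append(float(np.mean(np.concatenate(held_papes))))
    if not fold_means:
        raise MSTError("no fold produced an evaluable held-out timeframe")
    return float(np.mean(fold_means))


def evaluate_subset(
    subset: Sequence[int], table: ErrorTable, config: GAConfig,
    folds: Sequence[np.ndarray] | None = None, X: np.ndarray | None = None,
) -> SubsetEvaluation:
    fitness = cv_fitness(subset, table, config, folds=folds, X=X)
    if X is None:
        X = _covariate_matrix(table.timeframes, config.split_covariates)
    tree = fit_cart(
        X,
        label_subset(table, subset),
        config.split_covariates,
        table.model_names,
        max_depth=config.max_depth,
        min_leaf_fraction=config.min_leaf_fraction,
    )
    ordered = tuple(sorted(subset))
    return SubsetEvaluation(
        subset=ordered,
        subset_names=tuple(table.model_names[i] for i in ordered),
        fitness=fitness,
        tree=tree,
    )


# ---------------------------------------------------------------------------
# genetic algorithm


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def ga_search(
    registry: Sequence[PKModelSpec],
    timeframes: Sequence[Timeframe] | ErrorTable,
    config: GAConfig | None = None,
) -> SubsetEvaluation:
    """Evolve model-subset bitmasks minimizing the cross-validated fitness.

    Tournament selection, uniform crossover, per-bit mutation and elitism;
    empty offspring are repaired by switching one random bit on.  The search
    is fully reproducible from ``config.seed`` and returns the best-ever
    subset with its tree refitted on all timeframes.
    """
    config = config or GAConfig()
    table = timeframes if isinstance(timeframes, ErrorTable) else ErrorTable(registry, timeframes)
    n = len(table.registry)
    if n < 1:
        raise MSTError("registry must contain at least one model")
    folds = episode_folds(table.timeframes, config.cv_folds, config.seed)
    X = _covariate_matrix(table.timeframes, config.split_covariates)
    p_mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / n
    rng = np.random.default_rng(config.seed)

    cache: dict[tuple[int, ...], float] = {}

    def fitness_of(mask: np.ndarray) -> float:
        key = tuple(np.flatnonzero(mask))
        if key not in cache:
            cache[key] = cv_fitness(key, table, config, folds=folds, X=X)
        return cache[key]

    population = [
        _repair(rng.random(n) < 0.5, rng) for _ in range(config.population_size)
    ]
    scores = np.array([fitness_of(m) for m in population])
    best_mask = population[int(np.argmin(scores))].copy()
    best_score = float(scores.min())

    for _ in range(config.generations):
        order = np.argsort(scores, kind="stable")
        elites = [population[i].copy() for i in order[: config.elitism]]
        children: list[np.ndarray] = []
        while len(children) < config.population_size - config.elitism:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(population), size=config.tournament_size)
                winner = min(contenders, key=lambda i: scores[i])
                parents.append(population[winner])
            if rng.random() < config.crossover_rate:
                take_first = rng.random(n) < 0.5
                child = np.where(take_first, parents[0], parents[1])
            else:
                child = parents[0].copy()
            flip = rng.random(n) < p_mut
            child = np.logical_xor(child, flip)
            children.append(_repair(child, rng))
        population = elites + children
        scores = np.array([fitness_of(m) for m in population])
        gen_best = int(np.argmin(scores))
        if scores[gen_best] < best_score:
            best_score = float(scores[gen_best])
            best_mask = population[gen_best].copy()

    return evaluate_subset(tuple(np.flatnonzero(best_mask)), table, config, folds=folds, X=X)


def exhaustive_search(
    registry: Sequence[PKModelSpec],
    timeframes: Sequence[Timeframe] | ErrorTable,
    config: GAConfig | None = None,
) -> SubsetEvaluation:
    """Enumerate every non-empty subset (oracle for small registries)."""
    config = config or GAConfig()
    table = timeframes if isinstance(timeframes, ErrorTable) else ErrorTable(registry, timeframes)
    n = len(table.registry)
    folds = episode_folds(table.timeframes, config.cv_folds, config.seed)
    X = _covariate_matrix(table.timeframes, config.split_covariates)
    best: SubsetEvaluation | None = None
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            fitness = cv_fitness(subset, table, config, folds=folds, X=X)
            if best is None or fitness < best.fitness:
                best = evaluate_subset(subset, table, config, folds=folds, X=X)
    assert best is not None
    return best


def mst_assignment_rate(
    tree: DecisionTree, subset: Sequence[int], table: ErrorTable
) -> float:
    """Share of timeframes (%) where the tree picks the individually best model."""
    if not table.timeframes:
        raise MSTError("no timeframes to assess")
    hits = 0
    for t, tf in enumerate(table.timeframes):
        if apply_mst(tree, tf.frozen_covariates) == label_best_model(t, subset, table):
            hits += 1
    return hits / len(table.timeframes) * 100.0


# ---------------------------------------------------------------------------
# estimator


class ModelSelectionTool(BaseEstimator):
    """GA + CART model selection tool, sklearn estimator style.

    ``fit`` runs the genetic subset search on labelled timeframes;
    ``predict`` maps covariate vectors (or timeframes) to model names via the
    fitted tree.

    Parameters mirror :class:`GAConfig`; ``random_state`` seeds the search.

    Attributes
    ----------
    subset_ : tuple of registry indices in the selected subset
    subset_names_ : tuple of model names
    tree_ : DecisionTree fitted on all timeframes
    fitness_ : cross-validated mean PAPE of the subset, %
    """

    def __init__(
        self,
        registry: Sequence[PKModelSpec] = (),
        population_size: int = 50,
        generations: int = 100,
        crossover_rate: float = 0.8,
        mutation_rate: float | None = None,
        elitism: int = 2,
        tournament_size: int = 3,
        cv_folds: int = 10,
        max_depth: int = 3,
        min_leaf_fraction: float = 0.05,
        split_covariates: tuple[str, ...] = DEFAULT_SPLIT_COVARIATES,
        random_state: int = 0,
    ):
        self.registry = registry
        self.population_size = population_size
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.elitism = elitism
        self.tournament_size = tournament_size
        self.cv_folds = cv_folds
        self.max_depth = max_depth
        self.min_leaf_fraction = min_leaf_fraction
        self.split_covariates = split_covariates
        self.random_state = random_state

    def _config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            elitism=self.elitism,
            tournament_size=self.tournament_size,
            cv_folds=self.cv_folds,
            max_depth=self.max_depth,
            min_leaf_fraction=self.min_leaf_fraction,
            split_covariates=tuple(self.split_covariates),
            seed=self.random_state,
        )

    def fit(self, X: Sequence[Timeframe], y: None = None) -> "ModelSelectionTool":
        if not self.registry:
            raise ValueError("registry must contain at least one model")
        table = X if isinstance(X, ErrorTable) else ErrorTable(self.registry, X)
        result = ga_search(table.registry, table, self._config())
        self.error_table_ = table
        self.result_ = result
        self.subset_ = result.subset
        self.subset_names_ = result.subset_names
        self.tree_ = result.tree
        self.fitness_ = result.fitness
        return self

    def predict(self, X: Sequence[Timeframe] | Sequence[CovariateVector]) -> list[str]:
        vectors = [
            x.frozen_covariates if isinstance(x, Timeframe) else x for x in X
        ]
        return [apply_mst(self.tree_, v) for v in vectors]

    def assignment_rate(self, X: Sequence[Timeframe] | ErrorTable | None = None) -> float:
        table = X if isinstance(X, ErrorTable) else (
            self.error_table_ if X is None else ErrorTable(list(self.registry), X)
        )
        return mst_assignment_rate(self.tree_, self.subset_, table)
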