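"""AutoML engine: joint learner / feature / hyperparameter search.

One continuous solution vector in the unit cube encodes three decision
spaces at once:

    x = ( k | delta_1 .. delta_m | lambda_1 .. lambda_p )

where ``k`` selects the base learner (1=LR, 2=SVM, 3=XGBoost, 4=LightGBM),
``delta`` is a binary feature mask (gene > 0.5), and ``lambda`` holds
normalized hyperparameter genes mapped into the selected model's ranges
(log-scaled where appropriate, rounded for integers).  The improved leech
optimizer searches this cube against a dynamically weighted fitness

    f(x) = w1(t) * ACC_cv  +  w2(t) * (1 - ||delta||_0 / m)  +  w3 * exp(-T / T_max)

combining stratified 10-fold cross-validated accuracy, feature sparsity and
a training-cost term.  w1 decays and w2 grows over iterations (accuracy
first, parsimony terminally); T is a deterministic per-candidate cost proxy
so the fitness is bit-reproducible.  The search only ever sees the training
table; held-out rows never enter the loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import optimizer as opt
from .cohort import OUTCOME_COLUMN

__all__ = [
    "MODEL_NAMES",
    "Param",
    "HyperparamSpace",
    "default_space",
    "FitnessWeights",
    "SolutionVector",
    "FittedRiskModel",
    "decode_solution",
    "cv_fitness",
    "fitness_components",
    "search",
    "fit_baseline",
    "SearchResult",
]

MODEL_NAMES = {1: "logistic_regression", 2: "svm", 3: "xgboost", 4: "lightgbm"}

# deterministic relative training-cost units per learner (see methods note)
_MODEL_COST = {1: 1.0, 2: 4.0, 3: 8.0, 4: 6.0}


@dataclass(frozen=True)
class Param:
    name: str
    low: float
    high: float
    scale: str = "linear"  # linear | log
    kind: str = "continuous"  # continuous | integer

    def __post_init__(self) -> None:
        if self.low >= self.high:
            raise ValueError(f"{self.name}: lower bound must be < upper bound")
        if self.scale == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log-scaled bounds must be positive")

    def map_gene(self, g: float) -> float | int:
        g = min(max(g, 0.0), 1.0)
        if self.scale == "log":
            value = 10.0 ** (
                math.log10(self.low)
                + g * (math.log10(self.high) - math.log10(self.low))
            )
        else:
            value = self.low + g * (self.high - self.low)
        if self.kind == "integer":
            return int(min(max(round(value), self.low), self.high))
        return value


@dataclass(frozen=True)
class HyperparamSpace:
    """Per-model hyperparameter ranges; n_genes is the widest model's size.

    ``n_estimators`` fixes the tree count used by the boosted learners (not
    itself searched).
    """

    params: dict[int, tuple[Param, ...]]
    n_estimators: int = 80

    @property
    def n_genes(self) -> int:
        return max(len(v) for v in self.params.values())


def default_space(n_estimators: int = 80) -> HyperparamSpace:
    """Default conditional search space.

    The LightGBM block uses the published ranges (learning rate [1e-5, 0.1]
    log, depth 3-12, subsample 0.6-1.0, L2 [1e-6, 1e-2] log); XGBoost
    mirrors them; LR and SVM expose their usual regularization knobs.
    Boosted ensembles use a fixed tree count (``n_estimators``).
    """
    gbm = (
        Param("learning_rate", 1e-5, 0.1, scale="log"),
        Param("max_depth", 3, 12, kind="integer"),
        Param("subsample", 0.6, 1.0),
        Param("reg_lambda", 1e-6, 1e-2, scale="log"),
    )
    return HyperparamSpace(
        params={
            1: (Param("C", 1e-3, 1e3, scale="log"),),
            2: (Param("C", 1e-2, 1e2, scale="log"),
                Param("gamma", 1e-4, 1e1, scale="log")),
            3: gbm,
            4: gbm,
        },
        n_estimators=n_estimators,
    )


@dataclass(frozen=True)
class FitnessWeights:
    """Dynamic weights: w1 decays accuracy emphasis, w2 raises sparsity.

    The terminal sparsity weight acts as a tie-breaker: the per-feature
    parsimony bonus (w2_end / m / w1_end, about 0.4 accuracy points at
    m = 13) stays below the resolution of repeated cross-validation, so a
    feature is pruned only when it contributes no measurable accuracy —
    never in exchange for a measurable accuracy loss.  See docs/methods.md
    for the calibration argument.
    """

    w1_start: float = 1.0
    w1_end: float = 0.6
    w2_start: float = 0.0
    w2_end: float = 0.03
    w3: float = 0.05
    t_max_cost: float = 8.0  # normalizer for the cost proxy (max learner cost)

    def w1(self, t: float) -> float:
        return self.w1_start + (self.w1_end - self.w1_start) * min(max(t, 0.0), 1.0)

    def w2(self, t: float) -> float:
        return self.w2_start + (self.w2_end - self.w2_start) * min(max(t, 0.0), 1.0)


@dataclass(frozen=True)
class SolutionVector:
    k: int
    delta: np.ndarray  # bool mask, length m
    hyperparams: dict[str, float | int]
    raw_lambda: np.ndarray

    @property
    def model_name(self) -> str:
        return MODEL_NAMES[self.k]

    def cache_key(self) -> tuple:
        return (
            self.k,
            self.delta.tobytes(),
            tuple(sorted((n, round(float(v), 12)) for n, v in self.hyperparams.items())),
        )


@dataclass
class FittedRiskModel:
    """A fitted learner plus the exact feature view it was trained on."""

    model_id: int
    feature_names: list[str]
    estimator: object
    artifact_version: str = "ppcml-risk-model-1"

    @property
    def model_name(self) -> str:
        return MODEL_NAMES[self.model_id]

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise ValueError(f"table is missing model features: {missing}")
        X = table[self.feature_names].to_numpy(dtype=float)
        return self.estimator.predict_proba(X)[:, 1]


def decode_solution(
    raw: np.ndarray, space: HyperparamSpace, m: int
) -> SolutionVector:
    """Decode a unit-cube vector into (learner, feature mask, hyperparams).

    ``k = 1 + floor(4 * raw[0])`` clamped to 4; mask bits are genes > 0.5
    with an all-zero mask repaired by setting the single largest feature
    gene; lambda genes beyond the selected model's parameter count are
    ignored (conditional-space convention).
    """
    raw = np.asarray(raw, dtype=float)
    if len(raw) != 1 + m + space.n_genes:
        raise ValueError(
            f"expected vector of length {1 + m + space.n_genes}, got {len(raw)}"
        )
    k = min(4, 1 + int(raw[0] * 4))
    feature_genes = raw[1:1 + m]
    delta = feature_genes > 0.5
    if not delta.any():
        delta = np.zeros(m, dtype=bool)
        delta[int(np.argmax(feature_genes))] = True
    lam = raw[1 + m:]
    params = space.params[k]
    hyper = {p.name: p.map_gene(lam[i]) for i, p in enumerate(params)}
    return SolutionVector(k=k, delta=delta, hyperparams=hyper, raw_lambda=lam.copy())


def _build_estimator(
    k: int, hyperparams: dict, seed: int, n_estimators: int = 80
):
    # LR and SVM are scale-sensitive (raw features span ~0.8 to ~240 units),
    # so both sit behind a standardizer; trees are scale-invariant
    if k == 1:
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=seed, **hyperparams),
        )
    if k == 2:
        # Platt-style sigmoid calibration via SVC's built-in probability fit
        return make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", probability=True, random_state=seed, **hyperparams),
        )
    if k == 3:
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=n_estimators, tree_method="hist", n_jobs=1,
            random_state=seed, eval_metric="logloss", verbosity=0, **hyperparams,
        )
    if k == 4:
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=n_estimators, n_jobs=1, random_state=seed,
            verbose=-1, **hyperparams,
        )
    raise ValueError(f"unknown model id {k}")


def _cost_proxy(k: int, n_selected: int, m: int) -> float:
    """Deterministic relative training cost of a candidate configuration."""
    return _MODEL_COST[k] * (0.5 + 0.5 * n_selected / m)


def _split_xy(train_table: pd.DataFrame, feature_columns: list[str] | None):
    if feature_columns is None:
        feature_columns = [c for c in train_table.columns if c != OUTCOME_COLUMN]
    X = train_table[feature_columns]
    y = train_table[OUTCOME_COLUMN].to_numpy(dtype=int)
    return X, y, feature_columns


def _raw_components(
    sol: SolutionVector,
    train_table: pd.DataFrame,
    t_max_cost: float,
    seed: int,
    folds: int,
    feature_columns: list[str] | None,
    n_estimators: int,
    cv_seed: int | None = None,
) -> tuple[float, float, float]:
    """(cv_accuracy, sparsity, efficiency) for one candidate; weight-free."""
    X, y, feature_columns = _split_xy(train_table, feature_columns)
    m = len(feature_columns)
    if len(sol.delta) != m:
        raise ValueError(f"mask length {len(sol.delta)} != feature count {m}")
    cols = [c for c, keep in zip(feature_columns, sol.delta) if keep]
    Xs = X[cols].to_numpy(dtype=float)
    est = _build_estimator(sol.k, sol.hyperparams, seed, n_estimators)
    cv = StratifiedKFold(
        n_splits=folds, shuffle=True,
        random_state=seed if cv_seed is None else cv_seed,
    )
    acc = float(cross_val_score(est, Xs, y, cv=cv, scoring="accuracy").mean())
    sparsity = 1.0 - len(cols) / m
    efficiency = math.exp(-_cost_proxy(sol.k, len(cols), m) / t_max_cost)
    return acc, sparsity, efficiency


def fitness_components(
    sol: SolutionVector,
    train_table: pd.DataFrame,
    weights: FitnessWeights,
    t: float,
    seed: int = 0,
    folds: int = 10,
    feature_columns: list[str] | None = None,
    n_estimators: int = 80,
) -> dict[str, float]:
    """The three fitness terms plus the combined value, for one candidate."""
    acc, sparsity, efficiency = _raw_components(
        sol, train_table, weights.t_max_cost, seed, folds, feature_columns,
        n_estimators,
    )
    value = weights.w1(t) * acc + weights.w2(t) * sparsity + weights.w3 * efficiency
    return {
        "cv_accuracy": acc,
        "sparsity": sparsity,
        "efficiency": efficiency,
        "w1": weights.w1(t),
        "w2": weights.w2(t),
        "w3": weights.w3,
        "fitness": value,
    }


def cv_fitness(
    sol: SolutionVector,
    train_table: pd.DataFrame,
    weights: FitnessWeights,
    t: float,
    seed: int = 0,
    folds: int = 10,
    feature_columns: list[str] | None = None,
    n_estimators: int = 80,
) -> float:
    """Dynamically weighted CV fitness of one candidate (to maximize)."""
    return fitness_components(
        sol, train_table, weights, t, seed, folds, feature_columns, n_estimators
    )["fitness"]


def _gene_for(param: Param, value: float) -> float:
    """Inverse of Param.map_gene (clipped to [0, 1])."""
    if param.scale == "log":
        g = (math.log10(value) - math.log10(param.low)) / (
            math.log10(param.high) - math.log10(param.low)
        )
    else:
        g = (value - param.low) / (param.high - param.low)
    return min(max(g, 0.0), 1.0)


# sensible reference hyperparameters per learner for warm-start candidates
_WARM_VALUES = {
    1: {"C": 1.0},
    2: {"C": 1.0},  # gamma filled per feature count at call time
    3: {"learning_rate": 0.05, "max_depth": 7, "subsample": 0.8,
        "reg_lambda": 1e-4},
    4: {"learning_rate": 0.05, "max_depth": 7, "subsample": 0.8,
        "reg_lambda": 1e-4},
}


def _warm_start_rows(space: HyperparamSpace, m: int) -> np.ndarray:
    """Four full-feature reference candidates, one per base learner.

    Standard AutoML warm start: the search population always contains each
    learner on all features at reference hyperparameters, so the optimized
    model can only improve on (never silently lose to) the unpruned
    reference configurations.
    """
    rows = []
    for k in (1, 2, 3, 4):
        row = np.full(1 + m + space.n_genes, 0.5)
        row[0] = (k - 0.5) / 4.0
        row[1:1 + m] = 0.9  # every feature bit on
        values = dict(_WARM_VALUES[k])
        if k == 2:
            values["gamma"] = 1.0 / m  # 'scale' heuristic on standardized data
        for i, p in enumerate(space.params[k]):
            row[1 + m + i] = _gene_for(p, values.get(p.name, p.map_gene(0.5)))
        rows.append(row)
    return np.array(rows)


@dataclass
class SearchResult:
    best_solution: SolutionVector
    model: FittedRiskModel
    trace: np.ndarray  # per-iteration best fitness (maximization scale)
    selected_features: list[str]
    evaluations: int


def search(
    train_table: pd.DataFrame,
    optimizer_config: opt.OptimizerConfig | None = None,
    space: HyperparamSpace | None = None,
    weights: FitnessWeights | None = None,
    seed: int = 0,
    folds: int = 10,
    feature_columns: list[str] | None = None,
    population_size: int = 12,
    max_iterations: int = 15,
    confirm_top: int = 8,
    confirm_cv_repeats: int = 5,
) -> SearchResult:
    """Run the IBSLO-driven AutoML search on the training table.

    Maximizes the weighted CV fitness by minimizing its negation over the
    unit cube.  Identical decoded candidates are cached, so the converged
    phase of the search costs little.  The initial population is warm-started
    with the four full-feature reference learners; the terminal shortlist of
    ``confirm_top`` candidates is confirmed by repeated cross-validation
    (``confirm_cv_repeats`` fold seeds) and the winner is refit on the full
    training table.
    """
    space = space or default_space()
    weights = weights or FitnessWeights()
    n_estimators = getattr(space, "n_estimators", 80)
    _, y, feature_columns = _split_xy(train_table, feature_columns)
    if min((y == 0).sum(), (y == 1).sum()) < folds:
        raise ValueError("too few rows per class for the requested fold count")
    m = len(feature_columns)
    dim = 1 + m + space.n_genes
    if optimizer_config is None:
        optimizer_config = opt.OptimizerConfig(
            dim=dim, bounds=(0.0, 1.0), population_size=population_size,
            max_iterations=max_iterations, seed=seed, variant="ibslo",
        )
    total_iters = optimizer_config.max_iterations
    # cache the weight-free CV terms, keyed by decoded candidate; weights are
    # re-applied at the current iteration so the dynamic schedule stays honest
    cache: dict[tuple, tuple[float, float, float]] = {}
    decoded: dict[tuple, SolutionVector] = {}
    state = {"iter": 0, "evals": 0}

    def objective(X: np.ndarray) -> np.ndarray:
        t = min(state["iter"] / max(total_iters, 1), 1.0)
        out = np.empty(len(X))
        for i, row in enumerate(np.clip(X, 0.0, 1.0)):
            sol = decode_solution(row, space, m)
            key = sol.cache_key()
            if key not in cache:
                cache[key] = _raw_components(
                    sol, train_table, weights.t_max_cost, seed, folds,
                    feature_columns, n_estimators,
                )
                decoded[key] = sol
                state["evals"] += 1
            acc, sparsity, efficiency = cache[key]
            out[i] = -(weights.w1(t) * acc + weights.w2(t) * sparsity
                       + weights.w3 * efficiency)
        return out

    result = opt.optimize(
        objective, optimizer_config,
        iteration_hook=lambda it: state.__setitem__("iter", it),
        initial_candidates=_warm_start_rows(space, m),
    )
    # Final selection.  Fitness values recorded at different iterations sit on
    # different weight scales, so every evaluated candidate is re-scored under
    # the terminal weights.  The single-CV screening accuracy of an argmax over
    # ~100 candidates is optimistically biased, so the shortlist is confirmed
    # with repeated cross-validation (fresh fold seeds) before the winner is
    # chosen (deterministic tie-break by cache key).
    def terminal_fitness(key: tuple, acc: float) -> float:
        _, sparsity, efficiency = cache[key]
        return (weights.w1(1.0) * acc + weights.w2(1.0) * sparsity
                + weights.w3 * efficiency)

    shortlist = sorted(
        sorted(cache, key=repr),
        key=lambda k: terminal_fitness(k, cache[k][0]),
        reverse=True,
    )[:confirm_top]
    confirmed: dict[tuple, float] = {}
    for key in shortlist:
        accs = [cache[key][0]]
        for r in range(1, confirm_cv_repeats):
            accs.append(
                _raw_components(
                    decoded[key], train_table, weights.t_max_cost, seed, folds,
                    feature_columns, n_estimators, cv_seed=seed + 7919 * r,
                )[0]
            )
        confirmed[key] = float(np.mean(accs))
    best_key = max(sorted(confirmed, key=repr),
                   key=lambda k: terminal_fitness(k, confirmed[k]))
    best = decoded[best_key]
    cols = [c for c, keep in zip(feature_columns, best.delta) if keep]
    est = _build_estimator(best.k, best.hyperparams, seed, n_estimators)
    est.fit(train_table[cols].to_numpy(dtype=float),
            train_table[OUTCOME_COLUMN].to_numpy(dtype=int))
    model = FittedRiskModel(model_id=best.k, feature_names=cols, estimator=est)
    return SearchResult(
        best_solution=best, model=model, trace=-result.history,
        selected_features=cols, evaluations=state["evals"],
    )


def fit_baseline(
    model_id: int,
    train_table: pd.DataFrame,
    seed: int = 0,
    feature_columns: list[str] | None = None,
    default_params: dict | None = None,
) -> FittedRiskModel:
    """Fit one of the four reference learners on all features with defaults.

    Defaults: LR C=1 (lbfgs), SVM C=1 rbf with Platt-calibrated
    probabilities, XGBoost and LightGBM library defaults with 100 trees.
    """
    X, y, feature_columns = _split_xy(train_table, feature_columns)
    params = default_params or {}
    est = _build_estimator(model_id, params, seed, n_estimators=100)
    est.fit(X.to_numpy(dtype=float), y)
    return FittedRiskModel(
        model_id=model_id, feature_names=feature_columns, estimator=est
    )
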