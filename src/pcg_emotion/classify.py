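"""GA-wrapped feature selection and SVM emotion classification.

Emotions are mapped to binary valence/arousal classes via Russell's
circumplex (sad/angry = low valence; relaxed/sad = low arousal).  A binary
feature-mask genetic algorithm maximizes stratified 5-fold CV accuracy of
an RBF-kernel SVM; repeated runs are aggregated by top-20% retention and
per-feature selection frequency; c/g are then grid-tuned on the selected
subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, PcgEmotionError

EMOTIONS = ("relaxed", "happy", "sad", "angry")
LOW_VALENCE = frozenset({"sad", "angry"})
LOW_AROUSAL = frozenset({"relaxed", "sad"})
TASKS = ("valence", "arousal", "four_class")

GA_DEFAULTS = {
    "population": 30,
    "generations": 50,
    "crossover_prob": 0.7,
    "mutation_prob": None,   # None -> 1/D per bit
    "tournament_size": 3,
    "init_prob": 0.5,
}

GRID_DEFAULTS = {
    "log2c": (-5, 15, 2),   # lo, hi (inclusive), step
    "log2g": (-15, 3, 2),
}


@dataclass(frozen=True)
class EmotionLabel:
    """A 4-class emotion label with its Russell-circumplex projections."""

    emotion: str

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}")

    @property
    def valence(self) -> str:
        return "low" if self.emotion in LOW_VALENCE else "high"

    @property
    def arousal(self) -> str:
        return "low" if self.emotion in LOW_AROUSAL else "high"


def map_labels(emotions, task: str) -> tuple[np.ndarray, dict[str, int]]:
    """Map emotion labels to task classes; returns (classes, class counts).

    For the binary tasks classes are ``low``/``high``; for ``four_class``
    the emotion names themselves.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    labels = [e if isinstance(e, EmotionLabel) else EmotionLabel(str(e))
              for e in emotions]
    if task == "valence":
        classes = np.array([lab.valence for lab in labels])
    elif task == "arousal":
        classes = np.array([lab.arousal for lab in labels])
    else:
        classes = np.array([lab.emotion for lab in labels])
    order = (["low", "high"] if task != "four_class" else list(EMOTIONS))
    counts = {c: int(np.sum(classes == c)) for c in order if np.any(classes == c)}
    return classes, counts


def _svc(c: float, g: float) -> SVC:
    # inverse-frequency class weights guard the 43-vs-14 imbalance
    return SVC(kernel="rbf", C=c, gamma=g, class_weight="balanced")


def cv_fitness(matrix: np.ndarray, classes: np.ndarray, mask: np.ndarray,
               c: float = 1.0, g: float = 0.1, folds: int = 5,
               seed: int = 0) -> float:
    """Mean stratified k-fold CV accuracy of an RBF SVM on the masked features.

    Standardization is fit per training fold inside the pipeline, so no
    test-fold statistics leak into training.  An empty mask is penalized
    with fitness 0.
    """
    mask = np.asarray(mask, dtype=bool)
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(classes)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if mask.shape != (X.shape[1],):
        raise ValueError("mask length must equal feature count")
    if not mask.any():
        return 0.0
    Xm = X[:, mask]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(Xm, y):
        model = make_pipeline(StandardScaler(), _svc(c, g))
        model.fit(Xm[train], y[train])
        accs.append(float(np.mean(model.predict(Xm[test]) == y[test])))
    return float(np.mean(accs))


@dataclass
class GaRun:
    """One GA feature-selection run: best mask, fitness and its trace."""

    best_mask: np.ndarray
    best_fitness: float
    fitness_trace: pd.DataFrame   # columns: generation, best, mean
    seed: int

    def __post_init__(self) -> None:
        self.best_mask = np.asarray(self.best_mask, dtype=bool)
        best = self.fitness_trace["best"].to_numpy()
        if np.any(np.diff(best) < -1e-12):
            raise PcgEmotionError("elitism violated: best-fitness trace decreased")
        if abs(self.best_fitness - float(best.max())) > 1e-12:
            raise PcgEmotionError("best_fitness must equal the trace maximum")


def ga_select(matrix: np.ndarray, classes: np.ndarray,
              ga_config: dict | None = None, seed: int = 0,
              c: float = 1.0, g: float = 0.1, folds: int = 5) -> GaRun:
    """Binary-mask GA maximizing :func:`cv_fitness`.

    Tournament selection, uniform crossover, per-bit mutation and 1-elitism;
    the best-fitness trace is therefore non-decreasing.  Fitness values are
    cached per mask.
    """
    cfg = dict(GA_DEFAULTS)
    if ga_config:
        unknown = set(ga_config) - set(cfg)
        if unknown:
            raise ConfigError(f"unknown GA config keys: {sorted(unknown)}")
        cfg.update(ga_config)
    pop_size = int(cfg["population"])
    n_gen = int(cfg["generations"])
    if pop_size < 2 or n_gen < 1:
        raise ConfigError("GA needs population >= 2 and generations >= 1")

    X = np.asarray(matrix, dtype=float)
    y = np.asarray(classes)
    D = X.shape[1]
    if D < 2:
        raise ConfigError("need at least 2 features to select from")
    p_mut = cfg["mutation_prob"] if cfg["mutation_prob"] is not None else 1.0 / D
    t_size = int(cfg["tournament_size"])

    rng = np.random.default_rng(seed)
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = cv_fitness(X, y, mask, c=c, g=g, folds=folds, seed=seed)
        return cache[key]

    pop = rng.random((pop_size, D)) < cfg["init_prob"]
    # guard against all-false individuals at init
    for i in range(pop_size):
        if not pop[i].any():
            pop[i, rng.integers(D)] = True
    fits = np.array([fitness(ind) for ind in pop])

    trace = []
    best_idx = int(np.argmax(fits))
    best_mask, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    trace.append((0, best_fit, float(np.mean(fits))))

    for gen in range(1, n_gen):
        new_pop = [best_mask.copy()]  # elitism
        while len(new_pop) < pop_size:
            # tournament parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, pop_size, size=t_size)
                parents.append(pop[contenders[np.argmax(fits[contenders])]].copy())
            a, b = parents
            if rng.random() < cfg["crossover_prob"]:
                swap = rng.random(D) < 0.5
                a[swap], b[swap] = b[swap], a[swap].copy()
            for child in (a, b):
                flip = rng.random(D) < p_mut
                child ^= flip
                if len(new_pop) < pop_size:
                    new_pop.append(child)
        pop = np.array(new_pop)
        fits = np.array([fitness(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()
        trace.append((gen, best_fit, float(np.mean(fits))))

    trace_df = pd.DataFrame(trace, columns=["generation", "best", "mean"])
    return GaRun(best_mask=best_mask, best_fitness=best_fit,
                 fitness_trace=trace_df, seed=seed)


@dataclass
class SelectionAggregate:
    """Top-20% aggregation of repeated GA runs into one feature subset."""

    runs: list[GaRun]
    retained: list[GaRun]
    weight: np.ndarray
    optimal_subset: np.ndarray   # boolean mask
    threshold: float
    fallback_used: bool = False


def aggregate_selection(runs: list[GaRun],
                        weight_threshold: float = 0.5) -> SelectionAggregate:
    """Retain the top 20% of runs by best fitness and vote per feature.

    ``weight_j`` is the fraction of retained runs selecting feature j; the
    optimal subset keeps features with weight >= threshold, falling back to
    the single best run's mask if the vote empties the subset.
    """
    if len(runs) < 5:
        raise ValueError("need at least 5 runs to aggregate")
    n_keep = math.ceil(0.2 * len(runs))
    # stable sort: ties broken by run order (seed order)
    order = sorted(range(len(runs)), key=lambda i: -runs[i].best_fitness)
    retained = [runs[i] for i in order[:n_keep]]
    masks = np.vstack([r.best_mask for r in retained])
    weight = masks.mean(axis=0)
    subset = weight >= weight_threshold
    fallback = False
    if not subset.any():
        subset = retained[0].best_mask.copy()
        fallback = True
    return SelectionAggregate(runs=list(runs), retained=retained, weight=weight,
                              optimal_subset=subset, threshold=weight_threshold,
                              fallback_used=fallback)


def tune_cg(matrix: np.ndarray, classes: np.ndarray, subset: np.ndarray,
            grid_config: dict | None = None, folds: int = 5,
            seed: int = 0) -> tuple[float, float, pd.DataFrame]:
    """Exhaustive log2 grid search for (c, g) maximizing CV accuracy.

    Returns (c*, g*, curve) where the curve holds one row per grid point.
    """
    cfg = dict(GRID_DEFAULTS)
    if grid_config:
        unknown = set(grid_config) - set(cfg)
        if unknown:
            raise ConfigError(f"unknown grid config keys: {sorted(unknown)}")
        cfg.update(grid_config)
    subset = np.asarray(subset, dtype=bool)
    if not subset.any():
        raise ValueError("subset must select at least one feature")
    lo_c, hi_c, st_c = cfg["log2c"]
    lo_g, hi_g, st_g = cfg["log2g"]
    rows = []
    best = (-1.0, None, None)
    for lc in range(lo_c, hi_c + 1, st_c):
        for lg in range(lo_g, hi_g + 1, st_g):
            c, g = 2.0 ** lc, 2.0 ** lg
            acc = cv_fitness(matrix, classes, subset, c=c, g=g,
                             folds=folds, seed=seed)
            rows.append({"log2c": lc, "log2g": lg, "c": c, "g": g, "accuracy": acc})
            if acc > best[0]:
                best = (acc, c, g)
    curve = pd.DataFrame(rows)
    return best[1], best[2], curve


def evaluate(y_true: np.ndarray, y_pred: np.ndarray,
             positive: str = "high") -> dict:
    """Confusion-matrix report: accuracy, per-class recall, and (for binary
    tasks) sensitivity/specificity with ``positive`` as the positive class.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = sorted(set(y_true) | set(y_pred))
    k = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    accuracy = float(np.trace(cm) / len(y_true))
    recalls = {}
    for lab in labels:
        row = cm[idx[lab]]
        recalls[lab] = float(row[idx[lab]] / row.sum()) if row.sum() else float("nan")
    report = {
        "accuracy": accuracy,
        "per_class_recall": recalls,
        "macro_recall": float(np.nanmean(list(recalls.values()))),
        "confusion_matrix": cm.tolist(),
        "labels": [str(lab) for lab in labels],
    }
    if k == 2 and positive in idx:
        negative = next(lab for lab in labels if lab != positive)
        present = set(y_true)
        report["sensitivity"] = recalls[positive] if positive in present else None
        report["specificity"] = recalls[negative] if negative in present else None
    return report


def cross_val_predictions(matrix: np.ndarray, classes: np.ndarray,
                          subset: np.ndarray, c: float, g: float,
                          folds: int = 5, seed: int = 0) -> np.ndarray:
    """Out-of-fold predictions of the tuned model on the selected subset."""
    subset = np.asarray(subset, dtype=bool)
    X = np.asarray(matrix, dtype=float)[:, subset]
    y = np.asarray(classes)
    preds = np.empty(len(y), dtype=y.dtype)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        model = make_pipeline(StandardScaler(), _svc(c, g))
        model.fit(X[train], y[train])
        preds[test] = model.predict(X[test])
    return preds


@dataclass
class TaskResult:
    """Full selection + tuning + evaluation result for one block/task pair."""

    block: str
    task: str
    aggregate: SelectionAggregate
    c: float
    g: float
    cv_accuracy: float
    report: dict
    curve: pd.DataFrame = field(repr=False, default=None)


def run_task(matrix: np.ndarray, classes: np.ndarray, block: str, task: str,
             n_runs: int = 30, base_seed: int = 0,
             ga_config: dict | None = None, grid_config: dict | None = None,
             weight_threshold: float = 0.5, folds: int = 5) -> TaskResult:
    """Repeated GA selection, aggregation, c/g tuning and CV evaluation."""
    runs = [ga_select(matrix, classes, ga_config=ga_config, seed=base_seed + i,
                      folds=folds)
            for i in range(n_runs)]
    agg = aggregate_selection(runs, weight_threshold=weight_threshold)
    c, g, curve = tune_cg(matrix, classes, agg.optimal_subset,
                          grid_config=grid_config, folds=folds, seed=base_seed)
    acc = cv_fitness(matrix, classes, agg.optimal_subset, c=c, g=g,
                     folds=folds, seed=base_seed)
    preds = cross_val_predictions(matrix, classes, agg.optimal_subset, c, g,
                                  folds=folds, seed=base_seed)
    report = evaluate(classes, preds)
    return TaskResult(block=block, task=task, aggregate=agg, c=c, g=g,
                      cv_accuracy=acc, report=report, curve=curve)
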