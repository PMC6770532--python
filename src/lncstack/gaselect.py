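"""Genetic-algorithm wrapper feature selection with a random-forest
cross-validated AUC fitness (GA-RF).

A chromosome is a binary mask over the feature columns. Fitness is the
mean AUC of a stratified k-fold cross-validation of a random forest
restricted to the masked columns. Evolution uses tournament selection,
single-point crossover and per-gene flip-bit mutation; a hall of fame
keeps the best distinct masks ever evaluated and the loop stops early
once the best fitness plateaus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, check_X_y

from .assemble import FeatureSchema


@dataclass(frozen=True)
class GAConfig:
    """GA-RF hyperparameters (defaults: the full-scale profile)."""

    pop_size: int = 500
    generations: int = 50
    tournament_size: int = 3
    crossover_prob: float = 0.5
    gene_flip_prob: float = 0.05
    individual_mutation_prob: float = 0.2
    rf_trees: int = 100
    cv_folds: int = 10
    seed: int = 0
    top_n: int = 10
    plateau_patience: int = 5
    plateau_tol: float = 1e-4

    def __post_init__(self):
        for p in (self.crossover_prob, self.gene_flip_prob,
                  self.individual_mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.pop_size < self.top_n:
            raise ValueError("pop_size must be >= top_n")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


#: small profile for interactive/desk use: same operators, reduced budget
DESK_PROFILE = GAConfig(pop_size=60, generations=25, cv_folds=5, rf_trees=50)


def init_population(n_genes: int, cfg: GAConfig, rng: np.random.Generator):
    """pop_size chromosomes with i.i.d. Bernoulli(0.5) genes."""
    return (rng.random((cfg.pop_size, n_genes)) < 0.5).astype(np.uint8)


def _mask_key(mask: np.ndarray) -> bytes:
    return np.packbits(mask.astype(np.uint8)).tobytes()


def fitness(
    mask: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    cfg: GAConfig,
    cache: Optional[dict] = None,
) -> float:
    """Stratified cv_folds-fold CV AUC of a seeded random forest on the
    masked columns; the all-zero mask scores 0 by definition."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("fitness requires both classes in y")
    key = _mask_key(mask)
    if cache is not None and key in cache:
        return cache[key]
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        value = 0.0
    else:
        Xm = np.asarray(X, dtype=float)[:, mask]
        skf = StratifiedKFold(
            n_splits=cfg.cv_folds, shuffle=True,
            random_state=cfg.seed % (2**31),
        )
        aucs = []
        for tr, te in skf.split(Xm, y):
            rf = RandomForestClassifier(
                n_estimators=cfg.rf_trees,
                random_state=cfg.seed % (2**31),
                n_jobs=1,
            )
            rf.fit(Xm[tr], y[tr])
            pos = list(rf.classes_).index(1)
            aucs.append(roc_auc_score(y[te], rf.predict_proba(Xm[te])[:, pos]))
        value = float(np.mean(aucs))
    if cache is not None:
        cache[key] = value
    return value


def _tournament(fits: np.ndarray, cfg: GAConfig, rng) -> np.ndarray:
    """Indices of pop_size tournament winners (best of tournament_size
    uniformly drawn contestants; ties go to the first drawn)."""
    n = len(fits)
    contestants = rng.integers(0, n, size=(n, cfg.tournament_size))
    winners = contestants[np.arange(n), np.argmax(fits[contestants], axis=1)]
    return winners


def evolve(
    X,
    y,
    cfg: GAConfig,
    rng: Optional[np.random.Generator] = None,
    initial_population: Optional[np.ndarray] = None,
) -> tuple[list[tuple[np.ndarray, float]], dict]:
    """Run the GA and return (hall_of_fame, history).

    The hall of fame holds the ``cfg.top_n`` best distinct chromosomes
    ever evaluated, sorted by decreasing fitness. History records
    per-generation best/mean population fitness and the running best.
    ``initial_population`` overrides the Bernoulli(0.5) initialization.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    X = np.asarray(X, dtype=float)
    n_genes = X.shape[1]
    cache: dict[bytes, float] = {}
    seen: dict[bytes, np.ndarray] = {}

    def evaluate(pop: np.ndarray) -> np.ndarray:
        fits = np.empty(len(pop))
        for i, chrom in enumerate(pop):
            fits[i] = fitness(chrom, X, y, cfg, cache=cache)
            seen.setdefault(_mask_key(chrom), chrom.copy())
        return fits

    if initial_population is None:
        pop = init_population(n_genes, cfg, rng)
    else:
        pop = np.asarray(initial_population, dtype=np.uint8).copy()
    fits = evaluate(pop)
    history = {
        "best": [float(fits.max())],
        "mean": [float(fits.mean())],
        "best_ever": [float(fits.max())],
    }
    best_ever = float(fits.max())
    stall = 0
    for _ in range(cfg.generations):
        parents = pop[_tournament(fits, cfg, rng)].copy()
        # single-point crossover on consecutive pairs
        for i in range(0, cfg.pop_size - 1, 2):
            if rng.random() < cfg.crossover_prob:
                point = int(rng.integers(1, n_genes))
                tail = parents[i, point:].copy()
                parents[i, point:] = parents[i + 1, point:]
                parents[i + 1, point:] = tail
        # flip-bit mutation
        for i in range(cfg.pop_size):
            if rng.random() < cfg.individual_mutation_prob:
                flips = rng.random(n_genes) < cfg.gene_flip_prob
                parents[i, flips] ^= 1
        pop = parents
        fits = evaluate(pop)
        gen_best = float(fits.max())
        history["best"].append(gen_best)
        history["mean"].append(float(fits.mean()))
        if gen_best > best_ever + cfg.plateau_tol:
            best_ever = gen_best
            stall = 0
        else:
            stall += 1
        history["best_ever"].append(best_ever)
        if stall >= cfg.plateau_patience:
            break
    ranked = sorted(
        seen.items(), key=lambda kv: (-cache[kv[0]], kv[0])
    )[: cfg.top_n]
    hall = [(chrom, cache[key]) for key, chrom in ranked]
    return hall, history


def decode(mask: np.ndarray, schema: FeatureSchema) -> list[str]:
    """Feature names of the set genes, in schema order."""
    return [schema.names[i] for i in np.flatnonzero(np.asarray(mask))]


def subset_intersection(subsets: Sequence[Sequence[str]],
                        schema: Optional[FeatureSchema] = None) -> list[str]:
    """Intersection of feature-name lists, returned in schema order
    (or in the order of the first list when no schema is given)."""
    if not subsets:
        return []
    common = set(subsets[0])
    for s in subsets[1:]:
        common &= set(s)
    order = schema.names if schema is not None else list(subsets[0])
    return [n for n in order if n in common]


def save_selection_report(hall, history, schema: FeatureSchema, cfg: GAConfig,
                          path) -> None:
    """JSON report: config/seed, per-generation fitness, final subsets."""
    report = {
        "config": asdict(cfg),
        "history": history,
        "subsets": [
            {"fitness": fit, "features": decode(mask, schema)}
            for mask, fit in hall
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)


def load_selection_report(path, schema: Optional[FeatureSchema] = None):
    """Load a selection report; returns (masks, fitnesses, report dict)."""
    if schema is None:
        from .assemble import feature_schema

        schema = feature_schema()
    with open(path, encoding="utf-8") as fh:
        report = json.load(fh)
    index = {n: i for i, n in enumerate(schema.names)}
    masks, fits = [], []
    for sub in report["subsets"]:
        mask = np.zeros(schema.n_features, dtype=np.uint8)
        for name in sub["features"]:
            mask[index[name]] = 1
        masks.append(mask)
        fits.append(sub["fitness"])
    return masks, fits, report


class GeneticFeatureSelector(BaseEstimator):
    """scikit-learn style wrapper around :func:`evolve`.

    Fitted attributes: ``subsets_`` (list of boolean masks, best first),
    ``fitnesses_``, ``history_``, ``support_`` (union of the masks).
    ``transform`` restricts X to the union support; the individual masks
    feed :class:`~lncstack.ensemble.StackedForestClassifier`.
    """

    def __init__(self, config: Optional[GAConfig] = None,
                 random_state: Optional[int] = None):
        self.config = config
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        cfg = self.config or GAConfig()
        if self.random_state is not None:
            cfg = replace(cfg, seed=int(self.random_state))
        hall, history = evolve(X, y, cfg)
        self.config_ = cfg
        self.subsets_ = [m.astype(bool) for m, _ in hall]
        self.fitnesses_ = [f for _, f in hall]
        self.history_ = history
        self.support_ = np.any(self.subsets_, axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "support_")
        return np.asarray(X)[:, self.support_]
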