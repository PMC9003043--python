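"""Wrapper feature selection over the 10 candidate features.

Two wrappers, one per classifier branch:

* **Exhaustive SVM search** (static branch): every one of the
  ``2^10 - 1 = 1023`` non-empty feature subsets is scored by fitting a
  Gaussian-kernel SVM on 70% of the training frames and measuring the
  misclassification rate ("loss") on the held-out 30%; the subset with the
  lowest loss wins, ties broken by smaller cardinality then mask order.

* **Steady-state genetic algorithm** (sequence branch): a population of 50
  binary 10-gene chromosomes (one forced to all-ones so the full feature
  set is always tried) evolves for 10 generations; fitness is the percent
  of correctly classified frames (%CC) of a reference two-layer LSTM
  trained for 20 epochs on the chromosome's features.  Chromosomes proposed
  more than once are served from a fitness cache, so the fresh-evaluation
  budget never exceeds population x generations = 500.

Subsets are boolean masks over the candidate feature columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .exceptions import ConfigError, EvaluationError
from .features import FEATURE_NAMES
from .models import LSTMSequenceClassifier

__all__ = [
    "enumerate_subsets",
    "subset_names",
    "ExhaustiveSVMSelector",
    "GeneticSubsetSelector",
    "GAConfig",
    "SelectionResult",
    "svm_wrapper_select",
    "ga_select",
    "lstm_fitness",
    "make_lstm_fitness",
]


def mask_to_int(mask: np.ndarray) -> int:
    return int(sum(1 << i for i, b in enumerate(mask) if b))


def int_to_mask(value: int, n: int) -> np.ndarray:
    return np.array([(value >> i) & 1 for i in range(n)], dtype=bool)


def subset_names(mask, names: tuple[str, ...] = FEATURE_NAMES) -> tuple[str, ...]:
    """Feature names selected by a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    return tuple(n for n, b in zip(names, mask) if b)


def enumerate_subsets(n: int) -> list[np.ndarray]:
    """All 2^n - 1 non-empty boolean masks over n features, each once."""
    if not 1 <= n <= 20:
        raise ConfigError(f"feature count must be in [1, 20], got {n}")
    return [int_to_mask(m, n) for m in range(1, 2**n)]


@dataclass
class SelectionResult:
    """Outcome of a wrapper selection run."""

    ranking: pd.DataFrame          # one row per evaluated subset, best first
    best_subset: np.ndarray        # boolean mask
    best_score: float              # loss (SVM branch) or %CC (GA branch)
    n_evaluations: int             # fresh classifier fits
    n_duplicates: int = 0          # proposals served from cache (GA branch)
    log: dict = field(default_factory=dict)


class ExhaustiveSVMSelector(BaseEstimator):
    """Exhaustive wrapper selection scored by a Gaussian-kernel SVM.

    ``fit(X, y)`` draws one stratified 70/30 train/validation split, then
    scores every non-empty subset of the columns of ``X`` by the SVM's
    held-out misclassification rate.  Fitted attributes: ``support_`` (the
    winning mask), ``best_loss_``, ``results_`` (full ranking).
    """

    def __init__(
        self,
        val_fraction: float = 0.30,
        C: float = 1.0,
        gamma: str | float = "scale",
        random_state: int | None = None,
    ):
        self.val_fraction = val_fraction
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ConfigError("need at least 2 classes for wrapper selection")
        X_tr, X_val, y_tr, y_val = train_test_split(
            X,
            y,
            test_size=self.val_fraction,
            stratify=y,
            random_state=self.random_state,
        )
        rows = []
        for mask in enumerate_subsets(X.shape[1]):
            clf = SVC(kernel="rbf", C=self.C, gamma=self.gamma)
            clf.fit(X_tr[:, mask], y_tr)
            loss = float(np.mean(clf.predict(X_val[:, mask]) != y_val))
            rows.append(
                {
                    "mask": mask_to_int(mask),
                    "n_features": int(mask.sum()),
                    "loss": loss,
                }
            )
        results = pd.DataFrame(rows).sort_values(
            ["loss", "n_features", "mask"], kind="mergesort", ignore_index=True
        )
        self.results_ = results
        self.n_features_in_ = X.shape[1]
        self.support_ = int_to_mask(int(results.loc[0, "mask"]), X.shape[1])
        self.best_loss_ = float(results.loc[0, "loss"])
        self.n_evaluations_ = len(results)
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        return np.asarray(X)[..., self.support_]


def svm_wrapper_select(
    X, y, val_fraction: float = 0.30, seed: int | None = None, **svm_params
) -> SelectionResult:
    """Functional form of :class:`ExhaustiveSVMSelector`."""
    sel = ExhaustiveSVMSelector(
        val_fraction=val_fraction, random_state=seed, **svm_params
    ).fit(X, y)
    return SelectionResult(
        ranking=sel.results_,
        best_subset=sel.support_,
        best_score=sel.best_loss_,
        n_evaluations=sel.n_evaluations_,
        log={"val_fraction": val_fraction, "svm": {"kernel": "rbf", **svm_params}},
    )


@dataclass(frozen=True)
class GAConfig:
    """Steady-state GA configuration.

    The initial population counts as the first generation, so the total
    proposal budget is ``population_size * generations``.
    """

    population_size: int = 50
    generations: int = 10
    gene_count: int = 10
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # default 1 / gene_count
    tournament_k: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.generations < 1:
            raise ConfigError("population_size >= 2 and generations >= 1 required")
        if not 1 <= self.gene_count <= 20:
            raise ConfigError("gene_count must be in [1, 20]")


class GeneticSubsetSelector(BaseEstimator):
    """Steady-state GA over binary feature masks with a cached fitness.

    ``fitness`` maps a boolean mask to a finite score (higher is better).
    One chromosome of the initial population is forced to all-ones.  Each
    later generation proposes ``population_size`` offspring via binary
    tournament selection, uniform crossover and per-gene bit-flip mutation;
    an offspring replaces the current worst individual when it improves on
    it.  Re-proposed masks are looked up from the cache and never retrained.
    """

    def __init__(
        self,
        fitness,
        population_size: int = 50,
        generations: int = 10,
        gene_count: int = 10,
        crossover_prob: float = 0.9,
        mutation_prob: float | None = None,
        tournament_k: int = 2,
        random_state: int | None = None,
    ):
        self.fitness = fitness
        self.population_size = population_size
        self.generations = generations
        self.gene_count = gene_count
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.tournament_k = tournament_k
        self.random_state = random_state

    # -- GA internals -------------------------------------------------------

    def _evaluate(self, mask: np.ndarray) -> float:
        key = mask_to_int(mask)
        if key in self._cache_:
            self._n_duplicates_ += 1
            return self._cache_[key]
        score = float(self.fitness(mask.copy()))
        if not np.isfinite(score):
            raise EvaluationError(
                f"fitness returned non-finite score {score!r} for mask {key:b}"
            )
        self._cache_[key] = score
        return score

    def _repair(self, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(self.gene_count)] = True
        return mask

    def _tournament(self, scores: np.ndarray, rng: np.random.Generator) -> int:
        contenders = rng.integers(0, len(scores), size=self.tournament_k)
        return int(contenders[np.argmax(scores[contenders])])

    def fit(self, X=None, y=None):
        cfg = GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            gene_count=self.gene_count,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            tournament_k=self.tournament_k,
            seed=self.random_state,
        )
        rng = np.random.default_rng(cfg.seed)
        p_mut = cfg.mutation_prob if cfg.mutation_prob is not None else 1.0 / cfg.gene_count
        self._cache_: dict[int, float] = {}
        self._n_duplicates_ = 0
        n_proposals = 0

        # Initial population: all-ones chromosome + random non-empty masks.
        population = [np.ones(cfg.gene_count, dtype=bool)]
        while len(population) < cfg.population_size:
            population.append(self._repair(rng.random(cfg.gene_count) < 0.5, rng))
        scores = np.array([self._evaluate(m) for m in population])
        n_proposals += cfg.population_size
        history = [{"generation": 1, "best": float(scores.max()), "mean": float(scores.mean())}]

        for gen in range(2, cfg.generations + 1):
            for _ in range(cfg.population_size):
                i = self._tournament(scores, rng)
                j = self._tournament(scores, rng)
                a, b = population[i], population[j]
                if rng.random() < cfg.crossover_prob:
                    take_a = rng.random(cfg.gene_count) < 0.5
                    child = np.where(take_a, a, b)
                else:
                    child = a.copy()
                flip = rng.random(cfg.gene_count) < p_mut
                child = self._repair(child ^ flip, rng)
                n_proposals += 1
                score = self._evaluate(child)
                worst = int(np.argmin(scores))
                if score > scores[worst]:
                    population[worst] = child
                    scores[worst] = score
            history.append(
                {"generation": gen, "best": float(scores.max()), "mean": float(scores.mean())}
            )

        ranking = (
            pd.DataFrame(
                {
                    "mask": list(self._cache_.keys()),
                    "score": list(self._cache_.values()),
                }
            )
            .assign(n_features=lambda d: d["mask"].map(lambda m: bin(m).count("1")))
            .sort_values(["score", "n_features", "mask"],
                         ascending=[False, True, True], kind="mergesort",
                         ignore_index=True)
        )
        self.results_ = ranking
        self.history_ = pd.DataFrame(history)
        self.best_subset_ = int_to_mask(int(ranking.loc[0, "mask"]), cfg.gene_count)
        self.best_score_ = float(ranking.loc[0, "score"])
        self.n_evaluations_ = len(self._cache_)
        self.n_duplicates_ = self._n_duplicates_
        self.n_proposals_ = n_proposals
        self.support_ = self.best_subset_
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        return np.asarray(X)[..., self.support_]


def ga_select(fitness, config: GAConfig | None = None, **overrides) -> SelectionResult:
    """Functional form of :class:`GeneticSubsetSelector`."""
    cfg = config if config is not None else GAConfig(**overrides)
    sel = GeneticSubsetSelector(
        fitness,
        population_size=cfg.population_size,
        generations=cfg.generations,
        gene_count=cfg.gene_count,
        crossover_prob=cfg.crossover_prob,
        mutation_prob=cfg.mutation_prob,
        tournament_k=cfg.tournament_k,
        random_state=cfg.seed,
    ).fit()
    return SelectionResult(
        ranking=sel.results_,
        best_subset=sel.best_subset_,
        best_score=sel.best_score_,
        n_evaluations=sel.n_evaluations_,
        n_duplicates=sel.n_duplicates_,
        log={"n_proposals": sel.n_proposals_, "history": sel.history_},
    )


def lstm_fitness(
    subset,
    X_seq: np.ndarray,
    y_seq: np.ndarray,
    epochs: int = 20,
    seed: int | None = None,
    val_fraction: float = 0.30,
    hidden1: int = 100,
    hidden2: int = 75,
    dropout: float = 0.30,
    batch_size: int = 32,
    learning_rate: float = 3e-3,
) -> float:
    """%CC of the reference two-layer LSTM on a held-out validation split.

    The reference network is LSTM(hidden1) -> dropout -> LSTM(hidden2) ->
    dropout -> fully connected -> softmax, trained ``epochs`` epochs on the
    subset's feature columns; the score is the percentage of correctly
    classified frames on a sequence-level validation partition of the
    training data.  Deterministic given (seed, subset).
    """
    mask = np.asarray(subset, dtype=bool)
    if not mask.any():
        raise ConfigError("subset must select at least one feature")
    import warnings

    X_sub = np.asarray(X_seq, dtype=np.float32)[..., mask]
    flat = X_sub.reshape(-1, X_sub.shape[-1])
    if np.any(flat.std(axis=0) < 1e-12):
        warnings.warn("subset contains an all-constant feature column", stacklevel=2)
    rng = np.random.default_rng(seed)
    n = len(X_sub)
    order = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        raise ConfigError("not enough sequences to split for fitness evaluation")
    model = LSTMSequenceClassifier(
        variant="2LSTM",
        hidden1=hidden1,
        hidden2=hidden2,
        dropout=dropout,
        epochs=epochs,
        batch_size=batch_size,
        learning_rate=learning_rate,
        random_state=int(rng.integers(0, 2**31)),
    )
    model.fit(X_sub[tr_idx], np.asarray(y_seq)[tr_idx])
    return 100.0 * model.score(X_sub[val_idx], np.asarray(y_seq)[val_idx])


def make_lstm_fitness(X_seq, y_seq, **kwargs):
    """Bind data and settings into a ``mask -> %CC`` fitness callable."""

    def fitness(mask):
        return lstm_fitness(mask, X_seq, y_seq, **kwargs)

    return fitness
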