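"""Reference desk-scale benchmarks: selector recovery and model comparison.

These routines define the package's reproducible study conditions at sizes
a single CPU handles in minutes.  They are used both by the test suite and
by the acceptance script, so the numbers they produce always come from
running the actual pipeline.

* :func:`planted_feature_frames` builds a generative 5-class frame set in
  which only named feature columns carry class information, the rest being
  pure noise — the ground truth a wrapper selector should recover.
* :func:`svm_recovery_benchmark` measures how often the exhaustive SVM
  wrapper's winning subset contains the planted informative features.
* :func:`ga_recovery_benchmark` measures how often the steady-state GA
  finds the brute-force-verified optimum of a shaped subset landscape.
* :func:`sequence_model_benchmark` trains the best sequence network
  (2BLSTM2D) and the static MLP on a posture-scripted synthetic database
  with a subject-wise split and reports per-frame accuracy and per-class
  sensitivity — in particular for the transition class, which only temporal
  context can resolve.
* :func:`paired_transition_sensitivity` repeats a reduced version of that
  comparison over paired seeds.
"""

from __future__ import annotations

import numpy as np

from .datasets import DatasetSplit, build_lstm_dataset, build_mlp_dataset, split_by_subject
from .evaluation import confusion_matrix, per_class_metrics
from .exceptions import ConfigError
from .features import FEATURE_NAMES
from .models import LSTMSequenceClassifier, MLPPostureClassifier
from .selection import (
    enumerate_subsets,
    ga_select,
    mask_to_int,
    svm_wrapper_select,
)
from .synthetic import NoiseModel, PostureScript, benchmark_frame_table

#: Class-mean offsets of the informative features in the planted benchmark:
#: five postures separated along two axes, the rest of the feature space
#: being unit noise.
_PLANTED_MEANS: dict[int, tuple[float, float]] = {
    1: (1.0, 2.0),
    2: (1.0, 0.5),
    3: (-1.0, -2.0),
    4: (0.0, 0.0),
    5: (0.5, -0.5),
}


def planted_feature_frames(
    seed: int,
    n_per_class: int = 50,
    informative: tuple[str, str] = ("B_pitch", "Z_Head"),
    within_sd: float = 0.3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generative 5-class data where only two named features are informative.

    Returns ``(X, y, informative_mask)`` with ``X`` of shape
    ``(5 * n_per_class, 10)``: the informative columns are class-mean plus
    ``within_sd`` Gaussian scatter, all other columns standard normal noise.
    """
    idx = [FEATURE_NAMES.index(f) for f in informative]
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for cls, (a, b) in _PLANTED_MEANS.items():
        x = rng.standard_normal((n_per_class, len(FEATURE_NAMES)))
        x[:, idx[0]] = a + within_sd * rng.standard_normal(n_per_class)
        x[:, idx[1]] = b + within_sd * rng.standard_normal(n_per_class)
        X_parts.append(x)
        y_parts.append(np.full(n_per_class, cls))
    mask = np.zeros(len(FEATURE_NAMES), dtype=bool)
    mask[idx] = True
    return np.vstack(X_parts), np.concatenate(y_parts), mask


def svm_recovery_benchmark(
    seeds, n_per_class: int = 50, informative: tuple[str, str] = ("B_pitch", "Z_Head")
) -> dict:
    """Fraction of seeds on which the exhaustive SVM wrapper recovers the
    planted informative features (winning subset contains both)."""
    seeds = list(seeds)
    hits = 0
    losses = []
    for seed in seeds:
        X, y, truth = planted_feature_frames(seed, n_per_class, informative)
        result = svm_wrapper_select(X, y, seed=seed)
        hits += bool(np.all(result.best_subset[truth]))
        losses.append(result.best_score)
    return {
        "n_seeds": len(seeds),
        "n_recovered": hits,
        "recovery_rate": hits / len(seeds),
        "mean_best_loss": float(np.mean(losses)),
    }


def shaped_landscape(target_mask: np.ndarray):
    """Fitness = gene count minus Hamming distance to a hidden target subset.

    The unique global optimum is the target itself; the Hamming shaping
    gives the GA a gradient toward it.
    """
    target = mask_to_int(np.asarray(target_mask, dtype=bool))
    n = len(target_mask)

    def fitness(mask) -> float:
        return float(n - bin(mask_to_int(np.asarray(mask, dtype=bool)) ^ target).count("1"))

    return fitness


def ga_recovery_benchmark(seeds, target_mask: np.ndarray | None = None) -> dict:
    """Fraction of seeds on which the GA finds the landscape's optimum.

    The optimum is first verified unique by brute force over all 1023
    subsets; GA runs use the standard budget (population 50, 10
    generations).
    """
    if target_mask is None:
        target_mask = np.array([0, 1, 0, 0, 1, 0, 0, 0, 1, 0], dtype=bool)
    target_mask = np.asarray(target_mask, dtype=bool)
    fitness = shaped_landscape(target_mask)
    scored = [(fitness(m), mask_to_int(m)) for m in enumerate_subsets(len(target_mask))]
    best = max(s for s, _ in scored)
    optima = [m for s, m in scored if s == best]
    if optima != [mask_to_int(target_mask)]:
        raise ConfigError("shaped landscape does not have the target as unique optimum")

    seeds = list(seeds)
    hits = 0
    budgets_ok = True
    for seed in seeds:
        result = ga_select(fitness, seed=seed)
        hits += mask_to_int(result.best_subset) == mask_to_int(target_mask)
        budgets_ok &= result.log["n_proposals"] <= 50 * 10
    return {
        "n_seeds": len(seeds),
        "n_recovered": hits,
        "recovery_rate": hits / len(seeds),
        "within_budget": bool(budgets_ok),
    }


def _benchmark_split(
    seed: int, cycles: int, n_train_subjects: int = 2, n_test_subjects: int = 1
):
    n_subjects = n_train_subjects + n_test_subjects
    frames = benchmark_frame_table(
        n_subjects=n_subjects,
        script=PostureScript.default(cycles=cycles),
        noise=NoiseModel(),
        seed=seed,
    )
    subjects = sorted(frames["subject_id"].unique())
    split = DatasetSplit(tuple(subjects[:n_train_subjects]), tuple(subjects[n_train_subjects:]))
    train_df, test_df, _ = split_by_subject(frames, split)
    return frames, train_df, test_df


def _class5_sensitivity(truth, pred) -> float:
    cm = confusion_matrix(np.ravel(truth), np.ravel(pred))
    return float(per_class_metrics(cm).loc[5, "sensitivity"])


def sequence_model_benchmark(
    seed: int,
    cycles: int = 4,
    epochs: int = 50,
    hidden1: int = 125,
    dropout: float = 0.45,
    mlp_max_epochs: int = 1000,
) -> dict:
    """Train 2BLSTM2D and the MLP on the synthetic benchmark, subject-wise.

    Training data: two subjects following the standard posture script
    (``cycles`` cycles of 10 s holds with 2 s transitions, joint jitter and
    missing bursts at default levels); test data: one held-out subject.
    Returns per-frame accuracies and per-class sensitivities of both
    branches, each evaluated on its own database (sequences with retained
    sentinels for the recurrent model, sentinel-free frames for the MLP).
    """
    rng = np.random.default_rng(seed)
    data_seed, lstm_seed, mlp_seed = (int(s) for s in rng.integers(0, 2**31, 3))
    _, train_df, test_df = _benchmark_split(data_seed, cycles)

    X_tr, y_tr, _, train_report = build_lstm_dataset(train_df)
    X_te, y_te, _, _ = build_lstm_dataset(test_df)
    lstm = LSTMSequenceClassifier(
        variant="2BLSTM2D", hidden1=hidden1, dropout=dropout, epochs=epochs,
        random_state=lstm_seed,
    )
    lstm.fit(X_tr, y_tr)
    lstm_pred = lstm.predict(X_te)

    feats = list(FEATURE_NAMES)
    mlp_train, _ = build_mlp_dataset(train_df)
    mlp_test, _ = build_mlp_dataset(test_df)
    mlp = MLPPostureClassifier(max_epochs=mlp_max_epochs, random_state=mlp_seed)
    mlp.fit(mlp_train[feats].to_numpy(), mlp_train["label"].to_numpy())
    mlp_pred = mlp.predict(mlp_test[feats].to_numpy())
    mlp_truth = mlp_test["label"].to_numpy()

    return {
        "n_train_frames": int(len(train_df)),
        "n_test_frames": int(len(test_df)),
        "train_sentinel_fraction": train_report["sentinel_fraction"],
        "lstm_accuracy": float(np.mean(lstm_pred == y_te)),
        "mlp_accuracy": float(np.mean(mlp_pred == mlp_truth)),
        "lstm_class5_sensitivity": _class5_sensitivity(y_te, lstm_pred),
        "mlp_class5_sensitivity": _class5_sensitivity(mlp_truth, mlp_pred),
    }


def paired_transition_sensitivity(
    seeds,
    cycles: int = 2,
    epochs: int = 15,
    hidden1: int = 50,
    dropout: float = 0.30,
    mlp_max_epochs: int = 400,
) -> dict:
    """Paired-seed comparison of transition-class sensitivity, reduced scale.

    For every seed a fresh benchmark is generated and both branches are
    trained and tested subject-wise; the comparison is paired because both
    see the same data per seed.  Reports per-seed sensitivities, the mean
    difference and the number of seeds on which the sequence model wins.
    """
    results = [
        sequence_model_benchmark(
            seed, cycles=cycles, epochs=epochs, hidden1=hidden1, dropout=dropout,
            mlp_max_epochs=mlp_max_epochs,
        )
        for seed in seeds
    ]
    lstm_c5 = np.array([r["lstm_class5_sensitivity"] for r in results])
    mlp_c5 = np.array([r["mlp_class5_sensitivity"] for r in results])
    lstm_acc = np.array([r["lstm_accuracy"] for r in results])
    mlp_acc = np.array([r["mlp_accuracy"] for r in results])
    return {
        "n_seeds": len(results),
        "lstm_class5_sensitivity": lstm_c5.tolist(),
        "mlp_class5_sensitivity": mlp_c5.tolist(),
        "mean_class5_gap": float(np.mean(lstm_c5 - mlp_c5)),
        "n_class5_wins": int(np.sum(lstm_c5 > mlp_c5)),
        "mean_lstm_accuracy": float(lstm_acc.mean()),
        "mean_mlp_accuracy": float(mlp_acc.mean()),
    }
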