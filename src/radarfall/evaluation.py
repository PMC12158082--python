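"""Cross-validation harness and trial-table scoring.

k-fold cross-validation rotates a held-out test fold through the data;
per-fold accuracy is the fraction of correctly classified test samples
and the final accuracy is the arithmetic mean over folds.  Trial-table
scoring compares detections against ground-truth states over the 20
summarized lying/fall trials, either as reported by the monitoring
system (``mode="reported"``) or as re-decided by the rule-based
classifier from each trial's frame count and peak speed
(``mode="rule"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import CLASS_ORDER, ModelConfig, build_model, predict_batch, train_model
from .core import TrialRecord
from .fall import DetectorConfig, classify_transition
from .preprocessing import standardize_sequence

__all__ = [
    "CVResult",
    "TrialScore",
    "kfold_indices",
    "fold_accuracy",
    "final_accuracy",
    "run_cv",
    "score_trials",
]


@dataclass(frozen=True)
class CVResult:
    """Per-fold accuracies, their mean, and each sample's fold id."""

    fold_accuracies: list[float]
    final_accuracy: float
    fold_assignments: np.ndarray


@dataclass(frozen=True)
class TrialScore:
    """Accuracy summary over a set of trials.

    ``confusion`` maps ``(true_state, detected_state)`` to a count over
    the states ``lying``/``fall``.
    """

    overall_accuracy: float
    per_state_accuracy: dict
    n_correct: int
    n_trials: int
    confusion: dict = field(default_factory=dict)


def kfold_indices(n_samples: int, k: int = 5, seed: int = 0,
                  labels=None) -> np.ndarray:
    """Assign each of ``n_samples`` to one of ``k`` folds (sizes differ
    by at most one), stratified by ``labels`` when given; deterministic
    under ``seed``."""
    from sklearn.model_selection import KFold, StratifiedKFold

    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n_samples:
        raise ValueError(f"k={k} exceeds n_samples={n_samples}")
    assign = np.empty(n_samples, dtype=int)
    if labels is not None:
        labels = np.asarray([getattr(l, "value", l) for l in labels])
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
        splits = splitter.split(np.zeros(n_samples), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
        splits = splitter.split(np.zeros(n_samples))
    for fold, (_, test_idx) in enumerate(splits):
        assign[test_idx] = fold
    return assign


def fold_accuracy(predictions, truth) -> float:
    """Fraction of correct predictions in one test fold."""
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    if not predictions:
        raise ValueError("empty fold")
    return sum(p == t for p, t in zip(predictions, truth)) / len(truth)


def final_accuracy(fold_accuracies) -> float:
    """Arithmetic mean of the per-fold accuracies."""
    accs = list(fold_accuracies)
    if not accs:
        raise ValueError("no fold accuracies")
    return float(np.mean(accs))


def run_cv(frames, labels, model_cfg: ModelConfig | None = None,
           k: int = 5, seed: int = 0, preprocess_seed: int = 0) -> CVResult:
    """k-fold cross-validation of the posture classifier.

    ``frames`` may be raw Frames (canonicalized here) or already
    NormalizedFrames.  One model is trained per held-out fold; the
    result carries per-fold accuracy and their mean.
    """
    from .preprocessing import NormalizedFrame

    model_cfg = model_cfg or ModelConfig()
    if not all(isinstance(f, NormalizedFrame) for f in frames):
        frames = standardize_sequence(frames, seed=preprocess_seed)
    labels = list(labels)
    assign = kfold_indices(len(frames), k=k, seed=seed, labels=labels)
    fold_accs = []
    for fold in range(k):
        test_mask = assign == fold
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        cfg_fold = ModelConfig(**{**model_cfg.__dict__, "seed": model_cfg.seed + fold})
        model = build_model(cfg_fold)
        train_model(model, [frames[i] for i in train_idx],
                    [labels[i] for i in train_idx], cfg_fold)
        preds = [r.label for r in predict_batch(model, [frames[i] for i in test_idx])]
        fold_accs.append(fold_accuracy(preds, [labels[i] for i in test_idx]))
    return CVResult(fold_accuracies=fold_accs,
                    final_accuracy=final_accuracy(fold_accs),
                    fold_assignments=assign)


def score_trials(trials: list[TrialRecord], mode: str = "reported",
                 detector_cfg: DetectorConfig | None = None) -> TrialScore:
    """Score trial summaries against their ground-truth state.

    ``mode="reported"`` scores the detection column as printed;
    ``mode="rule"`` re-runs :func:`~radarfall.fall.classify_transition`
    on each trial's (frames, peak |velocity|) pair, which requires the
    velocity-variant table.
    """
    if mode not in ("reported", "rule"):
        raise ValueError(f"mode must be reported|rule, got {mode!r}")
    if not trials:
        raise ValueError("no trials to score")
    cfg = detector_cfg or DetectorConfig()
    states = ("lying", "fall")
    confusion = {(a, b): 0 for a in states for b in states}
    correct_by_state = {s: 0 for s in states}
    total_by_state = {s: 0 for s in states}
    n_correct = 0
    for tr in trials:
        if mode == "rule":
            if tr.variant != "velocity":
                raise ValueError(
                    "rule mode needs velocity-variant trials (peak speed missing)"
                )
            decided = classify_transition(tr.frames, tr.peak_magnitude, cfg)
            detected = "lying" if decided == "lying_down" else "fall"
        else:
            detected = tr.detection
        confusion[(tr.state, detected)] += 1
        total_by_state[tr.state] += 1
        if detected == tr.state:
            n_correct += 1
            correct_by_state[tr.state] += 1
    per_state = {
        s: (correct_by_state[s] / total_by_state[s]) if total_by_state[s] else float("nan")
        for s in states
    }
    return TrialScore(
        overall_accuracy=n_correct / len(trials),
        per_state_accuracy=per_state,
        n_correct=n_correct,
        n_trials=len(trials),
        confusion=confusion,
    )
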