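"""Split protocols (k-fold CV, session transfer, leave-one-subject-out) and
confusion-matrix metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .networks import N_CLASSES, FusionModel, task_predict
from .preprocess import TrialSet, concat_trialsets

__all__ = [
    "SplitPlan",
    "EvalReport",
    "kfold_split",
    "session_transfer_split",
    "loso_split",
    "evaluate",
    "report_from_confusion",
]


@dataclass
class SplitPlan:
    protocol: str  # kfold | semi_transfer | transfer | loso
    train_ids: np.ndarray
    test_ids: np.ndarray
    k: int = 4
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.train_ids = np.asarray(self.train_ids, dtype=np.int64)
        self.test_ids = np.asarray(self.test_ids, dtype=np.int64)
        if np.intersect1d(self.train_ids, self.test_ids).size:
            raise ValueError("train and test sets overlap")
        for ids, name in ((self.train_ids, "train"), (self.test_ids, "test")):
            if len(np.unique(ids)) != len(ids):
                raise ValueError(f"duplicate trial in {name} set")


@dataclass
class EvalReport:
    """Confusion matrix (rows = true, cols = predicted) with derived metrics."""

    confusion: np.ndarray
    accuracy: float
    sensitivity: np.ndarray  # per-class recall: diag / row sum
    precision: np.ndarray  # per-class PPV: diag / col sum
    n_trials: int

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity.tolist(),
            "precision": self.precision.tolist(),
            "n_trials": self.n_trials,
        }


def kfold_split(trials: TrialSet, k: int = 4, seed: int = 0) -> list[SplitPlan]:
    """Class-stratified k-fold plans; deterministic under ``seed``."""
    n = len(trials)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"cannot split {n} trials into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        SplitPlan("kfold", train_idx, test_idx, k=k, seed=seed, meta={"fold": f})
        for f, (train_idx, test_idx) in enumerate(skf.split(np.zeros(n), trials.labels))
    ]


def session_transfer_split(
    sessions: list[TrialSet], mode: str = "semi", seed: int = 0, test_session: int = 0
) -> tuple[SplitPlan, TrialSet]:
    """Session-transfer plans over concatenated sessions.

    ``semi``: test on a random class-stratified half of the test session,
    train on its other half plus all remaining sessions.  ``full``: test on
    the whole test session, train on the others only.
    Returns (plan, concatenated trial set the indices refer to).
    """
    if len(sessions) < 2:
        raise ValueError("session transfer needs at least 2 sessions")
    if mode not in ("semi", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    data = concat_trialsets(sessions)
    bounds = np.cumsum([0] + [len(s) for s in sessions])
    sess_of = np.zeros(len(data), dtype=np.int64)
    for s in range(len(sessions)):
        sess_of[bounds[s] : bounds[s + 1]] = s
    test_mask = sess_of == test_session
    if mode == "full":
        train_ids = np.flatnonzero(~test_mask)
        test_ids = np.flatnonzero(test_mask)
    else:
        rng = np.random.default_rng(seed)
        test_pool = np.flatnonzero(test_mask)
        half: list[int] = []
        for c in np.unique(data.labels[test_pool]):
            cls = test_pool[data.labels[test_pool] == c]
            half.extend(rng.choice(cls, size=len(cls) // 2, replace=False))
        test_ids = np.sort(np.asarray(half, dtype=np.int64))
        train_ids = np.setdiff1d(np.arange(len(data)), test_ids)
    protocol = "semi_transfer" if mode == "semi" else "transfer"
    return SplitPlan(protocol, train_ids, test_ids, seed=seed,
                     meta={"test_session": test_session}), data


def loso_split(subjects: list[TrialSet]) -> tuple[list[SplitPlan], TrialSet]:
    """Leave-one-subject-out: one plan per held-out subject; domain ids in the
    concatenated set are subject indices (for adversarial training)."""
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    data = concat_trialsets(subjects)
    bounds = np.cumsum([0] + [len(s) for s in subjects])
    plans = []
    for s in range(len(subjects)):
        test_ids = np.arange(bounds[s], bounds[s + 1])
        train_ids = np.concatenate(
            [np.arange(bounds[j], bounds[j + 1]) for j in range(len(subjects)) if j != s]
        )
        plans.append(SplitPlan("loso", train_ids, test_ids, meta={"test_subject": s}))
    return plans, data


def report_from_confusion(confusion: np.ndarray) -> EvalReport:
    confusion = np.asarray(confusion, dtype=np.int64)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(confusion).astype(np.float64)
    row = confusion.sum(axis=1).astype(np.float64)
    col = confusion.sum(axis=0).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(row > 0, diag / row, np.nan)
        prec = np.where(col > 0, diag / col, np.nan)
    return EvalReport(
        confusion=confusion,
        accuracy=float(diag.sum() / total),
        sensitivity=sens,
        precision=prec,
        n_trials=int(total),
    )


def evaluate(model: FusionModel, test: TrialSet, images: np.ndarray) -> EvalReport:
    """Deterministic inference on a test set -> confusion matrix, accuracy,
    per-class sensitivity and precision.  Argmax ties break to the lowest
    class index."""
    if len(test) == 0:
        raise ValueError("empty test set")
    probs = task_predict(model, test.trials, np.asarray(images))
    pred = probs.argmax(axis=1)
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(confusion, (test.labels, pred), 1)
    return report_from_confusion(confusion)
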