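"""Cross-validation protocol, multi-target loss, and the CV training loop.

Protocol: a held-out test set (default 1,000 subjects) is removed, the rest
is split into 10 folds; one model per fold is trained from scratch on the
nine complementary folds (Adam, initial learning rate 1e-4, 5 epochs) and
predicts logits for the common held-out set, giving a K-model prediction
grid whose spread measures model-side variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings; defaults follow the screening-study protocol."""

    learning_rate: float = 1e-4
    epochs: int = 5
    batch_size: int = 64
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass(frozen=True)
class CVPlan:
    """Held-out test ids plus k disjoint folds covering the remaining ids."""

    test_ids: tuple
    folds: tuple  # tuple of tuples of ids
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_ids(self, fold_index: int) -> List:
        return [i for j, f in enumerate(self.folds) if j != fold_index for i in f]


def make_cv_plan(subject_ids: Sequence, k: int = 10, test_n: int = 1000,
                 seed: int = 0) -> CVPlan:
    """Uniform random disjoint partition: test set + k folds (sizes differ <= 1)."""
    ids = list(subject_ids)
    if test_n >= len(ids):
        raise ValueError(f"test_n={test_n} must be smaller than the cohort ({len(ids)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    test = tuple(ids[i] for i in perm[:test_n])
    rest = [ids[i] for i in perm[test_n:]]
    folds = tuple(tuple(chunk) for chunk in np.array_split(np.array(rest, dtype=object), k))
    return CVPlan(test_ids=test, folds=folds, seed=seed)


def multi_target_loss(logits: Sequence[float], labels: Sequence[int]) -> float:
    """Sum over findings of BCE-with-logits, in the numerically stable form.

    -[y log σ(u) + (1-y) log(1-σ(u))] = max(u, 0) - u·y + log(1 + e^{-|u|})
    """
    u = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("logits must be finite")
    return float(np.sum(np.maximum(u, 0.0) - u * y + np.log1p(np.exp(-np.abs(u)))))


def train_and_predict(images: np.ndarray, labels: np.ndarray,
                      subject_ids: Sequence[str], plan: CVPlan,
                      train_config: TrainConfig,
                      backend_factory: Callable[[int], "SmallCNN"],
                      finding_names: Sequence[str] = ("pleural_thickening", "scoliosis"),
                      augment_fn=None, model_dir=None) -> pd.DataFrame:
    """Train one fresh model per fold; predict logits for the held-out test set.

    ``backend_factory(seed)`` must return an untrained backend with
    fit/predict_logits.  Returns the tidy K-model grid
    (subject_id, finding, model_index, logit).
    """
    index = {sid: i for i, sid in enumerate(subject_ids)}
    test_idx = np.array([index[s] for s in plan.test_ids])
    rows = []
    for fold in range(plan.k):
        train_idx = np.array([index[s] for s in plan.train_ids(fold)])
        model = backend_factory(train_config.seed + fold)
        cfg = TrainConfig(
            learning_rate=train_config.learning_rate,
            epochs=train_config.epochs,
            batch_size=train_config.batch_size,
            seed=train_config.seed + 1000 * (fold + 1),
            optimizer=train_config.optimizer,
        )
        try:
            model.fit(images[train_idx], labels[train_idx], cfg, augment_fn=augment_fn)
            logits = model.predict_logits(images[test_idx])
        except Exception as exc:  # re-raise with fold context
            raise RuntimeError(f"backend failed on CV fold {fold}") from exc
        if model_dir is not None and hasattr(model, "save"):
            from pathlib import Path

            Path(model_dir).mkdir(parents=True, exist_ok=True)
            model.save(Path(model_dir) / f"model_{fold + 1:02d}.npz")
        for j, name in enumerate(finding_names):
            for sid, u in zip(plan.test_ids, logits[:, j]):
                rows.append((sid, name, fold + 1, float(u)))
    return pd.DataFrame(rows, columns=["subject_id", "finding", "model_index", "logit"])
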