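"""Positive-unlabeled classification (PUC) for blank-signal removal.

Even pure-solvent control recordings show small, short pulse events
("blank signals", attributed to electrode-atom migration and
contamination), and the same events contaminate every sample recording.
There is no ground truth for which sample-solution events are blanks, so
removal is a positive-unlabeled problem: blank-solution signals are the
labeled positives, sample-solution signals are unlabeled.

The estimator follows Elkan & Noto: train a probabilistic classifier ``g``
to separate labeled from unlabeled examples, estimate the label frequency
``c = P(labeled | positive)`` as the mean of ``g`` over held-out positives
(their estimator e1), and score any example's probability of being a blank
as ``P(positive | x) = g(x) / c`` (clipped to [0, 1]).  The default inner
classifier is Gaussian naive Bayes; any scikit-learn style probabilistic
binary classifier can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler

__all__ = ["PUCConfig", "PUModel", "fit_puc", "blank_posterior", "filter_blanks"]


@dataclass(frozen=True)
class PUCConfig:
    """Positive-unlabeled fit settings.

    ``holdout_fraction`` of the positives is held out to estimate ``c``;
    rows with blank posterior >= ``threshold`` are removed by the filter.
    """

    holdout_fraction: float = 0.2
    threshold: float = 0.5
    seed: int = 0
    inner: Any = field(default_factory=GaussianNB)

    def __post_init__(self) -> None:
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0, 1)")


@dataclass
class PUModel:
    """Fitted Elkan-Noto model: standardizer + inner classifier + constant c."""

    scaler: StandardScaler
    inner: Any
    c: float
    threshold: float
    feature_names: list[str]
    seed: int

    def is_fitted(self) -> bool:
        return self.c is not None and 0.0 < self.c <= 1.0


def _feature_matrix(table: pd.DataFrame, feature_names: list[str]) -> np.ndarray:
    missing = set(feature_names) - set(table.columns)
    if missing:
        raise ValueError(f"feature table is missing columns: {sorted(missing)}")
    return table[feature_names].to_numpy(dtype=float)


def fit_puc(positive: pd.DataFrame, unlabeled: pd.DataFrame, config: PUCConfig = PUCConfig()) -> PUModel:
    """Fit the PU blank model from labeled blanks and unlabeled sample signals.

    The inner classifier is trained on z-scored features to separate the
    (non-held-out) positives from the unlabeled pool; ``c`` is the mean
    inner score over the positive holdout, clipped into (0, 1].

    Raises on empty inputs, mismatched columns, or a positive holdout of
    fewer than 5 rows (too small to estimate ``c``).
    """
    if len(positive) == 0 or len(unlabeled) == 0:
        raise ValueError("positive and unlabeled tables must both be non-empty")
    feature_names = [c for c in positive.columns if c != "label"]
    if [c for c in unlabeled.columns if c != "label"] != feature_names:
        raise ValueError("positive and unlabeled tables must share the same feature columns")

    rng = np.random.default_rng(config.seed)
    n_pos = len(positive)
    n_hold = int(round(config.holdout_fraction * n_pos))
    if n_hold < 5:
        raise ValueError(
            f"positive holdout would have {n_hold} rows (< 5); provide more blank "
            f"signals or raise holdout_fraction"
        )
    perm = rng.permutation(n_pos)
    hold_idx, fit_idx = perm[:n_hold], perm[n_hold:]
    if fit_idx.size == 0:
        raise ValueError("no positives left for fitting after holdout")

    x_pos = _feature_matrix(positive, feature_names)
    x_unl = _feature_matrix(unlabeled, feature_names)
    x_train = np.vstack([x_pos[fit_idx], x_unl])
    y_train = np.concatenate([np.ones(fit_idx.size), np.zeros(len(x_unl))])
    if len(np.unique(y_train)) < 2:
        raise ValueError("degenerate single-class training set")

    scaler = StandardScaler().fit(x_train)
    inner = clone(config.inner)
    inner.fit(scaler.transform(x_train), y_train)
    g_hold = inner.predict_proba(scaler.transform(x_pos[hold_idx]))[:, 1]
    c = float(np.clip(g_hold.mean(), 1e-12, 1.0))
    return PUModel(
        scaler=scaler,
        inner=inner,
        c=c,
        threshold=config.threshold,
        feature_names=feature_names,
        seed=config.seed,
    )


def blank_posterior(model: PUModel, features: pd.DataFrame) -> np.ndarray:
    """Per-row probability of being a blank signal: clip(g(x)/c, 0, 1)."""
    if not model.is_fitted():
        raise ValueError("PU model is not fitted")
    x = model.scaler.transform(_feature_matrix(features, model.feature_names))
    g = model.inner.predict_proba(x)[:, 1]
    return np.clip(g / model.c, 0.0, 1.0)


def filter_blanks(
    model: PUModel, unlabeled: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Split an unlabeled table into retained molecule signals and removed blanks.

    Rows whose blank posterior is >= the model threshold are removed.
    Returns (retained, removed, report); the report carries the counts,
    the retention fraction, ``c``, the threshold and the seed.
    """
    post = blank_posterior(model, unlabeled)
    keep = post < model.threshold
    retained = unlabeled.loc[keep].copy()
    removed = unlabeled.loc[~keep].copy()
    report = {
        "n_input": int(len(unlabeled)),
        "n_retained": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "retention_fraction": float(keep.mean()) if len(unlabeled) else float("nan"),
        "c": model.c,
        "threshold": model.threshold,
        "seed": model.seed,
    }
    return retained, removed, report
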