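"""Plurality-vote accuracy over repeated per-signal predictions.

A molecule measured n times yields n independent per-signal predictions;
the species is called by plurality vote.  With per-signal accuracy p over
k classes, errors spread uniformly over the k-1 wrong classes and ties at
the top broken uniformly at random, the vote accuracy is an exact sum over
multinomial count vectors; a Monte Carlo companion covers large n.  Both
the uniform-error and uniform-tie assumptions are modelling choices (the
error profile of a real classifier need not be uniform) and are recorded
in the output metadata of the CLI/pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VoteModel",
    "plurality_accuracy_exact",
    "plurality_accuracy_mc",
    "vote_curve",
]

#: Enumeration guard: number of wrong-class count vectors, ~C(n+k-2, k-2).
_MAX_ENUM_TERMS = 500_000


@dataclass(frozen=True)
class VoteModel:
    """k classes, per-signal accuracy p, uniform errors, uniform tie-break."""

    k: int = 4
    p: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least two classes")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("per-signal accuracy must lie in [0, 1]")


def _compositions(total: int, parts: int):
    """Yield all tuples of ``parts`` non-negative ints summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for rest in _compositions(total - head, parts - 1):
            yield (head, *rest)


def plurality_accuracy_exact(model: VoteModel, n: int) -> float:
    """Exact probability that the plurality vote over n signals is correct.

    Sums the multinomial probability of every count vector in which the
    true class is the strict plurality, plus 1/(tie size) times the
    probability of each vector where it ties for the top.  Feasible for
    moderate n (for k=4 up to n ~ 40 and beyond); raises and points to
    :func:`plurality_accuracy_mc` past the enumeration guard.
    """
    if n < 1:
        raise ValueError("need at least one signal")
    n_terms = math.comb(n + model.k - 2, model.k - 2)
    if n_terms > _MAX_ENUM_TERMS:
        raise ValueError(
            f"enumeration over {n_terms} count vectors exceeds the guard; "
            f"use plurality_accuracy_mc for this n"
        )
    p, k = model.p, model.k
    q = (1.0 - p) / (k - 1)
    log_fact = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, n + 1)))))
    total = 0.0
    for t in range(n, -1, -1):  # count of correct votes
        # log C(n, t) * p^t, guarded for p in {0, 1}
        if (p == 0.0 and t > 0) or (p == 1.0 and t < n):
            continue
        log_pt = (log_fact[n] - log_fact[t]) + (t * math.log(p) if t else 0.0)
        rem = n - t
        for wrong in _compositions(rem, k - 1):
            m = max(wrong) if wrong else 0
            if m > t:
                continue
            share = 1.0 if m < t else 1.0 / (1 + sum(1 for w in wrong if w == t))
            if rem and q == 0.0:
                continue
            log_w = -sum(log_fact[w] for w in wrong) + (rem * math.log(q) if rem else 0.0)
            total += share * math.exp(log_pt + log_w)
    return min(total, 1.0)


def plurality_accuracy_mc(
    model: VoteModel, n: int, reps: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte Carlo plurality-vote accuracy and its standard error.

    Tie credit is fractional (1 / tie size), matching the exact
    enumeration, so the two agree within Monte Carlo error wherever both
    run.  Requires ``reps >= 1000``.
    """
    if n < 1:
        raise ValueError("need at least one signal")
    if reps < 1000:
        raise ValueError("use at least 1000 Monte Carlo repetitions")
    rng = np.random.default_rng(seed)
    probs = np.full(model.k, (1.0 - model.p) / (model.k - 1))
    probs[0] = model.p
    counts = rng.multinomial(n, probs, size=reps)
    true = counts[:, 0]
    wrong_max = counts[:, 1:].max(axis=1)
    n_tied = (counts[:, 1:] == true[:, None]).sum(axis=1)
    outcome = np.where(true > wrong_max, 1.0, np.where(true == wrong_max, 1.0 / (1 + n_tied), 0.0))
    est = float(outcome.mean())
    se = float(outcome.std(ddof=1) / math.sqrt(reps))
    return est, se


def vote_curve(
    model: VoteModel,
    n_values,
    reps: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy-vs-n table, exact where enumeration is feasible, else MC.

    Columns: n, accuracy, method ('exact'|'mc'), se (0 for exact rows).
    """
    rows = []
    for i, n in enumerate(n_values):
        try:
            acc = plurality_accuracy_exact(model, int(n))
            rows.append({"n": int(n), "accuracy": acc, "method": "exact", "se": 0.0})
        except ValueError:
            acc, se = plurality_accuracy_mc(model, int(n), reps=reps, seed=seed + i)
            rows.append({"n": int(n), "accuracy": acc, "method": "mc", "se": se})
    return pd.DataFrame(rows)
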