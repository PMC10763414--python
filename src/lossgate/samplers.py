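"""Acquisition strategies over an unlabeled pool.

The proposed strategy ranks pool patches by the LPM's predicted loss but
first drops every candidate whose predicted loss reaches the threshold of its
*predicted* class — the region where unlabelable (noisy) patches concentrate —
and then takes an equal per-class share of the budget from the survivors.
Disabling the filter (``thresholds=None``) yields the plain learning-loss
baseline: the identical pipeline without the gate.

Also provided: the classic comparison strategies — least confidence, softmax
entropy, BALD (mutual information over Monte-Carlo-dropout passes), core-set
k-center greedy, and uniform random sampling.  Every strategy breaks ties by
ascending patch id so that selections are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import entr, softmax
from scipy.spatial.distance import cdist

from .plcm import ThresholdSet

__all__ = [
    "Selection",
    "topk_by_predicted_loss",
    "propose_filtered_topk",
    "learning_loss_sampler",
    "least_confidence",
    "entropy_sampler",
    "bald_scores",
    "bald_sampler",
    "coreset_kgreedy",
    "random_sampler",
]


@dataclass(frozen=True)
class Selection:
    """An ordered acquisition decision with per-id diagnostics."""

    strategy: str
    chosen_ids: tuple[str, ...]
    budget: int
    scores: dict[str, float] = field(default_factory=dict)
    predicted_class: dict[str, int] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.chosen_ids)) != len(self.chosen_ids):
            raise ValueError("selection contains duplicate ids")
        if len(self.chosen_ids) > self.budget:
            raise ValueError("selection exceeds budget")

    @property
    def empty(self) -> bool:
        return len(self.chosen_ids) == 0

    def to_json(self, path: str | Path) -> None:
        doc = {
            "strategy": self.strategy,
            "seed": self.seed,
            "budget": self.budget,
            "chosen": [
                {
                    "id": i,
                    "score": round(self.scores.get(i, float("nan")), 8),
                    "predicted_class": self.predicted_class.get(i),
                }
                for i in self.chosen_ids
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def _rank(ids, scores, descending=True):
    """Indices ordered by score (desc/asc) with ascending-id tie-break."""
    key = (lambda k: (-scores[k], ids[k])) if descending else (lambda k: (scores[k], ids[k]))
    return sorted(range(len(ids)), key=key)


# ---------------------------------------------------------------------------
# proposed / learning-loss


def topk_by_predicted_loss(ids, predicted_losses, budget: int) -> list[str]:
    """Global top-k by predicted loss: the set maximizing the summed predicted
    loss over all subsets of size <= budget (ties broken by ascending id)."""
    lhat = np.asarray(predicted_losses, dtype=float)
    order = _rank(list(ids), lhat, descending=True)
    return [ids[i] for i in order[:budget]]


def propose_filtered_topk(
    ids,
    predicted_classes,
    predicted_losses,
    thresholds: ThresholdSet | None,
    budget: int,
) -> Selection:
    """Threshold-gated, class-balanced top-k by predicted loss.

    Candidates with ``l_hat >= threshold`` of their *predicted* class are
    excluded (an undefined class threshold excludes nobody).  The budget is
    split into equal per-class quotas (floor(budget / C), remainder going one
    by one to the classes with the most surviving candidates); a class whose
    survivors cannot fill its quota hands the shortfall to the globally
    highest-loss remaining survivors.  Within a class, candidates are taken by
    descending predicted loss.

    Returns an empty Selection when every candidate is filtered out; the
    caller decides the fallback.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    ids = list(ids)
    cls = np.asarray(predicted_classes)
    lhat = np.asarray(predicted_losses, dtype=float)
    if not (len(ids) == len(cls) == len(lhat)):
        raise ValueError("ids, classes and losses must align")
    n_classes = (
        thresholds.n_classes if thresholds is not None else int(cls.max(initial=0)) + 1
    )
    gates = thresholds.gates() if thresholds is not None else np.full(n_classes, np.inf)

    survivors: dict[int, list[int]] = {t: [] for t in range(n_classes)}
    for i in range(len(ids)):
        if lhat[i] < gates[cls[i]]:
            survivors[cls[i]].append(i)
    for t in survivors:  # descending loss, ascending id
        survivors[t].sort(key=lambda i: (-lhat[i], ids[i]))

    name = "proposed" if thresholds is not None else "ll"
    total_surv = sum(len(v) for v in survivors.values())
    if total_surv == 0:
        return Selection(name, (), budget)

    quota = {t: budget // n_classes for t in range(n_classes)}
    remainder = budget - sum(quota.values())
    by_richness = sorted(range(n_classes), key=lambda t: (-len(survivors[t]), t))
    for t in by_richness[:remainder]:
        quota[t] += 1

    taken: list[int] = []
    leftover: list[int] = []
    for t in range(n_classes):
        taken.extend(survivors[t][: quota[t]])
        leftover.extend(survivors[t][quota[t] :])
    shortfall = min(budget, total_surv) - len(taken)
    if shortfall > 0:  # refill from the highest-loss survivors anywhere
        leftover.sort(key=lambda i: (-lhat[i], ids[i]))
        taken.extend(leftover[:shortfall])

    taken.sort(key=lambda i: (-lhat[i], ids[i]))
    return Selection(
        name,
        tuple(ids[i] for i in taken),
        budget,
        scores={ids[i]: float(lhat[i]) for i in taken},
        predicted_class={ids[i]: int(cls[i]) for i in taken},
    )


def learning_loss_sampler(ids, predicted_classes, predicted_losses, budget: int) -> Selection:
    """Unfiltered learning-loss baseline == proposed sampler with no gate."""
    return propose_filtered_topk(ids, predicted_classes, predicted_losses, None, budget)


# ---------------------------------------------------------------------------
# softmax-based baselines


def least_confidence(ids, class_scores, budget: int) -> Selection:
    """Take the ``budget`` items with the lowest maximum softmax probability."""
    probs = softmax(np.asarray(class_scores, dtype=np.float64), axis=1)
    conf = probs.max(axis=1)
    order = _rank(list(ids), conf, descending=False)[:budget]
    return Selection(
        "lc",
        tuple(ids[i] for i in order),
        budget,
        scores={ids[i]: float(conf[i]) for i in order},
        predicted_class={ids[i]: int(np.argmax(probs[i])) for i in order},
    )


def entropy_sampler(ids, class_scores, budget: int) -> Selection:
    """Take the ``budget`` items with the highest softmax Shannon entropy."""
    probs = softmax(np.asarray(class_scores, dtype=np.float64), axis=1)
    ent = entr(probs).sum(axis=1)  # entr handles 0*log(0) = 0
    order = _rank(list(ids), ent, descending=True)[:budget]
    return Selection(
        "entropy",
        tuple(ids[i] for i in order),
        budget,
        scores={ids[i]: float(ent[i]) for i in order},
        predicted_class={ids[i]: int(np.argmax(probs[i])) for i in order},
    )


# ---------------------------------------------------------------------------
# BALD


def bald_scores(probs_stack: np.ndarray) -> np.ndarray:
    """Mutual information between predictions and parameters.

    ``probs_stack``: (T, B, C) softmax outputs of T stochastic passes.
    Score = entropy of the mean prediction minus mean per-pass entropy;
    non-negative by Jensen's inequality, zero when all passes agree.
    """
    probs_stack = np.asarray(probs_stack, dtype=np.float64)
    if probs_stack.ndim != 3 or probs_stack.shape[0] < 2:
        raise ValueError("need a (T>=2, B, C) stack of stochastic passes")
    mean = probs_stack.mean(axis=0)
    h_mean = entr(mean).sum(axis=1)
    mean_h = entr(probs_stack).sum(axis=2).mean(axis=0)
    return h_mean - mean_h


def bald_sampler(ids, probs_stack: np.ndarray, budget: int) -> Selection:
    """Take the ``budget`` items with the highest mutual information."""
    mi = bald_scores(probs_stack)
    mean = np.asarray(probs_stack).mean(axis=0)
    order = _rank(list(ids), mi, descending=True)[:budget]
    return Selection(
        "bald",
        tuple(ids[i] for i in order),
        budget,
        scores={ids[i]: float(mi[i]) for i in order},
        predicted_class={ids[i]: int(np.argmax(mean[i])) for i in order},
    )


# ---------------------------------------------------------------------------
# core-set k-center greedy


def coreset_kgreedy(ids, pool_embeddings, labeled_embeddings, budget: int) -> Selection:
    """Greedy k-center: repeatedly pick the pool point farthest from the
    nearest covered center (labeled points plus previous picks).

    With an empty labeled set the first center is the lowest-id pool point
    (a fixed stand-in for an arbitrary starting point, kept for determinism).
    """
    ids = list(ids)
    pool = np.asarray(pool_embeddings, dtype=np.float64)
    if pool.ndim != 2 or len(ids) != len(pool):
        raise ValueError("pool embeddings must be (n, d) aligned with ids")
    chosen: list[int] = []
    scores: dict[str, float] = {}
    labeled = np.asarray(labeled_embeddings, dtype=np.float64)
    if labeled.size == 0:
        seed_idx = min(range(len(ids)), key=lambda i: ids[i])
        chosen.append(seed_idx)
        scores[ids[seed_idx]] = float("inf")
        min_dist = cdist(pool, pool[[seed_idx]]).ravel()
    else:
        min_dist = cdist(pool, labeled).min(axis=1)
    taken = set(chosen)
    while len(chosen) < min(budget, len(ids)):
        candidates = [i for i in range(len(ids)) if i not in taken]
        best = min(candidates, key=lambda i: (-min_dist[i], ids[i]))
        scores[ids[best]] = float(min_dist[best])
        chosen.append(best)
        taken.add(best)
        min_dist = np.minimum(min_dist, cdist(pool, pool[[best]]).ravel())
    return Selection("coreset", tuple(ids[i] for i in chosen), budget, scores=scores)


# ---------------------------------------------------------------------------
# random


def random_sampler(ids, budget: int, seed: int | np.random.Generator) -> Selection:
    """Uniform sample without replacement; order fixed by the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids_sorted = sorted(ids)
    k = min(budget, len(ids_sorted))
    pick = rng.choice(len(ids_sorted), size=k, replace=False)
    chosen = tuple(ids_sorted[i] for i in pick)
    return Selection(
        "random",
        chosen,
        budget,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )
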