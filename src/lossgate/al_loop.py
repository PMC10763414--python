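"""Iterative active-learning experiment harness.

Protocol per trial: a fixed initial labeled set of clean patches is drawn
once (identically for every strategy compared within the trial); then, each
iteration, the model is retrained from scratch on the current labeled set,
evaluated on the clean held-out test split, and asked to spend the budget on
pool patches.  The oracle (the corpus manifest) reveals each chosen patch's
class — or declares it noisy, in which case the patch is discarded: it leaves
the unlabeled pool but never enters the labeled set.  Pool bookkeeping obeys

    D_U(i+1) = D_U(i) - p_n - p_l        D_L(i+1) = D_L(i) + p_l

with |p_n| + |p_l| = budget whenever the pool suffices.  The headline noise
metric is the N-ratio, the percentage of the per-iteration budget spent on
noisy patches; summaries exclude iteration 1, whose labeled set is the fixed
clean seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import samplers
from .lpm import JointModel, TrainConfig, predict_losses, train_joint
from .plcm import DEFAULT_ALPHAS, DEFAULT_Z, ThresholdSet, thresholds_from_trace
from .synthetic import CLASS_NAMES, NOISY, Corpus

__all__ = [
    "STRATEGIES",
    "ExperimentConfig",
    "PoolState",
    "IterationRecord",
    "Oracle",
    "n_ratio",
    "run_iteration",
    "run_experiment",
    "aggregate_records",
    "noise_summary",
]

logger = logging.getLogger(__name__)

STRATEGIES = ("proposed", "ll", "lc", "entropy", "bald", "coreset", "random")


class PoolError(RuntimeError):
    """Pool bookkeeping contract violated."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment protocol; defaults are the 1/10-scale desk protocol
    (pool ~3,000 clean + noise, initial 100, budget 100, 10 iterations,
    5 trials).  The full-scale protocol (1,000/1,000) is reachable by config.
    """

    iterations: int = 10
    budget: int = 100
    initial_labeled: int = 100
    trials: int = 5
    alphas: tuple[float, ...] | float = DEFAULT_ALPHAS
    z_epochs: int = DEFAULT_Z
    collect: str = "predicted"  # which loss feeds the thresholds: predicted | true
    bald_passes: int = 25
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.budget < 1 or self.trials < 1:
            raise ValueError("iterations, budget and trials must be >= 1")
        if self.initial_labeled < 1:
            raise ValueError("initial_labeled must be >= 1")


@dataclass
class PoolState:
    """Disjoint unlabeled / labeled / discarded id sets at one iteration."""

    unlabeled: set[str]
    labeled: dict[str, int]  # id -> revealed class index
    discarded: set[str] = field(default_factory=set)
    iteration: int = 0

    def check(self) -> None:
        lab = set(self.labeled)
        if self.unlabeled & lab or self.unlabeled & self.discarded or lab & self.discarded:
            raise PoolError("unlabeled/labeled/discarded sets overlap")

    @property
    def total(self) -> int:
        return len(self.unlabeled) + len(self.labeled) + len(self.discarded)


class Oracle:
    """Labeling authority backed by the corpus manifest's hidden answers."""

    def __init__(self, corpus: Corpus):
        self._corpus = corpus

    def answer(self, state: PoolState, patch_id: str) -> str:
        """Reveal the patch's answer and move it out of the unlabeled pool.

        Clean patches join the labeled set; noisy patches are discarded.
        """
        if patch_id not in state.unlabeled:
            raise PoolError(f"patch {patch_id} is not in the unlabeled pool")
        ans = self._corpus[patch_id].oracle_answer
        state.unlabeled.remove(patch_id)
        if ans == NOISY:
            state.discarded.add(patch_id)
        else:
            state.labeled[patch_id] = CLASS_NAMES.index(ans)
        return ans


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    trial: int
    strategy: str
    n_labeled: int
    accuracy: float
    n_noisy: int
    n_clean: int
    n_ratio: float
    truncated: bool
    per_class_selected: tuple[int, ...]
    thresholds: tuple[float | None, ...] = ()

    def to_row(self) -> dict:
        d = asdict(self)
        d["per_class_selected"] = ";".join(map(str, self.per_class_selected))
        d["thresholds"] = ";".join(
            "undefined" if t is None else f"{t:.6g}" for t in self.thresholds
        )
        return d


def n_ratio(mean_noise: float, budget: int) -> float:
    """Percentage of the budget spent on noisy patches: mean/budget * 100."""
    if not (0 <= mean_noise <= budget):
        raise ValueError("mean noise count must lie in [0, budget]")
    return mean_noise / budget * 100.0


# ---------------------------------------------------------------------------
# one iteration


def _select(
    strategy: str,
    corpus: Corpus,
    state: PoolState,
    model: JointModel,
    thresholds: ThresholdSet | None,
    cfg: ExperimentConfig,
    rng: np.random.Generator,
) -> samplers.Selection:
    pool_ids = sorted(state.unlabeled)
    if not pool_ids:  # pool exhausted: empty selection, record flags truncation
        return samplers.Selection(strategy, (), 0)
    budget = min(cfg.budget, len(pool_ids))
    images = corpus.images(pool_ids)
    if strategy in ("proposed", "ll"):
        cls, lhat = predict_losses(model, images)
        gate = thresholds if strategy == "proposed" else None
        sel = samplers.propose_filtered_topk(pool_ids, cls, lhat, gate, budget)
        if sel.empty:  # fail-open fallback: ungated selection keeps the loop alive
            logger.warning("all candidates filtered out; falling back to ungated top-k")
            sel = samplers.propose_filtered_topk(pool_ids, cls, lhat, None, budget)
        return sel
    if strategy == "lc":
        logits, _, _ = model.forward(images)
        return samplers.least_confidence(pool_ids, logits, budget)
    if strategy == "entropy":
        logits, _, _ = model.forward(images)
        return samplers.entropy_sampler(pool_ids, logits, budget)
    if strategy == "bald":
        stack = model.stochastic_proba(images, cfg.bald_passes, rng)
        return samplers.bald_sampler(pool_ids, stack, budget)
    if strategy == "coreset":
        labeled_ids = sorted(state.labeled)
        return samplers.coreset_kgreedy(
            pool_ids,
            model.features(images),
            model.features(corpus.images(labeled_ids)) if labeled_ids else np.empty((0,)),
            budget,
        )
    if strategy == "random":
        return samplers.random_sampler(pool_ids, budget, rng)
    raise ValueError(f"unknown strategy {strategy!r} (choose from {STRATEGIES})")


def run_iteration(
    corpus: Corpus,
    state: PoolState,
    model: JointModel,
    strategy: str,
    cfg: ExperimentConfig,
    *,
    thresholds: ThresholdSet | None = None,
    accuracy: float = float("nan"),
    trial: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[samplers.Selection, IterationRecord]:
    """Select with ``strategy``, query the oracle, apply the pool update law."""
    state.check()
    state.iteration += 1
    rng = rng or np.random.default_rng(0)
    n_labeled_at_train = len(state.labeled)
    sel = _select(strategy, corpus, state, model, thresholds, cfg, rng)
    per_class = [0] * len(CLASS_NAMES)
    n_noisy = 0
    oracle = Oracle(corpus)
    for pid in sel.chosen_ids:
        ans = oracle.answer(state, pid)
        if ans == NOISY:
            n_noisy += 1
        else:
            per_class[CLASS_NAMES.index(ans)] += 1
    state.check()
    n_sel = len(sel.chosen_ids)
    record = IterationRecord(
        iteration=state.iteration,
        trial=trial,
        strategy=strategy,
        n_labeled=n_labeled_at_train,
        accuracy=accuracy,
        n_noisy=n_noisy,
        n_clean=n_sel - n_noisy,
        n_ratio=n_ratio(n_noisy, cfg.budget),
        truncated=n_sel < cfg.budget,
        per_class_selected=tuple(per_class),
        thresholds=(
            tuple(c.threshold for c in thresholds.per_class) if thresholds else ()
        ),
    )
    return sel, record


# ---------------------------------------------------------------------------
# full experiment


def _initial_state(corpus: Corpus, cfg: ExperimentConfig, rng: np.random.Generator) -> PoolState:
    pool_ids = sorted(corpus.pool_ids)
    clean = [i for i in pool_ids if corpus[i].oracle_answer != NOISY]
    if cfg.initial_labeled > len(clean):
        raise ValueError("initial_labeled exceeds the clean pool")
    pick = rng.choice(len(clean), size=cfg.initial_labeled, replace=False)
    initial = {clean[i] for i in pick}
    labeled = {i: CLASS_NAMES.index(corpus[i].oracle_answer) for i in sorted(initial)}
    return PoolState(unlabeled=set(pool_ids) - initial, labeled=labeled)


def _test_accuracy(model: JointModel, corpus: Corpus) -> float:
    ids = corpus.test_ids
    if not ids:
        return float("nan")
    probs = model.predict_proba(corpus.images(ids))
    return float(np.mean(np.argmax(probs, axis=1) == corpus.labels(ids)))


def run_trial(
    corpus: Corpus,
    strategy: str,
    cfg: ExperimentConfig,
    seed: int,
    trial: int,
) -> tuple[list[IterationRecord], list[samplers.Selection], list[ThresholdSet | None]]:
    """One trial: iterate train-from-scratch -> evaluate -> sample -> update.

    Seeds are derived so that the initial labeled set and the per-iteration
    model initialisations depend only on (seed, trial), never on the strategy
    — compared strategies start from the same clean data and the same models.
    """
    rng_init = np.random.default_rng(np.random.SeedSequence([seed, trial, 1]))
    state = _initial_state(corpus, cfg, rng_init)
    records, selections, thresholdsets = [], [], []
    for it in range(1, cfg.iterations + 1):
        model_seed = int(
            np.random.SeedSequence([seed, trial, it, 2]).generate_state(1)[0] % (2**31)
        )
        model = JointModel(
            n_classes=len(CLASS_NAMES),
            patch_size=corpus.patches[0].image.shape[0],
            seed=model_seed,
            lam=cfg.train.lam,
            epsilon=cfg.train.epsilon,
        )
        labeled_ids = sorted(state.labeled)
        labels = np.array([state.labeled[i] for i in labeled_ids])
        tc = TrainConfig(
            epochs=cfg.train.epochs,
            batch_size=cfg.train.batch_size,
            lr=cfg.train.lr,
            momentum=cfg.train.momentum,
            lam=cfg.train.lam,
            epsilon=cfg.train.epsilon,
            seed=model_seed,
        )
        model, trace = train_joint(model, corpus.images(labeled_ids), labels, tc)
        acc = _test_accuracy(model, corpus)
        thresholds = None
        if strategy == "proposed":
            thresholds = thresholds_from_trace(
                trace,
                alphas=cfg.alphas,
                z=min(cfg.z_epochs, cfg.train.epochs),
                collect=cfg.collect,
                provenance={"iteration": it, "trial": trial},
            )
        rng_strat = np.random.default_rng(np.random.SeedSequence([seed, trial, it, 3]))
        sel, rec = run_iteration(
            corpus,
            state,
            model,
            strategy,
            cfg,
            thresholds=thresholds,
            accuracy=acc,
            trial=trial,
            rng=rng_strat,
        )
        logger.info(
            "trial %d iter %d [%s]: |D_L|=%d acc=%.3f |p_n|=%d thresholds=%s",
            trial, it, strategy, rec.n_labeled, acc, rec.n_noisy, rec.thresholds,
        )
        records.append(rec)
        selections.append(sel)
        thresholdsets.append(thresholds)
    return records, selections, thresholdsets


def run_experiment(
    corpus: Corpus,
    strategy: str,
    cfg: ExperimentConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """All trials of one strategy; one row per (trial, iteration)."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r} (choose from {STRATEGIES})")
    rows = []
    for trial in range(1, cfg.trials + 1):
        records, _, _ = run_trial(corpus, strategy, cfg, seed, trial)
        rows.extend(r.to_row() for r in records)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aggregation


def aggregate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- std of accuracy and noise count per (strategy, iteration)."""
    g = records.groupby(["strategy", "iteration"])
    out = g.agg(
        accuracy_mean=("accuracy", "mean"),
        accuracy_std=("accuracy", lambda s: s.std(ddof=0)),
        n_noisy_mean=("n_noisy", "mean"),
        n_labeled_mean=("n_labeled", "mean"),
    ).reset_index()
    return out


def noise_summary(records: pd.DataFrame, budget: int) -> pd.DataFrame:
    """Per-strategy Mean / Total / N-ratio noise bookkeeping.

    Iteration 1 is excluded (its labeled set is the fixed clean seed), so
    Total averages each trial's summed noise count over the remaining
    iterations, Mean divides Total by that iteration count, and N-ratio is
    Mean over budget as a percentage.
    """
    rows = []
    post = records[records["iteration"] > 1]
    for strat, grp in post.groupby("strategy"):
        per_trial_total = grp.groupby("trial")["n_noisy"].sum()
        n_iter = grp["iteration"].nunique()
        total = float(per_trial_total.mean())
        mean = total / n_iter
        rows.append(
            {
                "strategy": strat,
                "mean": mean,
                "total": total,
                "n_ratio": n_ratio(mean, budget),
            }
        )
    return pd.DataFrame(rows)
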