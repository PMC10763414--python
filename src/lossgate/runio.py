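"""Run directories, the alpha-sensitivity sweep, and report generation.

A run directory is self-describing: ``manifest.json`` holds the full config
(plus its hash and the corpus location), ``records.csv`` the per-iteration
records, ``aggregate.csv`` / ``noise_summary.csv`` the mean +/- std tables,
and ``selections/`` one JSON per (trial, iteration) acquisition.  Re-executing
from the manifest reproduces the selection JSONs bit for bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import al_loop
from .al_loop import ExperimentConfig, aggregate_records, noise_summary, run_trial
from .config import ConfigError, RunConfig
from .synthetic import CLASS_NAMES, Corpus, clean_twin, generate_corpus, read_corpus

__all__ = ["execute_run", "rerun_from_manifest", "sweep_alpha", "report", "DataError"]

logger = logging.getLogger(__name__)

RUN_FILES = ("manifest.json", "records.csv", "aggregate.csv", "noise_summary.csv")


class DataError(RuntimeError):
    """A run directory or corpus directory is missing required artifacts."""


def execute_run(
    corpus: Corpus,
    config: RunConfig,
    out_dir: str | Path,
    corpus_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run all trials of ``config.strategy`` and write a run directory."""
    out = Path(out_dir)
    (out / "selections").mkdir(parents=True, exist_ok=True)
    (out / "thresholds").mkdir(exist_ok=True)
    cfg = config.to_experiment_config()
    rows = []
    for trial in range(1, cfg.trials + 1):
        records, selections, thresholdsets = run_trial(
            corpus, config.strategy, cfg, config.seed, trial
        )
        rows.extend(r.to_row() for r in records)
        for rec, sel, ts in zip(records, selections, thresholdsets):
            sel_out = type(sel)(
                strategy=sel.strategy,
                chosen_ids=sel.chosen_ids,
                budget=sel.budget,
                scores=sel.scores,
                predicted_class=sel.predicted_class,
                seed=config.seed,
            )
            sel_out.to_json(out / "selections" / f"t{trial}_i{rec.iteration}.json")
            if ts is not None:
                ts.to_json(
                    out / "thresholds" / f"t{trial}_i{rec.iteration}.json", CLASS_NAMES
                )
    records_df = pd.DataFrame(rows)
    records_df.to_csv(out / "records.csv", index=False, lineterminator="\n")
    aggregate_records(records_df).to_csv(out / "aggregate.csv", index=False, lineterminator="\n")
    noise_summary(records_df, cfg.budget).to_csv(
        out / "noise_summary.csv", index=False, lineterminator="\n"
    )
    manifest = {
        "schema_version": config.schema_version,
        "config": config.to_dict(),
        "config_hash": config.hash,
        "corpus_dir": None if corpus_dir is None else str(corpus_dir),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return records_df


def rerun_from_manifest(run_dir: str | Path, out_dir: str | Path) -> pd.DataFrame:
    """Re-execute a stored run from its manifest (determinism contract)."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"{run_dir} has no manifest.json")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    config = RunConfig.from_dict(manifest["config"])
    if manifest.get("corpus_dir"):
        corpus = read_corpus(manifest["corpus_dir"])
        corpus_dir = manifest["corpus_dir"]
    else:
        corpus = generate_corpus(config.corpus.to_spec())
        corpus_dir = None
    return execute_run(corpus, config, out_dir, corpus_dir=corpus_dir)


# ---------------------------------------------------------------------------
# alpha sensitivity sweep


def sweep_alpha(
    corpus: Corpus,
    alpha_grid: list[float | tuple[float, ...]],
    config: RunConfig,
    include_controls: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noise/accuracy sensitivity to the threshold multiplier alpha.

    For each alpha in the grid the full experiment is re-run with the proposed
    strategy.  With ``include_controls`` two reference columns are added: the
    filter-disabled run (the unfiltered learning-loss strategy, alpha -> inf)
    and, when the corpus knows its own spec, the proposed strategy on the
    matched noise-free corpus.

    Returns (accuracy table: one row per iteration x setting with mean/std,
    noise table: one row per setting with mean/total/N-ratio).
    """
    if not alpha_grid:
        raise ConfigError("alpha grid must be non-empty")
    cfg = config.to_experiment_config()
    settings: list[tuple[str, str, Corpus, ExperimentConfig]] = []
    for alpha in alpha_grid:
        a = tuple(alpha) if isinstance(alpha, (list, tuple)) else float(alpha)
        label = f"alpha={alpha}" if np.isscalar(a) else f"alpha={tuple(a)}"
        settings.append(
            (label, "proposed", corpus, _with_alphas(cfg, a))
        )
    if include_controls:
        settings.append(("no_threshold", "ll", corpus, cfg))
        if corpus.spec is not None:
            clean = generate_corpus(clean_twin(corpus.spec))
            settings.append(("clean_dataset", "proposed", clean, cfg))
        else:
            logger.warning("corpus has no spec; skipping the clean-dataset control")
    acc_rows, noise_rows = [], []
    for label, strategy, corp, c in settings:
        records = al_loop.run_experiment(corp, strategy, c, seed=config.seed)
        agg = aggregate_records(records)
        for row in agg.itertuples(index=False):
            acc_rows.append(
                {
                    "setting": label,
                    "iteration": row.iteration,
                    "accuracy_mean": row.accuracy_mean,
                    "accuracy_std": row.accuracy_std,
                }
            )
        ns = noise_summary(records, c.budget).iloc[0]
        noise_rows.append(
            {
                "setting": label,
                "mean": ns["mean"],
                "total": ns["total"],
                "n_ratio": ns["n_ratio"],
            }
        )
    return pd.DataFrame(acc_rows), pd.DataFrame(noise_rows)


def _with_alphas(cfg: ExperimentConfig, alphas) -> ExperimentConfig:
    return ExperimentConfig(
        iterations=cfg.iterations,
        budget=cfg.budget,
        initial_labeled=cfg.initial_labeled,
        trials=cfg.trials,
        alphas=alphas,
        z_epochs=cfg.z_epochs,
        collect=cfg.collect,
        bald_passes=cfg.bald_passes,
        train=cfg.train,
    )


# ---------------------------------------------------------------------------
# report


def report(run_dirs: list[str | Path], out_dir: str | Path, plots: bool = True) -> Path:
    """Render a combined summary of stored runs (pure function of their CSVs).

    Writes ``report.md``, ``combined_noise_summary.csv`` and, when ``plots``
    is on, accuracy and cumulative-noise figures.  Raises :class:`DataError`
    listing any missing files.
    """
    run_dirs = [Path(d) for d in run_dirs]
    if not run_dirs:
        raise DataError("no run directories given")
    missing = [
        f"{d}/{f}" for d in run_dirs for f in RUN_FILES if not (d / f).exists()
    ]
    if missing:
        raise DataError("missing run files: " + ", ".join(missing))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    frames = []
    for d in run_dirs:
        rec = pd.read_csv(d / "records.csv")
        rec["run"] = d.name
        frames.append(rec)
    records = pd.concat(frames, ignore_index=True)
    budget = int(
        json.loads((run_dirs[0] / "manifest.json").read_text())["config"]["experiment"][
            "budget"
        ]
    )
    agg = aggregate_records(records)
    noise = noise_summary(records, budget)
    noise.to_csv(out / "combined_noise_summary.csv", index=False, lineterminator="\n")

    lines = ["# Active-learning run report", ""]
    lines.append("## Noise selection (iteration 1 excluded)")
    lines.append("")
    lines.append("```\n" + noise.round(2).to_string(index=False) + "\n```")
    lines.append("")
    lines.append("## Accuracy per iteration (mean +/- std over trials)")
    lines.append("")
    piv = agg.pivot(index="iteration", columns="strategy", values="accuracy_mean")
    lines.append("```\n" + piv.round(3).to_string() + "\n```")
    lines.append("")
    (out / "report.md").write_text("\n".join(lines) + "\n", encoding="utf-8")

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for strat, g in agg.groupby("strategy"):
            ax.plot(g["iteration"], g["accuracy_mean"], marker="o", label=strat)
            ax.fill_between(
                g["iteration"],
                g["accuracy_mean"] - g["accuracy_std"],
                g["accuracy_mean"] + g["accuracy_std"],
                alpha=0.2,
            )
        ax.set_xlabel("iteration")
        ax.set_ylabel("test accuracy")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "accuracy.png", metadata={"Software": None})
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(6, 4))
        cum = (
            records.groupby(["strategy", "iteration"])["n_noisy"]
            .mean()
            .groupby(level=0)
            .cumsum()
            .reset_index()
        )
        for strat, g in cum.groupby("strategy"):
            ax.plot(g["iteration"], g["n_noisy"], marker="o", label=strat)
        ax.set_xlabel("iteration")
        ax.set_ylabel("cumulative noisy selections (mean over trials)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "cumulative_noise.png", metadata={"Software": None})
        plt.close(fig)
    return out / "report.md"
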