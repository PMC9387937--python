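"""End-to-end experiment orchestration.

``run_experiment`` turns one config into a full report: obtain an envelope
(synthesize it, or condition an EDF recording against a block-label table),
build the 30-s epoch grid, compute the requested feature families with the
z-scoring each contractually requires (mean/variance: raw envelope;
covariance, slow, fast, GPFA: per-5-minute z-scored envelope), decode each
family under 7-fold buffered blocked CV with class balancing, and attach the
finite binomial chance level to every accuracy.  Everything is deterministic
given the config seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifiers, features, gpfa, preprocess, synthetic, validation

logger = logging.getLogger(__name__)

#: feature family -> requires per-5-minute z-scored envelope
FAMILY_NEEDS_ZSCORE = {
    "mean": False,
    "variance": False,
    "covariance": True,
    "slow": True,
    "fast": True,
    "gpfa": True,
}
DEFAULT_FAMILIES = ("mean", "variance", "covariance", "slow", "fast")


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read and validate a block-label TSV (start_s, end_s, state).

    Blocks must be non-overlapping; unknown state names pass through as
    labels.  An empty table is returned as-is (downstream stages refuse it).
    """
    blocks = pd.read_csv(path, sep="\t")
    missing = {"start_s", "end_s", "state"} - set(blocks.columns)
    if missing:
        raise ValueError(f"label file missing columns: {sorted(missing)}")
    blocks = blocks.sort_values("start_s").reset_index(drop=True)
    if np.any(blocks["end_s"].to_numpy() <= blocks["start_s"].to_numpy()):
        raise ValueError("blocks must have positive duration")
    if np.any(blocks["start_s"].to_numpy()[1:] < blocks["end_s"].to_numpy()[:-1] - 1e-9):
        raise ValueError("blocks overlap")
    return blocks


@dataclass
class ExperimentConfig:
    """One experiment: data source, feature families, CV / decoder settings."""

    families: tuple[str, ...] = DEFAULT_FAMILIES
    n_folds: int = 7
    buffer_folds: int = 1
    alpha: float = 0.05
    epoch_s: float = 30.0
    zscore_window_s: float = 300.0
    svm_C: float = 1.0
    gpfa_p: int = 4
    gpfa_max_iter: int = 100
    gpfa_tol: float = 1e-5
    seed: int = 0
    # family -> bool overrides of the Table-contract z-scoring; validation only
    zscore_overrides: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.families) - set(FAMILY_NEEDS_ZSCORE)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        for fam, z in self.zscore_overrides.items():
            if fam in FAMILY_NEEDS_ZSCORE and z != FAMILY_NEEDS_ZSCORE[fam]:
                raise ValueError(
                    f"family {fam!r} contractually requires "
                    f"zscore={FAMILY_NEEDS_ZSCORE[fam]}"
                )


def run_experiment(
    env: preprocess.EnvelopeSeries,
    blocks: pd.DataFrame,
    config: ExperimentConfig | None = None,
) -> dict:
    """Decode behavioral state from every requested feature family.

    Returns a report dict: per family, the per-fold accuracies, mean and SE in
    percent, and the balanced trial count; plus the binomial chance level for
    the balanced dataset and the config echo.
    """
    config = config or ExperimentConfig()
    if blocks.empty:
        raise ValueError("no labeled blocks")

    es_raw = features.epoch(env, blocks, config.epoch_s)
    env_z = preprocess.zscore_segments(env, config.zscore_window_s)
    es_z = features.epoch(env_z, blocks, config.epoch_s)
    plan = validation.make_cv_plan(es_raw.n_epochs, config.n_folds, config.buffer_folds)
    labels = es_raw.labels

    classes, counts = np.unique(labels, return_counts=True)
    n_balanced = int(counts.min()) * classes.size
    chance = validation.chance_level(n_balanced, classes.size, config.alpha)

    mv = features.epoch_mean_var(es_raw)
    q = es_raw.n_channels
    report: dict = {
        "families": {},
        "chance": {
            "level_pct": chance.level_pct,
            "level_pct_rounded": chance.level_pct_rounded,
            "n_trials": n_balanced,
            "n_classes": int(classes.size),
            "alpha": config.alpha,
        },
        "n_epochs": int(es_raw.n_epochs),
        "classes": classes.tolist(),
        "config": config,
    }

    slow = fast = None
    for fam in config.families:
        logger.info("decoding family %r", fam)
        if fam == "mean":
            res = classifiers.train_eval_svm(mv[:, :q], labels, plan, config.seed, config.svm_C)
        elif fam == "variance":
            res = classifiers.train_eval_svm(mv[:, q:], labels, plan, config.seed, config.svm_C)
        elif fam == "covariance":
            cov = features.epoch_covariance(es_z)
            res = classifiers.train_eval_mdm(cov.matrices, labels, plan, config.seed)
        elif fam in ("slow", "fast"):
            if slow is None:
                slow, fast = features.bandsplit_features(env_z, es_z)
            feat = slow if fam == "slow" else fast
            res = classifiers.train_eval_svm(feat, labels, plan, config.seed, config.svm_C)
        elif fam == "gpfa":
            folds = gpfa.fit_fold_latents(
                es_z.epochs, labels, plan, config.gpfa_p, config.seed,
                max_iter=config.gpfa_max_iter, tol=config.gpfa_tol,
            )
            curve = gpfa.factor_decoding_curve(folds, labels, order="slow_first")
            res = classifiers.DecodingResult(
                curve.per_fold[:, -1], curve.n_test_per_fold, curve.n_classes
            )
        report["families"][fam] = {
            "per_fold_pct": (100.0 * res.per_fold).tolist(),
            "mean_pct": res.mean_pct,
            "se_pct": res.se_pct,
            "n_balanced": res.n_balanced_total,
            "chance_level_pct": chance.level_pct,
        }
    return report


def synthesize_default_dataset(
    seed: int = 0, n_repeats: int = 6, q: int = 12
) -> tuple[preprocess.EnvelopeSeries, pd.DataFrame, synthetic.GroundTruth]:
    """The default synthetic study conditions: four states, all four planted
    differences (mean, variance, covariance, timescale), interleaved 5-minute
    blocks."""
    specs = synthetic.demo_state_specs(q)
    schedule = synthetic.Schedule.repeated([s.name for s in specs], n_repeats)
    return synthetic.generate_envelope_dataset(specs, schedule, seed)
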