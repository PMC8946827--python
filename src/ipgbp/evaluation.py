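"""Accuracy statistics for cuffless-BP agreement with the cuff reference.

Implements the evaluation battery used for BP devices: mean error
(ME = mean of prediction − reference) and mean absolute error with their
sample standard deviations, Bland–Altman bias and 1.96·SD limits of
agreement, five-number box summaries, and the AAMI accuracy criterion
(|ME| ≤ 5 mmHg and error SD ≤ 8 mmHg).  Also provides the trial-stratified
120/30 train/test split: the five beats of a trial share one cuff label,
so they must never straddle the partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ipgbp.ssrnet import compute_quartiles

__all__ = [
    "EvaluationReport",
    "split_dataset",
    "mean_error",
    "mean_absolute_error",
    "bland_altman",
    "aami_check",
    "box_stats",
    "evaluate_predictions",
]

AAMI_ME_LIMIT = 5.0  # mmHg
AAMI_SD_LIMIT = 8.0  # mmHg


@dataclass
class EvaluationReport:
    """Agreement statistics for one target (SBP or DBP) on a test set."""

    target: str
    n: int
    ME: float
    ME_SD: float
    MAE: float
    MAE_SD: float
    bland_altman: tuple[float, float, float]  # bias, lower LoA, upper LoA
    aami_pass: bool

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _check_lengths(y, x):
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError(f"length mismatch: {y.size} predictions vs {x.size} references")
    if y.size == 0:
        raise ValueError("empty input")
    return y, x


def mean_error(y, x) -> tuple[float, float]:
    """ME = mean(y - x) and the sample SD (n-1) of the differences."""
    y, x = _check_lengths(y, x)
    d = y - x
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return float(d.mean()), sd


def mean_absolute_error(y, x) -> tuple[float, float]:
    """MAE = mean(|y - x|) and the sample SD (n-1) of the absolute differences."""
    y, x = _check_lengths(y, x)
    a = np.abs(y - x)
    sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    return float(a.mean()), sd


def bland_altman(y, x, return_table: bool = False):
    """Bland–Altman bias and 1.96·SD limits of agreement.

    Bias is mean(y - x) (identical to ME); limits are bias ± 1.96 × sample
    SD of the differences.  ``return_table=True`` also returns the per-pair
    (mean, difference) table for plotting.
    """
    y, x = _check_lengths(y, x)
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    if return_table:
        table = pd.DataFrame({"mean": (y + x) / 2.0, "difference": d})
        return (bias, lo, hi), table
    return bias, lo, hi


def aami_check(ME: float, SD: float) -> bool:
    """AAMI accuracy criterion: |mean error| ≤ 5 mmHg and SD ≤ 8 mmHg."""
    if not (np.isfinite(ME) and np.isfinite(SD)):
        raise ValueError("ME and SD must be finite")
    return bool(abs(ME) <= AAMI_ME_LIMIT and SD <= AAMI_SD_LIMIT)


def box_stats(values) -> tuple[float, float, float, float, float]:
    """(min, Q1, median, Q3, max) with the linear-interpolation quartiles."""
    v = np.asarray(values, dtype=float).ravel()
    q1, q2, q3 = compute_quartiles(v)
    return float(v.min()), q1, q2, q3, float(v.max())


def split_dataset(
    pairs,
    n_train: int = 120,
    n_test: int = 30,
    seed: int = 0,
    trial_ids=None,
):
    """Random train/test split, stratified by trial when ``trial_ids`` given.

    ``pairs`` is a sequence of (image, reference) items (or any items) with
    ``len(pairs) == n_train + n_test``.  With ``trial_ids``, whole trials
    are assigned to one partition, so the test side gets
    ``n_test / beats_per_trial`` complete trials; beats sharing a cuff
    label never leak across the split.  Deterministic in ``seed``.
    """
    pairs = list(pairs)
    total = n_train + n_test
    if len(pairs) != total:
        raise ValueError(f"expected exactly {total} pairs ({n_train} train + {n_test} test), got {len(pairs)}")
    rng = np.random.default_rng(seed)

    if trial_ids is None:
        order = rng.permutation(total)
        test_idx = set(order[:n_test].tolist())
    else:
        trial_ids = np.asarray(trial_ids)
        if trial_ids.size != total:
            raise ValueError("trial_ids length must match pairs")
        unique = pd.unique(trial_ids)
        per_trial = total // unique.size
        if n_test % per_trial:
            raise ValueError(
                f"n_test={n_test} is not a whole number of trials ({per_trial} beats per trial)"
            )
        n_test_trials = n_test // per_trial
        chosen = set(rng.permutation(unique)[:n_test_trials].tolist())
        test_idx = {i for i, t in enumerate(trial_ids) if t in chosen}
        if len(test_idx) != n_test:
            raise ValueError("trials are unbalanced; cannot form the requested test size")

    train = [p for i, p in enumerate(pairs) if i not in test_idx]
    test = [p for i, p in enumerate(pairs) if i in test_idx]
    return train, test


def evaluate_predictions(target: str, y, x) -> EvaluationReport:
    """Full report: ME/MAE ± SD, Bland–Altman, AAMI verdict."""
    me, me_sd = mean_error(y, x)
    mae, mae_sd = mean_absolute_error(y, x)
    ba = bland_altman(y, x)
    return EvaluationReport(
        target=target,
        n=int(np.asarray(y).size),
        ME=me,
        ME_SD=me_sd,
        MAE=mae,
        MAE_SD=mae_sd,
        bland_altman=ba,
        aami_pass=aami_check(me, me_sd),
    )
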