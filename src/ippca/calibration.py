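"""Simulation experiments: TW distribution fit, EigenDev ROC, threshold calibration.

Three experiments mirror the statistic-validation studies behind the
stopping criteria, all driven by the Balding-Nichols generator in
:mod:`ippca.popsim`:

* ``tw_fit_experiment`` -- subsample a homogeneous panel at a ladder of
  sample sizes and measure how far the empirical distribution of the
  Tracy-Widom statistic strays from the TW1 law (Kolmogorov distance, the
  quantity a p-p plot displays).
* ``roc_experiment`` -- sweep the EigenDev threshold over a grid and trace
  (FPR, TPR) from replicated null and structured subsamples.
* ``calibrate_threshold`` -- per sample size, take the empirical
  (1 - target FPR) quantile of the null EigenDev statistics (inverted-CDF
  order statistic) and average the per-size thresholds.

``assignment_accuracy`` scores a resolved partition against truth labels by
optimal leaf-to-group matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from ippca.criteria import eigendev_from_table, tw_from_table
from ippca.exceptions import UsageError
from ippca.genotype_io import GenotypeTable
from ippca.popsim import PRESETS, SimulationConfig, simulate, subsample, subsample_balanced
from ippca.tracy_widom import tw1_cdf

__all__ = [
    "RocCurve",
    "PPFitReport",
    "CalibrationResult",
    "tw_fit_experiment",
    "roc_experiment",
    "calibrate_threshold",
    "assignment_accuracy",
    "default_threshold_grid",
]


def default_threshold_grid() -> np.ndarray:
    """The EigenDev threshold sweep used for ROC curves (0.077 .. 0.387)."""
    return np.round(np.arange(0.077, 0.387 + 1e-9, 0.01), 3)


@dataclass
class RocCurve:
    sample_size: int
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    null_stats: np.ndarray
    alt_stats: np.ndarray
    replicates: int
    seed: int


@dataclass
class PPFitReport:
    sample_size: int
    stats: np.ndarray  # TW statistics over replicates
    ks_distance: float  # max |empirical CDF - TW1 CDF|
    replicates: int
    seed: int


@dataclass
class CalibrationResult:
    target_fpr: float
    sample_sizes: tuple[int, ...]
    per_size_thresholds: dict[int, float]
    threshold: float  # arithmetic mean over sizes
    null_stats: dict[int, np.ndarray]
    replicates: int
    seed: int


def _null_config(config: Optional[SimulationConfig]) -> SimulationConfig:
    return config if config is not None else PRESETS["desk-null"]


def _eigendev_stats(
    pool: GenotypeTable,
    size: int,
    replicates: int,
    seed: int,
    variance_fraction: float,
    balanced: bool,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    out = np.empty(replicates)
    for r in range(replicates):
        sub_seed = int(rng.integers(2**31))
        sub = (
            subsample_balanced(pool, size, sub_seed)
            if balanced
            else subsample(pool, size, sub_seed)
        )
        out[r], _ = eigendev_from_table(sub, variance_fraction)
    return out


def tw_fit_experiment(
    sample_sizes: Sequence[int] = tuple(range(10, 201, 10)),
    replicates: int = 50,
    base_config: Optional[SimulationConfig] = None,
    seed: int = 0,
) -> list[PPFitReport]:
    """TW-statistic distribution fit on homogeneous subsamples, per sample size."""
    config = _null_config(base_config)
    if config.divergence != 0.0:
        raise UsageError("tw_fit_experiment needs a homogeneous (divergence 0) config")
    if replicates < 20:
        warnings.warn(f"{replicates} replicates: quantile comparison underpowered")
    pool = simulate(replace(config, seed=config.seed + seed))
    reports = []
    rng = np.random.default_rng(seed + 1)
    for size in sample_sizes:
        stats = np.empty(replicates)
        for r in range(replicates):
            sub = subsample(pool, size, int(rng.integers(2**31)))
            stats[r], _ = tw_from_table(sub)
        reports.append(
            PPFitReport(
                sample_size=int(size),
                stats=stats,
                ks_distance=kolmogorov_distance(stats, tw1_cdf),
                replicates=replicates,
                seed=seed,
            )
        )
    return reports


def kolmogorov_distance(sample: np.ndarray, cdf) -> float:
    """max |F_emp - F| over the sample points (both one-sided sups)."""
    x = np.sort(np.asarray(sample, dtype=np.float64))
    n = len(x)
    theo = np.asarray(cdf(x), dtype=np.float64)
    d_plus = np.max(np.arange(1, n + 1) / n - theo)
    d_minus = np.max(theo - np.arange(0, n) / n)
    return float(max(d_plus, d_minus))


def roc_experiment(
    sample_sizes: Sequence[int] = (100, 200, 500),
    threshold_grid: Optional[np.ndarray] = None,
    replicates: int = 200,
    null_config: Optional[SimulationConfig] = None,
    alt_config: Optional[SimulationConfig] = None,
    seed: int = 0,
    variance_fraction: float = 0.90,
) -> list[RocCurve]:
    """EigenDev ROC per sample size from replicated null and structured subsamples.

    The structured arm subsamples the two-population panel evenly from both
    subpopulations.  Decision convention matches the engine: structured iff
    statistic > threshold (strict).
    """
    grid = default_threshold_grid() if threshold_grid is None else np.asarray(threshold_grid, float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise UsageError("threshold grid must be increasing with at least 2 points")
    null_cfg = _null_config(null_config)
    alt_cfg = alt_config if alt_config is not None else PRESETS["desk-twopop"]
    if null_cfg.divergence != 0.0:
        raise UsageError("null_config must have divergence 0")
    if alt_cfg.divergence <= 0.0:
        raise UsageError("alt_config must have divergence > 0")
    null_pool = simulate(replace(null_cfg, seed=null_cfg.seed + seed))
    alt_pool = simulate(replace(alt_cfg, seed=alt_cfg.seed + seed + 7919))
    curves = []
    for k, size in enumerate(sample_sizes):
        null_stats = _eigendev_stats(
            null_pool, size, replicates, seed + 13 * k + 1, variance_fraction, balanced=False
        )
        alt_stats = _eigendev_stats(
            alt_pool, size, replicates, seed + 13 * k + 2, variance_fraction, balanced=True
        )
        fpr = np.array([(null_stats > t).mean() for t in grid])
        tpr = np.array([(alt_stats > t).mean() for t in grid])
        curves.append(
            RocCurve(
                sample_size=int(size),
                thresholds=grid.copy(),
                fpr=fpr,
                tpr=tpr,
                null_stats=null_stats,
                alt_stats=alt_stats,
                replicates=replicates,
                seed=seed,
            )
        )
    return curves


def calibrate_threshold(
    target_fpr: float = 0.10,
    sample_sizes: Sequence[int] = (100, 200, 500),
    replicates: int = 200,
    null_config: Optional[SimulationConfig] = None,
    seed: int = 0,
    variance_fraction: float = 0.90,
) -> CalibrationResult:
    """EigenDev threshold achieving a target false-positive rate, per size and averaged.

    Per size the threshold is the empirical (1 - target_fpr) quantile of the
    null statistics, inverted-CDF (type-1 order statistic) convention; the
    calibrated value is the arithmetic mean over sizes.
    """
    if not 0.0 < target_fpr < 1.0:
        raise UsageError("target_fpr must be in (0, 1)")
    needed = max(20, int(np.ceil(1.0 / min(target_fpr, 1.0 - target_fpr))))
    if replicates < needed:
        raise UsageError(
            f"{replicates} replicates too few for the {1 - target_fpr:.0%} quantile; "
            f"need at least {needed}"
        )
    config = _null_config(null_config)
    if config.divergence != 0.0:
        raise UsageError("calibration needs a homogeneous (divergence 0) null config")
    pool = simulate(replace(config, seed=config.seed + seed))
    per_size: dict[int, float] = {}
    stats_by_size: dict[int, np.ndarray] = {}
    for k, size in enumerate(sample_sizes):
        stats = _eigendev_stats(
            pool, size, replicates, seed + 101 * k + 3, variance_fraction, balanced=False
        )
        stats_by_size[int(size)] = stats
        per_size[int(size)] = float(
            np.quantile(stats, 1.0 - target_fpr, method="inverted_cdf")
        )
    return CalibrationResult(
        target_fpr=target_fpr,
        sample_sizes=tuple(int(s) for s in sample_sizes),
        per_size_thresholds=per_size,
        threshold=float(np.mean(list(per_size.values()))),
        null_stats=stats_by_size,
        replicates=replicates,
        seed=seed,
    )


def assignment_accuracy(
    assignment: dict[str, str], truth: dict[str, str]
) -> tuple[float, int]:
    """Fraction of individuals correctly assigned under the best leaf-to-group matching.

    The matching maximizes the total number of agreeing individuals over all
    one-to-one matchings of predicted leaves to truth groups (Hungarian
    algorithm on the contingency table); unmatched surplus leaves contribute
    zero.  Returns (accuracy, K_error = K_predicted - K_truth).
    """
    if set(assignment) != set(truth):
        raise UsageError("assignment and truth must cover the same individuals")
    pred_labels = sorted(set(assignment.values()))
    true_labels = sorted(set(truth.values()))
    table = np.zeros((len(pred_labels), len(true_labels)), dtype=np.int64)
    pi = {lab: i for i, lab in enumerate(pred_labels)}
    ti = {lab: i for i, lab in enumerate(true_labels)}
    for ind, p in assignment.items():
        table[pi[p], ti[truth[ind]]] += 1
    rows, cols = linear_sum_assignment(table, maximize=True)
    accuracy = float(table[rows, cols].sum()) / len(assignment)
    return accuracy, len(pred_labels) - len(true_labels)
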