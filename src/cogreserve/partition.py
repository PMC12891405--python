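"""Incremental variance partition with a reliability-based noise ceiling.

Assembles the multimodal staircase: cumulative stacked out-of-sample R^2 for
each prefix of a block order (e.g. confounds, +GMV, +WMI, +rFC), its spread
across fold-assignment repeats, a descriptive one-sided paired test on each
increment, and the ceiling implied by the target's test-retest reliability.
R^2 values are reported in percent, matching the way variance-explained bar
charts are usually drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from cogreserve.prediction import CVConfig, cross_validated_r2, fit_block_model, stack
from cogreserve.synthetic import MultimodalDataset

import logging

logger = logging.getLogger(__name__)

__all__ = [
    "ReliabilityEstimate",
    "VariancePartition",
    "incremental_partition",
    "noise_ceiling",
    "increment_test",
    "reserve_score",
]


@dataclass(frozen=True)
class ReliabilityEstimate:
    """Test-retest reliability of the target score, typically estimated from
    an independent cohort."""

    r_test_retest: float
    n_reliability_sample: int = 0
    source_label: str = ""

    def __post_init__(self):
        if not 0 < self.r_test_retest <= 1:
            raise ValueError("reliability must lie in (0, 1]")


@dataclass(frozen=True)
class VariancePartition:
    """The staircase: one row per cumulative block set (all in percent)."""

    block_sets: tuple  # ordered tuple of block-name tuples
    r2_mean: np.ndarray
    r2_sd: np.ndarray
    increments: np.ndarray  # successive differences of r2_mean
    increment_p: np.ndarray  # descriptive one-sided paired p per increment
    ceiling: float  # percent, NaN if no reliability supplied
    n_repeats: int
    per_repeat_r2: np.ndarray  # (n_sets, n_repeats), percent

    def to_frame(self):
        import pandas as pd

        pad = [np.nan]  # the first block set has no increment
        return pd.DataFrame(
            {
                "block_set": ["+".join(bs) for bs in self.block_sets],
                "r2_mean_pct": np.round(self.r2_mean, 1),
                "r2_sd_pct": np.round(self.r2_sd, 2),
                "increment_pct": pad + list(np.round(self.increments, 1)),
                "increment_p": pad + list(self.increment_p),
                "ceiling_pct": np.round(self.ceiling, 1),
            }
        )


def noise_ceiling(rel: ReliabilityEstimate, convention: str = "r") -> float:
    """Maximum explainable variance (percent) given target reliability.

    Default convention: the ceiling is the reliability coefficient itself
    (the proportion of observed-score variance attributable to true score);
    ``convention="r_squared"`` returns its square instead.
    """
    r = rel.r_test_retest
    if convention == "r":
        return 100.0 * r
    if convention == "r_squared":
        return 100.0 * r * r
    raise ValueError(f"unknown ceiling convention {convention!r}")


def increment_test(r2_small: np.ndarray, r2_large: np.ndarray) -> float:
    """One-sided paired Wilcoxon signed-rank p-value that the larger block
    set explains more variance than the smaller, paired by repeat.

    Exact null distribution for n <= 25 repeats.  Repeats share the data, so
    the p-value is descriptive, not a population-level inference.  Invariant
    to adding a constant to both vectors; identical vectors give p = 1.
    """
    a = np.asarray(r2_small, dtype=float).ravel()
    b = np.asarray(r2_large, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 repeats")
    diff = b - a
    if np.all(diff == 0):
        return 1.0
    method = "exact" if a.size <= 25 else "approx"
    res = stats.wilcoxon(diff, alternative="greater", method=method)
    return float(res.pvalue)


def incremental_partition(
    data: MultimodalDataset,
    order: tuple | list,
    cv: CVConfig,
    reliability: ReliabilityEstimate | None = None,
    ceiling_convention: str = "r",
) -> VariancePartition:
    """Compute the cumulative stacked-R^2 staircase over a block order.

    For each repeat, every block in ``order`` is fit once with the nested-CV
    elastic net; each cumulative prefix of the order is then stacked
    (cross-fitted NNLS) and scored out-of-sample.  Means, SDs and successive
    increments are taken across repeats; increments telescope exactly to the
    difference between the last and first cumulative mean.
    """
    order = tuple(order)
    unknown = set(order) - set(data.block_names)
    if unknown:
        raise ValueError(f"unknown block(s) in order: {sorted(unknown)}")
    if len(order) == 0:
        raise ValueError("order must contain at least one block")

    n_sets = len(order)
    r2 = np.empty((n_sets, cv.n_repeats))
    for rep in range(cv.n_repeats):
        preds = []
        for name in order:
            bp = fit_block_model(data.block(name), data.target, cv, repeat=rep)
            logger.debug(
                "repeat %d block %s: chosen penalties %s", rep, name, bp.chosen_penalties
            )
            preds.append(bp)
        for j in range(n_sets):
            sr = stack(preds[: j + 1], data.target, cv, repeat=rep)
            r2[j, rep] = 100.0 * cross_validated_r2(data.target, sr.oof_pred)
        logger.info(
            "repeat %d/%d: cumulative R2 (%%) = %s",
            rep + 1, cv.n_repeats, np.round(r2[:, rep], 1),
        )

    r2_mean = r2.mean(axis=1)
    r2_sd = r2.std(axis=1, ddof=1) if cv.n_repeats > 1 else np.zeros(n_sets)
    increments = np.diff(r2_mean)
    if cv.n_repeats >= 2:
        inc_p = np.array(
            [increment_test(r2[j], r2[j + 1]) for j in range(n_sets - 1)]
        )
    else:
        inc_p = np.full(max(n_sets - 1, 0), np.nan)
    ceiling = (
        noise_ceiling(reliability, ceiling_convention)
        if reliability is not None
        else float("nan")
    )
    return VariancePartition(
        block_sets=tuple(order[: j + 1] for j in range(n_sets)),
        r2_mean=r2_mean,
        r2_sd=r2_sd,
        increments=increments,
        increment_p=inc_p,
        ceiling=ceiling,
        n_repeats=cv.n_repeats,
        per_repeat_r2=r2,
    )


def reserve_score(y: np.ndarray, clinical_pred: np.ndarray) -> np.ndarray:
    """Residual cognitive-reserve score from an out-of-fold clinical
    prediction.

    The clinical (e.g. grey-matter) prediction is affinely recalibrated by
    OLS and subtracted from the observed score; positive values mean better
    cognition than the clinical measure predicts.  Residuals sum to zero.
    """
    y = np.asarray(y, dtype=float).ravel()
    pred = np.asarray(clinical_pred, dtype=float).ravel()
    if y.size != pred.size:
        raise ValueError("length mismatch")
    if np.ptp(pred) == 0:
        raise ValueError("clinical prediction is constant; calibration undefined")
    design = np.column_stack([np.ones_like(pred), pred])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta
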