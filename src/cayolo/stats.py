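"""Paired statistical validation of two detectors on a shared test set.

McNemar's test on discordant image-level outcomes (continuity-corrected
chi-square by default, exact binomial for small counts) and a percentile
bootstrap confidence interval for the accuracy difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = ["PairedOutcomes", "mcnemar", "bootstrap_accuracy_diff",
           "compare_models"]


@dataclass
class PairedOutcomes:
    """Per-image correctness of model A and model B."""

    a_correct: np.ndarray
    b_correct: np.ndarray

    def __post_init__(self):
        self.a_correct = np.asarray(self.a_correct, dtype=bool)
        self.b_correct = np.asarray(self.b_correct, dtype=bool)
        if self.a_correct.shape != self.b_correct.shape:
            raise ValueError("correctness vectors must have equal length")

    @property
    def n(self) -> int:
        return self.a_correct.size

    @property
    def b(self) -> int:
        """Discordant count: A correct, B wrong."""
        return int(np.sum(self.a_correct & ~self.b_correct))

    @property
    def c(self) -> int:
        """Discordant count: A wrong, B correct."""
        return int(np.sum(~self.a_correct & self.b_correct))


def mcnemar(b: int, c: int, mode: str = "cc") -> Tuple[float, float]:
    """McNemar's test from discordant counts.

    mode="cc": continuity-corrected chi-square statistic
    (|b-c|-1)^2 / (b+c) with 1 df.  mode="exact": two-sided binomial
    p = min(1, 2 P(X <= min(b, c))), X ~ Binomial(b+c, 1/2).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        warnings.warn("no discordant pairs; p-value is 1 by convention")
        return 0.0, 1.0
    if mode == "cc":
        stat = max(abs(b - c) - 1, 0) ** 2 / (b + c)
        return float(stat), float(sps.chi2.sf(stat, df=1))
    if mode == "exact":
        k = min(b, c)
        p = min(1.0, 2.0 * sps.binom.cdf(k, b + c, 0.5))
        return float(k), float(p)
    raise ValueError("mode must be 'cc' or 'exact'")


def bootstrap_accuracy_diff(outcomes: PairedOutcomes, n_boot: int = 10000,
                            level: float = 0.95, seed: int = 0):
    """Percentile bootstrap CI for acc_A - acc_B, in percentage points.

    Resamples image indices with replacement; returns
    (mean difference, (ci_low, ci_high)).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    if outcomes.n < 1:
        raise ValueError("need at least one test image")
    rng = np.random.default_rng(seed)
    a = outcomes.a_correct.astype(float)
    b = outcomes.b_correct.astype(float)
    idx = rng.integers(0, outcomes.n, size=(n_boot, outcomes.n))
    diffs = (a[idx].mean(axis=1) - b[idx].mean(axis=1)) * 100.0
    lo, hi = np.percentile(diffs, [(1 - level) / 2 * 100,
                                   (1 + level) / 2 * 100])
    return float(diffs.mean()), (float(lo), float(hi))


def compare_models(a_correct: Sequence[bool], b_correct: Sequence[bool],
                   n_boot: int = 10000, level: float = 0.95, seed: int = 0):
    """Full paired comparison report (mirrors the statistical summary table)."""
    out = PairedOutcomes(np.asarray(a_correct), np.asarray(b_correct))
    stat, p = mcnemar(out.b, out.c)
    mean_diff, ci = bootstrap_accuracy_diff(out, n_boot, level, seed)
    return {
        "n": out.n,
        "acc_a": float(out.a_correct.mean()),
        "acc_b": float(out.b_correct.mean()),
        "discordant_b": out.b,
        "discordant_c": out.c,
        "mcnemar_statistic": stat,
        "mcnemar_p": p,
        "mean_accuracy_diff_pct": mean_diff,
        "ci_pct": list(ci),
        "ci_level": level,
        "significant_mcnemar": p < 0.05,
        "significant_bootstrap": ci[0] > 0 or ci[1] < 0,
    }
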