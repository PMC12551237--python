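"""Trial design: single-arm vs two-arm sample sizes and arm comparisons.

A single-arm trial with synthetic controls evaluates each patient against
their own predicted counterfactual, so the outcome is a within-patient
difference and the test is a paired (one-sample) t-test; a standard RCT
compares two independent groups with a two-sample t-test.  Sample sizes are
the smallest n whose exact noncentral-t power reaches the target (normal
approximations are off by a couple of patients at these sizes, which
matters).  Tests are two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .assessment import Instance, uems

__all__ = [
    "DesignParams",
    "DesignInputs",
    "ArmComparison",
    "power_paired",
    "power_two_sample",
    "paired_n",
    "two_sample_n",
    "monte_carlo_power",
    "estimate_design_inputs",
    "bootstrap_design",
    "arm_compare",
]

_N_MAX = 1_000_000


@dataclass(frozen=True)
class DesignParams:
    """Detectable effect (motor points), outcome SD, significance and power.

    For the paired design ``sd`` is the standard deviation of the paired
    differences; for the two-sample design it is the per-observation SD.
    """

    delta: float = 5.0
    sd: float = 10.0
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.sd <= 0:
            raise ValueError("delta and sd must be positive")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


def power_paired(n: int, p: DesignParams) -> float:
    """Exact power of the two-sided one-sample t-test on n paired differences."""
    df = n - 1
    nc = p.delta / (p.sd / np.sqrt(n))
    tc = stats.t.ppf(1 - p.alpha / 2, df)
    return float(1 - stats.nct.cdf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))


def power_two_sample(n_per_group: int, p: DesignParams) -> float:
    """Exact power of the two-sided two-sample t-test with equal arms."""
    df = 2 * n_per_group - 2
    nc = p.delta / (p.sd * np.sqrt(2.0 / n_per_group))
    tc = stats.t.ppf(1 - p.alpha / 2, df)
    return float(1 - stats.nct.cdf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))


def _smallest_n(power_fn, p: DesignParams, n_min: int) -> int:
    n = n_min
    while n <= _N_MAX:
        if power_fn(n, p) >= p.power:
            return n
        n += 1
    raise ValueError(f"target power {p.power} unreachable below n={_N_MAX}")


def paired_n(p: DesignParams) -> int:
    """Smallest number of patients for the single-arm (paired) design."""
    return _smallest_n(power_paired, p, 2)


def two_sample_n(p: DesignParams) -> int:
    """Smallest per-group size for the two-arm design (equal groups)."""
    return _smallest_n(power_two_sample, p, 2)


def monte_carlo_power(
    n: int, p: DesignParams, design: str = "paired",
    n_reps: int = 100_000, seed: int = 0,
) -> float:
    """Simulated rejection rate of the design at sample size ``n``."""
    rng = np.random.default_rng(seed)
    if design == "paired":
        x = rng.normal(p.delta, p.sd, size=(n_reps, n))
        t = x.mean(1) / (x.std(1, ddof=1) / np.sqrt(n))
        crit = stats.t.ppf(1 - p.alpha / 2, n - 1)
    elif design == "two_sample":
        x = rng.normal(p.delta, p.sd, size=(n_reps, n))
        y = rng.normal(0.0, p.sd, size=(n_reps, n))
        sp = np.sqrt((x.var(1, ddof=1) + y.var(1, ddof=1)) / 2)
        t = (x.mean(1) - y.mean(1)) / (sp * np.sqrt(2.0 / n))
        crit = stats.t.ppf(1 - p.alpha / 2, 2 * n - 2)
    else:
        raise ValueError("design must be 'paired' or 'two_sample'")
    return float((np.abs(t) > crit).mean())


# ---------------------------------------------------------------------------
# Design inputs estimated from a cohort + synthetic-control model
# ---------------------------------------------------------------------------

@dataclass
class DesignInputs:
    """Outcome variability estimates for the two designs.

    ``sd_two_sample`` is the SD of the observed UEMS improvement across
    patients; ``sd_paired`` the SD of (observed - synthetic-control) UEMS
    improvement per patient.  A systematic offset of the synthetic controls
    does not inflate ``sd_paired``; it is surfaced as ``bias`` instead.
    """

    sd_two_sample: float
    sd_paired: float
    bias: float
    n: int

    @property
    def bias_flagged(self) -> bool:
        return abs(self.bias) > 1.0  # more than one motor point of drift


def _uems_improvements(instances: Sequence[Instance], predictor) -> tuple[np.ndarray, np.ndarray]:
    obs = np.array([uems(i.late) - uems(i.early) for i in instances], dtype=float)
    pred = np.asarray(predictor.predict_batch(list(instances)), dtype=float)
    uems_pred = pred[:, :10].sum(axis=1)  # C5-T1 block of the 20-vector
    uems_early = np.array([uems(i.early) for i in instances], dtype=float)
    return obs, uems_pred - uems_early


def estimate_design_inputs(instances: Sequence[Instance], predictor) -> DesignInputs:
    """Estimate the two outcome SDs from a cohort and its synthetic controls."""
    if len(instances) < 3:
        raise ValueError("need at least 3 instances to estimate design inputs")
    obs, syn = _uems_improvements(instances, predictor)
    diff = obs - syn
    return DesignInputs(
        sd_two_sample=float(np.std(obs, ddof=1)),
        sd_paired=float(np.std(diff, ddof=1)),
        bias=float(np.mean(diff)),
        n=len(instances),
    )


def bootstrap_design(
    instances: Sequence[Instance],
    predictor,
    params: DesignParams = DesignParams(),
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Patient-level bootstrap of the two required sample sizes.

    Resamples instances with replacement, re-estimates both SDs and the
    resulting single-arm size and RCT total (twice the per-group size), and
    reports medians with (2.5, 97.5) percentile intervals.  Zero-variance
    resamples are flagged and skipped.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    obs, syn = _uems_improvements(instances, predictor)
    rng = np.random.default_rng(seed)
    singles, totals, degenerate = [], [], 0
    n = len(obs)
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        sd2 = np.std(obs[idx], ddof=1)
        sdp = np.std(obs[idx] - syn[idx], ddof=1)
        if sd2 <= 0 or sdp <= 0:
            degenerate += 1
            continue
        p2 = DesignParams(params.delta, sd2, params.alpha, params.power)
        pp = DesignParams(params.delta, sdp, params.alpha, params.power)
        singles.append(paired_n(pp))
        totals.append(2 * two_sample_n(p2))

    def ci(vals):
        return {
            "median": float(np.median(vals)),
            "p2.5": float(np.percentile(vals, 2.5)),
            "p97.5": float(np.percentile(vals, 97.5)),
        }

    return {
        "single_arm_n": ci(singles),
        "rct_total_n": ci(totals),
        "n_boot": n_boot,
        "degenerate_resamples": degenerate,
    }


# ---------------------------------------------------------------------------
# Arm comparison (case-study style)
# ---------------------------------------------------------------------------

@dataclass
class ArmComparison:
    """Group means with empirical percentile spread and the t-test result."""

    mean_a: float
    mean_b: float
    percentiles_a: tuple[float, float]
    percentiles_b: tuple[float, float]
    statistic: float
    p_value: float
    test_type: str

    def summary(self) -> str:
        return (
            f"{self.test_type} t-test: "
            f"A {self.mean_a:.2f} ({self.percentiles_a[0]:.2f}, {self.percentiles_a[1]:.2f}) "
            f"vs B {self.mean_b:.2f} ({self.percentiles_b[0]:.2f}, {self.percentiles_b[1]:.2f}); "
            f"t = {self.statistic:.3f}, p = {self.p_value:.3f}"
        )


def arm_compare(group_a, group_b, paired: bool) -> ArmComparison:
    """Compare two outcome vectors with the design-appropriate t-test.

    Paired comparisons (patient vs own synthetic control) require aligned,
    equal-length vectors; two-sample comparisons do not.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length, aligned groups")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
    return ArmComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        percentiles_a=(float(np.percentile(a, 2.5)), float(np.percentile(a, 97.5))),
        percentiles_b=(float(np.percentile(b, 2.5)), float(np.percentile(b, 97.5))),
        statistic=float(res.statistic), p_value=float(res.pvalue),
        test_type="paired" if paired else "two-sample",
    )
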