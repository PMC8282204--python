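"""The five Monte Carlo evaluation statistics for one study condition.

Convergence rate, relative parameter bias, mean squared error, 95%
confidence-interval coverage and power are computed over the
replications of a condition.  Only replications classified as converged
enter the parameter-level summaries; the convergence rate itself is
reported over all replications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import FIXED_EFFECT_NAMES, VARIANCE_NAMES, GenerationParams
from .estimate import ConvergenceStatus, FitResult, classify_convergence

__all__ = [
    "relative_bias",
    "mse",
    "coverage_95",
    "power",
    "convergence_rate",
    "summarize_condition",
    "ConditionSummary",
]

#: Tolerance thresholds from the methodological literature: relative
#: bias within 5% and coverage within [0.91, 0.98] are acceptable.
BIAS_TOLERANCE = 0.05
COVERAGE_BAND = (0.91, 0.98)


def relative_bias(estimates, truth: float) -> float:
    """(mean(estimates) - truth) / truth; undefined for truth == 0."""
    if truth == 0.0:
        raise ZeroDivisionError("relative bias is undefined for a zero true value")
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates supplied")
    return float((estimates.mean() - truth) / truth)


def mse(estimates, truth: float) -> float:
    """Mean squared deviation from truth (squared bias plus variance)."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates supplied")
    return float(np.mean((estimates - truth) ** 2))


def coverage_95(intervals, truth: float) -> float:
    """Proportion of closed intervals containing the true value."""
    lo = np.asarray([iv[0] for iv in intervals], dtype=float)
    hi = np.asarray([iv[1] for iv in intervals], dtype=float)
    if np.any(lo > hi):
        raise ValueError("interval with lo > hi")
    return float(np.mean((lo <= truth) & (truth <= hi)))


def power(p_values, alpha: float = 0.05) -> float:
    """Proportion of replications rejecting the null: p strictly < alpha."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(np.mean(p < alpha))


def convergence_rate(classifications) -> float:
    """Proportion of replications classified as converged."""
    cls = list(classifications)
    if not cls:
        raise ValueError("no classifications supplied")
    n_conv = sum(1 for c in cls if c == ConvergenceStatus.CONVERGED)
    return n_conv / len(cls)


@dataclass
class ConditionSummary:
    """Per-parameter Monte Carlo summaries for one condition.

    ``table`` has one row per parameter with columns ``truth,
    relative_bias, mse, coverage_95, power, bias_flag, coverage_flag``.
    Relative bias is absent (NaN) for zero-truth parameters and power is
    reported for fixed effects only.
    """

    condition_label: str
    n_total: int
    n_converged: int
    convergence_rate: float
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tidy(self) -> pd.DataFrame:
        """Long format: one row per parameter x statistic."""
        if self.table.empty:
            return pd.DataFrame(
                [
                    {
                        "condition": self.condition_label,
                        "parameter": "",
                        "statistic": "convergence_rate",
                        "value": self.convergence_rate,
                    }
                ]
            )
        rows = []
        for param, row in self.table.iterrows():
            for stat in ("relative_bias", "mse", "coverage_95", "power"):
                rows.append(
                    {
                        "condition": self.condition_label,
                        "parameter": param,
                        "statistic": stat,
                        "value": row[stat],
                    }
                )
        rows.append(
            {
                "condition": self.condition_label,
                "parameter": "",
                "statistic": "convergence_rate",
                "value": self.convergence_rate,
            }
        )
        return pd.DataFrame(rows)


def summarize_condition(
    fits: list[FitResult], truth: GenerationParams
) -> ConditionSummary:
    """Apply the five statistics to one condition's replications.

    Replications enter the parameter summaries only when classified as
    converged.  If none converged the summary carries the convergence
    rate alone and an empty table.
    """
    if not fits:
        raise ValueError("no fits supplied")
    statuses = [classify_convergence(f) for f in fits]
    keep = [f for f, s in zip(fits, statuses) if s == ConvergenceStatus.CONVERGED]
    label = fits[0].condition_label
    n_total = len(fits)
    n_conv = len(keep)
    rate = n_conv / n_total
    if n_conv == 0:
        return ConditionSummary(label, n_total, 0, rate)

    true_values = truth.true_values()
    rows = {}
    for name in FIXED_EFFECT_NAMES + VARIANCE_NAMES:
        tv = true_values[name]
        est = np.array([f.estimates[name] for f in keep])
        ivs = [f.conf_ints[name] for f in keep]
        finite_iv = [iv for iv in ivs if np.isfinite(iv[0]) and np.isfinite(iv[1])]
        rb = relative_bias(est, tv) if tv != 0.0 else np.nan
        cov = coverage_95(finite_iv, tv) if finite_iv else np.nan
        if name in FIXED_EFFECT_NAMES:
            pv = [f.p_values[name] for f in keep if np.isfinite(f.p_values[name])]
            pw = power(pv) if pv else np.nan
        else:
            pw = np.nan
        rows[name] = {
            "truth": tv,
            "relative_bias": rb,
            "mse": mse(est, tv),
            "coverage_95": cov,
            "power": pw,
            "bias_flag": bool(abs(rb) > BIAS_TOLERANCE) if np.isfinite(rb) else False,
            "coverage_flag": (
                bool(cov < COVERAGE_BAND[0] or cov > COVERAGE_BAND[1])
                if np.isfinite(cov)
                else False
            ),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parameter"
    return ConditionSummary(label, n_total, n_conv, rate, table)
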