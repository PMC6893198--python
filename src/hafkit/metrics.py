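"""Accuracy scoring: RMSE and effective coverage.

Effective coverage converts the error of a set of allele-frequency estimates
into the read depth at which plain binomial sampling would show the same
error. For estimates p_est at n sites with known truth p_true,

    RMSE_estimated  = sqrt( sum (p_est - p_true)^2 / n )
    RMSE_theoretical = sqrt( sum p_true (1 - p_true) / (C * n) )

and solving RMSE_theoretical = RMSE_estimated for C gives

    C_effective = sum p_true (1 - p_true) / sum (p_est - p_true)^2 .

Because numerator and denominator are computed over the same set of true
frequencies, the metric does not depend on the underlying allele-frequency
spectrum. It measures read-sampling error only; sampling of individuals from
the population is a separate, unaffected source of error and is out of scope.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class AccuracyReport:
    n_sites: int
    rmse_estimated: float
    sum_ptrue_var: float
    effective_coverage: float
    n_excluded: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "n_sites": self.n_sites,
            "rmse": self.rmse_estimated,
            "effective_coverage": self.effective_coverage,
            "n_excluded": self.n_excluded,
        }, indent=2)


def _paired(est, truth):
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError(f"site mismatch: {est.shape} estimates vs {truth.shape} truths")
    keep = ~(np.isnan(est) | np.isnan(truth))
    return est[keep], truth[keep], int((~keep).sum())


def rmse(est, truth) -> float:
    """Root mean squared error between estimated and true frequencies.

    NaN entries (sites without an estimate) are excluded pairwise.
    """
    e, t, _ = _paired(est, truth)
    if e.size == 0:
        raise ValueError("no scorable sites")
    return float(np.sqrt(np.mean((e - t) ** 2)))


def effective_coverage(est, truth, exclude_fixed: bool = False) -> float:
    """Binomial-equivalent coverage of a set of frequency estimates.

    Sites with p_true in {0, 1} contribute nothing to the numerator; by
    default they are retained (their estimation error still inflates the
    denominator), ``exclude_fixed=True`` drops them entirely.
    """
    e, t, _ = _paired(est, truth)
    if exclude_fixed:
        seg = (t > 0) & (t < 1)
        e, t = e[seg], t[seg]
    if e.size == 0:
        raise ValueError("no scorable sites")
    num = float(np.sum(t * (1.0 - t)))
    den = float(np.sum((e - t) ** 2))
    if num == 0.0:
        raise ValueError("all true frequencies fixed (0 or 1): effective coverage undefined")
    if den == 0.0:
        warnings.warn("zero squared error: effective coverage is infinite")
        return math.inf
    return num / den


def score(est, truth, exclude_fixed: bool = False) -> AccuracyReport:
    """Full accuracy report (RMSE + effective coverage) for a track pair."""
    e, t, n_excl = _paired(est, truth)
    if exclude_fixed:
        seg = (t > 0) & (t < 1)
        n_excl += int((~seg).sum())
        e, t = e[seg], t[seg]
    if e.size == 0:
        raise ValueError("no scorable sites")
    den = float(np.sum((e - t) ** 2))
    num = float(np.sum(t * (1.0 - t)))
    if num == 0.0:
        raise ValueError("all true frequencies fixed (0 or 1): effective coverage undefined")
    if den == 0.0:
        warnings.warn("zero squared error: effective coverage is infinite")
        ec = math.inf
    else:
        ec = num / den
    return AccuracyReport(
        n_sites=int(e.size),
        rmse_estimated=float(np.sqrt(den / e.size)),
        sum_ptrue_var=num,
        effective_coverage=ec,
        n_excluded=n_excl,
    )
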