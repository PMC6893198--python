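"""Log-linear predictor of HAF effective coverage.

Across simulation regimes, effective coverage (EC) is well described by two
covariates: Rwin, the mean number of reads overlapping at least one SNP site
per frequency-estimation window (the information supply for inference), and
M, the percent of founder genotype calls that are missing. The model is

    log10(EC) = a * log10(Rwin) + b * log10(1 + M) + c

with M in PERCENT units (0-100) — the 1+M term is scale-sensitive, so a
fraction-vs-percent mixup silently changes b. The model is linear in its
coefficients, so ordinary least squares in log space fits it exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from hafkit.hapfreq import ObservationSet, extract_observations


@dataclass
class ECObservation:
    """One (simulation) measurement of effective coverage and its covariates."""

    Rwin: float
    M: float  # percent missing founder calls, 0-100
    EC: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.Rwin <= 0 or self.EC <= 0 or self.M < 0:
            raise ValueError("require Rwin > 0, EC > 0, M >= 0")


def compute_rwin(sam_or_obs, table, plan) -> float:
    """Mean count of reads overlapping >=1 SNP site per frequency window.

    Counts merged template observations (a read pair counts once).
    """
    if plan.n_freq_windows == 0:
        raise ValueError("empty window plan")
    obs = sam_or_obs if isinstance(sam_or_obs, ObservationSet) else \
        extract_observations(sam_or_obs, table)
    pos0 = table.positions - 1
    counts = []
    for (start, end) in plan.freq_windows:
        lo = int(np.searchsorted(pos0, start, side="left"))
        hi = int(np.searchsorted(pos0, end, side="left"))
        counts.append(obs.reads_in_site_range(lo, hi))
    return float(np.mean(counts))


class EffectiveCoverageModel:
    """Two-covariate log-linear EC regression with a fit/predict interface.

    Fitted attributes (set by :meth:`fit`): ``a_``, ``b_``, ``c_`` —
    regression coefficients; ``r2_`` — R^2 on the log10(EC) scale;
    ``n_`` — number of observations.
    """

    def __init__(self):
        self.a_ = self.b_ = self.c_ = None
        self.r2_ = None
        self.n_ = None

    @property
    def is_fitted(self) -> bool:
        return self.a_ is not None

    def fit(self, observations) -> "EffectiveCoverageModel":
        """Least-squares fit of log10(EC) on (log10(Rwin), log10(1+M), 1).

        ``observations`` is a sequence of :class:`ECObservation` or a tuple of
        arrays (Rwin, M, EC). Needs >=3 observations with >=2 distinct Rwin
        and >=2 distinct M values; otherwise the degenerate covariate is named
        in the error.
        """
        if isinstance(observations, tuple) and len(observations) == 3:
            rwin, m, ec = (np.asarray(x, dtype=float) for x in observations)
        else:
            rwin = np.array([o.Rwin for o in observations], dtype=float)
            m = np.array([o.M for o in observations], dtype=float)
            ec = np.array([o.EC for o in observations], dtype=float)
        if rwin.size < 3:
            raise ValueError("need at least 3 observations")
        if np.unique(rwin).size < 2:
            raise ValueError("Rwin is constant: coefficient a unidentifiable")
        if np.unique(m).size < 2:
            raise ValueError("M is constant: coefficient b unidentifiable")
        y = np.log10(ec)
        X = np.column_stack([np.log10(rwin), np.log10(1.0 + m),
                             np.ones_like(y)])
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 3:
            raise ValueError("rank-deficient design (collinear Rwin and M)")
        self.a_, self.b_, self.c_ = (float(v) for v in coef)
        resid = y - X @ coef
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
        self.n_ = int(y.size)
        return self

    def predict(self, Rwin, M):
        """EC = 10^(a log10(Rwin) + b log10(1+M) + c); vectorised."""
        if not self.is_fitted:
            raise ValueError("model is not fitted")
        Rwin = np.asarray(Rwin, dtype=float)
        M = np.asarray(M, dtype=float)
        if np.any(Rwin <= 0) or np.any(M < 0):
            raise ValueError("require Rwin > 0 and M >= 0")
        out = 10.0 ** (self.a_ * np.log10(Rwin) + self.b_ * np.log10(1.0 + M)
                       + self.c_)
        return float(out) if out.ndim == 0 else out

    def get_params(self) -> dict:
        return {"a": self.a_, "b": self.b_, "c": self.c_}

    def to_json(self, path=None, provenance=None):
        d = {"model": "log10(EC) = a*log10(Rwin) + b*log10(1+M) + c",
             "M_units": "percent (0-100)",
             "a": self.a_, "b": self.b_, "c": self.c_,
             "r2": self.r2_, "n": self.n_}
        if provenance:
            d["provenance"] = provenance
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, path) -> "EffectiveCoverageModel":
        with open(path) as fh:
            d = json.load(fh)
        m = cls()
        m.a_, m.b_, m.c_ = d["a"], d["b"], d["c"]
        m.r2_ = d.get("r2")
        m.n_ = d.get("n")
        return m


def recommend_table(model: EffectiveCoverageModel, L: float, R: float,
                    generations, coverages, snp_density: float,
                    M: float = 0.0, q: float = 0.18):
    """Predicted EC over a (generation x coverage) grid for planning.

    Rwin is approximated from the design: the window size follows the
    exponential fragment-length quantile model, reads overlap >=1 SNP site
    essentially always at typical densities, and the expected number of
    templates per window is coverage * window_size / (2 * 150).
    """
    import pandas as pd

    from hafkit.windows import WindowParams, window_size_at_generation

    rows = []
    for g in generations:
        w = window_size_at_generation(WindowParams(L=int(L), R=R, G=g, q=q))
        for cov in coverages:
            rwin = cov * w / (2 * 150.0)
            rows.append({
                "generations": g, "coverage": cov, "window_bp": w,
                "Rwin": rwin, "predicted_EC": model.predict(rwin, M),
            })
    return pd.DataFrame(rows)
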