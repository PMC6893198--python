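"""Recombination-scaled window planning for haplotype-frequency inference.

Haplotype frequencies are estimated under the assumption that no recombination
breakpoint falls inside an inference window. After G generations of
recombination at rate R per bp per generation on a chromosome of length L, the
lengths of unrecombined founder fragments are modelled as Exponential with rate

    lambda = (L*R*G + 1) / L        [per bp]

(the +1/L term accounts for the chromosome ends bounding every fragment).
The window size is set to the q-th quantile of that distribution (default
q = 0.18), so only 18% of fragments are expected to be shorter than a window;
windows therefore shrink as generations accumulate. Frequency-estimation
windows overlap with a step of 10% of the window size, putting interior sites
in exactly 10 windows, and each set of read likelihoods is organised in
enclosing windows 10x the size, with a step of half that size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_QUANTILE = 0.18
MIN_WINDOW = 1_000


@dataclass(frozen=True)
class WindowParams:
    """Inputs to window sizing.

    L: chromosome length (bp); R: mean recombination rate (crossovers per bp
    per generation); G: generations since population founding; q: quantile of
    the fragment-length distribution used as the window size.
    """

    L: int
    R: float
    G: float
    q: float = DEFAULT_QUANTILE

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("chromosome length L must be positive")
        if self.R < 0:
            raise ValueError("recombination rate R must be >= 0")
        if self.G < 0:
            raise ValueError("generations G must be >= 0")
        if not 0 < self.q < 1:
            raise ValueError("quantile q must lie in (0, 1)")


@dataclass
class WindowPlan:
    """Overlapping frequency-estimation windows plus enclosing likelihood windows.

    All intervals are 0-based half-open ``(start, end)``; SNP positions are
    1-based (VCF convention) and converted at module boundaries.
    """

    L: int
    window_size: int
    freq_step: int
    freq_windows: list = field(default_factory=list)
    lik_windows: list = field(default_factory=list)

    @property
    def lik_size(self) -> int:
        return 10 * self.window_size

    @property
    def lik_step(self) -> int:
        return self.lik_size // 2

    @property
    def n_freq_windows(self) -> int:
        return len(self.freq_windows)

    def freq_windows_array(self) -> np.ndarray:
        return np.asarray(self.freq_windows, dtype=np.int64).reshape(-1, 2)

    def windows_covering(self, pos0: int) -> list:
        """Indices of frequency windows containing 0-based position ``pos0``."""
        return [i for i, (a, b) in enumerate(self.freq_windows) if a <= pos0 < b]

    def to_bed(self, path, chrom: str):
        with open(path, "w") as fh:
            for a, b in self.freq_windows:
                fh.write(f"{chrom}\t{a}\t{b}\n")


def fragment_rate(p: WindowParams) -> float:
    """Exponential rate (per bp) of unrecombined fragment lengths: (L*R*G+1)/L."""
    return (p.L * p.R * p.G + 1.0) / p.L


def window_size_at_generation(p: WindowParams, min_window: int = MIN_WINDOW) -> int:
    """Window size = q-th quantile of Exp(lambda), in bp.

    -ln(1-q)/lambda rounded to the nearest bp, clamped to [min_window, L].
    """
    lam = fragment_rate(p)
    size = -math.log1p(-p.q) / lam
    return int(min(max(round(size), min_window), p.L))


def build_plan(p: WindowParams, override_size: int | None = None,
               min_window: int = MIN_WINDOW,
               mean_snp_spacing: float | None = None) -> WindowPlan:
    """Build the full window plan for one chromosome.

    ``override_size`` bypasses the quantile model (used e.g. for fixed 1000 kb
    / 100 kb / 10 kb windows on unrecombined pools). Terminal windows are
    clipped at L rather than dropped so chromosome ends stay covered.
    """
    size = int(override_size) if override_size is not None else window_size_at_generation(p, min_window)
    size = min(size, p.L)
    if mean_snp_spacing is not None and size < 10 * mean_snp_spacing:
        logger.warning(
            "window size %d bp is < 10x the mean inter-SNP distance (%.0f bp); "
            "windows may contain too few SNPs", size, mean_snp_spacing,
        )
    step = max(1, round(0.10 * size))
    plan = WindowPlan(L=p.L, window_size=size, freq_step=step)
    plan.freq_windows = _tile(p.L, size, step)
    lik_size = min(10 * size, p.L)
    plan.lik_windows = _tile(p.L, lik_size, max(1, lik_size // 2))
    return plan


def _tile(L: int, size: int, step: int) -> list:
    """Offset-`step` windows of `size` covering [0, L); terminal windows clipped."""
    wins = []
    s = 0
    while s + size <= L:
        wins.append((s, s + size))
        s += step
    while wins and wins[-1][1] < L or not wins:
        wins.append((s, L))
        s += step
    return wins
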