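"""Founder-haplotype frequency inference from pooled reads.

Every read sampled from the pool originates from one founder haplotype (no
recombination breakpoints are assumed within an inference window). At the SNP
sites a read covers, its bases either match or mismatch each founder's allele;
with per-base error probability eps = 10^(-Q/10) from the base quality Q, the
read likelihood against haplotype h is

    log P(read | h) = sum over covered SNP sites of
                      log(1 - eps)  where the observed allele equals h's,
                      log(eps / 3)  where it differs (bases that are neither
                                    ref nor alt mismatch every founder).

Monomorphic positions contribute identically to every founder and cancel, so
only SNP sites carry information. Window haplotype frequencies f are the
maximum-likelihood mixture weights of this read mixture, obtained by EM:

    f_h  <-  mean over reads r of  f_h P(r|h) / sum_h' f_h' P(r|h').
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam

logging.getLogger(__name__).addHandler(logging.NullHandler())
logger = logging.getLogger(__name__)

OBS_REF = 0
OBS_ALT = 1
OBS_OTHER = 2

MAX_EPS = 0.75


@dataclass
class ReadObservation:
    """One (merged) read's observations at the SNP sites it covers."""

    read_id: str
    site_indices: np.ndarray
    obs_alleles: np.ndarray  # per site: OBS_REF / OBS_ALT / OBS_OTHER
    errors_eps: np.ndarray


class ObservationSet:
    """Flat, site-sorted container of all informative read observations.

    Stores one entry per (read, covered SNP site); entries are sorted by site
    index so a window's entries are a contiguous slice. Iteration yields
    per-read :class:`ReadObservation` views.
    """

    def __init__(self, read_ids, entry_read, entry_site, entry_allele, entry_eps,
                 n_skipped=0):
        self.read_ids = list(read_ids)
        order = np.lexsort((entry_read, entry_site))
        self.entry_read = np.asarray(entry_read, dtype=np.int64)[order]
        self.entry_site = np.asarray(entry_site, dtype=np.int64)[order]
        self.entry_allele = np.asarray(entry_allele, dtype=np.int8)[order]
        self.entry_eps = np.asarray(entry_eps, dtype=np.float64)[order]
        self.n_skipped = n_skipped

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    def __len__(self) -> int:
        return len(self.read_ids)

    def __iter__(self):
        by_read = np.argsort(self.entry_read, kind="stable")
        bounds = np.searchsorted(self.entry_read[by_read], np.arange(self.n_reads + 1))
        for r in range(self.n_reads):
            sl = by_read[bounds[r]:bounds[r + 1]]
            yield ReadObservation(
                self.read_ids[r], self.entry_site[sl], self.entry_allele[sl],
                self.entry_eps[sl],
            )

    def site_slice(self, site_lo: int, site_hi: int):
        """Entry index range for sites with table index in [site_lo, site_hi)."""
        a = np.searchsorted(self.entry_site, site_lo, side="left")
        b = np.searchsorted(self.entry_site, site_hi, side="left")
        return a, b

    def reads_in_site_range(self, site_lo: int, site_hi: int) -> int:
        a, b = self.site_slice(site_lo, site_hi)
        return int(np.unique(self.entry_read[a:b]).size)


@dataclass
class WindowFrequencies:
    """EM output for one frequency-estimation window (simplex over founders)."""

    window: tuple
    freqs: np.ndarray
    n_reads: int
    converged: bool
    n_iter: int


@dataclass
class LikelihoodMatrix:
    """Per-window read x founder log-likelihoods."""

    window: tuple
    read_index: np.ndarray
    loglik: np.ndarray


def extract_observations(sam_path, table, region=None) -> ObservationSet:
    """Decode aligned reads into per-SNP-site observations.

    Paired mates are merged into one observation per template (on mate
    disagreement at a site, the higher-quality base wins). Unmapped,
    secondary, supplementary and duplicate-flagged reads are skipped; reads
    covering no SNP site are omitted. ``region`` is an optional 0-based
    half-open (start, end) interval filter on reference overlap.
    """
    pos0 = table.positions - 1  # SNP positions, 0-based
    ref_b = table.ref_allele
    alt_b = table.alt_allele
    per_template: dict = {}
    n_skipped = 0
    mode = "rb" if str(sam_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(sam_path), mode, check_sq=False) as af:
        for r in af:
            if r.is_unmapped or r.is_secondary or r.is_supplementary or r.is_duplicate:
                n_skipped += 1
                continue
            rs, re_ = r.reference_start, r.reference_end
            if region is not None and (re_ <= region[0] or rs >= region[1]):
                continue
            lo = int(np.searchsorted(pos0, rs, side="left"))
            hi = int(np.searchsorted(pos0, re_, side="left"))
            if lo == hi:
                continue
            seq = r.query_sequence
            qual = r.query_qualities
            cig = r.cigartuples
            if cig is not None and len(cig) == 1 and cig[0][0] in (0, 7, 8):
                ref2query = None  # contiguous: offset arithmetic suffices
            else:
                ref2query = dict(
                    (rp, qp) for qp, rp in r.get_aligned_pairs(matches_only=True)
                )
            sites = per_template.setdefault(r.query_name, {})
            for j in range(lo, hi):
                if ref2query is None:
                    qpos = int(pos0[j] - rs)
                else:
                    qpos = ref2query.get(int(pos0[j]))
                    if qpos is None:
                        continue  # site deleted/skipped in this read
                base = seq[qpos]
                q = qual[qpos] if qual is not None else 30
                if base == ref_b[j]:
                    allele = OBS_REF
                elif base == alt_b[j]:
                    allele = OBS_ALT
                else:
                    allele = OBS_OTHER
                prev = sites.get(j)
                if prev is None or q > prev[2]:
                    sites[j] = (allele, min(10.0 ** (-q / 10.0), MAX_EPS), q)
    if n_skipped:
        logger.info("skipped %d unmapped/secondary/supplementary/duplicate reads", n_skipped)
    read_ids, e_read, e_site, e_allele, e_eps = [], [], [], [], []
    for qname, sites in per_template.items():
        if not sites:
            continue
        ridx = len(read_ids)
        read_ids.append(qname)
        for j, (allele, eps, _q) in sites.items():
            e_read.append(ridx)
            e_site.append(j)
            e_allele.append(allele)
            e_eps.append(eps)
    return ObservationSet(read_ids, e_read, e_site, e_allele, e_eps, n_skipped)


def read_loglik(obs: ReadObservation, hap_alleles: np.ndarray) -> float:
    """log P(read | haplotype) for one read against one (imputed) haplotype."""
    h = np.asarray(hap_alleles)[obs.site_indices]
    match = obs.obs_alleles == h  # OBS_OTHER (2) never equals a 0/1 haplotype allele
    eps = obs.errors_eps
    return float(np.sum(np.where(match, np.log1p(-eps), np.log(eps / 3.0))))


def window_likelihoods(obs: ObservationSet, genotypes: np.ndarray,
                       site_lo: int, site_hi: int, window=None) -> LikelihoodMatrix:
    """Read x founder log-likelihood matrix over sites [site_lo, site_hi).

    Only reads covering at least one SNP site in the range appear as rows;
    ``read_index`` maps rows back to :class:`ObservationSet` read indices.
    """
    a, b = obs.site_slice(site_lo, site_hi)
    if a == b:
        return LikelihoodMatrix(window, np.empty(0, dtype=np.int64),
                                np.empty((0, genotypes.shape[0])))
    sites = obs.entry_site[a:b]
    reads = obs.entry_read[a:b]
    alle = obs.entry_allele[a:b]
    eps = obs.entry_eps[a:b]
    uniq, inv = np.unique(reads, return_inverse=True)
    log_mis = np.log(eps / 3.0)
    delta = np.log1p(-eps) - log_mis  # log(1-eps) - log(eps/3), always > 0
    g_cols = genotypes[:, sites].T.astype(np.float64)  # (n_entries, n_founders)
    alle_col = alle[:, None]
    match = np.where(alle_col == OBS_ALT, g_cols,
                     np.where(alle_col == OBS_REF, 1.0 - g_cols, 0.0))
    contrib = match * delta[:, None]
    contrib += log_mis[:, None]
    order = np.argsort(inv, kind="stable")
    inv_sorted = inv[order]
    starts = np.flatnonzero(np.r_[True, np.diff(inv_sorted) > 0])
    loglik = np.add.reduceat(contrib[order], starts, axis=0)
    return LikelihoodMatrix(window, uniq, loglik)


def data_loglik(loglik: np.ndarray, freqs: np.ndarray) -> float:
    """Total data log-likelihood sum_r log sum_h f_h P(r|h)."""
    m = loglik.max(axis=1, keepdims=True)
    return float(np.sum(np.log(np.exp(loglik - m) @ freqs)) + m.sum())


def em_frequencies(lik: LikelihoodMatrix, tol: float = 1e-6, max_iter: int = 500,
                   return_trajectory: bool = False):
    """Maximum-likelihood founder-haplotype frequencies for one window.

    Uniform initialisation; convergence when the largest frequency change in
    an iteration falls below ``tol``. Frequencies may reach 0 (no
    regularisation). A window with zero informative reads yields uniform
    frequencies flagged unconverged.
    """
    n_reads, n_h = lik.loglik.shape
    if n_reads == 0:
        logger.warning("window %s: no informative reads; returning uniform frequencies",
                       lik.window)
        wf = WindowFrequencies(lik.window, np.full(n_h, 1.0 / n_h), 0, False, 0)
        return (wf, []) if return_trajectory else wf
    m = lik.loglik.max(axis=1, keepdims=True)
    L = np.exp(lik.loglik - m)  # scaled likelihoods; row max == 1
    LT = np.ascontiguousarray(L.T)
    f = np.full(n_h, 1.0 / n_h)
    traj = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # f_new_h = f_h/n * sum_r L[r,h] / (L @ f)_r  (two BLAS matvecs)
        tot = L @ f
        f_new = f * (LT @ (1.0 / tot)) / n_reads
        if return_trajectory:
            traj.append(float(np.sum(np.log(tot)) + m.sum()))
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            converged = True
            break
    f = np.clip(f, 0.0, None)
    f /= f.sum()
    wf = WindowFrequencies(lik.window, f, n_reads, converged, it)
    return (wf, traj) if return_trajectory else wf


def infer_chromosome(sam_or_obs, table, plan, tol: float = 1e-6,
                     max_iter: int = 500) -> list:
    """Estimate founder-haplotype frequencies in every frequency window.

    ``sam_or_obs`` is a SAM/BAM path or a pre-extracted
    :class:`ObservationSet` (extraction is done once for the chromosome and
    shared across windows, so the enclosing likelihood-window chunking is a
    pure reuse of computation: per-window results are identical to computing
    each window's likelihoods directly).
    """
    if table.has_missing:
        raise ValueError("inference requires an imputed table (no MISSING calls)")
    obs = sam_or_obs if isinstance(sam_or_obs, ObservationSet) else \
        extract_observations(sam_or_obs, table)
    pos0 = table.positions - 1
    out = []
    for (start, end) in plan.freq_windows:
        site_lo = int(np.searchsorted(pos0, start, side="left"))
        site_hi = int(np.searchsorted(pos0, end, side="left"))
        lik = window_likelihoods(obs, table.genotypes, site_lo, site_hi,
                                 window=(start, end))
        out.append(em_frequencies(lik, tol=tol, max_iter=max_iter))
    return out
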