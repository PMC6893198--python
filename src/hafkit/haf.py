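"""Haplotype-derived allele frequencies (HAFs) and raw allele frequencies.

The HAF at a site is the frequency-weighted count of founder haplotypes
carrying the alternate allele: HAF = sum_h w_h * a_h, where w is the mean of
the haplotype-frequency vectors of every inference window overlapping the
site, a_h is 1 for ALT founders and 0 for REF founders, and founders with a
MISSING call contribute a fractional count equal to the alt fraction among
genotyped founders at the site. Fractional counts deliberately use the
original, unimputed table: imputation feeds haplotype inference, while the
HAF weighting honestly reflects genotype uncertainty.

Raw AFs, the per-site baseline, are the fraction of informative mapped reads
(those showing either the ref or the alt base) carrying the alternate allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hafkit.founders import SNPTable, MISSING, ALT
from hafkit.hapfreq import ObservationSet, OBS_REF, OBS_ALT, extract_observations

logger = logging.getLogger(__name__)


@dataclass
class AlleleFrequencyTrack:
    """Per-site estimated allele frequencies with per-site support.

    ``support`` is the number of overlapping inference windows (HAF) or the
    informative read depth (RAW). Sites without an estimate carry NaN.
    """

    chrom: str
    positions: np.ndarray
    est_freq: np.ndarray
    method: str  # "HAF" or "RAW"
    support: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom,
            "pos": self.positions,
            "freq": self.est_freq,
            "support": self.support,
        })

    def write(self, path, header_comments=()):
        with open(path, "w") as fh:
            for c in header_comments:
                fh.write(f"#{c}\n")
            fh.write(f"#method={self.method}\n")
            fh.write("chrom\tpos\tfreq\tsupport\n")
            self.to_dataframe().to_csv(fh, sep="\t", header=False, index=False,
                                       float_format="%.10g")

    @classmethod
    def read(cls, path) -> "AlleleFrequencyTrack":
        method = "HAF"
        with open(path) as fh:
            comments = []
            p = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    comments.append(line)
                    p = fh.tell()
                else:
                    break
            fh.seek(p)
            df = pd.read_csv(fh, sep="\t")
        for c in comments:
            if c.startswith("#method="):
                method = c.strip().split("=", 1)[1]
        return cls(str(df["chrom"].iloc[0]), df["pos"].to_numpy(),
                   df["freq"].to_numpy(dtype=float), method,
                   df["support"].to_numpy())


def site_haplotype_weights(pos: int, window_freqs: list) -> np.ndarray:
    """Mean haplotype-frequency vector over windows overlapping 1-based ``pos``.

    Raises if no window overlaps the site.
    """
    pos0 = pos - 1
    vecs = [wf.freqs for wf in window_freqs
            if wf.window[0] <= pos0 < wf.window[1]]
    if not vecs:
        raise ValueError(f"no inference window overlaps position {pos}")
    return np.mean(vecs, axis=0)


def haf_site(weights: np.ndarray, table: SNPTable, site: int) -> float:
    """HAF at one site from a founder weight vector (simplex).

    Uses the original table: MISSING founders get the fractional alt count.
    """
    col = table.genotypes[:, site]
    a = (col == ALT).astype(float)
    miss = col == MISSING
    if miss.any():
        genotyped = ~miss
        a[miss] = (col == ALT).sum() / genotyped.sum()
    return float(np.clip(np.dot(weights, a), 0.0, 1.0))


def haf_chromosome(window_freqs: list, table: SNPTable, sites=None,
                   fully_genotyped_only: bool = False) -> AlleleFrequencyTrack:
    """HAF track over the chromosome (vectorised over sites).

    ``sites`` optionally restricts to a subset of site indices;
    ``fully_genotyped_only`` further drops sites with any MISSING founder
    call, the restriction used when scoring accuracy against truth.
    Sites covered by no window are skipped (NaN) with a warning.
    """
    n_sites = table.n_sites
    idx = np.arange(n_sites) if sites is None else np.asarray(sites)
    if fully_genotyped_only:
        idx = idx[table.fully_genotyped_sites()[idx]]
    pos0 = table.positions - 1
    n_f = table.n_founders
    wsum = np.zeros((n_sites, n_f))
    wcount = np.zeros(n_sites, dtype=np.int64)
    for wf in window_freqs:
        a, b = wf.window
        lo = int(np.searchsorted(pos0, a, side="left"))
        hi = int(np.searchsorted(pos0, b, side="left"))
        wsum[lo:hi] += wf.freqs
        wcount[lo:hi] += 1
    covered = wcount[idx] > 0
    if not covered.all():
        logger.warning("%d sites covered by no inference window: skipped",
                       int((~covered).sum()))
    # founder allele matrix with fractional counts at MISSING calls
    g = table.genotypes[:, idx]
    a_mat = (g == ALT).astype(float)
    miss = g == MISSING
    if miss.any():
        frac = table.alt_fractions()[idx]
        a_mat[miss] = np.broadcast_to(frac, a_mat.shape)[miss]
    weights = np.full((idx.size, n_f), np.nan)
    weights[covered] = wsum[idx[covered]] / wcount[idx[covered], None]
    haf = np.clip(np.einsum("sf,fs->s", weights, a_mat), 0.0, 1.0)
    return AlleleFrequencyTrack(table.chrom, table.positions[idx], haf, "HAF",
                                wcount[idx])


def raw_af(sam_or_obs, table: SNPTable, sites=None) -> AlleleFrequencyTrack:
    """Raw allele frequencies: per-site ALT / (ALT + REF) base counts.

    Bases that are neither ref nor alt are discarded; zero-coverage sites are
    NaN (excluded from scoring). Counts come from merged template
    observations, so an overlapping mate pair contributes its consensus base
    once.
    """
    obs = sam_or_obs if isinstance(sam_or_obs, ObservationSet) else \
        extract_observations(sam_or_obs, table)
    n_sites = table.n_sites
    n_alt = np.bincount(obs.entry_site[obs.entry_allele == OBS_ALT], minlength=n_sites)
    n_ref = np.bincount(obs.entry_site[obs.entry_allele == OBS_REF], minlength=n_sites)
    depth = n_alt + n_ref
    with np.errstate(invalid="ignore"):
        freq = np.where(depth > 0, n_alt / np.maximum(depth, 1), np.nan)
    idx = np.arange(n_sites) if sites is None else np.asarray(sites)
    return AlleleFrequencyTrack(table.chrom, table.positions[idx], freq[idx],
                                "RAW", depth[idx])
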