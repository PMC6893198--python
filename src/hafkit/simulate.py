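"""Synthetic E+R data: founder panels, forward evolution, pools, and reads.

This module is the test harness for the whole pipeline. It generates a
synthetic founder panel (a stand-in for a sequenced inbred-line panel),
forward-simulates a randomly mating population with recombination and
selection on an additive trait, samples pooled individuals whose exact allele
frequencies are known from their breakpoint mosaics, and emits pre-aligned
paired-end reads in SAM format with a quality-aware error model.

Model summary
-------------
* Panel: per site the alternate-allele count k is drawn from a neutral
  site-frequency spectrum (P(k) proportional to 1/k) or uniform, and assigned
  to a random founder subset; missing calls are placed uniformly at random.
* Evolution: N diploids, non-overlapping generations. Founding individuals
  are homozygous copies of random founders. Each offspring draws two parents
  with probability proportional to fitness; each transmitted gamete receives
  Poisson(L*R) crossovers at uniform positions (or map-distributed). The
  trait is additive over the selected loci with per-genotype contributions
  0 / s / 2s plus Normal(0, Ve) environmental noise; fitness decays linearly
  with distance from the trait optimum: w = max(0, 1 - |optimum - T|).
* Reads: 150 bp paired ends from uniformly placed fragments of a uniformly
  chosen pooled chromosome, substitution errors at a fixed per-base rate with
  a lower base quality on error bases, emitted pre-aligned (full-match CIGAR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pysam

from hafkit.founders import SNPTable, ALT, MISSING

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# founder panel


@dataclass
class PanelSpec:
    """Parameters of a synthetic founder panel.

    snp_density defaults to ~12.3 SNPs/kb, the density of known segregating
    biallelic sites on a well-characterised Drosophila chromosome arm
    (283,437 sites over ~23 Mb).
    """

    n_founders: int = 99
    L: int = 5_000_000
    snp_density: float = 283_437 / 23e6
    af_spectrum: str = "neutral_1_over_i"
    missing_rate: float = 0.0
    seed: int = 0
    chrom: str = "chrSim"

    def __post_init__(self):
        if self.snp_density * self.L < 100:
            raise ValueError("panel too sparse: need snp_density * L >= 100")
        if not 0 <= self.missing_rate <= 0.15:
            raise ValueError("missing_rate must be in [0, 0.15]")
        if self.af_spectrum not in ("neutral_1_over_i", "uniform"):
            raise ValueError(f"unknown af_spectrum {self.af_spectrum!r}")


def generate_panel(spec: PanelSpec):
    """Synthesise a founder SNP table and matching reference sequence.

    Returns ``(table, ref_codes)`` where ``ref_codes`` is a uint8 array over
    {0:A, 1:C, 2:G, 3:T} of length L with the ref alleles embedded.
    """
    rng = np.random.default_rng(spec.seed)
    n_sites = int(round(spec.snp_density * spec.L))
    n_f = spec.n_founders
    positions = np.sort(rng.choice(spec.L, size=n_sites, replace=False)) + 1
    ref_codes = rng.integers(0, 4, size=spec.L, dtype=np.uint8)
    ref_site = ref_codes[positions - 1]
    alt_site = (ref_site + rng.integers(1, 4, size=n_sites, dtype=np.uint8)) % 4
    ks = np.arange(1, n_f)
    if spec.af_spectrum == "neutral_1_over_i":
        p = (1.0 / ks) / np.sum(1.0 / ks)
    else:
        p = np.full(ks.size, 1.0 / ks.size)
    k = rng.choice(ks, size=n_sites, p=p)
    perm = rng.random((n_sites, n_f)).argsort(axis=1)
    is_alt_sorted = np.arange(n_f)[None, :] < k[:, None]
    geno = np.zeros((n_sites, n_f), dtype=np.int8)
    geno[np.arange(n_sites)[:, None], perm] = is_alt_sorted
    geno = geno.T  # founders x sites
    if spec.missing_rate > 0:
        miss = rng.random(geno.shape) < spec.missing_rate
        all_miss = miss.all(axis=0)
        if all_miss.any():  # keep >= 1 genotyped founder per site
            miss[rng.integers(0, n_f, size=int(all_miss.sum())),
                 np.nonzero(all_miss)[0]] = False
        geno[miss] = MISSING
    alphabet = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    table = SNPTable(spec.chrom, positions, alphabet[ref_site],
                     alphabet[alt_site], geno,
                     [f"F{i:03d}" for i in range(n_f)])
    return table, ref_codes


def write_fasta(ref_codes: np.ndarray, path, chrom: str, width: int = 70):
    seq = _BASES[ref_codes].tobytes().decode()
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def read_fasta(path):
    """Load the first record of a FASTA as (name, uint8 codes)."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    raw = np.frombuffer(str(rec.seq).upper().encode(), dtype=np.uint8)
    codes = np.zeros(raw.size, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    return rec.id, codes


# ---------------------------------------------------------------------------
# recombinant chromosomes and forward simulation


class RecombinantChromosome:
    """Breakpoint mosaic of founder IDs tiling [0, L).

    ``starts`` holds segment start coordinates (starts[0] == 0); segment i
    spans [starts[i], starts[i+1]) and carries ``founders[i]``.
    """

    __slots__ = ("starts", "founders", "_sel_cache")

    def __init__(self, starts, founders):
        self.starts = np.asarray(starts, dtype=np.float64)
        self.founders = np.asarray(founders, dtype=np.int32)
        self._sel_cache = None

    @classmethod
    def pure(cls, founder: int) -> "RecombinantChromosome":
        return cls(np.zeros(1), np.array([founder], dtype=np.int32))

    @property
    def n_segments(self) -> int:
        return self.founders.size

    def founder_at(self, pos) -> int:
        i = np.searchsorted(self.starts, pos, side="right") - 1
        return int(self.founders[i])

    def founders_at(self, positions) -> np.ndarray:
        idx = np.searchsorted(self.starts, positions, side="right") - 1
        return self.founders[idx]

    def segment_lengths(self, L: int) -> np.ndarray:
        ends = np.append(self.starts[1:], float(L))
        return ends - self.starts


@dataclass
class SelectionRegime:
    """Selected loci feeding an additive trait.

    Per-locus genotype contributions are 0, s, 2s for ref-homozygote,
    heterozygote, alt-homozygote; trait = sum + Normal(0, Ve); fitness
    w = max(0, 1 - |optimum - T|).
    """

    sites: np.ndarray  # SNP-table site indices
    s: float = 0.025
    Ve: float = 0.01
    optimum: float = 1.0

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=np.int64)
        if np.unique(self.sites).size != self.sites.size:
            raise ValueError("selected sites must be distinct")


class RecombinationMap:
    """Piecewise-constant crossover rate: list of (start, end, rate per bp)."""

    def __init__(self, intervals):
        self.starts = np.array([a for a, _, _ in intervals], dtype=float)
        self.ends = np.array([b for _, b, _ in intervals], dtype=float)
        self.rates = np.array([r for _, _, r in intervals], dtype=float)
        self.weights = self.rates * (self.ends - self.starts)
        self.total = float(self.weights.sum())

    def sample_positions(self, k: int, rng) -> np.ndarray:
        seg = rng.choice(self.weights.size, size=k, p=self.weights / self.total)
        u = rng.random(k)
        return self.starts[seg] + u * (self.ends[seg] - self.starts[seg])


def _gamete(c1, c2, L, expected_xo, rng, recomb_map=None):
    k = rng.poisson(expected_xo)
    if k == 0:
        return c1 if rng.random() < 0.5 else c2
    if recomb_map is not None:
        xs = np.sort(recomb_map.sample_positions(k, rng))
    else:
        xs = np.sort(rng.random(k) * L)
    bounds = np.concatenate(([0.0], xs, [float(L)]))
    cur = int(rng.integers(2))
    srcs = (c1, c2)
    starts_out, founders_out = [], []
    for i in range(bounds.size - 1):
        a, b = bounds[i], bounds[i + 1]
        if a >= b:
            continue
        c = srcs[cur]
        cur ^= 1
        i0 = np.searchsorted(c.starts, a, side="right") - 1
        i1 = np.searchsorted(c.starts, b, side="left")
        ss = c.starts[i0:i1].copy()
        ss[0] = a
        starts_out.append(ss)
        founders_out.append(c.founders[i0:i1])
    starts = np.concatenate(starts_out)
    founders = np.concatenate(founders_out)
    keep = np.r_[True, founders[1:] != founders[:-1]]  # merge same-founder runs
    return RecombinantChromosome(starts[keep], founders[keep])


def _sel_alleles(chrom: RecombinantChromosome, sel_pos, alt_by_founder) -> np.ndarray:
    if chrom._sel_cache is None:
        if chrom.n_segments == 1:
            chrom._sel_cache = alt_by_founder[chrom.founders[0]]
        else:
            chrom._sel_cache = alt_by_founder[chrom.founders_at(sel_pos)]
    return chrom._sel_cache


@dataclass
class Population:
    """One generation: N diploids as pairs of recombinant chromosomes."""

    generation: int
    individuals: list  # list of (RecombinantChromosome, RecombinantChromosome)
    L: int

    @property
    def n(self) -> int:
        return len(self.individuals)

    def chromosomes(self) -> list:
        return [c for pair in self.individuals for c in pair]

    def allele_frequency(self, site_pos0, alt_by_founder_site) -> float:
        """Population frequency of the alternate allele at one 0-based position."""
        cnt = sum(int(alt_by_founder_site[c.founder_at(site_pos0)])
                  for c in self.chromosomes())
        return cnt / (2 * self.n)


def forward_simulate(table: SNPTable, regime: SelectionRegime, L: int, G: int,
                     N: int = 1000, recomb_rate: float = 2.4e-8,
                     recomb_map: RecombinationMap | None = None,
                     seed: int = 0, yield_every: int | None = None):
    """Evolve N diploids for G non-overlapping generations; return the final
    :class:`Population` (or a list of snapshots when ``yield_every`` is set).

    Founding individuals are homozygous copies of uniformly drawn founders.
    The conservative convention of applying the full (female) crossover rate
    to every gamete is used, so recombination accrues faster than in systems
    where one sex does not recombine.
    """
    rng = np.random.default_rng(seed)
    n_f = table.n_founders
    if np.any(table.genotypes[:, regime.sites] == MISSING):
        raise ValueError("selected sites must be genotyped in all founders "
                         "(use an imputed table)")
    alt_by_founder = (table.genotypes[:, regime.sites] == ALT).astype(np.int8)
    sel_pos = table.positions[regime.sites] - 1.0
    expected_xo = recomb_map.total if recomb_map is not None else L * recomb_rate
    pop = [
        (RecombinantChromosome.pure(f), RecombinantChromosome.pure(f))
        for f in rng.integers(0, n_f, size=N)
    ]
    snapshots = [Population(0, pop, L)] if yield_every else None
    for g in range(1, G + 1):
        counts = np.array([
            _sel_alleles(c1, sel_pos, alt_by_founder).sum(dtype=np.int64)
            + _sel_alleles(c2, sel_pos, alt_by_founder).sum(dtype=np.int64)
            for c1, c2 in pop
        ])
        trait = regime.s * counts + rng.normal(0.0, math.sqrt(regime.Ve), size=N)
        fitness = np.maximum(0.0, 1.0 - np.abs(regime.optimum - trait))
        total_w = fitness.sum()
        if total_w == 0:
            raise RuntimeError(
                f"generation {g}: every individual has zero fitness (seed={seed})")
        p = fitness / total_w
        parents = rng.choice(N, size=(N, 2), p=p)  # selfing allowed
        pop = [
            (_gamete(*pop[pa], L, expected_xo, rng, recomb_map),
             _gamete(*pop[pb], L, expected_xo, rng, recomb_map))
            for pa, pb in parents
        ]
        if yield_every and (g % yield_every == 0 or g == G):
            snapshots.append(Population(g, pop, L))
    return snapshots if yield_every else Population(G, pop, L)


# ---------------------------------------------------------------------------
# pool sampling


@dataclass
class PoolSample:
    """Sampled chromosomes with exact per-site true allele frequencies."""

    chromosomes: list
    true_af: np.ndarray
    generation: int
    L: int

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def write_truth(self, path, table: SNPTable, header_comments=()):
        with open(path, "w") as fh:
            for c in header_comments:
                fh.write(f"#{c}\n")
            fh.write("chrom\tpos\ttrue_af\n")
            for p, a in zip(table.positions, self.true_af):
                fh.write(f"{table.chrom}\t{p}\t{a:.10g}\n")

    def write_breakpoints(self, path, chrom: str):
        with open(path, "w") as fh:
            fh.write("chromosome\tsegment_start\tsegment_end\tfounder\n")
            for i, c in enumerate(self.chromosomes):
                ends = np.append(c.starts[1:], float(self.L))
                for s, e, f in zip(c.starts, ends, c.founders):
                    fh.write(f"{i}\t{s:.0f}\t{e:.0f}\t{f}\n")


def true_allele_frequencies(chromosomes, table: SNPTable, L: int) -> np.ndarray:
    """Exact pooled alt-allele frequency per SNP site from segment mosaics.

    Uses the (imputed) table the reads are simulated from, so truth and reads
    share the same founder alleles.
    """
    pos0 = table.positions - 1
    alt = (table.genotypes == ALT).astype(np.int32)
    counts = np.zeros(table.n_sites, dtype=np.int64)
    for c in chromosomes:
        ends = np.append(c.starts[1:], float(L))
        for s, e, f in zip(c.starts, ends, c.founders):
            lo = np.searchsorted(pos0, s, side="left")
            hi = np.searchsorted(pos0, e, side="left")
            counts[lo:hi] += alt[f, lo:hi]
    return counts / len(chromosomes)


def sample_pool(population: Population, table: SNPTable, n_individuals: int = 100,
                seed: int = 0) -> PoolSample:
    """Sample n individuals without replacement; truth is computed exactly."""
    if population.n < n_individuals:
        raise ValueError(f"population of {population.n} < pool size {n_individuals}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(population.n, size=n_individuals, replace=False)
    chroms = [c for i in idx for c in population.individuals[i]]
    af = true_allele_frequencies(chroms, table, population.L)
    return PoolSample(chroms, af, population.generation, population.L)


def unrecombined_pool(table: SNPTable, L: int) -> PoolSample:
    """Equal-proportion pool of one unrecombined chromosome per founder."""
    chroms = [RecombinantChromosome.pure(f) for f in range(table.n_founders)]
    af = true_allele_frequencies(chroms, table, L)
    return PoolSample(chroms, af, 0, L)


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadSimSpec:
    """Paired-end read simulation parameters (quality-aware error model)."""

    coverage: float = 5.0
    read_length: int = 150
    paired: bool = True
    insert_min: int = 450
    insert_max: int = 500
    error_rate: float = 0.002
    qual_correct: int = 30
    qual_error: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min > insert_max")
        if self.paired and self.insert_min < 2 * self.read_length:
            raise ValueError("insert size must fit two non-overlapping mates")


def simulate_reads(pool: PoolSample, ref_codes: np.ndarray, table: SNPTable,
                   spec: ReadSimSpec, out_sam, chrom: str | None = None):
    """Emit pre-aligned paired-end reads from the pooled chromosomes as SAM.

    Fragments are placed uniformly on uniformly chosen pooled chromosomes;
    bases are copied from the mosaic haplotype (reference with the founder's
    alt alleles substituted), then flipped to a uniformly chosen different
    base with probability ``error_rate``. Correct bases carry
    ``qual_correct``, error bases the lower ``qual_error``. Reads are written
    with full-match CIGARs at their true positions (pre-aligned; no aligner).
    Returns the number of templates written.
    """
    if table.has_missing:
        raise ValueError("read simulation requires an imputed table")
    rng = np.random.default_rng(spec.seed)
    L = pool.L
    rl = spec.read_length
    chrom = chrom or table.chrom
    pos0 = table.positions - 1
    alt_code = np.zeros(table.n_sites, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        alt_code[table.alt_allele == chr(b)] = i
    is_alt = table.genotypes == ALT  # founders x sites
    if spec.paired:
        n_templates = math.ceil(spec.coverage * L / (2 * rl))
        inserts = rng.integers(spec.insert_min, spec.insert_max + 1,
                               size=n_templates)
        inserts = np.minimum(inserts, L)
        frag_start = (rng.random(n_templates) * (L - inserts + 1)).astype(np.int64)
        m1 = frag_start
        m2 = frag_start + inserts - rl
        starts = np.empty(2 * n_templates, dtype=np.int64)
        starts[0::2] = m1
        starts[1::2] = m2
        tmpl_of_mate = np.repeat(np.arange(n_templates), 2)
    else:
        n_templates = math.ceil(spec.coverage * L / rl)
        starts = (rng.random(n_templates) * (L - rl + 1)).astype(np.int64)
        inserts = None
        tmpl_of_mate = np.arange(n_templates)
    chrom_idx = rng.integers(0, pool.n_chromosomes, size=n_templates)

    n_mates = starts.size
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": int(L)}],
        "PG": [{"ID": "hafkit", "PN": "hafkit simulate reads",
                "CL": f"coverage={spec.coverage} error_rate={spec.error_rate} "
                      f"seed={spec.seed}"}],
    })
    out = pysam.AlignmentFile(str(out_sam), "w", header=header)
    chunk = 20_000
    qual_ok = np.full(rl, spec.qual_correct, dtype=np.uint8)
    for c0 in range(0, n_mates, chunk):
        c1 = min(c0 + chunk, n_mates)
        sl = slice(c0, c1)
        s_arr = starts[sl]
        cid = chrom_idx[tmpl_of_mate[sl]]
        mat = ref_codes[s_arr[:, None] + np.arange(rl)]
        # substitute founder alt alleles at covered SNP sites
        lo = np.searchsorted(pos0, s_arr, side="left")
        hi = np.searchsorted(pos0, s_arr + rl, side="left")
        for i in range(c1 - c0):
            if lo[i] == hi[i]:
                continue
            ch = pool.chromosomes[cid[i]]
            sites = np.arange(lo[i], hi[i])
            if ch.n_segments == 1:
                fs = np.repeat(ch.founders[0], sites.size)
            else:
                fs = ch.founders_at(pos0[sites])
            sub = is_alt[fs, sites]
            if sub.any():
                mat[i, pos0[sites[sub]] - s_arr[i]] = alt_code[sites[sub]]
        # sequencing errors: flip to a uniform different base, lower quality
        quals = np.broadcast_to(qual_ok, mat.shape).copy()
        if spec.error_rate > 0:
            n_err = rng.binomial(rl, spec.error_rate, size=c1 - c0)
            for i in np.nonzero(n_err)[0]:
                epos = rng.choice(rl, size=n_err[i], replace=False)
                shift = rng.integers(1, 4, size=n_err[i]).astype(np.uint8)
                mat[i, epos] = (mat[i, epos] + shift) % 4
                quals[i, epos] = spec.qual_error
        _write_mates(out, header, chrom, mat, quals, s_arr, sl, tmpl_of_mate,
                     starts, inserts, spec, rng)
    out.close()
    return n_templates


def _write_mates(out, header, chrom, mat, quals, s_arr, sl, tmpl_of_mate,
                 starts, inserts, spec, rng):
    rl = spec.read_length
    seq_bytes = _BASES[mat]
    for i in range(mat.shape[0]):
        mate_idx = sl.start + i
        tmpl = tmpl_of_mate[mate_idx]
        a = pysam.AlignedSegment(header)
        a.query_name = f"sim{tmpl}"
        a.reference_id = 0
        a.reference_start = int(s_arr[i])
        a.mapping_quality = 60
        a.cigarstring = f"{rl}M"
        a.query_sequence = seq_bytes[i].tobytes().decode()
        a.query_qualities = quals[i].tolist()
        if spec.paired:
            first = mate_idx % 2 == 0
            flag = 0x1 | 0x2
            flag |= 0x40 if first else 0x80
            flag |= 0x20 if first else 0x10  # mate2 on the reverse strand
            a.flag = flag
            a.next_reference_id = 0
            mate_start = starts[mate_idx + 1] if first else starts[mate_idx - 1]
            a.next_reference_start = int(mate_start)
            tlen = int(inserts[tmpl])
            a.template_length = tlen if first else -tlen
        else:
            a.flag = 0
        out.write(a)
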