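"""Founder genotype panel: loading, validation, imputation.

The haplotype reference panel is a founder-by-site matrix of biallelic SNP
genotypes. Inbred founder lines are effectively haploid, so each call is REF,
ALT, or MISSING; residual heterozygosity is treated as MISSING by default.
Missing calls bias haplotype-frequency inference, so the panel is imputed
before inference — but downstream HAF weighting uses the *original* table,
giving missing founders a fractional allele count instead of a hard call.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

REF = 0
ALT = 1
MISSING = -1

_NUCS = frozenset("ACGT")


@dataclass
class SNPTable:
    """Founder-by-site biallelic genotype matrix.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    positions : ndarray of int
        1-based coordinates, strictly increasing.
    ref_allele, alt_allele : ndarray of single-character str
        Per-site alleles, ``ref != alt``.
    genotypes : ndarray of int8, shape (n_founders, n_sites)
        Entries in {0 (REF), 1 (ALT), -1 (MISSING)}.
    founder_ids : list of str
        Ordered founder labels, one per matrix row.
    """

    chrom: str
    positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    genotypes: np.ndarray
    founder_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype="U1")
        self.alt_allele = np.asarray(self.alt_allele, dtype="U1")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.founder_ids = list(self.founder_ids)
        self._validate()

    def _validate(self):
        if self.positions.ndim != 1:
            raise ValueError("positions must be 1-D")
        n_sites = self.positions.size
        if n_sites and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.genotypes.shape != (len(self.founder_ids), n_sites):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} != "
                f"({len(self.founder_ids)} founders, {n_sites} sites)"
            )
        if np.any(self.ref_allele == self.alt_allele):
            raise ValueError("ref and alt allele identical at some site")
        if n_sites and np.any((self.genotypes == MISSING).all(axis=0)):
            raise ValueError("site with no genotyped founder")

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)

    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def has_missing(self) -> bool:
        return bool(np.any(self.genotypes == MISSING))

    def alt_fractions(self) -> np.ndarray:
        """Per-site fraction of *genotyped* founders carrying the alternate allele."""
        genotyped = self.genotypes != MISSING
        n_alt = (self.genotypes == ALT).sum(axis=0)
        return n_alt / genotyped.sum(axis=0)

    def fully_genotyped_sites(self) -> np.ndarray:
        """Boolean mask of sites where every founder has a called genotype."""
        return ~(self.genotypes == MISSING).any(axis=0)

    def write(self, path, header_comments=()):
        """Write the text SNP-table format (one row per site).

        Columns: chrom, pos (1-based), ref, alt, genotype string with one
        character per founder (0=REF, 1=ALT, .=MISSING). Lines starting with
        ``#`` are comments; the founder-id header is required for round-trips.
        """
        chars = np.full(self.genotypes.shape, ".", dtype="U1")
        chars[self.genotypes == REF] = "0"
        chars[self.genotypes == ALT] = "1"
        with open(path, "w") as fh:
            for c in header_comments:
                fh.write(f"#{c}\n")
            fh.write("#founders=" + ",".join(self.founder_ids) + "\n")
            for i in range(self.n_sites):
                fh.write(
                    f"{self.chrom}\t{self.positions[i]}\t{self.ref_allele[i]}\t"
                    f"{self.alt_allele[i]}\t{''.join(chars[:, i])}\n"
                )

    @classmethod
    def read(cls, path) -> "SNPTable":
        founder_ids = None
        chroms, pos, ref, alt, geno = [], [], [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("#founders="):
                        founder_ids = line[len("#founders="):].split(",")
                    continue
                f = line.split("\t")
                chroms.append(f[0])
                pos.append(int(f[1]))
                ref.append(f[2])
                alt.append(f[3])
                geno.append(f[4])
        if founder_ids is None:
            raise ValueError(f"{path}: missing '#founders=' header line")
        if not pos:
            raise ValueError(f"{path}: empty SNP table")
        if len(set(chroms)) > 1:
            raise ValueError("SNP table spans multiple chromosomes")
        g = np.frombuffer("".join(geno).encode(), dtype="S1").reshape(len(pos), -1)
        mat = np.full(g.shape, MISSING, dtype=np.int8)
        mat[g == b"0"] = REF
        mat[g == b"1"] = ALT
        return cls(chroms[0], np.array(pos), np.array(ref), np.array(alt), mat.T, founder_ids)


@dataclass
class ImputedSNPTable(SNPTable):
    """SNPTable with every MISSING call filled in.

    ``imputed_mask`` is True exactly where the source table was MISSING.
    """

    imputed_mask: np.ndarray = None

    def _validate(self):
        super()._validate()
        if np.any(self.genotypes == MISSING):
            raise ValueError("imputed table contains MISSING calls")
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros(self.genotypes.shape, dtype=bool)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        if self.imputed_mask.shape != self.genotypes.shape:
            raise ValueError("imputed_mask shape mismatch")


def alt_fraction(table: SNPTable, site: int) -> float:
    """Fraction of genotyped founders with the alternate allele at one site.

    MISSING founders are ignored; raises if no founder is genotyped.
    """
    col = table.genotypes[:, site]
    genotyped = col != MISSING
    n = int(genotyped.sum())
    if n == 0:
        raise ValueError(f"site index {site}: all founders missing")
    return float((col == ALT).sum() / n)


def vcf_to_snptable(vcf_path, het_policy: str = "missing", seed: int = 0) -> SNPTable:
    """Convert a founder VCF (one sample per founder line) to a SNPTable.

    Multiallelic and non-SNP records are skipped; heterozygous calls become
    MISSING under the default policy (``het_policy="random"`` instead picks one
    allele at random — useful for experiments, not the recommended workflow).
    Sites monomorphic across genotyped founders are dropped, as are sites with
    no genotyped founder at all.
    """
    from cyvcf2 import VCF

    if het_policy not in ("missing", "random"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    rng = np.random.default_rng(seed)
    try:
        vcf = VCF(vcf_path)
    except Exception as e:  # cyvcf2 raises bare OSError on malformed input
        raise ValueError(f"cannot parse VCF {vcf_path}: {e}") from e
    founder_ids = list(vcf.samples)
    chroms, pos, ref, alt, cols = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        if v.REF not in _NUCS or v.ALT[0] not in _NUCS:
            continue
        col = np.full(len(founder_ids), MISSING, dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if not alleles:
                continue
            if all(a == 0 for a in alleles):
                col[i] = REF
            elif all(a == 1 for a in alleles):
                col[i] = ALT
            elif het_policy == "random":
                col[i] = ALT if rng.random() < 0.5 else REF
            # het under "missing" policy: leave MISSING
        called = col[col != MISSING]
        if called.size == 0 or np.all(called == called[0]):
            continue  # uncalled or monomorphic: no haplotype information
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        cols.append(col)
    if not pos:
        raise ValueError(f"{vcf_path}: no segregating biallelic SNPs found")
    if len(set(chroms)) > 1:
        raise ValueError("VCF spans multiple chromosomes; split per chromosome first")
    return SNPTable(
        chroms[0], np.array(pos), np.array(ref), np.array(alt),
        np.stack(cols, axis=1), founder_ids,
    )


def _major_allele(col: np.ndarray) -> int:
    """More common allele among genotyped founders; ties favour REF."""
    n_alt = int((col == ALT).sum())
    n_ref = int((col == REF).sum())
    return ALT if n_alt > n_ref else REF


def impute(table: SNPTable, method: str = "nearest_neighbor", k: int = 20) -> ImputedSNPTable:
    """Fill every MISSING call in the panel.

    nearest_neighbor copies the allele of the founder with fewest mismatches
    to the target founder at its k nearest genotyped flanking sites (the local
    haplotype-similarity signal that read-to-haplotype assignment itself
    exploits); if the best-matching founders disagree at the site the major
    allele is used. major_allele fills with the more common allele among
    genotyped founders (ties -> REF).
    """
    if method not in ("nearest_neighbor", "major_allele"):
        raise ValueError(f"unknown imputation method {method!r}")
    g = table.genotypes.copy()
    mask = table.genotypes == MISSING
    if method == "major_allele" or table.n_founders < 2:
        for f, s in zip(*np.nonzero(mask)):
            g[f, s] = _major_allele(table.genotypes[:, s])
    else:
        geno = table.genotypes
        for f in range(table.n_founders):
            miss_sites = np.nonzero(mask[f])[0]
            if miss_sites.size == 0:
                continue
            called_sites = np.nonzero(~mask[f])[0]
            if called_sites.size == 0:
                for s in miss_sites:
                    g[f, s] = _major_allele(geno[:, s])
                continue
            for s in miss_sites:
                g[f, s] = _impute_one(geno, f, s, called_sites, k)
    return ImputedSNPTable(
        table.chrom, table.positions.copy(), table.ref_allele.copy(),
        table.alt_allele.copy(), g, list(table.founder_ids), imputed_mask=mask,
    )


def _impute_one(geno, f, s, called_sites, k):
    # k nearest flanking sites where founder f is genotyped (index distance)
    j = np.searchsorted(called_sites, s)
    lo = max(0, j - k)
    flank = called_sites[lo:j + k]
    if flank.size > k:
        order = np.argsort(np.abs(flank - s), kind="stable")[:k]
        flank = flank[order]
    target = geno[f, flank]
    cand = geno[:, flank]
    comparable = cand != MISSING
    mismatches = ((cand != target[None, :]) & comparable).sum(axis=1)
    mismatches[f] = np.iinfo(mismatches.dtype).max
    called_at_s = geno[:, s] != MISSING
    mismatches[~called_at_s] = np.iinfo(mismatches.dtype).max
    if not called_at_s.any():
        return _major_allele(geno[:, s])
    best = np.nonzero(mismatches == mismatches.min())[0]
    alleles = geno[best, s]
    if np.all(alleles == alleles[0]):
        return int(alleles[0])
    return _major_allele(geno[:, s])
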