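# Methods

This note documents the models implemented in hafkit, the parameters that
matter, the numerical choices, and what the built-in synthetic data does and
does not capture about real experiments.

## Founder panel and imputation

The haplotype reference panel is a founder × site matrix over {REF, ALT,
MISSING} at biallelic SNPs with strictly increasing 1-based positions
(`hafkit.founders.SNPTable`). Inbred founder lines are treated as haploid:
heterozygous VCF calls are residual heterozygosity and become MISSING under
the default policy (a `het_policy="random"` option exists for
experimentation). Sites monomorphic across genotyped founders carry no
haplotype information and are dropped at VCF conversion; sites where *every*
founder is missing are rejected.

Missing calls bias haplotype-frequency inference, so the panel is imputed
before inference. The default imputer fills a missing call from the founder
with the fewest mismatches at the k = 20 nearest sites where the target
founder is genotyped (ties broken by the site's major allele) — the same
local-haplotype-similarity signal that read-to-haplotype assignment exploits.
A `major_allele` method (per-site majority, ties → REF) is the fallback.
Imputation is idempotent, and on a panel where every founder has an exact
duplicate it recovers masked calls exactly (both tested).

Deliberate asymmetry: *inference* uses the imputed table, but HAF weighting
uses the **original** table — a founder whose call is missing at a site
contributes a fractional allele count equal to the alternate-allele fraction
among genotyped founders, honestly reflecting genotype uncertainty instead of
trusting the imputed call.

## Window geometry

Haplotype frequencies are estimated assuming no recombination breakpoint
inside a window. Unrecombined fragment lengths after G generations at
recombination rate R (crossovers/bp/generation, the female rate applied to
every gamete as a conservative convention) on a chromosome of length L are
modelled as Exponential with rate

    λ = (L·R·G + 1) / L    [per bp]

(the +1/L accounts for chromosome ends bounding every fragment). The window
size is the q-th quantile, −ln(1−q)/λ, rounded to the nearest bp, clamped to
[1 kb, L]; q defaults to 0.18, i.e. 18% of fragments are expected to be
shorter than the window. Both q and a fixed override size are exposed.

Frequency windows tile [0, L) at a step of 10% of the window size, so
interior positions fall in exactly 10 windows (tested exhaustively); terminal
windows are clipped, never dropped, so ends stay covered by ≥1 window.
Likelihood windows are 10× the frequency-window size with a step of half
their size; in this implementation they are purely an organisational unit —
read observations are extracted once per chromosome and shared, so per-window
results are identical to computing each window directly (tested).

Coordinates: windows are 0-based half-open; SNP positions are 1-based (VCF
convention); conversion happens at module boundaries.

## Read likelihoods and EM

A read observation is the set of SNP sites a read covers with, per site, the
observed allele (REF/ALT/OTHER) and the base-error probability
ε = 10^(−Q/10) (capped at 0.75). Paired mates merge into one observation per
template; where mates disagree at a site the higher-quality base wins. Reads
flagged unmapped/secondary/supplementary/duplicate are skipped; extraction is
CIGAR-aware (a deleted site is simply not observed). Only SNP sites enter the
likelihood — monomorphic positions contribute equally to every founder and
cancel:

    log P(r | h) = Σ_sites log(1−ε)  if the observed allele equals h's,
                   Σ_sites log(ε/3)  otherwise (OTHER mismatches everyone).

Window frequencies are the ML mixture weights, fitted by EM with uniform
initialisation, convergence when the largest per-iteration frequency change
drops below 1e-6, a 500-iteration cap, and no regularisation (frequencies may
reach 0). Likelihoods are exponentiated once (row-max scaled) and each
iteration is two matrix–vector products; the data log-likelihood is
non-decreasing per iteration (asserted in tests) and the solution matches a
dense simplex grid search on small problems (tested at 1e-3 resolution). On a
representative benchmark window the EM error equals the empirical Cramér–Rao
bound, i.e. the estimator is statistically efficient. Windows with zero
informative reads return uniform frequencies flagged unconverged.

## HAF and raw AF

Per site, the founder weight vector is the unweighted arithmetic mean of the
frequency vectors of all overlapping windows (10 for interior sites; the
per-site window count is reported so edge sites are identifiable), and
HAF = Σ_h w_h·a_h with the fractional-count rule above. HAF is linear in the
weights, lies in [0, 1] (clipped against float round-off), and with exact
window frequencies equal to the pool's founder proportions it reproduces the
true pooled frequency exactly at fully genotyped sites (tested). Sites
covered by no window are NaN and excluded from scoring, with the count
reported. Raw AFs are ALT/(ALT+REF) base counts from the same merged
template observations — with the default 450–500 bp inserts mates never
overlap, so this equals per-read counting; zero-coverage sites are NaN.

## Effective coverage

For estimates p_est against truth p_true over n sites,

    RMSE = sqrt(Σ(p_est − p_true)²/n),
    C_eff = Σ p_true(1 − p_true) / Σ(p_est − p_true)²

— the binomial-sampling depth whose expected RMSE matches the observed one.
Binomially sampled frequencies at depth C score C_eff ≈ C regardless of the
underlying frequency spectrum (both tested). Sites lacking an estimate are
excluded pairwise with the exclusion count reported; fixed-truth sites
(p_true ∈ {0,1}) contribute only error by default, with an opt-in exclusion
flag. The metric covers read-sampling error only; sampling of individuals
from the population is a separate, unaffected error source and out of scope.

## Synthetic data

The generator is the package's study-condition harness, not a fixture.

**Panel.** n founders (default 99) on L bp (default 5 Mb) at a SNP density
of 283,437 sites / 23 Mb ≈ 12.3/kb — the density of known segregating
biallelic sites on a well-characterised Drosophila chromosome arm. Per site
the alternate-allele count k follows a neutral spectrum (P(k) ∝ 1/k,
k = 1..n−1; a uniform option exists) over a random founder subset; sites are
mutually independent. Missing calls are placed uniformly at random at a
configurable rate (≤15%), always leaving ≥1 genotyped founder per site. The
reference sequence is random with the ref alleles embedded.

**Evolution.** N = 1000 diploids, non-overlapping generations, founded as
homozygous copies of uniformly drawn founders. Each offspring draws two
parents (selfing allowed) with probability ∝ fitness; each gamete receives
Poisson(L·R) crossovers at uniform positions (a piecewise-constant map is
accepted). The trait is additive over the selected loci with genotype
contributions 0/s/2s plus Normal(0, Ve = 0.01) noise; fitness
w = max(0, 1 − |1 − T|) decays linearly from the optimum 1. Defaults
s = 0.025, 5 selected loci, R = 2.4e-8/bp. Neutral trajectories are
martingales and strong selection raises selected-allele frequencies (both
tested). Chromosomes are breakpoint mosaics of founder IDs; adjacent
same-founder segments merge, so a crossover joining identical founder copies
is invisible — see limitations.

**Pools and truth.** Pools sample individuals without replacement (default
100 diploids, or one unrecombined chromosome per founder for the simplest
scenario); true allele frequencies are computed exactly from the segment
mosaics and the imputed founder genotypes the reads are built from, and are
multiples of 1/(2·n_individuals).

**Reads.** 150 bp paired ends on 450–500 bp fragments placed uniformly on
uniformly chosen pooled chromosomes, emitted pre-aligned (full-match CIGAR,
true positions, no aligner). Substitution errors hit each base with
probability 0.002, flip to a uniformly chosen different base, and carry
quality Q10; correct bases carry Q30. Template count = ⌈coverage·L/300⌉.
Observed error rate and mean depth match their targets (tested).

## Effective-coverage model

log10(EC) = a·log10(Rwin) + b·log10(1+M) + c, with Rwin the mean number of
templates overlapping ≥1 SNP site per frequency window and **M in percent
(0–100)** — the 1+M offset makes the units load-bearing. The model is linear
in its coefficients, so it is fitted by ordinary least squares in log space
(no iterative solver needed); the fit demands ≥3 observations and ≥2 distinct
values of each covariate, naming the degenerate covariate otherwise.
Noise-free data round-trips the coefficients to 1e-8, and a fit on a small
simulation grid predicts a held-out cell within |mean log10 residual| < 0.2
(both tested). A `recommend` command tabulates predicted EC over a
generation × coverage grid for experimental design.

## Benchmark scale and observed accuracy

The standard benchmark (tests and `scripts/acceptance.py`) uses 99 founders
on 5 Mb at 12.3 SNPs/kb — a deliberate single-CPU desk scale. Measured
effective coverages: ~1400x for 5x reads with 1000 kb windows and ~300x for
1x/1000 kb and 10x/100 kb on the unrecombined equal pool, and ~250–430x for
5x reads at generation 50 with adaptive (~142 kb) windows.

What passing these does and does not show about real data: the synthetic
panel has **independent sites**, i.e. no linkage disequilibrium between
founder columns. Real inbred panels share long haplotype tracts, and EM
confusion between locally identical founders is HAF-neutral (the confused
founders carry the same alleles), so HAF accuracy on real panels at matched
Rwin can exceed the independent-sites benchmark — in a side experiment, a
crude 20-haplotype block panel raised EC by ~30% at identical read supply.
The benchmark is therefore a conservative floor in this respect, while
lacking real-data error sources (mapping error, index hopping, uneven
pooling, founder-genotype mistakes) that push the other way.

## Known limitations

* The exponential fragment-length model slightly overstates visible
  breakpoint density: gamete crossovers between identical homozygous
  chromosomes (all of generation 1, and IBD pairs later) produce no founder
  switch. The distributional fit holds in the many-founders, G ≪ N regime
  and is tested there, pooling replicate populations because a single
  pedigree carries correlated breakpoint counts.
* No de novo mutation, no sex-specific recombination, no overlapping
  generations, no within-window recombination modelling, no per-site
  confidence intervals, no uneven-pooling correction.
* The mate-merge consensus counts an overlapping pair's base once in raw
  AFs; with default inserts mates cannot overlap, so this is only reachable
  with non-default read geometry.
* Imputation is a local-similarity method chosen for its alignment with the
  inference model; it is not tuned against any external imputation
  benchmark.
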