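"""Reference benchmark scenarios for HAF accuracy.

These functions run the full pipeline — synthetic panel, pooled-read
simulation, window planning, EM inference, HAF computation, scoring — under
two standard scenarios and return the resulting effective coverage:

* an equal-proportion pool of unrecombined founder chromosomes (the simplest
  case: one chromosome per founder, no recombination), scored at a fixed
  inference window size;
* a pool sampled after forward evolution with recombination and selection,
  scored with adaptive (fragment-length-quantile) windows.

The default problem size is a 5 Mb chromosome with 99 founders at
~12.3 SNPs/kb — a 5 Mb slice of the density of a well-characterised
Drosophila chromosome arm, sized to run on a single CPU in minutes.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from hafkit.founders import impute
from hafkit.windows import WindowParams, build_plan
from hafkit.hapfreq import extract_observations, infer_chromosome
from hafkit.haf import haf_chromosome
from hafkit.metrics import effective_coverage
from hafkit.ecmodel import compute_rwin
from hafkit.simulate import (PanelSpec, ReadSimSpec, SelectionRegime,
                             forward_simulate, generate_panel, sample_pool,
                             simulate_reads, unrecombined_pool)

DEFAULT_L = 5_000_000
DEFAULT_FOUNDERS = 99


def make_reference_panel(seed: int, L: int = DEFAULT_L,
                         n_founders: int = DEFAULT_FOUNDERS):
    """Standard benchmark panel: neutral spectrum, no missing calls."""
    spec = PanelSpec(n_founders=n_founders, L=L, seed=seed)
    table, ref_codes = generate_panel(spec)
    imputed = impute(table, "major_allele")  # identity: no missing calls
    return spec, table, imputed, ref_codes


def _score_pool(pool, spec, table, imputed, ref_codes, coverage, plan,
                seed, workdir=None):
    def run(d):
        sam = Path(d) / "pool.sam"
        simulate_reads(pool, ref_codes, imputed,
                       ReadSimSpec(coverage=coverage, seed=seed), sam)
        obs = extract_observations(sam, table)
        wfs = infer_chromosome(obs, imputed, plan)
        track = haf_chromosome(wfs, table)
        ec = effective_coverage(track.est_freq, pool.true_af)
        return {
            "effective_coverage": float(ec),
            "rwin": float(compute_rwin(obs, table, plan)),
            "n_sites": int(table.n_sites),
            "window_size": int(plan.window_size),
        }

    if workdir is not None:
        return run(workdir)
    with tempfile.TemporaryDirectory() as d:
        return run(d)


def unrecombined_benchmark(coverage: float, window_size: int, seed: int,
                           panel=None, workdir=None) -> dict:
    """Effective coverage of HAFs for the equal unrecombined founder pool."""
    spec, table, imputed, ref_codes = panel or make_reference_panel(seed)
    pool = unrecombined_pool(imputed, spec.L)
    plan = build_plan(WindowParams(L=spec.L, R=0, G=0),
                      override_size=window_size)
    return _score_pool(pool, spec, table, imputed, ref_codes, coverage, plan,
                       seed=seed + 1, workdir=workdir)


def evolved_benchmark(seed: int, G: int = 50, coverage: float = 5.0,
                      n_selected: int = 5, s: float = 0.025, N: int = 1000,
                      recomb_rate: float = 2.4e-8, n_individuals: int = 100,
                      panel=None, workdir=None) -> dict:
    """Effective coverage of HAFs after forward evolution with selection.

    Windows are sized adaptively from the exponential fragment-length model
    at the default quantile (q = 0.18).
    """
    spec, table, imputed, ref_codes = panel or make_reference_panel(seed)
    rng = np.random.default_rng(seed + 2)
    sites = np.sort(rng.choice(table.n_sites, size=n_selected, replace=False))
    regime = SelectionRegime(sites=sites, s=s)
    pop = forward_simulate(imputed, regime, L=spec.L, G=G, N=N,
                           recomb_rate=recomb_rate, seed=seed + 3)
    pool = sample_pool(pop, imputed, n_individuals, seed=seed + 4)
    plan = build_plan(WindowParams(L=spec.L, R=recomb_rate, G=G))
    out = _score_pool(pool, spec, table, imputed, ref_codes, coverage, plan,
                      seed=seed + 5, workdir=workdir)
    out["generation"] = G
    return out
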