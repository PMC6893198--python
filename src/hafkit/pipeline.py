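"""End-to-end pipeline: panel -> windows -> inference -> HAF -> accuracy.

Runs the full simulation-backed workflow with one global seed and writes every
artifact (SNP table, reference FASTA, SAM, truth, frequency tracks, accuracy
report) plus a manifest with SHA-256 checksums. All stage seeds are derived
deterministically from the global seed, so a rerun reproduces every file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from hafkit import __version__
from hafkit.founders import impute
from hafkit.windows import WindowParams, build_plan
from hafkit.hapfreq import extract_observations, infer_chromosome
from hafkit.haf import haf_chromosome, raw_af
from hafkit.metrics import score
from hafkit.simulate import (PanelSpec, ReadSimSpec, SelectionRegime,
                             generate_panel, forward_simulate, sample_pool,
                             unrecombined_pool, simulate_reads, write_fasta)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one simulation-backed end-to-end run."""

    outdir: str = "hafkit_run"
    seed: int = 0
    # panel
    n_founders: int = 99
    L: int = 1_000_000
    snp_density: float = 283_437 / 23e6
    missing_rate: float = 0.0
    # evolution (G = 0 means an unrecombined equal-founder pool)
    G: int = 0
    N: int = 1000
    n_selected: int = 5
    s: float = 0.025
    recomb_rate: float = 2.4e-8
    n_individuals: int = 100
    # reads
    coverage: float = 5.0
    error_rate: float = 0.002
    # windows: fixed size, or adaptive from the fragment-length model
    window_size: int | None = None
    quantile: float = 0.18
    fully_genotyped_only: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _stage_seeds(seed: int, n: int = 8) -> list:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full pipeline; returns the accuracy report dict.

    Stages: synthesise panel -> (optionally) forward-simulate and sample a
    pool -> simulate reads -> plan windows -> infer haplotype frequencies ->
    compute HAF and raw-AF tracks -> score both against exact truth.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    stamp = [f"hafkit={__version__}", f"seed={config.seed}"]

    def stage(name):
        logger.info("stage %s", name)
        return name

    st = stage("panel")
    try:
        spec = PanelSpec(n_founders=config.n_founders, L=config.L,
                         snp_density=config.snp_density,
                         missing_rate=config.missing_rate, seed=seeds[0])
        table, ref_codes = generate_panel(spec)
        table.write(out / "founders.snp", header_comments=stamp)
        write_fasta(ref_codes, out / "reference.fa", table.chrom)
        imputed = impute(table) if table.has_missing else impute(table, "major_allele")

        st = stage("pool")
        if config.G > 0:
            rng = np.random.default_rng(seeds[1])
            sel = np.sort(rng.choice(table.n_sites, size=config.n_selected,
                                     replace=False))
            regime = SelectionRegime(sites=sel, s=config.s)
            pop = forward_simulate(imputed, regime, L=config.L, G=config.G,
                                   N=config.N, recomb_rate=config.recomb_rate,
                                   seed=seeds[2])
            pool = sample_pool(pop, imputed, config.n_individuals, seed=seeds[3])
        else:
            pool = unrecombined_pool(imputed, config.L)
        pool.write_truth(out / "truth.tsv", table, header_comments=stamp)
        pool.write_breakpoints(out / "breakpoints.tsv", table.chrom)

        st = stage("reads")
        rspec = ReadSimSpec(coverage=config.coverage,
                            error_rate=config.error_rate, seed=seeds[4])
        simulate_reads(pool, ref_codes, imputed, rspec, out / "pool.sam")

        st = stage("windows")
        params = WindowParams(L=config.L, R=config.recomb_rate, G=config.G,
                              q=config.quantile)
        plan = build_plan(params, override_size=config.window_size,
                          mean_snp_spacing=config.L / table.n_sites)
        plan.to_bed(out / "plan.bed", table.chrom)

        st = stage("infer")
        obs = extract_observations(out / "pool.sam", table)
        window_freqs = infer_chromosome(obs, imputed, plan)
        with open(out / "window_freqs.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tfounder\tfreq\n")
            for wf in window_freqs:
                for fid, fr in zip(table.founder_ids, wf.freqs):
                    fh.write(f"{table.chrom}\t{wf.window[0]}\t{wf.window[1]}"
                             f"\t{fid}\t{fr:.8g}\n")

        st = stage("haf")
        haf_track = haf_chromosome(window_freqs, table,
                                   fully_genotyped_only=config.fully_genotyped_only)
        haf_track.write(out / "haf.tsv", header_comments=stamp)
        raw_track = raw_af(obs, table)
        raw_track.write(out / "raw.tsv", header_comments=stamp)

        st = stage("score")
        pos_idx = np.searchsorted(table.positions, haf_track.positions)
        haf_report = score(haf_track.est_freq, pool.true_af[pos_idx])
        raw_report = score(raw_track.est_freq, pool.true_af)
        cfg_dict = asdict(config)
        cfg_dict.pop("outdir")  # path is environment, not science
        report = {
            "config": cfg_dict,
            "window_size": plan.window_size,
            "n_freq_windows": plan.n_freq_windows,
            "haf": json.loads(haf_report.to_json()),
            "raw": json.loads(raw_report.to_json()),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{st}' failed: {e}") from e

    manifest = {p.name: _sha256(p) for p in sorted(out.iterdir())
                if p.name != "manifest.json"}
    with open(out / "manifest.json", "w") as fh:
        json.dump({"version": __version__, "seed": config.seed,
                   "files": manifest}, fh, indent=2)
    return report
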