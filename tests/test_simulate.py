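import math

import numpy as np
import pysam
import pytest
from scipy import stats

from hafkit.founders import ALT, MISSING, impute
from hafkit.haf import raw_af
from hafkit.hapfreq import extract_observations
from hafkit.metrics import effective_coverage
from hafkit.simulate import (PanelSpec, PoolSample, ReadSimSpec,
                             RecombinantChromosome, SelectionRegime,
                             forward_simulate, generate_panel, sample_pool,
                             simulate_reads, true_allele_frequencies,
                             unrecombined_pool, write_fasta, read_fasta)
from hafkit.windows import WindowParams, fragment_rate


class TestPanel:
    def test_no_missing_when_rate_zero(self, small_panel):
        _, table, _ = small_panel
        assert not np.any(table.genotypes == MISSING)

    def test_missing_rate_applied_but_every_site_called(self):
        spec = PanelSpec(n_founders=10, L=200_000, missing_rate=0.1, seed=3)
        table, _ = generate_panel(spec)
        frac = np.mean(table.genotypes == MISSING)
        assert 0.07 < frac < 0.13
        assert np.all((table.genotypes != MISSING).sum(axis=0) >= 1)

    def test_two_founders_forces_singletons(self):
        spec = PanelSpec(n_founders=2, L=100_000, seed=4)
        table, _ = generate_panel(spec)
        assert np.all((table.genotypes == ALT).sum(axis=0) == 1)
        pool = unrecombined_pool(impute(table, "major_allele"), spec.L)
        assert set(np.round(pool.true_af, 6)) <= {0.5}

    def test_neutral_spectrum_follows_one_over_k(self):
        spec = PanelSpec(n_founders=10, L=2_000_000, snp_density=0.025, seed=5)
        table, _ = generate_panel(spec)  # 50k sites
        k = (table.genotypes == ALT).sum(axis=0)
        counts = np.bincount(k, minlength=10)[1:10]
        expect = (1 / np.arange(1, 10, dtype=float))
        expect = expect / expect.sum() * counts.sum()
        chi2 = ((counts - expect) ** 2 / expect).sum()
        # 8 degrees of freedom
        assert chi2 < stats.chi2.ppf(0.999, df=8)

    def test_reference_embeds_ref_alleles(self, small_panel):
        _, table, ref = small_panel
        alphabet = np.array(list("ACGT"))
        assert np.array_equal(alphabet[ref[table.positions - 1]],
                              table.ref_allele)

    def test_fasta_roundtrip(self, tmp_path, small_panel):
        _, table, ref = small_panel
        write_fasta(ref[:5000], tmp_path / "r.fa", "chrSim")
        name, back = read_fasta(tmp_path / "r.fa")
        assert name == "chrSim"
        assert np.array_equal(back, ref[:5000])


class TestForwardSimulate:
    def test_generation_zero_is_single_segment_founders(self, small_imputed,
                                                        small_panel):
        spec, _, _ = small_panel
        regime = SelectionRegime(sites=np.array([0, 10]), s=0.0)
        pop = forward_simulate(small_imputed, regime, L=spec.L, G=0, N=30,
                               seed=1)
        assert pop.generation == 0
        assert all(c.n_segments == 1 for c in pop.chromosomes())

    def test_neutral_drift_is_martingale(self, small_imputed, small_panel):
        # with s=0 the selected-site frequency is a martingale: the mean
        # change over replicate populations is within 3 SE of zero
        spec, table, _ = small_panel
        site = int(np.argmin(np.abs(table.alt_fractions() - 0.5)))
        regime = SelectionRegime(sites=np.array([site]), s=0.0)
        alt = (small_imputed.genotypes[:, site] == ALT).astype(int)
        pos0 = float(table.positions[site] - 1)
        deltas = []
        for rep in range(200):
            pop0 = forward_simulate(small_imputed, regime, L=spec.L, G=0,
                                    N=60, seed=1000 + rep)
            af0 = pop0.allele_frequency(pos0, alt)
            popG = forward_simulate(small_imputed, regime, L=spec.L, G=8,
                                    N=60, seed=1000 + rep)
            deltas.append(popG.allele_frequency(pos0, alt) - af0)
        deltas = np.array(deltas)
        se = deltas.std(ddof=1) / math.sqrt(len(deltas))
        assert abs(deltas.mean()) < 3 * se

    def test_selection_raises_allele_frequency(self):
        # single selected site at frequency 0.5 (two-founder panel), strong
        # selection: mean final frequency must exceed the initial frequency
        spec = PanelSpec(n_founders=2, L=100_000, snp_density=0.005, seed=6)
        table, _ = generate_panel(spec)
        imp = impute(table, "major_allele")
        site = 10
        alt = (imp.genotypes[:, site] == ALT).astype(int)
        pos0 = float(table.positions[site] - 1)
        regime = SelectionRegime(sites=np.array([site]), s=0.1)
        finals = []
        for rep in range(50):
            pop = forward_simulate(imp, regime, L=spec.L, G=25, N=100,
                                   seed=2000 + rep)
            finals.append(pop.allele_frequency(pos0, alt))
        finals = np.array(finals)
        se = finals.std(ddof=1) / math.sqrt(len(finals))
        assert finals.mean() > 0.5 + 3 * se

    def test_fragment_lengths_exponential(self):
        # unrecombined-segment lengths at generation G follow Exp(lambda)
        # with lambda = (L*R*G + 1)/L (KS test, alpha = 0.01). Fragments are
        # pooled over replicate populations: a single pedigree carries
        # correlated breakpoint counts, and the exponential model holds in
        # the many-founders large-L regime with G << N.
        spec = PanelSpec(n_founders=99, L=20_000_000, snp_density=5e-5, seed=7)
        table, _ = generate_panel(spec)
        imp = impute(table, "major_allele")
        regime = SelectionRegime(sites=np.array([0]), s=0.0)
        R, G = 2.4e-8, 30
        lengths = []
        for seed in (1, 2, 3, 4, 5):
            pop = forward_simulate(imp, regime, L=spec.L, G=G, N=800,
                                   recomb_rate=R, seed=seed)
            pool = sample_pool(pop, imp, 60, seed=seed + 100)
            lengths.append(np.concatenate(
                [c.segment_lengths(spec.L) for c in pool.chromosomes]))
        lengths = np.concatenate(lengths)
        lam = fragment_rate(WindowParams(L=spec.L, R=R, G=G))
        rng = np.random.default_rng(10)
        sub = rng.choice(lengths, size=600, replace=False)
        _, pval = stats.kstest(sub, "expon", args=(0, 1 / lam))
        assert pval > 0.01

    def test_all_zero_fitness_raises(self, small_imputed, small_panel):
        spec, _, _ = small_panel
        # optimum far away with no genetic or environmental variance to reach it
        regime = SelectionRegime(sites=np.array([0]), s=0.0, Ve=1e-12,
                                 optimum=5.0)
        with pytest.raises(RuntimeError, match="zero fitness"):
            forward_simulate(small_imputed, regime, L=spec.L, G=1, N=20,
                             seed=11)


class TestSamplePool:
    def test_true_af_multiples_of_chromosome_count(self, small_imputed,
                                                   small_panel):
        spec, _, _ = small_panel
        regime = SelectionRegime(sites=np.array([0]), s=0.0)
        pop = forward_simulate(small_imputed, regime, L=spec.L, G=3, N=50,
                               seed=12)
        pool = sample_pool(pop, small_imputed, 20, seed=13)
        assert pool.n_chromosomes == 40
        frac = pool.true_af * 40
        assert np.allclose(frac, np.round(frac))

    def test_sampling_everyone_recovers_population_af(self, small_imputed,
                                                      small_panel):
        spec, table, _ = small_panel
        regime = SelectionRegime(sites=np.array([5]), s=0.0)
        pop = forward_simulate(small_imputed, regime, L=spec.L, G=2, N=30,
                               seed=14)
        pool = sample_pool(pop, small_imputed, 30, seed=15)
        alt = (small_imputed.genotypes[:, 5] == ALT).astype(int)
        pos0 = float(table.positions[5] - 1)
        assert pool.true_af[5] == pytest.approx(
            pop.allele_frequency(pos0, alt))

    def test_unrecombined_pool_matches_alt_fraction(self, small_imputed,
                                                    small_panel):
        spec, _, _ = small_panel
        pool = unrecombined_pool(small_imputed, spec.L)
        assert pool.true_af == pytest.approx(small_imputed.alt_fractions())

    def test_breakpoint_table_roundtrips_truth(self, tmp_path, small_imputed,
                                               small_panel):
        import pandas as pd

        spec, table, _ = small_panel
        regime = SelectionRegime(sites=np.array([0]), s=0.0)
        pop = forward_simulate(small_imputed, regime, L=spec.L, G=5, N=30,
                               seed=16)
        pool = sample_pool(pop, small_imputed, 10, seed=17)
        pool.write_breakpoints(tmp_path / "bp.tsv", table.chrom)
        df = pd.read_csv(tmp_path / "bp.tsv", sep="\t")
        chroms = []
        for _, grp in df.groupby("chromosome", sort=True):
            grp = grp.sort_values("segment_start")
            chroms.append(RecombinantChromosome(
                grp["segment_start"].to_numpy(float),
                grp["founder"].to_numpy()))
        af = true_allele_frequencies(chroms, small_imputed, spec.L)
        assert af == pytest.approx(pool.true_af)


class TestSimulateReads:
    def test_error_free_reads_match_source(self, tmp_path, small_panel,
                                           small_imputed):
        spec, table, ref = small_panel
        pool = unrecombined_pool(small_imputed, spec.L)
        sam = tmp_path / "p.sam"
        simulate_reads(pool, ref, small_imputed,
                       ReadSimSpec(coverage=0.5, error_rate=0.0, seed=18), sam)
        obs = extract_observations(sam, table)
        # every observed base is ref or alt (never OTHER) at quality 30
        assert np.all(obs.entry_allele != 2)
        assert np.allclose(obs.entry_eps, 1e-3)
        # and raw frequencies at high depth approximate truth
        track = raw_af(obs, table)
        ok = track.support >= 1
        assert np.nanmean(np.abs(track.est_freq[ok] - pool.true_af[ok])) < 0.3

    def test_observed_error_rate_near_spec(self, tmp_path, small_panel,
                                           small_imputed):
        # compare simulated read bases against the reconstructed source
        # haplotype: mismatch fraction ~ 0.002 within 3 binomial SD
        spec, table, ref = small_panel
        chroms = [RecombinantChromosome.pure(0)]
        af = true_allele_frequencies(chroms, small_imputed, spec.L)
        pool = PoolSample(chroms, af, 0, spec.L)
        sam = tmp_path / "e.sam"
        simulate_reads(pool, ref, small_imputed,
                       ReadSimSpec(coverage=5, error_rate=0.002, seed=19), sam)
        hap = ref.copy()
        alt_sites = small_imputed.genotypes[0] == ALT
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        alt_codes = np.array([code[b] for b in small_imputed.alt_allele])
        hap[small_imputed.positions[alt_sites] - 1] = alt_codes[alt_sites]
        n_bases = n_mis = 0
        n_err_q = 0
        with pysam.AlignmentFile(str(sam), "r") as af_:
            for r in af_:
                seq = np.array([code[b] for b in r.query_sequence])
                src = hap[r.reference_start:r.reference_start + len(seq)]
                n_bases += len(seq)
                mis = seq != src
                n_mis += int(mis.sum())
                q = np.array(r.query_qualities)
                n_err_q += int((q[mis] == 10).sum())
        rate = n_mis / n_bases
        sd = math.sqrt(0.002 * 0.998 / n_bases)
        assert abs(rate - 0.002) < 3 * sd
        assert n_err_q == n_mis  # every error carries the low quality score

    def test_coverage_accounting(self, tmp_path, small_panel, small_imputed):
        spec, table, ref = small_panel
        pool = unrecombined_pool(small_imputed, spec.L)
        sam = tmp_path / "c.sam"
        n = simulate_reads(pool, ref, small_imputed,
                           ReadSimSpec(coverage=10, seed=20), sam)
        assert n == math.ceil(10 * spec.L / 300)
        depth_bases = 0
        with pysam.AlignmentFile(str(sam), "r") as af_:
            for r in af_:
                depth_bases += r.query_length
        assert depth_bases / spec.L == pytest.approx(10, rel=0.05)

    def test_raw_af_effective_coverage_tracks_depth(self, tmp_path,
                                                    small_panel,
                                                    small_imputed):
        # closes the loop with the metric: error-free reads at depth C score
        # an effective coverage within [0.7C, 1.3C]
        spec, table, ref = small_panel
        pool = unrecombined_pool(small_imputed, spec.L)
        C = 25
        sam = tmp_path / "ec.sam"
        simulate_reads(pool, ref, small_imputed,
                       ReadSimSpec(coverage=C, error_rate=0.0, seed=21), sam)
        track = raw_af(sam, table)
        ec = effective_coverage(track.est_freq, pool.true_af)
        assert 0.7 * C <= ec <= 1.3 * C
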