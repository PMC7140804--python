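"""Generator contracts: mosaics, probabilities, phenotypes, expression, DAM."""

import numpy as np
import pytest
from scipy import stats

from dsprsleep import simpanel as sp
from dsprsleep.sleepmetrics import find_bouts


def mosaics_equal(a, b):
    for ma, mb in zip(a, b):
        if ma.genotype != mb.genotype or ma.subpop != mb.subpop:
            return False
        for panel in ("A", "B"):
            ha, hb = ma.haplotype(panel), mb.haplotype(panel)
            for chrom in ha:
                if not (
                    np.array_equal(ha[chrom][0], hb[chrom][0])
                    and np.array_equal(ha[chrom][1], hb[chrom][1])
                ):
                    return False
    return True


class TestSimulatePanel:
    def test_zero_cm_map_gives_single_segments(self):
        gm = sp.GenomeMap([sp.Chromosome("c", 1_000_000, 0.0)], spacing_bp=100_000)
        for m in sp.simulate_panel(20, gm, generations=1, seed=0):
            for panel in ("A", "B"):
                breaks, founders = m.haplotype(panel)["c"]
                assert len(breaks) == 0 and len(founders) == 1

    def test_breakpoint_density_matches_closed_form(self, small_genome):
        mosaics = sp.simulate_panel(200, small_genome, seed=1)
        observed = np.mean(
            [m.n_breakpoints("A") + m.n_breakpoints("B") for m in mosaics]
        ) / 2.0
        expected = sp.expected_breakpoints_per_haplotype(small_genome, 50)
        assert abs(observed - expected) / expected < 0.15

    def test_seed_reproducibility(self, small_genome):
        a = sp.simulate_panel(30, small_genome, seed=42)
        b = sp.simulate_panel(30, small_genome, seed=42)
        assert mosaics_equal(a, b)

    def test_drift_grows_with_generations(self, small_genome):
        """Per-position founder-frequency variance is monotone in generations."""
        spread = []
        for gens in (5, 50, 200):
            v = []
            for seed in range(5):
                mosaics = sp.simulate_panel(150, small_genome, generations=gens, seed=seed)
                probs = sp.mosaics_to_probs(mosaics, small_genome)
                freq = probs.probs.mean(axis=0)  # (positions, 16)
                v.append(np.mean((freq - 1.0 / 8) ** 2))
            spread.append(np.mean(v))
        assert spread[0] < spread[1] < spread[2]

    def test_input_validation(self, small_genome):
        with pytest.raises(sp.SimulationError):
            sp.simulate_panel(0, small_genome)
        with pytest.raises(sp.SimulationError):
            sp.simulate_panel(10, small_genome, generations=0)
        with pytest.raises(sp.SimulationError):
            sp.GenomeMap([])


class TestMosaicsToProbs:
    def test_one_hot_at_certainty_one(self, small_genome):
        mosaics = sp.simulate_panel(10, small_genome, seed=3)
        probs = sp.mosaics_to_probs(mosaics, small_genome)
        m, pos = mosaics[0], 7
        bp = small_genome.grid["bp"].iloc[pos]
        truth = int(m.founder_at("A", "2", bp))
        vec = probs.probs[0, pos, :8]
        assert vec[truth - 1] == 1.0 and vec.sum() == 1.0

    def test_certainty_spreads_residual_mass(self, small_genome):
        mosaics = sp.simulate_panel(5, small_genome, seed=3)
        probs = sp.mosaics_to_probs(mosaics, small_genome, certainty=0.9)
        block = probs.probs[:, :, :8]
        assert np.allclose(block.sum(axis=-1), 1.0, atol=1e-9)
        assert np.allclose(np.sort(block, axis=-1)[..., -1], 0.9)
        assert np.allclose(np.sort(block, axis=-1)[..., 0], 0.1 / 7)

    def test_matches_segment_walker_oracle(self, small_genome):
        """Per-position founder frequencies equal a brute-force segment walk."""
        mosaics = sp.simulate_panel(40, small_genome, seed=9)
        probs = sp.mosaics_to_probs(mosaics, small_genome)
        grid_bp = small_genome.grid["bp"].to_numpy()
        for pos in (0, 13, 49):
            counts = np.zeros(8)
            for m in mosaics:  # independent linear walk over segments
                breaks, founders = m.maternal["2"]
                f = None
                for b, lab in zip(list(breaks) + [np.inf], founders):
                    if grid_bp[pos] <= b:
                        f = lab
                        break
                counts[f - 1] += 1
            assert np.allclose(probs.probs[:, pos, :8].mean(axis=0), counts / 40)

    def test_certainty_out_of_range(self, small_genome):
        mosaics = sp.simulate_panel(2, small_genome, seed=0)
        with pytest.raises(sp.SimulationError):
            sp.mosaics_to_probs(mosaics, small_genome, certainty=0.0)


class TestSimulatePhenotypes:
    def test_null_model_has_no_genotype_variance(self, panel200):
        """With no QTL and h2=0, the among-genotype F test stays null."""
        rejections = 0
        for seed in range(10):
            df = sp.simulate_phenotypes(
                panel200, [], h2_target=0.0, n_flies_per_genotype=6, seed=seed
            )
            groups = [g["value"].to_numpy() for _, g in df.groupby("genotype")]
            _, p = stats.f_oneway(*groups)
            rejections += p < 0.01
        assert rejections <= 2

    def test_noise_free_biallelic_qtl_gives_two_classes(self, panel200):
        effects = np.array([10.0] * 4 + [-10.0] * 4 + [0.0] * 8)
        qtl = sp.PlantedQTL("2", 2_500_000, effects)
        df = sp.simulate_phenotypes(panel200, [qtl], h2_target=1.0, seed=1)
        classes = np.unique(np.round(df["value"].to_numpy(), 9))
        assert len(classes) == 2

    def test_subpop_shift_and_determinism(self, panel200):
        kw = dict(h2_target=0.5, subpop_shift=5.0, n_flies_per_genotype=4, seed=3)
        a = sp.simulate_phenotypes(panel200, [], **kw)
        b = sp.simulate_phenotypes(panel200, [], **kw)
        assert a.equals(b)
        means = a.groupby("subpop")["value"].mean()
        assert means[2] - means[1] == pytest.approx(5.0, abs=1.0)

    def test_off_map_qtl_rejected(self, panel200):
        qtl = sp.PlantedQTL("2", 2_500_000, np.arange(16.0))
        qtl.chrom = "nope"
        with pytest.raises(sp.SimulationError):
            sp.simulate_phenotypes(panel200, [qtl], h2_target=0.5, seed=0)

    def test_constant_effects_rejected(self):
        with pytest.raises(sp.SimulationError):
            sp.PlantedQTL("2", 1000, np.ones(16))


class TestSimulateExpression:
    def test_noise_free_expression_is_exact(self, panel200):
        rng = np.random.default_rng(2)
        gene = sp.CisGene("g1", "2", 1_200_000, sp.random_effect_vector(rng))
        expr, truth = sp.simulate_expression(panel200, [gene], noise_sd=0.0, seed=0)
        idx = panel200.position_index("2", 1_200_000)
        assert np.allclose(expr["g1"].to_numpy(), panel200.at(idx) @ gene.effects)
        assert truth.loc[0, "gene"] == "g1"

    def test_constant_effect_vector_gives_flat_expression(self, panel200):
        gene = sp.CisGene("flat", "2", 1_200_000, np.full(16, 3.0))
        expr, _ = sp.simulate_expression(panel200, [gene], noise_sd=0.0, seed=0)
        assert np.ptp(expr["flat"].to_numpy()) < 1e-12

    def test_planted_effects_recovered_by_founder_means(self, small_genome):
        """Founder means of simulated expression track the planted vector."""
        from dsprsleep.qtlscan import founder_means

        mosaics = sp.simulate_panel(400, small_genome, seed=21)
        probs = sp.mosaics_to_probs(mosaics, small_genome)
        rng = np.random.default_rng(3)
        gene = sp.CisGene("g1", "2", 2_500_000, sp.random_effect_vector(rng))
        expr, _ = sp.simulate_expression(probs, [gene], noise_sd=0.3, seed=4)
        idx = probs.position_index("2", 2_500_000)
        import pandas as pd

        fm = founder_means(probs, idx, pd.Series(expr["g1"].to_numpy(), index=probs.genotypes))
        planted = np.array(
            [
                gene.effects[(0 if p == "A" else 8) + f - 1]
                for p, f in zip(fm["panel"], fm["founder"])
            ]
        )
        r = np.corrcoef(planted, fm["mean"])[0, 1]
        assert fm.shape[0] >= 8 and r > 0.9


class TestSimulateDam:
    def test_no_sleep_onset_means_no_bouts(self):
        arch = sp.SleepArchitecture(
            p_onset_light=0.0, p_onset_dark=0.0, p_wake_light=0.5,
            p_wake_dark=0.5, rate_light=5.0, rate_dark=5.0,
        )
        m = sp.simulate_dam(arch, n_flies=4, n_days=1, seed=0)
        # waking zero-count minutes can still occur by Poisson chance, but
        # with rate 5 a 5-min zero run is essentially impossible
        assert sum(b.length for b in find_bouts(m.channel(1))) == 0

    def test_absorbing_sleep_state(self):
        arch = sp.SleepArchitecture(
            p_onset_light=1.0, p_onset_dark=1.0, p_wake_light=0.0,
            p_wake_dark=0.0, rate_light=5.0, rate_dark=5.0,
        )
        m = sp.simulate_dam(arch, n_flies=2, n_days=1, seed=0)
        bouts = find_bouts(m.channel(1))
        assert sum(b.length for b in bouts) == 1440

    def test_sleep_fraction_matches_censored_stationary_oracle(self):
        """Long-run detected sleep fraction vs the chain's closed form,
        adjusted for the >=5-min rule by enumerating the geometric run-length
        distribution."""
        onset, wake = 0.10, 0.05
        arch = sp.SleepArchitecture(
            p_onset_light=onset, p_onset_dark=onset, p_wake_light=wake,
            p_wake_dark=wake, rate_light=5.0, rate_dark=5.0,
        )
        m = sp.simulate_dam(arch, n_flies=1, n_days=70, seed=8)
        trace = m.channel(1)
        detected = sum(b.length for b in find_bouts(trace)) / len(trace)
        pi_sleep = onset / (onset + wake)
        lengths = np.arange(1, 20_000)
        pmf = wake * (1 - wake) ** (lengths - 1)  # geometric run lengths
        frac_long = float((lengths * pmf)[lengths >= 5].sum() / (lengths * pmf).sum())
        assert abs(detected - pi_sleep * frac_long) < 0.02

    def test_light_column_follows_photoperiod(self):
        m = sp.simulate_dam(sp.SleepArchitecture(), n_flies=1, n_days=2, seed=0)
        assert m.light[:720].all() and not m.light[720:1440].any()
        assert m.light[1440:2160].all()

    def test_seed_reproducibility(self):
        a = sp.simulate_dam(sp.SleepArchitecture(), n_flies=8, n_days=2, seed=5)
        b = sp.simulate_dam(sp.SleepArchitecture(), n_flies=8, n_days=2, seed=5)
        assert np.array_equal(a.counts, b.counts)
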