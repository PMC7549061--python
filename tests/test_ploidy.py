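"""The mixture machinery must satisfy EM's guarantees (monotone objective,
normalised weights, free-model nesting) and recover known ploidies from
labelled simulations."""

import warnings

import numpy as np
import pytest

import musaqc as mq
from musaqc.exceptions import InsufficientSitesError, InvalidParameterError


def het_freqs(ploidy, n_sites, depth=30, error=0.005, seed=0):
    cols, _ = mq.simulate_heterozygous_sites(ploidy, n_sites, depth, error, seed)
    return mq.extract_site_frequencies(cols, min_depth=10, min_minor_reads=3)


class TestExtractSiteFrequencies:
    def test_homozygous_columns_excluded(self):
        cols = [mq.PileupColumn("c", 1, "A", 30, (30, 0, 0, 0), 0)]
        assert mq.extract_site_frequencies(cols) == []

    def test_balanced_site_gives_half(self):
        cols = [mq.PileupColumn("c", 1, "A", 30, (15, 0, 15, 0), 0)]
        (f,) = mq.extract_site_frequencies(cols)
        assert f.alt_fraction == 0.5

    def test_fraction_polarised_against_reference(self):
        # 10 ref, 20 alt reads: alt fraction 2/3 even though ref is the minor base
        cols = [mq.PileupColumn("c", 1, "A", 30, (10, 20, 0, 0), 0)]
        (f,) = mq.extract_site_frequencies(cols)
        assert f.alt_fraction == pytest.approx(2 / 3)

    def test_min_minor_reads_gate(self):
        cols = [mq.PileupColumn("c", 1, "A", 30, (28, 2, 0, 0), 0)]
        assert mq.extract_site_frequencies(cols, min_minor_reads=3) == []

    @pytest.mark.parametrize("comp,mode", [("AAB", 1 / 3), ("ABB", 2 / 3)])
    def test_hybrid_histogram_mode_at_dosage(self, comp, mode):
        pair = mq.generate_subgenomes(seed=29, n_chrom=1, chrom_length=100_000, divergence_rate=0.005)
        acc = mq.compose_genotype(pair, mq.GenotypeSpec(comp))
        positions = {"chr01": [s.pos for s in pair.truth_sites]}
        pu = mq.simulate_pileup(acc, mean_depth=50, error_rate=0.0, seed=30, positions=positions)
        freqs = mq.extract_site_frequencies(pu)
        hist, edges = np.histogram([f.alt_fraction for f in freqs], bins=20, range=(0, 1))
        peak = (edges[hist.argmax()] + edges[hist.argmax() + 1]) / 2
        assert abs(peak - mode) < 0.08


class TestDenoise:
    def test_clean_diploid_retains_nearly_all_sites(self):
        freqs = het_freqs(2, 3000, error=0.0, seed=4)
        kept = mq.denoise(freqs)
        assert len(kept) >= 0.99 * len(freqs)

    def test_uniform_contamination_is_preferentially_removed(self):
        """Labelled simulation: the contamination fraction must drop, and
        contaminated sites must be removed at a much higher rate than clean
        ones (the free-mean mixture cannot remove haze overlapping the
        cluster, so full halving is not attainable)."""
        freqs = het_freqs(2, 3000, error=0.0, seed=4)
        rng = np.random.default_rng(8)
        noise = rng.uniform(0, 1, size=int(0.25 * len(freqs)))
        noise = noise[(noise > 0) & (noise < 1)]
        clean_vals = [f.alt_fraction for f in freqs]
        labelled = [
            mq.SiteFrequency("c", i + 1, 30, v)
            for i, v in enumerate(list(clean_vals) + list(noise))
        ]
        kept = mq.denoise(labelled)
        kept_pos = {f.pos for f in kept}
        n_clean = len(clean_vals)
        kept_noise = sum(1 for i in range(n_clean, len(labelled)) if (i + 1) in kept_pos)
        kept_clean = sum(1 for i in range(n_clean) if (i + 1) in kept_pos)
        before = len(noise) / len(labelled)
        after = kept_noise / len(kept)
        assert after <= 0.75 * before
        assert kept_clean / n_clean >= 0.97
        assert kept_noise / len(noise) <= 0.6

    def test_too_few_sites_is_an_error_not_a_silent_drop(self):
        freqs = het_freqs(2, 100, seed=5)[:20]
        with pytest.raises(InsufficientSitesError):
            mq.denoise(freqs)


class TestFixedModelFit:
    def test_point_mass_at_half_prefers_diploid_model(self):
        x = np.full(200, 0.5) + np.linspace(-1e-3, 1e-3, 200)  # avoid zero sd
        fits = {p: mq.fit_fixed_model(x, p) for p in (2, 3, 4)}
        assert fits[2].log_likelihood >= fits[3].log_likelihood
        assert fits[2].log_likelihood >= fits[4].log_likelihood

    def test_weights_sum_to_one(self):
        for p in (2, 3, 4):
            fit = mq.fit_fixed_model(het_freqs(3, 1000, seed=6), p)
            assert fit.weights.sum() == pytest.approx(1.0, abs=1e-8)
            assert fit.means.tolist() == list(mq.ploidy.FIXED_MEANS[p])

    def test_em_matches_grid_search_oracle(self):
        """Dense (weight, sd) grid with nested refinement: EM must agree to
        1e-3 nats on triploid-shaped data."""
        rng = np.random.default_rng(3)
        n = 2000
        comp = rng.random(n) < 0.5
        x = np.where(comp, rng.normal(1 / 3, 0.05, n), rng.normal(2 / 3, 0.05, n))
        x = np.clip(x, 1e-3, 1 - 1e-3)
        fit = mq.fit_fixed_model(x, 3)

        def loglik(w1, sd):
            z1 = (x - 1 / 3) / sd
            z2 = (x - 2 / 3) / sd
            dens = (
                w1 * np.exp(-0.5 * z1 * z1) + (1 - w1) * np.exp(-0.5 * z2 * z2)
            ) / (sd * np.sqrt(2 * np.pi))
            return float(np.log(dens).sum())

        w_grid = np.linspace(0.01, 0.99, 50)
        s_grid = np.linspace(0.01, 0.15, 60)
        best = (-np.inf, 0.5, 0.05)
        for _ in range(4):
            for w in w_grid:
                for s in s_grid:
                    ll = loglik(w, s)
                    if ll > best[0]:
                        best = (ll, w, s)
            dw = (w_grid[1] - w_grid[0]) * 2
            ds = (s_grid[1] - s_grid[0]) * 2
            w_grid = np.linspace(max(1e-3, best[1] - dw), min(1 - 1e-3, best[1] + dw), 41)
            s_grid = np.linspace(max(1e-3, best[2] - ds), best[2] + ds, 41)
        assert fit.log_likelihood == pytest.approx(best[0], abs=1e-3)

    def test_insufficient_sites_raises(self):
        with pytest.raises(InsufficientSitesError):
            mq.fit_fixed_model(np.full(10, 0.5), 2)

    def test_frequencies_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidParameterError):
            mq.fit_fixed_model(np.array([0.5] * 60 + [1.2]), 2)


class TestFreeModelFit:
    def test_delta_small_against_matching_model(self):
        freqs = het_freqs(2, 2000, seed=7)
        _, fits = mq.infer_ploidy(freqs, seed=7)
        assert fits["diploid"].delta_loglik < fits["triploid"].delta_loglik
        assert fits["diploid"].delta_loglik < 10.0

    def test_permutation_invariance(self):
        freqs = het_freqs(3, 800, seed=8)
        x = np.array([f.alt_fraction for f in freqs])
        rng = np.random.default_rng(0)
        fit1 = mq.fit_free_model(x, seed=1)
        fit2 = mq.fit_free_model(rng.permutation(x), seed=1)
        assert fit1.log_likelihood == pytest.approx(fit2.log_likelihood, abs=1e-6)

    def test_free_model_nests_every_fixed_model(self):
        for p, seed in ((2, 10), (3, 11), (4, 12)):
            freqs = het_freqs(p, 1500, seed=seed)
            _, fits = mq.infer_ploidy(freqs, seed=seed)
            n = fits["free"].n_sites
            for name in ("diploid", "triploid", "tetraploid"):
                assert (
                    fits["free"].log_likelihood
                    >= fits[name].log_likelihood - 1e-6 * n
                )
                assert fits[name].delta_loglik >= -1e-6 * n

    def test_seeded_determinism(self):
        freqs = het_freqs(4, 1000, seed=13)
        res1 = mq.PloidyModel(freqs).fit(seed=3)
        res2 = mq.PloidyModel(freqs).fit(seed=3)
        for name in res1.fits:
            assert res1.fits[name].log_likelihood == res2.fits[name].log_likelihood
            assert np.array_equal(res1.fits[name].weights, res2.fits[name].weights)
        assert res1.observed_ploidy == res2.observed_ploidy


class TestEmDiagnostics:
    def test_objective_non_decreasing_every_iteration(self):
        for p in (2, 3, 4):
            freqs = het_freqs(p, 1500, seed=20 + p)
            res = mq.PloidyModel(freqs).fit(seed=p)
            for fit in res.fits.values():
                trace = fit.loglik_trace
                assert np.all(np.diff(trace) >= -1e-9)


class TestInferPloidy:
    @pytest.mark.parametrize("ploidy,seed", [(3, 101), (4, 102)])
    def test_labelled_simulation_recovered(self, ploidy, seed):
        freqs = het_freqs(ploidy, 5000, depth=50, error=0.0, seed=seed)
        observed, _ = mq.infer_ploidy(freqs, seed=seed)
        assert observed == ploidy

    def test_diploid_recovered_via_lower_ploidy_tie_rule(self):
        freqs = het_freqs(2, 5000, depth=30, seed=103)
        observed, fits = mq.infer_ploidy(freqs, seed=103)
        assert observed == 2
        # nesting: the tetraploid model can beat the diploid only by an
        # overfitting-scale margin, never by a signal-scale one
        margin = np.log(len(freqs))
        assert fits["tetraploid"].delta_loglik >= fits["diploid"].delta_loglik - margin
        assert fits["triploid"].delta_loglik > fits["diploid"].delta_loglik + 100

    def test_insufficient_sites_returns_undetermined(self):
        observed, fits = mq.infer_ploidy(np.full(10, 0.5), seed=0)
        assert observed is None
        assert fits == {}

    def test_results_summary_reports_all_models(self):
        res = mq.PloidyModel(het_freqs(3, 600, seed=40)).fit(seed=40)
        text = res.summary()
        for token in ("free", "diploid", "triploid", "tetraploid", "inferred ploidy: 3"):
            assert token in text
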