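import math

import numpy as np
import pytest

from ictal.features import entropy as ent
from ictal.features.entropy import (EmbeddingParams, FuzzyParams,
                                    SubbandEnergies)

import oracles


class TestShannonAndLogEnergy:
    def test_uniform_eight_bins(self):
        # 8 equal-count bins over [0, 8)
        x = np.repeat(np.arange(8, dtype=float) + 0.5, 16)
        assert ent.shannon_entropy(x, bins=8) == pytest.approx(3.0)

    def test_constant_is_zero(self):
        assert ent.shannon_entropy(np.full(100, 7.0)) == 0.0

    def test_matches_histogram_oracle(self, rng):
        x = rng.standard_normal(500)
        counts, _ = np.histogram(x, bins=64)
        p = counts[counts > 0] / 500
        assert ent.shannon_entropy(x) == pytest.approx(
            -np.sum(p * np.log2(p)), abs=1e-12)

    def test_log_energy_closed_forms(self, rng):
        assert ent.log_energy_entropy(np.ones(3)) == pytest.approx(0.0, abs=1e-9)
        assert ent.log_energy_entropy(np.array([math.e, math.e])) == \
            pytest.approx(4.0, abs=1e-9)
        x = rng.standard_normal(50)
        assert ent.log_energy_entropy(x) == pytest.approx(
            sum(math.log(v * v + 1e-12) for v in x), abs=1e-9)


class TestSpectralEntropy:
    def test_white_noise_high(self):
        vals = [ent.spectral_entropy(
            np.random.default_rng(s).standard_normal(868), 173.6)
            for s in range(20)]
        assert np.mean(vals) > 0.85

    def test_sinusoid_low(self):
        fs, n = 173.6, 868
        f0 = 20 * fs / n
        x = np.sin(2 * np.pi * f0 * np.arange(n) / fs)
        assert ent.spectral_entropy(x, fs) < 0.1

    def test_bounded_unit_interval(self, rng):
        for _ in range(10):
            v = ent.spectral_entropy(rng.standard_normal(256), 100.0)
            assert 0.0 <= v <= 1.0


class TestSampleEntropy:
    def test_regular_alternation_is_zero(self):
        x = np.array([1.0, 2, 1, 2, 1, 2, 1, 2])
        assert ent.sample_entropy(x, m=2, r=0.1) == 0.0

    def test_matches_exhaustive_pair_count(self, rng):
        for _ in range(5):
            x = rng.standard_normal(20)
            got = ent.sample_entropy(x, m=2, r=0.5)
            want = oracles.sample_entropy(x, 2, 0.5)
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, abs=1e-9)

    def test_constant_signal_is_zero(self):
        assert ent.sample_entropy(np.full(20, 3.0)) == 0.0

    def test_no_matches_returns_infinite_sentinel(self):
        x = np.array([0.0, 100.0, -50.0, 400.0, -300.0, 900.0])
        assert math.isinf(ent.sample_entropy(x, m=2, r=1e-6))


class TestPermutationEntropies:
    def test_monotone_single_pattern(self):
        pe, norm = ent.permutation_entropy(np.arange(50, dtype=float))
        assert pe == 0.0 and norm == 0.0

    def test_hand_enumeration(self):
        x = np.array([4.0, 7, 9, 10, 6, 11, 3])
        pe, _ = ent.permutation_entropy(x, m=2, L=1)
        expect = -(4 / 6) * math.log2(4 / 6) - (2 / 6) * math.log2(2 / 6)
        assert pe == pytest.approx(expect, abs=1e-12)

    def test_uniform_patterns_normalised_to_one(self):
        # 19 samples give 18 ordinal pairs: 9 rising, 9 falling
        x = np.tile([0.0, 1.0], 10)[:-1]
        _, norm = ent.permutation_entropy(x, m=2, L=1)
        assert norm == pytest.approx(1.0, abs=1e-9)

    def test_matches_oracle(self, rng):
        x = rng.standard_normal(30)
        got, _ = ent.permutation_entropy(x, m=3, L=1)
        assert got == pytest.approx(
            oracles.permutation_entropy_bits(x, 3, 1), abs=1e-9)

    def test_renyi_closed_form_two_patterns(self):
        x = np.array([4.0, 7, 9, 10, 6, 11, 3])  # p = (2/3, 1/3)
        got = ent.permutation_renyi_entropy(x, m=2, L=1, alpha=2.0)
        assert got == pytest.approx(math.log(9 / 5), abs=1e-12)

    def test_renyi_limit_brackets_shannon(self, rng):
        x = rng.standard_normal(100)
        shannon_nats = ent.permutation_entropy(x, 3, 1)[0] * math.log(2)
        lo = ent.permutation_renyi_entropy(x, 3, 1, alpha=1 + 1e-4)
        hi = ent.permutation_renyi_entropy(x, 3, 1, alpha=1 - 1e-4)
        assert lo <= shannon_nats + 1e-6
        assert hi >= shannon_nats - 1e-6

    def test_renyi_alpha_one_rejected(self, rng):
        with pytest.raises(ValueError, match="permutation_entropy"):
            ent.permutation_renyi_entropy(rng.standard_normal(30), alpha=1.0)

    def test_renyi_matches_oracle(self, rng):
        x = rng.standard_normal(30)
        assert ent.permutation_renyi_entropy(x, 3, 1, 2.0) == pytest.approx(
            oracles.permutation_renyi(x, 3, 1, 2.0), abs=1e-9)


class TestWaveletEntropies:
    def test_uniform_bands_shannon(self):
        se = SubbandEnergies(np.ones(9))
        assert ent.wavelet_entropy_avg(se, se, "shannon") == \
            pytest.approx(math.log(9), abs=1e-12)

    def test_degenerate_distribution_zero(self):
        se = SubbandEnergies(np.array([1.0, 0, 0, 0]))
        for kind in ("shannon", "renyi", "tsallis"):
            assert ent.wavelet_entropy_avg(se, se, kind) == pytest.approx(0.0)

    def test_tsallis_limit_brackets_shannon(self, rng):
        q = rng.random(9)
        se = SubbandEnergies(q)
        shannon = ent.wavelet_entropy(se.q, "shannon")
        lo = ent.wavelet_entropy(se.q, "tsallis", alpha=1 + 1e-4)
        hi = ent.wavelet_entropy(se.q, "tsallis", alpha=1 - 1e-4)
        assert min(lo, hi) <= shannon <= max(lo, hi)

    def test_renyi_alpha_two_closed_form(self, rng):
        q = rng.random(5)
        se = SubbandEnergies(q)
        assert ent.wavelet_entropy(se.q, "renyi", 2.0) == pytest.approx(
            -math.log(np.sum(se.q**2)), abs=1e-12)

    def test_zero_total_energy_rejected(self):
        with pytest.raises(ValueError):
            SubbandEnergies(np.zeros(5))


class TestGraphEntropy:
    def test_visibility_edges_match_naive_definition(self, rng):
        for _ in range(10):
            x = rng.standard_normal(30)
            fast = set(map(tuple, map(sorted,
                       ent.horizontal_visibility_edges(x))))
            assert fast == oracles.hvg_edges_naive(x)

    def test_monotone_chain_hand_computation(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        # chain graph: interior nodes have 2 equal-weight links -> ln 2
        expect = 6 * math.log(2) / 8
        assert ent.graph_entropy(x) == pytest.approx(expect, abs=1e-12)

    def test_equal_weights_give_log_degree(self):
        # hub with equal excursions: node 0 of [2,1,2] chain pattern
        x = np.array([0.0, 2, 0, 2, 0, 2, 0, 2, 0])
        v = ent.graph_entropy(x)
        assert v > 0  # every connected node has entropy log(degree) >= 0

    def test_offset_invariance(self, rng):
        x = rng.standard_normal(64)
        assert ent.graph_entropy(x + 42.0) == pytest.approx(
            ent.graph_entropy(x), abs=1e-12)


class TestFuzzyFamily:
    def test_constant_signal_zero(self):
        assert ent.fuzzy_entropy(np.full(20, 5.0)) == 0.0

    def test_matches_brute_force(self, rng):
        x = rng.standard_normal(20)
        got = ent.fuzzy_entropy(x, FuzzyParams(m=2, n=2, r=0.2))
        assert got == pytest.approx(oracles.fuzzy_entropy(x, 2, 2, 0.2),
                                    abs=1e-9)

    def test_non_increasing_in_tolerance(self, rng):
        x = rng.standard_normal(60)
        vals = [ent.fuzzy_entropy(x, FuzzyParams(r=r)) for r in (0.1, 0.3, 0.6)]
        assert vals[0] >= vals[1] >= vals[2]

    def test_rcmfe_scale_one_equals_fuzzy(self, rng):
        x = rng.standard_normal(40)
        assert ent.rcmfe(x, scales=(1,))[0] == pytest.approx(
            ent.fuzzy_entropy(x), abs=1e-12)

    def test_rcmfe_scale_two_matches_oracle(self, rng):
        x = rng.standard_normal(30)
        got = ent.rcmfe(x, FuzzyParams(m=2, n=2, r=0.2), scales=(2,))[0]
        assert got == pytest.approx(oracles.rcmfe_mu(x, 2, 2, 0.2, 2), abs=1e-9)

    def test_rcmfe_infeasible_scale_lists_feasible(self, rng):
        with pytest.raises(ValueError, match="feasible"):
            ent.rcmfe(rng.standard_normal(12), scales=(2, 8))

    def test_rcmfe_multiscale_signature(self):
        """White-noise RCMFE decreases with scale; 1/f-type noise stays
        flatter (20-seed mean curves ordered at the largest scale)."""
        scales = (1, 2, 3, 4, 5)
        white_curves, pink_curves = [], []
        for s in range(20):
            g = np.random.default_rng(s)
            w = g.standard_normal(400)
            spec = np.fft.rfft(g.standard_normal(400))
            f = np.fft.rfftfreq(400)
            f[0] = f[1]
            pink = np.fft.irfft(spec / np.sqrt(f), 400)
            pink /= pink.std()
            white_curves.append(ent.rcmfe(w, scales=scales))
            pink_curves.append(ent.rcmfe(pink, scales=scales))
        wm = np.mean(white_curves, axis=0)
        pm = np.mean(pink_curves, axis=0)
        assert wm[0] > wm[-1]  # white noise loses complexity with scale
        wdrop = wm[0] - wm[-1]
        pdrop = pm[0] - pm[-1]
        assert pdrop < wdrop  # 1/f stays flatter

    def test_sigma_variant_needs_scale_two(self, rng):
        with pytest.raises(ValueError, match="tau >= 2"):
            ent.rcmfe(rng.standard_normal(40), variant="sigma", scales=(1,))

    def test_averaged_fuzzy_constant_zero(self):
        assert ent.averaged_fuzzy_entropy(np.ones(16)) == 0.0

    def test_averaged_fuzzy_matches_brute_force(self, rng):
        x = rng.standard_normal(16)
        got = ent.averaged_fuzzy_entropy(x, FuzzyParams(m=2, n=2, r=0.2))
        want = oracles.averaged_fuzzy_entropy(x, 2, 2, 0.2)
        assert got == pytest.approx(want, abs=1e-9)

    def test_translation_shift_zero_equals_plain_fuzzy(self, rng):
        """The T variant with zero offset is the identity operator, so its
        entropy equals the plain fuzzy entropy."""
        from ictal.features.entropy import _abs_tolerance, _transformed_phi
        x = rng.standard_normal(25)
        p = FuzzyParams()
        tol = _abs_tolerance(x, p, True)
        count = x.size - p.m
        pm = _transformed_phi(x, p.m, p.n, tol, "T", 0, count)
        pm1 = _transformed_phi(x, p.m + 1, p.n, tol, "T", 0, count)
        assert -math.log(pm1 / pm) == pytest.approx(ent.fuzzy_entropy(x),
                                                    abs=1e-12)

    def test_fractional_alpha_zero_reduces_to_fuzzy(self, rng):
        x = rng.standard_normal(30)
        assert ent.fractional_fuzzy_entropy(x, alpha=0.0) == pytest.approx(
            ent.fuzzy_entropy(x), abs=1e-12)

    def test_fractional_constant_signal_closed_form(self):
        from scipy.special import digamma, gamma
        for alpha in (0.2, 0.5, 0.9):
            got = ent.fractional_fuzzy_entropy(np.full(20, 2.0), alpha=alpha)
            expect = -(digamma(1) - digamma(1 - alpha)) / gamma(1 + alpha)
            assert got == pytest.approx(float(expect), abs=1e-12)

    def test_fractional_matches_chained_oracle(self, rng):
        from scipy.special import digamma, gamma
        x = rng.standard_normal(30)
        alpha = 0.5
        fe = oracles.fuzzy_entropy(x, 2, 2, 0.2)
        rho = math.exp(-fe)
        expect = -(rho**-alpha) * (math.log(rho) + digamma(1)
                                   - digamma(1 - alpha)) / gamma(1 + alpha)
        got = ent.fractional_fuzzy_entropy(x, FuzzyParams(), alpha=alpha)
        assert got == pytest.approx(float(expect), abs=1e-9)

    def test_fractional_alpha_domain(self, rng):
        with pytest.raises(ValueError):
            ent.fractional_fuzzy_entropy(rng.standard_normal(20), alpha=1.0)


class TestInherentFuzzy:
    def test_emd_completeness(self, rng):
        from ictal.features.emd import emd
        x = rng.standard_normal(256)
        parts = emd(x)
        assert np.max(np.abs(np.sum(parts, axis=0) - x)) < 1e-8

    def test_pure_sinusoid_first_imf_dominates(self):
        from ictal.features.emd import emd
        t = np.linspace(0, 4, 512)
        x = np.sin(2 * np.pi * 5 * t)
        parts = emd(x)
        energies = [np.sum(p**2) for p in parts]
        assert energies[0] / np.sum(x**2) >= 0.95

    def test_trend_removal(self):
        from ictal.features.emd import trend_removed
        t = np.linspace(0, 4, 512)
        slope = 3.0
        x = np.sin(2 * np.pi * 6 * t) + slope * t
        xh = trend_removed(x)
        fit = np.polyfit(t, xh, 1)[0]
        assert abs(fit) < 0.05 * slope

    def test_monotone_input_rejected(self):
        with pytest.raises(ValueError, match="oscillatory"):
            ent.inherent_fuzzy_entropy(np.arange(128, dtype=float))

    def test_scale_one_equals_fuzzy_of_detrended(self, rng):
        from ictal.features.emd import trend_removed
        x = rng.standard_normal(128)
        got = ent.inherent_fuzzy_entropy(x, scales=(1,))[0]
        xh = trend_removed(x)
        assert got == pytest.approx(ent.fuzzy_entropy(xh), abs=1e-12)


class TestOrderingProperties:
    def test_noise_exceeds_sinusoid(self):
        """Mean entropy of white noise exceeds that of an equal-variance
        sinusoid for sample, permutation, fuzzy and spectral entropy."""
        fs, n = 173.6, 400
        t = np.arange(n) / fs
        sine = np.sin(2 * np.pi * 10 * t)
        sine = sine / sine.std()
        stats = {"sampen": [], "pe": [], "fuzzen": [], "spectral": []}
        for s in range(20):
            g = np.random.default_rng(s)
            w = g.standard_normal(n)
            w /= w.std()
            stats["sampen"].append(
                ent.sample_entropy(w) - ent.sample_entropy(sine))
            stats["pe"].append(ent.permutation_entropy(w)[0]
                               - ent.permutation_entropy(sine)[0])
            stats["fuzzen"].append(ent.fuzzy_entropy(w)
                                   - ent.fuzzy_entropy(sine))
            stats["spectral"].append(ent.spectral_entropy(w, fs)
                                     - ent.spectral_entropy(sine, fs))
        for name, diffs in stats.items():
            assert np.mean(diffs) > 0, name

    def test_determinism(self, rng):
        x = rng.standard_normal(100)
        for fn in (lambda: ent.fuzzy_entropy(x),
                   lambda: ent.sample_entropy(x),
                   lambda: ent.graph_entropy(x),
                   lambda: ent.permutation_entropy(x)[0]):
            assert fn() == fn()
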