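import numpy as np
import pytest

from imspeech.emd import (DirectionSet, InsufficientExtremaError, direction_set,
                          emd, envelope, find_extrema, imf_dominant_frequency,
                          mean_envelope, memd, multivariate_envelope, na_memd,
                          sift)
from imspeech.io import ConfigurationError
from imspeech.synthetic import generate_tone_mixture


def smooth_random_signal(rng, n=512, n_components=6):
    """Random band-limited signal: a handful of incommensurate sinusoids."""
    t = np.arange(n) / n
    freqs = rng.uniform(3, 60, n_components)
    amps = rng.uniform(0.3, 1.0, n_components)
    phases = rng.uniform(0, 2 * np.pi, n_components)
    return sum(a * np.sin(2 * np.pi * f * t + p)
               for f, a, p in zip(freqs, amps, phases))


def zero_crossings(x):
    return int(np.sum(np.abs(np.diff(np.sign(x[x != 0]))) > 0))


def dominant_imf_for(imfset, channel, freq, rate):
    """Index of the IMF whose dominant frequency is closest to ``freq``."""
    doms = [imf_dominant_frequency(imfset.imfs[channel, i], rate)
            for i in range(imfset.n_imfs)]
    return int(np.argmin(np.abs(np.array(doms) - freq)))


class TestFindExtrema:
    def test_sinusoid_extrema_counts(self):
        t = np.arange(250) / 250.0
        x = np.sin(2 * np.pi * 5 * t)
        maxima, minima = find_extrema(x)
        assert abs(len(maxima) - 5) <= 1
        assert abs(len(minima) - 5) <= 1
        assert np.all(x[maxima] > 0.99)

    def test_monotone_and_constant_have_no_extrema(self):
        maxima, minima = find_extrema(np.linspace(0, 1, 50))
        assert maxima.size == 0 and minima.size == 0
        maxima, minima = find_extrema(np.ones(50))
        assert maxima.size == 0 and minima.size == 0

    def test_plateau_resolved_to_midpoint(self):
        x = np.array([0, 1, 2, 2, 2, 1, 0, -1, -1, 0], dtype=float)
        maxima, minima = find_extrema(x)
        assert list(maxima) == [3]  # midpoint of samples 2..4
        assert list(minima) == [7]  # midpoint of samples 7..8

    def test_extrema_interleave(self, rng):
        x = smooth_random_signal(rng)
        maxima, minima = find_extrema(x)
        merged = sorted([(i, "M") for i in maxima] + [(i, "m") for i in minima])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestEnvelope:
    def test_two_knots_give_line(self):
        x = np.zeros(11)
        x[2], x[8] = 1.0, 3.0
        env = envelope(x, np.array([2, 8]))
        assert env[5] == pytest.approx(2.0)
        assert np.allclose(env[2:9], np.linspace(1.0, 3.0, 7))

    def test_matches_reference_natural_spline(self, rng):
        """The envelope is exactly the natural cubic spline through the
        knots (independent oracle: scipy's CubicSpline)."""
        from scipy.interpolate import CubicSpline

        x = rng.standard_normal(120)
        knots = np.sort(rng.choice(np.arange(120), size=9, replace=False))
        env = envelope(x, knots)
        ref = CubicSpline(knots, x[knots], bc_type="natural")(np.arange(120))
        assert np.abs(env - ref).max() < 1e-10

    def test_cubic_polynomial_reproduced_away_from_ends(self):
        """Spline interpolation of a cubic is exact up to the natural end
        conditions, whose influence decays geometrically with knot count:
        knots at the ends, polynomial recovered in the interior."""
        t = np.arange(211, dtype=float)
        poly = 1e-4 * t ** 3 - 0.01 * t ** 2 + 0.3 * t - 2
        knots = np.arange(0, 211, 7)
        env = envelope(poly, knots)
        interior = slice(70, 141)
        assert np.abs(env[interior] - poly[interior]).max() < 1e-6
        assert np.abs(env[knots] - poly[knots]).max() < 1e-9

    def test_sinusoid_upper_envelope_flat(self):
        t = np.arange(1000) / 250.0
        x = 2.0 * np.sin(2 * np.pi * 8 * t)
        maxima, _ = find_extrema(x)
        env = envelope(x, maxima)
        interior = env[maxima[0]:maxima[-1]]
        assert interior.std() < 0.05 * 2.0

    def test_single_knot_rejected(self):
        with pytest.raises(InsufficientExtremaError):
            envelope(np.zeros(10), np.array([4]))


class TestMeanEnvelope:
    def test_zero_mean_sinusoid_envelope_mean_near_zero(self):
        t = np.arange(1000) / 250.0
        x = np.sin(2 * np.pi * 8 * t)
        pair = mean_envelope(x)
        interior = slice(100, -100)
        assert np.abs(pair.mean[interior]).max() < 0.02

    def test_constant_shift_equivariance(self):
        t = np.arange(1000) / 250.0
        x = np.sin(2 * np.pi * 8 * t)
        m0 = mean_envelope(x).mean
        m3 = mean_envelope(x + 3.0).mean
        assert np.allclose(m3 - m0, 3.0, atol=1e-9)

    def test_mean_is_elementwise_average(self, rng):
        x = smooth_random_signal(rng)
        pair = mean_envelope(x)
        assert np.array_equal(pair.mean, (pair.upper + pair.lower) / 2)

    def test_monotone_signal_signals_residue(self):
        with pytest.raises(InsufficientExtremaError):
            mean_envelope(np.linspace(0, 1, 100))


class TestSift:
    def test_sinusoid_is_already_an_imf(self):
        t = np.arange(500) / 250.0
        x = np.sin(2 * np.pi * 10 * t)
        d = sift(x)
        assert np.corrcoef(d, x)[0, 1] > 0.99

    def test_detail_satisfies_imf_counting_rule(self, rng):
        hits = 0
        for i in range(10):
            x = smooth_random_signal(np.random.default_rng(100 + i))
            d = sift(x)
            maxima, minima = find_extrema(d)
            if abs((maxima.size + minima.size) - zero_crossings(d)) <= 1:
                hits += 1
        assert hits >= 9


class TestEMD:
    def test_two_tone_separation(self, two_tone_channel):
        x, _ = two_tone_channel
        s = emd(x, source_rate=250.0)
        t = np.arange(x.size) / 250.0
        fast = np.sin(2 * np.pi * 50 * t)
        slow = np.sin(2 * np.pi * 5 * t)
        assert abs(np.corrcoef(s.imfs[0, 0], fast)[0, 1]) > 0.95
        assert abs(np.corrcoef(s.imfs[0, 1], slow)[0, 1]) > 0.95

    def test_completeness_on_random_signals(self):
        for i in range(20):
            rng = np.random.default_rng(i)
            x = smooth_random_signal(rng) + 0.1 * rng.standard_normal(512)
            s = emd(x)
            err = np.abs(s.reconstruct()[0] - x).max()
            assert err < 1e-8 * max(1.0, np.abs(x).max())

    def test_linear_ramp_is_pure_residue(self):
        x = np.linspace(0, 5, 200)
        s = emd(x)
        assert s.n_imfs == 0
        assert np.array_equal(s.residue[0], x)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ConfigurationError):
            emd(np.zeros(8))


class TestDirectionSet:
    def test_uniform_angle_2d(self):
        ds = direction_set(2, 4, scheme="uniform_angle")
        expected = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], dtype=float)
        assert np.allclose(ds.vectors, expected, atol=1e-12)

    @pytest.mark.parametrize("dim,K", [(2, 8), (3, 64), (5, 64), (9, 128)])
    def test_unit_norms_and_distinct(self, dim, K):
        ds = direction_set(dim, K)
        norms = np.linalg.norm(ds.vectors, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)
        assert np.unique(np.round(ds.vectors, 9), axis=0).shape[0] == K

    def test_k_less_than_dim_rejected(self):
        with pytest.raises(ConfigurationError):
            direction_set(5, 3)

    def test_more_uniform_than_random(self):
        """Low-discrepancy directions have a larger minimal pairwise angle
        than the median of i.i.d. random direction sets."""

        def min_angle(vecs):
            g = np.clip(np.abs(vecs @ vecs.T), 0, 1)
            np.fill_diagonal(g, 0)
            return np.arccos(g.max())  # smallest angle between any pair

        ours = min_angle(direction_set(3, 64).vectors)
        rng = np.random.default_rng(0)
        rand_angles = []
        for _ in range(100):
            v = rng.standard_normal((64, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            rand_angles.append(min_angle(v))
        assert ours > np.median(rand_angles)


@pytest.fixture(scope="module")
def two_tone_4ch():
    rec, _ = generate_tone_mixture([5.0, 50.0], [1.0, 1.0], 2.048, 250.0, 4)
    return rec.data


@pytest.fixture(scope="module")
def replicated():
    rec, _ = generate_tone_mixture([5.0, 50.0], [1.0, 1.0], 2.048, 250.0, 1)
    return np.tile(rec.data, (4, 1))


class TestMEMD:
    def test_cross_channel_mode_alignment(self, two_tone_4ch):
        s = memd(two_tone_4ch, n_directions=16, source_rate=250.0)
        fast_idx = [dominant_imf_for(s, c, 50.0, 250.0) for c in range(4)]
        slow_idx = [dominant_imf_for(s, c, 5.0, 250.0) for c in range(4)]
        assert len(set(fast_idx)) == 1
        assert len(set(slow_idx)) == 1
        assert fast_idx[0] < slow_idx[0]

    def test_per_channel_completeness(self, two_tone_4ch):
        s = memd(two_tone_4ch, n_directions=16, source_rate=250.0)
        err = np.abs(s.reconstruct() - two_tone_4ch).max()
        assert err < 1e-8 * np.abs(two_tone_4ch).max()

    def test_single_common_oscillation_concentrates_energy(self):
        rec, _ = generate_tone_mixture([10.0], [1.0], 2.0, 250.0, 3)
        s = memd(rec.data, n_directions=16, source_rate=250.0)
        energies = (s.imfs ** 2).sum(axis=(0, 2))
        assert energies[0] / energies.sum() > 0.9

    def test_envelope_mean_is_average_of_curves(self, two_tone_4ch):
        dirs = direction_set(4, 16)
        env = multivariate_envelope(two_tone_4ch, dirs)
        assert np.allclose(env.mean, env.curves.mean(axis=0), atol=1e-12)

    def test_reduces_to_emd_with_opposite_directions(self, two_tone_channel):
        """A 1-D embedding with directions {+1, -1} makes the multivariate
        local mean identical to the univariate envelope mean, so the
        decompositions agree."""
        x, _ = two_tone_channel
        dirs = DirectionSet(vectors=np.array([[1.0], [-1.0]]), scheme="manual")
        sm = memd(x[None, :], directions=dirs, source_rate=250.0)
        su = emd(x, source_rate=250.0)
        assert sm.n_imfs == su.n_imfs
        for i in range(su.n_imfs):
            assert np.allclose(sm.imfs[0, i], su.imfs[0, i], atol=1e-9)


class TestNAMEMD:
    def test_noise_channels_discarded(self, replicated):
        s = na_memd(replicated, q=1, n_directions=16, seed=0, source_rate=250.0)
        assert s.n_channels == 4

    def test_deterministic_under_seed(self, replicated):
        a = na_memd(replicated, q=1, n_directions=16, seed=7, source_rate=250.0)
        b = na_memd(replicated, q=1, n_directions=16, seed=7, source_rate=250.0)
        assert np.array_equal(a.imfs, b.imfs)

    def test_zero_variance_channel_rejected(self):
        x = np.vstack([np.zeros(256), np.random.default_rng(0).standard_normal(256)])
        with pytest.raises(ConfigurationError):
            na_memd(x, q=1)

    def test_noise_forces_at_least_as_many_modes(self, replicated):
        plain = memd(replicated, n_directions=16, source_rate=250.0)
        assisted = na_memd(replicated, q=1, n_directions=16, seed=0,
                           source_rate=250.0)
        assert assisted.n_imfs >= plain.n_imfs


class TestDominantFrequency:
    def test_sinusoid_frequency_recovered(self):
        t = np.arange(500) / 250.0
        x = np.sin(2 * np.pi * 50 * t)
        assert imf_dominant_frequency(x, 250.0) == pytest.approx(50.0, abs=0.5)

    def test_zero_signal_undefined(self):
        assert np.isnan(imf_dominant_frequency(np.zeros(100), 250.0))

    def test_white_noise_filter_bank_ordering(self):
        """NA-MEMD acts as a quasi-dyadic filter bank on white noise: every
        channel's successive IMFs occupy strictly lower bands (the added
        noise channel is what stabilizes this ordering)."""
        x = np.random.default_rng(0).standard_normal((2, 1024))
        s = na_memd(x, q=1, n_directions=16, seed=50, source_rate=250.0)
        for c in range(2):
            doms = [imf_dominant_frequency(s.imfs[c, i], 250.0)
                    for i in range(s.n_imfs)]
            assert all(a > b for a, b in zip(doms, doms[1:]))
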