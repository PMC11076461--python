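"""wPLI and AEC-c estimator contracts, analytic limits and null behavior."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import hilbert

from eegmst import (
    ConnectivityMatrix,
    EpochSet,
    aec_matrix,
    aec_pair,
    analytic_signal,
    band_by_name,
    global_mean_connectivity,
    orthogonalize,
    wpli_matrix,
    wpli_pair,
)
from eegmst.connectivity import _aec_epoch

FS = 512.0


def carrier(freq, n=4096, fs=FS, phase=0.0):
    t = np.arange(n) / fs
    return np.cos(2 * np.pi * freq * t + phase)


def narrowband(rng, band, n=4096, fs=FS):
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, rng.standard_normal(n))


def make_epochs(data_per_epoch, band_name="alpha"):
    arr = np.asarray(data_per_epoch, dtype=float)
    arr = arr - arr.mean(axis=-1, keepdims=True)
    labels = tuple(f"C{i}" for i in range(arr.shape[1]))
    return EpochSet(band=band_by_name(band_name), fs=FS, epochs=arr, channel_labels=labels)


class TestAnalyticSignal:
    def test_unit_cosine_has_unit_envelope(self):
        z = analytic_signal(carrier(10.0))
        env = np.abs(z)[200:-200]
        assert np.allclose(env, 1.0, atol=0.01)
        np.testing.assert_allclose(z.real, carrier(10.0), atol=1e-10)

    def test_envelope_scales_with_amplitude(self):
        z = analytic_signal(3.5 * carrier(10.0))
        assert np.allclose(np.abs(z)[200:-200], 3.5, atol=0.05)

    def test_phase_advances_at_carrier_rate(self):
        z = analytic_signal(carrier(10.0))
        dphi = np.diff(np.unwrap(np.angle(z)))[200:-200]
        assert np.allclose(dphi, 2 * np.pi * 10.0 / FS, atol=1e-3)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            analytic_signal(np.array([1.0, np.nan, 2.0]))


class TestWpliPair:
    def test_constant_lag_gives_one(self):
        n = 1024
        zi = np.exp(1j * np.linspace(0, 40 * np.pi, n))
        zj = zi * np.exp(-1j * np.pi / 4)
        assert wpli_pair(zi, zj) == pytest.approx(1.0)

    def test_zero_lag_gives_zero(self):
        z = analytic_signal(carrier(10.0))
        assert wpli_pair(z, z) == 0.0

    def test_alternating_imaginary_parts(self):
        # Im terms +2, -1 in equal proportion: |mean| = 0.5, mean|.| = 1.5
        zi = np.ones(8, dtype=complex)
        zj = np.empty(8, dtype=complex)
        zj[::2] = 1.0 - 2.0j   # Im(zi conj(zj)) = +2
        zj[1::2] = 1.0 + 1.0j  # Im(zi conj(zj)) = -1
        assert wpli_pair(zi, zj) == pytest.approx(1.0 / 3.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            wpli_pair(np.ones(4, complex), np.ones(5, complex))

    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 100))
    def test_amplitude_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        zi = analytic_signal(narrowband(rng, band_by_name("alpha")))
        zj = analytic_signal(narrowband(rng, band_by_name("alpha")))
        w = wpli_pair(zi, zj)
        assert 0.0 <= w <= 1.0
        assert wpli_pair(scale * zi, zj) == pytest.approx(w, rel=1e-9)


class TestWpliMatrix:
    def test_phase_delayed_channel_detected(self):
        """A channel pair with ~pi/2 lag at band center shows near-maximal
        wPLI; averaged over seeds it exceeds 0.8."""
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            epochs = []
            for _ in range(3):
                z = hilbert(narrowband(rng, band_by_name("alpha")))
                a = z.real
                b = (z * np.exp(-1j * np.pi / 2)).real
                epochs.append([a, b])
            m = wpli_matrix(make_epochs(epochs))
            vals.append(m.values[0, 1])
        assert np.mean(vals) > 0.8

    def test_independent_noise_null_level(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            epochs = [
                [narrowband(rng, band_by_name("alpha")) for _ in range(2)]
                for _ in range(7)
            ]
            m = wpli_matrix(make_epochs(epochs))
            vals.append(m.values[0, 1])
        assert np.mean(vals) < 0.2

    def test_duplicated_channel_is_zero(self):
        rng = np.random.default_rng(7)
        x = narrowband(rng, band_by_name("alpha"))
        m = wpli_matrix(make_epochs([[x, x]]))
        assert m.values[0, 1] == 0.0

    def test_matrix_matches_pairwise_estimator(self):
        rng = np.random.default_rng(8)
        epochs = np.array([
            [narrowband(rng, band_by_name("alpha")) for _ in range(4)]
            for _ in range(3)
        ])
        m = wpli_matrix(make_epochs(epochs))
        es = make_epochs(epochs)
        expected = np.zeros((4, 4))
        for e in range(3):
            z = [analytic_signal(es.epochs[e, c]) for c in range(4)]
            for i in range(4):
                for j in range(i + 1, 4):
                    expected[i, j] += wpli_pair(z[i], z[j]) / 3
        expected += expected.T
        np.testing.assert_allclose(m.values, expected, atol=1e-12)


class TestOrthogonalize:
    def test_collinear_residual_vanishes(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(1000)
        assert np.abs(orthogonalize(x, 2 * x)).max() < 1e-10

    def test_orthogonal_input_unchanged(self):
        n = 1000
        x = carrier(10.0, n)
        y = np.sin(2 * np.pi * 10.0 * np.arange(n) / FS)  # quadrature
        out = orthogonalize(x, y)
        np.testing.assert_allclose(out, y - y.mean(), atol=1e-3)

    def test_residual_uncorrelated_with_regressor(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(5000)
        y = 0.7 * x + rng.standard_normal(5000)
        r = orthogonalize(x, y)
        assert abs(np.corrcoef(x, r)[0, 1]) < 1e-10

    def test_recovers_independent_component(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(50_000)
        n = rng.standard_normal(50_000)
        r = orthogonalize(x, x + n)
        assert np.corrcoef(n, r)[0, 1] > 0.99

    def test_zero_regressor_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            orthogonalize(np.zeros(10), np.ones(10))


class TestAecPair:
    def test_identical_signals_give_zero(self):
        rng = np.random.default_rng(12)
        x = narrowband(rng, band_by_name("alpha"))
        assert aec_pair(x, x) == 0.0

    def test_shared_envelope_orthogonal_carriers(self):
        """Quadrature carriers sharing one slow envelope: orthogonalization
        leaves the envelope intact, so the correlation is near 1."""
        n = 4096
        t = np.arange(n) / FS
        m = 1.0 + 0.5 * np.sin(2 * np.pi * 0.4 * t)
        x = m * np.cos(2 * np.pi * 10 * t)
        y = m * np.sin(2 * np.pi * 10 * t)
        assert aec_pair(x, y) > 0.9

    def test_independent_noise_null(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            x = narrowband(rng, band_by_name("alpha"))
            y = narrowband(rng, band_by_name("alpha"))
            vals.append(abs(aec_pair(x, y)))
        assert np.mean(vals) < 0.1

    def test_zero_lag_mixture_of_one_source_suppressed(self):
        """Two zero-lag mixtures of a single source: the leakage-correction
        contract — AEC-c stays near zero, and wPLI is exactly zero."""
        vals_aec, vals_wpli = [], []
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            s = narrowband(rng, band_by_name("alpha"))
            a, b = 1.0 * s, 0.6 * s
            vals_aec.append(abs(aec_pair(a, b)))
            vals_wpli.append(wpli_pair(analytic_signal(a), analytic_signal(b)))
        assert np.mean(vals_aec) < 0.1
        assert np.max(vals_wpli) == 0.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(13)
        x = narrowband(rng, band_by_name("alpha"))
        y = 0.5 * x + narrowband(rng, band_by_name("alpha"))
        assert aec_pair(x, y) == pytest.approx(aec_pair(y, x), abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="16 samples"):
            aec_pair(np.ones(8), np.ones(8))


class TestAecMatrix:
    def test_vectorized_matrix_matches_pairwise_estimator(self):
        """The epoch-matrix fast path (analytic-signal linearity) agrees with
        the definitional pairwise estimator to machine precision."""
        rng = np.random.default_rng(14)
        data = np.stack([narrowband(rng, band_by_name("alpha")) for _ in range(5)])
        data[1] += 0.4 * data[0]  # add some leakage structure
        data = data - data.mean(axis=1, keepdims=True)
        fast = _aec_epoch(data)
        for i in range(5):
            for j in range(i + 1, 5):
                assert fast[i, j] == pytest.approx(
                    aec_pair(data[i], data[j]), abs=1e-10
                )

    def test_envelope_coupled_pair_dominates(self):
        rng = np.random.default_rng(15)
        n = 4096
        t = np.arange(n) / FS
        epochs = []
        for _ in range(5):
            m = 1.0 + 0.6 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
            ch0 = m * narrowband(rng, band_by_name("alpha"))
            ch1 = m * narrowband(rng, band_by_name("alpha"))
            ch2 = narrowband(rng, band_by_name("alpha"))
            epochs.append([ch0, ch1, ch2])
        m = aec_matrix(make_epochs(epochs))
        assert m.values[0, 1] > m.values[0, 2]
        assert m.values[0, 1] > m.values[1, 2]


class TestGlobalMean:
    def test_constant_matrix(self):
        vals = np.full((4, 4), 0.3)
        np.fill_diagonal(vals, 0.0)
        m = ConnectivityMatrix("wPLI", None, vals, ("a", "b", "c", "d"))
        assert global_mean_connectivity(m) == pytest.approx(0.3)

    def test_three_channel_mean(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 0.2
        vals[0, 2] = vals[2, 0] = 0.4
        vals[1, 2] = vals[2, 1] = 0.6
        m = ConnectivityMatrix("wPLI", None, vals, ("a", "b", "c"))
        assert global_mean_connectivity(m) == pytest.approx(0.4)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(16)
        v = rng.uniform(0, 1, (5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        labels = tuple("abcde")
        m = ConnectivityMatrix("wPLI", None, v, labels)
        perm = [3, 1, 4, 0, 2]
        mp = ConnectivityMatrix(
            "wPLI", None, v[np.ix_(perm, perm)], tuple(labels[i] for i in perm)
        )
        assert global_mean_connectivity(m) == pytest.approx(
            global_mean_connectivity(mp)
        )


class TestMatrixInvariants:
    def test_symmetry_and_zero_diagonal_enforced(self):
        bad = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ConnectivityMatrix("wPLI", None, bad, ("a", "b"))
        bad2 = np.array([[0.5, 0.2], [0.2, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            ConnectivityMatrix("wPLI", None, bad2, ("a", "b"))
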