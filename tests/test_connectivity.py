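"""Phase extraction, phase lag index, connectivity matrices and the
edgewise group comparison."""

import math

import numpy as np
import pytest
from scipy.signal import hilbert

from ebnt import (ConnectivityMatrix, Recording, band_by_name, band_segments,
                  connectivity_matrix, coupled_pairs,
                  edgewise_group_comparison, generate_cohort, global_mean_pli,
                  instantaneous_phase, pli, segment)

from conftest import sinusoid


def brute_force_pli(x, y):
    """Independent re-implementation: explicit per-sample loop over the
    phase-difference series with three-valued sign."""
    phix = np.angle(hilbert(x))
    phiy = np.angle(hilbert(y))
    total = 0.0
    for a, b in zip(phix, phiy):
        d = a - b
        while d <= -math.pi:
            d += 2 * math.pi
        while d > math.pi:
            d -= 2 * math.pi
        total += float(d > 0) - float(d < 0)
    return abs(total / len(phix))


class TestInstantaneousPhase:
    def test_phase_slope_matches_frequency(self):
        x = sinusoid(10, duration=5.0)
        phase = np.unwrap(instantaneous_phase(x))
        core = slice(100, -100)
        slope = np.polyfit(np.arange(1250)[core] / 250.0, phase[core], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10, rel=0.01)

    def test_quadrature_pair(self):
        t = np.arange(0, 5, 1 / 250)
        d = instantaneous_phase(np.cos(2 * np.pi * 10 * t)) \
            - instantaneous_phase(np.sin(2 * np.pi * 10 * t))
        d = np.angle(np.exp(1j * d))  # wrap to (-pi, pi]
        core = slice(50, -50)
        np.testing.assert_allclose(d[core], np.pi / 2, atol=0.05)

    def test_negation_shifts_by_pi(self):
        x = sinusoid(10)
        d = np.abs(np.angle(np.exp(
            1j * (instantaneous_phase(x) - instantaneous_phase(-x)))))
        core = slice(50, -50)
        np.testing.assert_allclose(d[core], np.pi, atol=0.05)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros(100))


class TestPLI:
    def test_consistent_lag_gives_one(self):
        x = sinusoid(10)
        y = sinusoid(10, phase=np.pi / 4)
        assert pli(x, y) == 1.0

    def test_zero_lag_gives_zero(self):
        x = sinusoid(10)
        assert pli(x, x) == 0.0

    def test_independent_noise_near_zero_and_matches_oracle(self, rng):
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        value = pli(x, y)
        assert value < 0.05
        assert value == pytest.approx(brute_force_pli(x, y), abs=1e-12)

    def test_symmetry_and_amplitude_invariance(self, rng):
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        assert pli(x, y) == pytest.approx(pli(y, x), abs=1e-12)
        assert pli(3.7 * x, y) == pytest.approx(pli(x, y), abs=1e-12)
        assert 0 <= pli(x, y) <= 1

    def test_lagged_quadrature_locked_for_any_length(self):
        # one full cycle upward: perfect locking regardless of length
        for duration in (0.2, 1.0, 3.0):
            x = sinusoid(10, duration=duration)
            y = sinusoid(10, duration=duration, phase=np.pi / 2)
            assert pli(x, y) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pli(np.ones(10), np.ones(11))


class TestConnectivityMatrix:
    def _segmented(self, data, fs=250.0, seg_len=1.0):
        rec = Recording("s", data, fs)
        return segment(rec, seg_len, band=band_by_name("alpha"))

    def test_single_segment_equals_pairwise_pli(self, rng):
        data = rng.standard_normal((3, 500))
        cm = connectivity_matrix(self._segmented(data, seg_len=2.0))
        for i in range(3):
            for j in range(i + 1, 3):
                assert cm.matrix[i, j] == \
                    pytest.approx(pli(data[i], data[j]), abs=1e-12)

    def test_identical_segments_average_to_single(self, rng):
        data = rng.standard_normal((3, 250))
        twice = np.hstack([data, data])
        cm1 = connectivity_matrix(self._segmented(data))
        cm2 = connectivity_matrix(self._segmented(twice))
        np.testing.assert_allclose(cm1.matrix, cm2.matrix, atol=1e-12)
        assert cm2.n_segments_averaged == 2

    def test_mean_over_segments_matches_brute_force(self, rng):
        data = rng.standard_normal((3, 750))
        seg = self._segmented(data)  # 3 segments of 250
        cm = connectivity_matrix(seg)
        for i in range(3):
            for j in range(i + 1, 3):
                expected = np.mean([brute_force_pli(s[i], s[j])
                                    for s in seg.segments])
                assert cm.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_matrix_symmetric_zero_diagonal_in_unit_interval(self, rng):
        data = rng.standard_normal((4, 1000))
        m = connectivity_matrix(self._segmented(data)).matrix
        np.testing.assert_array_equal(m, m.T)
        np.testing.assert_array_equal(np.diag(m), 0.0)
        assert np.all((m >= 0) & (m <= 1))


class TestGlobalMeanPLI:
    def _cm(self, matrix):
        return ConnectivityMatrix("s", "alpha", matrix, 1)

    def test_constant_off_diagonal(self):
        m = np.full((5, 5), 0.3)
        np.fill_diagonal(m, 0.0)
        assert global_mean_pli(self._cm(m)) == pytest.approx(0.3)

    def test_three_channel_arithmetic(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.1
        m[0, 2] = m[2, 0] = 0.2
        m[1, 2] = m[2, 1] = 0.3
        assert global_mean_pli(self._cm(m)) == pytest.approx(0.2)

    def test_matches_loop_over_pairs(self, rng):
        from conftest import random_symmetric_matrix
        m = random_symmetric_matrix(7, rng, high=0.9)
        total, count = 0.0, 0
        for i in range(7):
            for j in range(i + 1, 7):
                total += m[i, j]
                count += 1
        assert global_mean_pli(self._cm(m)) == \
            pytest.approx(total / count, abs=1e-12)


class TestEdgewiseComparison:
    def _matrices(self, values):
        """values: subjects x edges for a 3-channel net."""
        out = []
        iu = np.triu_indices(3, 1)
        for k, v in enumerate(values):
            m = np.zeros((3, 3))
            m[iu] = v
            m += m.T
            out.append(ConnectivityMatrix(f"s{k}", "alpha", m, 1))
        return out

    def test_identical_groups_yield_nothing(self, rng):
        vals = rng.uniform(0.1, 0.5, size=(3, 3))
        g = self._matrices(vals)
        res = edgewise_group_comparison(g, self._matrices(vals))
        assert not res.significant.any()

    def test_hand_computed_t(self):
        g1 = self._matrices([[0.1, 0.15, 0.5], [0.2, 0.25, 0.5],
                             [0.3, 0.35, 0.5]])
        g2 = self._matrices([[0.4, 0.45, 0.5], [0.5, 0.55, 0.5],
                             [0.6, 0.65, 0.5]])
        res = edgewise_group_comparison(g1, g2)
        # edge 0: {.1,.2,.3} vs {.4,.5,.6} -> pooled t = -3.674
        assert res.t_stat[0] == pytest.approx(-3.674, abs=0.001)
        assert res.p_raw[0] == pytest.approx(0.0214, abs=0.001)
        assert res.sign[0] == -1
        # edge 2 is constant across everyone -> degenerate, not tested
        assert res.degenerate[2]
        assert np.isnan(res.t_stat[2])

    def test_ground_truth_recovery_on_synthetic_cohort(self,
                                                       small_cohort_config):
        cfg = small_cohort_config
        cfg.n_subjects_per_group = 6
        recs = generate_cohort(cfg)
        band = band_by_name("alpha")
        cms = {1: [], 2: []}
        for r in recs:
            cms[r.group].append(connectivity_matrix(band_segments(r, band)))
        res = edgewise_group_comparison(cms[1], cms[2])
        found = res.significant_edges()
        assert found, "expected some significant edges"
        truth = set(coupled_pairs(cfg)["alpha"])
        n_true = sum(e in truth for e in found)
        # majority of detected edges are truly coupled, and the group-1
        # mean exceeds group 2 on them
        assert n_true / len(found) > 0.5
        idx = [k for k, e in enumerate(res.edges) if e in set(found)]
        assert (res.sign[idx] == 1).mean() > 0.9

    def test_needs_two_subjects_per_group(self):
        g = self._matrices([[0.1, 0.2, 0.3]])
        with pytest.raises(ValueError):
            edgewise_group_comparison(g, g)
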