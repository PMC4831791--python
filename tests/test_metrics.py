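import math

import numpy as np
import pytest

from shmoo.metrics import (
    SimResult,
    accuracy,
    cap_angle,
    is_polarized,
    polarization_time,
    window_fractions,
)
from shmoo.mesh import window_size


def seg_angle(j, n=60):
    return (j + 0.5) * 2 * math.pi / n


class TestIsPolarized:
    def test_uniform_is_not_polarized(self):
        flag, _ = is_polarized(np.ones(60))
        assert not flag

    def test_point_mass_is_polarized(self):
        mu = np.zeros(60)
        mu[13] = 1.0
        flag, start = is_polarized(mu)
        assert flag
        w = window_size(60, 0.1)
        assert 13 in set((start + np.arange(w)) % 60)

    def test_exactly_half_is_strict(self):
        """A window holding exactly 50% does not qualify; epsilon more does."""
        n, w = 60, window_size(60, 0.1)
        mu = np.ones(n)
        # put exactly half the total in one window: window sum = s*w, rest
        # (n-w) cells hold the other half
        s = (n - w) / w
        mu[:w] = s
        fr = window_fractions(mu)
        assert fr.max() == pytest.approx(0.5, abs=1e-12)
        assert not is_polarized(mu)[0]
        mu[0] += 1e-6
        assert is_polarized(mu)[0]

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            mu = rng.exponential(size=40) ** 3
            w = window_size(40, 0.1)
            brute = max(
                sum(mu[(s + k) % 40] for k in range(w)) for s in range(40)
            ) / mu.sum()
            assert is_polarized(mu)[0] == (brute > 0.5)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            is_polarized(np.zeros(60))

    def test_mass_transfer_into_best_window_monotone(self):
        rng = np.random.default_rng(6)
        mu = rng.uniform(0.5, 2.0, 60)
        mu[10:16] *= 30  # polarized around segment 12
        assert is_polarized(mu)[0]
        _, start = is_polarized(mu)
        w = window_size(60, 0.1)
        donor = (start + w + 5) % 60
        mu2 = mu.copy()
        mu2[(start + 2) % 60] += mu2[donor]
        mu2[donor] = 0.0
        assert is_polarized(mu2)[0]


class TestCapAngle:
    def test_point_mass_angle(self):
        mu = np.zeros(60)
        mu[19] = 2.0
        assert cap_angle(mu) == pytest.approx(seg_angle(19), abs=1e-12)

    def test_symmetric_bump_centred(self):
        # bump centred on a segment edge so the even-width winning window
        # can sit symmetrically around it
        n = 60
        theta = np.array([seg_angle(j, n) for j in range(n)])
        theta0 = 2 * math.pi * 30 / n
        mu = np.exp(np.cos(theta - theta0) * 40)
        assert cap_angle(mu) == pytest.approx(theta0, abs=1e-10)

    def test_two_segment_weighted_mean(self):
        mu = np.zeros(60)
        mu[10], mu[11] = 2.0, 1.0
        z = 2 * np.exp(1j * seg_angle(10)) + 1 * np.exp(1j * seg_angle(11))
        assert cap_angle(mu) == pytest.approx(float(np.angle(z)) % (2 * math.pi))

    def test_unpolarized_rejected(self):
        with pytest.raises(ValueError):
            cap_angle(np.ones(60))

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(2)
        mu = rng.uniform(0, 1, 60)
        mu[5:11] += 50
        k = 17
        shift = k * 2 * math.pi / 60
        a1 = cap_angle(mu)
        a2 = cap_angle(np.roll(mu, k))
        assert (a2 - a1) % (2 * math.pi) == pytest.approx(shift, abs=1e-9)


class TestAccuracy:
    def test_perfect_alignment(self):
        assert accuracy([0.3, 0.3], 0.3) == pytest.approx(1.0)

    def test_opposed_pair_cancels(self):
        tg = 1.0
        assert accuracy([tg + math.pi / 2, tg - math.pi / 2], tg) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_uniform_angles_average_to_zero(self):
        rng = np.random.default_rng(3)
        ang = rng.uniform(0, 2 * math.pi, 10**4)
        assert abs(accuracy(ang, 0.7)) < 0.03

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        ang = rng.uniform(0, 2 * math.pi, 100)
        d = 1.234
        assert accuracy(ang + d, 0.5 + d) == pytest.approx(accuracy(ang, 0.5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy([], 0.0)


class TestPolarizationTime:
    def test_never_polarized(self):
        kym = np.ones((5, 60))
        assert polarization_time(kym, np.arange(5.0)) is None

    def test_polarized_from_start(self):
        mu = np.zeros(60)
        mu[0] = 1.0
        kym = np.tile(mu, (4, 1))
        assert polarization_time(kym, np.arange(4.0) * 60) == 0.0

    def test_first_crossing_found(self):
        n, w = 60, window_size(60, 0.1)
        rows = []
        for k in range(6):
            mu = np.ones(n)
            mu[:w] = 1.0 + 3.0 * k  # sharpens over time
            rows.append(mu)
        kym = np.array(rows)
        times = np.arange(6.0) * 60
        t = polarization_time(kym, times)
        # brute-force scan with the same criterion
        expect = next(
            times[k] for k in range(6) if is_polarized(kym[k])[0]
        )
        assert t == expect


class TestSimResult:
    def test_flag_consistency_enforced(self):
        with pytest.raises(ValueError):
            SimResult(polarized=True, t_pol=None, cap_angle=None,
                      kymograph=None, kymograph_times=None)
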