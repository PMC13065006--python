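"""Mechanical energy computation and positive/negative work bookkeeping."""
import numpy as np
import pytest

from mechwork.energetics import (
    EnergySeries,
    WorkSummary,
    com_energy,
    cycle_work,
    limb_energies,
    positive_negative_work,
    trial_work,
)
from mechwork.signal_processing import TimeSeries


def _energy(total, rate=200.0):
    total = np.asarray(total, dtype=float)
    return EnergySeries(ke=np.zeros_like(total), pe=total, total=total,
                        rate=rate, subject_mass=70.0)


class TestComEnergy:
    def test_constant_velocity(self):
        t = np.arange(400) / 200.0
        pos = np.stack([2.0 * t, np.zeros_like(t), np.ones_like(t)], axis=1)
        e = com_energy(TimeSeries(pos, 200.0), 77.2)
        assert np.allclose(e.ke, 2.0, atol=1e-9)
        assert np.allclose(e.pe, 0.0)

    def test_raised_point_potential(self):
        z = np.concatenate([np.zeros(100), np.ones(100)])
        pos = np.stack([np.zeros(200), np.zeros(200), z], axis=1)
        e = com_energy(TimeSeries(pos, 200.0), 77.2, g=9.81)
        assert e.pe[-1] == pytest.approx(9.81)

    def test_ballistic_conservation(self):
        rate = 200.0
        t = np.arange(int(rate)) / rate
        pos = np.stack([1.5 * t, 2.0 * t, 1.0 + 4.0 * t - 0.5 * 9.81 * t**2], axis=1)
        e = com_energy(TimeSeries(pos, rate), 77.2, g=9.81)
        assert np.ptp(e.total) < 1e-3

    def test_too_short(self):
        with pytest.raises(ValueError):
            com_energy(TimeSeries(np.zeros((2, 3)), 200.0), 70.0)


class TestLimbEnergies:
    def test_rest_is_zero(self, scaled_male):
        zeros = {s.name: np.zeros((50, 3)) for s in scaled_male}
        limbs = limb_energies(zeros, zeros, scaled_male, 200.0)
        assert set(limbs) == {"legs", "arms", "trunk"}
        for e in limbs.values():
            assert np.allclose(e.total, 0.0)

    def test_single_segment_unit_velocity(self):
        from mechwork.body_model import SegmentParameters, scale_segment_parameters

        table = (SegmentParameters("solo", 1 - 1e-9, 0.5, (0.3, 0.3, 0.3), "legs"),)
        scaled = scale_segment_parameters(70.0, {"solo": 0.5}, table)
        v = {"solo": np.tile([1.0, 0, 0], (10, 1))}
        w = {"solo": np.zeros((10, 3))}
        limbs = limb_energies(v, w, scaled, 200.0)
        assert np.allclose(limbs["legs"].ke, 0.5)

    def test_matches_per_sample_resummation(self, scaled_male, rng):
        v = {s.name: rng.normal(size=(30, 3)) for s in scaled_male}
        w = {s.name: rng.normal(size=(30, 3)) for s in scaled_male}
        limbs = limb_energies(v, w, scaled_male, 200.0)
        M = sum(s.mass for s in scaled_male)
        for i in (0, 15, 29):  # brute-force oracle at a few samples
            expected = {"legs": 0.0, "arms": 0.0, "trunk": 0.0}
            for s in scaled_male:
                ke = 0.5 * s.mass * v[s.name][i] @ v[s.name][i]
                ke += 0.5 * w[s.name][i] @ (np.array(s.inertia_principal) * w[s.name][i])
                expected[s.limb_group] += ke / M
            for group, value in expected.items():
                assert limbs[group].ke[i] == pytest.approx(value, abs=1e-12)

    def test_missing_segment_kinematics(self, scaled_male):
        v = {s.name: np.zeros((10, 3)) for s in scaled_male}
        w = dict(v)
        del v["hand_l"]
        with pytest.raises(KeyError, match="hand_l"):
            limb_energies(v, w, scaled_male, 200.0)


class TestWorkBookkeeping:
    def test_hand_enumerable(self):
        w_pos, w_neg = positive_negative_work(_energy([0, 2, 1, 3]), 0, 3)
        assert (w_pos, w_neg) == (4.0, -1.0)

    def test_monotone_rise(self):
        w_pos, w_neg = positive_negative_work(_energy(np.linspace(1.0, 5.0, 20)), 0, 19)
        assert w_pos == pytest.approx(4.0)
        assert w_neg == 0.0

    def test_random_walks_match_scan_oracle(self, rng):
        for _ in range(50):
            e = rng.normal(size=300).cumsum()
            start, end = 3, 290
            w_pos, w_neg = positive_negative_work(_energy(e), start, end)
            o_pos = o_neg = 0.0  # independent sequential scan
            for i in range(start, end):
                d = e[i + 1] - e[i]
                if d > 0:
                    o_pos += d
                else:
                    o_neg += d
            assert w_pos == pytest.approx(o_pos, abs=1e-9)
            assert w_neg == pytest.approx(o_neg, abs=1e-9)
            assert w_pos + w_neg == pytest.approx(e[end] - e[start], abs=1e-9)

    def test_index_errors(self):
        e = _energy([0, 1, 2])
        with pytest.raises(IndexError):
            positive_negative_work(e, 2, 2)
        with pytest.raises(IndexError):
            positive_negative_work(e, 0, 3)


class TestCycleWork:
    @staticmethod
    def _summary(section, scale=1.0, proxies=True):
        base = dict(
            w_ext_pos=10.0 * scale, w_ext_neg=-9.0 * scale,
            w_int_pos=5.0 * scale, w_int_neg=-4.0 * scale,
            w_tot_pos=15.0 * scale, w_tot_neg=-13.0 * scale,
        )
        if proxies:
            base.update(
                w_pelvis_pos=12.0 * scale, w_pelvis_neg=-11.0 * scale,
                w_bb_pos=30.0 * scale, w_bb_neg=-28.0 * scale,
            )
        return WorkSummary(section=section, **base)

    def test_three_sets_plus_sprint(self):
        cycle = cycle_work(self._summary("groundstrokes"), self._summary("sprint", 0.5))
        assert cycle.w_ext_pos == pytest.approx(3 * 10 + 5)
        assert cycle.w_tot_neg == pytest.approx(3 * -13 + -6.5)
        assert cycle.section == "cycle"

    def test_fieldwise_oracle(self, rng):
        a = self._summary("groundstrokes", scale=float(rng.uniform(0.5, 2)))
        b = self._summary("sprint", scale=float(rng.uniform(0.5, 2)))
        cycle = cycle_work(a, b)
        for name in ("w_ext_pos", "w_int_neg", "w_pelvis_pos", "w_bb_neg"):
            assert getattr(cycle, name) == pytest.approx(
                3 * getattr(a, name) + getattr(b, name)
            )

    def test_absent_proxy_propagates(self):
        cycle = cycle_work(
            self._summary("groundstrokes", proxies=False), self._summary("sprint")
        )
        assert cycle.w_pelvis_pos is None and cycle.w_bb_neg is None

    def test_mismatched_sections(self):
        with pytest.raises(ValueError):
            cycle_work(self._summary("sprint"), self._summary("sprint"))


class TestWorkSummaryInvariants:
    def test_decomposition_enforced(self):
        with pytest.raises(ValueError, match="w_tot_pos"):
            WorkSummary(section="cycle", w_ext_pos=1.0, w_ext_neg=0.0,
                        w_int_pos=1.0, w_int_neg=0.0, w_tot_pos=3.0, w_tot_neg=0.0)

    def test_sign_conventions_enforced(self):
        with pytest.raises(ValueError, match="w_ext_neg"):
            WorkSummary(section="cycle", w_ext_pos=1.0, w_ext_neg=0.5,
                        w_int_pos=0.0, w_int_neg=0.0, w_tot_pos=1.0, w_tot_neg=0.5)


class TestTrialWork:
    def test_identical_proxies_equal_external(self, noiseless_trial, scaled_male):
        trial, truth = noiseless_trial
        clone = trial.with_kinematics(pelvis=trial.com.copy(), pseudo_com=trial.com.copy())
        gs, sprint = trial_work(clone, truth.boundaries, scaled_male)
        for s in (gs, sprint):
            assert s.w_pelvis_pos == s.w_ext_pos
            assert s.w_bb_neg == s.w_ext_neg

    def test_frozen_segments_zero_internal(self, noiseless_trial, scaled_male):
        trial, truth = noiseless_trial
        frozen = trial.with_kinematics(
            segment_positions={n: trial.com + 0.1 for n in trial.segment_positions},
            segment_angular_velocities={
                n: np.zeros_like(w) for n, w in trial.segment_angular_velocities.items()
            },
        )
        gs, sprint = trial_work(frozen, truth.boundaries, scaled_male)
        assert gs.w_int_pos == pytest.approx(0.0, abs=1e-9)
        assert sprint.w_int_neg == pytest.approx(0.0, abs=1e-9)

    def test_translation_and_datum_invariance(self, noiseless_trial, scaled_male):
        trial, truth = noiseless_trial
        gs, _ = trial_work(trial, truth.boundaries, scaled_male)
        shift = np.array([5.0, -3.0, 2.0])  # includes a height-datum change
        shifted = trial.with_kinematics(
            com=trial.com + shift,
            segment_positions={n: p + shift for n, p in trial.segment_positions.items()},
            pelvis=trial.pelvis + shift,
        )
        gs2, _ = trial_work(shifted, truth.boundaries, scaled_male)
        assert gs2.w_ext_pos == pytest.approx(gs.w_ext_pos, rel=1e-9)
        assert gs2.w_int_neg == pytest.approx(gs.w_int_neg, rel=1e-9)
        assert gs2.w_pelvis_pos == pytest.approx(gs.w_pelvis_pos, rel=1e-9)

    def test_absent_proxy_flagged_not_zero(self, noiseless_trial, scaled_male):
        trial, truth = noiseless_trial
        gs, sprint = trial_work(trial, truth.boundaries, scaled_male)
        assert gs.w_bb_pos is None  # no camera data attached
        assert gs.w_pelvis_pos is not None and gs.w_pelvis_pos > 0


def test_superimposed_sinusoid_adds_2ak():
    """A sinusoid of amplitude A over k periods adds ~2Ak of positive work."""
    rate, A, k, duration = 200.0, 1.5, 12, 6.0
    t = np.arange(int(rate * duration)) / rate
    base = np.full_like(t, 4.0)
    w_pos0, _ = positive_negative_work(_energy(base), 0, t.size - 1)
    assert w_pos0 == 0.0
    ripple = A * np.sin(2 * np.pi * (k / duration) * t)
    w_pos1, _ = positive_negative_work(_energy(base + ripple), 0, t.size - 1)
    assert w_pos1 - w_pos0 == pytest.approx(2 * A * k, rel=0.02)
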