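import numpy as np
import pytest

from paleogait.bodies import G
from paleogait.dynamics import (
    IS_HIND,
    LIMB_NAMES,
    MIRROR,
    Limb,
    LimbForceState,
    TrunkState,
    accelerations,
    attachment_offset,
    joint_position,
    leg_geometry,
    limb_kinetics,
    limb_power_split,
)
from paleogait.fixtures import BATRACHOTOMUS


class TestJointPosition:
    def test_level_trunk_offsets(self):
        s = TrunkState(x=0.0, z=1.0, theta=0.0)
        hip = joint_position(s, BATRACHOTOMUS, "hip")
        glenoid = joint_position(s, BATRACHOTOMUS, "glenoid")
        assert hip == pytest.approx((-0.248, 1.0))
        assert glenoid == pytest.approx((0.552, 1.0))

    def test_centered_com_symmetric(self):
        import dataclasses
        body = dataclasses.replace(BATRACHOTOMUS, MF_prime=0.5)
        s = TrunkState(x=0.3, z=1.0, theta=0.0)
        hip = joint_position(s, body, "hip")
        glenoid = joint_position(s, body, "glenoid")
        assert hip[0] - s.x == pytest.approx(-(glenoid[0] - s.x))

    @pytest.mark.parametrize("theta", [-1.2, -0.3, 0.0, 0.4, 1.5])
    def test_girdle_separation_is_rigid(self, theta):
        s = TrunkState(x=0.1, z=0.9, theta=theta)
        hip = joint_position(s, BATRACHOTOMUS, "hip")
        glenoid = joint_position(s, BATRACHOTOMUS, "glenoid")
        assert np.linalg.norm(glenoid - hip) == pytest.approx(BATRACHOTOMUS.LB)


class TestLegGeometry:
    def test_vertical_leg(self):
        s = TrunkState(x=0.248, z=0.8, theta=0.0)  # hip at x = 0
        limb = Limb("hip", max_length=0.76, foot_x=0.0)
        L, u, Ldot = leg_geometry(s, BATRACHOTOMUS, limb)
        assert L == pytest.approx(0.8)
        assert u == pytest.approx((0.0, 1.0))
        assert Ldot == pytest.approx(0.0)

    def test_length_rate_matches_finite_difference(self):
        s = TrunkState(x=0.1, z=0.8, theta=0.2, xdot=1.1, zdot=-0.3,
                       thetadot=0.7)
        limb = Limb("glenoid", max_length=0.46, foot_x=0.6)
        L, _, Ldot = leg_geometry(s, BATRACHOTOMUS, limb)
        dt = 1e-6
        s2 = TrunkState(x=s.x + s.xdot * dt, z=s.z + s.zdot * dt,
                        theta=s.theta + s.thetadot * dt,
                        xdot=s.xdot, zdot=s.zdot, thetadot=s.thetadot)
        L2, _, _ = leg_geometry(s2, BATRACHOTOMUS, limb)
        assert Ldot == pytest.approx((L2 - L) / dt, rel=1e-5, abs=1e-6)


class TestAccelerations:
    def _limbs(self, feet):
        return [Limb("hip" if h else "glenoid",
                     BATRACHOTOMUS.LH if h else BATRACHOTOMUS.LF, foot_x=fx)
                for h, fx in zip(IS_HIND, feet)]

    def test_free_fall(self):
        s = TrunkState(x=0, z=1.0, theta=0.0)
        acc = accelerations(s, BATRACHOTOMUS, self._limbs([0, 0, 0.5, 0.5]),
                            [0, 0, 0, 0])
        assert acc == pytest.approx((0.0, -G, 0.0))

    def test_static_balance_under_com_support(self):
        import dataclasses
        body = dataclasses.replace(BATRACHOTOMUS, MF_prime=0.0)
        # hip coincides with COM; a vertical hindlimb through the COM with
        # F = Mg balances gravity with no pitch moment
        s = TrunkState(x=0.0, z=0.7, theta=0.0)
        limbs = self._limbs([0.0, 0.0, 0.5, 0.5])
        acc = accelerations(s, body, limbs, [body.M * G, 0, 0, 0])
        assert acc == pytest.approx((0.0, 0.0, 0.0), abs=1e-10)

    def test_linear_in_forces(self):
        s = TrunkState(x=0.1, z=0.8, theta=0.1)
        limbs = self._limbs([-0.3, 0.1, 0.5, 0.7])
        F1 = np.array([100.0, 50.0, 80.0, 10.0])
        F2 = np.array([20.0, 90.0, 0.0, 60.0])
        a1 = np.array(accelerations(s, BATRACHOTOMUS, limbs, F1))
        a2 = np.array(accelerations(s, BATRACHOTOMUS, limbs, F2))
        a12 = np.array(accelerations(s, BATRACHOTOMUS, limbs, F1 + F2))
        grav = np.array([0.0, -G, 0.0])
        assert a12 - grav == pytest.approx((a1 - grav) + (a2 - grav))

    def test_zero_length_leg_rejected(self):
        s = TrunkState(x=0.248, z=0.0, theta=0.0)  # hip on the ground
        with pytest.raises(ValueError):
            accelerations(s, BATRACHOTOMUS, self._limbs([0.0, 0, 0.5, 0.5]),
                          [1.0, 0, 0, 0])


class TestPowerSplit:
    @pytest.mark.parametrize("F,rate,expected", [
        (100.0, 0.1, (10.0, 0.0)),
        (100.0, -0.1, (0.0, 10.0)),
        (0.0, 5.0, (0.0, 0.0)),
    ])
    def test_split(self, F, rate, expected):
        assert limb_power_split(F, rate) == pytest.approx(expected)

    def test_split_reconstructs_signed_power(self):
        for F, rate in [(50, 0.3), (50, -0.3), (0, 0.0), (120, 1.2)]:
            plus, minus = limb_power_split(F, rate)
            assert plus - minus == pytest.approx(F * rate)
            assert plus * minus == 0.0
            assert plus >= 0 and minus >= 0


class TestVectorizedKinetics:
    def test_matches_scalar_api(self):
        rng = np.random.default_rng(0)
        K = 5
        x, z = rng.uniform(-0.5, 0.5, K), rng.uniform(0.6, 1.0, K)
        th = rng.uniform(-0.4, 0.4, K)
        vx, vz, om = (rng.normal(0, 1, K) for _ in range(3))
        F = rng.uniform(0, 500, (K, 4))
        p = rng.uniform(-0.5, 1.0, 4)
        kin = limb_kinetics(x, z, th, vx, vz, om, F, p, BATRACHOTOMUS)
        for k in range(K):
            s = TrunkState(x[k], z[k], th[k], vx[k], vz[k], om[k])
            limbs = [Limb("hip" if h else "glenoid",
                          BATRACHOTOMUS.LH if h else BATRACHOTOMUS.LF, p[i])
                     for i, h in enumerate(IS_HIND)]
            acc = accelerations(s, BATRACHOTOMUS, limbs, F[k])
            assert kin.ax[k] == pytest.approx(acc[0])
            assert kin.az[k] == pytest.approx(acc[1])
            assert kin.alpha[k] == pytest.approx(acc[2])
            for i in range(4):
                L, u, Ldot = leg_geometry(s, BATRACHOTOMUS, limbs[i])
                assert kin.L[k, i] == pytest.approx(L)
                assert kin.Ldot[k, i] == pytest.approx(Ldot)


def test_limb_state_validation():
    with pytest.raises(ValueError):
        LimbForceState(F=-1.0)
    with pytest.raises(ValueError):
        TrunkState(x=0, z=1, theta=2.0)
    with pytest.raises(ValueError):
        Limb("hip", max_length=0.0)


def test_mirror_map_is_involution():
    assert [MIRROR[MIRROR[i]] for i in range(4)] == [0, 1, 2, 3]
    assert LIMB_NAMES == ("LH", "RH", "LF", "RF")
    assert attachment_offset(BATRACHOTOMUS, "glenoid") - attachment_offset(
        BATRACHOTOMUS, "hip") == pytest.approx(BATRACHOTOMUS.LB)
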