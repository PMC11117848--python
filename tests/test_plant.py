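"""Plant mechanics: kinematic closure, static load paths, stepping."""

import math

import numpy as np
import pytest

from limbsim import (
    ActuatorCommand,
    InfeasibleConfigurationError,
    PlantParameters,
    PlantState,
    applied_joint_loads,
    equilibrate,
    joint_loads,
    kinematics,
    step,
)
from limbsim.plant import DEFAULT_DURATIONS


class TestKinematics:
    def test_straight_leg(self, plant):
        k = kinematics(0.0, 0.0, plant)
        assert k["theta_tibia_deg"] == pytest.approx(0.0, abs=1e-12)
        assert k["hip_height_m"] == pytest.approx(
            plant.L_tibia_m + plant.L_femur_m
        )

    def test_right_isoceles_geometry(self):
        p = PlantParameters(L_tibia_m=0.4, L_femur_m=0.4)
        k = kinematics(90.0, 0.0, p)
        assert k["hip_height_m"] == pytest.approx(0.4 * math.sqrt(2), rel=1e-12)
        assert k["theta_tibia_deg"] == pytest.approx(45.0, rel=1e-10)

    def test_closure_residual(self, plant):
        # ankle at origin, hip at the prescribed AP offset, angles summing
        # to the flexion angle: rebuild positions from the returned angles
        for flex, hip in [(10.0, -120.0), (75.0, 40.0), (120.0, -80.0)]:
            k = kinematics(flex, hip, plant)
            tt = math.radians(k["theta_tibia_deg"])
            tf = math.radians(k["theta_femur_deg"])
            x_hip = plant.L_tibia_m * math.sin(tt) + plant.L_femur_m * math.sin(tf)
            assert abs(x_hip - hip * 1e-3) < 1e-9
            assert k["theta_tibia_deg"] - k["theta_femur_deg"] == pytest.approx(
                flex, abs=1e-9
            )

    def test_out_of_reach(self, plant):
        reach_mm = (plant.L_tibia_m + plant.L_femur_m) * 1000.0
        with pytest.raises(InfeasibleConfigurationError):
            kinematics(0.0, reach_mm, plant)

    def test_hip_height_derivative_sign(self, plant):
        # flexing lowers the hip for flexed postures
        k = kinematics(40.0, 0.0, plant)
        assert k["dhip_height_dflexion_m_per_rad"] < 0.0


class TestStaticLoads:
    def test_all_zero_command_zero_loads(self, plant_nog):
        loads = applied_joint_loads(0.0, plant_nog, ActuatorCommand())
        for key in ("ap_N", "ie_Nm", "vv_Nm", "comp_N", "Q_flexion_Nm"):
            assert loads[key] == pytest.approx(0.0, abs=1e-12)

    def test_vv_lever_law(self, plant_nog):
        loads = applied_joint_loads(
            0.0, plant_nog, ActuatorCommand(ankle_ml_N=10.0)
        )
        assert loads["vv_Nm"] == pytest.approx(10.0 * plant_nog.L_tibia_m)

    def test_ap_torque_lever_law(self, plant_nog):
        loads = applied_joint_loads(
            0.0, plant_nog, ActuatorCommand(ankle_fe_Nm=8.0)
        )
        assert abs(loads["ap_N"]) == pytest.approx(8.0 / plant_nog.L_tibia_m)

    def test_ie_transmission_along_axis(self, plant_nog):
        loads = applied_joint_loads(
            0.0, plant_nog, ActuatorCommand(ankle_ie_Nm=5.0)
        )
        assert loads["ie_Nm"] == pytest.approx(5.0)

    def test_straight_leg_compression_sums_hip_and_muscles(self, plant_nog):
        cmd = ActuatorCommand(hip_vert_N=500.0, quad_N=200.0, ham_N=100.0)
        loads = applied_joint_loads(0.0, plant_nog, cmd)
        expect = -(500.0 + plant_nog.quad_compression_frac * 200.0
                   + plant_nog.ham_compression_frac * 100.0)
        assert loads["comp_N"] == pytest.approx(expect)

    def test_hip_load_cross_couples_into_ap_at_flexion(self, plant_nog):
        cmd = ActuatorCommand(hip_vert_N=1000.0)
        straight = applied_joint_loads(0.0, plant_nog, cmd)
        flexed = applied_joint_loads(60.0, plant_nog, cmd)
        assert straight["ap_N"] == pytest.approx(0.0, abs=1e-9)
        assert flexed["ap_N"] > 50.0  # anterior shear appears with flexion

    def test_pelvic_rotation_couples_hip_load_into_vv(self, plant_nog):
        cmd = ActuatorCommand(hip_vert_N=1000.0)
        neutral = applied_joint_loads(30.0, plant_nog, cmd, motion=(0.0, 0.0))
        rotated = applied_joint_loads(30.0, plant_nog, cmd, motion=(0.0, 15.0))
        assert neutral["vv_Nm"] == pytest.approx(0.0, abs=1e-9)
        expect = 1000.0 * plant_nog.pelvis_vv_lever_m * math.sin(
            math.radians(15.0)
        )
        assert rotated["vv_Nm"] == pytest.approx(expect)

    def test_newton_euler_consistency_random(self, plant_nog):
        """Loads from compliance deflections at equilibrium equal the
        statically applied loads (force/moment balance on the tibia),
        recomputed here with independent vector arithmetic."""
        rng = np.random.default_rng(123)
        p = plant_nog.with_(lock_flexion=True)
        Lt, Lf = p.L_tibia_m, p.L_femur_m
        for _ in range(1000):
            flex = rng.uniform(0.0, 110.0)
            hip = rng.uniform(-150.0, 120.0)
            psi = rng.uniform(-25.0, 25.0)
            cmd = ActuatorCommand(
                hip_vert_N=rng.uniform(0, 2500),
                quad_N=rng.uniform(0, 4000),
                ham_N=rng.uniform(0, 2000),
                ankle_fe_Nm=rng.uniform(-200, 200),
                ankle_ie_Nm=rng.uniform(-100, 100),
                ankle_ml_N=rng.uniform(-800, 800),
            )
            got = applied_joint_loads(flex, p, cmd, motion=(hip, psi))

            # independent statics: explicit sagittal vectors
            phi = math.radians(flex)
            k = kinematics(flex, hip, p)
            tt = math.radians(k["theta_tibia_deg"])
            tf = math.radians(k["theta_femur_deg"])
            cf = max(math.cos(tf), 0.2)
            Nf = cmd.hip_vert_N / cf
            delta = p.pelvis_tilt_coupling * math.radians(psi)
            axf = max(math.cos(phi), 0.15)
            comp = (
                -Nf * axf
                - p.quad_compression_frac * cmd.quad_N
                - p.ham_compression_frac * cmd.ham_N
            )
            ap = (
                cmd.ankle_fe_Nm / Lt
                + p.hip_shear_frac * Nf * math.sin(phi)
                + (cmd.quad_N + cmd.ham_N) * math.sin(delta)
            )
            ie = cmd.ankle_ie_Nm * math.cos(tt) + (
                cmd.quad_N + cmd.ham_N
            ) * p.muscle_ie_offset_m * math.sin(delta)
            vv = cmd.ankle_ml_N * Lt + cmd.hip_vert_N * \
                p.pelvis_vv_lever_m * math.sin(math.radians(psi))
            assert comp == pytest.approx(got["comp_N"], rel=1e-8, abs=1e-8)
            assert ap == pytest.approx(got["ap_N"], rel=1e-8, abs=1e-8)
            assert ie == pytest.approx(got["ie_Nm"], rel=1e-8, abs=1e-8)
            assert vv == pytest.approx(got["vv_Nm"], rel=1e-8, abs=1e-8)

    def test_compliance_loads_equal_applied_at_equilibrium(self, plant_nog):
        p = plant_nog.with_(lock_flexion=True)
        rng = np.random.default_rng(5)
        for _ in range(20):
            cmd = ActuatorCommand(
                hip_vert_N=rng.uniform(0, 1500),
                quad_N=rng.uniform(0, 2000),
                ankle_fe_Nm=rng.uniform(-80, 80),
                ankle_ie_Nm=rng.uniform(-40, 40),
                ankle_ml_N=rng.uniform(-400, 400),
            )
            flex = rng.uniform(0, 90)
            motion = (rng.uniform(-100, 100), rng.uniform(-15, 15))
            state = equilibrate(
                PlantState(flexion_deg=flex), cmd, motion, p, tol=1e-12
            )
            measured = joint_loads(state, p, cmd, motion)
            applied = applied_joint_loads(flex, p, cmd, motion)
            assert measured.ap_N == pytest.approx(applied["ap_N"], abs=1e-6)
            assert measured.ie_Nm == pytest.approx(applied["ie_Nm"], abs=1e-8)
            assert measured.vv_Nm == pytest.approx(applied["vv_Nm"], abs=1e-8)

    def test_monotone_local_gains(self, plant_nog):
        """Each mapped actuator channel moves its joint-load channel
        monotonically near random operating points."""
        rng = np.random.default_rng(77)
        for _ in range(100):
            flex = rng.uniform(5.0, 100.0)
            hip = rng.uniform(-120.0, 80.0)
            psi = rng.uniform(-20.0, 20.0)
            base = dict(
                hip_vert_N=rng.uniform(0, 2000),
                quad_N=rng.uniform(0, 3000),
                ham_N=rng.uniform(0, 1500),
                ankle_fe_Nm=rng.uniform(-100, 100),
                ankle_ie_Nm=rng.uniform(-60, 60),
                ankle_ml_N=rng.uniform(-500, 500),
            )
            for channel, axis, sign in [
                ("hip_vert_N", "comp_N", -1.0),
                ("ankle_fe_Nm", "ap_N", +1.0),
                ("ankle_ie_Nm", "ie_Nm", +1.0),
                ("ankle_ml_N", "vv_Nm", +1.0),
            ]:
                lo = applied_joint_loads(
                    flex, plant_nog, ActuatorCommand(**base), (hip, psi)
                )
                bumped = dict(base)
                bumped[channel] += 1.0
                hi = applied_joint_loads(
                    flex, plant_nog, ActuatorCommand(**bumped), (hip, psi)
                )
                assert sign * (hi[axis] - lo[axis]) > 0.0

    def test_flexion_moment_signs(self, plant_nog):
        """Hip load flexes an unopposed flexed knee; enough quadriceps
        tension reverses the generalized moment."""
        cmd_flex = ActuatorCommand(hip_vert_N=800.0)
        q = applied_joint_loads(45.0, plant_nog, cmd_flex)["Q_flexion_Nm"]
        assert q > 0.0
        cmd_ext = ActuatorCommand(hip_vert_N=800.0, quad_N=8000.0)
        q2 = applied_joint_loads(45.0, plant_nog, cmd_ext)["Q_flexion_Nm"]
        assert q2 < 0.0
        # hamstrings flex
        q3 = applied_joint_loads(
            45.0, plant_nog, ActuatorCommand(ham_N=500.0)
        )["Q_flexion_Nm"]
        assert q3 > 0.0

    def test_negative_muscle_tension_rejected(self):
        with pytest.raises(ValueError):
            ActuatorCommand(quad_N=-1.0)


class TestStepping:
    def test_unloaded_springs_relax_to_zero(self, plant_nog):
        p = plant_nog.with_(lock_flexion=True)
        state = PlantState(ap_mm=3.0, ie_deg=2.0, vv_deg=-1.0)
        out = equilibrate(state, ActuatorCommand(), (0.0, 0.0), p, tol=1e-12)
        assert abs(out.ap_mm) < 1e-8
        assert abs(out.ie_deg) < 1e-8
        assert abs(out.vv_deg) < 1e-8

    def test_spring_settles_at_hookes_law(self, plant_nog):
        p = plant_nog.with_(lock_flexion=True)
        F = 25.0
        out = equilibrate(PlantState(), ActuatorCommand(ankle_ml_N=F),
                          (0.0, 0.0), p, tol=1e-12)
        assert out.vv_deg == pytest.approx(
            F * p.L_tibia_m / p.k_vv_Nm_per_deg, rel=1e-6
        )

    def test_dynamic_matches_quasi_static_steady_state(self, plant_nog):
        cmd = ActuatorCommand(ankle_ml_N=200.0, ankle_fe_Nm=30.0,
                              ankle_ie_Nm=10.0)
        p_qs = plant_nog.with_(lock_flexion=True)
        p_dyn = p_qs.with_(mode="dynamic")
        qs = equilibrate(PlantState(), cmd, (0.0, 0.0), p_qs, tol=1e-12)
        dyn = equilibrate(PlantState(), cmd, (0.0, 0.0), p_dyn,
                          dt=0.0005, tol=1e-10)
        for field in ("ap_mm", "ie_deg", "vv_deg"):
            a, b = getattr(qs, field), getattr(dyn, field)
            assert b == pytest.approx(a, rel=1e-4, abs=1e-6)

    def test_modes_agree_under_stabilizing_muscle_law(self, plant_nog):
        """With a proportional muscle law closing the flexion DOF, the
        dynamic mode settles to the quasi-static fixed point."""
        target = 40.0
        kp = 500.0

        def run(params, dt):
            state = PlantState(flexion_deg=35.0)
            for i in range(80000):
                u = kp * (state.flexion_deg - target)
                cmd = ActuatorCommand(hip_vert_N=300.0, quad_N=max(u, 0.0),
                                      ham_N=max(-u, 0.0))
                nxt = step(state, cmd, (0.0, 0.0), i * dt, params, dt=dt)
                if (abs(nxt.flexion_deg - state.flexion_deg) < 1e-12
                        and i > 1000):
                    return nxt
                state = nxt
            return state

        qs = run(plant_nog, 0.002)
        dyn = run(plant_nog.with_(mode="dynamic"), 0.0002)
        assert dyn.flexion_deg == pytest.approx(qs.flexion_deg, abs=1e-3)

    def test_step_duration_lookup(self, plant):
        for act, dur in DEFAULT_DURATIONS.items():
            assert plant.duration(act) == dur
        assert plant.with_(activity_duration_s=2.5).duration("gait") == 2.5
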