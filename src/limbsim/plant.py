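"""Reduced-order rigid-link lower-limb mechanism.

The plant stands in for a deformable finite-element limb model: a rigid
femur and tibia chained ankle-to-hip in the sagittal plane, with the knee's
secondary degrees of freedom (AP translation, IE rotation, VV rotation)
represented as lumped linear compliances.  The ankle is fixed in AP/SI
translation and free otherwise; the hip is free in SI translation, fixed in
ML, with its AP position kinematically prescribed.  Actuators apply a
vertical hip load, lumped quadriceps/hamstring tensions, and ML force plus
IE and flexion-extension torques at the ankle.

Load sign conventions follow the telemetric-implant tibial frame:
+anterior AP force, +internal IE torque, +varus VV torque, and negative
axial force = compression.  Angles are degrees at the interface and radians
internally.

Load path (see docs/methods.md for the derivation):

* the femur is a two-force member, so a vertical hip load ``W`` arrives at
  the knee as an axial femur force ``W / cos(theta_f)``; its component
  along the tibial axis is compressive and its transverse component is AP
  shear -- the flexion-dependent cross-coupling the controller must reject;
* muscle tensions compress the joint through lumped fractions and load the
  flexion DOF through effective moment arms (quadriceps extend, hamstrings
  flex);
* pelvic rotation tilts the muscle frame and offsets the hip-load line in
  the frontal plane, coupling into AP, IE and VV;
* the flexion DOF is driven by virtual work of the hip load and segment
  weights against hip height -- an inverted-pendulum-like DOF with no
  open-loop stable equilibrium, regularized by viscous damping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K

#: physical durations of the 0-100% cycle [s]: the simulator plays the
#: activities back slower than real time, as load-controlled joint rigs do,
#: keeping actuation rates modest while leaving the cycle-domain profiles
#: unchanged
DEFAULT_DURATIONS = {"gait": 4.0, "step_down": 6.0, "dkb": 8.0}


class InfeasibleConfigurationError(ValueError):
    """The requested flexion / hip AP combination is outside the reach."""


class PlantSolverError(RuntimeError):
    """The equilibrium solve failed; carries the residual and cycle time."""


@dataclass(frozen=True)
class PlantParameters:
    """Geometry, inertia, compliance and damping of the reduced plant.

    All values are package defaults chosen for a generic adult lower limb
    and are fully configurable; none are fitted quantities.
    """

    L_tibia_m: float = 0.40
    L_femur_m: float = 0.42
    m_femur_kg: float = 11.0
    m_tibia_kg: float = 6.0
    quad_moment_arm_m: float = 0.05
    ham_moment_arm_m: float = 0.035
    #: fraction of muscle tension appearing as TF compression (the
    #: patellofemoral mechanism diverts part of the extensor force)
    quad_compression_frac: float = 0.75
    ham_compression_frac: float = 0.8
    #: muscle-line sagittal tilt per degree of (transverse) pelvic rotation;
    #: most of a transverse rotation stays out of the sagittal plane
    pelvis_tilt_coupling: float = 0.05
    #: lever converting muscle-line tilt into IE torque [m]
    muscle_ie_offset_m: float = 0.01
    #: frontal-plane lever of the hip load under pelvic rotation [m]
    pelvis_vv_lever_m: float = 0.08
    #: fraction of the hip-path transverse force reaching the tray as AP
    #: shear (articular conformity carries the remainder)
    hip_shear_frac: float = 0.25
    k_ap_N_per_mm: float = 30.0
    k_ie_Nm_per_deg: float = 0.5
    k_vv_Nm_per_deg: float = 1.5
    #: per-DOF damping; the flexion value sets the quasi-static relaxation
    c_flexion_Nms_per_rad: float = 15.0
    c_ap_Ns_per_mm: float = 0.045
    c_ie_Nms_per_deg: float = 0.00075
    c_vv_Nms_per_deg: float = 0.00225
    g_m_s2: float = 9.81
    mode: str = "quasi_static"
    dt_s: float = 0.0005
    #: override the per-activity durations with a single value if set
    activity_duration_s: float | None = None
    lock_flexion: bool = False
    #: feasibility margin on the horizontal reach |hip_ap| < margin * reach
    reach_margin: float = 0.95
    # dynamic-mode effective inertias
    I_flexion_kgm2: float = 0.53
    I_ap_Ns2_per_mm: float = 0.005
    I_ie_Nms2_per_deg: float = 0.001
    I_vv_Nms2_per_deg: float = 0.002

    def __post_init__(self) -> None:
        for name in (
            "L_tibia_m", "L_femur_m", "quad_moment_arm_m", "ham_moment_arm_m",
            "k_ap_N_per_mm", "k_ie_Nm_per_deg", "k_vv_Nm_per_deg",
            "c_flexion_Nms_per_rad", "c_ap_Ns_per_mm", "c_ie_Nms_per_deg",
            "c_vv_Nms_per_deg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.mode not in ("quasi_static", "dynamic"):
            raise ValueError(f"unknown plant mode {self.mode!r}")
        if self.activity_duration_s is not None and self.activity_duration_s <= 0:
            raise ValueError("activity_duration_s must be > 0")

    def duration(self, activity: str) -> float:
        if self.activity_duration_s is not None:
            return self.activity_duration_s
        return DEFAULT_DURATIONS[activity]

    def to_array(self) -> np.ndarray:
        p = np.zeros(K.NPARAM)
        p[K.P_LT] = self.L_tibia_m
        p[K.P_LF] = self.L_femur_m
        p[K.P_MF] = self.m_femur_kg
        p[K.P_MT] = self.m_tibia_kg
        p[K.P_RQ] = self.quad_moment_arm_m
        p[K.P_RH] = self.ham_moment_arm_m
        p[K.P_CQ] = self.quad_compression_frac
        p[K.P_CH] = self.ham_compression_frac
        p[K.P_KAPPA] = self.pelvis_tilt_coupling
        p[K.P_RIE] = self.muscle_ie_offset_m
        p[K.P_RPELV] = self.pelvis_vv_lever_m
        p[K.P_KAP] = self.k_ap_N_per_mm
        p[K.P_KIE] = self.k_ie_Nm_per_deg
        p[K.P_KVV] = self.k_vv_Nm_per_deg
        p[K.P_CFL] = self.c_flexion_Nms_per_rad
        p[K.P_CAP] = self.c_ap_Ns_per_mm
        p[K.P_CIE] = self.c_ie_Nms_per_deg
        p[K.P_CVV] = self.c_vv_Nms_per_deg
        p[K.P_G] = self.g_m_s2
        p[K.P_LOCK] = 1.0 if self.lock_flexion else 0.0
        p[K.P_REACH] = self.reach_margin
        p[K.P_IFL] = self.I_flexion_kgm2
        p[K.P_IAP] = self.I_ap_Ns2_per_mm
        p[K.P_IIE] = self.I_ie_Nms2_per_deg
        p[K.P_IVV] = self.I_vv_Nms2_per_deg
        p[K.P_HSF] = self.hip_shear_frac
        return p

    def with_(self, **kwargs) -> "PlantParameters":
        return replace(self, **kwargs)


@dataclass
class PlantState:
    """Flexion plus the three compliant secondary displacements (+rates)."""

    flexion_deg: float = 0.0
    ap_mm: float = 0.0
    ie_deg: float = 0.0
    vv_deg: float = 0.0
    flexion_rate_dps: float = 0.0
    ap_rate: float = 0.0
    ie_rate: float = 0.0
    vv_rate: float = 0.0


@dataclass(frozen=True)
class ActuatorCommand:
    """The five load actuators; muscle tensions must be non-negative."""

    hip_vert_N: float = 0.0     # positive = downward, compressing the limb
    quad_N: float = 0.0
    ham_N: float = 0.0
    ankle_fe_Nm: float = 0.0
    ankle_ie_Nm: float = 0.0
    ankle_ml_N: float = 0.0

    def __post_init__(self) -> None:
        if self.quad_N < 0 or self.ham_N < 0:
            raise ValueError("muscle tensions must be non-negative (muscles pull)")


@dataclass(frozen=True)
class PrescribedMotion:
    """Kinematically imposed hip AP position and pelvic rotation over the cycle."""

    cycle_pct: np.ndarray
    hip_ap_mm: np.ndarray
    pelvic_rot_deg: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cycle_pct, dtype=float)
        object.__setattr__(self, "cycle_pct", c)
        object.__setattr__(self, "hip_ap_mm", np.asarray(self.hip_ap_mm, float))
        object.__setattr__(self, "pelvic_rot_deg",
                           np.asarray(self.pelvic_rot_deg, float))
        if not (c[0] == 0.0 and c[-1] == 100.0 and np.all(np.diff(c) > 0)):
            raise ValueError("motion must cover the full 0-100% cycle")
        if self.hip_ap_mm.shape != c.shape or self.pelvic_rot_deg.shape != c.shape:
            raise ValueError("motion channels must match the cycle grid")

    def at(self, pct: float) -> tuple[float, float]:
        return (
            float(np.interp(pct, self.cycle_pct, self.hip_ap_mm)),
            float(np.interp(pct, self.cycle_pct, self.pelvic_rot_deg)),
        )

    @classmethod
    def constant(cls, hip_ap_mm: float = 0.0, pelvic_rot_deg: float = 0.0):
        return cls(
            cycle_pct=np.array([0.0, 100.0]),
            hip_ap_mm=np.array([hip_ap_mm, hip_ap_mm]),
            pelvic_rot_deg=np.array([pelvic_rot_deg, pelvic_rot_deg]),
        )


@dataclass(frozen=True)
class JointLoads:
    """Controlled tibiofemoral quantities in the tibial frame."""

    comp_N: float
    ap_N: float
    ie_Nm: float
    vv_Nm: float
    flexion_deg: float

    def as_array(self) -> np.ndarray:
        # axis order used throughout: flexion, comp, ap, ie, vv
        return np.array(
            [self.flexion_deg, self.comp_N, self.ap_N, self.ie_Nm, self.vv_Nm]
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def kinematics(
    flexion_deg: float, hip_ap_mm: float, params: PlantParameters
) -> dict:
    """Solve the sagittal closure for segment angles and hip height.

    The ankle sits at the origin; ``hip_ap_mm`` is the prescribed anterior
    offset of the hip.  Returns tilt angles of tibia and femur from
    vertical (deg), the hip height (m), and the derivative of hip height
    with respect to flexion (m/rad) used by the flexion generalized moment.

    Raises :class:`InfeasibleConfigurationError` when the hip offset
    exceeds the feasible horizontal reach at the given flexion.
    """
    phi = math.radians(flexion_deg)
    ok, theta_t, theta_f, y_h, dtheta_t, dy_h, _, _ = K.geom(
        phi, hip_ap_mm * 1e-3, params.L_tibia_m, params.L_femur_m,
        params.reach_margin,
    )
    if not ok:
        reach = math.sqrt(
            params.L_tibia_m ** 2 + params.L_femur_m ** 2
            + 2 * params.L_tibia_m * params.L_femur_m * math.cos(phi)
        )
        raise InfeasibleConfigurationError(
            f"hip AP offset {hip_ap_mm:.1f} mm exceeds "
            f"{params.reach_margin:.0%} of the {reach * 1e3:.1f} mm reach "
            f"at {flexion_deg:.1f} deg flexion"
        )
    return {
        "theta_tibia_deg": math.degrees(theta_t),
        "theta_femur_deg": math.degrees(theta_f),
        "hip_height_m": y_h,
        "dtheta_tibia_dflexion": dtheta_t,
        "dhip_height_dflexion_m_per_rad": dy_h,
    }


def flexion_gravity_arm(
    flexion_deg: float, hip_ap_mm: float, params: PlantParameters
) -> float:
    """Hip-load flexion-moment arm ``-d(hip height)/d(flexion)`` [m/rad].

    Positive for flexed postures: a downward hip load then produces a
    flexing generalized moment that the quadriceps must balance.
    """
    return -kinematics(flexion_deg, hip_ap_mm, params)[
        "dhip_height_dflexion_m_per_rad"
    ]


def joint_loads(
    state: PlantState,
    params: PlantParameters,
    cmd: ActuatorCommand,
    motion: tuple[float, float] = (0.0, 0.0),
) -> JointLoads:
    """Joint loads for a state/command pair (``motion`` = hip_ap_mm, psi_deg).

    AP/IE/VV come from the compliance-element deflections; the axial load
    and flexion are instantaneous functions of the configuration and the
    command.  At equilibrium the compliance loads equal the statically
    applied loads (see :func:`applied_joint_loads`).
    """
    p = params.to_array()
    ok, flex, comp, ap, ie, vv = K.measure(
        math.radians(state.flexion_deg), state.ap_mm, state.ie_deg,
        state.vv_deg, cmd.hip_vert_N, cmd.quad_N, cmd.ham_N,
        cmd.ankle_fe_Nm, cmd.ankle_ie_Nm, cmd.ankle_ml_N,
        motion[0] * 1e-3, motion[1], p,
    )
    if not ok:
        raise InfeasibleConfigurationError(
            f"infeasible configuration at flexion {state.flexion_deg:.1f} deg, "
            f"hip AP {motion[0]:.1f} mm"
        )
    return JointLoads(comp_N=comp, ap_N=ap, ie_Nm=ie, vv_Nm=vv, flexion_deg=flex)


def applied_joint_loads(
    flexion_deg: float,
    params: PlantParameters,
    cmd: ActuatorCommand,
    motion: tuple[float, float] = (0.0, 0.0),
) -> dict:
    """Statically applied generalized loads on the four DOFs.

    Returns the flexion generalized moment [N*m] plus the applied AP force,
    IE torque, VV torque and axial load; at spring equilibrium the
    compliance loads of :func:`joint_loads` equal the corresponding values
    here (force/moment balance on the tibia).
    """
    p = params.to_array()
    ok, q_phi, q_ap, q_ie, q_vv, comp = K.applied_loads(
        math.radians(flexion_deg), motion[0] * 1e-3, motion[1],
        cmd.hip_vert_N, cmd.quad_N, cmd.ham_N,
        cmd.ankle_fe_Nm, cmd.ankle_ie_Nm, cmd.ankle_ml_N, p,
    )
    if not ok:
        raise InfeasibleConfigurationError(
            f"infeasible configuration at flexion {flexion_deg:.1f} deg"
        )
    return {
        "Q_flexion_Nm": q_phi,
        "ap_N": q_ap,
        "ie_Nm": q_ie,
        "vv_Nm": q_vv,
        "comp_N": comp,
    }


def step(
    state: PlantState,
    cmd: ActuatorCommand,
    motion: tuple[float, float],
    t: float,
    params: PlantParameters,
    dt: float | None = None,
) -> PlantState:
    """Advance the plant by one step of ``dt`` seconds.

    quasi_static mode: one implicit viscous-relaxation substep (springs get
    the exact backward-Euler update; the flexion DOF is solved by fixed
    point iteration).  dynamic mode: one semi-implicit Euler step of the
    second-order equations.  Under constant inputs that admit a stable
    equilibrium both modes settle to the same state (see
    :func:`equilibrate`).
    """
    if dt is None:
        dt = params.dt_s
    p = params.to_array()
    xh = motion[0] * 1e-3
    psi = motion[1]
    if params.mode == "quasi_static":
        ok, phi, ap, ie, vv = K.substep_qs(
            math.radians(state.flexion_deg), state.ap_mm, state.ie_deg,
            state.vv_deg, cmd.hip_vert_N, cmd.quad_N, cmd.ham_N,
            cmd.ankle_fe_Nm, cmd.ankle_ie_Nm, cmd.ankle_ml_N, xh, psi, dt, p,
        )
        if not ok:
            raise PlantSolverError(
                f"quasi-static substep infeasible at t={t:.4f}s"
            )
        return PlantState(
            flexion_deg=math.degrees(phi), ap_mm=ap, ie_deg=ie, vv_deg=vv
        )
    ok, phi, dphi, ap, dap, ie, die, vv, dvv = K.substep_dyn(
        math.radians(state.flexion_deg),
        math.radians(state.flexion_rate_dps),
        state.ap_mm, state.ap_rate, state.ie_deg, state.ie_rate,
        state.vv_deg, state.vv_rate,
        cmd.hip_vert_N, cmd.quad_N, cmd.ham_N,
        cmd.ankle_fe_Nm, cmd.ankle_ie_Nm, cmd.ankle_ml_N, xh, psi, dt, p,
    )
    if not ok:
        raise PlantSolverError(f"dynamic substep infeasible at t={t:.4f}s")
    return PlantState(
        flexion_deg=math.degrees(phi), flexion_rate_dps=math.degrees(dphi),
        ap_mm=ap, ap_rate=dap, ie_deg=ie, ie_rate=die, vv_deg=vv, vv_rate=dvv,
    )


def equilibrate(
    state: PlantState,
    cmd: ActuatorCommand,
    motion: tuple[float, float],
    params: PlantParameters,
    dt: float = 0.002,
    max_steps: int = 200_000,
    tol: float = 1e-10,
) -> PlantState:
    """Run :func:`step` under constant inputs until the state stops moving.

    Raises :class:`PlantSolverError` with the residual if no fixed point is
    reached (the unlocked flexion DOF has no open-loop stable equilibrium
    under constant loads; lock it or supply balanced muscle commands).
    """
    prev = state
    for i in range(max_steps):
        nxt = step(prev, cmd, motion, i * dt, params, dt=dt)
        resid = max(
            abs(nxt.flexion_deg - prev.flexion_deg),
            abs(nxt.ap_mm - prev.ap_mm),
            abs(nxt.ie_deg - prev.ie_deg),
            abs(nxt.vv_deg - prev.vv_deg),
        )
        prev = nxt
        if resid < tol:
            return prev
    raise PlantSolverError(
        f"no equilibrium after {max_steps} steps (last residual {resid:.3e})"
    )
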