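"""Scalar numerical kernels for the reduced-order limb mechanism.

Everything here is plain float arithmetic so it can be JIT-compiled with
numba; the public dataclass API lives in :mod:`limbsim.plant` and
:mod:`limbsim.control`.  If numba is unavailable the kernels run as pure
Python with identical semantics.

Parameter vectors (``pvec``) are packed by :meth:`PlantParameters.to_array`
using the ``P_*`` indices below.  Angles are radians internally; the
interface converts to degrees.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap

# --- pvec layout -----------------------------------------------------------
P_LT = 0        # tibia length [m]
P_LF = 1        # femur length [m]
P_MF = 2        # femur mass [kg]
P_MT = 3        # tibia mass [kg]
P_RQ = 4        # quadriceps (extensor) moment arm [m]
P_RH = 5        # hamstring (flexor) moment arm [m]
P_CQ = 6        # quad tension -> TF compression fraction [-]
P_CH = 7        # ham tension -> TF compression fraction [-]
P_KAPPA = 8     # muscle-line tilt per deg pelvic rotation [deg/deg]
P_RIE = 9       # muscle-tilt -> IE torque offset [m]
P_RPELV = 10    # pelvic-rotation VV lever [m]
P_KAP = 11      # AP compliance [N/mm]
P_KIE = 12      # IE compliance [N*m/deg]
P_KVV = 13      # VV compliance [N*m/deg]
P_CFL = 14      # flexion damping [N*m*s/rad]
P_CAP = 15      # AP damping [N*s/mm]
P_CIE = 16      # IE damping [N*m*s/deg]
P_CVV = 17      # VV damping [N*m*s/deg]
P_G = 18        # gravity [m/s^2]
P_LOCK = 19     # 1.0 -> flexion DOF locked
P_REACH = 20    # feasibility margin on horizontal reach [-]
P_IFL = 21      # flexion inertia [kg*m^2] (dynamic mode)
P_IAP = 22      # AP effective mass [N*s^2/mm]
P_IIE = 23     # IE effective inertia [N*m*s^2/deg]
P_IVV = 24     # VV effective inertia [N*m*s^2/deg]
P_HSF = 25     # hip-path shear transmission fraction to the tray AP load [-]
NPARAM = 26

# flexion joint stops [rad]
PHI_MIN = -0.2618   # ~ -15 deg hyperextension
PHI_MAX = 2.7925    # ~ 160 deg


@njit(cache=False)
def geom(phi, xh_m, Lt, Lf, reach_margin):
    """Closed-form sagittal closure of the ankle-grounded two-link chain.

    Given knee flexion ``phi`` (rad) and hip AP offset ``xh_m`` (m, ankle at
    the origin, +anterior), returns the tibia/femur tilt angles from
    vertical, hip height, and the analytic derivatives with respect to phi
    used for the flexion generalized moment (virtual work).

    Returns ``(ok, theta_t, theta_f, y_h, dtheta_t, dy_h, dy_cf, dy_ct)``.
    """
    A = Lt + Lf * math.cos(phi)
    B = -Lf * math.sin(phi)
    R2 = A * A + B * B
    R = math.sqrt(R2)
    s = xh_m / R
    if abs(s) > reach_margin:
        return False, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    delta = math.atan2(B, A)
    theta_t = math.asin(s) - delta
    theta_f = theta_t - phi
    ct = math.cos(theta_t)
    cf = math.cos(theta_f)
    st = math.sin(theta_t)
    sf = math.sin(theta_f)
    y_h = Lt * ct + Lf * cf
    # d/dphi of R, delta, theta_t (implicit differentiation of the closure)
    dR = -Lt * Lf * math.sin(phi) / R
    ds = -xh_m * dR / R2
    ddelta = -Lf * (Lt * math.cos(phi) + Lf) / R2
    dtheta_t = ds / math.sqrt(1.0 - s * s) - ddelta
    dtheta_f = dtheta_t - 1.0
    dy_h = -Lt * st * dtheta_t - Lf * sf * dtheta_f
    dy_cf = -Lt * st * dtheta_t - 0.5 * Lf * sf * dtheta_f  # femur COM height
    dy_ct = -0.5 * Lt * st * dtheta_t                        # tibia COM height
    return True, theta_t, theta_f, y_h, dtheta_t, dy_h, dy_cf, dy_ct


@njit(cache=False)
def applied_loads(phi, xh_m, psi_deg, W, Tq, Th, Mfe, Mie, Fml, p):
    """Generalized loads on the four plant DOFs plus the axial joint load.

    The femur is treated as a two-force member carrying the vertical hip
    load ``W`` along its axis (magnitude ``W / cos(theta_f)``); quadriceps
    and hamstring tensions cross the joint with lumped moment arms and
    compression fractions; pelvic rotation tilts the muscle frame by
    ``kappa * psi`` and offsets the hip-load line in the frontal plane.

    Returns ``(ok, Q_phi[N*m], Q_ap[N], Q_ie[N*m], Q_vv[N*m], comp[N])``:
    generalized flexion moment (+ = flexing), applied AP shear (+anterior),
    applied IE and VV torques, and the (signed, - = compression) axial load.
    """
    ok, theta_t, theta_f, y_h, dtheta_t, dy_h, dy_cf, dy_ct = geom(
        phi, xh_m, p[P_LT], p[P_LF], p[P_REACH]
    )
    if not ok:
        return False, 0.0, 0.0, 0.0, 0.0, 0.0
    psi = psi_deg * math.pi / 180.0
    delta = p[P_KAPPA] * psi  # muscle-line tilt, rad
    cf = math.cos(theta_f)
    if cf < 0.2:
        cf = 0.2
    Nf = W / cf  # axial force in the femur two-force member

    # axial transmission factor: cos(phi), floored so the conforming
    # articulation never converts hip load into distraction at deep flexion
    axf = math.cos(phi)
    if axf < 0.15:
        axf = 0.15
    comp = -Nf * axf - p[P_CQ] * Tq - p[P_CH] * Th
    # only a fraction of the hip-path transverse component reaches the tray
    # as AP shear; articular conformity and femoral rollback carry the rest
    Q_ap = (
        Mfe / p[P_LT]
        + p[P_HSF] * Nf * math.sin(phi)
        + (Tq + Th) * math.sin(delta)
    )
    Q_ie = Mie * math.cos(theta_t) + (Tq + Th) * p[P_RIE] * math.sin(delta)
    Q_vv = Fml * p[P_LT] + W * p[P_RPELV] * math.sin(psi)
    # virtual work: hip load and segment weights act on falling heights
    Q_phi = (
        -(W * dy_h + p[P_MF] * p[P_G] * dy_cf + p[P_MT] * p[P_G] * dy_ct)
        - p[P_RQ] * Tq
        + p[P_RH] * Th
        + Mfe * dtheta_t
    )
    return True, Q_phi, Q_ap, Q_ie, Q_vv, comp


@njit(cache=False)
def substep_qs(phi, ap, ie, vv, W, Tq, Th, Mfe, Mie, Fml, xh_m, psi_deg, dt, p):
    """One viscous-dominated (quasi-static) implicit relaxation substep.

    The flexion DOF obeys ``c_fl * dphi/dt = Q_phi`` solved implicitly by
    fixed-point iteration (the statically unstable inverted-pendulum DOF is
    regularized by damping); the three compliant DOFs have the closed-form
    backward-Euler update of a damped spring.
    """
    if p[P_LOCK] < 0.5:
        phi_new = phi
        for _ in range(6):
            ok, Q_phi, _, _, _, _ = applied_loads(
                phi_new, xh_m, psi_deg, W, Tq, Th, Mfe, Mie, Fml, p
            )
            if not ok:
                return False, phi, ap, ie, vv
            phi_new = phi + dt / p[P_CFL] * Q_phi
            if phi_new < PHI_MIN:
                phi_new = PHI_MIN
            elif phi_new > PHI_MAX:
                phi_new = PHI_MAX
    else:
        phi_new = phi
    ok, Q_phi, Q_ap, Q_ie, Q_vv, comp = applied_loads(
        phi_new, xh_m, psi_deg, W, Tq, Th, Mfe, Mie, Fml, p
    )
    if not ok:
        return False, phi, ap, ie, vv
    ap_new = (p[P_CAP] / dt * ap + Q_ap) / (p[P_CAP] / dt + p[P_KAP])
    ie_new = (p[P_CIE] / dt * ie + Q_ie) / (p[P_CIE] / dt + p[P_KIE])
    vv_new = (p[P_CVV] / dt * vv + Q_vv) / (p[P_CVV] / dt + p[P_KVV])
    return True, phi_new, ap_new, ie_new, vv_new


@njit(cache=False)
def substep_dyn(phi, dphi, ap, dap, ie, die, vv, dvv,
                W, Tq, Th, Mfe, Mie, Fml, xh_m, psi_deg, dt, p):
    """Semi-implicit Euler step of the second-order equations of motion."""
    ok, Q_phi, Q_ap, Q_ie, Q_vv, comp = applied_loads(
        phi, xh_m, psi_deg, W, Tq, Th, Mfe, Mie, Fml, p
    )
    if not ok:
        return False, phi, dphi, ap, dap, ie, die, vv, dvv
    if p[P_LOCK] < 0.5:
        dphi = dphi + dt * (Q_phi - p[P_CFL] * dphi) / p[P_IFL]
        phi = phi + dt * dphi
        if phi < PHI_MIN:
            phi, dphi = PHI_MIN, 0.0
        elif phi > PHI_MAX:
            phi, dphi = PHI_MAX, 0.0
    dap = dap + dt * (Q_ap - p[P_KAP] * ap - p[P_CAP] * dap) / p[P_IAP]
    ap = ap + dt * dap
    die = die + dt * (Q_ie - p[P_KIE] * ie - p[P_CIE] * die) / p[P_IIE]
    ie = ie + dt * die
    dvv = dvv + dt * (Q_vv - p[P_KVV] * vv - p[P_CVV] * dvv) / p[P_IVV]
    vv = vv + dt * dvv
    return True, phi, dphi, ap, dap, ie, die, vv, dvv


@njit(cache=False)
def measure(phi, ap, ie, vv, W, Tq, Th, Mfe, Mie, Fml, xh_m, psi_deg, p):
    """Joint loads in the tibial frame for the current state and command.

    AP/IE/VV are read from the compliance elements (the load the implant
    constraint actually carries, ``k * deflection``); the axial load and
    flexion angle are instantaneous.
    """
    ok, Q_phi, Q_ap, Q_ie, Q_vv, comp = applied_loads(
        phi, xh_m, psi_deg, W, Tq, Th, Mfe, Mie, Fml, p
    )
    flex_deg = phi * 180.0 / math.pi
    return (
        ok,
        flex_deg,
        comp,
        p[P_KAP] * ap,
        p[P_KIE] * ie,
        p[P_KVV] * vv,
    )


@njit(cache=False)
def pid_step(kp, ki, kd, error, integral, prev_error, dt, lo, hi):
    """One discrete PID update with clamped output and anti-windup.

    The integral accumulates ``error * dt`` except while the unclamped
    command is saturated in the direction of the error (conditional
    integration).  Returns ``(command, new_integral)``.
    """
    integ = integral + error * dt
    deriv = kd * (error - prev_error) / dt
    raw = kp * error + ki * integ + deriv
    if (raw > hi and error > 0.0) or (raw < lo and error < 0.0):
        integ = integral  # suspend integration against the saturated bound
        raw = kp * error + ki * integ + deriv
    if raw > hi:
        raw = hi
    elif raw < lo:
        raw = lo
    return raw, integ


@njit(cache=False)
def split_flexion_demand(u, baseline, r_quad, r_ham):
    """Route a signed extensor demand to non-negative muscle tensions.

    Positive demand goes to the quadriceps; negative demand goes to the
    hamstrings scaled by the moment-arm ratio so the commanded knee moment
    magnitude is preserved.  A co-contraction baseline adds to both.
    """
    if u >= 0.0:
        quad = u + baseline
        ham = baseline
    else:
        quad = baseline
        ham = -u * (r_quad / r_ham) + baseline
    return quad, ham


@njit(cache=False)
def run_closed_loop(tgt, motion, gains, axis_lo, axis_hi, p, dt, n_sub,
                    n_settle, baseline):
    """Full closed-loop pass over one activity cycle.

    ``tgt``    : (5, N) targets [flexion_deg, comp_N, ap_N, ie_Nm, vv_Nm]
    ``motion`` : (2, N) prescribed [hip_ap_mm, pelvic_rot_deg]
    ``gains``  : (5, 3) kp/ki/kd per axis, in the same axis order
    ``axis_lo/hi`` : (5,) PID output bounds in mapped actuator units

    Axis-to-actuator mapping (one axis, one actuator): flexion -> signed
    extensor demand split over quad/ham; comp -> vertical hip load;
    ap -> ankle FE torque; ie -> ankle IE torque; vv -> ankle ML force.
    Error signs are chosen so positive gains are stabilizing on every axis.

    Returns ``(ok, achieved (5,N), commands (6,N), integrals (5,N))`` where
    commands rows are [hip_vert_N, quad_N, ham_N, ankle_fe_Nm, ankle_ie_Nm,
    ankle_ml_N].  Deterministic: no randomness anywhere.
    """
    n = tgt.shape[1]
    ach = np.zeros((5, n))
    cmds = np.zeros((6, n))
    integ_out = np.zeros((5, n))

    signs = np.empty(5)
    signs[0] = -1.0  # more extensor demand -> less flexion
    signs[1] = -1.0  # more hip load -> more negative (compressive) load
    signs[2] = 1.0
    signs[3] = 1.0
    signs[4] = 1.0

    phi = tgt[0, 0] * math.pi / 180.0
    if phi < PHI_MIN:
        phi = PHI_MIN
    elif phi > PHI_MAX:
        phi = PHI_MAX
    ap = 0.0
    ie = 0.0
    vv = 0.0
    integ = np.zeros(5)
    prev_e = np.zeros(5)
    W = 0.0
    Tq = 0.0
    Th = 0.0
    Mfe = 0.0
    Mie = 0.0
    Fml = 0.0
    dt_sub = dt / n_sub

    for k in range(n_settle + n):
        if k < n_settle:
            i = 0
        else:
            i = k - n_settle
        xh = motion[0, i] * 0.001
        psi = motion[1, i]

        okm, mflex, mcomp, map_, mie_, mvv_ = measure(
            phi, ap, ie, vv, W, Tq, Th, Mfe, Mie, Fml, xh, psi, p
        )
        if not okm:
            return False, ach, cmds, integ_out

        u = np.empty(5)
        for a in range(5):
            if a == 0:
                e = signs[a] * (tgt[a, i] - mflex)
            elif a == 1:
                e = signs[a] * (tgt[a, i] - mcomp)
            elif a == 2:
                e = signs[a] * (tgt[a, i] - map_)
            elif a == 3:
                e = signs[a] * (tgt[a, i] - mie_)
            else:
                e = signs[a] * (tgt[a, i] - mvv_)
            cmd_a, integ_a = pid_step(
                gains[a, 0], gains[a, 1], gains[a, 2],
                e, integ[a], prev_e[a], dt, axis_lo[a], axis_hi[a]
            )
            u[a] = cmd_a
            integ[a] = integ_a
            prev_e[a] = e

        Tq, Th = split_flexion_demand(u[0], baseline, p[P_RQ], p[P_RH])
        W = u[1]
        if W < 0.0:
            W = 0.0
        Mfe = u[2]
        Mie = u[3]
        Fml = u[4]

        for _ in range(n_sub):
            oks, phi, ap, ie, vv = substep_qs(
                phi, ap, ie, vv, W, Tq, Th, Mfe, Mie, Fml, xh, psi, dt_sub, p
            )
            if not oks:
                return False, ach, cmds, integ_out

        if k >= n_settle:
            okm, mflex, mcomp, map_, mie_, mvv_ = measure(
                phi, ap, ie, vv, W, Tq, Th, Mfe, Mie, Fml, xh, psi, p
            )
            if not okm:
                return False, ach, cmds, integ_out
            ach[0, i] = mflex
            ach[1, i] = mcomp
            ach[2, i] = map_
            ach[3, i] = mie_
            ach[4, i] = mvv_
            cmds[0, i] = W
            cmds[1, i] = Tq
            cmds[2, i] = Th
            cmds[3, i] = Mfe
            cmds[4, i] = Mie
            cmds[5, i] = Fml
            for a in range(5):
                integ_out[a, i] = integ[a]

    return True, ach, cmds, integ_out
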