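"""Per-axis PID control and the closed-loop target-tracking simulation.

Five loops run simultaneously, one per controlled quantity, each mapped to
exactly one actuator:

====================  =============================  ====
controlled axis       actuator                       sign
====================  =============================  ====
flexion angle         quad/ham split (extensor +)     -1
compressive load      vertical hip load               -1
AP load               ankle flexion-extension torque  +1
IE torque             ankle IE torque                 +1
VV torque             ankle ML force                  +1
====================  =============================  ====

The sign column is the error sign convention folded into each loop so that
positive gains are stabilizing on the default plant: e.g. raising the hip
load makes the axial load *more negative* (more compressive), and raising
the extensor demand *reduces* flexion.

Only the proportional and integral gains are meant to be tuned (grid
search, :mod:`limbsim.calibration`); the derivative term exists for
generality and defaults to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels as K
from .plant import PlantParameters, PrescribedMotion
from .profiles import ActivityProfile

#: axis order used by every (5, ...) array in the package
AXES = ("flexion", "comp", "ap", "ie", "vv")

AXIS_UNITS = {"flexion": "deg", "comp": "N", "ap": "N", "ie": "Nm", "vv": "Nm"}

#: command channel order of ClosedLoopResult.commands rows
COMMAND_CHANNELS = (
    "hip_vert_N", "quad_N", "ham_N", "ankle_fe_Nm", "ankle_ie_Nm", "ankle_ml_N"
)


@dataclass(frozen=True)
class AxisGains:
    kp: float = 0.0
    ki: float = 0.0
    kd: float = 0.0

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0 or self.kd < 0:
            raise ValueError("PID gains must be non-negative")


@dataclass(frozen=True)
class PIDGains:
    """Controller parameters for the five axes."""

    flexion: AxisGains = field(default_factory=AxisGains)
    comp: AxisGains = field(default_factory=AxisGains)
    ap: AxisGains = field(default_factory=AxisGains)
    ie: AxisGains = field(default_factory=AxisGains)
    vv: AxisGains = field(default_factory=AxisGains)

    def to_array(self) -> np.ndarray:
        return np.array(
            [[getattr(self, a).kp, getattr(self, a).ki, getattr(self, a).kd]
             for a in AXES]
        )

    def with_axis(self, axis: str, kp: float, ki: float,
                  kd: float = 0.0) -> "PIDGains":
        return replace(self, **{axis: AxisGains(kp=kp, ki=ki, kd=kd)})

    @classmethod
    def from_dict(cls, d: dict) -> "PIDGains":
        return cls(**{a: AxisGains(**d[a]) for a in AXES if a in d})

    def to_dict(self) -> dict:
        return {
            a: {"kp": getattr(self, a).kp, "ki": getattr(self, a).ki,
                "kd": getattr(self, a).kd}
            for a in AXES
        }


@dataclass(frozen=True)
class CommandLimits:
    """Actuator command bounds (generous, keep the plant physical)."""

    muscle_N: float = 8000.0
    hip_vert_N: float = 5000.0
    ankle_torque_Nm: float = 500.0
    ankle_ml_N: float = 1000.0

    def axis_bounds(self, params: PlantParameters) -> tuple[np.ndarray, np.ndarray]:
        """Per-axis PID output bounds in mapped actuator units.

        The flexion axis output is a signed extensor demand; its negative
        bound is scaled by the moment-arm ratio so the hamstring stays
        within its own tension limit after the split.
        """
        ratio = params.ham_moment_arm_m / params.quad_moment_arm_m
        lo = np.array([
            -self.muscle_N * ratio, 0.0,
            -self.ankle_torque_Nm, -self.ankle_torque_Nm, -self.ankle_ml_N,
        ])
        hi = np.array([
            self.muscle_N, self.hip_vert_N,
            self.ankle_torque_Nm, self.ankle_torque_Nm, self.ankle_ml_N,
        ])
        return lo, hi


@dataclass(frozen=True)
class ControlMapping:
    """Axis -> (actuator, error sign); bijective over the five actuators."""

    mapping: dict = field(default_factory=lambda: {
        "flexion": ("extensor_split", -1.0),
        "comp": ("hip_vert_N", -1.0),
        "ap": ("ankle_fe_Nm", +1.0),
        "ie": ("ankle_ie_Nm", +1.0),
        "vv": ("ankle_ml_N", +1.0),
    })

    def __post_init__(self) -> None:
        if set(self.mapping) != set(AXES):
            raise ValueError(f"mapping must cover exactly the axes {AXES}")
        actuators = [v[0] for v in self.mapping.values()]
        if len(set(actuators)) != len(actuators):
            raise ValueError("each controlled axis must map to its own actuator")


@dataclass(frozen=True)
class ControlSettings:
    """Loop-rate and housekeeping settings of the closed-loop simulation.

    The control period ``ctrl_dt_s`` is fixed in physical time (not per
    cycle percent) so one gain set has the same loop dynamics across
    activities of different durations; the number of updates per cycle
    follows from the activity duration.  ``n_sub`` plant substeps run
    between updates, and ``n_settle`` unrecorded lead-in updates hold the
    initial targets so the reported RMSE measures tracking, not the
    cold-start transient.
    """

    ctrl_dt_s: float = 0.002
    n_sub: int = 2
    n_settle: int = 100
    baseline_cocontraction_N: float = 0.0
    limits: CommandLimits = field(default_factory=CommandLimits)

    def __post_init__(self) -> None:
        if self.ctrl_dt_s <= 0 or self.n_sub < 1 or self.n_settle < 0:
            raise ValueError("invalid control settings")
        if self.baseline_cocontraction_N < 0:
            raise ValueError("co-contraction baseline must be >= 0")

    def n_ctrl(self, duration_s: float) -> int:
        return max(2, int(round(duration_s / self.ctrl_dt_s)))


@dataclass
class ClosedLoopResult:
    """Trajectories and per-axis RMSE of one closed-loop run."""

    activity: str
    cycle_pct: np.ndarray            # (N,)
    targets: np.ndarray              # (5, N) axis order AXES
    achieved: np.ndarray             # (5, N)
    commands: np.ndarray             # (6, N) COMMAND_CHANNELS order
    motion: np.ndarray               # (2, N) hip_ap_mm, pelvic_rot_deg
    integrals: np.ndarray            # (5, N) PID integral states
    gains: PIDGains
    duration_s: float

    @property
    def rmse(self) -> dict[str, float]:
        err = self.achieved - self.targets
        return {a: float(np.sqrt(np.mean(err[i] ** 2)))
                for i, a in enumerate(AXES)}

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: targets, achieved and actuator channels per sample."""
        data = {"cycle_pct": self.cycle_pct}
        for i, a in enumerate(AXES):
            data[f"target_{a}_{AXIS_UNITS[a]}"] = self.targets[i]
            data[f"achieved_{a}_{AXIS_UNITS[a]}"] = self.achieved[i]
        for i, c in enumerate(COMMAND_CHANNELS):
            data[c] = self.commands[i]
        data["hip_ap_mm"] = self.motion[0]
        data["pelvic_rot_deg"] = self.motion[1]
        return pd.DataFrame(data)

    def plot(self, axes=None):
        """Five-panel target-vs-achieved figure (matplotlib)."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(5, 1, sharex=True, figsize=(7, 10))
        for i, a in enumerate(AXES):
            axes[i].plot(self.cycle_pct, self.targets[i], "k--", label="target")
            axes[i].plot(self.cycle_pct, self.achieved[i], "C0-", label="achieved")
            axes[i].set_ylabel(f"{a} [{AXIS_UNITS[a]}]")
        axes[0].legend(loc="best")
        axes[-1].set_xlabel("activity cycle [%]")
        return axes


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def pid_step(
    gains: AxisGains,
    error: float,
    integral_state: float,
    prev_error: float,
    dt: float,
    limits: tuple[float, float],
) -> tuple[float, float]:
    """One discrete PID update with output clamping and anti-windup.

    ``command = kp*e + ki*I + kd*(e - e_prev)/dt`` clamped to ``limits``;
    the integral accumulates ``e*dt`` except while the command is saturated
    in the direction of the error (conditional integration).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return K.pid_step(
        gains.kp, gains.ki, gains.kd, error, integral_state, prev_error, dt,
        limits[0], limits[1],
    )


def split_flexion_demand(
    u: float, baseline: float, params: PlantParameters | None = None
) -> tuple[float, float]:
    """Route a signed extensor demand to (quad_N, ham_N), both >= 0.

    Negative demand is carried by the hamstrings scaled by the moment-arm
    ratio so the knee-moment magnitude is preserved; the co-contraction
    baseline adds to both muscles.
    """
    if baseline < 0:
        raise ValueError("co-contraction baseline must be >= 0")
    if params is None:
        params = PlantParameters()
    return K.split_flexion_demand(
        u, baseline, params.quad_moment_arm_m, params.ham_moment_arm_m
    )


def _targets_matrix(targets: ActivityProfile, grid_pct: np.ndarray) -> np.ndarray:
    tgt = np.empty((5, grid_pct.size))
    src = {
        "flexion": targets.flexion_deg, "comp": targets.comp_N,
        "ap": targets.ap_N, "ie": targets.ie_Nm, "vv": targets.vv_Nm,
    }
    for i, a in enumerate(AXES):
        tgt[i] = np.interp(grid_pct, targets.cycle_pct, src[a])
    return tgt


def simulate_closed_loop(
    targets: ActivityProfile,
    gains: PIDGains,
    mapping: ControlMapping | None = None,
    params: PlantParameters | None = None,
    motion: PrescribedMotion | None = None,
    settings: ControlSettings | None = None,
) -> ClosedLoopResult:
    """Drive the plant through one activity cycle under five PID loops.

    Targets are interpolated onto the control grid; at each update the
    loops read the achieved joint loads, form per-axis errors, and apply
    commands through the plant's quasi-static stepping.  Deterministic:
    identical inputs produce identical output.  By default the motion
    inputs are the target profile's own hip/pelvis channels
    (patient-specific scenario).
    """
    if mapping is None:
        mapping = ControlMapping()
    if params is None:
        params = PlantParameters()
    if settings is None:
        settings = ControlSettings()
    if motion is None:
        motion = PrescribedMotion(
            cycle_pct=targets.cycle_pct,
            hip_ap_mm=targets.hip_ap_mm,
            pelvic_rot_deg=targets.pelvic_rot_deg,
        )
    duration = params.duration(targets.activity)
    n_ctrl = settings.n_ctrl(duration)
    n = n_ctrl + 1
    grid = np.linspace(0.0, 100.0, n)
    tgt = _targets_matrix(targets, grid)
    mot = np.vstack([
        np.interp(grid, motion.cycle_pct, motion.hip_ap_mm),
        np.interp(grid, motion.cycle_pct, motion.pelvic_rot_deg),
    ])
    lo, hi = settings.limits.axis_bounds(params)
    dt = duration / n_ctrl
    ok, ach, cmds, integ = K.run_closed_loop(
        tgt, mot, gains.to_array(), lo, hi, params.to_array(), dt,
        settings.n_sub, settings.n_settle, settings.baseline_cocontraction_N,
    )
    if not ok:
        # locate the failure point for the error message
        reached = int(np.flatnonzero(np.any(cmds != 0.0, axis=0)).size)
        from .plant import PlantSolverError

        raise PlantSolverError(
            f"plant solve failed during closed loop of {targets.activity!r} "
            f"near cycle {100.0 * reached / n_ctrl:.1f}%"
        )
    return ClosedLoopResult(
        activity=targets.activity, cycle_pct=grid, targets=tgt, achieved=ach,
        commands=cmds, motion=mot, integrals=integ, gains=gains,
        duration_s=duration,
    )
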