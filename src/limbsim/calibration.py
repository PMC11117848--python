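"""Gain tuning, motion scenarios, and RMSE aggregation.

The controller gains are calibrated the way the original simulator work
did it: by uniformly varying the proportional and integral gains of each
axis and keeping the pair with the lowest RMSE between achieved and target
loading.  Two boundary-condition scenarios are compared:

* ``patient_specific`` -- each run uses the patient's own hip AP position
  and pelvic rotation;
* ``activity_average`` -- every patient of an activity is driven with the
  cohort-average motion for that activity.

Per (activity, axis, scenario) the mean and sample SD of the per-patient
RMSE form an :class:`RMSETable`; :func:`overall_axis_rmse`,
:func:`percent_reduction` and :func:`average_reduction` reproduce the
cohort-level reporting arithmetic.  A packaged reference table from a
published nine-patient telemetric-implant cohort ships with the package
(:func:`reference_rmse_table`) for exercising that arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .control import (
    AXES,
    AXIS_UNITS,
    ClosedLoopResult,
    ControlMapping,
    ControlSettings,
    PIDGains,
    simulate_closed_loop,
)
from .plant import PlantParameters, PlantSolverError, PrescribedMotion
from .profiles import ActivityProfile, CohortDataset, PatientRecord, cohort_average_motion

#: coordinate-wise tuning order: the load path is dominated by compression
#: and flexion, so those are settled first
TUNE_ORDER = ("comp", "flexion", "ap", "ie", "vv")

SCENARIOS = ("activity_average", "patient_specific")


class TuningError(RuntimeError):
    """Every candidate gain pair failed to simulate on some axis."""


@dataclass(frozen=True)
class GainGrid:
    """Per-axis kp and ki candidate lists (uniformly spaced, ascending)."""

    flexion: tuple[tuple[float, ...], tuple[float, ...]]
    comp: tuple[tuple[float, ...], tuple[float, ...]]
    ap: tuple[tuple[float, ...], tuple[float, ...]]
    ie: tuple[tuple[float, ...], tuple[float, ...]]
    vv: tuple[tuple[float, ...], tuple[float, ...]]

    def __post_init__(self) -> None:
        for axis in AXES:
            kp, ki = getattr(self, axis)
            for vals in (kp, ki):
                if len(vals) == 0:
                    raise ValueError(f"{axis}: empty candidate list")
                if any(v < 0 for v in vals):
                    raise ValueError(f"{axis}: negative gain candidate")
                if list(vals) != sorted(vals):
                    raise ValueError(f"{axis}: candidates must be ascending")

    def axis(self, name: str) -> tuple[tuple[float, ...], tuple[float, ...]]:
        return getattr(self, name)

    @classmethod
    def from_ranges(cls, ranges: dict, n: int = 7) -> "GainGrid":
        """Uniform n-point grids from {axis: ((kp_lo, kp_hi), (ki_lo, ki_hi))}."""
        kw = {}
        for axis in AXES:
            (kp_lo, kp_hi), (ki_lo, ki_hi) = ranges[axis]
            kw[axis] = (
                tuple(np.linspace(kp_lo, kp_hi, n)),
                tuple(np.linspace(ki_lo, ki_hi, n)),
            )
        return cls(**kw)


def default_gain_grid(n: int = 7) -> GainGrid:
    """Default search ranges, set per axis by dimensional analysis of the
    default plant's static input-output gains (documented in the methods
    note); all configurable."""
    return GainGrid.from_ranges(
        {
            "flexion": ((200.0, 2000.0), (0.0, 1800.0)),
            "comp": ((0.05, 0.65), (20.0, 260.0)),
            "ap": ((0.02, 0.26), (10.0, 130.0)),
            "ie": ((0.1, 1.3), (50.0, 650.0)),
            "vv": ((0.25, 3.25), (125.0, 1625.0)),
        },
        n=n,
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Which hip/pelvis motion drives the simulation."""

    scenario: str
    cohort: CohortDataset | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "activity_average" and self.cohort is None:
            raise ValueError("activity_average scenario requires a cohort")

    def motion_for(self, patient: PatientRecord, activity: str,
                   n_points: int = 101) -> PrescribedMotion:
        prof = patient.activities[activity]
        if self.scenario == "patient_specific":
            return PrescribedMotion(
                cycle_pct=prof.cycle_pct,
                hip_ap_mm=prof.hip_ap_mm,
                pelvic_rot_deg=prof.pelvic_rot_deg,
            )
        hip, pelv = cohort_average_motion(self.cohort, activity, n_points)
        return PrescribedMotion(
            cycle_pct=np.linspace(0.0, 100.0, n_points),
            hip_ap_mm=hip,
            pelvic_rot_deg=pelv,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def rmse(target: np.ndarray, achieved: np.ndarray) -> float:
    """Root mean square error between two equal-length series."""
    target = np.asarray(target, dtype=float)
    achieved = np.asarray(achieved, dtype=float)
    if target.shape != achieved.shape or target.size < 1:
        raise ValueError(
            f"length mismatch: target {target.shape} vs achieved {achieved.shape}"
        )
    return float(np.sqrt(np.mean((target - achieved) ** 2)))


def loading_misfit(result: ClosedLoopResult) -> float:
    """Whole-loading tuning objective: per-axis RMSE over target range,
    summed across the five axes (constant-target axes count absolute)."""
    total = 0.0
    for i, axis in enumerate(AXES):
        rng = float(result.targets[i].max() - result.targets[i].min())
        r = result.rmse[axis]
        total += r / rng if rng > 0 else r
    return total


def _initial_gains(grid: GainGrid) -> PIDGains:
    """Pre-tuning operating point: the middle candidate of each axis grid."""
    gains = PIDGains()
    for axis in AXES:
        kp, ki = grid.axis(axis)
        gains = gains.with_axis(axis, kp[len(kp) // 2], ki[len(ki) // 2])
    return gains


def tune_gains(
    targets: ActivityProfile,
    grid: GainGrid,
    mapping: ControlMapping | None = None,
    params: PlantParameters | None = None,
    motion: PrescribedMotion | None = None,
    settings: ControlSettings | None = None,
) -> PIDGains:
    """Coordinate-wise uniform grid search for the P and I gains.

    Axes are visited in :data:`TUNE_ORDER` starting from the middle of each
    grid; per axis every (kp, ki) pair is evaluated with the other axes
    held at their current-best gains, scoring each candidate by the fit to
    the desired loading as a whole -- the sum over all five axes of the
    closed-loop RMSE normalized by that axis's target peak-to-peak range.
    The whole-loading objective matters because the loops interact (e.g.
    aggressive flexion gains track flexion marginally better while their
    quadriceps activity pollutes the compressive load).  Candidates are
    enumerated in ascending (ki, kp) order with strict improvement, so
    ties resolve to the smallest ki then the smallest kp.  One refinement
    pass repeats the sweep.  Failing candidates score infinitely badly; if
    every candidate of an axis fails a :class:`TuningError` lists the
    failures.  Deterministic throughout.
    """
    best = _initial_gains(grid)
    for _sweep in range(2):
        for axis in TUNE_ORDER:
            kp_list, ki_list = grid.axis(axis)
            pairs = sorted(
                ((ki, kp) for ki in ki_list for kp in kp_list)
            )
            best_score = math.inf
            best_pair = None
            failures = []
            for ki, kp in pairs:
                cand = best.with_axis(axis, kp, ki)
                try:
                    res = simulate_closed_loop(
                        targets, cand, mapping=mapping, params=params,
                        motion=motion, settings=settings,
                    )
                except PlantSolverError as exc:
                    failures.append((kp, ki, str(exc)))
                    continue
                score = loading_misfit(res)
                if not math.isfinite(score):
                    failures.append((kp, ki, "non-finite RMSE"))
                    continue
                if score < best_score:
                    best_score = score
                    best_pair = (kp, ki)
            if best_pair is None:
                raise TuningError(
                    f"axis {axis!r}: all {len(pairs)} candidates failed: "
                    + "; ".join(f"kp={kp},ki={ki}: {m}" for kp, ki, m in failures[:5])
                )
            best = best.with_axis(axis, *best_pair)
    return best


def run_patient(
    patient: PatientRecord,
    activity: str,
    scenario: ScenarioSpec,
    grid: GainGrid,
    params: PlantParameters | None = None,
    settings: ControlSettings | None = None,
    mapping: ControlMapping | None = None,
) -> ClosedLoopResult:
    """Tune gains for one patient/activity/scenario, then simulate.

    Gains are tuned independently per combination (the scenarios do not
    share gains); the motion inputs are selected by the scenario.
    """
    if not patient.has(activity):
        raise KeyError(
            f"patient {patient.patient_id!r} has no {activity!r} data"
        )
    targets = patient.activities[activity]
    motion = scenario.motion_for(patient, activity, n_points=targets.n_points)
    gains = tune_gains(targets, grid, mapping=mapping, params=params,
                       motion=motion, settings=settings)
    return simulate_closed_loop(targets, gains, mapping=mapping, params=params,
                                motion=motion, settings=settings)


# ---------------------------------------------------------------------------
# RMSE table
# ---------------------------------------------------------------------------

@dataclass
class RMSETable:
    """Mean and sample SD of per-patient RMSE per (activity, axis, scenario).

    Backed by a tidy DataFrame with columns ``activity, scenario, axis,
    mean, sd, n, unit``; the SD uses the n-1 denominator and is reported
    as 0 (with n = 1 visible) for single-patient runs.
    """

    frame: pd.DataFrame

    _REQUIRED = ("activity", "scenario", "axis", "mean", "sd", "n", "unit")

    def __post_init__(self) -> None:
        missing = [c for c in self._REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"RMSETable missing columns {missing}")
        if (self.frame["mean"] < 0).any() or (self.frame["sd"] < 0).any():
            raise ValueError("RMSE means and SDs must be >= 0")

    def entry(self, activity: str, axis: str, scenario: str) -> pd.Series:
        m = self.frame[
            (self.frame.activity == activity)
            & (self.frame.axis == axis)
            & (self.frame.scenario == scenario)
        ]
        if len(m) != 1:
            raise KeyError(
                f"no unique entry for ({activity}, {axis}, {scenario})"
            )
        return m.iloc[0]

    def mean(self, activity: str, axis: str, scenario: str) -> float:
        return float(self.entry(activity, axis, scenario)["mean"])

    def activities(self, scenario: str, axis: str) -> list[str]:
        m = self.frame[(self.frame.axis == axis) & (self.frame.scenario == scenario)]
        return sorted(m.activity.unique())

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RMSETable":
        return cls(frame=pd.read_csv(path))

    def pretty(self) -> str:
        """Mean +/- SD layout: activity rows, axis columns, scenario blocks."""
        blocks = []
        for scen in sorted(self.frame.scenario.unique()):
            sub = self.frame[self.frame.scenario == scen]
            wide = sub.pivot(index="activity", columns="axis", values="mean")
            sds = sub.pivot(index="activity", columns="axis", values="sd")
            cells = wide.round(2).astype(str) + " +/- " + sds.round(2).astype(str)
            blocks.append(f"[{scen}]\n{cells.to_string()}")
        return "\n\n".join(blocks)


def build_rmse_table(
    cohort: CohortDataset,
    grid: GainGrid,
    params: PlantParameters | None = None,
    settings: ControlSettings | None = None,
    activities: tuple[str, ...] | None = None,
    scenarios: tuple[str, ...] = SCENARIOS,
    progress=None,
) -> RMSETable:
    """Tune and simulate every (patient, activity, scenario); aggregate RMSE.

    Patients missing an activity are skipped for that activity.  Means are
    invariant to patient ordering.  ``progress`` may be a callable invoked
    with (patient_id, activity, scenario, rmse_dict) after each run.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if activities is None:
        activities = tuple(
            sorted(
                {a for p in cohort for a in p.activities},
                key=["gait", "step_down", "dkb"].index,
            )
        )
    rows = []
    for activity in activities:
        present = cohort.patients_with(activity)
        for scenario in scenarios:
            spec = ScenarioSpec(scenario=scenario, cohort=cohort)
            per_axis: dict[str, list[float]] = {a: [] for a in AXES}
            for patient in present:
                res = run_patient(patient, activity, spec, grid,
                                  params=params, settings=settings)
                for a in AXES:
                    per_axis[a].append(res.rmse[a])
                if progress is not None:
                    progress(patient.patient_id, activity, scenario, res.rmse)
            for a in AXES:
                vals = np.array(per_axis[a])
                rows.append(
                    {
                        "activity": activity,
                        "scenario": scenario,
                        "axis": a,
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                        "n": int(vals.size),
                        "unit": AXIS_UNITS[a],
                    }
                )
    return RMSETable(frame=pd.DataFrame(rows))


def overall_axis_rmse(table: RMSETable, scenario: str) -> dict[str, float]:
    """Unweighted mean over the three activity-level means, per axis."""
    out = {}
    for axis in AXES:
        acts = table.activities(scenario, axis)
        missing = {"gait", "step_down", "dkb"} - set(acts)
        if missing:
            raise KeyError(
                f"axis {axis!r}, scenario {scenario!r}: missing activities "
                f"{sorted(missing)}"
            )
        out[axis] = float(
            np.mean([table.mean(a, axis, scenario) for a in
                     ("gait", "step_down", "dkb")])
        )
    return out


def percent_reduction(table: RMSETable, activity: str, axis: str) -> float:
    """RMSE reduction (%) from activity-average to patient-specific motion.

    Negative when patient-specific motion worsens the fit for a cell.
    """
    avg = table.mean(activity, axis, "activity_average")
    spec = table.mean(activity, axis, "patient_specific")
    if avg == 0.0:
        raise ZeroDivisionError(
            f"({activity}, {axis}): activity_average mean RMSE is zero"
        )
    return 100.0 * (avg - spec) / avg


def average_reduction(table: RMSETable) -> float:
    """Unweighted mean of percent_reduction over all 15 activity/axis cells."""
    vals = []
    for activity in ("gait", "step_down", "dkb"):
        for axis in AXES:
            vals.append(percent_reduction(table, activity, axis))
    return float(np.mean(vals))


def reference_rmse_table() -> RMSETable:
    """The packaged nine-patient telemetric-cohort reference RMSE table."""
    with resources.files("limbsim.data").joinpath(
        "reference_rmse_table.csv"
    ).open() as fh:
        return RMSETable(frame=pd.read_csv(fh))
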