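"""Model/Results front-end over the functional modules.

Three estimator-style entry points mirror the common statistical-modelling
API (construct from data, ``fit()``, inspect a Results object):

* :class:`PatientCalibration` -- one patient/activity: grid-search PID
  tuning plus the tuned closed-loop run;
* :class:`CohortStudy` -- the full cohort x activity x scenario
  calibration with the RMSE table and scenario-comparison arithmetic;
* :class:`ActuatorPCA` -- the principal-component model of the calibrated
  actuator profiles, with mode reconstruction and sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration as cal
from . import pca as pca_mod
from .control import (
    AXES,
    AXIS_UNITS,
    ClosedLoopResult,
    ControlSettings,
    PIDGains,
    simulate_closed_loop,
)
from .plant import PlantParameters, PrescribedMotion
from .profiles import ActivityProfile, CohortDataset


@dataclass
class PatientCalibration:
    """Tune and run the simulator for one target profile.

    ``motion`` defaults to the profile's own hip/pelvis channels (the
    patient-specific scenario); pass a :class:`PrescribedMotion` to impose
    e.g. a cohort-average motion.
    """

    targets: ActivityProfile
    motion: PrescribedMotion | None = None
    plant: PlantParameters = field(default_factory=PlantParameters)
    grid: cal.GainGrid = field(default_factory=cal.default_gain_grid)
    settings: ControlSettings = field(default_factory=ControlSettings)

    def fit(self) -> "PatientCalibrationResults":
        gains = cal.tune_gains(
            self.targets, self.grid, params=self.plant, motion=self.motion,
            settings=self.settings,
        )
        run = simulate_closed_loop(
            self.targets, gains, params=self.plant, motion=self.motion,
            settings=self.settings,
        )
        return PatientCalibrationResults(model=self, gains=gains, run=run)

    def run(self, gains: PIDGains) -> ClosedLoopResult:
        """Closed-loop run with explicit gains (no tuning)."""
        return simulate_closed_loop(
            self.targets, gains, params=self.plant, motion=self.motion,
            settings=self.settings,
        )


@dataclass
class PatientCalibrationResults:
    model: PatientCalibration
    gains: PIDGains
    run: ClosedLoopResult

    @property
    def rmse(self) -> dict[str, float]:
        return self.run.rmse

    def summary(self) -> str:
        rows = []
        for a in AXES:
            g = getattr(self.gains, a)
            tgt = self.run.targets[AXES.index(a)]
            rng = float(tgt.max() - tgt.min())
            rows.append({
                "axis": a, "unit": AXIS_UNITS[a], "kp": g.kp, "ki": g.ki,
                "rmse": self.rmse[a],
                "rmse_pct_range": 100.0 * self.rmse[a] / rng if rng > 0
                else np.nan,
            })
        tbl = pd.DataFrame(rows).to_string(index=False, float_format="%.4g")
        return (
            f"Closed-loop calibration: activity={self.run.activity}, "
            f"duration={self.run.duration_s:g}s, "
            f"ctrl_dt={self.model.settings.ctrl_dt_s:g}s\n{tbl}"
        )

    def plot(self, axes=None):
        return self.run.plot(axes=axes)


@dataclass
class CohortStudy:
    """Calibrate a cohort under both motion scenarios and compare them."""

    cohort: CohortDataset
    plant: PlantParameters = field(default_factory=PlantParameters)
    grid: cal.GainGrid = field(default_factory=cal.default_gain_grid)
    settings: ControlSettings = field(default_factory=ControlSettings)
    activities: tuple[str, ...] | None = None
    scenarios: tuple[str, ...] = cal.SCENARIOS

    def fit(self, progress=None) -> "CohortStudyResults":
        runs: dict[tuple[str, str, str], ClosedLoopResult] = {}
        acts = self.activities
        if acts is None:
            acts = tuple(
                sorted({a for p in self.cohort for a in p.activities},
                       key=["gait", "step_down", "dkb"].index)
            )
        rows = []
        for activity in acts:
            present = self.cohort.patients_with(activity)
            for scenario in self.scenarios:
                spec = cal.ScenarioSpec(scenario=scenario, cohort=self.cohort)
                per_axis = {a: [] for a in AXES}
                for patient in present:
                    res = cal.run_patient(
                        patient, activity, spec, self.grid,
                        params=self.plant, settings=self.settings,
                    )
                    runs[(patient.patient_id, activity, scenario)] = res
                    for a in AXES:
                        per_axis[a].append(res.rmse[a])
                    if progress is not None:
                        progress(patient.patient_id, activity, scenario,
                                 res.rmse)
                for a in AXES:
                    vals = np.array(per_axis[a])
                    rows.append({
                        "activity": activity, "scenario": scenario, "axis": a,
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                        "n": int(vals.size), "unit": AXIS_UNITS[a],
                    })
        table = cal.RMSETable(frame=pd.DataFrame(rows))
        return CohortStudyResults(model=self, rmse_table=table, runs=runs)


@dataclass
class CohortStudyResults:
    model: CohortStudy
    rmse_table: cal.RMSETable
    runs: dict[tuple[str, str, str], ClosedLoopResult]

    def overall_axis_rmse(self, scenario: str = "patient_specific"):
        return cal.overall_axis_rmse(self.rmse_table, scenario)

    def percent_reduction(self, activity: str, axis: str) -> float:
        return cal.percent_reduction(self.rmse_table, activity, axis)

    def average_reduction(self) -> float:
        return cal.average_reduction(self.rmse_table)

    def results_for(self, activity: str,
                    scenario: str = "patient_specific"):
        return [r for (pid, act, scen), r in sorted(self.runs.items())
                if act == activity and scen == scenario]

    def ensemble(self, activity: str, scenario: str = "patient_specific",
                 n_points: int = 101) -> pca_mod.ActuatorEnsemble:
        return pca_mod.assemble_ensemble(
            self.results_for(activity, scenario), activity, n_points=n_points
        )

    def summary(self) -> str:
        lines = [
            f"Cohort study: {len(self.model.cohort)} patients, "
            f"scenarios={list(self.model.scenarios)}",
            self.rmse_table.pretty(),
        ]
        if set(self.model.scenarios) == set(cal.SCENARIOS):
            try:
                lines.append(
                    f"average RMSE reduction over 15 activity x axis cells: "
                    f"{self.average_reduction():.1f}%"
                )
            except KeyError:
                pass
        return "\n\n".join(lines)


@dataclass
class ActuatorPCA:
    """PCA estimator over an assembled actuator ensemble."""

    ensemble: pca_mod.ActuatorEnsemble

    @classmethod
    def from_results(cls, results: list[ClosedLoopResult], activity: str,
                     n_points: int = 101, include_hamstring: bool = False):
        return cls(ensemble=pca_mod.assemble_ensemble(
            results, activity, n_points=n_points,
            include_hamstring=include_hamstring,
        ))

    def fit(self) -> "ActuatorPCAResults":
        return ActuatorPCAResults(model=self,
                                  pca=pca_mod.fit_pca(self.ensemble))


@dataclass
class ActuatorPCAResults:
    model: ActuatorPCA
    pca: pca_mod.PCAModel

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.pca.variance_fractions

    def mode_profile(self, pc_index: int, k: float):
        return pca_mod.mode_profile(self.pca, pc_index, k)

    def sample(self, n: int, seed: int, n_components: int | None = None,
               truncation: float = 2.0):
        return pca_mod.sample_ebc(self.pca, n, seed,
                                  n_components=n_components,
                                  truncation=truncation)

    def summary(self, n_show: int = 5) -> str:
        k = min(n_show, self.pca.n_components)
        fr = self.variance_fractions
        rows = [
            {"PC": i + 1, "variance_fraction": fr[i],
             "cumulative": float(fr[: i + 1].sum())}
            for i in range(k)
        ]
        tbl = pd.DataFrame(rows).to_string(index=False, float_format="%.4f")
        head = (
            f"Actuator-profile PCA: activity={self.model.ensemble.activity}, "
            f"{self.model.ensemble.n_instances} instances, "
            f"{len(self.pca.channels)} channels x {self.pca.n_points} points"
        )
        if self.pca.zero_variance:
            head += " [zero total variance]"
        return f"{head}\n{tbl}"

    def plot_modes(self, pc_index: int = 0, k: float = 1.0, axes=None):
        """Mean +/- k SD mode profiles per channel (matplotlib)."""
        import matplotlib.pyplot as plt

        chans = self.pca.channels
        if axes is None:
            _, axes = plt.subplots(len(chans), 1, sharex=True,
                                   figsize=(7, 2 * len(chans)))
        grid = np.linspace(0.0, 100.0, self.pca.n_points)
        mean = pca_mod.mode_profile(self.pca, pc_index, 0.0)
        plus = pca_mod.mode_profile(self.pca, pc_index, k)
        minus = pca_mod.mode_profile(self.pca, pc_index, -k)
        for ax, c in zip(axes, chans):
            ax.plot(grid, mean[c], "k-", label="mean")
            ax.plot(grid, plus[c], "C0--", label=f"+{k:g} SD")
            ax.plot(grid, minus[c], "C3--", label=f"-{k:g} SD")
            ax.set_ylabel(c)
        axes[0].legend(loc="best")
        axes[-1].set_xlabel("activity cycle [%]")
        return axes
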