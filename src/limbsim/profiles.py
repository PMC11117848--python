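"""Target-profile data model and I/O.

A lower-limb simulator is driven toward per-patient, per-activity *target
profiles*: the tibiofemoral loads and knee flexion measured by a telemetric
implant, together with the hip/pelvis motion inputs, all parameterized on a
normalized 0-100% activity cycle.

Sign conventions (tibial frame): +anterior AP force, +internal IE torque,
+varus VV torque, negative axial force = compression.  Units are fixed:
N, N*m, deg, mm; files never carry units.

The on-disk dialect is a plain CSV with one header row::

    cycle_pct,flexion_deg,comp_N,ap_N,ie_Nm,vv_Nm,pelvic_rot_deg,hip_ap_mm

one file per patient per activity, named ``<patient_id>_<activity>.csv``.
A cohort is described by a YAML/JSON manifest listing patient metadata and
per-activity file paths (see :func:`read_cohort_manifest`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

ACTIVITIES = ("gait", "step_down", "dkb")

#: channel order of the profile dialect (after the cycle column)
CHANNELS = (
    "flexion_deg",
    "comp_N",
    "ap_N",
    "ie_Nm",
    "vv_Nm",
    "pelvic_rot_deg",
    "hip_ap_mm",
)

_COLUMNS = ("cycle_pct",) + CHANNELS


class ProfileValidationError(ValueError):
    """A profile file or array set violates the profile invariants."""


@dataclass(frozen=True)
class ActivityProfile:
    """One patient's target waveforms for one activity.

    All channels share the ``cycle_pct`` grid, which is strictly increasing
    from 0 to 100.  All values must be finite.
    """

    activity: str
    cycle_pct: np.ndarray
    flexion_deg: np.ndarray
    comp_N: np.ndarray
    ap_N: np.ndarray
    ie_Nm: np.ndarray
    vv_Nm: np.ndarray
    pelvic_rot_deg: np.ndarray
    hip_ap_mm: np.ndarray

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ProfileValidationError(
                f"unknown activity {self.activity!r}; expected one of {ACTIVITIES}"
            )
        cyc = np.asarray(self.cycle_pct, dtype=float)
        object.__setattr__(self, "cycle_pct", cyc)
        if cyc.ndim != 1 or cyc.size < 2:
            raise ProfileValidationError("cycle_pct must be 1-D with >= 2 samples")
        if not np.all(np.isfinite(cyc)):
            raise ProfileValidationError("cycle_pct contains non-finite values")
        if not (cyc[0] == 0.0 and cyc[-1] == 100.0):
            raise ProfileValidationError(
                f"cycle_pct must span [0, 100]; got [{cyc[0]}, {cyc[-1]}]"
            )
        if not np.all(np.diff(cyc) > 0):
            i = int(np.flatnonzero(np.diff(cyc) <= 0)[0])
            raise ProfileValidationError(
                f"cycle_pct not strictly increasing at row {i + 1} "
                f"({cyc[i]} -> {cyc[i + 1]})"
            )
        for name in CHANNELS:
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != cyc.shape:
                raise ProfileValidationError(
                    f"column {name}: length {v.size} != cycle length {cyc.size}"
                )
            if not np.all(np.isfinite(v)):
                i = int(np.flatnonzero(~np.isfinite(v))[0])
                raise ProfileValidationError(
                    f"column {name}: non-finite value at row {i}"
                )

    @property
    def n_points(self) -> int:
        return self.cycle_pct.size

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(name)
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in _COLUMNS})

    def equals(self, other: "ActivityProfile", rtol: float = 0.0, atol: float = 0.0) -> bool:
        if self.activity != other.activity or self.n_points != other.n_points:
            return False
        return all(
            np.allclose(getattr(self, c), getattr(other, c), rtol=rtol, atol=atol)
            for c in _COLUMNS
        )


@dataclass
class PatientRecord:
    """Patient metadata plus the activities recorded for that patient.

    ``gait`` may be absent (the telemetric cohort this emulates had one
    patient without gait data); missing activities are never imputed.
    """

    patient_id: str
    body_mass_kg: float
    height_m: float
    activities: dict[str, ActivityProfile] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)  # e.g. implant orientation; opaque

    def __post_init__(self) -> None:
        if not self.activities:
            raise ProfileValidationError(
                f"patient {self.patient_id!r}: at least one activity required"
            )
        for act in self.activities:
            if act not in ACTIVITIES:
                raise ProfileValidationError(
                    f"patient {self.patient_id!r}: unknown activity {act!r}"
                )

    def has(self, activity: str) -> bool:
        return activity in self.activities


@dataclass
class CohortDataset:
    """Ordered list of patients with unique ids."""

    patients: list[PatientRecord]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ProfileValidationError("patient_ids must be unique")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def patients_with(self, activity: str) -> list[PatientRecord]:
        return [p for p in self.patients if p.has(activity)]

    def get(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_profile(path: str | Path, activity: str | None = None) -> ActivityProfile:
    """Read a profile CSV; activity defaults to parsing the file name.

    Raises :class:`ProfileValidationError` naming the offending column/row
    for missing columns, non-monotone cycle grids, or non-finite values.
    """
    path = Path(path)
    if activity is None:
        stem = path.stem
        for act in ACTIVITIES:
            if stem.endswith(f"_{act}"):
                activity = act
                break
        else:
            raise ProfileValidationError(
                f"cannot infer activity from file name {path.name!r}; pass activity="
            )
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ProfileValidationError(
            f"{path.name}: missing column(s) {', '.join(missing)}"
        )
    return ActivityProfile(
        activity=activity, **{c: df[c].to_numpy(dtype=float) for c in _COLUMNS}
    )


def write_profile(profile: ActivityProfile, path: str | Path) -> None:
    """Write a profile CSV at 9 significant digits (round-trip stable)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    profile.to_frame().to_csv(path, index=False, float_format="%.9g")


def resample(profile: ActivityProfile, n_points: int) -> ActivityProfile:
    """Linearly resample every channel onto a uniform n-point 0-100% grid.

    Endpoints are preserved exactly; a profile already on the uniform grid
    of the same size is returned unchanged (idempotence).
    """
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    new_cyc = np.linspace(0.0, 100.0, n_points)
    if profile.n_points == n_points and np.array_equal(profile.cycle_pct, new_cyc):
        return profile
    data = {
        c: np.interp(new_cyc, profile.cycle_pct, getattr(profile, c))
        for c in CHANNELS
    }
    return ActivityProfile(activity=profile.activity, cycle_pct=new_cyc, **data)


def cohort_average_motion(
    cohort: CohortDataset, activity: str, n_points: int
) -> tuple[np.ndarray, np.ndarray]:
    """Average hip AP position and pelvic rotation across the cohort.

    This is the "activity-specific" motion scenario: the pointwise mean of
    the resampled ``hip_ap_mm`` and ``pelvic_rot_deg`` channels over every
    patient that has the activity.  Patients missing the activity are
    excluded from the mean, not zero-filled.

    Returns ``(hip_ap_mm, pelvic_rot_deg)`` on the uniform n-point grid.
    """
    present = cohort.patients_with(activity)
    if not present:
        raise ValueError(f"no patient in the cohort has activity {activity!r}")
    hips = np.empty((len(present), n_points))
    pelvs = np.empty((len(present), n_points))
    for i, p in enumerate(present):
        prof = resample(p.activities[activity], n_points)
        hips[i] = prof.hip_ap_mm
        pelvs[i] = prof.pelvic_rot_deg
    return hips.mean(axis=0), pelvs.mean(axis=0)


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortDataset, directory: str | Path,
                 manifest_name: str = "cohort.yaml") -> Path:
    """Write profile files plus a YAML manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for p in cohort:
        files = {}
        for act, prof in p.activities.items():
            fname = f"{p.patient_id}_{act}.csv"
            write_profile(prof, directory / fname)
            files[act] = fname
        entries.append(
            {
                "patient_id": p.patient_id,
                "body_mass_kg": float(p.body_mass_kg),
                "height_m": float(p.height_m),
                "activities": files,
            }
        )
    manifest = directory / manifest_name
    with open(manifest, "w") as fh:
        yaml.safe_dump({"patients": entries}, fh, sort_keys=False)
    return manifest


def read_cohort_manifest(manifest_path: str | Path) -> CohortDataset:
    """Load a cohort from a YAML/JSON manifest; paths resolve relative to it."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, Mapping) or "patients" not in spec:
        raise ProfileValidationError(
            f"{manifest_path.name}: manifest must contain a 'patients' list"
        )
    base = manifest_path.parent
    patients = []
    for entry in spec["patients"]:
        acts = {
            act: read_profile(base / fname, activity=act)
            for act, fname in entry["activities"].items()
        }
        patients.append(
            PatientRecord(
                patient_id=str(entry["patient_id"]),
                body_mass_kg=float(entry["body_mass_kg"]),
                height_m=float(entry["height_m"]),
                activities=acts,
            )
        )
    return CohortDataset(patients=patients)
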