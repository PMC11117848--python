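"""PCA of actuator load profiles and boundary-condition sampling.

Once every patient's actuator loading has been calibrated, the per-patient
actuator profiles form an ensemble whose principal components describe how
the simulator's boundary conditions co-vary across the cohort (e.g. a
larger vertical hip load demanding larger ankle flexion-extension and IE
torques).  Sampling PC scores then generates *new* boundary-condition sets
that preserve those inter-actuator relationships -- the basis for
probabilistic simulator studies beyond the measured cohort.

The ensemble concatenates seven channels per instance -- the AP, IE,
compressive and VV load actuators, the quadriceps tension, and the two
prescribed motions (hip AP, pelvic rotation).  Channels mix units (N, N*m,
mm, deg), so each channel block is standardized by its pooled SD before
the decomposition and every output is transformed back to physical units.
PCA is fitted per activity by default; pooling across activities is
available by assembling a mixed ensemble explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .control import COMMAND_CHANNELS, ClosedLoopResult

#: ensemble channel order; values name the source series of a closed-loop run
ACTUATOR_CHANNELS = (
    "ap_act", "ie_act", "comp_act", "vv_act", "quad_act",
    "hip_ap_mm", "pelvic_rot_deg",
)

ACTUATOR_UNITS = {
    "ap_act": "Nm", "ie_act": "Nm", "comp_act": "N", "vv_act": "N",
    "quad_act": "N", "ham_act": "N", "hip_ap_mm": "mm", "pelvic_rot_deg": "deg",
}

_CMD_ROW = {c: i for i, c in enumerate(COMMAND_CHANNELS)}
#: actuator channel -> (array name on ClosedLoopResult, row)
_SOURCE = {
    "ap_act": ("commands", _CMD_ROW["ankle_fe_Nm"]),
    "ie_act": ("commands", _CMD_ROW["ankle_ie_Nm"]),
    "comp_act": ("commands", _CMD_ROW["hip_vert_N"]),
    "vv_act": ("commands", _CMD_ROW["ankle_ml_N"]),
    "quad_act": ("commands", _CMD_ROW["quad_N"]),
    "ham_act": ("commands", _CMD_ROW["ham_N"]),
    "hip_ap_mm": ("motion", 0),
    "pelvic_rot_deg": ("motion", 1),
}


@dataclass
class ActuatorEnsemble:
    """Instances x (channels * n_points) matrix of standardized profiles.

    ``matrix`` holds the standardized values; ``scaling`` is the pooled
    (cross-instance, cross-cycle) SD each channel block was divided by,
    with zero-SD channels scaled by 1 and flagged.
    """

    activity: str
    channels: tuple[str, ...]
    n_points: int
    matrix: np.ndarray
    scaling: np.ndarray
    zero_sd: np.ndarray
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, f = self.matrix.shape
        if n < 2:
            raise ValueError("an ensemble needs >= 2 instances for PCA")
        if f != len(self.channels) * self.n_points:
            raise ValueError("matrix width != channels * n_points")

    @property
    def n_instances(self) -> int:
        return self.matrix.shape[0]

    def block(self, channel: str, row: np.ndarray) -> np.ndarray:
        i = self.channels.index(channel)
        return row[i * self.n_points: (i + 1) * self.n_points]

    def unscale(self, row: np.ndarray) -> dict[str, np.ndarray]:
        """Split a feature row into named channels in physical units."""
        return {
            c: self.block(c, row) * self.scaling[i]
            for i, c in enumerate(self.channels)
        }

    def physical_matrix(self) -> np.ndarray:
        """The ensemble with the channel standardization inverted."""
        out = self.matrix.copy()
        for i in range(len(self.channels)):
            out[:, i * self.n_points: (i + 1) * self.n_points] *= self.scaling[i]
        return out


@dataclass
class PCAModel:
    """Mean, orthonormal components and variances of an actuator ensemble.

    Components live in the standardized feature space; ``scaling`` maps
    them back to physical units channel-block-wise.  The sign convention
    fixes each component's largest-magnitude coefficient positive.
    """

    channels: tuple[str, ...]
    n_points: int
    scaling: np.ndarray
    mean: np.ndarray
    components: np.ndarray          # (k, features), orthonormal rows
    variances: np.ndarray           # (k,) score variances, n-1 denominator
    variance_fractions: np.ndarray  # (k,) sums to 1 unless zero_variance
    zero_variance: bool = False

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def unscale(self, row: np.ndarray) -> dict[str, np.ndarray]:
        return {
            c: row[i * self.n_points: (i + 1) * self.n_points] * self.scaling[i]
            for i, c in enumerate(self.channels)
        }

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Standardized feature row from a (k,) score vector."""
        scores = np.asarray(scores, dtype=float)
        return self.mean + scores @ self.components

    def unscaled_mean(self) -> np.ndarray:
        """The mean feature row in physical units (concatenated channels)."""
        row = self.mean.copy()
        for i in range(len(self.channels)):
            row[i * self.n_points: (i + 1) * self.n_points] *= self.scaling[i]
        return row


def assemble_ensemble(
    results: list[ClosedLoopResult],
    activity: str,
    n_points: int = 101,
    include_hamstring: bool = False,
) -> ActuatorEnsemble:
    """Concatenate per-patient actuator profiles into a PCA-ready matrix.

    Each instance is the concatenation of its channels resampled onto a
    uniform ``n_points`` grid, each channel block divided by its pooled
    cross-instance, cross-cycle SD (recorded in the scaling metadata).
    """
    results = [r for r in results if r.activity == activity]
    if len(results) < 2:
        raise ValueError(
            f"need >= 2 closed-loop results of activity {activity!r}"
        )
    channels = ACTUATOR_CHANNELS + (("ham_act",) if include_hamstring else ())
    grid = np.linspace(0.0, 100.0, n_points)
    n = len(results)
    raw = np.empty((n, len(channels) * n_points))
    for j, res in enumerate(results):
        for i, c in enumerate(channels):
            attr, row = _SOURCE[c]
            series = getattr(res, attr)[row]
            raw[j, i * n_points: (i + 1) * n_points] = np.interp(
                grid, res.cycle_pct, series
            )
    scaling = np.ones(len(channels))
    zero_sd = np.zeros(len(channels), dtype=bool)
    for i in range(len(channels)):
        block = raw[:, i * n_points: (i + 1) * n_points]
        # pooled SD of the cross-instance deviations: pointwise variance
        # across instances, pooled over the cycle
        sd = float(np.sqrt(np.mean(block.var(axis=0))))
        if sd > 0.0:
            scaling[i] = sd
            block /= sd
        else:
            zero_sd[i] = True
    return ActuatorEnsemble(
        activity=activity, channels=channels, n_points=n_points, matrix=raw,
        scaling=scaling, zero_sd=zero_sd,
        units={c: ACTUATOR_UNITS[c] for c in channels},
    )


def fit_pca(ensemble: ActuatorEnsemble) -> PCAModel:
    """Column-mean-centered SVD of the standardized ensemble.

    Retains ``min(instances - 1, features)`` components; variance
    fractions are the squared singular values over their sum, so they sum
    to one and are non-increasing.  An all-identical ensemble yields a
    zero-total-variance model, flagged rather than an error.
    """
    X = ensemble.matrix
    n, f = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, f)
    S = S[:k]
    components = Vt[:k].copy()
    total = float(np.sum(S ** 2))
    zero_variance = not (total > 0.0)
    if zero_variance:
        fractions = np.zeros(k)
        variances = np.zeros(k)
    else:
        fractions = S ** 2 / total
        variances = S ** 2 / (n - 1)
    # deterministic sign: largest-|coefficient| entry of each component > 0
    for i in range(k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    return PCAModel(
        channels=ensemble.channels, n_points=ensemble.n_points,
        scaling=ensemble.scaling.copy(), mean=mean, components=components,
        variances=variances, variance_fractions=fractions,
        zero_variance=zero_variance,
    )


def mode_profile(
    model: PCAModel, pc_index: int, k: float
) -> dict[str, np.ndarray]:
    """Mean actuator profile perturbed along one mode.

    Returns the per-channel profiles of ``mean + k * sqrt(var_pc) * PC``
    in physical units; ``k`` is the score in SD units (k = 0 gives the
    mean profile exactly).
    """
    if not (0 <= pc_index < model.n_components):
        raise IndexError(
            f"pc_index {pc_index} out of range [0, {model.n_components})"
        )
    row = model.mean + k * np.sqrt(model.variances[pc_index]) * \
        model.components[pc_index]
    return model.unscale(row)


def sample_ebc(
    model: PCAModel,
    n: int,
    seed: int,
    n_components: int | None = None,
    truncation: float = 2.0,
) -> list[dict[str, np.ndarray]]:
    """Draw new boundary-condition profile sets from the PCA model.

    Scores are drawn independently per retained component from zero-mean
    Gaussians with the component's variance, truncated at +/-
    ``truncation`` SD, then reconstructed to physical units.  Seeded and
    reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_components is None:
        n_components = model.n_components
    if not (0 <= n_components <= model.n_components):
        raise ValueError(
            f"n_components {n_components} exceeds available "
            f"{model.n_components}"
        )
    if truncation < 0:
        raise ValueError("truncation must be >= 0")
    rng = np.random.default_rng(seed)
    sds = np.sqrt(model.variances[:n_components])
    if truncation == 0.0 or n_components == 0:
        scores = np.zeros((n, n_components))
    else:
        scores = stats.truncnorm.rvs(
            -truncation, truncation, size=(n, n_components), random_state=rng
        ) * sds
    out = []
    for i in range(n):
        full = np.zeros(model.n_components)
        full[:n_components] = scores[i]
        out.append(model.unscale(model.reconstruct(full)))
    return out
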