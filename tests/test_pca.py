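"""PCA of actuator ensembles: decomposition, modes, sampling."""

import numpy as np
import pytest

from limbsim import (
    ActuatorEnsemble,
    assemble_ensemble,
    fit_pca,
    make_template,
    mode_profile,
    sample_ebc,
    simulate_closed_loop,
)
from limbsim.pca import ACTUATOR_CHANNELS
from tests.test_control import GOOD_GAINS


@pytest.fixture(scope="module")
def gait_runs():
    """A handful of distinct closed-loop runs of the same activity."""
    runs = []
    for scale in (0.85, 1.0, 1.15, 1.3):
        tpl = make_template("gait")
        prof = type(tpl)(
            activity="gait", cycle_pct=tpl.cycle_pct,
            flexion_deg=tpl.flexion_deg * scale,
            comp_N=tpl.comp_N * scale, ap_N=tpl.ap_N * scale,
            ie_Nm=tpl.ie_Nm * scale, vv_Nm=tpl.vv_Nm * scale,
            pelvic_rot_deg=tpl.pelvic_rot_deg * scale,
            hip_ap_mm=tpl.hip_ap_mm * scale,
        )
        runs.append(simulate_closed_loop(prof, GOOD_GAINS))
    return runs


def _synthetic_ensemble(n, fractions, seed=0, n_points=40,
                        channels=("a", "b")):
    """Ensemble drawn from a known low-rank Gaussian model."""
    rng = np.random.default_rng(seed)
    f = len(channels) * n_points
    basis = np.linalg.qr(rng.normal(size=(f, len(fractions))))[0].T
    total_var = 25.0
    scores = rng.normal(
        size=(n, len(fractions))
    ) * np.sqrt(np.array(fractions) * total_var)
    X = scores @ basis + rng.normal(0, 1e-6, size=(n, f))
    return ActuatorEnsemble(
        activity="gait", channels=tuple(channels), n_points=n_points,
        matrix=X, scaling=np.ones(len(channels)),
        zero_sd=np.zeros(len(channels), dtype=bool),
    )


class TestAssemble:
    def test_matrix_shape(self, gait_runs):
        ens = assemble_ensemble(gait_runs, "gait", n_points=101)
        assert ens.matrix.shape == (len(gait_runs), 7 * 101)
        assert ens.channels == ACTUATOR_CHANNELS

    def test_channel_standardization_round_trip(self, gait_runs):
        ens = assemble_ensemble(gait_runs, "gait", n_points=51)
        phys = ens.physical_matrix()
        for i, c in enumerate(ens.channels):
            blk = phys[:, i * 51: (i + 1) * 51]
            scaled_back = blk / ens.scaling[i]
            np.testing.assert_allclose(
                scaled_back, ens.matrix[:, i * 51: (i + 1) * 51],
                rtol=1e-12,
            )
            if not ens.zero_sd[i]:
                pooled = np.sqrt(np.mean(blk.var(axis=0)))
                assert pooled == pytest.approx(ens.scaling[i], rel=1e-9)

    def test_identical_results_flagged_zero_sd(self, gait_runs):
        ens = assemble_ensemble([gait_runs[0], gait_runs[0]], "gait",
                                n_points=31)
        assert ens.zero_sd.all()
        np.testing.assert_allclose(ens.scaling, 1.0)

    def test_hamstring_channel_optional(self, gait_runs):
        ens = assemble_ensemble(gait_runs, "gait", n_points=31,
                                include_hamstring=True)
        assert "ham_act" in ens.channels
        assert ens.matrix.shape[1] == 8 * 31

    def test_requires_two_instances(self, gait_runs):
        with pytest.raises(ValueError):
            assemble_ensemble(gait_runs[:1], "gait")


class TestFit:
    def test_rank_one_data_single_component(self):
        ens = _synthetic_ensemble(30, [1.0], seed=3)
        model = fit_pca(ens)
        assert model.variance_fractions[0] == pytest.approx(1.0, abs=1e-6)

    def test_two_feature_covariance_fractions(self):
        # four instances of two features with sample covariance
        # [[2, 0], [0, 1]]: eigenvalues 2 and 1 -> fractions 2/3, 1/3
        X = np.array([
            [np.sqrt(3.0), 0.0],
            [-np.sqrt(3.0), 0.0],
            [0.0, np.sqrt(1.5)],
            [0.0, -np.sqrt(1.5)],
        ])  # n-1 covariance is diag(2, 1)
        cov = np.cov(X.T)
        np.testing.assert_allclose(cov, np.diag([2.0, 1.0]), atol=1e-12)
        ens = ActuatorEnsemble(
            activity="gait", channels=("a", "b"), n_points=1, matrix=X,
            scaling=np.ones(2), zero_sd=np.zeros(2, dtype=bool),
        )
        model = fit_pca(ens)
        np.testing.assert_allclose(model.variance_fractions,
                                   [2.0 / 3.0, 1.0 / 3.0], atol=1e-12)

    def test_full_reconstruction_identity(self, gait_runs):
        ens = assemble_ensemble(gait_runs, "gait", n_points=41)
        model = fit_pca(ens)
        Xc = ens.matrix - model.mean
        scores = Xc @ model.components.T
        recon = model.mean + scores @ model.components
        np.testing.assert_allclose(recon, ens.matrix, atol=1e-10)

    def test_components_orthonormal(self, gait_runs):
        model = fit_pca(assemble_ensemble(gait_runs, "gait", n_points=41))
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(model.n_components),
                                   atol=1e-10)

    def test_fractions_sum_to_one_non_increasing(self, gait_runs):
        model = fit_pca(assemble_ensemble(gait_runs, "gait", n_points=41))
        assert model.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(model.variance_fractions) <= 1e-12)

    def test_sign_convention(self, gait_runs):
        model = fit_pca(assemble_ensemble(gait_runs, "gait", n_points=41))
        for comp in model.components:
            assert comp[np.argmax(np.abs(comp))] > 0.0

    def test_degenerate_ensemble_flagged(self, gait_runs):
        ens = assemble_ensemble([gait_runs[0], gait_runs[0]], "gait",
                                n_points=21)
        model = fit_pca(ens)
        assert model.zero_variance
        np.testing.assert_allclose(model.variance_fractions, 0.0)

    def test_fraction_recovery_known_model(self):
        """Fractions 0.75 / 0.20 / 0.05 recovered within +/-0.03 at
        n = 200 instances."""
        ens = _synthetic_ensemble(200, [0.75, 0.20, 0.05], seed=2)
        model = fit_pca(ens)
        np.testing.assert_allclose(
            model.variance_fractions[:3], [0.75, 0.20, 0.05], atol=0.03
        )

    def test_matches_sklearn(self, gait_runs):
        from sklearn.decomposition import PCA

        ens = assemble_ensemble(gait_runs, "gait", n_points=41)
        model = fit_pca(ens)
        sk = PCA().fit(ens.matrix)
        k = model.n_components
        np.testing.assert_allclose(
            model.variance_fractions[:k],
            sk.explained_variance_ratio_[:k], atol=1e-8,
        )


class TestModes:
    def test_zero_score_is_the_mean(self, gait_runs):
        ens = assemble_ensemble(gait_runs, "gait", n_points=41)
        model = fit_pca(ens)
        prof = mode_profile(model, 0, 0.0)
        expect = model.unscale(model.mean)
        for c in model.channels:
            np.testing.assert_allclose(prof[c], expect[c], atol=1e-12)

    def test_symmetry_about_mean(self, gait_runs):
        model = fit_pca(assemble_ensemble(gait_runs, "gait", n_points=41))
        mean = mode_profile(model, 0, 0.0)
        plus = mode_profile(model, 0, 1.0)
        minus = mode_profile(model, 0, -1.0)
        for c in model.channels:
            np.testing.assert_allclose(plus[c] + minus[c], 2 * mean[c],
                                       atol=1e-9)

    def test_rank_one_mode_recovers_generator_direction(self):
        ens = _synthetic_ensemble(100, [1.0], seed=5)
        model = fit_pca(ens)
        prof = mode_profile(model, 0, 1.0)
        row = np.concatenate([prof[c] for c in model.channels])
        expect = model.mean + np.sqrt(model.variances[0]) * model.components[0]
        np.testing.assert_allclose(row, expect, atol=1e-9)

    def test_index_out_of_range(self, gait_runs):
        model = fit_pca(assemble_ensemble(gait_runs, "gait", n_points=21))
        with pytest.raises(IndexError):
            mode_profile(model, model.n_components, 1.0)


class TestSampling:
    def test_seed_determinism(self, gait_runs):
        model = fit_pca(assemble_ensemble(gait_runs, "gait", n_points=31))
        a = sample_ebc(model, 5, seed=9)
        b = sample_ebc(model, 5, seed=9)
        for pa, pb in zip(a, b):
            for c in model.channels:
                np.testing.assert_array_equal(pa[c], pb[c])

    def test_sample_mean_near_model_mean(self):
        ens = _synthetic_ensemble(100, [0.6, 0.4], seed=2)
        model = fit_pca(ens)
        samples = sample_ebc(model, 10000, seed=1)
        mat = np.vstack([
            np.concatenate([s[c] for c in model.channels]) for s in samples
        ])
        se = mat.std(axis=0) / np.sqrt(len(samples))
        err = np.abs(mat.mean(axis=0) - model.unscaled_mean())
        assert np.all(err < 3.0 * np.maximum(se, 1e-12) + 1e-9)

    def test_zero_truncation_returns_the_mean(self, gait_runs):
        model = fit_pca(assemble_ensemble(gait_runs, "gait", n_points=31))
        samples = sample_ebc(model, 3, seed=4, truncation=0.0)
        expect = model.unscale(model.mean)
        for s in samples:
            for c in model.channels:
                np.testing.assert_allclose(s[c], expect[c], atol=1e-12)

    def test_scores_respect_truncation(self):
        ens = _synthetic_ensemble(80, [0.7, 0.3], seed=8)
        model = fit_pca(ens)
        samples = sample_ebc(model, 2000, seed=3, truncation=1.0)
        mat = np.vstack([
            np.concatenate([s[c] for s_c in [model.channels] for c in s_c])
            for s in samples
        ])
        scores = (mat - model.unscaled_mean()) @ model.components.T
        for j in range(model.n_components):
            sd = np.sqrt(model.variances[j])
            if sd > 1e-9:
                assert np.max(np.abs(scores[:, j])) <= sd + 1e-6

    def test_sampling_preserves_cross_channel_correlation(self):
        """A generator whose PC1 couples two channel peaks yields samples
        whose peak correlation matches the generator within 0.1."""
        rng = np.random.default_rng(21)
        n_points, n = 30, 1000
        t = np.linspace(0, 1, n_points)
        bump = np.exp(-(((t - 0.5) / 0.2) ** 2))
        direction = np.concatenate([bump, -0.8 * bump])
        direction /= np.linalg.norm(direction)
        scores = rng.normal(0, 3.0, size=(4000, 1))
        X = 5.0 + scores @ direction[None, :] \
            + rng.normal(0, 0.05, size=(4000, 2 * n_points))
        ens = ActuatorEnsemble(
            activity="gait", channels=("u", "v"), n_points=n_points,
            matrix=X, scaling=np.ones(2), zero_sd=np.zeros(2, dtype=bool),
        )
        truth = np.corrcoef(
            X[:, :n_points].max(axis=1), X[:, n_points:].min(axis=1)
        )[0, 1]
        model = fit_pca(ens)
        samples = sample_ebc(model, n, seed=6, n_components=1)
        peaks_u = np.array([s["u"].max() for s in samples])
        peaks_v = np.array([s["v"].min() for s in samples])
        got = np.corrcoef(peaks_u, peaks_v)[0, 1]
        assert got == pytest.approx(truth, abs=0.1)

    def test_invalid_requests(self, gait_runs):
        model = fit_pca(assemble_ensemble(gait_runs, "gait", n_points=21))
        with pytest.raises(ValueError):
            sample_ebc(model, 0, seed=1)
        with pytest.raises(ValueError):
            sample_ebc(model, 1, seed=1, n_components=99)
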