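"""Factor model: standardization, ML fit, varimax, Bartlett scores, labelling."""

import numpy as np
import pandas as pd
import pytest

from adiposeg import factors
from adiposeg.factors import (
    FactorModel,
    bartlett_scores,
    label_and_sign,
    ml_factor_fit,
    standardize_log,
    varimax_criterion,
    varimax_rotate,
)
from adiposeg.simulate import MEASURE_COLUMNS, simulate_cohort


def grid_varimax_oracle(lam, n_angles=360_000):
    """Brute-force 1-D search over the rotation angle (k=2 oracle)."""
    phi = np.linspace(-np.pi / 4, np.pi / 4, n_angles, endpoint=False)
    c, s = np.cos(phi), np.sin(phi)
    h = np.sqrt((lam**2).sum(axis=1))
    w = lam / h[:, None]
    a = w[:, 0, None] * c + w[:, 1, None] * s  # (p, n_angles)
    b = -w[:, 0, None] * s + w[:, 1, None] * c
    crit = (a**2).var(axis=0) + (b**2).var(axis=0)
    i = int(np.argmax(crit))
    return phi[i], float(crit[i])


def make_model(lam, psi=None, names=None):
    lam = np.asarray(lam, dtype=float)
    p, k = lam.shape
    if psi is None:
        psi = np.clip(1 - (lam**2).sum(axis=1), 0.005, 1.0)
    return FactorModel(
        loadings=lam,
        uniquenesses=np.asarray(psi, float),
        rotation=np.eye(k),
        var_explained=(lam**2).sum(axis=0) / p,
        cov_explained=1.0,
        variable_names=tuple(names or (f"v{i}" for i in range(p))),
    )


class TestStandardizeLog:
    def test_closed_form_column(self):
        df = pd.DataFrame({c: [1.0, np.e, np.e**2] for c in MEASURE_COLUMNS})
        df["waist_cm"] = [2.0, 4.0, 8.0]  # avoid all-identical correlations
        z = standardize_log(df)
        # sample-SD convention: log(1, e, e^2) -> (-1, 0, 1)
        np.testing.assert_allclose(z["height_m"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_normalization_contract(self, paper_cohort):
        z = standardize_log(paper_cohort)
        assert np.abs(z.mean()).max() < 1e-12
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_constant_column_rejected(self, paper_cohort):
        df = paper_cohort.copy()
        df["fat_kg"] = 25.0
        with pytest.raises(ValueError, match="zero variance"):
            standardize_log(df)

    def test_nonpositive_names_row_and_column(self, paper_cohort):
        df = paper_cohort.copy()
        df.loc[7, "hip_cm"] = -1.0
        with pytest.raises(ValueError, match=r"hip_cm.*7"):
            standardize_log(df)


class TestMlFactorFit:
    def test_k0_rejected(self, paper_cohort):
        z = standardize_log(paper_cohort)
        with pytest.raises(ValueError):
            ml_factor_fit(z, k=0)

    def test_recovers_generating_structure(self, unit_latent_config):
        cohort = simulate_cohort(unit_latent_config)
        z = standardize_log(cohort)
        model = ml_factor_fit(z, k=2)
        lam = np.asarray(unit_latent_config.loading_matrix)
        target = lam @ lam.T + np.diag(unit_latent_config.uniquenesses)
        fitted = model.loadings @ model.loadings.T + np.diag(model.uniquenesses)
        assert np.max(np.abs(fitted - target)) < 0.02

    def test_rotational_indeterminacy(self, unit_latent_config, paper_cohort):
        # an orthogonal rotation of the generating loadings leaves the fitted
        # common covariance invariant
        z = standardize_log(paper_cohort)
        model = ml_factor_fit(z, k=2)
        phi = 0.7
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        rotated = model.loadings @ rot
        np.testing.assert_allclose(
            rotated @ rotated.T, model.loadings @ model.loadings.T, atol=1e-10
        )

    def test_communality_plus_uniqueness_is_one(self, paper_cohort):
        z = standardize_log(paper_cohort)
        model = ml_factor_fit(z, k=2)
        np.testing.assert_allclose(
            model.communalities + model.uniquenesses, 1.0, atol=1e-5
        )

    def test_agrees_with_sklearn_oracle(self, unit_latent_config):
        # independent implementation of the same ML problem
        sklearn_fa = pytest.importorskip("sklearn.decomposition")
        cohort = simulate_cohort(unit_latent_config)
        z = standardize_log(cohort)
        model = ml_factor_fit(z, k=2)
        fa = sklearn_fa.FactorAnalysis(n_components=2, tol=1e-6, max_iter=5000)
        fa.fit(z.to_numpy())
        theirs = fa.components_.T @ fa.components_ + np.diag(fa.noise_variance_)
        ours = model.loadings @ model.loadings.T + np.diag(model.uniquenesses)
        assert np.max(np.abs(ours - theirs)) < 0.01

    def test_var_explained_on_study_conditions(self, paper_cohort):
        z = standardize_log(paper_cohort)
        model = ml_factor_fit(z, k=2)
        assert 0.75 <= model.var_explained_total <= 0.85
        assert model.cov_explained > 0.90


# five fixed loading sets for the rotation oracle: a toy pair, the generator
# pattern, and rotated/perturbed versions
_TOY = np.array([[0.8, 0.6], [-0.6, 0.8]])
_GEN = np.array(
    [[0.9, 0.0], [0.3, 0.85], [0.1, 0.85], [0.9, 0.35], [0.9, 0.35], [0.0, 0.95]]
)


def _rot(phi):
    return np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])


_LOADING_SETS = [
    _TOY,
    _TOY @ _rot(0.5),
    _GEN,
    _GEN @ _rot(-0.3),
    _GEN @ _rot(0.61) + 0.01 * np.sin(np.arange(12)).reshape(6, 2),
]


class TestVarimax:
    @pytest.mark.parametrize("lam", _LOADING_SETS, ids=range(5))
    def test_matches_grid_search_oracle(self, lam):
        model = varimax_rotate(make_model(lam))
        _, oracle_crit = grid_varimax_oracle(lam)
        ours = varimax_criterion(model.loadings)
        assert ours >= oracle_crit - 1e-4
        assert abs(ours - oracle_crit) < 1e-4

    @pytest.mark.parametrize("lam", _LOADING_SETS, ids=range(5))
    def test_criterion_non_decreasing(self, lam):
        before = varimax_criterion(lam)
        after = varimax_criterion(varimax_rotate(make_model(lam)).loadings)
        assert after >= before - 1e-12

    def test_fixed_point(self):
        once = varimax_rotate(make_model(_GEN))
        twice = varimax_rotate(once)
        assert varimax_criterion(twice.loadings) == pytest.approx(
            varimax_criterion(once.loadings), abs=1e-10
        )

    @pytest.mark.parametrize("lam", _LOADING_SETS, ids=range(5))
    def test_communalities_invariant(self, lam):
        model = make_model(lam)
        rotated = varimax_rotate(model)
        np.testing.assert_allclose(
            rotated.communalities, model.communalities, atol=1e-10
        )

    def test_rotation_matrix_orthonormal(self):
        rotated = varimax_rotate(make_model(_GEN))
        np.testing.assert_allclose(
            rotated.rotation.T @ rotated.rotation, np.eye(2), atol=1e-8
        )


class TestBartlettScores:
    def test_noise_free_exact_inversion(self):
        rng = np.random.default_rng(4)
        f = rng.standard_normal((50, 2))
        z = f @ _GEN.T  # exactly the common part, no unique noise
        model = make_model(_GEN)
        scores = bartlett_scores(z, model)
        np.testing.assert_allclose(scores.to_numpy(), f, atol=1e-6)

    def test_zero_row_gives_zero_scores(self):
        model = make_model(_GEN)
        scores = bartlett_scores(np.zeros((3, 6)), model)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-14)

    def test_singular_gram_rejected(self):
        lam = np.tile([[0.8], [0.5], [0.3], [0.7], [0.6], [0.4]], (1, 2))
        with pytest.raises(ValueError, match="singular"):
            bartlett_scores(np.zeros((3, 6)), make_model(lam))

    def test_unbiasedness_against_known_latents(self):
        # E[score | latent] = latent under the model, so regressing each
        # score on the matching true latent gives slope 1
        rng = np.random.default_rng(8)
        n = 10_000
        f = rng.standard_normal((n, 2))
        psi = np.clip(1 - (_GEN**2).sum(axis=1), 0.005, 1.0)
        x = f @ _GEN.T + rng.standard_normal((n, 6)) * np.sqrt(psi)
        z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        # rotate to the simple-structure basis the loadings were built in,
        # then align columns by correlation
        model = varimax_rotate(ml_factor_fit(z, k=2))
        scores = bartlett_scores(z, model).to_numpy()
        for j in range(2):
            corrs = [abs(np.corrcoef(scores[:, i], f[:, j])[0, 1]) for i in range(2)]
            i = int(np.argmax(corrs))
            sc = scores[:, i] * np.sign(np.corrcoef(scores[:, i], f[:, j])[0, 1])
            slope = np.polyfit(f[:, j], sc, 1)[0]
            assert slope == pytest.approx(1.0, abs=0.05)


class TestLabelAndSign:
    def test_sign_convention_flips_fat(self):
        lam = np.array(
            [[0.9, 0.0], [0.2, -0.8], [0.1, -0.8], [0.8, -0.3], [0.8, -0.3], [0.0, -0.95]]
        )
        model = make_model(lam, names=MEASURE_COLUMNS)
        scores = pd.DataFrame(np.ones((4, 2)), columns=["factor1", "factor2"])
        labelled, new_scores = label_and_sign(model, scores)
        assert labelled.factor_labels == ("Frame", "Adiposity")
        assert labelled.loadings[5, 1] == pytest.approx(0.95)
        np.testing.assert_allclose(new_scores["adiposity"], -1.0)

    def test_column_permutation_invariance(self):
        model = make_model(_GEN, names=MEASURE_COLUMNS)
        swapped = make_model(_GEN[:, ::-1], names=MEASURE_COLUMNS)
        scores = pd.DataFrame(
            np.arange(8.0).reshape(4, 2), columns=["factor1", "factor2"]
        )
        a, sa = label_and_sign(model, scores)
        b, sb = label_and_sign(swapped, scores[scores.columns[::-1]])
        np.testing.assert_allclose(a.loadings, b.loadings)
        np.testing.assert_allclose(sa.to_numpy(), sb.to_numpy()[:, [0, 1]])

    def test_ambiguous_pattern_warns(self):
        lam = np.array(
            [[0.5, 0.52], [0.3, 0.8], [0.1, 0.8], [0.8, 0.3], [0.8, 0.3], [0.0, 0.9]]
        )
        model = make_model(lam, names=MEASURE_COLUMNS)
        scores = pd.DataFrame(np.zeros((2, 2)), columns=["factor1", "factor2"])
        with pytest.warns(UserWarning, match="ambiguous"):
            label_and_sign(model, scores)

    def test_frame_is_skeletal_factor_on_simulated_cohort(self, paper_cohort):
        z = standardize_log(paper_cohort)
        model = varimax_rotate(ml_factor_fit(z, k=2))
        scores = bartlett_scores(z, model)
        model, scores = label_and_sign(model, scores)
        lam = pd.DataFrame(
            model.loadings, index=model.variable_names, columns=["frame", "adiposity"]
        )
        assert lam.loc["height_m", "frame"] > 0.6
        assert lam.loc["lean_kg", "frame"] > 0.6
        assert lam.loc["bone_kg", "frame"] > 0.6
        assert lam.loc["fat_kg", "adiposity"] > 0.6
        # labelled scores track their marker measurements
        assert scores["adiposity"].corr(paper_cohort["fat_kg"]) > 0.5
        assert scores["frame"].corr(paper_cohort["height_m"]) > 0.5
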