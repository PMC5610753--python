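"""Factor extraction, varimax rotation, FA-MLR and PCRA."""

import numpy as np
import pandas as pd
import pytest

from qsarlab import (DescriptorTable, FAMLR, PCRA, FactorAnalysisVarimax,
                     SyntheticSpec, fa_mlr, factor_analysis, generate_dataset,
                     pcra, varimax)
from qsarlab.exceptions import ConfigError
from qsarlab.factors import varimax_criterion


def _two_factor_table(n=60, seed=0, noise=0.0):
    """Ten descriptors spanned by two latent factors; activity on factor 1."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n, 2))
    Q, _ = np.linalg.qr(raw - raw.mean(axis=0))   # exactly orthogonal latents
    f1, f2 = (Q * np.sqrt(n)).T
    cols = {}
    for j in range(5):
        cols[f"A{j}"] = f1 * (1 + 0.1 * j) + noise * rng.normal(size=n)
    for j in range(5):
        cols[f"B{j}"] = f2 * (1 - 0.05 * j) + noise * rng.normal(size=n)
    X = pd.DataFrame(cols, index=[f"c{i}" for i in range(n)])
    y = 2.0 * f1 + 0.3 * rng.normal(size=n)
    return DescriptorTable(X, pd.Series(y, index=X.index))


def test_exact_low_rank_data_needs_two_factors():
    table = _two_factor_table()
    fa = FactorAnalysisVarimax(0.95).fit(table)
    assert fa.model_.n_factors == 2
    assert np.sum(fa.explained_variance_ratio_) == pytest.approx(1.0, abs=1e-9)


def test_rotation_is_orthonormal_and_preserves_communality(small_table):
    fa = FactorAnalysisVarimax(0.95).fit(small_table)
    R = fa.rotation_
    assert np.linalg.norm(R.T @ R - np.eye(R.shape[1])) < 1e-8
    # communalities are rotation invariant
    eig = fa.eigenvalues_[:fa.model_.n_factors]
    # unrotated loadings reconstructed from scores/eigen decomposition
    unrot = fa.loadings_.to_numpy() @ R.T
    np.testing.assert_allclose((unrot ** 2).sum(axis=1),
                               fa.communalities_.to_numpy(), atol=1e-8)
    assert np.all(np.diff(fa.explained_variance_ratio_) <= 1e-12)
    assert np.sum(fa.explained_variance_ratio_) <= 1 + 1e-9


def test_varimax_fixed_point_on_axis_aligned_loadings():
    L = np.array([[0.9, 0.0], [0.8, 0.0], [0.0, 0.7], [0.0, 0.95]])
    rotated, R = varimax(L)
    # unchanged up to column sign/order
    gram = np.abs(rotated.T @ L)
    assert np.allclose(np.sort(gram.max(axis=0)),
                       np.sort((L ** 2).sum(axis=0)), atol=1e-6)
    assert varimax_criterion(rotated) >= varimax_criterion(L) - 1e-10


def test_varimax_matches_grid_search_oracle(small_table):
    """For 2 factors the optimal orthogonal rotation is a single angle:
    exhaustive fine-grid search bounds the achievable criterion."""
    fa = FactorAnalysisVarimax(0.7).fit(small_table)
    L = fa.loadings_.to_numpy() @ fa.rotation_.T   # unrotated
    L = L[:, :2]
    h = np.sqrt((L ** 2).sum(axis=1))
    h = np.where(h > 0, h, 1.0)
    Ln = L / h[:, None]

    def crit_at(theta):
        c, s = np.cos(theta), np.sin(theta)
        return varimax_criterion(Ln @ np.array([[c, -s], [s, c]]))

    grid_best = max(crit_at(t) for t in np.linspace(0, np.pi / 2, 20001))
    ours, _ = varimax(L)
    ours_crit = varimax_criterion(ours / h[:, None])
    assert ours_crit == pytest.approx(grid_best, abs=1e-6)


def test_varimax_agrees_with_statsmodels(small_table):
    """Raw (un-normalized) varimax reaches the same criterion optimum as
    statsmodels' GPA implementation (which also optimizes raw varimax)."""
    from statsmodels.multivariate.factor_rotation import rotate_factors

    fa = FactorAnalysisVarimax(0.9).fit(small_table)
    L = fa.loadings_.to_numpy() @ fa.rotation_.T
    sm_rot, _ = rotate_factors(L, "varimax")
    ours, _ = varimax(L, kaiser=False)
    assert varimax_criterion(ours) == pytest.approx(
        varimax_criterion(sm_rot), abs=1e-6)


def test_factor_reconstruction_within_discarded_variance(small_table):
    fa = FactorAnalysisVarimax(0.8).fit(small_table)
    Z = ((small_table.X[fa.columns_] - fa.mean_) / fa.sd_).to_numpy()
    recon = fa.scores_.to_numpy() @ fa.loadings_.to_numpy().T
    discarded = 1.0 - np.sum(fa.explained_variance_ratio_)
    n, p = Z.shape
    assert np.sum((Z - recon) ** 2) <= discarded * (n - 1) * p + 1e-6


def test_variance_target_validation(small_table):
    with pytest.raises(ConfigError):
        FactorAnalysisVarimax(1.5).fit(small_table)
    with pytest.raises(ConfigError):
        FactorAnalysisVarimax(0.0).fit(small_table)


def test_fa_mlr_pool_comes_from_activity_factor():
    table = _two_factor_table(noise=0.05, seed=3)
    est = FAMLR(variance_target=0.95, loading_threshold=0.6).fit(table)
    # activity loads on factor 1 = the A-block; pool must stay in-block
    assert set(est.pool_) <= {f"A{j}" for j in range(5)}
    assert est.selected_ and set(est.selected_) <= set(est.pool_)


def test_fa_mlr_threshold_too_strict():
    table = _two_factor_table(noise=0.5, seed=5)
    with pytest.raises(ConfigError, match="empty"):
        FAMLR(loading_threshold=0.999).fit(table)


def test_fa_mlr_model_reproducible_by_ols(small_table):
    est = FAMLR(loading_threshold=0.3).fit(small_table)
    from qsarlab import fit_ols

    direct = fit_ols(small_table, est.selected_)
    np.testing.assert_allclose(direct.coef, est.model_.coef, atol=1e-10)


def test_pcra_scores_orthogonal_and_planted_factor_found():
    table = _two_factor_table(noise=0.05, seed=9)
    est = PCRA(variance_target=0.95).fit(table)
    scores = est.fa_.scores_[list(est.selected_)]
    gram = np.corrcoef(scores.to_numpy(), rowvar=False)
    if gram.ndim == 2:
        assert np.max(np.abs(gram - np.eye(len(gram)))) < 1e-8
    # the factor aligned with activity must be selected
    corr = est.fa_.scores_.corrwith(table.activity).abs()
    assert corr[list(est.selected_)].max() == pytest.approx(corr.max())


def test_pcra_coefficients_invariant_to_pool(small_table):
    """Orthogonal predictors: coefficients don't depend on unselected factors."""
    est = PCRA(variance_target=0.95).fit(small_table)
    from qsarlab import StepwiseMLR

    score_table = est.fa_.score_table(activity=small_table.activity)
    refit = StepwiseMLR().fit(score_table.subset(list(est.selected_))
                              .with_activity(small_table.activity))
    np.testing.assert_allclose(np.sort(refit.model_.coef),
                               np.sort(est.model_.coef), atol=1e-8)


def test_functional_wrappers(small_table):
    fm = factor_analysis(small_table, 0.95)
    assert fm.loadings.shape[1] == fm.n_factors
    m1 = pcra(small_table, fm)
    m2 = pcra(small_table)
    assert set(m1.names) == set(m2.names)
    m3 = fa_mlr(small_table, fm, loading_threshold=0.3)
    assert m3.names
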