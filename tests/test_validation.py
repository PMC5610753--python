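"""Fit statistics, LOO cross-validation, external set, Y-randomization."""

import numpy as np
import pytest

from qsarlab import (DescriptorTable, OLSRegression, StepwiseMLR,
                     SyntheticSpec, external_validate, fit_ols,
                     fit_statistics, generate_dataset, loo_cross_validate,
                     validation_report, y_randomization)
from qsarlab.exceptions import (InsufficientDataError, LeakageError,
                                SpecificationError)


def _dataset(noise=0.3, seed=1, n_train=25, n_test=7, p=5):
    spec = SyntheticSpec(n_train=n_train, n_test=n_test, p=p, support=(0, 2),
                         beta=(1.0, -1.0), intercept=5.0, noise_sd=noise,
                         seed=seed)
    return generate_dataset(spec)


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------

def test_perfect_fit_statistics():
    ds = _dataset(noise=0.0)
    m = fit_ols(ds.train, ["D000", "D002"])
    rep = fit_statistics(m, ds.train)
    assert rep.r2 == pytest.approx(1.0, abs=1e-12)
    assert rep.se == pytest.approx(0.0, abs=1e-7)


def test_mean_model_has_zero_r2():
    ds = _dataset()
    y = ds.train.activity.to_numpy()
    from qsarlab import LinearModel

    mean_model = LinearModel(("D000",), np.array([0.0]), float(y.mean()))
    rep = fit_statistics(mean_model, ds.train)
    assert rep.r2 == pytest.approx(0.0, abs=1e-12)


def test_fit_statistics_match_textbook_formulas():
    ds = _dataset(noise=0.5, seed=9)
    m = fit_ols(ds.train, ["D000", "D001", "D002"])
    rep = fit_statistics(m, ds.train)
    y = ds.train.activity.to_numpy()
    yhat = m.predict(ds.train)
    n, k = len(y), 3
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    assert rep.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)
    assert rep.se == pytest.approx(np.sqrt(ss_res / (n - k - 1)), abs=1e-10)
    f_expect = (np.sum((yhat - y.mean()) ** 2) / k) / (ss_res / (n - k - 1))
    assert rep.f_statistic == pytest.approx(f_expect, abs=1e-10)


def test_fit_statistics_dof_guard():
    ds = _dataset(n_train=4, n_test=0, p=5)
    m = fit_ols(_dataset(n_train=25).train, ["D000", "D001", "D002"])
    with pytest.raises(InsufficientDataError):
        fit_statistics(m, ds.train)


# ---------------------------------------------------------------------------
# LOO
# ---------------------------------------------------------------------------

def test_noiseless_system_has_unit_q2():
    ds = _dataset(noise=0.0)
    q2, rmscv, preds = loo_cross_validate(
        OLSRegression(selected=["D000", "D002"]), ds.train)
    assert q2 == pytest.approx(1.0, abs=1e-10)
    assert rmscv == pytest.approx(0.0, abs=1e-6)
    assert set(preds) == set(ds.train.ids)


def test_press_matches_bruteforce_refit_oracle():
    ds = _dataset(noise=0.4, seed=4)
    sel = ["D000", "D002", "D003"]
    q2, rmscv, preds = loo_cross_validate(OLSRegression(selected=sel),
                                          ds.train)
    y = ds.train.activity.to_numpy()
    ids = ds.train.ids
    press = 0.0
    for i, cid in enumerate(ids):
        rest = [c for c in ids if c != cid]
        m = fit_ols(ds.train.select_rows(rest), sel)
        press += (y[i] - m.predict(ds.train.select_rows([cid]))[0]) ** 2
    assert q2 == pytest.approx(1 - press / np.sum((y - y.mean()) ** 2),
                               abs=1e-9)
    assert rmscv == pytest.approx(np.sqrt(press / len(y)), abs=1e-9)


def test_permuted_activity_gives_nonpositive_mean_q2():
    ds = _dataset(noise=0.3, seed=6)
    rng = np.random.default_rng(0)
    y = ds.train.activity.to_numpy()
    q2s = []
    for _ in range(100):
        table = ds.train.with_activity(y[rng.permutation(len(y))])
        q2, _, _ = loo_cross_validate(OLSRegression(selected=["D000", "D002"]),
                                      table)
        q2s.append(q2)
    assert np.mean(q2s) <= 0.0


def test_strict_mode_reruns_selection(planted_table):
    est = StepwiseMLR()
    q2_frozen, _, _ = loo_cross_validate(est, planted_table, strict=False)
    q2_strict, _, _ = loo_cross_validate(est, planted_table, strict=True)
    assert q2_frozen == pytest.approx(1.0, abs=1e-3)
    assert q2_strict == pytest.approx(1.0, abs=1e-3)


def test_loo_row_order_invariance():
    ds = _dataset(noise=0.4, seed=13)
    sel = ["D000", "D002"]
    q2_a, _, _ = loo_cross_validate(OLSRegression(selected=sel), ds.train)
    shuffled = ds.train.select_rows(ds.train.ids[::-1])
    q2_b, _, _ = loo_cross_validate(OLSRegression(selected=sel), shuffled)
    assert q2_a == pytest.approx(q2_b, abs=1e-12)


# ---------------------------------------------------------------------------
# external validation
# ---------------------------------------------------------------------------

def test_noiseless_external_prediction_is_exact():
    ds = _dataset(noise=0.0)
    m = fit_ols(ds.train, ["D000", "D002"])
    r2p, sep = external_validate(m, ds.test)
    assert r2p == pytest.approx(1.0, abs=1e-10)
    assert sep == pytest.approx(0.0, abs=1e-6)


def test_constant_predictor_has_nonpositive_r2p():
    ds = _dataset(noise=0.2)
    from qsarlab import LinearModel

    const = LinearModel(("D000",), np.array([0.0]), 5.0)
    r2p, _ = external_validate(const, ds.test)
    assert r2p <= 0.0


def test_leakage_detected():
    ds = _dataset()
    m = fit_ols(ds.train, ["D000"])
    with pytest.raises(LeakageError):
        external_validate(m, ds.train, training_ids=ds.train.ids)


def test_external_equals_fit_statistics_on_training_set():
    ds = _dataset(noise=0.5, seed=2)
    m = fit_ols(ds.train, ["D000", "D002"])
    rep = fit_statistics(m, ds.train)
    r2p, sep = external_validate(m, ds.train, training_ids=())  # check off
    assert r2p == pytest.approx(rep.r2, abs=1e-12)
    n, k = rep.n_train, 2
    assert sep == pytest.approx(rep.se * np.sqrt((n - k - 1) / n), abs=1e-12)


def test_calibrated_noise_yields_expected_external_r2():
    """Signal variance Σβ² = 4.38; noise σ chosen so the population external
    R² is 0.87: σ² = 4.38·(1−0.87)/0.87.  A single 7-compound R²p is heavily
    skewed by its random denominator, so SSres/SStot are pooled over 50
    replicate test sets; the pooled R²p must land within ±0.1 of 0.87."""
    beta = (1.2, -1.0, 0.9, 0.7, -0.8)
    sig_var = float(np.sum(np.square(beta)))
    sigma = np.sqrt(sig_var * (1 - 0.87) / 0.87)
    ss_res = ss_tot = 0.0
    for seed in range(50):
        spec = SyntheticSpec(n_train=27, n_test=7, p=10,
                             support=(0, 2, 4, 6, 8), beta=beta,
                             intercept=4.97, noise_sd=sigma, seed=3000 + seed)
        ds = generate_dataset(spec)
        m = fit_ols(ds.train, [f"D{j:03d}" for j in (0, 2, 4, 6, 8)])
        y = ds.test.activity.to_numpy()
        yhat = m.predict(ds.test)
        ss_res += np.sum((y - yhat) ** 2)
        ss_tot += np.sum((y - y.mean()) ** 2)
    assert abs((1 - ss_res / ss_tot) - 0.87) < 0.1


# ---------------------------------------------------------------------------
# Y-randomization
# ---------------------------------------------------------------------------

def test_true_model_beats_all_permutations(planted_table):
    yr = y_randomization(StepwiseMLR(), planted_table, n_perm=100, seed=1)
    assert yr.original > yr.permuted.max()
    assert yr.percentile == 100.0


def test_y_randomization_deterministic(planted_table):
    a = y_randomization(OLSRegression(selected=["D003"]), planted_table,
                        n_perm=20, seed=9)
    b = y_randomization(OLSRegression(selected=["D003"]), planted_table,
                        n_perm=20, seed=9)
    np.testing.assert_array_equal(a.permuted, b.permuted)


def test_y_randomization_needs_enough_permutations(planted_table):
    with pytest.raises(SpecificationError):
        y_randomization(StepwiseMLR(), planted_table, n_perm=5)


def test_validation_report_layout():
    ds = _dataset(noise=0.3, seed=7)
    rep = validation_report(OLSRegression(selected=["D000", "D002"]),
                            ds.train, ds.test, n_perm=10)
    text = rep.to_text()
    assert "R2_c" in text and "Q2" in text
    assert rep.n_train == 25 and rep.n_test == 7
    assert rep.y_randomization["n_permutations"] == 10
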