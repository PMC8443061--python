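"""SVD/closed-form variance oracles, the epistemic+aleatoric split, the
sliding-window aleatoric estimator, and z-score semantics."""

import numpy as np
import pytest

from normgp.datasets import Dataset, GeneratorConfig, make_all, make_dataset3
from normgp.decomposition import (
    SlidingWindowAleatoric,
    decompose_uncertainty,
    estimate_aleatoric_sliding_window,
    linear_variance_closed_form,
    svd_variance_form,
    z_scores,
)
from normgp.gpr import fit, predict_var
from normgp.kernels import RBF, Linear


# -- SVD quadratic form -----------------------------------------------------


def test_svd_form_single_point_by_hand():
    """X=[[1]]: the 1x1 SVD gives sigma = 1/sigma_train and the variance
    x*^2 sigma_tr^2/(1+sigma_tr^2)... evaluated against the hand formula."""
    s2 = 0.04
    form = svd_variance_form([[1.0]], "linear", sigma2_train=s2, sigma2_test=0.01)
    assert form.singular_values[0] == pytest.approx(1.0 / np.sqrt(s2))
    for xstar in (-2.0, 0.0, 0.5, 3.0):
        expected = xstar**2 * s2 / (1.0 + s2) + 0.01
        assert form(xstar) == pytest.approx(expected, abs=1e-12)


def test_svd_form_linear_minimum_at_origin():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 1))
    form = svd_variance_form(X, "linear", sigma2_train=0.0025, sigma2_test=0.0025)
    assert form(0.0) == pytest.approx(0.0025, abs=1e-15)


@pytest.mark.parametrize("feature_map, kernel, tol", [
    ("linear", Linear(), 1e-10),
    ("rbf", RBF(1.0), 1e-6),
])
def test_svd_form_equals_gp_variance(feature_map, kernel, tol):
    """The SVD quadratic form reproduces the GP predictive variance."""
    rng = np.random.default_rng(8)
    X = rng.uniform(-np.pi, np.pi, size=(50, 1))
    s2 = 0.0025
    model = fit(Dataset(X=X, y=rng.normal(size=50)), kernel, noise_variance=s2)
    form = svd_variance_form(X, feature_map, sigma2_train=s2, sigma2_test=s2, order=40)
    xs = np.linspace(-np.pi, np.pi, 41)
    assert np.max(np.abs(form.evaluate(xs) - predict_var(model, xs[:, None]))) < tol


def test_svd_form_quadratic_term_nonnegative():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(20, 1))
    form = svd_variance_form(X, "rbf", sigma2_train=0.01, sigma2_test=0.0)
    assert np.all(form.shrinkage >= 0.0)
    assert np.all(form.shrinkage <= 1.0)
    for x in np.linspace(-3, 3, 25):
        assert form(x) >= 0.0


def test_svd_form_orthonormal_V():
    rng = np.random.default_rng(13)
    form = svd_variance_form(rng.normal(size=(15, 1)), "rbf", 0.01, 0.0, order=25)
    V = form.V
    assert np.max(np.abs(V.T @ V - np.eye(V.shape[1]))) < 1e-10


def test_svd_form_input_validation():
    with pytest.raises(ValueError):
        svd_variance_form(np.zeros((0, 1)), "linear", 0.01, 0.0)
    with pytest.raises(ValueError):
        svd_variance_form([[1.0]], "linear", sigma2_train=0.0, sigma2_test=0.0)
    with pytest.raises(ValueError):
        svd_variance_form(np.zeros((3, 2)), "linear", 0.01, 0.0)


# -- closed form ------------------------------------------------------------


def test_closed_form_properties():
    X = np.array([[0.0]])
    # an uninformative-at-origin point gives no shrinkage at all
    assert linear_variance_closed_form(X, 0.01, 0.002, 1.5) == pytest.approx(
        1.5**2 + 0.002
    )
    rng = np.random.default_rng(6)
    Xr = rng.normal(size=(12, 1))
    assert linear_variance_closed_form(Xr, 0.01, 0.002, 0.0) == pytest.approx(0.002)
    a = linear_variance_closed_form(Xr, 0.01, 0.002, 1.7)
    assert a == pytest.approx(linear_variance_closed_form(Xr, 0.01, 0.002, -1.7))


def test_closed_form_matches_gp_variance_on_random_draws():
    """Eq-for-eq agreement with the full GP computation, 100 random draws."""
    rng = np.random.default_rng(14)
    for _ in range(100):
        n = int(rng.integers(1, 30))
        X = rng.normal(scale=rng.uniform(0.5, 2.0), size=(n, 1))
        s2 = float(rng.uniform(0.001, 1.0))
        xstar = float(rng.uniform(-3, 3))
        model = fit(Dataset(X=X, y=rng.normal(size=n)), Linear(), noise_variance=s2)
        cf = linear_variance_closed_form(X, s2, s2, xstar)
        gp = predict_var(model, [[xstar]])[0]
        assert abs(cf - gp) < 1e-10


# -- sliding window ---------------------------------------------------------


def test_constant_residuals_give_zero_variance():
    x = np.linspace(0, 10, 200)
    est = SlidingWindowAleatoric(window=1.0, min_points=5).fit(x, np.full(200, 3.3))
    out = est.estimate(np.linspace(1, 9, 15))
    assert np.all(out.reliable)
    # prefix-sum roundoff leaves ~1e-13 where the exact variance is 0
    assert np.allclose(out.values, 0.0, atol=1e-10)


def test_homoskedastic_estimates_near_uniform_variance(benchmarks):
    """Dataset 3 residual variance is pi^2/3 ~ 3.29 across the interior."""
    ds = benchmarks["dataset3"]
    out = estimate_aleatoric_sliding_window(
        ds, None, np.linspace(-2.0, 2.0, 9)[:, None], window=1.0
    )
    assert np.all(out.reliable)
    assert np.allclose(out.values, np.pi**2 / 3.0, rtol=0.25)
    assert np.mean(out.values) == pytest.approx(np.pi**2 / 3.0, rel=0.1)


def test_sparse_middle_of_dataset2_is_flagged(benchmarks):
    """Dataset 2 has almost no inputs near 0: no estimate, only a flag."""
    ds = benchmarks["dataset2"]
    out = estimate_aleatoric_sliding_window(ds, ds.y * 0.0, np.array([[0.0]]))
    assert not out.reliable[0]
    assert np.isnan(out.values[0])


def test_heteroskedastic_envelope_recovery(big_heteroskedastic):
    """n=1e5 windowed estimates converge to (sin(x)/2+1)^2 pi^2/3 within 5%."""
    ds = big_heteroskedastic
    xs = np.linspace(-np.pi + 0.3, np.pi - 0.3, 25)
    out = estimate_aleatoric_sliding_window(ds, None, xs[:, None], window=0.3)
    envelope = (np.sin(xs) / 2.0 + 1.0) ** 2 * np.pi**2 / 3.0
    assert np.all(out.reliable)
    assert np.max(np.abs(out.values / envelope - 1.0)) < 0.05


def test_envelope_ratio_between_half_pi_points(big_heteroskedastic):
    """Var(y | x ~ pi/2) / Var(y | x ~ -pi/2) ~ (1.5/0.5)^2 = 9."""
    out = estimate_aleatoric_sliding_window(
        big_heteroskedastic, None, np.array([[np.pi / 2], [-np.pi / 2]]), window=0.4
    )
    assert out.values[0] / out.values[1] == pytest.approx(9.0, rel=0.1)


def test_window_edge_is_half_open():
    x = np.array([0.0, 1.0, 2.0])
    est = SlidingWindowAleatoric(window=2.0, min_points=2).fit(x, np.array([0.0, 1.0, 4.0]))
    # window [0, 2) around x*=1 contains x=0,1 but not x=2
    out = est.estimate([1.0])
    assert out.n_in_window[0] == 2
    assert out.values[0] == pytest.approx(np.var([0.0, 1.0], ddof=1))


def test_sliding_window_validation():
    with pytest.raises(ValueError):
        SlidingWindowAleatoric(window=-1.0).fit([0.0, 1.0], [0.0, 0.0])
    with pytest.raises(ValueError):
        SlidingWindowAleatoric(min_points=1).fit([0.0, 1.0], [0.0, 0.0])


# -- decomposition and z-scores ---------------------------------------------


def _small_model():
    rng = np.random.default_rng(17)
    X = rng.uniform(-2, 2, size=(80, 1))
    y = rng.normal(size=80)
    return fit(Dataset(X=X, y=y), RBF(1.0), noise_variance=0.0025), X, y


def test_zero_aleatoric_reduces_to_gp_variance():
    model, X, y = _small_model()
    res = decompose_uncertainty(model, X, aleatoric=None, y=y)
    assert np.allclose(res.total_var, predict_var(model, X), atol=1e-14)
    assert np.allclose(res.total_var, res.epistemic_var + res.aleatoric_var)


def test_negative_aleatoric_estimate_is_an_error():
    model, X, y = _small_model()
    est = estimate_aleatoric_sliding_window(
        Dataset(X=X, y=y), np.zeros(80), X, window=2.0, min_points=5
    )
    est.values[0] = -0.1
    with pytest.raises(ValueError):
        decompose_uncertainty(model, X, est, y=y)


def test_z_scores_zero_residual_and_modes():
    model, X, _ = _small_model()
    y_on_mean = model.predict(X)
    est = estimate_aleatoric_sliding_window(
        Dataset(X=X, y=y_on_mean), y_on_mean, X, window=2.0, min_points=5
    )
    res = decompose_uncertainty(model, X, est, y=y_on_mean)
    assert np.allclose(z_scores(res, "gpr_variance_only"), 0.0)
    assert np.allclose(z_scores(res, "decomposed_total")[res.unreliable == 0], 0.0)
    with pytest.raises(ValueError):
        z_scores(res, "bogus")


def test_z_scores_require_observations():
    model, X, _ = _small_model()
    res = decompose_uncertainty(model, X, aleatoric=None)
    with pytest.raises(ValueError):
        z_scores(res)


def test_result_table_round_trip(tmp_path):
    model, X, y = _small_model()
    est = estimate_aleatoric_sliding_window(
        Dataset(X=X, y=y), np.zeros(80), X, window=1.0, min_points=5
    )
    res = decompose_uncertainty(model, X, est, y=y)
    out = tmp_path / "normative.tsv"
    res.write(out)
    import pandas as pd

    df = pd.read_csv(out, sep="\t")
    assert list(df.columns) == [
        "x", "y", "y_reference", "epistemic_var", "aleatoric_var",
        "total_var", "z_gpr_only", "z_corrected", "unreliable_flag",
    ]
    assert len(df) == 80
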