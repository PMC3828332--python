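"""LARS path correctness: closed forms, cross-implementation oracle, invariants."""

import numpy as np
import pandas as pd
import pytest

from tsnet import fixtures as fx
from tsnet.lars import (
    FitOptions,
    adjusted_r_squared,
    fit_group,
    lars_path,
    select_step,
    standardize,
)
from tsnet.preprocess import CoexpressionGroup


def _random_design(seed, n=20, p=10):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"x{j}" for j in range(p)])
    y = rng.normal(size=n)
    return standardize(X, y)


# ------------------------------------------------------------ standardize

def test_standardize_unit_norm_and_centering():
    d = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}), [4.0, 5.0, 9.0])
    assert np.allclose(d.X[:, 0], [-0.70710678, 0.0, 0.70710678])
    assert d.y.mean() == pytest.approx(0.0)
    assert np.allclose(np.linalg.norm(d.X, axis=0), 1.0)


def test_standardize_drops_constant_columns():
    d = standardize(
        pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [4.0, 4.0, 4.0]}),
        [1.0, 2.0, 3.0],
    )
    assert d.columns == ["a"] and d.dropped == ["c"]


def test_standardize_idempotent_on_retained_columns():
    d1 = _random_design(0)
    d2 = standardize(pd.DataFrame(d1.X, columns=d1.columns), d1.y)
    assert np.allclose(d1.X, d2.X)


def test_standardize_all_constant_is_error():
    with pytest.raises(ValueError, match="constant"):
        standardize(pd.DataFrame({"a": [1.0, 1.0, 1.0]}), [1.0, 2.0, 3.0])


def test_standardize_needs_three_observations():
    with pytest.raises(ValueError, match="3 observations"):
        standardize(pd.DataFrame({"a": [1.0, 2.0]}), [1.0, 2.0])


# ------------------------------------------------------------ path

def test_single_predictor_path_is_ols():
    d = _random_design(1, p=1)
    path = lars_path(d)
    assert path.n_steps == 1
    assert path.breakpoints[1].coef[0] == pytest.approx(float(d.X[:, 0] @ d.y))


def test_orthogonal_response_gives_zero_steps():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(12, 3))
    X -= X.mean(axis=0)
    y = rng.normal(size=12)
    y -= y.mean()
    # project response out of the column space
    y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]
    d = standardize(pd.DataFrame(X), y)
    path = lars_path(d)
    assert path.n_steps == 0
    assert np.allclose(path.breakpoints[0].coef, 0.0)


def test_orthonormal_design_entry_order_and_correlations():
    """Under an orthonormal design the path activates columns in |x'y| order
    and at the m-th breakpoint every active |correlation| equals the
    (m+1)-th initial |x'y|."""
    n, targets = 8, (0.9, 0.5, 0.2)
    raw = np.random.default_rng(3).normal(size=(n, 4))
    raw -= raw.mean(axis=0)                 # zero-mean columns survive centering
    q, _ = np.linalg.qr(raw)
    X = q[:, :3]
    y = sum(t * X[:, j] for j, t in enumerate(targets))
    d = standardize(pd.DataFrame(X, columns=["a", "b", "c"]), y)
    c0 = np.abs(d.X.T @ d.y)
    assert np.allclose(sorted(c0), sorted(targets))
    order = list(np.argsort(-c0))
    path = lars_path(d)
    assert [bp.active[-1] for bp in path.breakpoints[1:]] == order
    ranked = sorted(c0, reverse=True)
    for m in (1, 2):
        assert path.breakpoints[m].max_abs_corr == pytest.approx(ranked[m], abs=1e-10)
    assert path.breakpoints[3].max_abs_corr == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize("seed", range(10))
def test_path_matches_reference_implementation(seed):
    sk = pytest.importorskip("sklearn.linear_model")
    d = _random_design(seed)
    path = lars_path(d)
    _, _, coefs = sk.lars_path(d.X, d.y, method="lar")
    ours = np.array([bp.coef for bp in path.breakpoints]).T
    assert ours.shape == coefs.shape
    assert np.abs(ours - coefs).max() < 1e-8


@pytest.mark.parametrize("seed", range(10))
def test_equal_correlation_invariant_and_residual_monotone(seed):
    d = _random_design(seed, n=25, p=15)
    path = lars_path(d)
    prev_rss = np.inf
    for bp in path.breakpoints[1:]:
        resid = d.y - d.X @ bp.coef
        c = d.X.T @ resid
        active_abs = np.abs(c[bp.active])
        assert active_abs.max() - active_abs.min() < 1e-8
        inactive = [j for j in range(d.n_predictors) if j not in bp.active]
        if inactive:
            assert np.abs(c[inactive]).max() <= active_abs.max() + 1e-8
        rss = float(resid @ resid)
        assert rss <= prev_rss + 1e-10
        prev_rss = rss


def test_duplicate_column_skipped_not_fatal(caplog):
    rng = np.random.default_rng(7)
    x = rng.normal(size=20)
    X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=20)})
    y = 2 * x + rng.normal(size=20) * 0.01
    d = standardize(X, y)
    path = lars_path(d)
    assert not path.aborted
    active_names = {d.columns[j] for j in path.breakpoints[-1].active}
    assert "a" in active_names and not {"a", "b"} <= active_names


# ------------------------------------------------------------ adjusted R^2

def test_adjusted_r_squared_formula_cases():
    y = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])          # TSS = 10
    assert adjusted_r_squared(y, y, 2) == pytest.approx(1.0)
    fitted = y.copy()
    fitted[0] += 1.0                                    # RSS = 1, R^2 = 0.9
    assert adjusted_r_squared(y, fitted, 2) == pytest.approx(0.8)
    assert adjusted_r_squared(y, np.zeros(5), 0) == pytest.approx(0.0)


def test_adjusted_r_squared_errors():
    y = np.array([-1.0, 0.0, 1.0])
    with pytest.raises(ValueError, match="N > p"):
        adjusted_r_squared(y, y, 2)
    with pytest.raises(ValueError, match="total sum of squares"):
        adjusted_r_squared(np.ones(5), np.ones(5), 1)


# ------------------------------------------------------------ selection

@pytest.mark.parametrize("criterion", ["cp", "ebic"])
def test_noiseless_two_predictor_support_selected_exactly(criterion):
    rng = np.random.default_rng(11)
    X = pd.DataFrame(rng.normal(size=(20, 8)), columns=[f"x{j}" for j in range(8)])
    y = 3.0 * X["x2"] - 1.5 * X["x5"]
    d = standardize(X, y)
    fit = select_step(lars_path(d), d, criterion=criterion)
    assert sorted(fit.selected) == ["x2", "x5"]
    assert fit.adjusted_r2 == pytest.approx(1.0)


def test_selected_coefficients_back_transform_to_original_scale():
    rng = np.random.default_rng(12)
    X = pd.DataFrame(rng.normal(loc=50, scale=7, size=(30, 5)),
                     columns=list("abcde"))
    y = 4.0 + 0.7 * X["b"] - 1.2 * X["d"]
    d = standardize(X, y)
    fit = select_step(lars_path(d), d)
    assert sorted(fit.selected) == ["b", "d"]
    assert fit.coefficients["b"] == pytest.approx(0.7, abs=1e-6)
    assert fit.coefficients["d"] == pytest.approx(-1.2, abs=1e-6)
    assert fit.intercept == pytest.approx(4.0, abs=1e-4)


def test_fixed_k_zero_is_intercept_only():
    d = _random_design(13)
    fit = select_step(lars_path(d), d, criterion="max_steps_k", k=0)
    assert fit.selected == [] and fit.adjusted_r2 == pytest.approx(0.0)


def test_fixed_k_beyond_path_is_error():
    d = _random_design(14, p=3)
    with pytest.raises(ValueError, match="outside selectable path"):
        select_step(lars_path(d), d, criterion="max_steps_k", k=7)


def test_pure_noise_selects_tiny_models():
    """Null calibration: with no signal the default criterion keeps the
    selected model essentially empty (median size <= 2 over 100 seeds)."""
    sizes = []
    for seed in range(100):
        X, _, _ = fx.simulate_design(seed + 2000)
        y = np.random.default_rng(seed + 9000).normal(size=len(X))
        d = standardize(X, y)
        fit = select_step(lars_path(d, max_steps=min(d.n_obs - 2,
                                                     d.n_predictors)), d)
        sizes.append(len(fit.selected))
    assert np.median(sizes) <= 2


# ------------------------------------------------------------ fit_group

def _toy_group(seed=0, n=20, noise=0.0):
    rng = np.random.default_rng(seed)
    X, y, truth = fx.simulate_design(seed, n_obs=n, n_tf=10, n_sf=5,
                                     support=3, noise_sd=noise)
    members = [f"iso{i:03d}" for i in range(n)]
    X.index = members
    tf = X[[c for c in X.columns if c.startswith("TF")]]
    sf = X[[c for c in X.columns if c.startswith("SF")]]
    samples = [f"up_{j}" for j in range(3)] + [f"down_{j}" for j in range(3)]
    expr = pd.DataFrame(
        np.column_stack([np.tile(y, (3, 1)).T, np.tile(y * 0.3, (3, 1)).T]),
        index=members, columns=samples,
    )
    group = CoexpressionGroup(1, members, expr)
    conds = {s: s.rsplit("_", 1)[0] for s in samples}
    ups = {m: "up" for m in members}
    return group, tf, sf, conds, ups, truth


def test_fit_group_recovers_planted_support_noiseless():
    group, tf, sf, conds, ups, truth = _toy_group()
    fit = fit_group(group, tf, sf, conds, ups)
    assert sorted(fit.selected) == sorted(truth["factors"])
    assert fit.adjusted_r2 >= 0.999
    assert fit.kept
    assert all(fit.factor_types[f] == ("TF" if f.startswith("TF") else "SF")
               for f in fit.selected)


def test_fit_group_row_permutation_invariance():
    group, tf, sf, conds, ups, _ = _toy_group(seed=5)
    fit1 = fit_group(group, tf, sf, conds, ups)
    perm = list(reversed(group.members))
    group2 = CoexpressionGroup(1, perm, group.expression.loc[perm])
    fit2 = fit_group(group2, tf, sf, conds, ups)
    assert fit1.selected == fit2.selected
    for f in fit1.selected:
        assert fit1.coefficients[f] == pytest.approx(fit2.coefficients[f])
    assert fit1.adjusted_r2 == pytest.approx(fit2.adjusted_r2)


def test_fit_group_pure_noise_not_kept():
    group, tf, sf, conds, ups, _ = _toy_group(seed=8)
    rng = np.random.default_rng(99)
    noise_expr = pd.DataFrame(
        rng.normal(10, 1, size=group.expression.shape),
        index=group.members, columns=group.expression.columns,
    )
    group_noise = CoexpressionGroup(1, group.members, noise_expr)
    fit = fit_group(group_noise, tf, sf, conds, ups)
    assert not fit.kept


def test_fit_group_too_small_is_error():
    group, tf, sf, conds, ups, _ = _toy_group()
    tiny = CoexpressionGroup(1, group.members[:2],
                             group.expression.iloc[:2])
    with pytest.raises(ValueError, match=">= 3 members"):
        fit_group(tiny, tf, sf, conds, ups)


def test_fit_group_missing_strength_rows_treated_as_zero(caplog):
    group, tf, sf, conds, ups, truth = _toy_group(seed=3)
    sf_missing = sf.drop(index=group.members[:2])
    with caplog.at_level("INFO"):
        fit = fit_group(group, tf, sf_missing, conds, ups)
    assert fit.n_obs == len(group.members)
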