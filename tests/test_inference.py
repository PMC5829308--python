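"""Linear models, PERMANOVA, partial db-RDA, BY correction, OTU screen."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway

import gmbiome as g
from gmbiome.errors import (
    CollinearityError,
    DegenerateInputError,
    InvalidArgumentError,
)

from conftest import toy_distance


def euclid_dist(y, ids=None):
    y = np.asarray(y, dtype=float)
    D = np.abs(y[:, None] - y[None, :])
    ids = ids or [f"S{i}" for i in range(len(y))]
    return g.DistanceMatrix(pd.DataFrame(D, index=ids, columns=ids))


# -- OLS ---------------------------------------------------------------------

def test_exact_line_recovered():
    x = np.arange(10.0)
    design = pd.DataFrame({"x": x})
    fit = g.ols_fit(2.0 * x, design)
    assert fit.params["x"] == pytest.approx(2.0, abs=1e-12)
    assert fit.rsquared == pytest.approx(1.0, abs=1e-12)


def test_matches_normal_equation_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n, p = 40, 4
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        design = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
        fit = g.ols_fit(y, design)
        Xi = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)


def test_null_regression_calibrated():
    rng = np.random.default_rng(1)
    hits = 0
    reps = 1000
    for _ in range(reps):
        x = rng.standard_normal(213)
        y = rng.standard_normal(213)
        fit = g.ols_fit(y, pd.DataFrame({"x": x}))
        hits += fit.pvalues["x"] <= 0.05
    assert 0.03 <= hits / reps <= 0.07


def test_collinear_design_names_aliased_terms():
    x = np.arange(12.0)
    design = pd.DataFrame({"a": x, "b": 2 * x})
    with pytest.raises(CollinearityError) as err:
        g.ols_fit(np.ones(12), design)
    assert "b" in err.value.aliased or "a" in err.value.aliased


# -- backward selection ------------------------------------------------------

def make_selection_data(seed, beta_f1=-0.5, beta_f3=0.0, beta_int=0.3,
                        noise=1.0, n=213):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame({
        "age": rng.uniform(1, 80, n),
        "f1": rng.standard_normal(n),
        "f2": rng.standard_normal(n),
        "f3": rng.standard_normal(n),
    })
    y = (beta_f1 * data.f1 + beta_f3 * data.f3
         + beta_int * data.f1 * data.f3 + noise * rng.standard_normal(n))
    return y, data


def test_selection_keeps_generating_terms():
    hits = 0
    reps = 50
    terms = ["age", "f1", "f2", "f3", "f1:f3"]
    for seed in range(reps):
        y, data = make_selection_data(seed)
        fit = g.backward_select(y, data, terms)
        kept = set(fit.terms)
        hits += kept == {"f1", "f3", "f1:f3"}
    assert hits / reps >= 0.8


def test_selection_respects_marginality():
    # f3 has no main effect but its interaction is strong: f3 must be kept
    y, data = make_selection_data(1, beta_f1=-0.8, beta_int=0.8, noise=0.5)
    fit = g.backward_select(y, data, ["f1", "f3", "f1:f3"])
    assert {"f1", "f3", "f1:f3"} <= set(fit.terms)


def test_all_null_predictors_mostly_reduce_to_intercept():
    intercept_only = 0
    reps = 40
    for seed in range(reps):
        rng = np.random.default_rng(1000 + seed)
        data = pd.DataFrame(rng.standard_normal((100, 3)),
                            columns=["a", "b", "c"])
        y = rng.standard_normal(100)
        fit = g.backward_select(y, data, ["a", "b", "c"])
        intercept_only += len(fit.terms) == 0
    assert intercept_only / reps >= 0.6


def test_dropping_terms_never_raises_r2():
    y, data = make_selection_data(2)
    full = g.fit_terms(y, data, ["age", "f1", "f2", "f3", "f1:f3"])
    selected = g.backward_select(y, data, ["age", "f1", "f2", "f3", "f1:f3"])
    assert selected.rsquared <= full.rsquared + 1e-12
    for step in selected.path:
        assert step["p_drop"] > 0.05


# -- prediction profiles -----------------------------------------------------

def test_profile_requires_interaction_and_emits_steps():
    y, data = make_selection_data(3)
    fit = g.fit_terms(y, data, ["f1", "f3", "f1:f3"])
    prof = g.prediction_profile(fit, data, "f1", "f3", steps=100)
    assert prof["moderator_value"].nunique() == 100
    no_int = g.fit_terms(y, data, ["f1", "f3"])
    with pytest.raises(InvalidArgumentError):
        g.prediction_profile(no_int, data, "f1", "f3")


def test_profile_hand_computed_point():
    y, data = make_selection_data(4)
    fit = g.fit_terms(y, data, ["f1", "f3", "f1:f3"])
    prof = g.prediction_profile(fit, data, "f1", "f3", steps=3,
                                focal_steps=2)
    b = fit.params
    row = prof.iloc[-1]  # moderator at max, focal at max
    expected = (b["Intercept"] + b["f1"] * row.focal_value
                + b["f3"] * row.moderator_value
                + b["f1:f3"] * row.focal_value * row.moderator_value)
    assert row.predicted == pytest.approx(expected, abs=1e-10)


def test_profile_at_zero_moderator_is_main_effect_line():
    y, data = make_selection_data(5)
    fit = g.fit_terms(y, data, ["f1", "f3", "f1:f3"])
    prof = g.prediction_profile(fit, data, "f1", "f3", steps=4,
                                focal_steps=5)
    line0 = prof[prof.moderator_value == 0.0]
    b = fit.params
    expected = b["Intercept"] + b["f1"] * line0.focal_value
    np.testing.assert_allclose(line0.predicted, expected, atol=1e-10)


# -- PERMANOVA ---------------------------------------------------------------

def test_permanova_hand_example_equals_anova_f():
    y = np.array([1.0, 2.0, 3.0, 5.0])
    groups = pd.DataFrame({"grp": ["A", "A", "B", "B"]},
                          index=[f"S{i}" for i in range(4)])
    res = g.permanova(euclid_dist(y), groups, ["grp"], n_perm=99, seed=0)
    assert res.loc[0, "pseudo_f"] == pytest.approx(5.0, abs=1e-8)


def test_permanova_equals_classical_anova_on_random_instances():
    rng = np.random.default_rng(2)
    for _ in range(10):
        n = int(rng.integers(8, 20))
        y = rng.standard_normal(n)
        labels = rng.choice(["A", "B", "C"], size=n)
        if len(set(labels)) < 2 or min(np.bincount(
                pd.factorize(labels)[0])) < 2:
            continue
        data = pd.DataFrame({"grp": labels},
                            index=[f"S{i}" for i in range(n)])
        res = g.permanova(euclid_dist(y), data, ["grp"], n_perm=9, seed=0)
        ref = f_oneway(*(y[labels == lab] for lab in sorted(set(labels))))
        assert res.loc[0, "pseudo_f"] == pytest.approx(ref.statistic,
                                                       abs=1e-8)


def test_permanova_decomposition_and_reproducibility():
    rng = np.random.default_rng(3)
    dist = toy_distance(30, rng)
    data = pd.DataFrame({
        "grp": rng.choice(["A", "B"], 30),
        "x": rng.standard_normal(30),
    }, index=dist.sample_ids)
    res1 = g.permanova(dist, data, ["grp", "x"], n_perm=99, seed=5)
    res2 = g.permanova(dist, data, ["grp", "x"], n_perm=99, seed=5)
    pd.testing.assert_frame_equal(res1, res2)
    ss = res1.set_index("term")["ss"]
    assert ss["grp"] + ss["x"] + ss["Residual"] == \
        pytest.approx(ss["Total"], abs=1e-8)


def test_permanova_duplicated_term_raises():
    rng = np.random.default_rng(4)
    dist = toy_distance(12, rng)
    data = pd.DataFrame({"x": rng.standard_normal(12)},
                        index=dist.sample_ids)
    data["y"] = data["x"]
    with pytest.raises(CollinearityError):
        g.permanova(dist, data, ["x", "y"], n_perm=9, seed=0)


def test_permanova_matches_skbio():
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(5)
    dist = toy_distance(24, rng)
    labels = rng.choice(["A", "B", "C"], 24)
    data = pd.DataFrame({"grp": labels}, index=dist.sample_ids)
    mine = g.permanova(dist, data, ["grp"], n_perm=49, seed=0)
    sk_dm = skbio_stats.DistanceMatrix(dist.values.to_numpy(),
                                       ids=list(dist.sample_ids))
    ref = skbio_stats.permanova(sk_dm, labels, permutations=49)
    assert mine.loc[0, "pseudo_f"] == pytest.approx(ref["test statistic"],
                                                    abs=1e-8)


# -- partial db-RDA ----------------------------------------------------------

def test_dbrda_zero_distances_no_axes():
    ids = [f"S{i}" for i in range(8)]
    dist = g.DistanceMatrix(pd.DataFrame(np.zeros((8, 8)), index=ids,
                                         columns=ids))
    rng = np.random.default_rng(6)
    X = pd.DataFrame({"x": rng.standard_normal(8)}, index=ids)
    res = g.partial_dbrda(dist, X, n_perm=9, seed=0)
    assert res.eigenvalues.size == 0
    assert res.constrained_inertia == pytest.approx(0.0, abs=1e-10)


def test_dbrda_orthogonal_condition_leaves_axes_unchanged():
    """Constructed so the condition is exactly orthogonal to both the
    constraints and the response: partialling it out must not move the
    constrained eigenvalues."""
    n = 16
    ids = [f"S{i}" for i in range(n)]
    t = np.arange(n, dtype=float)
    x = np.cos(2 * np.pi * t / n)          # constraint
    c = np.sin(2 * np.pi * 3 * t / n)      # condition, orthogonal to x
    y = np.column_stack([x, np.cos(2 * np.pi * 2 * t / n)])  # response
    D = np.sqrt(((y[:, None, :] - y[None, :, :]) ** 2).sum(-1))
    dist = g.DistanceMatrix(pd.DataFrame(D, index=ids, columns=ids))
    X = pd.DataFrame({"x": x}, index=ids)
    C = pd.DataFrame({"c": c}, index=ids)
    plain = g.partial_dbrda(dist, X, n_perm=9, seed=0)
    partial = g.partial_dbrda(dist, X, condition=C, n_perm=9, seed=0)
    np.testing.assert_allclose(partial.eigenvalues, plain.eigenvalues,
                               atol=1e-6)


def test_dbrda_inertia_matches_permanova_ss():
    rng = np.random.default_rng(7)
    dist = toy_distance(25, rng)
    labels = rng.choice(["A", "B", "C"], 25)
    data = pd.DataFrame({"grp": labels}, index=dist.sample_ids)
    perm = g.permanova(dist, data, ["grp"], n_perm=9, seed=0)
    res = g.partial_dbrda(dist, data[["grp"]], n_perm=9, seed=0)
    ss = perm.set_index("term")["ss"]
    assert res.constrained_inertia == pytest.approx(ss["grp"], abs=1e-8)
    assert res.residual_inertia == pytest.approx(ss["Residual"], abs=1e-8)


def test_dbrda_rank_deficient_constraints_raise():
    rng = np.random.default_rng(8)
    dist = toy_distance(10, rng)
    X = pd.DataFrame({"x": rng.standard_normal(10)}, index=dist.sample_ids)
    X["x2"] = 2 * X["x"]
    with pytest.raises(CollinearityError):
        g.partial_dbrda(dist, X, n_perm=9, seed=0)


# -- BY adjustment -----------------------------------------------------------

def test_by_hand_case():
    adj = g.by_adjust([0.01, 0.02, 0.04])
    np.testing.assert_allclose(adj, [0.0550, 0.0550, 0.07333333], atol=1e-4)


def test_by_edge_cases():
    np.testing.assert_array_equal(g.by_adjust([1.0, 1.0]), [1.0, 1.0])
    np.testing.assert_array_equal(g.by_adjust([0.3]), [0.3])  # c(1) = 1
    with pytest.raises(InvalidArgumentError):
        g.by_adjust([0.5, 1.2])
    with pytest.raises(InvalidArgumentError):
        g.by_adjust([-0.1])


def test_by_matches_statsmodels_oracle():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(9)
    for _ in range(200):
        m = int(rng.integers(1, 60))
        p = rng.random(m)
        mine = g.by_adjust(p)
        ref = multipletests(p, method="fdr_by")[1]
        np.testing.assert_allclose(mine, ref, atol=1e-12)
        assert np.all(mine >= p - 1e-12)


# -- correlation screen ------------------------------------------------------

def test_screen_perfect_linear_otu():
    rng = np.random.default_rng(10)
    scores = pd.DataFrame({"f1": rng.standard_normal(50)},
                          index=[f"S{i}" for i in range(50)])
    abund = pd.DataFrame({
        "OTU_lin": 3.0 * scores["f1"] + 1.0,
        "OTU_noise": rng.standard_normal(50),
        "OTU_const": 2.0,
    }, index=scores.index)
    res = g.correlation_screen(abund, scores)
    lin = res[res.otu == "OTU_lin"].iloc[0]
    assert lin.r == pytest.approx(1.0, abs=1e-10)
    assert lin.significant
    const = res[res.otu == "OTU_const"].iloc[0]
    assert np.isnan(const.r) and not const.significant


def test_screen_requires_three_samples():
    scores = pd.DataFrame({"f1": [0.0, 1.0]}, index=["a", "b"])
    abund = pd.DataFrame({"o": [1.0, 2.0]}, index=["a", "b"])
    with pytest.raises(InvalidArgumentError):
        g.correlation_screen(abund, scores)


def test_screen_controls_fdr_under_global_null():
    """Independent Gaussian table: the fraction of replicates with any BY
    discovery at level 0.05 stays near or below 0.05."""
    rng = np.random.default_rng(11)
    false_hits = []
    for _ in range(200):
        n, m = 40, 200
        abund = pd.DataFrame(rng.standard_normal((n, m)),
                             index=[f"S{i}" for i in range(n)],
                             columns=[f"O{j}" for j in range(m)])
        scores = pd.DataFrame(rng.standard_normal((n, 3)),
                              columns=["f1", "f2", "f3"], index=abund.index)
        res = g.correlation_screen(abund, scores, alpha=0.05)
        false_hits.append(res["significant"].any())
    assert np.mean(false_hits) <= 0.07
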