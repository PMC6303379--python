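import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from rhizoct.sem import (
    PathModelError,
    PathModelSpec,
    carbon_dummies,
    code_carbon,
    compare_models,
    fit_path_model,
)
from rhizoct.tables import TableSpec, generate_table

VARS4 = ("carbon_score", "root_shoot_ratio", "d_respiration", "d_porosity")
GEN_EDGES = {
    ("carbon_score", "root_shoot_ratio"): 0.4,
    ("carbon_score", "d_respiration"): 0.5,
    ("root_shoot_ratio", "d_porosity"): -0.3,
}


@pytest.fixture(scope="module")
def big_table():
    return generate_table(TableSpec(n_per_cell=1700, edges=GEN_EDGES, seed=9))


def saturated_spec(variables):
    edges = tuple((a, b) for i, a in enumerate(variables) for b in variables[i + 1:])
    return PathModelSpec(variables=variables, edges=edges)


# -------------------------------------------------------------- carbon codes
@pytest.mark.parametrize("level, score", [("none", 1), ("moderate", 2), ("high", 3)])
def test_carbon_ordinal_coding(level, score):
    assert code_carbon(level) == score


def test_unknown_carbon_level_is_refused():
    with pytest.raises(PathModelError, match="low"):
        code_carbon("low")


def test_two_indicator_dummy_option():
    d = carbon_dummies(pd.Series(["none", "moderate", "high"]))
    assert d.values.tolist() == [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]


# ------------------------------------------------------------------ fitting
def test_saturated_model_fits_perfectly(big_table):
    fit = fit_path_model(big_table, saturated_spec(VARS4))
    assert fit.chi_square == 0.0
    assert fit.df == 0
    assert fit.gfi == pytest.approx(1.0, abs=1e-9)
    assert fit.rmsea == 0.0
    np.testing.assert_allclose(fit.implied_cov.values, fit.sample_cov.values, atol=1e-10)


def test_known_paths_recovered_at_large_n(big_table):
    spec = PathModelSpec(variables=VARS4, edges=tuple(GEN_EDGES))
    fit = fit_path_model(big_table, spec)
    est = {(r.cause, r.effect): r.estimate for r in fit.coefficients.itertuples()}
    for edge, w in GEN_EDGES.items():
        assert est[edge] == pytest.approx(w, abs=0.02)
    assert fit.p_chi > 0.01  # generating model should fit


def test_single_edge_coefficient_is_pearson_r(big_table):
    spec = PathModelSpec(
        variables=("carbon_score", "d_respiration"), edges=(("carbon_score", "d_respiration"),)
    )
    fit = fit_path_model(big_table, spec)
    r = np.corrcoef(big_table["carbon_score"], big_table["d_respiration"])[0, 1]
    assert fit.coefficients["estimate"].iloc[0] == pytest.approx(r, abs=1e-10)


def test_ml_discrepancy_minimiser_agrees_with_closed_form():
    """Independent route: numerically minimize F_ML over the free path
    coefficients and residual variances; must agree with the equation-wise
    least-squares solution for a recursive, uncorrelated-error model."""
    table = generate_table(TableSpec(n_per_cell=50, edges=GEN_EDGES, seed=10))
    spec = PathModelSpec(variables=VARS4, edges=tuple(GEN_EDGES))
    fit = fit_path_model(table, spec)
    S = fit.sample_cov.values
    p = len(VARS4)
    idx = {v: i for i, v in enumerate(VARS4)}
    edges = list(GEN_EDGES)

    def implied(theta):
        B = np.zeros((p, p))
        for (cause, effect), w in zip(edges, theta[: len(edges)]):
            B[idx[effect], idx[cause]] = w
        psi = np.zeros((p, p))
        psi[0, 0] = S[0, 0]  # exogenous variance fixed at its sample value
        for j, v in enumerate(VARS4[1:], start=1):
            psi[j, j] = np.exp(theta[len(edges) + j - 1])
        inv = np.linalg.inv(np.eye(p) - B)
        return inv @ psi @ inv.T

    def f_ml(theta):
        sigma = implied(theta)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e6
        return logdet + np.trace(S @ np.linalg.inv(sigma)) - np.linalg.slogdet(S)[1] - p

    theta0 = np.concatenate([np.zeros(len(edges)), np.zeros(p - 1)])
    res = scipy.optimize.minimize(f_ml, theta0, method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    est = {(r.cause, r.effect): r.estimate for r in fit.coefficients.itertuples()}
    for edge, w_num in zip(edges, res.x[: len(edges)]):
        assert est[edge] == pytest.approx(w_num, abs=1e-5)
    assert fit.chi_square == pytest.approx((fit.n - 1) * res.fun, abs=1e-3)


def test_chi_square_invariant_to_variable_rescaling(big_table):
    spec = PathModelSpec(variables=VARS4, edges=tuple(GEN_EDGES))
    fit = fit_path_model(big_table, spec)
    scaled = big_table.copy()
    scaled["d_respiration"] = scaled["d_respiration"] * 37.0 + 5.0
    fit2 = fit_path_model(scaled, spec)
    assert fit2.chi_square == pytest.approx(fit.chi_square, rel=1e-8)


def test_removing_a_true_edge_cannot_decrease_chi_square(big_table):
    # exogenous declared so the deleted path is a real constraint (cov fixed 0)
    full = PathModelSpec(variables=VARS4, edges=tuple(GEN_EDGES), exogenous=("carbon_score",))
    reduced_edges = tuple(e for e in GEN_EDGES if e != ("carbon_score", "d_respiration"))
    reduced = PathModelSpec(variables=VARS4, edges=reduced_edges, exogenous=("carbon_score",))
    f_full = fit_path_model(big_table, full)
    f_red = fit_path_model(big_table, reduced)
    assert f_red.chi_square >= f_full.chi_square
    assert f_red.df == f_full.df + 1


def test_cyclic_model_is_refused():
    with pytest.raises(PathModelError, match="cycle"):
        PathModelSpec(variables=("a", "b"), edges=(("a", "b"), ("b", "a")))


def test_n_must_exceed_variable_count(big_table):
    spec = PathModelSpec(variables=VARS4, edges=tuple(GEN_EDGES))
    with pytest.raises(PathModelError, match="exceed"):
        fit_path_model(big_table.head(3), spec)


# ---------------------------------------------------------------- comparison
def test_generating_model_outranks_misspecified_one():
    wins = 0
    n_seeds = 60
    spec_true = PathModelSpec(variables=VARS4, edges=tuple(GEN_EDGES), exogenous=("carbon_score",))
    spec_miss = PathModelSpec(
        variables=VARS4,
        edges=tuple(e for e in GEN_EDGES if e != ("carbon_score", "d_respiration")),
        exogenous=("carbon_score",),
    )
    for seed in range(n_seeds):
        table = generate_table(TableSpec(n_per_cell=34, edges=GEN_EDGES, seed=100 + seed))  # n ~ 200
        fits = [fit_path_model(table, spec_miss), fit_path_model(table, spec_true)]
        ranked = compare_models(fits)
        wins += ranked.iloc[0]["model"] == 1
    assert wins / n_seeds >= 0.9


def test_single_fit_returned_with_acceptability_flag(big_table):
    fit = fit_path_model(big_table, PathModelSpec(variables=VARS4, edges=tuple(GEN_EDGES)))
    out = compare_models([fit])
    assert len(out) == 1
    assert bool(out["acceptable"].iloc[0]) == (fit.p_chi > 0.05)


def test_comparison_requires_same_sample(big_table):
    spec = PathModelSpec(variables=VARS4, edges=tuple(GEN_EDGES))
    f1 = fit_path_model(big_table, spec)
    f2 = fit_path_model(big_table.sample(n=200, random_state=0), spec)
    with pytest.raises(PathModelError, match="same"):
        compare_models([f1, f2])


# ----------------------------------------------------------------- parsing
def test_model_text_round_trip():
    text = """
    # tolerant-cultivar habitat links
    d_connectivity <- rhizosheath_mass
    d_porosity <- root_hair_area
    rhizosheath_mass <- carbon_score
    """
    spec = PathModelSpec.from_text(text)
    assert ("carbon_score", "rhizosheath_mass") in spec.edges
    assert spec.exogenous == ("root_hair_area", "carbon_score")


def test_malformed_model_line_is_refused():
    with pytest.raises(PathModelError, match="line 1"):
        PathModelSpec.from_text("porosity -> carbon")
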