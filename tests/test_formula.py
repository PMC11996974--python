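import numpy as np
import pandas as pd
import pytest

from vwmmix import make_model
from vwmmix.formula import (
    FormulaError,
    build_design,
    cell_means_contrast,
    get_contrast,
    parse,
    parse_one,
    successive_diff_contrast,
    treatment_contrast,
)


class TestParsing:
    def test_basic_random_slopes(self):
        pf = parse_one("kappa ~ 0 + setsize + (0 + setsize || subID)")
        assert pf.parameter == "kappa"
        assert pf.intercept is False
        assert pf.terms == [("setsize",)]
        (rp,) = pf.random
        assert rp.group == "subID"
        assert rp.correlated is False
        assert rp.intercept is False
        assert rp.terms == [("setsize",)]

    def test_intercept_only(self):
        pf = parse_one("kappa ~ 1")
        assert pf.intercept is True
        assert pf.terms == []
        assert pf.random == []

    def test_correlated_flag(self):
        pf = parse_one("thetat ~ cond + (cond | subID)")
        assert pf.random[0].correlated is True

    def test_stratified_grouping(self):
        pf = parse_one("kappa ~ 0 + ageGroup + (RI | gr(id, by = ageGroup))")
        rp = pf.random[0]
        assert rp.group == "id"
        assert rp.by == "ageGroup"

    def test_interaction_and_star(self):
        pf = parse_one("kappa ~ RI:cueCond")
        assert pf.terms == [("RI", "cueCond")]
        pf2 = parse_one("kappa ~ RI*cueCond")
        assert pf2.terms == [("RI",), ("cueCond",), ("RI", "cueCond")]

    def test_duplicate_zero_marker_clashes(self):
        with pytest.raises(FormulaError):
            parse_one("kappa ~ 0 + ageGroup + 0 + RI")

    def test_zero_and_one_clash(self):
        with pytest.raises(FormulaError):
            parse_one("kappa ~ 0 + 1 + x")

    def test_malformed(self):
        with pytest.raises(FormulaError):
            parse_one("kappa ~ ")
        with pytest.raises(FormulaError):
            parse_one("kappa ~ x ~ y")
        with pytest.raises(FormulaError):
            parse_one("kappa ~ (x subID)")

    def test_unknown_parameter_with_model(self):
        model = make_model("mixture2p")
        with pytest.raises(FormulaError, match="not an estimable parameter"):
            parse(["thetant ~ 1"], model=model)
        parsed = parse(["kappa ~ 1", "thetat ~ 1"], model=model)
        assert len(parsed) == 2

    def test_duplicate_lhs(self):
        with pytest.raises(FormulaError, match="more than one formula"):
            parse(["kappa ~ 1", "kappa ~ x"])


class TestSuccessiveDifference:
    def test_k1_intercept_only(self):
        scheme = successive_diff_contrast(1)
        assert scheme.matrix.shape == (1, 1)
        assert scheme.matrix[0, 0] == 1.0

    def test_worked_example(self):
        # true means (1, 3, 3, 6) -> coefficients (2, 0, 3); brute-force solve
        scheme = successive_diff_contrast(4)
        means = np.array([1.0, 3.0, 3.0, 6.0])
        coefs = np.linalg.solve(scheme.matrix, means)  # independent oracle
        np.testing.assert_allclose(coefs, [1.0, 2.0, 0.0, 3.0])
        np.testing.assert_allclose(scheme.coefficients_for_means(means), coefs)
        np.testing.assert_allclose(scheme.matrix @ coefs, means, atol=1e-12)

    def test_nonnegative_coefficients_give_monotone_means(self):
        rng = np.random.default_rng(1)
        scheme = successive_diff_contrast(6)
        for _ in range(100):
            coefs = np.concatenate([[rng.normal()], rng.uniform(0, 3, 5)])
            means = scheme.matrix @ coefs
            assert np.all(np.diff(means) >= -1e-12)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            successive_diff_contrast(0)


@pytest.mark.parametrize("maker", [cell_means_contrast, treatment_contrast, successive_diff_contrast])
@pytest.mark.parametrize("k", [1, 2, 4, 8])
def test_every_scheme_reconstructs_cell_means_exactly(maker, k):
    rng = np.random.default_rng(k)
    scheme = maker(k)
    for _ in range(20):
        means = rng.normal(0, 5, k)
        coefs = scheme.coefficients_for_means(means)
        np.testing.assert_allclose(scheme.matrix @ coefs, means, atol=1e-10)


def _table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "y": rng.normal(size=n),
            "setsize": rng.choice([1, 2, 3, 6], n),
            "ageGroup": rng.choice(["old", "young"], n),
            "RI": rng.choice(["long", "short"], n),
            "subID": rng.integers(1, 6, n),
            "rt": rng.uniform(0.2, 2.0, n),
        }
    )


class TestBuildDesign:
    def test_cell_means_one_hot(self):
        tab = _table()
        dm = build_design(["kappa ~ 0 + setsize"], tab, factors=["setsize"])
        X = dm["kappa"].fixed.X
        assert X.shape[1] == 4
        np.testing.assert_allclose(X.sum(axis=1), 1.0)
        assert dm["kappa"].fixed.labels == ["setsize1", "setsize2", "setsize3", "setsize6"]

    def test_treatment_default_with_intercept(self):
        tab = _table()
        dm = build_design(["kappa ~ 1 + setsize"], tab, factors=["setsize"])
        assert dm["kappa"].fixed.labels == ["Intercept", "setsize2", "setsize3", "setsize6"]

    def test_per_group_intercepts_and_nested_effects(self):
        # "0 + ageGroup + RI:ageGroup": separate intercepts per age group,
        # plus a within-group RI effect for each age group
        tab = _table()
        dm = build_design(["kappa ~ 0 + ageGroup + RI:ageGroup"], tab)
        labels = dm["kappa"].fixed.labels
        assert labels[:2] == ["ageGroupold", "ageGroupyoung"]
        assert len(labels) == 4
        assert all(":" in lab for lab in labels[2:])
        assert np.linalg.matrix_rank(dm["kappa"].fixed.X) == 4

    def test_successive_difference_reproduces_arbitrary_means(self):
        rng = np.random.default_rng(3)
        n = 400
        tab = pd.DataFrame({"set_size": rng.choice(list(range(1, 9)), n)})
        dm = build_design(
            ["kappa ~ set_size"],
            tab,
            contrasts={"set_size": "successive_difference"},
            factors=["set_size"],
        )
        X = dm["kappa"].fixed.X
        assert X.shape[1] == 8  # intercept + 7 difference columns
        scheme = get_contrast("successive_difference", 8)
        means = rng.normal(0, 4, 8)
        coefs = scheme.coefficients_for_means(means)
        fitted = X @ coefs
        levels = sorted(tab["set_size"].unique())
        for i, lv in enumerate(levels):
            np.testing.assert_allclose(fitted[tab["set_size"] == lv], means[i], atol=1e-10)

    def test_design_rows_carry_leading_ones(self):
        tab = pd.DataFrame({"f": [1, 2, 3, 4]})
        dm = build_design(["kappa ~ f"], tab, contrasts={"f": "successive_difference"}, factors=["f"])
        X = dm["kappa"].fixed.X
        expected = np.array([[1, 0, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0], [1, 1, 1, 1]], dtype=float)
        np.testing.assert_allclose(X, expected)

    def test_random_block_structure(self):
        tab = _table()
        dm = build_design(["kappa ~ 0 + setsize + (0 + setsize || subID)"], tab, factors=["setsize"])
        (rb,) = dm["kappa"].random
        assert rb.Z.shape == (len(tab), 4)
        assert rb.correlated is False
        assert len(rb.levels) == tab["subID"].nunique()

    def test_stratified_random_block(self):
        tab = _table()
        # make subID nested in ageGroup so stratification is well defined
        tab["ageGroup"] = np.where(tab["subID"] <= 2, "old", "young")
        dm = build_design(
            ["kappa ~ 0 + ageGroup + (1 | gr(subID, by = ageGroup))"], tab
        )
        (rb,) = dm["kappa"].random
        assert rb.by == "ageGroup"
        assert rb.strata == ["old", "young"]
        assert set(rb.stratum_of_level) == {0, 1}

    def test_stratification_conflict_detected(self):
        tab = _table()
        with pytest.raises(FormulaError, match="spans multiple levels"):
            build_design(["kappa ~ 1 + (1 | gr(subID, by = ageGroup))"], tab)

    def test_rank_deficiency_names_aliased_columns(self):
        tab = _table()
        tab["dup"] = tab["rt"]
        with pytest.raises(FormulaError, match="aliased columns.*dup"):
            build_design(["kappa ~ rt + dup"], tab)

    def test_unknown_column(self):
        with pytest.raises(FormulaError, match="unknown column"):
            build_design(["kappa ~ nonexistent"], _table())

    def test_determinism(self):
        tab = _table()
        a = build_design(["kappa ~ 0 + setsize + (1 || subID)"], tab, factors=["setsize"])
        b = build_design(["kappa ~ 0 + setsize + (1 || subID)"], tab, factors=["setsize"])
        np.testing.assert_array_equal(a["kappa"].fixed.X, b["kappa"].fixed.X)
        assert a["kappa"].fixed.labels == b["kappa"].fixed.labels

    def test_covariate_column(self):
        tab = _table()
        dm = build_design(["kappa ~ rt"], tab)
        assert dm["kappa"].fixed.labels == ["Intercept", "rt"]
        np.testing.assert_allclose(dm["kappa"].fixed.X[:, 1], tab["rt"].to_numpy())
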