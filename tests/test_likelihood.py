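import numpy as np
import pytest
from scipy.integrate import quad

from vwmmix import (
    dataset_loglik,
    imm_component_probs,
    make_model,
    softmax_probs,
    trial_loglik,
)
from vwmmix.circular import vonmises_pdf
from vwmmix.likelihood import PreparedData, loglik, loglik_grad

from conftest import random_prepared_data


def _all_models():
    nt = ["l1", "l2", "l3"]
    d = ["d1", "d2", "d3"]
    return [
        make_model("mixture2p"),
        make_model("mixture3p", nt_cols=nt, set_size_col="ss"),
        make_model("imm_abc", nt_cols=nt, set_size_col="ss"),
        make_model("imm_bsc", nt_cols=nt, set_size_col="ss", distance_cols=d),
        make_model("imm_full", nt_cols=nt, set_size_col="ss", distance_cols=d),
    ]


class TestSoftmax:
    def test_worked_example(self):
        p = softmax_probs([2.0])
        assert round(float(p[0]), 2) == 0.88
        assert round(float(p[1]), 2) == 0.12

    def test_symmetry_three_components(self):
        p = softmax_probs([0.0, 0.0])
        np.testing.assert_allclose(p, [1 / 3, 1 / 3, 1 / 3])

    def test_against_brute_force(self):
        theta = np.array([1.0, 2.0, 0.0])
        expected = np.exp(theta) / np.exp(theta).sum()  # direct oracle
        np.testing.assert_allclose(softmax_probs([1.0, 2.0]), expected, atol=1e-12)

    def test_sums_to_one_and_overflow_safe(self):
        p = softmax_probs([800.0, -800.0])
        assert np.isfinite(p).all()
        assert p.sum() == pytest.approx(1.0)

    def test_matrix_input(self):
        p = softmax_probs(np.array([[2.0], [0.0]]))
        assert p.shape == (2, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)


class TestIMMProbs:
    def test_abc_zero_general_activation_kills_lures(self):
        p_mem, p_nt, p_guess = imm_component_probs((1.0, 0.0, 0.0, 1.0), 4, "abc")
        np.testing.assert_allclose(p_nt, 0.0)
        assert p_mem + p_guess == pytest.approx(1.0)

    def test_abc_worked_arithmetic(self):
        # a=0.5, c=1, b=1, set size 3: A = (1.5, 0.5, 0.5), denominator 3.5
        p_mem, p_nt, p_guess = imm_component_probs((1.0, 0.5, 0.0, 1.0), 3, "abc")
        assert p_mem == pytest.approx(1.5 / 3.5)
        np.testing.assert_allclose(p_nt, 0.5 / 3.5)
        assert p_guess == pytest.approx(1.0 / 3.5)

    def test_simplex(self):
        for version, act in [("abc", (0.7, 0.3, 0.0, 1.0)), ("bsc", (0.9, 0.0, 1.2, 1.0)),
                             ("full", (0.8, 0.4, 0.6, 1.0))]:
            p_mem, p_nt, p_guess = imm_component_probs(
                act, 4, version, distances=[0.5, 1.0, 2.0] if version != "abc" else None
            )
            assert p_mem + np.sum(p_nt) + p_guess == pytest.approx(1.0)

    def test_full_reduces_to_abc_in_large_s_limit(self):
        # with s -> inf the gradient term vanishes for every lure (D_j > 0),
        # collapsing the full model onto abc with the same (a, b, c)
        act_abc = imm_component_probs((1.2, 0.4, 0.0, 1.0), 4, "abc")
        act_full = imm_component_probs((1.2, 0.4, 1e8, 1.0), 4, "full", distances=[0.5, 1.0, 1.5])
        np.testing.assert_allclose(act_full[0], act_abc[0], atol=1e-12)
        np.testing.assert_allclose(act_full[1], act_abc[1], atol=1e-12)

    def test_full_s_zero_equalizes_items(self):
        p_mem, p_nt, _ = imm_component_probs((1.0, 0.5, 0.0, 1.0), 3, "full", distances=[0.7, 2.0])
        np.testing.assert_allclose(p_nt, p_mem)

    def test_negative_activation_rejected(self):
        with pytest.raises(ValueError):
            imm_component_probs((-0.1, 0.5, 0.0, 1.0), 3, "abc")

    def test_bsc_requires_distances(self):
        with pytest.raises(ValueError):
            imm_component_probs((1.0, 0.0, 1.0, 1.0), 3, "bsc")


class TestTrialLoglik:
    def test_2p_plug_in_oracle(self):
        # kappa = 4, theta_target = 2, x = 0.3: direct numeric oracle
        p = np.exp(2.0) / (np.exp(2.0) + 1.0)
        expected = np.log(p * vonmises_pdf(0.3, 0.0, 4.0) + (1 - p) / (2 * np.pi))
        model = make_model("mixture2p")
        got = trial_loglik(
            {"response_error": 0.3}, {"kappa": np.log(4.0), "thetat": 2.0}, model
        )
        assert got == pytest.approx(expected, abs=1e-8)

    def test_3p_at_set_size_one_equals_2p(self):
        m3 = make_model("mixture3p", nt_cols=["l1", "l2"], set_size_col="ss")
        m2 = make_model("mixture2p")
        row = {"response_error": 0.7, "ss": 1, "l1": np.nan, "l2": np.nan}
        ll3 = trial_loglik(row, {"kappa": 1.2, "thetat": 0.8, "thetant": 0.5}, m3)
        ll2 = trial_loglik(row, {"kappa": 1.2, "thetat": 0.8}, m2)
        assert ll3 == pytest.approx(ll2, abs=1e-12)

    def test_active_slot_missing_errors(self):
        m3 = make_model("mixture3p", nt_cols=["l1", "l2"], set_size_col="ss")
        with pytest.raises(ValueError, match="missing"):
            trial_loglik(
                {"response_error": 0.1, "ss": 3, "l1": 0.5, "l2": np.nan},
                {"kappa": 1.0, "thetat": 0.5, "thetant": 0.0},
                m3,
            )

    @pytest.mark.parametrize("model", _all_models(), ids=lambda m: m.name)
    def test_density_normalizes(self, model):
        rng = np.random.default_rng(hash(model.name) % 2**32)
        for _ in range(4):
            params = {p: rng.normal(0.3, 0.7) for p in model.parameters}
            row = {"response_error": 0.0, "ss": 3, "l1": 1.0, "l2": -2.0, "l3": np.nan,
                   "d1": 0.5, "d2": 1.5, "d3": np.nan}
            val, _ = quad(
                lambda x: np.exp(trial_loglik({**row, "response_error": x}, params, model)),
                -np.pi, np.pi, limit=200,
            )
            assert val == pytest.approx(1.0, abs=1e-6)


class TestEquivalences:
    def test_immabc_equals_mixture3p(self):
        """Mapping IMMabc activations to probabilities and evaluating the 3p
        likelihood reproduces the IMMabc log-density exactly."""
        rng = np.random.default_rng(8)
        data = random_prepared_data(rng, n=40)
        m_abc = make_model("imm_abc", nt_cols=["l1", "l2", "l3"], set_size_col="ss")
        m_3p = make_model("mixture3p", nt_cols=["l1", "l2", "l3"], set_size_col="ss")
        n = data.n_trials
        eta_abc = {"kappa": rng.normal(1, 0.5, n), "c": rng.normal(0, 0.5, n),
                   "a": rng.normal(-0.5, 0.5, n)}
        ll_abc = loglik(eta_abc, data, m_abc)
        # translate activations -> mixing weights relative to the guess (b = 1)
        c, a = np.exp(eta_abc["c"]), np.exp(eta_abc["a"])
        n_lures = np.maximum(data.set_size - 1, 1)
        eta_3p = {
            "kappa": eta_abc["kappa"],
            "thetat": np.log(a + c),  # log(A_target / b)
            "thetant": np.log(a * n_lures),  # combined lure weight
        }
        ll_3p = loglik(eta_3p, data, m_3p)
        np.testing.assert_allclose(ll_3p, ll_abc, atol=1e-10)

    def test_mixture2p_equals_3p_with_zero_nontarget(self):
        rng = np.random.default_rng(9)
        data = random_prepared_data(rng, n=30)
        m2 = make_model("mixture2p")
        m3 = make_model("mixture3p", nt_cols=["l1", "l2", "l3"], set_size_col="ss")
        n = data.n_trials
        kappa = rng.normal(1, 0.5, n)
        thetat = rng.normal(0.5, 1, n)
        ll2 = loglik({"kappa": kappa, "thetat": thetat}, data, m2)
        ll3 = loglik(
            {"kappa": kappa, "thetat": thetat, "thetant": np.full(n, -745.0)}, data, m3
        )
        np.testing.assert_allclose(ll3, ll2, atol=1e-10)

    def test_mixture2p_equals_immabc_with_zero_a(self):
        rng = np.random.default_rng(10)
        data = random_prepared_data(rng, n=30)
        m2 = make_model("mixture2p")
        m_abc = make_model("imm_abc", nt_cols=["l1", "l2", "l3"], set_size_col="ss")
        n = data.n_trials
        kappa = rng.normal(1, 0.5, n)
        c = np.exp(rng.normal(0, 0.5, n))
        ll_abc = loglik(
            {"kappa": kappa, "c": np.log(c), "a": np.full(n, -745.0)}, data, m_abc
        )
        # with a = 0: p_mem = c/(1+c), i.e. thetat = log(c)
        ll2 = loglik({"kappa": kappa, "thetat": np.log(c)}, data, m2)
        np.testing.assert_allclose(ll_abc, ll2, atol=1e-10)

    def test_guessing_kernel_virtually_uniform(self):
        model = make_model("mixture2p")
        x = np.linspace(-np.pi, np.pi, 501)
        # thetat -> -inf leaves only the guessing kernel
        ll = [trial_loglik({"response_error": xi}, {"kappa": 0.0, "thetat": -745.0}, model)
              for xi in x]
        rel = np.abs(np.exp(ll) * 2 * np.pi - 1.0)
        assert rel.max() < 1e-3


class TestDatasetLoglik:
    def _sim(self):
        import vwmmix as v

        m = make_model("mixture3p", nt_cols=["col_lure1", "col_lure2"], set_size_col="setsize")
        cfg = v.GenerativeConfig(
            model=m, n_subjects=2,
            cells=[{"set_size": 3, "kappa": 6.0, "p_mem": 0.7, "p_nt": 0.15}],
            n_trials=50, seed=1,
        )
        return m, v.simulate_trials(cfg).table

    def test_single_row_equals_trial_loglik(self):
        m, tab = self._sim()
        params = {"kappa": 1.5, "thetat": 1.0, "thetant": -0.5}
        row = tab.iloc[0]
        assert dataset_loglik(tab.iloc[[0]], params, m) == pytest.approx(
            trial_loglik(row, params, m), abs=1e-12
        )

    def test_permutation_invariance(self):
        m, tab = self._sim()
        params = {"kappa": 1.5, "thetat": 1.0, "thetant": -0.5}
        shuffled = tab.sample(frac=1.0, random_state=3)
        assert dataset_loglik(tab, params, m) == pytest.approx(
            dataset_loglik(shuffled, params, m), abs=1e-8
        )

    def test_matches_naive_loop_oracle(self):
        m, tab = self._sim()
        params = {"kappa": 1.5, "thetat": 1.0, "thetant": -0.5}
        total = sum(trial_loglik(row, params, m) for _, row in tab.iterrows())
        assert dataset_loglik(tab, params, m) == pytest.approx(total, abs=1e-8)


@pytest.mark.parametrize("model", _all_models(), ids=lambda m: m.name)
def test_gradients_match_finite_differences(model):
    rng = np.random.default_rng(17)
    data = random_prepared_data(rng, n=12)
    eta = {p: rng.normal(0.4, 0.6, data.n_trials) for p in model.parameters}
    ll, grads = loglik_grad(eta, data, model)
    eps = 1e-6
    for p in model.parameters:
        for i in range(data.n_trials):
            up = {k: v.copy() for k, v in eta.items()}
            dn = {k: v.copy() for k, v in eta.items()}
            up[p][i] += eps
            dn[p][i] -= eps
            fd = (loglik(up, data, model)[i] - loglik(dn, data, model)[i]) / (2 * eps)
            assert grads[p][i] == pytest.approx(fd, abs=1e-5)
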