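import numpy as np
import pandas as pd
import pytest

import vwmmix as v
from vwmmix.circular import k2sd, wrap_angle
from vwmmix.data import (
    SchemaError,
    find_slot_columns,
    normalize_table,
    prepare_arrays,
    read_table,
    recode_relative,
    validate_table,
    write_table,
)


class TestRecodeRelative:
    def test_worked_example(self):
        # target 0.7, non-targets (0.5, 0.9, 1.1) -> (-0.2, 0.2, 0.4)
        err, rel = recode_relative(0.9, 0.7, [0.5, 0.9, 1.1])
        np.testing.assert_allclose(rel, [-0.2, 0.2, 0.4], atol=1e-12)

    def test_response_at_target(self):
        err, _ = recode_relative(1.3, 1.3)
        assert err == 0.0

    def test_wraps_across_seam(self):
        _, rel = recode_relative(0.0, 3.0, [-3.0])
        assert rel[0] == pytest.approx(wrap_angle(-6.0))
        assert rel[0] == pytest.approx(2 * np.pi - 6.0, abs=1e-12)


def _standard_schema_table(n=30, seed=0, max_set_size=6):
    """Long-format table in the standard published-dataset layout."""
    rng = np.random.default_rng(seed)
    set_size = rng.choice([1, 2, 3, 6], n)
    rows = []
    for i in range(n):
        row = {
            "subID": int(rng.integers(1, 5)),
            "trial": i + 1,
            "setsize": int(set_size[i]),
            "response_error": float(rng.vonmises(0, 4)),
        }
        for j in range(max_set_size - 1):
            row[f"col_lure{j + 1}"] = (
                float(rng.uniform(-np.pi, np.pi)) if j < set_size[i] - 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


class TestValidation:
    def test_standard_schema_valid_for_2p(self):
        tab = _standard_schema_table()
        report = validate_table(tab, v.make_model("mixture2p"))
        assert report.ok and not report.warnings

    def test_standard_schema_valid_for_3p(self):
        tab = _standard_schema_table()
        model = v.make_model(
            "mixture3p", nt_cols=v.standard_nt_columns(6), set_size_col="setsize"
        )
        assert validate_table(tab, model).ok

    def test_missing_nt_columns_hard_error(self):
        tab = _standard_schema_table().drop(columns=["col_lure1"])
        model = v.make_model(
            "mixture3p", nt_cols=v.standard_nt_columns(6), set_size_col="setsize"
        )
        with pytest.raises(SchemaError, match="col_lure1"):
            validate_table(tab, model)

    def test_degrees_warning(self):
        tab = _standard_schema_table()
        tab["response_error"] = np.degrees(tab["response_error"])
        report = validate_table(tab, v.make_model("mixture2p"))
        assert any("degrees" in w for w in report.warnings)

    def test_active_slot_missing_flagged(self):
        tab = _standard_schema_table()
        tab.loc[tab["setsize"] >= 2, "col_lure1"] = np.nan
        model = v.make_model(
            "mixture3p", nt_cols=v.standard_nt_columns(6), set_size_col="setsize"
        )
        report = validate_table(tab, model)
        assert not report.ok


class TestNormalization:
    def test_zeros_beyond_set_size_become_missing(self):
        model = v.make_model("mixture3p", nt_cols=["col_lure1", "col_lure2"], set_size_col="setsize")
        tab = pd.DataFrame(
            {
                "setsize": [1, 2, 3],
                "response_error": [0.1, 0.2, 0.3],
                "col_lure1": [0.0, 0.5, -0.5],
                "col_lure2": [0.0, 0.0, 1.0],
            }
        )
        out = normalize_table(tab, model)
        assert np.isnan(out.loc[0, "col_lure1"]) and np.isnan(out.loc[0, "col_lure2"])
        assert out.loc[1, "col_lure1"] == 0.5 and np.isnan(out.loc[1, "col_lure2"])
        assert out.loc[2, "col_lure2"] == 1.0

    def test_zero_is_legal_for_active_slot(self):
        model = v.make_model("mixture3p", nt_cols=["col_lure1"], set_size_col="setsize")
        tab = pd.DataFrame({"setsize": [2], "response_error": [0.1], "col_lure1": [0.0]})
        out = normalize_table(tab, model)
        assert out.loc[0, "col_lure1"] == 0.0

    def test_angles_wrapped(self):
        model = v.make_model("mixture2p")
        tab = pd.DataFrame({"response_error": [6.0]})
        out = normalize_table(tab, model)
        assert out.loc[0, "response_error"] == pytest.approx(6.0 - 2 * np.pi)


def test_find_slot_columns_regex():
    tab = _standard_schema_table()
    cols = find_slot_columns(tab, r"col_lure\d+")
    assert cols == tuple(f"col_lure{j}" for j in range(1, 6))


def test_csv_round_trip(tmp_path):
    tab = _standard_schema_table()
    path = tmp_path / "trials.csv"
    write_table(tab, path)
    assert "nan" not in path.read_text().lower()  # missing values as empty fields
    model = v.make_model("mixture2p")
    back = read_table(path, model)
    np.testing.assert_allclose(back["response_error"], wrap_angle(tab["response_error"].to_numpy()))


class TestSimulator:
    def test_pure_memory_condition(self, model_2p):
        cfg = v.GenerativeConfig(
            model=model_2p, n_subjects=1,
            cells=[{"set_size": 1, "kappa": 8.0, "p_mem": 1.0}],
            n_trials=10_000, seed=3,
        )
        sim = v.simulate_trials(cfg)
        assert set(sim.labels) == {"target"}
        # empirical circular SD within 10% of k2sd(kappa_true)
        r = np.abs(np.mean(np.exp(1j * sim.table["response_error"].to_numpy())))
        emp_sd = np.sqrt(-2 * np.log(r))
        assert emp_sd == pytest.approx(k2sd(8.0), rel=0.1)

    def test_pure_guessing_condition(self, model_2p):
        cfg = v.GenerativeConfig(
            model=model_2p, n_subjects=1,
            cells=[{"set_size": 1, "kappa": 8.0, "p_mem": 1e-12}],
            n_trials=5_000, seed=4,
        )
        sim = v.simulate_trials(cfg)
        assert set(sim.labels) == {"guess"}
        err = sim.table["response_error"].to_numpy()
        # uniform errors: Rayleigh statistic small
        r = np.abs(np.mean(np.exp(1j * err)))
        assert 2 * err.size * r**2 < 13.8  # chi2(2) 0.999 quantile

    def test_set_size_one_has_no_lures(self, model_3p):
        cfg = v.GenerativeConfig(
            model=model_3p, n_subjects=2,
            cells=[{"set_size": 1, "kappa": 6.0, "p_mem": 0.7, "p_nt": 0.0}],
            n_trials=200, seed=5,
        )
        sim = v.simulate_trials(cfg)
        assert not any(lab.startswith("nontarget") for lab in sim.labels)
        assert sim.table[list(model_3p.nt_cols)].isna().all().all()

    def test_label_frequencies_converge(self, model_3p):
        p_mem, p_nt = 0.6, 0.25
        n = 10_000
        cfg = v.GenerativeConfig(
            model=model_3p, n_subjects=1,
            cells=[{"set_size": 3, "kappa": 6.0, "p_mem": p_mem, "p_nt": p_nt}],
            n_trials=n, seed=6,
        )
        sim = v.simulate_trials(cfg)
        for prob, count in [
            (p_mem, np.sum(sim.labels == "target")),
            (p_nt, np.sum(np.char.startswith(sim.labels, "nontarget"))),
            (1 - p_mem - p_nt, np.sum(sim.labels == "guess")),
        ]:
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(count / n - prob) < 3 * se + 1e-9

    def test_seed_determinism(self, model_3p):
        cfg = v.GenerativeConfig(
            model=model_3p, n_subjects=2,
            cells=[{"set_size": 3, "kappa": 6.0, "p_mem": 0.7, "p_nt": 0.1}],
            n_trials=25, random_sd={"kappa": 0.2}, seed=11,
        )
        a, b = v.simulate_trials(cfg), v.simulate_trials(cfg)
        pd.testing.assert_frame_equal(a.table, b.table)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_simulated_table_passes_validation(self, sim_3p, model_3p):
        assert validate_table(sim_3p.table, model_3p).ok
        prepared = prepare_arrays(sim_3p.table, model_3p)
        assert prepared.n_trials == len(sim_3p.table)

    def test_imm_distances_generated(self):
        model = v.make_model(
            "imm_full", nt_cols=["l1", "l2"], set_size_col="setsize",
            distance_cols=["d1", "d2"],
        )
        cfg = v.GenerativeConfig(
            model=model, n_subjects=1,
            cells=[{"set_size": 3, "kappa": 6.0, "c": 2.0, "a": 0.3, "s": 1.0}],
            n_trials=50, seed=7,
        )
        sim = v.simulate_trials(cfg)
        d = sim.table[["d1", "d2"]].to_numpy()
        assert np.all((d > 0) & (d <= np.pi))

    def test_inconsistent_design_rejected(self, model_3p):
        cfg = v.GenerativeConfig(
            model=model_3p, n_subjects=1,
            cells=[{"set_size": 9, "kappa": 5.0, "p_mem": 0.5, "p_nt": 0.2}],
            n_trials=5, seed=1,
        )
        with pytest.raises(ValueError, match="slot columns"):
            v.simulate_trials(cfg)

    def test_absolute_then_recode_round_trip(self):
        """Generating absolute locations and recoding them reproduces a
        directly generated relative layout (wrap of the difference)."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            target = rng.uniform(-np.pi, np.pi)
            lures_abs = rng.uniform(-np.pi, np.pi, size=3)
            resp = rng.uniform(-np.pi, np.pi)
            err, rel = recode_relative(resp, target, lures_abs)
            assert err == pytest.approx(wrap_angle(resp - target))
            np.testing.assert_allclose(rel, wrap_angle(lures_abs - target), atol=1e-12)
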