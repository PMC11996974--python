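import numpy as np
import pandas as pd
import pytest

import vwmmix as v


@pytest.fixture(scope="session")
def model_2p():
    return v.make_model("mixture2p")


@pytest.fixture(scope="session")
def model_3p():
    return v.make_model(
        "mixture3p",
        nt_cols=v.standard_nt_columns(6),
        set_size_col="setsize",
    )


@pytest.fixture(scope="session")
def sim_3p(model_3p):
    """Small mixed-set-size 3p dataset with known truth."""
    cfg = v.GenerativeConfig(
        model=model_3p,
        n_subjects=6,
        cells=[
            {"set_size": 2, "kappa": 8.0, "p_mem": 0.8, "p_nt": 0.1},
            {"set_size": 4, "kappa": 5.0, "p_mem": 0.6, "p_nt": 0.2},
        ],
        n_trials=30,
        random_sd={"kappa": 0.2, "thetat": 0.2, "thetant": 0.1},
        seed=42,
    )
    return v.simulate_trials(cfg)


@pytest.fixture(scope="session")
def twocond_fit(model_2p):
    """Shared small two-condition 2p fit with a large true thetat difference.

    Used by hypothesis / pp_check / summary tests; sample_prior enabled.
    """
    cfg = v.GenerativeConfig(
        model=model_2p,
        n_subjects=8,
        cells=[
            {"set_size": 1, "cond": "A", "kappa": 8.0, "p_mem": 0.92},
            {"set_size": 1, "cond": "B", "kappa": 8.0, "p_mem": 0.55},
        ],
        n_trials=40,
        random_sd={"kappa": 0.15, "thetat": 0.2},
        seed=5,
    )
    sim = v.simulate_trials(cfg)
    fit = v.fit(
        model_2p,
        ["kappa ~ 0 + cond + (1 || subID)", "thetat ~ 0 + cond + (1 || subID)"],
        sim.table,
        chains=2,
        warmup=300,
        iter=300,
        seed=21,
        sample_prior=True,
    )
    return sim, fit


def random_prepared_data(rng, n=20, max_slots=3, with_distances=True):
    from vwmmix.likelihood import PreparedData

    set_size = rng.integers(1, max_slots + 2, size=n)
    mask = np.arange(max_slots)[None, :] < (set_size - 1)[:, None]
    nt = np.where(mask, rng.uniform(-np.pi, np.pi, (n, max_slots)), 0.0)
    dist = np.where(mask, rng.uniform(0.05, np.pi, (n, max_slots)), 0.0)
    return PreparedData(
        x=rng.uniform(-np.pi, np.pi, n),
        set_size=set_size,
        nt=nt,
        nt_mask=mask,
        dist=dist if with_distances else None,
    )
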