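"""Model estimation: priors -> posterior -> HMC chains -> FitResult."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._posterior import Posterior
from .data import prepare_arrays
from .formula import build_design
from .models import ModelSpec, make_model
from .priors import default_priors, resolve_priors
from .sampler import sample_chain

__all__ = ["FitResult", "fit", "convergence_report", "ConvergenceReport"]


@dataclass
class FitResult:
    """Posterior draws plus provenance for one estimated model.

    ``draws`` holds constrained quantities, shape (chains, iterations,
    n_coefficients), aligned with ``coef_names``: fixed-effect coefficients
    ("kappa_setsize1"), random-effect SDs ("sd_subID__kappa_setsize1"),
    correlations ("cor_..."), and realized random effects ("r_...").
    """

    draws: np.ndarray
    coef_names: list
    model: ModelSpec
    formulas: list
    data: pd.DataFrame
    prior_table: pd.DataFrame
    divergences: list
    step_sizes: list
    accept_rates: list
    seed: int | None
    data_fingerprint: str
    contrasts: dict | None = None
    factors: list | None = None
    prior_draws: np.ndarray | None = None
    prior_names: list | None = None
    prior_only: bool = False

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one coefficient, shape (chains, iterations)."""
        try:
            idx = self.coef_names.index(name)
        except ValueError:
            raise KeyError(f"unknown coefficient {name!r}") from None
        return self.draws[:, :, idx]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def get_prior(self, name: str) -> np.ndarray:
        if self.prior_draws is None:
            raise ValueError("fit was run without sample_prior=True; no prior draws stored")
        try:
            idx = self.prior_names.index(name)
        except ValueError:
            raise KeyError(f"no prior draws for coefficient {name!r}") from None
        return self.prior_draws[:, idx]

    def rebuild_design(self):
        return build_design(
            self.formulas, self.data, contrasts=self.contrasts, factors=self.factors,
            model=self.model,
        )

    # -- persistence (text formats only) ------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        chains, iters, k = self.draws.shape
        tidy = pd.DataFrame(
            {
                "chain": np.repeat(np.arange(chains), iters * k),
                "iteration": np.tile(np.repeat(np.arange(iters), k), chains),
                "coefficient": np.tile(self.coef_names, chains * iters),
                "value": self.draws.reshape(-1),
            }
        )
        tidy.to_csv(path / "draws.csv", index=False)
        if self.prior_draws is not None:
            pd.DataFrame(self.prior_draws, columns=self.prior_names).to_csv(
                path / "prior_draws.csv", index=False
            )
        self.data.to_csv(path / "data.csv", index=False)
        self.prior_table.to_csv(path / "priors.csv", index=False)
        meta = {
            "model": {
                "name": self.model.name,
                "response_col": self.model.response_col,
                "nt_cols": list(self.model.nt_cols),
                "set_size_col": self.model.set_size_col,
                "distance_cols": list(self.model.distance_cols),
                "version": self.model.version,
            },
            "formulas": list(self.formulas),
            "contrasts": self.contrasts,
            "factors": list(self.factors) if self.factors else None,
            "coef_names": list(self.coef_names),
            "divergences": [int(d) for d in self.divergences],
            "step_sizes": [float(s) for s in self.step_sizes],
            "accept_rates": [float(a) for a in self.accept_rates],
            "seed": self.seed,
            "data_fingerprint": self.data_fingerprint,
            "prior_only": self.prior_only,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "FitResult":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        data = pd.read_csv(path / "data.csv")
        prior_table = pd.read_csv(path / "priors.csv")
        tidy = pd.read_csv(path / "draws.csv")
        coef_names = meta["coef_names"]
        chains = int(tidy["chain"].max()) + 1
        iters = int(tidy["iteration"].max()) + 1
        draws = (
            tidy["value"].to_numpy().reshape(chains, iters, len(coef_names))
        )
        prior_draws = prior_names = None
        if (path / "prior_draws.csv").exists():
            pdf = pd.read_csv(path / "prior_draws.csv")
            prior_names = list(pdf.columns)
            prior_draws = pdf.to_numpy()
        m = meta["model"]
        model = make_model(
            m["name"],
            response_col=m["response_col"],
            nt_cols=m["nt_cols"] or None,
            set_size_col=m["set_size_col"],
            distance_cols=m["distance_cols"] or None,
            version=m["version"],
        )
        return cls(
            draws=draws,
            coef_names=coef_names,
            model=model,
            formulas=meta["formulas"],
            data=data,
            prior_table=prior_table,
            divergences=meta["divergences"],
            step_sizes=meta["step_sizes"],
            accept_rates=meta["accept_rates"],
            seed=meta["seed"],
            data_fingerprint=meta["data_fingerprint"],
            contrasts=meta["contrasts"],
            factors=meta["factors"],
            prior_draws=prior_draws,
            prior_names=prior_names,
            prior_only=meta.get("prior_only", False),
        )


def _fingerprint(table: pd.DataFrame) -> str:
    return hashlib.sha256(table.to_csv(index=False).encode()).hexdigest()[:16]


def fit(
    model: ModelSpec,
    formulas,
    table: pd.DataFrame,
    priors=(),
    chains: int = 4,
    warmup: int = 1000,
    iter: int = 1000,
    seed: int | None = None,
    sample_prior: bool = False,
    cores: int = 1,
    contrasts: dict | None = None,
    factors=None,
    prior_only: bool = False,
    target_accept: float = 0.8,
    max_init_retries: int = 20,
) -> FitResult:
    """Estimate a measurement model by HMC over the hierarchical posterior.

    Defaults follow the usual four chains with 1000 warmup and 1000
    post-warmup iterations each. ``sample_prior=True`` additionally stores
    matched IID prior draws of the fixed effects and random-effect SDs (as
    needed for Savage-Dickey evidence ratios). ``prior_only=True`` disables
    the likelihood term (prior predictive sanity checks).

    Chains run sequentially regardless of ``cores`` (accepted for interface
    compatibility); results are deterministic given ``seed``.
    """
    if isinstance(formulas, str):
        formulas = [formulas]
    formulas = list(formulas)
    data = prepare_arrays(table, model)
    design = build_design(table=table, formulas=formulas, contrasts=contrasts, factors=factors, model=model)
    resolved = resolve_priors(model, design, priors)
    post = Posterior(model, design, data, resolved, prior_only=prior_only)
    prior_table = default_priors(
        model, formulas, table, contrasts=contrasts, factors=factors, user_priors=priors
    )

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains + 1)
    all_draws, divergences, step_sizes, accept_rates = [], [], [], []
    for ci in range(chains):
        rng = np.random.default_rng(chain_seeds[ci])
        init = None
        last_err = None
        for _ in range(max_init_retries):
            cand = post.init_vector(rng)
            try:
                post.check_finite(cand)
                lp, _ = post.logp_grad(cand)
                if np.isfinite(lp):
                    init = cand
                    break
            except RuntimeError as e:
                last_err = e
        if init is None:
            raise RuntimeError(
                f"chain {ci}: failed to find a finite initialization after "
                f"{max_init_retries} attempts"
            ) from last_err
        res = sample_chain(
            post.logp_grad,
            init,
            n_warmup=warmup,
            n_iter=iter,
            rng=rng,
            target_accept=target_accept,
            store_fn=post.constrain_store,
        )
        all_draws.append(res.draws)
        divergences.append(res.divergences)
        step_sizes.append(res.step_size)
        accept_rates.append(res.accept_rate)

    draws = np.stack(all_draws)  # (chains, iter, K)
    prior_draws = prior_names = None
    if sample_prior:
        prior_rng = np.random.default_rng(chain_seeds[chains])
        prior_names, prior_draws = post.sample_prior_draws(prior_rng, chains * iter)

    return FitResult(
        draws=draws,
        coef_names=list(post.coef_names),
        model=model,
        formulas=formulas,
        data=table,
        prior_table=prior_table,
        divergences=divergences,
        step_sizes=step_sizes,
        accept_rates=accept_rates,
        seed=seed,
        data_fingerprint=_fingerprint(table),
        contrasts=contrasts,
        factors=list(factors) if factors else None,
        prior_draws=prior_draws,
        prior_names=prior_names,
        prior_only=prior_only,
    )


@dataclass
class ConvergenceReport:
    per_coefficient: pd.DataFrame  # coefficient, rhat, ess_bulk, ess_tail
    divergences: int
    flagged: list  # coefficients with rhat > threshold
    warnings: list
    rhat_threshold: float = 1.05

    @property
    def ok(self) -> bool:
        return not self.flagged and self.divergences == 0


def convergence_report(fit_result: FitResult, rhat_threshold: float = 1.05) -> ConvergenceReport:
    """Split R-hat and effective sample size per coefficient, divergence count.

    Coefficients with R-hat above the threshold (default 1.05) are flagged.
    Single-chain fits produce a warning; split halves are then used.
    """
    import arviz as az

    notes = []
    if fit_result.n_chains < 2:
        msg = (
            "R-hat with a single chain is degenerate (split halves only); "
            "run >= 2 chains for a reliable diagnostic"
        )
        notes.append(msg)
        warnings.warn(msg)
    if fit_result.n_draws < 50:
        notes.append("fewer than 50 post-warmup draws: ESS estimates are unreliable")

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for idx, name in enumerate(fit_result.coef_names):
            arr = fit_result.draws[:, :, idx]
            if np.allclose(arr.std(), 0.0):
                rhat, essb, esst = np.nan, np.nan, np.nan
            else:
                rhat = float(az.rhat(arr))
                essb = float(az.ess(arr, method="bulk"))
                esst = float(az.ess(arr, method="tail"))
            rows.append(
                {"coefficient": name, "rhat": rhat, "ess_bulk": essb, "ess_tail": esst}
            )
    table = pd.DataFrame(rows)
    flagged = table.loc[table["rhat"] > rhat_threshold, "coefficient"].tolist()
    low_ess = table.loc[table["ess_bulk"] < 100, "coefficient"].tolist()
    if low_ess:
        notes.append(f"{len(low_ess)} coefficients with bulk ESS < 100")
    return ConvergenceReport(
        per_coefficient=table,
        divergences=int(sum(fit_result.divergences)),
        flagged=flagged,
        warnings=notes,
        rhat_threshold=rhat_threshold,
    )
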