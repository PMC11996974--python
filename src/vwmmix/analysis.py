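"""Post-estimation analysis: summaries, native-scale transforms, posterior
predictive checks, and Savage-Dickey hypothesis tests."""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import circular
from .data import prepare_arrays
from .fit import FitResult, convergence_report
from .likelihood import component_probs, softmax_probs

__all__ = [
    "SummaryTable",
    "summarize",
    "to_native",
    "PPCheckResult",
    "pp_check",
    "HypothesisResult",
    "hypothesis",
]

# fixed, documented smoothing kernel for circular density overlays
PPC_KERNEL_KAPPA = 20.0


@dataclass
class SummaryTable:
    """Two-section model summary: multilevel hyperparameters, then
    regression coefficients. Link-scale values (log-kappa, raw mixing
    weights); use :func:`to_native` before interpreting magnitudes."""

    hyperparameters: pd.DataFrame
    coefficients: pd.DataFrame

    def __repr__(self):  # pragma: no cover - cosmetic
        parts = []
        if len(self.hyperparameters):
            parts.append("Multilevel hyperparameters:\n" + self.hyperparameters.to_string(index=False))
        parts.append("Regression coefficients:\n" + self.coefficients.to_string(index=False))
        return "\n\n".join(parts)


def _summary_rows(fit: FitResult, names, diag: pd.DataFrame):
    rows = []
    diag_idx = diag.set_index("coefficient")
    for name in names:
        flat = fit.flat(name)
        rows.append(
            {
                "coefficient": name,
                "Estimate": float(np.mean(flat)),
                "Est.Error": float(np.std(flat, ddof=1)),
                "l-95% CI": float(np.quantile(flat, 0.025)),
                "u-95% CI": float(np.quantile(flat, 0.975)),
                "Rhat": float(diag_idx.loc[name, "rhat"]),
                "Bulk_ESS": float(diag_idx.loc[name, "ess_bulk"]),
                "Tail_ESS": float(diag_idx.loc[name, "ess_tail"]),
            }
        )
    return pd.DataFrame(rows)


def summarize(fit: FitResult) -> SummaryTable:
    """Deterministic summary of the sampled coefficients.

    The top section lists random-effect SDs (and correlations); the bottom
    section lists the fixed-effect regression coefficients. Realized
    subject-level effects (``r_...``) are available via ``fit.get`` but not
    tabulated here.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        diag = convergence_report(fit).per_coefficient
    hyper = [n for n in fit.coef_names if n.startswith(("sd_", "cor_"))]
    fixed = [n for n in fit.coef_names if not n.startswith(("sd_", "cor_", "r_"))]
    return SummaryTable(
        hyperparameters=_summary_rows(fit, hyper, diag),
        coefficients=_summary_rows(fit, fixed, diag),
    )


def to_native(draws, kind: str, as_degrees_sd: bool = False):
    """Transform link-scale draws to the native parameter scale.

    kind = "kappa": exponentiate (optionally chain kappa -> circular SD ->
    degrees with ``as_degrees_sd``); "theta-set": rows of mixing weights
    (reference appended) through the softmax, giving simplex rows (the
    two-component case reduces to the inverse logit); "imm-activation":
    exponentiate.
    """
    draws = np.asarray(draws, dtype=float)
    if kind == "kappa":
        native = np.exp(draws)
        if as_degrees_sd:
            return circular.rad2deg(circular.k2sd(native))
        return native
    if kind == "theta-set":
        # 1-d input: one weight per draw (the two-component case)
        if draws.ndim == 1:
            draws = draws[:, None]
        return softmax_probs(draws)
    if kind == "imm-activation":
        return np.exp(draws)
    raise ValueError(f"unknown kind {kind!r}; expected kappa, theta-set or imm-activation")


# ---------------------------------------------------------------------------
# posterior predictive check


@dataclass
class PPCheckResult:
    grid: np.ndarray  # (g,) angles in (-pi, pi]
    observed: np.ndarray  # (g,) smoothed observed density
    predicted: np.ndarray  # (n_draws, g) smoothed replicate densities
    draw_indices: np.ndarray

    def envelope_coverage(self) -> float:
        lo = self.predicted.min(axis=0)
        hi = self.predicted.max(axis=0)
        inside = (self.observed >= lo) & (self.observed <= hi)
        return float(np.mean(inside))


def _vm_kde(samples, grid, kernel_kappa=PPC_KERNEL_KAPPA):
    logc = -np.log(2 * np.pi) - circular.log_bessel_i0(kernel_kappa)
    dens = np.exp(kernel_kappa * np.cos(grid[:, None] - samples[None, :]) + logc)
    return dens.mean(axis=1)


def _coef_index(fit: FitResult):
    return {n: i for i, n in enumerate(fit.coef_names)}


def _eta_for_draw(fit: FitResult, design, idx, chain, it):
    eta = {}
    for param in fit.model.parameters:
        pdesign = design.params[param]
        beta = np.array(
            [fit.draws[chain, it, idx[f"{param}_{label}"]] for label in pdesign.fixed.labels]
        )
        e = pdesign.fixed.X @ beta
        for rb in pdesign.random:
            U = np.array(
                [
                    [
                        fit.draws[chain, it, idx[f"r_{rb.group}__{param}_{label}[{_fmt(level)}]"]]
                        for label in rb.labels
                    ]
                    for level in rb.levels
                ]
            )
            e = e + np.sum(rb.Z * U[rb.codes], axis=1)
        eta[param] = e
    return eta


def _fmt(value) -> str:
    s = str(value)
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s


def _simulate_replicate(eta, data, model, rng):
    p_t, p_slots, p_g = component_probs(eta, data, model)
    probs = np.concatenate([p_t[:, None], p_slots, p_g[:, None]], axis=1)
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    comp = (rng.uniform(size=(data.n_trials, 1)) > cum).sum(axis=1)
    kappa = np.exp(eta["kappa"])
    mu = np.zeros(data.n_trials)
    n_slots = data.nt.shape[1]
    is_slot = (comp >= 1) & (comp <= n_slots)
    mu[is_slot] = data.nt[is_slot, comp[is_slot] - 1]
    err = rng.vonmises(mu, kappa)
    guess = comp == n_slots + 1
    err[guess] = rng.uniform(-np.pi, np.pi, size=int(guess.sum()))
    return circular.wrap_angle(err)


def pp_check(fit: FitResult, n_draws: int = 10, seed: int | None = None, grid_size: int = 200) -> PPCheckResult:
    """Observed vs posterior-predicted response-error densities.

    For each of ``n_draws`` randomly selected posterior draws, a full
    replicate dataset is simulated under the original design (same
    subjects, lure geometry, set sizes) with that draw's parameters, then
    kernel-smoothed on the circle with a fixed von Mises kernel
    (concentration 20). Seed-deterministic.
    """
    total = fit.n_chains * fit.n_draws
    if n_draws > total:
        raise ValueError(f"n_draws={n_draws} exceeds the {total} stored posterior draws")
    rng = np.random.default_rng(seed)
    sel = rng.choice(total, size=n_draws, replace=False)
    design = fit.rebuild_design()
    data = prepare_arrays(fit.data, fit.model)
    idx = _coef_index(fit)
    grid = np.linspace(-np.pi, np.pi, grid_size, endpoint=False) + np.pi / grid_size
    observed = _vm_kde(data.x, grid)
    predicted = np.empty((n_draws, grid_size))
    for row, flat_i in enumerate(sel):
        chain, it = divmod(int(flat_i), fit.n_draws)
        eta = _eta_for_draw(fit, design, idx, chain, it)
        rep = _simulate_replicate(eta, data, fit.model, rng)
        predicted[row] = _vm_kde(rep, grid)
    return PPCheckResult(grid=grid, observed=observed, predicted=predicted, draw_indices=sel)


# ---------------------------------------------------------------------------
# Savage-Dickey hypothesis tests


@dataclass
class HypothesisResult:
    name: str
    statement: str
    kind: str  # "point" or "direction"
    estimate: float
    est_error: float
    ci_lower: float
    ci_upper: float
    evid_ratio: float  # BF01 for point hypotheses; posterior odds for directional
    evid_ratio_reciprocal: float
    post_prob: float | None
    note: str = ""


_OP_RE = re.compile(r"(=|>|<)")


def _eval_combination(expr: str, lookup):
    """Evaluate an arithmetic combination of coefficient draws.

    Coefficient names may contain characters that are not valid Python
    identifiers (":", "[", "]"); occurrences are substituted longest-first.
    """
    names = sorted(lookup.keys(), key=len, reverse=True)
    env = {}
    used = 0
    for name in names:
        if name in expr:
            var = f"__c{used}__"
            expr = expr.replace(name, var)
            env[var] = lookup[name]
            used += 1
    if not used:
        raise KeyError(f"no known coefficients referenced in {expr!r}")
    if re.search(r"[^\s0-9a-zA-Z_+\-*/().]", expr):
        raise ValueError(f"unsupported characters in hypothesis expression {expr!r}")
    return np.asarray(eval(expr, {"__builtins__": {}}, env))  # noqa: S307 - sanitized


def _density_at(draws, point):
    """Gaussian KDE (Scott plug-in bandwidth) evaluated at a point."""
    return float(stats.gaussian_kde(draws)(point)[0])


def hypothesis(fit: FitResult, statements) -> list:
    """Test linear/directional claims over coefficients.

    ``statements`` maps a name to a string like ``"kappa_setsize2 -
    kappa_setsize1 = 0"`` (point) or ``"thetat_condA > 0"`` (directional).
    Point hypotheses report the Savage-Dickey evidence ratio in favor of
    the stated equality, BF01 = posterior density / prior density at the
    point (its reciprocal, the BF10, is also returned); they require a fit
    run with ``sample_prior=True``. Directional hypotheses report the
    posterior probability of the stated direction and the corresponding
    posterior odds.
    """
    if isinstance(statements, (list, tuple)):
        statements = {f"H{i + 1}": s for i, s in enumerate(statements)}
    post_lookup = {n: fit.flat(n) for n in fit.coef_names}
    results = []
    for name, statement in statements.items():
        pieces = _OP_RE.split(statement)
        if len(pieces) != 3:
            raise ValueError(f"hypothesis {statement!r} must contain exactly one of =, >, <")
        lhs, op, rhs = (p.strip() for p in pieces)
        point = float(rhs)
        combo = _eval_combination(lhs, post_lookup) - point
        est = float(np.mean(combo))
        err = float(np.std(combo, ddof=1))
        lo, hi = (float(q) for q in np.quantile(combo, [0.025, 0.975]))
        note = ""
        if op == "=":
            kind = "point"
            post_prob = None
            if err < 1e-12:
                evid = np.nan
                note = "degenerate combination: all draws equal; no density ratio"
            else:
                if fit.prior_draws is None:
                    raise ValueError(
                        "point hypotheses need prior draws: re-run fit with sample_prior=True"
                    )
                prior_lookup = {
                    n: fit.prior_draws[:, i] for i, n in enumerate(fit.prior_names)
                }
                prior_combo = _eval_combination(lhs, prior_lookup) - point
                evid = _density_at(combo, 0.0) / _density_at(prior_combo, 0.0)
        else:
            kind = "direction"
            signed = combo if op == ">" else -combo
            post_prob = float(np.mean(signed > 0))
            evid = post_prob / max(1.0 - post_prob, 1.0 / combo.size)
        results.append(
            HypothesisResult(
                name=name,
                statement=statement,
                kind=kind,
                estimate=est,
                est_error=err,
                ci_lower=lo,
                ci_upper=hi,
                evid_ratio=float(evid),
                evid_ratio_reciprocal=float(1.0 / evid) if evid and np.isfinite(evid) and evid > 0 else np.nan,
                post_prob=post_prob,
                note=note,
            )
        )
    return results


def hypothesis_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "statement": r.statement,
                "kind": r.kind,
                "Estimate": r.estimate,
                "Est.Error": r.est_error,
                "l-95% CI": r.ci_lower,
                "u-95% CI": r.ci_upper,
                "Evid.Ratio": r.evid_ratio,
                "1/Evid.Ratio": r.evid_ratio_reciprocal,
                "Post.Prob": r.post_prob,
                "note": r.note,
            }
            for r in results
        ]
    )
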