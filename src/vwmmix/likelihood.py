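"""Per-trial mixture likelihoods, the softmax weight transform, and the
IMM activation-to-probability mapping.

Everything here operates on link-scale parameter values (log-kappa,
unbounded mixing weights, log-activations) and is vectorized across
trials. Gradient counterparts feed the HMC sampler; they are analytic
and verified against finite differences in the test suite.

Numerical policy: all mixture sums go through log-sum-exp and the softmax
uses max-subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .circular import bessel_ratio, log_bessel_i0, TWO_PI
from .models import ModelSpec, LOG_KAPPA_UNIFORM

__all__ = [
    "MixtureWeights",
    "IMMActivations",
    "PreparedData",
    "softmax_probs",
    "imm_component_probs",
    "trial_loglik",
    "dataset_loglik",
    "loglik",
    "loglik_grad",
    "component_probs",
]

KAPPA_UNIFORM = np.exp(LOG_KAPPA_UNIFORM)
LOG_2PI = np.log(TWO_PI)
NEG_INF = -np.inf


@dataclass
class MixtureWeights:
    """Unbounded weights of the non-reference components; reference fixed at 0."""

    theta: np.ndarray  # (K-1,) or (n, K-1)

    @property
    def K(self) -> int:
        return np.atleast_2d(self.theta).shape[-1] + 1


@dataclass
class IMMActivations:
    """IMM activation parameters; background noise b is fixed (= 1 by default)."""

    c: float
    a: float = 0.0
    s: float = 0.0
    b: float = 1.0


@dataclass
class PreparedData:
    """Column-extracted, slot-padded trial arrays for one model."""

    x: np.ndarray  # (n,) response error, wrapped
    set_size: np.ndarray  # (n,) int
    nt: np.ndarray  # (n, M) relative lure locations; 0 where inactive
    nt_mask: np.ndarray  # (n, M) bool, True for active slots
    dist: np.ndarray | None = None  # (n, M) context distances, 0 where inactive

    @property
    def n_trials(self) -> int:
        return self.x.shape[0]


def softmax_probs(weights, append_reference=True):
    """Softmax transform of mixing weights into simplex probabilities.

    p_i = exp(theta_i) / sum_j exp(theta_j), computed with max-subtraction.
    With ``append_reference`` (the default) a reference weight of 0 is
    appended as the last component, matching the convention that the
    guessing weight is fixed at 0.
    """
    if isinstance(weights, MixtureWeights):
        theta = weights.theta
    else:
        theta = weights
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    one_dim = theta.ndim == 1
    theta = np.atleast_2d(theta)
    if append_reference:
        theta = np.concatenate([theta, np.zeros((theta.shape[0], 1))], axis=1)
    shifted = theta - theta.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if one_dim else p


def imm_component_probs(act, set_size: int, version: str = "full", distances=None):
    """Map IMM activations to (p_mem, p_nontarget list, p_guess).

    Per-item activations with D_target = 0:

    - ``abc``:  A_target = a + c,           A_lure_j = a
    - ``bsc``:  A_target = c,               A_lure_j = c * exp(-s * D_j)
    - ``full``: A_target = a + c,           A_lure_j = a + c * exp(-s * D_j)

    Probabilities normalize over all items plus the background noise b:
    p_mem = A_target / (b + sum_j A_j), p_guess = b / (b + sum_j A_j).
    """
    if isinstance(act, IMMActivations):
        c, a, s, b = act.c, act.a, act.s, act.b
    else:
        c, a, s, b = act
    if min(c, a, s) < 0 or b < 0:
        raise ValueError("IMM activations must be nonnegative")
    set_size = int(set_size)
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    n_lures = set_size - 1
    if version == "abc":
        a_target = a + c
        a_lures = np.full(n_lures, a, dtype=float)
    elif version in ("bsc", "full"):
        if n_lures > 0:
            if distances is None:
                raise ValueError(f"version {version!r} requires lure distances")
            distances = np.asarray(distances, dtype=float)
            if distances.shape != (n_lures,):
                raise ValueError("need one distance per lure")
            if np.any(distances < 0):
                raise ValueError("distances must be nonnegative")
            grad = c * np.exp(-s * distances)
        else:
            grad = np.zeros(0)
        if version == "bsc":
            a_target = c
            a_lures = grad
        else:
            a_target = a + c
            a_lures = a + grad
    else:
        raise ValueError(f"unknown IMM version {version!r}")
    denom = b + a_target + a_lures.sum()
    return a_target / denom, a_lures / denom, b / denom


# ---------------------------------------------------------------------------
# vectorized likelihood


def _vm_parts(eta_kappa):
    # exp may overflow to inf during extreme sampler excursions; the
    # resulting non-finite log-density is rejected by the sampler
    with np.errstate(over="ignore"):
        kappa = np.exp(eta_kappa)
        return kappa, log_bessel_i0(kappa)


def _log_uniform_density(x):
    # guessing kernel: von Mises with log kappa = -100, numerically uniform
    return KAPPA_UNIFORM * np.cos(x) - LOG_2PI - log_bessel_i0(KAPPA_UNIFORM)


def _slot_logf(data: PreparedData, kappa, log_i0):
    """(n, M) von Mises log-density of x at each active lure location."""
    cosd = np.cos(data.x[:, None] - data.nt)
    logf = kappa[:, None] * cosd - LOG_2PI - log_i0[:, None]
    logf = np.where(data.nt_mask, logf, NEG_INF)
    return logf, cosd


def _imm_activations(eta, data: PreparedData, version: str):
    """Per-trial target/lure activations and partials wrt (log c, log a, log s)."""
    c = np.exp(eta["c"])
    a = np.exp(eta["a"]) if "a" in eta else np.zeros_like(c)
    s = np.exp(eta["s"]) if "s" in eta else np.zeros_like(c)
    mask = data.nt_mask
    if version == "abc":
        grad = np.zeros_like(data.nt)
    else:
        grad = np.exp(-s[:, None] * np.where(mask, data.dist, 0.0))
    if version == "abc":
        a_target = a + c
        a_slots = np.where(mask, a[:, None], 0.0)
    elif version == "bsc":
        a_target = c
        a_slots = np.where(mask, c[:, None] * grad, 0.0)
    else:  # full
        a_target = a + c
        a_slots = np.where(mask, a[:, None] + c[:, None] * grad, 0.0)
    return c, a, s, grad, a_target, a_slots


def _mixture_ll(log_p_target, log_p_slots, log_p_guess, logf_t, logf_slots, logf_g):
    stack = np.concatenate(
        [
            (log_p_target + logf_t)[:, None],
            log_p_slots + logf_slots,
            (log_p_guess + logf_g)[:, None],
        ],
        axis=1,
    )
    return logsumexp(stack, axis=1)


def loglik(eta: dict, data: PreparedData, model: ModelSpec) -> np.ndarray:
    """Per-trial log-likelihood (n,) for link-scale parameter arrays ``eta``."""
    return _loglik_impl(eta, data, model, want_grad=False)[0]


def loglik_grad(eta: dict, data: PreparedData, model: ModelSpec):
    """Per-trial log-likelihood and its gradient wrt each link-scale parameter.

    Returns ``(ll, grads)`` with ``grads[param]`` of shape (n,).
    """
    return _loglik_impl(eta, data, model, want_grad=True)


def _loglik_impl(eta, data, model, want_grad):
    # huge-but-finite eta can push kappa to inf; the resulting non-finite
    # log-density is handled (rejected) by the caller, so silence the noise
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _loglik_impl_inner(eta, data, model, want_grad)


def _loglik_impl_inner(eta, data, model, want_grad):
    n = data.n_trials
    for name in model.parameters:
        if eta[name].shape != (n,):
            raise ValueError(f"eta[{name!r}] must have shape ({n},)")
        if not np.all(np.isfinite(eta[name])):
            # off-support point reached by a sampler excursion: reject it
            ll = np.full(n, NEG_INF)
            if not want_grad:
                return ll, None
            return ll, {p: np.zeros(n) for p in model.parameters}
    kappa, log_i0 = _vm_parts(eta["kappa"])
    cos_x = np.cos(data.x)
    logf_t = kappa * cos_x - LOG_2PI - log_i0
    logf_g = _log_uniform_density(data.x)
    n_lures = data.set_size - 1
    has_lures = n_lures > 0

    if model.name in ("mixture2p", "mixture3p"):
        theta_t = eta["thetat"]
        if model.name == "mixture2p":
            theta = np.stack([theta_t, np.zeros(n)], axis=1)
            with np.errstate(invalid="ignore"):
                log_p = theta - logsumexp(theta, axis=1, keepdims=True)
            ll = logsumexp(
                np.stack([log_p[:, 0] + logf_t, log_p[:, 1] + logf_g], axis=1), axis=1
            )
            if not want_grad:
                return ll, None
            p = np.exp(log_p)
            w_t = np.exp(log_p[:, 0] + logf_t - ll)
            grads = {
                "thetat": w_t - p[:, 0],
                "kappa": kappa * w_t * (cos_x - bessel_ratio(kappa)),
            }
            return ll, grads

        logf_slots, cosd = _slot_logf(data, kappa, log_i0)
        with np.errstate(divide="ignore"):
            logf_nt = logsumexp(logf_slots, axis=1) - np.log(
                np.where(has_lures, n_lures, 1)
            )
        logf_nt = np.where(has_lures, logf_nt, NEG_INF)
        theta_nt = np.where(has_lures, eta["thetant"], NEG_INF)
        theta = np.stack([theta_t, theta_nt, np.zeros(n)], axis=1)
        shifted = theta - theta.max(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            log_p = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        comp = np.stack(
            [
                log_p[:, 0] + logf_t,
                np.where(has_lures, log_p[:, 1] + logf_nt, NEG_INF),
                log_p[:, 2] + logf_g,
            ],
            axis=1,
        )
        ll = logsumexp(comp, axis=1)
        if not want_grad:
            return ll, None
        p = np.exp(log_p)
        w_t = np.exp(comp[:, 0] - ll)
        w_nt = np.where(has_lures, np.exp(comp[:, 1] - ll), 0.0)
        # slot-level responsibilities
        with np.errstate(divide="ignore", invalid="ignore"):
            w_slots = np.where(
                data.nt_mask & has_lures[:, None],
                np.exp(
                    log_p[:, 1][:, None]
                    - np.log(np.maximum(n_lures, 1))[:, None]
                    + logf_slots
                    - ll[:, None]
                ),
                0.0,
            )
        A = bessel_ratio(kappa)
        g_kappa = kappa * (
            w_t * (cos_x - A) + np.sum(w_slots * (cosd - A[:, None]), axis=1)
        )
        grads = {
            "thetat": w_t - p[:, 0],
            "thetant": np.where(has_lures, w_nt - p[:, 1], 0.0),
            "kappa": g_kappa,
        }
        return ll, grads

    # IMM variants
    version = model.version
    c, a, s, grad_term, a_target, a_slots = _imm_activations(eta, data, version)
    b = model.fixed_constants["b"]
    denom = b + a_target + a_slots.sum(axis=1)
    with np.errstate(divide="ignore"):
        log_p_t = np.log(a_target) - np.log(denom)
        log_p_slots = np.where(
            data.nt_mask, np.log(np.where(data.nt_mask, a_slots, 1.0)), NEG_INF
        ) - np.log(denom)[:, None]
        log_p_g = np.log(b) - np.log(denom)
    logf_slots, cosd = _slot_logf(data, kappa, log_i0)
    ll = _mixture_ll(log_p_t, log_p_slots, log_p_g, logf_t, logf_slots, logf_g)
    if not want_grad:
        return ll, None

    # dll/dA_m = (exp(logf_m - ll) - 1) / denom for every item m
    dA_t = (np.exp(logf_t - ll) - 1.0) / denom
    dA_slots = np.where(
        data.nt_mask, (np.exp(logf_slots - ll[:, None]) - 1.0) / denom[:, None], 0.0
    )
    grads = {}
    if version == "abc":
        grads["c"] = c * dA_t
        grads["a"] = a * (dA_t + dA_slots.sum(axis=1))
    elif version == "bsc":
        grads["c"] = c * (dA_t + (dA_slots * grad_term).sum(axis=1))
        grads["s"] = s * (
            -(dA_slots * c[:, None] * np.where(data.nt_mask, data.dist, 0.0) * grad_term).sum(
                axis=1
            )
        )
    else:  # full
        grads["c"] = c * (dA_t + (dA_slots * grad_term).sum(axis=1))
        grads["a"] = a * (dA_t + dA_slots.sum(axis=1))
        grads["s"] = s * (
            -(dA_slots * c[:, None] * np.where(data.nt_mask, data.dist, 0.0) * grad_term).sum(
                axis=1
            )
        )
    w_t = np.exp(log_p_t + logf_t - ll)
    w_slots = np.where(
        data.nt_mask, np.exp(log_p_slots + logf_slots - ll[:, None]), 0.0
    )
    A = bessel_ratio(kappa)
    grads["kappa"] = kappa * (
        w_t * (cos_x - A) + np.sum(w_slots * (cosd - A[:, None]), axis=1)
    )
    return ll, grads


def component_probs(eta: dict, data: PreparedData, model: ModelSpec):
    """Per-trial component probabilities (p_target, p_slots (n, M), p_guess)."""
    n = data.n_trials
    n_lures = data.set_size - 1
    has_lures = n_lures > 0
    if model.name == "mixture2p":
        p = softmax_probs(eta["thetat"][:, None])
        return p[:, 0], np.zeros_like(data.nt), p[:, 1]
    if model.name == "mixture3p":
        theta_nt = np.where(has_lures, eta["thetant"], NEG_INF)
        theta = np.stack([eta["thetat"], theta_nt], axis=1)
        p = softmax_probs(theta)
        with np.errstate(invalid="ignore"):
            p_slot = np.where(
                data.nt_mask, (p[:, 1] / np.maximum(n_lures, 1))[:, None], 0.0
            )
        return p[:, 0], p_slot, p[:, 2]
    _, _, _, _, a_target, a_slots = _imm_activations(eta, data, model.version)
    b = model.fixed_constants["b"]
    denom = b + a_target + a_slots.sum(axis=1)
    return a_target / denom, a_slots / denom[:, None], b / denom


# ---------------------------------------------------------------------------
# row-level conveniences (spec surface)


def _prepare_single(row, model: ModelSpec) -> PreparedData:
    import pandas as pd

    get = row.get if hasattr(row, "get") else row.__getitem__
    x = float(get(model.response_col))
    if model.uses_nontargets:
        set_size = int(get(model.set_size_col))
        nt_vals, mask, dist = [], [], []
        for j, col in enumerate(model.nt_cols):
            active = j < set_size - 1
            v = get(col) if active else np.nan
            if active and (v is None or (isinstance(v, float) and np.isnan(v))):
                raise ValueError(f"active slot {col!r} has a missing feature value")
            nt_vals.append(float(v) if active else 0.0)
            mask.append(active)
            if model.uses_distances:
                d = get(model.distance_cols[j]) if active else 0.0
                if active and (d is None or (isinstance(d, float) and np.isnan(d))):
                    raise ValueError(
                        f"active slot {model.distance_cols[j]!r} has a missing distance"
                    )
                dist.append(float(d) if active else 0.0)
    else:
        set_size = 1
        nt_vals, mask, dist = [0.0], [False], [0.0]
    return PreparedData(
        x=np.array([x]),
        set_size=np.array([set_size]),
        nt=np.array([nt_vals]),
        nt_mask=np.array([mask]),
        dist=np.array([dist]) if (model.uses_distances or not model.uses_nontargets) else None,
    )


def trial_loglik(row, params: dict, model: ModelSpec) -> float:
    """Log-density of one trial's response error given link-scale parameters.

    ``row`` is a mapping (or pandas Series) with the model's required
    columns; ``params`` maps each estimable parameter to its link-scale
    value for this trial.
    """
    data = _prepare_single(row, model)
    eta = {}
    for k in model.parameters:
        value = float(params[k])
        if not np.isfinite(value):
            raise ValueError(f"parameter {k!r} must be finite, got {value}")
        eta[k] = np.array([value])
    return float(loglik(eta, data, model)[0])


def dataset_loglik(data, params, model: ModelSpec) -> float:
    """Total log-likelihood: sum of per-trial log-densities (order-independent).

    ``data`` may be a :class:`PreparedData` or a pandas DataFrame (which is
    prepared via the model's column roles); ``params`` maps parameter names
    to scalars or (n,) arrays of link-scale values.
    """
    if not isinstance(data, PreparedData):
        from .data import prepare_arrays

        data = prepare_arrays(data, model)
    n = data.n_trials
    eta = {}
    for k in model.parameters:
        v = np.asarray(params[k], dtype=float)
        eta[k] = np.full(n, float(v)) if v.ndim == 0 else v
    return float(loglik(eta, data, model).sum())
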