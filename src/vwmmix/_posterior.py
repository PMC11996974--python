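"""Assembly of the hierarchical log posterior and its gradient.

Unconstrained parameter vector layout, per model parameter in spec order:

1. fixed-effect coefficients (identity, or ``lb + exp(u)`` when bounded);
2. per random block: log random-effect SDs (one set per stratum when the
   grouping is stratified), then standardized effects z (non-centered),
   then — for correlated blocks — unconstrained partial correlations
   mapped to a correlation Cholesky factor via tanh.

All likelihood-touching gradients are analytic; only the tiny (q x q)
Cholesky constrain map is differentiated numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import PreparedData, loglik_grad, loglik

__all__ = ["Posterior", "chol_corr_constrain"]


def chol_corr_constrain(y: np.ndarray, q: int) -> np.ndarray:
    """Map unconstrained y (q*(q-1)/2,) to a correlation Cholesky factor."""
    z = np.tanh(y)
    L = np.zeros((q, q))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, q):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[idx] * np.sqrt(rem)
            rem -= L[i, j] ** 2
            idx += 1
        L[i, i] = np.sqrt(max(rem, 0.0))
    return L


def _chol_corr_jacobian(y: np.ndarray, q: int, eps: float = 1e-6):
    """dL/dy by central differences; the map is data-independent and tiny."""
    n = y.size
    jac = np.zeros((n, q, q))
    for k in range(n):
        yp, ym = y.copy(), y.copy()
        yp[k] += eps
        ym[k] -= eps
        jac[k] = (chol_corr_constrain(yp, q) - chol_corr_constrain(ym, q)) / (2 * eps)
    return jac


@dataclass
class _FixedBlock:
    parameter: str
    sl: slice
    X: np.ndarray
    labels: list
    mu: np.ndarray
    sigma: np.ndarray
    lb: np.ndarray  # -inf when unbounded

    @property
    def bounded(self):
        return np.isfinite(self.lb)


@dataclass
class _RandomBlockLayout:
    parameter: str
    group: str
    Z: np.ndarray
    labels: list
    codes: np.ndarray
    levels: list
    correlated: bool
    n_strata: int
    stratum_of_level: np.ndarray  # (G,)
    strata: list
    by: str | None
    sd_sl: slice  # size n_strata * q, ordered [stratum, coef]
    z_sl: slice  # size G * q, ordered [level, coef]
    cor_sl: slice | None  # size n_strata * q*(q-1)/2
    sd_prior_sigma: np.ndarray  # (n_strata, q)

    @property
    def q(self):
        return self.Z.shape[1]

    @property
    def G(self):
        return len(self.levels)


class Posterior:
    """Callable log posterior density + gradient over the unconstrained vector."""

    def __init__(self, model, design, data: PreparedData, resolved_priors, prior_only=False):
        self.model = model
        self.design = design
        self.data = data
        self.prior_only = prior_only
        self.fixed_blocks = []
        self.random_blocks = []
        self.coef_names = []  # names of *stored* (constrained) quantities
        self._store_specs = []  # instructions to build stored vector

        pos = 0
        for pname in model.parameters:
            if pname not in design.params:
                raise ValueError(f"no formula provided for parameter {pname!r}")
        for pname in model.parameters:
            pdesign = design.params[pname]
            P = pdesign.fixed.X.shape[1]
            mu = np.zeros(P)
            sigma = np.ones(P)
            lb = np.full(P, -np.inf)
            for j, label in enumerate(pdesign.fixed.labels):
                rp, _ = resolved_priors[("b", pname, label, None)]
                mu[j], sigma[j], lb[j] = rp.mu, rp.sigma, rp.lb
            fb = _FixedBlock(pname, slice(pos, pos + P), pdesign.fixed.X, pdesign.fixed.labels, mu, sigma, lb)
            pos += P
            self.fixed_blocks.append(fb)
            for label in pdesign.fixed.labels:
                self.coef_names.append(f"{pname}_{label}")

        for pname in model.parameters:
            for rb in design.params[pname].random:
                q = rb.Z.shape[1]
                G = len(rb.levels)
                if rb.by is not None:
                    n_strata = len(rb.strata)
                    stratum_of_level = rb.stratum_of_level
                    strata = rb.strata
                else:
                    n_strata = 1
                    stratum_of_level = np.zeros(G, dtype=int)
                    strata = [None]
                sd_sigma = np.ones((n_strata, q))
                for si, stratum in enumerate(strata):
                    for ci, label in enumerate(rb.labels):
                        coef = label if stratum is None else f"{label}:{rb.by}{_fmt(stratum)}"
                        rp, _ = resolved_priors[("sd", pname, coef, rb.group)]
                        sd_sigma[si, ci] = rp.sigma
                sd_sl = slice(pos, pos + n_strata * q)
                pos += n_strata * q
                z_sl = slice(pos, pos + G * q)
                pos += G * q
                cor_sl = None
                if rb.correlated and q > 1:
                    m = q * (q - 1) // 2
                    cor_sl = slice(pos, pos + n_strata * m)
                    pos += n_strata * m
                layout = _RandomBlockLayout(
                    pname, rb.group, rb.Z, rb.labels, rb.codes, rb.levels, rb.correlated and q > 1,
                    n_strata, stratum_of_level, strata, rb.by, sd_sl, z_sl, cor_sl, sd_sigma,
                )
                self.random_blocks.append(layout)
                for si, stratum in enumerate(strata):
                    for label in rb.labels:
                        suffix = "" if stratum is None else f":{rb.by}{_fmt(stratum)}"
                        self.coef_names.append(f"sd_{rb.group}__{pname}_{label}{suffix}")
                if layout.correlated:
                    for si, stratum in enumerate(strata):
                        suffix = "" if stratum is None else f":{rb.by}{_fmt(stratum)}"
                        for c2 in range(q):
                            for c1 in range(c2):
                                self.coef_names.append(
                                    f"cor_{rb.group}__{pname}_{rb.labels[c1]}"
                                    f"__{pname}_{rb.labels[c2]}{suffix}"
                                )
                for level in rb.levels:
                    for label in rb.labels:
                        self.coef_names.append(f"r_{rb.group}__{pname}_{label}[{_fmt(level)}]")

        self.n_dim = pos

    # -- unpacking helpers ---------------------------------------------------

    def _unpack_random(self, vec, layout: _RandomBlockLayout):
        q, G = layout.q, layout.G
        v = vec[layout.sd_sl].reshape(layout.n_strata, q)
        sigma = np.exp(v)
        z = vec[layout.z_sl].reshape(G, q)
        Ls = None
        if layout.correlated:
            m = q * (q - 1) // 2
            ys = vec[layout.cor_sl].reshape(layout.n_strata, m)
            Ls = np.stack([chol_corr_constrain(ys[s], q) for s in range(layout.n_strata)])
        return v, sigma, z, Ls

    def _group_effects(self, layout, sigma, z, Ls):
        """U (G, q): actual random effects per group level."""
        strat = layout.stratum_of_level
        if layout.correlated:
            Lz = np.einsum("gij,gj->gi", Ls[strat], z)
            return sigma[strat] * Lz, Lz
        return sigma[strat] * z, z

    def eta(self, vec):
        """Per-trial link-scale parameter values implied by the vector."""
        out = {}
        for fb in self.fixed_blocks:
            beta = vec[fb.sl].copy()
            b = fb.bounded
            beta[b] = fb.lb[b] + np.exp(beta[b])
            out[fb.parameter] = fb.X @ beta
        for layout in self.random_blocks:
            _, sigma, z, Ls = self._unpack_random(vec, layout)
            U, _ = self._group_effects(layout, sigma, z, Ls)
            out[layout.parameter] = out[layout.parameter] + np.sum(
                layout.Z * U[layout.codes], axis=1
            )
        return out

    # -- log posterior + gradient -------------------------------------------

    def logp_grad(self, vec):
        grad = np.zeros(self.n_dim)
        eta = {}
        caches = []
        logp = 0.0

        betas = {}
        for fb in self.fixed_blocks:
            u = vec[fb.sl]
            beta = u.copy()
            b = fb.bounded
            beta[b] = fb.lb[b] + np.exp(u[b])
            betas[fb.parameter] = (u, beta)
            eta[fb.parameter] = fb.X @ beta
        for layout in self.random_blocks:
            v, sigma, z, Ls = self._unpack_random(vec, layout)
            U, Lz = self._group_effects(layout, sigma, z, Ls)
            caches.append((v, sigma, z, Ls, U, Lz))
            eta[layout.parameter] = eta[layout.parameter] + np.sum(
                layout.Z * U[layout.codes], axis=1
            )

        if self.prior_only:
            g_eta = {p: np.zeros(self.data.n_trials) for p in self.model.parameters}
        else:
            ll, g_eta = loglik_grad(eta, self.data, self.model)
            logp += float(ll.sum())

        for fb in self.fixed_blocks:
            u, beta = betas[fb.parameter]
            logp += float(np.sum(-0.5 * ((beta - fb.mu) / fb.sigma) ** 2))
            b = fb.bounded
            logp += float(np.sum(u[b]))  # log-Jacobian of lb + exp(u)
            gbeta = fb.X.T @ g_eta[fb.parameter] - (beta - fb.mu) / fb.sigma**2
            gu = gbeta.copy()
            gu[b] = gbeta[b] * np.exp(u[b]) + 1.0
            grad[fb.sl] = gu

        for layout, cache in zip(self.random_blocks, caches):
            v, sigma, z, Ls, U, Lz = cache
            q, G = layout.q, layout.G
            g = g_eta[layout.parameter]
            # Gmat[g, c] = sum over trials in group g of Z[i, c] * g[i]
            Gmat = np.zeros((G, q))
            for c in range(q):
                Gmat[:, c] = np.bincount(layout.codes, weights=layout.Z[:, c] * g, minlength=G)

            strat = layout.stratum_of_level
            # priors
            logp += float(np.sum(-0.5 * (sigma / layout.sd_prior_sigma) ** 2) + np.sum(v))
            logp += float(np.sum(-0.5 * z**2))

            if layout.correlated:
                M = Gmat * sigma[strat]  # dll/d(Lz)
                gz = np.einsum("gji,gj->gi", Ls[strat], M) - z
                gsigma_per_level = Gmat * Lz  # (G, q): dll/dsigma at each level
            else:
                gz = sigma[strat] * Gmat - z
                gsigma_per_level = Gmat * z
            grad[layout.z_sl] = gz.reshape(-1)

            gsigma = np.zeros((layout.n_strata, q))
            np.add.at(gsigma, strat, gsigma_per_level)
            gv = gsigma * sigma - (sigma / layout.sd_prior_sigma) ** 2 + 1.0
            grad[layout.sd_sl] = gv.reshape(-1)

            if layout.correlated:
                m = q * (q - 1) // 2
                ys = vec[layout.cor_sl].reshape(layout.n_strata, m)
                logp += float(np.sum(-0.5 * ys**2))
                gL = np.zeros((layout.n_strata, q, q))
                contrib = np.einsum("gi,gj->gij", M, z)
                np.add.at(gL, strat, contrib)
                gy = np.zeros((layout.n_strata, m))
                for s in range(layout.n_strata):
                    jac = _chol_corr_jacobian(ys[s], q)
                    gy[s] = np.einsum("kij,ij->k", jac, gL[s]) - ys[s]
                grad[layout.cor_sl] = gy.reshape(-1)

        return logp, grad

    def logp(self, vec):
        return self.logp_grad(vec)[0]

    # -- storage -------------------------------------------------------------

    def constrain_store(self, vec):
        """Constrained, named quantities stored per draw (aligned with coef_names)."""
        out = []
        for fb in self.fixed_blocks:
            beta = vec[fb.sl].copy()
            b = fb.bounded
            beta[b] = fb.lb[b] + np.exp(beta[b])
            out.append(beta)
        for layout in self.random_blocks:
            _, sigma, z, Ls = self._unpack_random(vec, layout)
            out.append(sigma.reshape(-1))
            if layout.correlated:
                cors = []
                for s in range(layout.n_strata):
                    C = Ls[s] @ Ls[s].T
                    q = layout.q
                    for c2 in range(q):
                        for c1 in range(c2):
                            cors.append(C[c1, c2])
                out.append(np.array(cors))
            U, _ = self._group_effects(layout, sigma, z, Ls)
            out.append(U.reshape(-1))
        return np.concatenate(out) if out else np.zeros(0)

    def init_vector(self, rng, jitter=0.5):
        """Initial unconstrained values near the prior center, jittered."""
        vec = np.zeros(self.n_dim)
        for fb in self.fixed_blocks:
            u = fb.mu.copy()
            b = fb.bounded
            u[b] = np.log(np.maximum(fb.mu[b] - fb.lb[b], 0.5))
            vec[fb.sl] = u + rng.uniform(-jitter, jitter, size=u.size)
        for layout in self.random_blocks:
            vec[layout.sd_sl] = np.log(0.3) + rng.uniform(-jitter, jitter, size=layout.n_strata * layout.q)
            vec[layout.z_sl] = rng.normal(0, 0.1, size=layout.G * layout.q)
            if layout.correlated:
                vec[layout.cor_sl] = rng.normal(0, 0.05, size=layout.cor_sl.stop - layout.cor_sl.start)
        return vec

    def check_finite(self, vec):
        """Raise with the offending trial index when the likelihood is non-finite."""
        if self.prior_only:
            return
        eta = self.eta(vec)
        ll = loglik(eta, self.data, self.model)
        bad = np.flatnonzero(~np.isfinite(ll))
        if bad.size:
            raise RuntimeError(
                f"non-finite likelihood at initialization for trial index {int(bad[0])} "
                f"(and {bad.size - 1} more)"
            )

    def sample_prior_draws(self, rng, n_draws):
        """IID draws from the priors of fixed effects and random-effect SDs."""
        names, cols = [], []
        for fb in self.fixed_blocks:
            for j, label in enumerate(fb.labels):
                from .priors import ResolvedPrior

                rp = ResolvedPrior(fb.mu[j], fb.sigma[j], fb.lb[j], np.inf)
                names.append(f"{fb.parameter}_{label}")
                cols.append(rp.sample(rng, n_draws))
        for layout in self.random_blocks:
            for si, stratum in enumerate(layout.strata):
                for ci, label in enumerate(layout.labels):
                    suffix = "" if stratum is None else f":{layout.by}{_fmt(stratum)}"
                    names.append(f"sd_{layout.group}__{layout.parameter}_{label}{suffix}")
                    cols.append(
                        np.abs(rng.normal(0.0, layout.sd_prior_sigma[si, ci], size=n_draws))
                    )
        return names, np.column_stack(cols) if cols else np.zeros((n_draws, 0))


def _fmt(value) -> str:
    s = str(value)
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s
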