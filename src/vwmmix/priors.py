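"""Prior specification and resolution.

Every estimable coefficient resolves to exactly one effective prior; the
most specific matching user prior wins (coefficient-level beats
parameter-class-level beats package defaults). Defaults are weakly
informative on the link scales:

- log-kappa "intercept-like" coefficients (cell-means columns, explicit
  intercepts): normal(2, 1); difference-style coefficients: normal(0, 1)
- mixing-weight and IMM log-activation intercept-like coefficients:
  normal(0, 2); difference-style: normal(0, 1)
- random-effect SDs: half-normal(0, 1)
- correlation parameters: normal(0, 1) on unconstrained partial correlations

Fixed constants (target/uniform locations 0, log kappa_uniform = -100,
softmax reference weight 0, IMM b = 1) appear in the prior table as
``constant`` rows and are never sampled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["Prior", "prior", "default_priors", "resolve_priors", "ResolvedPrior"]

_DIST_RE = re.compile(r"^\s*([a-zA-Z_]+)\s*\(([^)]*)\)\s*$")


@dataclass(frozen=True)
class Prior:
    """One prior statement, possibly targeting a whole class of coefficients."""

    distribution: str
    args: tuple
    class_: str = "b"  # "b" (fixed effect), "sd", "cor"
    parameter: str | None = None  # model parameter (kappa, thetat, ...)
    coef: str | None = None  # design column label
    group: str | None = None  # grouping variable for sd/cor
    lb: float | None = None
    ub: float | None = None

    def specificity(self) -> int:
        return sum(x is not None for x in (self.parameter, self.coef, self.group))

    def matches(self, class_, parameter, coef, group) -> bool:
        if self.class_ != class_:
            return False
        for mine, theirs in ((self.parameter, parameter), (self.coef, coef), (self.group, group)):
            if mine is not None and mine != theirs:
                return False
        return True

    def describe(self) -> str:
        args = ", ".join(f"{a:g}" for a in self.args)
        return f"{self.distribution}({args})"


def prior(spec: str, class_="b", parameter=None, coef=None, group=None, lb=None, ub=None) -> Prior:
    """Parse a prior statement such as ``prior("normal(0, 1)", parameter="kappa", lb=0)``."""
    m = _DIST_RE.match(spec)
    if not m:
        raise ValueError(f"malformed prior specification {spec!r}")
    name = m.group(1).lower()
    if name not in ("normal",):
        raise ValueError(f"unsupported prior distribution {name!r} (supported: normal)")
    args = tuple(float(a) for a in m.group(2).split(",")) if m.group(2).strip() else ()
    if name == "normal" and len(args) != 2:
        raise ValueError("normal prior needs (mean, sd)")
    if name == "normal" and args[1] <= 0:
        raise ValueError("prior sd must be positive")
    return Prior(name, args, class_=class_, parameter=parameter, coef=coef, group=group, lb=lb, ub=ub)


@dataclass(frozen=True)
class ResolvedPrior:
    mu: float
    sigma: float
    lb: float  # -inf when unbounded
    ub: float

    def logpdf(self, value: float) -> float:
        # truncation normalizer omitted: constant wrt the sampled value
        return -0.5 * ((value - self.mu) / self.sigma) ** 2

    def grad(self, value: float) -> float:
        return -(value - self.mu) / self.sigma**2

    def sample(self, rng, size) -> np.ndarray:
        if np.isneginf(self.lb) and np.isposinf(self.ub):
            return rng.normal(self.mu, self.sigma, size=size)
        a = (self.lb - self.mu) / self.sigma
        b = (self.ub - self.mu) / self.sigma
        u = rng.uniform(size=size)
        return stats.truncnorm.ppf(u, a, b, loc=self.mu, scale=self.sigma)


def _intercept_like(label: str, scheme_names: dict, factor_levels: dict) -> bool:
    """Cell-means columns and explicit intercepts anchor the parameter's scale."""
    if label == "Intercept":
        return True
    if ":" in label:
        return False
    for factor, levels in factor_levels.items():
        if any(label == f"{factor}{_lvl}" for _lvl in map(_sanitize, levels)):
            # one-hot cell-means column <=> every level has its own column;
            # approximated here by checking the first level also has a column
            return scheme_names.get(factor) == "cell_means"
    return False


def _sanitize(level) -> str:
    s = str(level)
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s


def _default_fixed(model, parameter: str, label: str, intercept_like: bool) -> Prior:
    if parameter == "kappa":
        args = (2.0, 1.0) if intercept_like else (0.0, 1.0)
    else:  # mixing weights and IMM log-activations
        args = (0.0, 2.0) if intercept_like else (0.0, 1.0)
    return Prior("normal", args, class_="b", parameter=parameter, coef=label)


def _columns_are_cell_means(design, parameter, factor_levels) -> dict:
    """factor -> True when this parameter's design one-hot codes the factor."""
    labels = set(design.params[parameter].fixed.labels)
    out = {}
    for factor, levels in factor_levels.items():
        out[factor] = all(f"{factor}{_sanitize(lv)}" in labels for lv in levels)
    return {f: ("cell_means" if v else "other") for f, v in out.items()}


def default_priors(model, formulas, table, contrasts=None, factors=None, user_priors=()) -> pd.DataFrame:
    """The full effective prior table for a model/formula/data combination.

    Includes the fixed constants, a row per fixed-effect coefficient, per
    random-effect SD (per stratum when stratified), and per correlation
    block. User priors (``user_priors``) replace the matching default rows.
    """
    from .formula import build_design

    design = build_design(formulas, table, contrasts=contrasts, factors=factors, model=model)
    rows = []
    for name, value in model.fixed_constants.items():
        rows.append(
            {
                "class": "constant",
                "parameter": name,
                "coef": "",
                "group": "",
                "prior": f"constant({value:g})",
                "lb": "",
                "ub": "",
                "source": "fixed",
            }
        )
    resolved = resolve_priors(model, design, user_priors)
    for (class_, parameter, coef, group), (rp, src) in resolved.items():
        rows.append(
            {
                "class": class_,
                "parameter": parameter,
                "coef": coef or "",
                "group": group or "",
                "prior": f"normal({rp.mu:g}, {rp.sigma:g})",
                "lb": "" if np.isneginf(rp.lb) else f"{rp.lb:g}",
                "ub": "" if np.isposinf(rp.ub) else f"{rp.ub:g}",
                "source": src,
            }
        )
    return pd.DataFrame(rows)


def resolve_priors(model, design, user_priors=()):
    """Map every sampled coefficient to its effective prior.

    Returns a dict keyed by ``(class, parameter, coef, group)`` with values
    ``(ResolvedPrior, source)``.
    """
    user_priors = list(user_priors or ())
    for up in user_priors:
        if not isinstance(up, Prior):
            raise TypeError("user priors must be Prior objects (see vwmmix.priors.prior)")

    def effective(class_, parameter, coef, group, fallback: Prior):
        matching = [p for p in user_priors if p.matches(class_, parameter, coef, group)]
        if matching:
            best = max(matching, key=Prior.specificity)
            src = "user"
        else:
            best, src = fallback, "default"
        lb = best.lb if best.lb is not None else -np.inf
        ub = best.ub if best.ub is not None else np.inf
        return ResolvedPrior(best.args[0], best.args[1], lb, ub), src

    out = {}
    for pname, pdesign in design.params.items():
        schemes = _columns_are_cell_means(design, pname, design.factor_levels)
        for label in pdesign.fixed.labels:
            il = _intercept_like(label, schemes, design.factor_levels)
            out[("b", pname, label, None)] = effective(
                "b", pname, label, None, _default_fixed(model, pname, label, il)
            )
        for rb in pdesign.random:
            strata = rb.strata if rb.by is not None else [None]
            for stratum in strata:
                for label in rb.labels:
                    coef = label if stratum is None else f"{label}:{rb.by}{_sanitize(stratum)}"
                    fallback = Prior(
                        "normal", (0.0, 1.0), class_="sd", parameter=pname, coef=label,
                        group=rb.group, lb=0.0,
                    )
                    rp, src = effective("sd", pname, coef, rb.group, fallback)
                    if rp.lb < 0:
                        rp = ResolvedPrior(rp.mu, rp.sigma, 0.0, rp.ub)
                    out[("sd", pname, coef, rb.group)] = (rp, src)
            if rb.correlated and len(rb.labels) > 1:
                fallback = Prior("normal", (0.0, 1.0), class_="cor", parameter=pname, group=rb.group)
                out[("cor", pname, None, rb.group)] = effective(
                    "cor", pname, None, rb.group, fallback
                )
    return out
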