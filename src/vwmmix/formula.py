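"""Per-parameter model formulas and design-matrix construction.

The formula dialect mirrors common mixed-model syntax, restricted to what
the measurement models need::

    "kappa ~ 0 + setsize + (0 + setsize || subID)"
    "thetat ~ 1 + cond + (1 + cond | subID)"
    "kappa ~ 0 + ageGroup + RI:ageGroup + (RI | gr(id, by = ageGroup))"

- ``0 +`` suppresses the intercept (cell-means coding of the first factor);
  ``1 +`` states it explicitly. The two markers are mutually exclusive.
- ``(terms | group)`` adds correlated random effects over ``group``;
  ``(terms || group)`` leaves the random-effect correlations unestimated.
- ``gr(g, by = f)`` stratifies the grouping: separate variance components
  per level of ``f``.
- ``a:b`` is an interaction, ``a*b`` expands to ``a + b + a:b``.

Factor terms are expanded with a selectable contrast scheme per factor
(treatment coding by default; ``cell_means`` and ``successive_difference``
are also available). Coding follows the standard rule: a factor inside a
term receives reduced (contrast) coding only when the term's margin with
that factor removed is itself in the model, otherwise full one-hot coding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParameterFormula",
    "RandomPart",
    "ContrastScheme",
    "FormulaError",
    "parse",
    "parse_one",
    "cell_means_contrast",
    "treatment_contrast",
    "successive_diff_contrast",
    "get_contrast",
    "build_design",
    "DesignMatrices",
    "ParamDesign",
    "FixedDesign",
    "RandomBlock",
]


class FormulaError(ValueError):
    pass


@dataclass
class RandomPart:
    intercept: bool
    terms: list
    group: str
    correlated: bool
    by: str | None = None


@dataclass
class ParameterFormula:
    parameter: str
    intercept: bool
    terms: list  # list of tuples of variable names (len > 1 => interaction)
    random: list  # list of RandomPart


# ---------------------------------------------------------------------------
# parsing


def _split_top_level(expr: str, sep: str = "+"):
    parts, depth, buf = [], 0, []
    for ch in expr:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == sep and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return [p.strip() for p in parts if p.strip()]


def _parse_terms(expr: str, where: str):
    """Parse a fixed- or random-part term expression into (intercept, terms)."""
    intercept = True
    saw_zero = saw_one = False
    terms = []
    for tok in _split_top_level(expr):
        if tok == "0":
            if saw_zero:
                raise FormulaError(f"duplicate '0 +' intercept suppression in {where!r}")
            saw_zero = True
            intercept = False
        elif tok == "1":
            saw_one = True
            intercept = True
        elif "*" in tok:
            factors = [t.strip() for t in tok.split("*")]
            if any(not f for f in factors):
                raise FormulaError(f"malformed term {tok!r} in {where!r}")
            # a*b -> a + b + a:b (full factorial expansion)
            from itertools import combinations

            for r in range(1, len(factors) + 1):
                for combo in combinations(factors, r):
                    if combo not in terms:
                        terms.append(tuple(combo))
        else:
            parts = tuple(t.strip() for t in tok.split(":"))
            if any(not re.fullmatch(r"[A-Za-z_.][A-Za-z0-9_.]*", p) for p in parts):
                raise FormulaError(f"malformed term {tok!r} in {where!r}")
            if parts in terms:
                raise FormulaError(f"duplicate term {tok!r} in {where!r}")
            terms.append(parts)
    if saw_zero and saw_one:
        raise FormulaError(f"'0 +' and '1 +' clash in {where!r}")
    return intercept, terms


_GR_RE = re.compile(r"^gr\(\s*([A-Za-z_.][A-Za-z0-9_.]*)\s*(?:,\s*by\s*=\s*([A-Za-z_.][A-Za-z0-9_.]*)\s*)?\)$")


def _parse_group(spec: str, where: str):
    spec = spec.strip()
    m = _GR_RE.match(spec)
    if m:
        return m.group(1), m.group(2)
    if re.fullmatch(r"[A-Za-z_.][A-Za-z0-9_.]*", spec):
        return spec, None
    raise FormulaError(f"malformed grouping specification {spec!r} in {where!r}")


def parse_one(formula: str) -> ParameterFormula:
    """Parse a single ``"param ~ rhs"`` string."""
    if formula.count("~") != 1:
        raise FormulaError(f"formula must contain exactly one '~': {formula!r}")
    lhs, rhs = (s.strip() for s in formula.split("~"))
    if not re.fullmatch(r"[A-Za-z_.][A-Za-z0-9_.]*", lhs):
        raise FormulaError(f"malformed parameter name {lhs!r}")

    random_parts = []

    # pull out top-level parenthesized random parts
    def extract(match):
        inner = match.group(1)
        if "||" in inner:
            terms_expr, group_expr = inner.split("||")
            correlated = False
        elif "|" in inner:
            terms_expr, group_expr = inner.split("|", 1)
            correlated = True
        else:
            raise FormulaError(f"parenthesized group without '|' in {formula!r}")
        intercept, terms = _parse_terms(terms_expr, formula)
        group, by = _parse_group(group_expr, formula)
        random_parts.append(RandomPart(intercept, terms, group, correlated, by))
        return ""  # removed from fixed part

    fixed_expr = re.sub(r"\(((?:[^()]|\([^()]*\))*)\)", extract, rhs)
    fixed_expr = re.sub(r"\+\s*(\+|$)", r"\1", fixed_expr).strip().rstrip("+").strip()
    if not fixed_expr and not random_parts:
        raise FormulaError(f"empty right-hand side in {formula!r}")
    intercept, terms = _parse_terms(fixed_expr or "1", formula)
    return ParameterFormula(lhs, intercept, terms, random_parts)


def parse(formulas, model=None):
    """Parse one string or a sequence of strings into ParameterFormula objects.

    If ``model`` (a ModelSpec) is given, each left-hand side must be one of
    its estimable parameters.
    """
    if isinstance(formulas, str):
        formulas = [formulas]
    out = []
    seen = set()
    for f in formulas:
        pf = f if isinstance(f, ParameterFormula) else parse_one(f)
        if pf.parameter in seen:
            raise FormulaError(f"parameter {pf.parameter!r} appears in more than one formula")
        seen.add(pf.parameter)
        if model is not None and pf.parameter not in model.parameters:
            raise FormulaError(
                f"{pf.parameter!r} is not an estimable parameter of model {model.name!r} "
                f"(expected one of {tuple(model.parameters)})"
            )
        out.append(pf)
    return out


# ---------------------------------------------------------------------------
# contrasts


@dataclass
class ContrastScheme:
    """A k-level factor coding: square matrix mapping coefficients to cell means."""

    name: str
    k: int
    matrix: np.ndarray  # (k, k); column 0 is the intercept except for cell_means

    @property
    def has_intercept_column(self) -> bool:
        return self.name != "cell_means"

    def reduced(self) -> np.ndarray:
        """Columns without the intercept (used when a margin absorbs it)."""
        if self.has_intercept_column:
            return self.matrix[:, 1:]
        return self.matrix

    def coefficients_for_means(self, means) -> np.ndarray:
        """Solve for the coefficient vector reproducing the given cell means."""
        means = np.asarray(means, dtype=float)
        if means.shape != (self.k,):
            raise ValueError(f"expected {self.k} cell means")
        return np.linalg.solve(self.matrix, means)


def cell_means_contrast(k: int) -> ContrastScheme:
    if k < 1:
        raise ValueError("k must be >= 1")
    return ContrastScheme("cell_means", k, np.eye(k))


def treatment_contrast(k: int) -> ContrastScheme:
    """Dummy coding: intercept = first level, coefficients = level - first."""
    if k < 1:
        raise ValueError("k must be >= 1")
    m = np.zeros((k, k))
    m[:, 0] = 1.0
    for j in range(1, k):
        m[j, j] = 1.0
    return ContrastScheme("treatment", k, m)


def successive_diff_contrast(k: int) -> ContrastScheme:
    """Intercept = first level; coefficient j = mean(level j+1) - mean(level j).

    Design rows carry 1s in the first (level - 1) difference columns, so
    nonnegative coefficients imply non-decreasing cell means.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    m = np.zeros((k, k))
    m[:, 0] = 1.0
    for j in range(1, k):
        m[j:, j] = 1.0
    return ContrastScheme("successive_difference", k, m)


_CONTRASTS = {
    "cell_means": cell_means_contrast,
    "treatment": treatment_contrast,
    "successive_difference": successive_diff_contrast,
}


def get_contrast(name: str, k: int) -> ContrastScheme:
    if name not in _CONTRASTS:
        raise ValueError(f"unknown contrast scheme {name!r}; expected one of {tuple(_CONTRASTS)}")
    return _CONTRASTS[name](k)


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class FixedDesign:
    X: np.ndarray  # (n_trials, p)
    labels: list


@dataclass
class RandomBlock:
    group: str
    Z: np.ndarray  # (n_trials, q) term design
    labels: list  # q coefficient labels
    codes: np.ndarray  # (n_trials,) group index
    levels: list  # group level values, index order
    correlated: bool
    by: str | None = None
    stratum_of_level: np.ndarray | None = None  # (n_levels,) stratum index
    strata: list | None = None  # stratum level values


@dataclass
class ParamDesign:
    parameter: str
    fixed: FixedDesign
    random: list  # list of RandomBlock


@dataclass
class DesignMatrices:
    params: dict  # parameter -> ParamDesign
    n_trials: int
    factor_levels: dict  # factor -> levels used

    def __getitem__(self, parameter):
        return self.params[parameter]


def _is_factor(series: pd.Series, name: str, factors) -> bool:
    if factors and name in factors:
        return True
    return (
        isinstance(series.dtype, pd.CategoricalDtype)
        or series.dtype == object
        or series.dtype == bool
    )


def _factor_levels(series: pd.Series):
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [lv for lv in series.cat.categories if (series == lv).any()]
    return sorted(pd.unique(series.dropna()))


def _sanitize(level) -> str:
    s = str(level)
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s


def _encode_factor(series, levels, scheme: ContrastScheme, reduced: bool, name: str):
    """Return (matrix, labels) for one factor appearance."""
    level_idx = {lv: i for i, lv in enumerate(levels)}
    idx = series.map(level_idx)
    if idx.isna().any():
        raise FormulaError(f"column {name!r} contains missing values")
    idx = idx.to_numpy(dtype=int)
    if reduced:
        code = scheme.reduced()
        if scheme.name == "cell_means":
            labels = [f"{name}{_sanitize(lv)}" for lv in levels]
        else:
            labels = [f"{name}{_sanitize(lv)}" for lv in levels[1:]]
    else:
        code = np.eye(len(levels))
        labels = [f"{name}{_sanitize(lv)}" for lv in levels]
    return code[idx], labels


def _build_matrix(intercept, terms, table, contrasts, factors, factor_levels, where):
    n = len(table)
    cols, labels = [], []
    if intercept:
        cols.append(np.ones((n, 1)))
        labels.append("Intercept")

    # terms present in the model, for the margin rule (intercept counts as ())
    present = {()} if intercept else set()
    present.update(tuple(sorted(t)) for t in terms)

    for term in terms:
        pieces = []  # (matrix, labels) per component
        for var in term:
            if var not in table.columns:
                raise FormulaError(f"unknown column {var!r} in {where!r}")
            series = table[var]
            if _is_factor(series, var, factors):
                levels = factor_levels.setdefault(var, _factor_levels(series))
                margin = tuple(sorted(v for v in term if v != var))
                use_reduced = margin in present
                scheme_name = (contrasts or {}).get(var, "treatment")
                scheme = (
                    scheme_name
                    if isinstance(scheme_name, ContrastScheme)
                    else get_contrast(scheme_name, len(levels))
                )
                if use_reduced and scheme.name == "cell_means":
                    # cell-means coding never carries an implicit intercept
                    use_reduced = False
                mat, labs = _encode_factor(series, levels, scheme, use_reduced, var)
                pieces.append((mat, labs))
            else:
                vals = series.to_numpy(dtype=float)[:, None]
                if not np.all(np.isfinite(vals)):
                    raise FormulaError(f"covariate {var!r} contains non-finite values")
                pieces.append((vals, [var]))
        mat, labs = pieces[0]
        for m2, l2 in pieces[1:]:
            mat = np.einsum("np,nq->npq", mat, m2).reshape(n, -1)
            labs = [f"{a}:{b}" for a in labs for b in l2]
        cols.append(mat)
        labels.extend(labs)

    if not cols:
        return np.zeros((n, 0)), []
    X = np.hstack(cols)
    return X, labels


def _aliased_columns(X, labels, tol=1e-8):
    """Greedy rank scan: columns that do not increase the rank are aliased."""
    aliased = []
    basis = np.zeros((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.hstack([basis, X[:, [j]]])
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(X).max())) > basis.shape[1]:
            basis = cand
        else:
            aliased.append(labels[j])
    return aliased


def build_design(formulas, table: pd.DataFrame, contrasts=None, factors=None, model=None) -> DesignMatrices:
    """Build fixed and random design matrices for every parameter formula.

    Parameters
    ----------
    formulas : str, sequence of str, or parsed ParameterFormula objects
    table : trial data (one row per retrieval)
    contrasts : optional dict mapping factor name -> contrast scheme name
    factors : optional collection of numeric column names to treat as factors
    model : optional ModelSpec used to validate formula left-hand sides

    Raises
    ------
    FormulaError
        On unknown columns or a rank-deficient fixed design (the error names
        the aliased columns).
    """
    pfs = parse(formulas, model=model)
    factors = set(factors or ())
    factor_levels = {}
    params = {}
    for pf in pfs:
        X, labels = _build_matrix(
            pf.intercept, pf.terms, table, contrasts, factors, factor_levels, pf.parameter
        )
        if X.shape[1] == 0:
            raise FormulaError(f"parameter {pf.parameter!r} has no fixed-effect columns")
        aliased = _aliased_columns(X, labels)
        if aliased:
            raise FormulaError(
                f"rank-deficient fixed design for {pf.parameter!r}: aliased columns {aliased}"
            )
        blocks = []
        for rp in pf.random:
            if rp.group not in table.columns:
                raise FormulaError(f"unknown grouping column {rp.group!r}")
            Z, zlabels = _build_matrix(
                rp.intercept, rp.terms, table, contrasts, factors, factor_levels, pf.parameter
            )
            if Z.shape[1] == 0:
                raise FormulaError(f"empty random-effect part for {pf.parameter!r}")
            levels = _factor_levels(table[rp.group])
            codes = table[rp.group].map({lv: i for i, lv in enumerate(levels)}).to_numpy(dtype=int)
            stratum_of_level = None
            strata = None
            if rp.by is not None:
                if rp.by not in table.columns:
                    raise FormulaError(f"unknown stratification column {rp.by!r}")
                strata = _factor_levels(table[rp.by])
                sidx = table[rp.by].map({lv: i for i, lv in enumerate(strata)}).to_numpy(dtype=int)
                stratum_of_level = np.full(len(levels), -1, dtype=int)
                for code, s in zip(codes, sidx):
                    if stratum_of_level[code] == -1:
                        stratum_of_level[code] = s
                    elif stratum_of_level[code] != s:
                        raise FormulaError(
                            f"group {levels[code]!r} spans multiple levels of {rp.by!r}"
                        )
            blocks.append(
                RandomBlock(
                    group=rp.group,
                    Z=Z,
                    labels=zlabels,
                    codes=codes,
                    levels=levels,
                    correlated=rp.correlated,
                    by=rp.by,
                    stratum_of_level=stratum_of_level,
                    strata=strata,
                )
            )
        params[pf.parameter] = ParamDesign(pf.parameter, FixedDesign(X, labels), blocks)
    return DesignMatrices(params=params, n_trials=len(table), factor_levels=factor_levels)
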