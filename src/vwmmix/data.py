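"""Trial-data schema, validation, recoding, I/O, and a generative simulator.

The canonical layout is long format: one row per retrieval, with a subject
identifier, optional condition columns, the set size, the response error in
radians (wrapped to (-pi, pi]), one column per non-target slot holding the
lure's feature value *relative to the target*, and (for the distance-aware
IMM versions) one context-distance column per slot. Slots beyond
``set_size - 1`` are inactive and coded as missing; zeros in inactive slots
are accepted on load and normalized to missing, since a zero is a legal
relative location for an *active* slot.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import circular
from .likelihood import PreparedData, component_probs
from .models import ModelSpec

__all__ = [
    "SchemaError",
    "ValidationReport",
    "GenerativeConfig",
    "SimulationResult",
    "recode_relative",
    "validate_table",
    "normalize_table",
    "prepare_arrays",
    "simulate_trials",
    "read_table",
    "write_table",
    "find_slot_columns",
    "standard_nt_columns",
]

_PARAM_KEYS = {"kappa", "p_mem", "p_nt", "c", "a", "s"}


class SchemaError(ValueError):
    pass


def recode_relative(response, target, nt_absolute=()):
    """Recode absolute feature values relative to the target.

    Returns ``(response_error, nt_relative)`` where
    ``response_error = wrap(response - target)`` and
    ``nt_relative[j] = wrap(nt_absolute[j] - target)``.
    """
    response_error = circular.wrap_angle(np.subtract(response, target))
    nt_relative = [circular.wrap_angle(np.subtract(v, target)) for v in nt_absolute]
    return response_error, nt_relative


def standard_nt_columns(max_set_size: int = 6, prefix: str = "col_lure"):
    """Slot column names for a given maximum set size (M = max_set_size - 1)."""
    return tuple(f"{prefix}{j + 1}" for j in range(max_set_size - 1))


def find_slot_columns(table: pd.DataFrame, pattern: str):
    """Columns matching a regex, sorted by their embedded slot number.

    Supports the "provide the general pattern that several variables follow"
    style of slot declaration, e.g. ``find_slot_columns(df, r"col_lure\\d+")``.
    """
    rx = re.compile(pattern)
    hits = [c for c in table.columns if rx.fullmatch(c)]

    def key(c):
        m = re.search(r"(\d+)$", c)
        return int(m.group(1)) if m else 0

    return tuple(sorted(hits, key=key))


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _angle_columns(model: ModelSpec):
    return (model.response_col,) + model.nt_cols


def validate_table(table: pd.DataFrame, model: ModelSpec, strict: bool = True) -> ValidationReport:
    """Check a trial table against a model's schema.

    Missing required columns are a hard error (:class:`SchemaError`) when
    ``strict``. The report additionally flags slot/set-size mismatches and a
    likely degrees-coded table (> 1% of angle values with \\|v\\| > 2*pi).
    """
    report = ValidationReport()
    missing = [c for c in model.required_columns() if c not in table.columns]
    if missing:
        msg = f"model {model.name!r} requires missing columns: {missing}"
        if strict:
            raise SchemaError(msg)
        report.errors.append(msg)
        return report

    for col in _angle_columns(model):
        vals = pd.to_numeric(table[col], errors="coerce").to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and np.mean(np.abs(finite) > 2 * np.pi) > 0.01:
            report.warnings.append(
                f"column {col!r} looks degrees-coded: "
                f"{np.mean(np.abs(finite) > 2 * np.pi):.0%} of values exceed 2*pi in magnitude"
            )

    if model.uses_nontargets:
        set_size = table[model.set_size_col].to_numpy()
        if np.any(set_size < 1):
            report.errors.append("set_size values below 1")
        if np.any(set_size > model.max_slots + 1):
            report.errors.append(
                f"set_size exceeds {model.max_slots + 1} (only {model.max_slots} slot columns)"
            )
        nt = table[list(model.nt_cols)].to_numpy(dtype=float)
        for j in range(nt.shape[1]):
            active = set_size - 1 > j
            n_bad = int(np.sum(active & ~np.isfinite(nt[:, j])))
            if n_bad:
                report.errors.append(
                    f"{n_bad} rows have an active slot {model.nt_cols[j]!r} with a missing value"
                )
    return report


def normalize_table(table: pd.DataFrame, model: ModelSpec) -> pd.DataFrame:
    """Wrap angle columns and normalize inactive slots (zero or any value) to NaN."""
    out = table.copy()
    resp = out[model.response_col].to_numpy(dtype=float)
    out[model.response_col] = circular.wrap_angle(resp)
    if model.uses_nontargets:
        set_size = out[model.set_size_col].to_numpy(dtype=int)
        for j, col in enumerate(model.nt_cols):
            vals = out[col].to_numpy(dtype=float)
            active = set_size - 1 > j
            vals = np.where(active, vals, np.nan)
            with np.errstate(invalid="ignore"):
                vals = np.where(np.isfinite(vals), np.mod(vals, 2 * np.pi), vals)
                vals = np.where(vals > np.pi, vals - 2 * np.pi, vals)
                vals = np.where(vals == -np.pi, np.pi, vals)
            out[col] = vals
        for j, col in enumerate(model.distance_cols):
            vals = out[col].to_numpy(dtype=float)
            active = set_size - 1 > j
            out[col] = np.where(active, vals, np.nan)
    return out


def prepare_arrays(table: pd.DataFrame, model: ModelSpec) -> PreparedData:
    """Extract the slot-padded arrays the likelihood operates on.

    Raises on active slots with missing feature values.
    """
    report = validate_table(table, model)
    if not report.ok:
        raise SchemaError("; ".join(report.errors))
    table = normalize_table(table, model)
    n = len(table)
    x = table[model.response_col].to_numpy(dtype=float)
    if model.uses_nontargets:
        set_size = table[model.set_size_col].to_numpy(dtype=int)
        nt = table[list(model.nt_cols)].to_numpy(dtype=float)
        mask = (np.arange(nt.shape[1])[None, :] < (set_size - 1)[:, None])
        nt = np.where(mask, nt, 0.0)
        if model.uses_distances:
            dist = table[list(model.distance_cols)].to_numpy(dtype=float)
            if np.any(mask & ~np.isfinite(dist)):
                raise SchemaError("active slots with missing context distances")
            if np.any(mask & (dist < 0)):
                raise SchemaError("context distances must be nonnegative")
            dist = np.where(mask, dist, 0.0)
        else:
            dist = None
    else:
        set_size = np.ones(n, dtype=int)
        nt = np.zeros((n, 1))
        mask = np.zeros((n, 1), dtype=bool)
        dist = None
    return PreparedData(x=x, set_size=set_size, nt=nt, nt_mask=mask, dist=dist)


def read_table(path, model: ModelSpec | None = None) -> pd.DataFrame:
    """Read a long-format CSV (missing values as empty fields); optionally normalize."""
    table = pd.read_csv(path)
    if model is not None:
        validate_table(table, model)
        table = normalize_table(table, model)
    return table


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# generative simulator


@dataclass
class GenerativeConfig:
    """Design and true parameter values for simulated trial data.

    ``cells`` is a list of dicts, one per condition cell. Each cell carries
    ``set_size`` plus the model's native-scale parameter values: ``kappa``
    and ``p_mem`` (2p), additionally ``p_nt`` (3p), or ``c``/``a``/``s``
    (IMM, as applicable). Any other key is written to the table as a
    condition column. ``random_sd`` gives link-scale SDs of centered normal
    subject offsets per model parameter.
    """

    model: ModelSpec
    n_subjects: int
    cells: list
    n_trials: int  # per subject per cell
    random_sd: dict = field(default_factory=dict)
    seed: int | None = None
    subject_col: str = "subID"
    min_separation: float = 0.0  # optional minimum angular spacing of items


@dataclass
class SimulationResult:
    table: pd.DataFrame
    truth: pd.DataFrame  # per cell: link- and native-scale parameter values
    subject_effects: pd.DataFrame  # link-scale offsets per subject x cell x parameter
    labels: np.ndarray  # latent generating component per trial


def _cell_link_values(cell: dict, model: ModelSpec) -> dict:
    """Native-scale cell values -> link-scale values for each model parameter."""
    kappa = float(cell["kappa"])
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    link = {"kappa": np.log(kappa)}
    if model.name == "mixture2p":
        p_mem = float(cell["p_mem"])
        if not 0 < p_mem <= 1:
            raise ValueError("p_mem must lie in (0, 1]")
        p_guess = 1.0 - p_mem
        link["thetat"] = np.log(p_mem / max(p_guess, 1e-12))
    elif model.name == "mixture3p":
        p_mem, p_nt = float(cell["p_mem"]), float(cell["p_nt"])
        p_guess = 1.0 - p_mem - p_nt
        if min(p_mem, p_nt) < 0 or p_guess < 0:
            raise ValueError("(p_mem, p_nt, p_guess) must lie on the simplex")
        link["thetat"] = np.log(max(p_mem, 1e-12) / max(p_guess, 1e-12))
        link["thetant"] = np.log(max(p_nt, 1e-12) / max(p_guess, 1e-12))
    else:
        for name in model.parameters:
            if name == "kappa":
                continue
            val = float(cell[name])
            if val <= 0:
                raise ValueError(f"IMM activation {name!r} must be positive in simulation")
            link[name] = np.log(val)
    return link


def _place_items(rng, set_size: int, max_slots: int, min_separation: float):
    """Absolute target and lure locations, uniform on the circle."""
    for _ in range(200):
        locs = circular.wrap_angle(rng.uniform(-np.pi, np.pi, size=set_size))
        if min_separation <= 0 or set_size == 1:
            return locs
        d = np.abs(circular.wrap_angle(locs[:, None] - locs[None, :]))
        if np.min(d[np.triu_indices(set_size, 1)]) >= min_separation:
            return locs
    raise RuntimeError("could not place items with the requested minimum separation")


def simulate_trials(config: GenerativeConfig) -> SimulationResult:
    """Generate a trial table with the statistical structure the models assume.

    Per subject, link-scale random offsets are drawn from centered normals
    with the configured SDs (independently per cell, matching a
    by-condition random-slope structure). Per trial, non-targets are placed
    uniformly on the circle, the generating component is drawn from the
    model-implied probabilities, and the response error comes from the
    matching von Mises (uniform for guessing). Seed-deterministic.
    """
    model = config.model
    rng = np.random.default_rng(config.seed)
    max_slots = model.max_slots if model.uses_nontargets else 0
    set_size_col = model.set_size_col or "setsize"

    for cell in config.cells:
        if "set_size" not in cell:
            raise ValueError("every cell needs a 'set_size' entry")
        if int(cell["set_size"]) < 1:
            raise ValueError("set_size must be >= 1")
        if model.uses_nontargets and int(cell["set_size"]) > max_slots + 1:
            raise ValueError(
                f"cell set_size {cell['set_size']} exceeds the model's "
                f"{max_slots} slot columns + 1"
            )

    truth_rows, effect_rows = [], []
    cell_links = []
    for ci, cell in enumerate(config.cells):
        link = _cell_link_values(cell, model)
        cell_links.append(link)
        for pname, lval in link.items():
            truth_rows.append(
                {
                    "cell": ci,
                    "set_size": int(cell["set_size"]),
                    "parameter": pname,
                    "link_value": lval,
                    "native_value": float(np.exp(lval))
                    if model.parameters[pname] == "log"
                    else lval,
                    **{
                        k: v
                        for k, v in cell.items()
                        if k not in _PARAM_KEYS and k != "set_size"
                    },
                }
            )

    # subject offsets: one centered-normal draw per subject x cell x parameter
    offsets = {}
    for ci in range(len(config.cells)):
        for pname in model.parameters:
            sd = float(config.random_sd.get(pname, 0.0))
            draw = rng.normal(0.0, sd, size=config.n_subjects) if sd > 0 else np.zeros(config.n_subjects)
            offsets[(ci, pname)] = draw
            for s in range(config.n_subjects):
                effect_rows.append(
                    {"subject": s + 1, "cell": ci, "parameter": pname, "offset": draw[s]}
                )

    rows, labels = [], []
    trial_counter = {}
    for s in range(config.n_subjects):
        for ci, cell in enumerate(config.cells):
            set_size = int(cell["set_size"])
            n_lures = set_size - 1
            eta = {
                pname: np.full(config.n_trials, cell_links[ci][pname] + offsets[(ci, pname)][s])
                for pname in model.parameters
            }
            # item geometry in absolute coordinates, then relative recoding
            nt_rel = np.zeros((config.n_trials, max(max_slots, 1)))
            mask = np.zeros((config.n_trials, max(max_slots, 1)), dtype=bool)
            dist = np.zeros_like(nt_rel)
            n_store = min(n_lures, max_slots)  # 2p keeps no lure geometry
            for t in range(config.n_trials):
                locs = _place_items(rng, set_size, max_slots, config.min_separation)
                _, rel = recode_relative(locs[0], locs[0], locs[1:])
                nt_rel[t, :n_store] = rel[:n_store]
                mask[t, :n_store] = True
                if model.uses_distances and n_store:
                    dist[t, :n_store] = rng.uniform(0.0, np.pi, size=n_store)
            data = PreparedData(
                x=np.zeros(config.n_trials),
                set_size=np.full(config.n_trials, set_size),
                nt=nt_rel,
                nt_mask=mask,
                dist=dist if model.uses_distances else None,
            )
            p_t, p_slots, p_g = component_probs(eta, data, model)
            probs = np.concatenate([p_t[:, None], p_slots, p_g[:, None]], axis=1)
            cum = np.cumsum(probs, axis=1)
            cum[:, -1] = 1.0
            comp = (rng.uniform(size=(config.n_trials, 1)) > cum).sum(axis=1)

            kappa = np.exp(eta["kappa"])
            err = np.empty(config.n_trials)
            for t in range(config.n_trials):
                k = comp[t]
                if k == 0:
                    err[t] = circular.vonmises_sample(0.0, kappa[t], 1, rng=rng)[0]
                    labels.append("target")
                elif k <= max(max_slots, 1) and k - 1 < n_store:
                    err[t] = circular.vonmises_sample(nt_rel[t, k - 1], kappa[t], 1, rng=rng)[0]
                    labels.append(f"nontarget_{k}")
                else:
                    err[t] = circular.wrap_angle(rng.uniform(-np.pi, np.pi))
                    labels.append("guess")

            for t in range(config.n_trials):
                trial_counter[s] = trial_counter.get(s, 0) + 1
                row = {
                    config.subject_col: s + 1,
                    "trial": trial_counter[s],
                    set_size_col: set_size,
                    model.response_col: err[t],
                }
                for k, v in cell.items():
                    if k not in _PARAM_KEYS and k != "set_size":
                        row[k] = v
                for j in range(max_slots):
                    col = model.nt_cols[j] if model.uses_nontargets else None
                    if col is not None:
                        row[col] = nt_rel[t, j] if j < n_lures else np.nan
                for j, col in enumerate(model.distance_cols):
                    row[col] = dist[t, j] if j < n_lures else np.nan
                rows.append(row)

    table = pd.DataFrame(rows)
    return SimulationResult(
        table=table,
        truth=pd.DataFrame(truth_rows),
        subject_effects=pd.DataFrame(effect_rows),
        labels=np.array(labels),
    )
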