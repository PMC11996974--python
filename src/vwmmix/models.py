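"""Registry of the estimable measurement-model variants.

Five variants are supported:

- ``mixture2p``: target von Mises + uniform guessing; parameters ``kappa``
  (log link) and ``thetat`` (mixing weight of the target component).
- ``mixture3p``: adds non-target (swap) components sharing one mixing weight
  ``thetant`` split equally across lures.
- ``imm_abc`` / ``imm_bsc`` / ``imm_full``: the interference measurement
  model, which re-parameterizes the component probabilities through
  nonnegative activations (context ``c``, general ``a``, generalization
  slope ``s``; background noise ``b`` fixed to 1).

Fixed constants shared by all variants: the target and guessing locations
are 0, the guessing concentration is exp(-100) (numerically uniform), and
the guessing mixing weight is the softmax reference, fixed to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ModelSpec", "make_model", "component_layout", "MODEL_NAMES"]

MODEL_NAMES = ("mixture2p", "mixture3p", "imm_abc", "imm_bsc", "imm_full")
IMM_VERSIONS = ("abc", "bsc", "full")

LOG_KAPPA_UNIFORM = -100.0

# parameter -> link function, per model
_PARAMS = {
    "mixture2p": {"kappa": "log", "thetat": "identity"},
    "mixture3p": {"kappa": "log", "thetat": "identity", "thetant": "identity"},
    "imm_abc": {"kappa": "log", "c": "log", "a": "log"},
    "imm_bsc": {"kappa": "log", "c": "log", "s": "log"},
    "imm_full": {"kappa": "log", "c": "log", "a": "log", "s": "log"},
}


@dataclass(frozen=True)
class ModelSpec:
    """Complete static description of one estimable model variant."""

    name: str
    parameters: dict  # parameter name -> link function name
    fixed_constants: dict
    response_col: str
    nt_cols: tuple = ()
    set_size_col: str | None = None
    distance_cols: tuple = ()
    version: str | None = None  # IMM only

    @property
    def is_imm(self) -> bool:
        return self.name.startswith("imm")

    @property
    def uses_nontargets(self) -> bool:
        return self.name != "mixture2p"

    @property
    def uses_distances(self) -> bool:
        return self.name in ("imm_bsc", "imm_full")

    @property
    def max_slots(self) -> int:
        return len(self.nt_cols)

    def required_columns(self):
        cols = [self.response_col]
        if self.uses_nontargets:
            cols.append(self.set_size_col)
            cols.extend(self.nt_cols)
        if self.uses_distances:
            cols.extend(self.distance_cols)
        return cols


def make_model(
    name: str,
    response_col: str = "response_error",
    nt_cols=None,
    set_size_col: str | None = None,
    distance_cols=None,
    version: str | None = None,
) -> ModelSpec:
    """Build a :class:`ModelSpec` with the variant's fixed constants installed.

    ``name`` may be one of the five canonical names, or ``"imm"`` together
    with ``version`` in {"abc", "bsc", "full"} (defaulting to "full").
    """
    if name == "imm":
        version = version or "full"
        if version not in IMM_VERSIONS:
            raise ValueError(f"unknown IMM version {version!r}; expected one of {IMM_VERSIONS}")
        name = f"imm_{version}"
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    if name.startswith("imm"):
        version = name.split("_", 1)[1]

    nt_cols = tuple(nt_cols) if nt_cols else ()
    distance_cols = tuple(distance_cols) if distance_cols else ()

    spec = ModelSpec(
        name=name,
        parameters=dict(_PARAMS[name]),
        fixed_constants={
            "mu_target": 0.0,
            "mu_uniform": 0.0,
            "log_kappa_uniform": LOG_KAPPA_UNIFORM,
            "theta_reference": 0.0,  # guessing mixing weight (softmax reference)
            **({"b": 1.0} if name.startswith("imm") else {}),
        },
        response_col=response_col,
        nt_cols=nt_cols,
        set_size_col=set_size_col,
        distance_cols=distance_cols,
        version=version,
    )

    if spec.uses_nontargets:
        if not nt_cols:
            raise ValueError(f"{name} requires non-target feature columns (nt_cols)")
        if set_size_col is None:
            raise ValueError(f"{name} requires a set-size column")
    if spec.uses_distances:
        if not distance_cols:
            raise ValueError(f"{name} requires context-distance columns (distance_cols)")
        if len(distance_cols) != len(nt_cols):
            raise ValueError("distance_cols must match nt_cols slot for slot")
    return spec


def component_layout(model: ModelSpec, set_size: int):
    """Ordered component roles for one trial of the given set size.

    ``mixture2p`` always has (target, guess). All other variants have
    1 target + (set_size - 1) non-targets + 1 guess; at set size 1 every
    model reduces to (target, guess).
    """
    set_size = int(set_size)
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    if model.name == "mixture2p":
        return ("target", "guess")
    lures = tuple(f"nontarget_{j + 1}" for j in range(set_size - 1))
    return ("target",) + lures + ("guess",)
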