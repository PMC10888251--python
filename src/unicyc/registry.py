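"""Registry of reversible uni-uni enzyme parameter sets.

Ten literature-derived parameter sets are shipped with the package, one per
enzyme studied: triosephosphate isomerase (``tpi``), ketosteroid isomerase
(``ksi``), carbonic anhydrases I, II and the T200H mutant of II (``ca1``,
``ca2``, ``ca2_t200h``), three A-class beta-lactamases (``pc1``, ``rtem``,
``lac1``), beta-galactosidase (``beta_gal``) and glucose isomerase
(``glucose_isomerase``).

Each set stores second-order binding constants (M^-1 s^-1), first-order
transition constants (s^-1) and the reference environment (substrate,
product, optional buffer and enzyme concentrations in molar units).
:func:`build_rate_set` converts a parameter set plus an environment into the
2n pseudo-first-order rate constants ``k_1 .. k_2n`` of the cycle, with odd
indices forward and even indices backward.

Scheme conventions
------------------
* ``standard`` schemes bind substrate in the first forward transition
  (``k_1 = k_1* [S]``) and product in the last backward transition
  (``k_2n = k_2n* [P]``).
* The ``ca_buffer`` scheme used for the carbonic anhydrases binds CO2 in
  step 1 (``k_1 = k_1* [S]``), bicarbonate in the backward direction of
  step 2 (``k_4 = k_4* [P]``), and the proton-shuttling buffer in both
  directions of step 4 (``k_7 = k_7* [B]``, ``k_8 = k_8* [B]``).

Temperature is carried only as a label: every force in the package is
expressed per RT, so no numeric temperature ever enters a computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "Environment",
    "EnzymeParams",
    "RateSet",
    "ENZYME_NAMES",
    "load_enzyme",
    "build_rate_set",
    "binding_ligands",
    "read_params",
    "write_params",
]


@dataclass(frozen=True)
class Environment:
    """Concentrations defining one reference condition, in molar units."""

    substrate_conc: float
    product_conc: float
    enzyme_conc: float = 0.0
    buffer_conc: Optional[float] = None
    temperature_label: str = ""

    def __post_init__(self) -> None:
        for name in ("substrate_conc", "product_conc", "enzyme_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.buffer_conc is not None and self.buffer_conc < 0:
            raise ValueError("buffer_conc must be >= 0")


@dataclass(frozen=True)
class RateSet:
    """The 2n pseudo-first-order rate constants of one cycle instance.

    ``k[0] .. k[2n-1]`` hold ``k_1 .. k_2n`` in s^-1; odd 1-based indices
    are forward transitions, even ones backward (so ``k[2i-2]`` drives
    state ``i -> i+1`` and ``k[2i-1]`` drives ``i+1 -> i``, cyclically).
    """

    k: np.ndarray
    n_states: int

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=float)
        object.__setattr__(self, "k", k)
        if self.n_states not in (2, 3, 4):
            raise ValueError("n_states must be 2, 3 or 4")
        if k.shape != (2 * self.n_states,):
            raise ValueError(
                f"expected {2 * self.n_states} rate constants, got {k.shape}"
            )
        if not np.all(k > 0):
            raise ValueError("all rate constants must be strictly positive")

    def forward(self) -> np.ndarray:
        """Forward constants k_1, k_3, ... (one per catalytic step)."""
        return self.k[0::2]

    def backward(self) -> np.ndarray:
        """Backward constants k_2, k_4, ... (one per catalytic step)."""
        return self.k[1::2]

    def with_k(self, index: int, value: float) -> "RateSet":
        """Return a copy with the 1-based constant ``k_index`` replaced."""
        k = self.k.copy()
        k[index - 1] = value
        return RateSet(k=k, n_states=self.n_states)


@dataclass(frozen=True)
class EnzymeParams:
    """One enzyme's published constants plus its reference environment."""

    name: str
    n_states: int
    second_order: dict[str, float]
    first_order: dict[str, float]
    environment: Environment
    scheme_variant: str = "standard"
    full_name: str = ""
    alt_columns: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scheme_variant not in ("standard", "ca_buffer"):
            raise ValueError(f"unknown scheme_variant {self.scheme_variant!r}")
        expected = {f"k{i}" for i in range(1, 2 * self.n_states + 1)}
        got = set(self.second_order) | set(self.first_order)
        if got != expected:
            raise ValueError(
                f"rate-constant labels {sorted(got)} do not cover k1..k{2*self.n_states}"
            )
        for label, value in {**self.second_order, **self.first_order}.items():
            if value <= 0:
                raise ValueError(f"{label} must be strictly positive")


class RegistryError(KeyError):
    """Raised for unknown enzyme identifiers."""


def _registry() -> dict:
    with (resources.files("unicyc") / "data" / "enzymes.json").open() as fh:
        return json.load(fh)


ENZYME_NAMES = tuple(sorted(_registry()))


def _params_from_record(name: str, rec: dict) -> EnzymeParams:
    env = Environment(**rec["environment"])
    return EnzymeParams(
        name=name,
        n_states=rec["n_states"],
        second_order={k: float(v) for k, v in rec["second_order"].items()},
        first_order={k: float(v) for k, v in rec["first_order"].items()},
        environment=env,
        scheme_variant=rec.get("scheme_variant", "standard"),
        full_name=rec.get("full_name", ""),
        alt_columns=rec.get("alt_columns", {}),
    )


def load_enzyme(name: str) -> EnzymeParams:
    """Return the registered parameter set for ``name``, exactly as published.

    Raises
    ------
    RegistryError
        If ``name`` is not registered; the message lists valid identifiers.
    """
    reg = _registry()
    if name not in reg:
        raise RegistryError(
            f"unknown enzyme {name!r}; valid names: {', '.join(sorted(reg))}"
        )
    return _params_from_record(name, reg[name])


def binding_ligands(params: EnzymeParams) -> dict[str, str]:
    """Map each second-order rate-constant label to its ligand (S, P or B)."""
    n = params.n_states
    if params.scheme_variant == "ca_buffer":
        return {"k1": "S", "k4": "P", "k7": "B", "k8": "B"}
    return {"k1": "S", f"k{2 * n}": "P"}


def build_rate_set(params: EnzymeParams, env: Optional[Environment] = None) -> RateSet:
    """Build the pseudo-first-order rate constants at ``env`` concentrations.

    Binding-step constants are multiplied by the relevant free-ligand
    concentration (``k_i = k_i* [ligand]``); first-order constants pass
    through unchanged.
    """
    if env is None:
        env = params.environment
    conc = {"S": env.substrate_conc, "P": env.product_conc}
    ligands = binding_ligands(params)
    if "B" in ligands.values():
        if env.buffer_conc is None:
            raise ValueError(
                f"{params.name}: the ca_buffer scheme needs a buffer concentration"
            )
        conc["B"] = env.buffer_conc
    k = np.empty(2 * params.n_states)
    for i in range(1, 2 * params.n_states + 1):
        label = f"k{i}"
        if label in params.second_order:
            c = conc[ligands[label]]
            if c <= 0:
                raise ValueError(
                    f"{params.name}: {label} needs a positive "
                    f"[{ligands[label]}] concentration"
                )
            k[i - 1] = params.second_order[label] * c
        else:
            k[i - 1] = params.first_order[label]
    return RateSet(k=k, n_states=params.n_states)


def with_environment(params: EnzymeParams, **changes) -> EnzymeParams:
    """Return a copy of ``params`` with environment fields replaced."""
    return replace(params, environment=replace(params.environment, **changes))


def write_params(params: EnzymeParams, path: str | Path) -> None:
    """Serialize one parameter set to a self-describing JSON file."""
    rec = {
        "full_name": params.full_name,
        "n_states": params.n_states,
        "scheme_variant": params.scheme_variant,
        "second_order": params.second_order,
        "first_order": params.first_order,
        "environment": {
            "substrate_conc": params.environment.substrate_conc,
            "product_conc": params.environment.product_conc,
            "enzyme_conc": params.environment.enzyme_conc,
            "temperature_label": params.environment.temperature_label,
            **(
                {"buffer_conc": params.environment.buffer_conc}
                if params.environment.buffer_conc is not None
                else {}
            ),
        },
    }
    if params.alt_columns:
        rec["alt_columns"] = params.alt_columns
    Path(path).write_text(json.dumps({params.name: rec}, indent=2) + "\n")


def read_params(path: str | Path) -> EnzymeParams:
    """Read a single-enzyme JSON parameter file written by :func:`write_params`."""
    data = json.loads(Path(path).read_text())
    if len(data) != 1:
        raise ValueError(f"{path}: expected exactly one enzyme record")
    ((name, rec),) = data.items()
    return _params_from_record(name, rec)
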