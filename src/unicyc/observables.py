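"""Thermodynamic and kinetic observables of a uni-uni catalytic cycle.

All forces are dimensionless (divided by RT).  The total force is

    X_tot/RT = ln[(k_1 k_3 ... k_{2n-1}) / (k_2 k_4 ... k_{2n})]

and the per-transition force is X_i/RT = ln(k_{2i-1} p_i / (k_{2i} p_{i+1})).
Entropy production per R (equivalently, dissipation per RT) is the bilinear
product P = J X_tot/RT in s^-1, decomposed into per-step terms
P_i = J X_i/RT; at steady state P >= 0 because J and X_tot share their sign.

Performance parameters follow the forward-direction closed forms of the
reversible Michaelis-Menten schemes:

    2 states:  kcat = k_3,                 kcat/KM = k_1 k_3 / ([S](k_2+k_3))
    3 states:  kcat = k_5/(1 + k_4/k_3 + k_5/k_3),
               kcat/KM = k_1 k_3 k_5 / ([S](k_2 k_4 + k_2 k_5 + k_3 k_5))
    4 states:  kcat = k_3 k_5 k_7 / (k_3 k_5 + k_3 k_6 + k_3 k_7
                                     + k_4 k_6 + k_4 k_7 + k_5 k_7),
               kcat/KM = k_1 k_3 k_5 k_7
                         / ([S](k_2 k_4 k_6 + k_2 k_4 k_7
                                + k_2 k_5 k_7 + k_3 k_5 k_7))

(the kcat expressions are the saturating-substrate limits of the cycle
flux).  KM is obtained as kcat divided by kcat/KM, which is algebraically
identical to the textbook Michaelis-constant expressions and avoids their
typographically fragile nested forms.  Because the pseudo-first-order k_1
carries one factor of [S], the [S] in the specificity denominator cancels
and kcat/KM is a second-order constant in M^-1 s^-1.

Equilibrium constants come in two conventions: ``k_app``, the product of
the pseudo-first-order step equilibrium constants K_i = k_{2i-1}/k_{2i}
(concentration-dependent, equal to exp(X_tot/RT)), and ``k_chem``, the
same product with second-order constants in the binding steps
(concentration-independent; k_chem = k_app [P]/[S] for every scheme in the
registry).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .registry import Environment, EnzymeParams, RateSet
from .steady_state import SteadyState, steady_state

__all__ = [
    "ThermoKinetic",
    "step_forces",
    "total_force",
    "entropy_production",
    "kcat",
    "km",
    "specificity",
    "equilibrium_constants",
    "shannon_entropy",
    "evaluate",
]


@dataclass(frozen=True)
class ThermoKinetic:
    """Derived observables of one quasi-steady state."""

    step_forces: np.ndarray          # X_i/RT, dimensionless
    total_force: float               # X_tot/RT
    entropy_production: float        # P = J X_tot/RT, s^-1
    partial_entropy: np.ndarray      # P_i = J X_i/RT, s^-1
    step_equilibria: np.ndarray      # K_i = k_{2i-1}/k_{2i}
    k_app: float                     # prod K_i (concentration-dependent)
    k_chem: float                    # concentration-independent convention (nan if unknown)
    kcat: float                      # s^-1
    km: float                        # M
    efficiency: float                # kcat/KM, M^-1 s^-1
    shannon_entropy: float           # -sum p_i ln p_i, nats
    forward_force: bool              # True when X_tot/RT > 0


def step_forces(rates: RateSet, ss: SteadyState) -> np.ndarray:
    """Per-transition forces X_i/RT = ln(k_{2i-1} p_i / (k_{2i} p_{i+1}))."""
    p = ss.occupancies
    if np.any(p <= 0):
        raise ValueError("step forces need strictly positive occupancies")
    n = rates.n_states
    p_next = np.roll(p, -1)
    return np.log(rates.forward() * p / (rates.backward() * p_next))


def total_force(rates: RateSet) -> float:
    """X_tot/RT, the log-ratio of forward to backward rate-constant products."""
    return float(np.sum(np.log(rates.forward())) - np.sum(np.log(rates.backward())))


def entropy_production(rates: RateSet, ss: SteadyState) -> tuple[float, np.ndarray]:
    """Total and per-step entropy production per R, in s^-1."""
    forces = step_forces(rates, ss)
    partial = ss.flux * forces
    return float(ss.flux * total_force(rates)), partial


def kcat(rates: RateSet) -> float:
    """Forward turnover number (saturating-substrate cycle flux), s^-1."""
    k = rates.k
    n = rates.n_states
    if n == 2:
        return float(k[2])
    if n == 3:
        k3, k4, k5 = k[2], k[3], k[4]
        return float(k5 / (1.0 + k4 / k3 + k5 / k3))
    k3, k4, k5, k6, k7 = k[2], k[3], k[4], k[5], k[6]
    denom = k3 * k5 + k3 * k6 + k3 * k7 + k4 * k6 + k4 * k7 + k5 * k7
    return float(k3 * k5 * k7 / denom)


def specificity(rates: RateSet, env: Environment) -> float:
    """Forward specificity constant kcat/KM in M^-1 s^-1."""
    if env.substrate_conc <= 0:
        raise ValueError("specificity needs a positive substrate concentration")
    k = rates.k
    s = env.substrate_conc
    n = rates.n_states
    if n == 2:
        return float(k[0] * k[2] / (s * (k[1] + k[2])))
    if n == 3:
        denom = k[1] * k[3] + k[1] * k[4] + k[2] * k[4]
        return float(k[0] * k[2] * k[4] / (s * denom))
    denom = (
        k[1] * k[3] * k[5]
        + k[1] * k[3] * k[6]
        + k[1] * k[4] * k[6]
        + k[2] * k[4] * k[6]
    )
    return float(k[0] * k[2] * k[4] * k[6] / (s * denom))


def km(rates: RateSet, env: Environment) -> float:
    """Michaelis constant in molar units, as kcat divided by kcat/KM."""
    return kcat(rates) / specificity(rates, env)


def equilibrium_constants(
    rates: RateSet, params: Optional[EnzymeParams] = None
) -> tuple[np.ndarray, float, float]:
    """Step equilibrium constants K_i, and both overall conventions.

    Returns ``(K, k_app, k_chem)``.  ``k_chem`` needs the second-order
    constants and is nan when ``params`` is not given.
    """
    K = rates.forward() / rates.backward()
    k_app = float(np.prod(K))
    k_chem = float("nan")
    if params is not None:
        num, den = 1.0, 1.0
        for i in range(1, 2 * params.n_states + 1):
            label = f"k{i}"
            value = params.second_order.get(label, params.first_order.get(label))
            if i % 2:
                num *= value
            else:
                den *= value
        k_chem = num / den
    return K, k_app, k_chem


def shannon_entropy(ss: SteadyState) -> float:
    """Information entropy -sum p_i ln p_i of the occupancies, in nats."""
    p = ss.occupancies[ss.occupancies > 0]
    return float(-np.sum(p * np.log(p)))


def evaluate(
    rates: RateSet,
    env: Environment,
    params: Optional[EnzymeParams] = None,
    ss: Optional[SteadyState] = None,
) -> tuple[SteadyState, ThermoKinetic]:
    """Compute the full observable block for one quasi-steady state."""
    if ss is None:
        ss = steady_state(rates)
    forces = step_forces(rates, ss)
    xtot = total_force(rates)
    P = float(ss.flux * xtot)
    partial = ss.flux * forces
    K, k_app, k_chem = equilibrium_constants(rates, params)
    kc = kcat(rates)
    eff = specificity(rates, env)
    thermo = ThermoKinetic(
        step_forces=forces,
        total_force=xtot,
        entropy_production=P,
        partial_entropy=partial,
        step_equilibria=K,
        k_app=k_app,
        k_chem=k_chem,
        kcat=kc,
        km=kc / eff,
        efficiency=eff,
        shannon_entropy=shannon_entropy(ss),
        forward_force=xtot > 0,
    )
    return ss, thermo
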