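"""Box-Muller noise on rate constants under kinetic constraints.

The noise factor applied to a rate constant is a Box-Muller deviate with an
optional positive shift,

    g = sqrt(-2 ln s1) cos(2 pi s2) + shift      (or the sine variant),

with s1, s2 uniform on (0, 1).  Shift 0 gives a standard normal; shifts +1
or +2 move the distribution so that most (shift 2: almost all) multipliers
are positive.  A ``uniform`` distribution drawing multipliers from
U(0, 2) (mean 1, range configurable at the spec level) is provided for
parity with tick-based simulators that add uniform jitter instead.

Draw policies
-------------
``shared``        one (s1, s2) pair per sample step; a single g multiplies
                  every masked constant, so noise cancels in all
                  rate-constant ratios (the origin of the perfect
                  efficiency-dissipation proportionality under fixed
                  step equilibria).
``per_constant``  an independent g per masked constant.

Constraints (applied after multiplication)
------------------------------------------
``fixed_step_equilibria``            every backward constant is recomputed
                                     as k_{2i} = k_{2i-1}/K_i^obs so each
                                     step keeps its observed equilibrium
                                     constant, hence X_tot is pinned.
``fixed_total_force(i, j)``          the equilibrium constant of step i is
                                     scaled by the draw and step j is
                                     counter-scaled so that prod K_m (and
                                     the total force) is unchanged; the
                                     variation is carried by the backward
                                     constants k_{2i} and k_{2j}.
``replace_nonpositive_with_observed`` any constant whose multiplier is
                                     <= 0 reverts to its observed value.
``none``                             raw multiplication; a nonpositive
                                     result raises (use a shift or the
                                     replacement rule instead).

All draws come from a single seeded ``numpy.random.Generator``, so a run
is bit-reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .registry import RateSet

__all__ = ["NoiseSpec", "box_muller", "apply_noise"]


@dataclass(frozen=True)
class NoiseSpec:
    """How to perturb a rate set in one sampling step.

    ``mask`` lists 1-based rate-constant indices to perturb.  For
    ``fixed_step_equilibria`` the mask should cover forward constants
    (backward ones are recomputed); for ``fixed_total_force`` the pair of
    step indices (1-based catalytic steps) is given in ``force_pair``.
    """

    distribution: str = "normal_cos"  # normal_cos | normal_sin | uniform
    shift: float = 0.0
    draw_policy: str = "per_constant"  # shared | per_constant
    mask: tuple[int, ...] = ()
    constraint: str = "replace_nonpositive_with_observed"
    force_pair: Optional[tuple[int, int]] = None
    uniform_width: float = 2.0  # multipliers from U(0, uniform_width)

    def __post_init__(self) -> None:
        if self.distribution not in ("normal_cos", "normal_sin", "uniform"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.draw_policy not in ("shared", "per_constant"):
            raise ValueError(f"unknown draw_policy {self.draw_policy!r}")
        if self.constraint not in (
            "none",
            "fixed_step_equilibria",
            "fixed_total_force",
            "replace_nonpositive_with_observed",
        ):
            raise ValueError(f"unknown constraint {self.constraint!r}")
        if self.constraint == "fixed_total_force":
            if self.force_pair is None or self.force_pair[0] == self.force_pair[1]:
                raise ValueError(
                    "fixed_total_force needs two distinct step indices in force_pair"
                )
        elif not self.mask:
            raise ValueError("mask must name at least one rate constant")

    def to_dict(self) -> dict:
        return {
            "distribution": self.distribution,
            "shift": self.shift,
            "draw_policy": self.draw_policy,
            "mask": list(self.mask),
            "constraint": self.constraint,
            "force_pair": list(self.force_pair) if self.force_pair else None,
            "uniform_width": self.uniform_width,
        }


def box_muller(s1: float, s2: float, shift: float = 0.0, variant: str = "cos") -> float:
    """One Box-Muller deviate sqrt(-2 ln s1) trig(2 pi s2) + shift."""
    if not 0.0 < s1 <= 1.0:
        raise ValueError("s1 must lie in (0, 1]")
    if not 0.0 <= s2 < 1.0:
        raise ValueError("s2 must lie in [0, 1)")
    radius = math.sqrt(-2.0 * math.log(s1))
    angle = 2.0 * math.pi * s2
    trig = math.cos(angle) if variant == "cos" else math.sin(angle)
    return radius * trig + shift


def _draw(spec: NoiseSpec, rng: np.random.Generator) -> float:
    if spec.distribution == "uniform":
        return float(rng.random() * spec.uniform_width)
    s1 = 1.0 - rng.random()  # maps [0,1) onto (0,1]
    s2 = rng.random()
    variant = "cos" if spec.distribution == "normal_cos" else "sin"
    return box_muller(s1, s2, shift=spec.shift, variant=variant)


def apply_noise(
    rates: RateSet,
    observed: RateSet,
    spec: NoiseSpec,
    rng: np.random.Generator,
) -> RateSet:
    """Return a new rate set with one round of constrained noise applied.

    ``rates`` is the set to perturb (usually the observed one); ``observed``
    supplies the fallback values for the replacement rule and the reference
    step equilibria for the fixed-K constraint.
    """
    if rates.n_states != observed.n_states:
        raise ValueError("rates and observed must describe the same scheme")
    n2 = 2 * rates.n_states
    k = rates.k.copy()

    if spec.constraint == "fixed_total_force":
        i, j = spec.force_pair
        g = _draw(spec, rng)
        while g <= 0:
            g = _draw(spec, rng)
        # K_i *= g via the backward constant, K_j /= g likewise
        k[2 * i - 1] /= g
        k[2 * j - 1] *= g
        return RateSet(k=k, n_states=rates.n_states)

    mask = [m - 1 for m in spec.mask]
    if any(m < 0 or m >= n2 for m in mask):
        raise ValueError(f"mask indices must be within 1..{n2}")

    if spec.draw_policy == "shared":
        g_shared = _draw(spec, rng)
        draws = {m: g_shared for m in mask}
    else:
        draws = {m: _draw(spec, rng) for m in mask}

    for m in mask:
        new = k[m] * draws[m]
        if new <= 0:
            if spec.constraint == "replace_nonpositive_with_observed":
                new = observed.k[m]
            elif spec.constraint == "fixed_step_equilibria":
                new = observed.k[m]  # same replacement rule, then K re-pinned
            else:
                raise ValueError(
                    f"noise drove k_{m + 1} nonpositive; use a positive shift "
                    "or the replace_nonpositive_with_observed constraint"
                )
        k[m] = new

    if spec.constraint == "fixed_step_equilibria":
        K_obs = observed.forward() / observed.backward()
        k[1::2] = k[0::2] / K_obs

    return RateSet(k=k, n_states=rates.n_states)
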