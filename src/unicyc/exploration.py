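"""Deterministic scans, noisy quasi-steady-state sampling and reporting.

Every sampler in this module produces a :class:`SampleTable`: a tidy
pandas DataFrame (one row per quasi-steady state, columns for the rate
constants, occupancies, flux, forces, entropy production and performance
parameters) plus a provenance record sufficient to reproduce the run.

The samplers all share one evaluation path: a rate set and an environment
go through the diagram-method steady state and the observable block, so a
stored row can always be recomputed from its own rate constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .noise import NoiseSpec, apply_noise
from .observables import evaluate
from .registry import Environment, EnzymeParams, RateSet, build_rate_set, with_environment

__all__ = [
    "SampleTable",
    "FitResult",
    "evaluate_point",
    "stepwise_scan",
    "concentration_scan",
    "noisy_sample",
    "best_point",
    "linear_fit",
    "fold_report",
]


@dataclass
class SampleTable:
    """Ordered collection of evaluated quasi-steady states."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def rate_set(self, row: int | pd.Series, n_states: int) -> RateSet:
        """Rebuild the RateSet stored in one row."""
        if isinstance(row, int):
            row = self.data.iloc[row]
        k = np.array([row[f"k{i}"] for i in range(1, 2 * n_states + 1)])
        return RateSet(k=k, n_states=n_states)

    def positive_force(self) -> "SampleTable":
        """Rows with X_tot/RT > 0 (forward-running states)."""
        return SampleTable(
            data=self.data[self.data["x_tot"] > 0].copy(),
            provenance={**self.provenance, "filter": "x_tot > 0"},
        )

    def write_csv(self, path: str | Path, manifest: Optional[str | Path] = None) -> None:
        self.data.to_csv(path, index=False)
        if manifest is not None:
            Path(manifest).write_text(json.dumps(self.provenance, indent=2) + "\n")


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    through_origin: bool


def evaluate_point(
    rates: RateSet,
    env: Environment,
    step_index: int = 0,
    params: Optional[EnzymeParams] = None,
) -> dict:
    """One tidy row of observables for a rate set at given concentrations."""
    ss, thermo = evaluate(rates, env, params=params)
    n = rates.n_states
    row: dict = {"step": step_index}
    for i in range(2 * n):
        row[f"k{i + 1}"] = rates.k[i]
    for i in range(n):
        row[f"p{i + 1}"] = ss.occupancies[i]
    row["flux"] = ss.flux
    for i in range(n):
        row[f"x{i + 1}"] = thermo.step_forces[i]
    row["x_tot"] = thermo.total_force
    row["entropy_production"] = thermo.entropy_production
    for i in range(n):
        row[f"partial_entropy{i + 1}"] = thermo.partial_entropy[i]
    row["kcat"] = thermo.kcat
    row["km"] = thermo.km
    row["specificity"] = thermo.efficiency
    row["k_app"] = thermo.k_app
    row["shannon"] = thermo.shannon_entropy
    row["substrate_conc"] = env.substrate_conc
    row["product_conc"] = env.product_conc
    row["force_sign"] = 1 if thermo.total_force > 0 else -1
    return row


def stepwise_scan(
    base: RateSet,
    env: Environment,
    target: int,
    start: float,
    step: float,
    n_steps: int,
    couple_fixed_K: bool = False,
    params: Optional[EnzymeParams] = None,
) -> SampleTable:
    """Deterministic arithmetic scan of one rate constant.

    ``target`` is the 1-based index of the scanned constant, whose value is
    start + m*step for m = 0..n_steps-1.  With ``couple_fixed_K`` the
    partner constant of the same catalytic step is rescaled each row so the
    step's equilibrium constant keeps its base value (and with it the total
    force); otherwise the force sweeps along with the scan.
    """
    if start <= 0 or step <= 0:
        raise ValueError("start and step must be positive")
    step_idx = (target - 1) // 2  # 0-based catalytic step
    forward_target = target % 2 == 1
    partner = 2 * step_idx + 2 if forward_target else 2 * step_idx + 1
    K_base = base.k[2 * step_idx] / base.k[2 * step_idx + 1]
    rows = []
    for m in range(n_steps):
        value = start + m * step
        rates = base.with_k(target, value)
        if couple_fixed_K:
            if forward_target:
                rates = rates.with_k(partner, value / K_base)
            else:
                rates = rates.with_k(partner, value * K_base)
        rows.append(evaluate_point(rates, env, step_index=m, params=params))
    return SampleTable(
        data=pd.DataFrame(rows),
        provenance={
            "kind": "stepwise_scan",
            "target": target,
            "start": start,
            "step": step,
            "n_steps": n_steps,
            "couple_fixed_K": couple_fixed_K,
        },
    )


def concentration_scan(
    params: EnzymeParams,
    n_steps: int,
    conserve_sum: bool = True,
    substrate_step: Optional[float] = None,
) -> SampleTable:
    """Scan decreasing [S] / increasing [P] with [S]+[P] held fixed.

    Row 0 reproduces the registered reference condition.  By default the
    substrate decrement spreads 99% of the initial [S] over the scan, so
    concentrations stay strictly positive throughout.
    """
    env0 = params.environment
    total = env0.substrate_conc + env0.product_conc
    if conserve_sum and total <= 0:
        raise ValueError("conserve_sum needs [S]0 + [P]0 > 0")
    if substrate_step is None:
        substrate_step = 0.99 * env0.substrate_conc / max(n_steps - 1, 1)
    rows = []
    for m in range(n_steps):
        s = env0.substrate_conc - m * substrate_step
        if s <= 0:
            raise ValueError(f"step {m} drives the substrate concentration to {s} M")
        p = (total - s) if conserve_sum else env0.product_conc
        p_params = with_environment(params, substrate_conc=s, product_conc=p)
        rates = build_rate_set(p_params)
        rows.append(
            evaluate_point(rates, p_params.environment, step_index=m, params=p_params)
        )
    return SampleTable(
        data=pd.DataFrame(rows),
        provenance={
            "kind": "concentration_scan",
            "enzyme": params.name,
            "n_steps": n_steps,
            "conserve_sum": conserve_sum,
            "substrate_step": substrate_step,
        },
    )


def noisy_sample(
    base: RateSet,
    observed: RateSet,
    env: Environment,
    spec: NoiseSpec,
    n_steps: int,
    seed: int,
    params: Optional[EnzymeParams] = None,
    require_positive_force: bool = False,
    cumulative: bool = False,
) -> SampleTable:
    """Sample ``n_steps`` constrained noisy quasi-steady states.

    By default each step draws fresh noise from ``base``, so steps are
    independent.  With ``cumulative`` each step perturbs the previous
    step's rates instead - a multiplicative random walk that explores
    rate-constant space far beyond the reach of single unit-scale draws
    (constraints are still enforced against the observed set every step).
    With ``require_positive_force`` draws are rejected until X_tot/RT > 0
    (as in runs that only admit forward-running states).
    """
    rng = np.random.default_rng(seed)
    rows = []
    current = base
    for m in range(n_steps):
        while True:
            rates = apply_noise(current, observed, spec, rng)
            if not require_positive_force:
                break
            if np.sum(np.log(rates.forward())) > np.sum(np.log(rates.backward())):
                break
        if cumulative:
            current = rates
        rows.append(evaluate_point(rates, env, step_index=m, params=params))
    return SampleTable(
        data=pd.DataFrame(rows),
        provenance={
            "kind": "noisy_sample",
            "noise": spec.to_dict(),
            "n_steps": n_steps,
            "seed": seed,
            "require_positive_force": require_positive_force,
            "cumulative": cumulative,
        },
    )


_CRITERIA = {
    "max_specificity": "specificity",
    "max_entropy_production": "entropy_production",
    "max_kcat": "kcat",
}


def best_point(table: SampleTable, criterion: str = "max_specificity") -> pd.Series:
    """Row maximizing the criterion; ties break on the earliest step."""
    if len(table) == 0:
        raise ValueError("cannot pick a best point from an empty table")
    column = _CRITERIA.get(criterion)
    if column is None:
        raise ValueError(f"criterion must be one of {sorted(_CRITERIA)}")
    values = table.data[column].to_numpy()
    return table.data.iloc[int(np.argmax(values))]


def linear_fit(
    table: SampleTable,
    x: str = "entropy_production",
    y: str = "specificity",
    through_origin: bool = False,
    positive_force_only: bool = False,
) -> FitResult:
    """Ordinary least squares of y on x with R^2 = 1 - SS_res/SS_tot."""
    data = table.data
    if positive_force_only:
        data = data[data["x_tot"] > 0]
    if len(data) < 2:
        raise ValueError("need at least two points to fit")
    xv = data[x].to_numpy(dtype=float)
    yv = data[y].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise ValueError("degenerate fit: x has zero variance")
    if through_origin:
        slope = float(np.dot(xv, yv) / np.dot(xv, xv))
        intercept = 0.0
        resid = yv - slope * xv
    else:
        slope, intercept = (float(v) for v in np.polyfit(xv, yv, 1))
        resid = yv - (slope * xv + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=len(xv),
        through_origin=through_origin,
    )


def fold_report(observed: pd.Series, best: pd.Series) -> dict[str, float]:
    """Best-to-observed fold factors for the headline quantities."""
    report = {}
    for column in ("specificity", "entropy_production", "kcat", "flux"):
        if float(observed[column]) == 0:
            raise ValueError(f"observed {column} is zero; fold factor undefined")
        report[column] = float(best[column]) / float(observed[column])
    report["specificity_per_dissipation"] = (
        report["specificity"] / report["entropy_production"]
    )
    return report
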