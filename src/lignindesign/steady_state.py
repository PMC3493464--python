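"""Normalization, S-system derivation and log-linear steady-state solving.

A parameterized GMA instance is normalized to its sampled wild-type steady
state: each dependent variable X_i is replaced by Y_i = X_i / X_iS, so every
term's rate constant is eliminated in favour of the sampled steady-state
flux V_iS, and the wild-type operating point is Y = 1 with all enzyme
multipliers at 1.

Aggregating each variable's production terms into one power law (and
likewise consumption) — exponents combined as flux-weighted means — yields
the equivalent S-system at the operating point.  Its steady-state equations
are linear in log space, so a perturbed steady state is a single linear
solve; a damped numerical GMA fixed-point finder is kept alongside as an
independent oracle.

Enzyme down-regulation or knockout is a multiplicative factor on the
corresponding normalized enzyme activity (knockouts as a small residual
activity, never exactly zero: a zero multiplier lies outside the power-law
form's domain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import root

from .gma import GMAModel, KineticOrderSample
from .polytope import FluxSample

#: Exclusion rule: a perturbed steady state with any pool changed by strictly
#: more than this factor is ill-behaved and dropped from validity counting.
DEFAULT_FOLD_LIMIT = 1000.0

#: Condition-number ceiling above which the log-linear system is flagged
#: degenerate (singular for practical purposes) rather than solved.
DEFAULT_COND_LIMIT = 1e12

STATUS_OK = "ok"
STATUS_ILL_BEHAVED = "ill_behaved"
STATUS_DEGENERATE = "degenerate"
STATUS_NO_CONVERGENCE = "no_convergence"


@dataclass(frozen=True)
class PerturbationScenario:
    """Enzyme-activity multipliers mimicking a transgenic or mutant line.

    ``enzyme_multipliers`` holds the primary effect (0 < v < 1 for
    down-regulation); ``hierarchical_multipliers`` the secondary activity
    changes applied only when the screened design includes hierarchical
    regulation (e.g. CCR1/CCoAOMT up-regulation in the ccr2 knockout).
    """

    name: str
    enzyme_multipliers: Mapping[str, float] = field(default_factory=dict)
    hierarchical_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.enzyme_multipliers, self.hierarchical_multipliers):
            for enz, v in d.items():
                if v <= 0:
                    raise ValueError(f"multiplier for {enz} must be > 0, got {v}")

    def multipliers(self, enzymes: Sequence[str], hierarchical: bool = False) -> np.ndarray:
        m = np.ones(len(enzymes))
        for i, enz in enumerate(enzymes):
            if enz in self.enzyme_multipliers:
                m[i] = self.enzyme_multipliers[enz]
            if hierarchical and enz in self.hierarchical_multipliers:
                m[i] = m[i] * self.hierarchical_multipliers[enz]
        return m


IDENTITY_SCENARIO = PerturbationScenario("wild-type")


@dataclass
class NormalizedInstance:
    """A fully parameterized, wild-type-normalized GMA instance.

    ``fluxes[k]`` is the sampled steady-state flux V_kS of term k;
    ``f_dep[k, j]`` the kinetic order of dependent variable j in term k;
    ``f_enz[k, e]`` the (fixed, 0/1) kinetic order of enzyme e.  At Y = 1
    and unit multipliers every term equals its V_kS and all derivatives
    vanish by construction.
    """

    model: GMAModel
    fluxes: np.ndarray
    f_dep: np.ndarray
    f_enz: np.ndarray

    @property
    def dependent_vars(self) -> tuple[str, ...]:
        return self.model.dependent_vars

    @property
    def enzymes(self) -> tuple[str, ...]:
        return self.model.enzymes

    def wild_type_sg_ratio(self) -> float | None:
        try:
            iS = self.model.term_index("S_efflux")
            iG = self.model.term_index("G_efflux")
        except KeyError:
            return None
        return float(self.fluxes[iS] / self.fluxes[iG])


def normalize_instance(
    model: GMAModel,
    flux_sample: FluxSample | Mapping[str, float] | np.ndarray,
    kinetic_orders: KineticOrderSample | Mapping[tuple[str, str], float],
) -> NormalizedInstance:
    """Assemble the numeric exponent/flux arrays of a normalized instance."""
    T = len(model.terms)
    d = len(model.dependent_vars)
    var_idx = {v: j for j, v in enumerate(model.dependent_vars)}
    enz_idx = {e: j for j, e in enumerate(model.enzymes)}

    if isinstance(flux_sample, FluxSample):
        V = np.array([flux_sample.values[t.reaction] for t in model.terms])
    elif isinstance(flux_sample, Mapping):
        V = np.array([flux_sample[t.reaction] for t in model.terms])
    else:
        V = np.asarray(flux_sample, dtype=float)
    if V.shape != (T,):
        raise ValueError("flux sample length does not match the model's terms")
    if np.any(V <= 0):
        raise ValueError("all steady-state fluxes must be strictly positive")

    ko = kinetic_orders.as_dict() if isinstance(kinetic_orders, KineticOrderSample) \
        else dict(kinetic_orders)
    f_dep = np.zeros((T, d))
    f_enz = np.zeros((T, len(model.enzymes)))
    for k, term in enumerate(model.terms):
        for var, _role in term.roles:
            f_dep[k, var_idx[var]] = ko[(term.reaction, var)]
        for enz in term.enzymes:
            f_enz[k, enz_idx[enz]] = 1.0
    return NormalizedInstance(model=model, fluxes=V, f_dep=f_dep, f_enz=f_enz)


@dataclass
class SSystemInstance:
    """Aggregate production/consumption power laws per dependent variable.

    ``alpha[i]`` (= ``beta[i]``) is the total wild-type flux through variable
    i; ``G``/``H`` the flux-weighted production/consumption kinetic orders
    over dependent variables, ``G_enz``/``H_enz`` over enzyme activities.
    """

    dependent_vars: tuple[str, ...]
    enzymes: tuple[str, ...]
    alpha: np.ndarray
    beta: np.ndarray
    G: np.ndarray
    H: np.ndarray
    G_enz: np.ndarray
    H_enz: np.ndarray
    instance: NormalizedInstance


def derive_ssystem(inst: NormalizedInstance) -> SSystemInstance:
    """Aggregate the GMA instance into its operating-point S-system.

    Exponents of parallel terms combine as V-weighted means; a variable with
    a single production and a single consumption term keeps its GMA
    exponents unchanged.
    """
    model = inst.model
    d = len(model.dependent_vars)
    e = len(model.enzymes)
    alpha = np.zeros(d)
    beta = np.zeros(d)
    G = np.zeros((d, d))
    H = np.zeros((d, d))
    G_enz = np.zeros((d, e))
    H_enz = np.zeros((d, e))
    for i, var in enumerate(model.dependent_vars):
        prod = model.production_terms(var)
        cons = model.consumption_terms(var)
        Vp = inst.fluxes[prod]
        Vc = inst.fluxes[cons]
        alpha[i] = Vp.sum()
        beta[i] = Vc.sum()
        if alpha[i] <= 0 or beta[i] <= 0:
            raise ValueError(f"zero total flux through {var}")
        G[i] = Vp @ inst.f_dep[prod] / alpha[i]
        H[i] = Vc @ inst.f_dep[cons] / beta[i]
        G_enz[i] = Vp @ inst.f_enz[prod] / alpha[i]
        H_enz[i] = Vc @ inst.f_enz[cons] / beta[i]
    return SSystemInstance(
        dependent_vars=model.dependent_vars,
        enzymes=model.enzymes,
        alpha=alpha,
        beta=beta,
        G=G,
        H=H,
        G_enz=G_enz,
        H_enz=H_enz,
        instance=inst,
    )


@dataclass
class SteadyStateSolution:
    """Perturbed steady state in log-deviation form.

    ``log_deviations[j] = ln Y_j`` per dependent variable; ``flux_factors``
    the per-term ratios V/V_S; ``sg_ratio`` the predicted S/G (None when the
    model lacks S/G effluxes, e.g. toy systems).
    """

    scenario: str
    variables: tuple[str, ...]
    y: np.ndarray
    flux_factors: dict[str, float]
    sg_ratio: float | None
    status: str

    @property
    def log_deviations(self) -> dict[str, float]:
        return dict(zip(self.variables, self.y))

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK

    @property
    def max_fold_change(self) -> float:
        return float(np.exp(np.max(np.abs(self.y))))


def _term_flux_factors(
    inst: NormalizedInstance, y: np.ndarray, mu: np.ndarray
) -> dict[str, float]:
    lf = inst.f_dep @ y + inst.f_enz @ mu
    return {t.reaction: float(np.exp(lf[k])) for k, t in enumerate(inst.model.terms)}


def _finish_solution(
    inst: NormalizedInstance,
    scenario_name: str,
    y: np.ndarray,
    mu: np.ndarray,
    rho_wt: float | None,
    fold_limit: float,
    status: str = STATUS_OK,
) -> SteadyStateSolution:
    factors = _term_flux_factors(inst, y, mu)
    if status == STATUS_OK and np.max(np.abs(y), initial=0.0) > math.log(fold_limit):
        status = STATUS_ILL_BEHAVED
    sg = None
    if "S_efflux" in factors and "G_efflux" in factors:
        rho = inst.wild_type_sg_ratio() if rho_wt is None else rho_wt
        sg = float(rho * factors["S_efflux"] / factors["G_efflux"])
    return SteadyStateSolution(
        scenario=scenario_name,
        variables=inst.dependent_vars,
        y=y,
        flux_factors=factors,
        sg_ratio=sg,
        status=status,
    )


def solve_steady_state(
    ssys: SSystemInstance,
    scenario: PerturbationScenario,
    hierarchical: bool = False,
    rho_wt: float | None = None,
    fold_limit: float = DEFAULT_FOLD_LIMIT,
    cond_limit: float = DEFAULT_COND_LIMIT,
) -> SteadyStateSolution:
    """Solve the perturbed steady state of the S-system in log space.

    The steady-state condition alpha_i prod Y^g = beta_i prod Y^h becomes,
    after taking logarithms and using alpha = beta,

        (G - H) y = (H_enz - G_enz) ln(m)

    with m the enzyme multipliers.  A near-singular system (condition number
    above ``cond_limit``) is flagged degenerate, never raised.
    """
    inst = ssys.instance
    mu = np.log(scenario.multipliers(ssys.enzymes, hierarchical=hierarchical))
    A = ssys.G - ssys.H
    rhs = (ssys.H_enz - ssys.G_enz) @ mu
    d = A.shape[0]
    if d == 0:
        return _finish_solution(inst, scenario.name, np.zeros(0), mu, rho_wt, fold_limit)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > cond_limit:
        return _finish_solution(
            inst, scenario.name, np.full(d, np.nan), mu, rho_wt, fold_limit,
            status=STATUS_DEGENERATE,
        )
    y = np.linalg.solve(A, rhs)
    return _finish_solution(inst, scenario.name, y, mu, rho_wt, fold_limit)


def gma_numerical_steady_state(
    inst: NormalizedInstance,
    scenario: PerturbationScenario,
    hierarchical: bool = False,
    rho_wt: float | None = None,
    fold_limit: float = DEFAULT_FOLD_LIMIT,
    tol: float = 1e-12,
) -> SteadyStateSolution:
    """Find the GMA fixed point by root-finding in log space (test oracle).

    Residual of variable i at log-deviations y:

        F_i(y) = sum_{k in prod(i)} V_kS e^{f_k.y + e_k.mu}
               - sum_{k in cons(i)} V_kS e^{f_k.y + e_k.mu}

    started at y = 0 (the wild-type operating point).  Non-convergence is
    flagged, not raised, so callers can skip the instance in comparisons.
    """
    model = inst.model
    d = len(model.dependent_vars)
    mu = np.log(scenario.multipliers(inst.enzymes, hierarchical=hierarchical))
    prod_idx = [model.production_terms(v) for v in model.dependent_vars]
    cons_idx = [model.consumption_terms(v) for v in model.dependent_vars]

    def residual(y: np.ndarray) -> np.ndarray:
        rates = inst.fluxes * np.exp(inst.f_dep @ y + inst.f_enz @ mu)
        return np.array(
            [rates[prod_idx[i]].sum() - rates[cons_idx[i]].sum() for i in range(d)]
        )

    y0 = np.zeros(d)
    if np.linalg.norm(residual(y0)) < 1e-14:  # identity perturbation: y=0 is exact
        return _finish_solution(inst, scenario.name, y0, mu, rho_wt, fold_limit)
    sol = root(residual, y0, method="hybr", tol=tol)
    y = sol.x
    if np.linalg.norm(residual(y)) > 1e-8:
        return _finish_solution(
            inst, scenario.name, np.full(d, np.nan), mu, rho_wt, fold_limit,
            status=STATUS_NO_CONVERGENCE,
        )
    return _finish_solution(inst, scenario.name, y, mu, rho_wt, fold_limit)


def compute_sg_ratio(solution: SteadyStateSolution, rho_wt: float) -> float:
    """Predicted S/G ratio: rho_WT scaled by the S- vs G-efflux flux factors."""
    if solution.status == STATUS_DEGENERATE:
        raise ValueError("cannot compute an S/G ratio for a degenerate solution")
    try:
        fS = solution.flux_factors["S_efflux"]
        fG = solution.flux_factors["G_efflux"]
    except KeyError as exc:
        raise ValueError("solution has no S/G efflux terms") from exc
    return float(rho_wt * fS / fG)
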