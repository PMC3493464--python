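"""Monte-Carlo ensemble screening of pathway designs.

For each design, an ensemble of randomly parameterized, wild-type-normalized
model instantiations is generated (fluxes from the constrained polytope,
kinetic orders from their sign-constrained intervals) and each instantiation
is solved under all perturbation lines.  An instantiation is

* **ill-behaved** if any line moves any pool by more than 1000-fold, or the
  log-linear system is degenerate in any line (tallied separately);
* **valid** if it is well-behaved everywhere, the mean squared difference
  between predicted and observed S/G over the quantitative lines is below
  0.01, and the knockout predictions clear the 5% qualitative margins;
* **valid under relaxed criteria** if, with the same qualitative clauses,
  it passes either the strict MSE test or a per-line relative error of at
  most 25% (a superset by construction, so Q <= Q').

Q is the count of valid instantiations of a design, Q' the relaxed count.

The ensemble math is vectorized (stacked exponent tensors, batched linear
solves); a test pins the batched path to the per-instance reference solver
in :mod:`lignindesign.steady_state`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gma import GMAModel, KineticOrderBounds, build_gma, default_bounds
from .polytope import FluxPolytope, build_constraints, enumerate_vertices
from .scaffold import Design, Scaffold, base_scaffold, pattern_label
from .scenarios import ScenarioSet
from .steady_state import DEFAULT_COND_LIMIT, DEFAULT_FOLD_LIMIT

#: Instantiations per design at the full-scale screening setting; the
#: default desk-scale setting used by the CLI is 10^4.
FULL_SCALE_ENSEMBLE = 100_000

VERDICT_VALID = "valid"
VERDICT_VALID_RELAXED_ONLY = "valid_relaxed_only"
VERDICT_INVALID = "invalid"
VERDICT_ILL_BEHAVED = "ill_behaved"


@dataclass(frozen=True)
class ValidityCriteria:
    """Thresholds of the validity screen."""

    mse_threshold: float = 0.01   # squared S/G units, strict inequality
    qual_margin: float = 0.05     # fraction of the wild-type ratio
    relaxed_pct: float = 0.25     # per-line relative error under relaxed rules
    fold_limit: float = DEFAULT_FOLD_LIMIT
    cond_limit: float = DEFAULT_COND_LIMIT

    def __post_init__(self) -> None:
        for name in ("mse_threshold", "qual_margin", "relaxed_pct", "fold_limit",
                     "cond_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CRITERIA = ValidityCriteria()

# Polytope cache: vertex enumeration is exact and deterministic, so polytopes
# are shared across designs with the same topology/ratio/epsilon.
_POLYTOPE_CACHE: dict[tuple, FluxPolytope] = {}


def _cached_polytope(
    topology, rho_wt: float, scaffold: Scaffold, epsilon: float
) -> FluxPolytope:
    key = (topology.present_edges, float(rho_wt), float(epsilon))
    if key not in _POLYTOPE_CACHE:
        cs = build_constraints(topology, rho_wt, scaffold, epsilon=epsilon)
        _POLYTOPE_CACHE[key] = enumerate_vertices(cs)
    return _POLYTOPE_CACHE[key]


def design_seed_sequence(seed: int, design: Design) -> np.random.SeedSequence:
    """Deterministic per-design seed stream, independent of screening order."""
    # encode the sorted mechanism ids stably
    mech_code = 0
    for m in sorted(design.crosstalk):
        mech_code = mech_code * 37 + int(m[1:])
    return np.random.SeedSequence(
        [int(seed), design.topology.mask, mech_code, int(design.hierarchical)]
    )


@dataclass
class BatchSolution:
    """Vectorized steady-state solutions of one ensemble under one scenario."""

    y: np.ndarray          # (n, d) log deviations (NaN rows where degenerate)
    sg: np.ndarray         # (n,) predicted S/G ratios
    ill_behaved: np.ndarray   # (n,) bool
    degenerate: np.ndarray    # (n,) bool

    @property
    def behaved(self) -> np.ndarray:
        return ~(self.ill_behaved | self.degenerate)


class DesignEnsemble:
    """Precomputed structure for fast ensemble evaluation of one design.

    Holds the design's GMA structure as dense arrays: production/consumption
    membership (d x T), fixed enzyme exponents (T x E), the list of sampled
    (term, variable) kinetic-order intervals, and the flux polytope.
    """

    def __init__(
        self,
        design: Design,
        rho_wt: float,
        scaffold: Scaffold | None = None,
        bounds: KineticOrderBounds | None = None,
        epsilon: float = 1e-3,
    ) -> None:
        self.design = design
        self.rho_wt = float(rho_wt)
        scaffold = scaffold or base_scaffold()
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # vacuous mechanisms are expected here
            self.model: GMAModel = build_gma(design, scaffold)
        self.bounds = bounds or default_bounds(self.model)
        self.polytope = _cached_polytope(design.topology, rho_wt, scaffold, epsilon)

        model = self.model
        T = len(model.terms)
        d = len(model.dependent_vars)
        var_idx = {v: j for j, v in enumerate(model.dependent_vars)}
        enz_idx = {e: j for j, e in enumerate(model.enzymes)}
        self.Pm = np.zeros((d, T))
        self.Cm = np.zeros((d, T))
        self.Eexp = np.zeros((T, len(model.enzymes)))
        for k, t in enumerate(model.terms):
            if t.produces is not None:
                self.Pm[var_idx[t.produces], k] = 1.0
            if t.consumes is not None:
                self.Cm[var_idx[t.consumes], k] = 1.0
            for e in t.enzymes:
                self.Eexp[k, enz_idx[e]] = 1.0
        # sampled kinetic-order slots
        term_idx = {t.reaction: k for k, t in enumerate(model.terms)}
        self.pairs = [
            (term_idx[r], var_idx[v], lo, hi)
            for (r, v), (lo, hi) in self.bounds.intervals
        ]
        self.iS = term_idx["S_efflux"]
        self.iG = term_idx["G_efflux"]

    @property
    def n_dependent(self) -> int:
        return self.Pm.shape[0]

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` instantiations: fluxes (n, T) and exponents (n, T, d)."""
        k = self.polytope.n_vertices
        lam = np.ones((n, 1)) if k == 1 else rng.dirichlet(np.ones(k), size=n)
        F = lam @ self.polytope.vertices
        T, d = self.Eexp.shape[0], self.n_dependent
        f_dep = np.zeros((n, T, d))
        if self.pairs:
            lo = np.array([p[2] for p in self.pairs])
            hi = np.array([p[3] for p in self.pairs])
            draws = rng.uniform(lo, hi, size=(n, len(self.pairs)))
            for p, (ti, vi, _lo, _hi) in enumerate(self.pairs):
                f_dep[:, ti, vi] = draws[:, p]
        return F, f_dep

    def solve(
        self,
        F: np.ndarray,
        f_dep: np.ndarray,
        multipliers: np.ndarray,
        criteria: ValidityCriteria = DEFAULT_CRITERIA,
    ) -> BatchSolution:
        """Solve the perturbed S-system steady states of a sampled batch."""
        mu = np.log(np.asarray(multipliers, dtype=float))
        alpha = F @ self.Pm.T                      # (n, d)
        beta = F @ self.Cm.T
        Gn = np.einsum("nk,ik,nkj->nij", F, self.Pm, f_dep) / alpha[..., None]
        Hn = np.einsum("nk,ik,nkj->nij", F, self.Cm, f_dep) / beta[..., None]
        GE = np.einsum("nk,ik,ke->nie", F, self.Pm, self.Eexp) / alpha[..., None]
        HE = np.einsum("nk,ik,ke->nie", F, self.Cm, self.Eexp) / beta[..., None]
        A = Gn - Hn
        rhs = (HE - GE) @ mu

        with np.errstate(all="ignore"):
            cond = np.linalg.cond(A)
        degenerate = ~np.isfinite(cond) | (cond > criteria.cond_limit)
        A_safe = A.copy()
        A_safe[degenerate] = np.eye(A.shape[-1])
        y = np.linalg.solve(A_safe, rhs[..., None])[..., 0]
        ill = np.max(np.abs(y), axis=1) > math.log(criteria.fold_limit)
        ill &= ~degenerate
        y = y.copy()
        y[degenerate] = np.nan

        log_factor = (
            np.einsum("nj,nj->n", f_dep[:, self.iS, :], y)
            - np.einsum("nj,nj->n", f_dep[:, self.iG, :], y)
            + (self.Eexp[self.iS] - self.Eexp[self.iG]) @ mu
        )
        with np.errstate(all="ignore"):
            sg = self.rho_wt * np.exp(log_factor)
        return BatchSolution(y=y, sg=sg, ill_behaved=ill, degenerate=degenerate)

    def run(
        self,
        scenario_set: ScenarioSet,
        n: int,
        rng: np.random.Generator,
        criteria: ValidityCriteria = DEFAULT_CRITERIA,
    ) -> dict[str, BatchSolution]:
        """Sample one ensemble and solve it under every scenario entry."""
        F, f_dep = self.sample(n, rng)
        out = {}
        for entry in scenario_set.entries:
            mult = entry.to_perturbation().multipliers(
                self.model.enzymes, hierarchical=self.design.hierarchical
            )
            out[entry.name] = self.solve(F, f_dep, mult, criteria)
        return out


def evaluate_instantiation(
    predictions: Mapping[str, float | None],
    scenario_set: ScenarioSet,
    criteria: ValidityCriteria = DEFAULT_CRITERIA,
) -> str:
    """Classify one instantiation's S/G predictions against the observations.

    ``predictions`` maps scenario name to predicted S/G ratio, with ``None``
    (or NaN) marking lines where the instantiation was ill-behaved or
    degenerate.  Raises ``KeyError`` if a scenario prediction is missing.
    """
    preds = {}
    for entry in scenario_set.entries:
        p = predictions[entry.name]
        if p is None or not np.isfinite(p):
            return VERDICT_ILL_BEHAVED
        preds[entry.name] = float(p)

    rho = scenario_set.rho_wt
    qual_ok = True
    for entry in scenario_set.qualitative:
        p = preds[entry.name]
        if entry.direction == "down":
            qual_ok &= p < (1.0 - criteria.qual_margin) * rho
        else:
            qual_ok &= p > (1.0 + criteria.qual_margin) * rho

    quant = scenario_set.quantitative
    if quant:
        errors = np.array([preds[e.name] - e.observed_sg for e in quant])
        mse_ok = float(np.mean(errors**2)) < criteria.mse_threshold
        rel_ok = all(
            abs(preds[e.name] - e.observed_sg) / e.observed_sg <= criteria.relaxed_pct
            for e in quant
        )
    else:
        mse_ok = rel_ok = True

    if qual_ok and mse_ok:
        return VERDICT_VALID
    if qual_ok and rel_ok:
        return VERDICT_VALID_RELAXED_ONLY
    return VERDICT_INVALID


@dataclass
class DesignScreenResult:
    """Ensemble outcome for one design."""

    design: Design
    n_sampled: int
    n_ill_behaved: int
    n_degenerate: int
    Q: int
    Q_prime: int
    valid_records: pd.DataFrame = field(repr=False)

    @property
    def n_behaved(self) -> int:
        return self.n_sampled - self.n_ill_behaved - self.n_degenerate


def _vector_verdicts(
    solutions: Mapping[str, BatchSolution],
    scenario_set: ScenarioSet,
    criteria: ValidityCriteria,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized evaluation; returns (valid, relaxed_valid, ill, degenerate)."""
    names = scenario_set.names
    degenerate = np.any([solutions[s].degenerate for s in names], axis=0)
    ill = np.any([solutions[s].ill_behaved for s in names], axis=0) & ~degenerate
    behaved = ~(ill | degenerate)

    rho = scenario_set.rho_wt
    qual_ok = behaved.copy()
    for entry in scenario_set.qualitative:
        sg = solutions[entry.name].sg
        with np.errstate(invalid="ignore"):
            if entry.direction == "down":
                qual_ok &= sg < (1.0 - criteria.qual_margin) * rho
            else:
                qual_ok &= sg > (1.0 + criteria.qual_margin) * rho

    quant = scenario_set.quantitative
    if quant:
        with np.errstate(all="ignore"):
            err = np.stack(
                [solutions[e.name].sg - e.observed_sg for e in quant], axis=1
            )
            err = np.where(np.isfinite(err), err, np.inf)
            mse_ok = np.mean(err**2, axis=1) < criteria.mse_threshold
            rel_ok = np.all(
                np.abs(err) / np.array([e.observed_sg for e in quant])
                <= criteria.relaxed_pct,
                axis=1,
            )
    else:
        mse_ok = rel_ok = np.ones_like(behaved)

    valid = behaved & qual_ok & mse_ok
    relaxed = behaved & qual_ok & (mse_ok | rel_ok)
    return valid, relaxed, ill, degenerate


def screen_design(
    design: Design,
    scenario_set: ScenarioSet,
    n: int,
    seed: int,
    criteria: ValidityCriteria = DEFAULT_CRITERIA,
    scaffold: Scaffold | None = None,
    bounds: KineticOrderBounds | None = None,
    keep_records: str = "valid",
) -> DesignScreenResult:
    """Screen one design with an ensemble of ``n`` random instantiations.

    Sampling is seeded deterministically from ``(seed, design)`` so results
    do not depend on which other designs are screened alongside.
    ``keep_records`` selects which instantiations populate the records table
    (``"valid"``, ``"relaxed"`` or ``"none"``).
    """
    if n < 1:
        raise ValueError("ensemble size n must be >= 1")
    ensemble = DesignEnsemble(design, scenario_set.rho_wt, scaffold, bounds)
    rng = np.random.default_rng(design_seed_sequence(seed, design))
    solutions = ensemble.run(scenario_set, n, rng, criteria)
    valid, relaxed, ill, degenerate = _vector_verdicts(
        solutions, scenario_set, criteria
    )

    if keep_records == "none":
        records = pd.DataFrame()
    else:
        mask = relaxed if keep_records == "relaxed" else valid
        idx = np.flatnonzero(mask)
        cols: dict[str, np.ndarray] = {
            "design": np.repeat(design.id, idx.size),
            "instantiation": idx,
        }
        for name in scenario_set.names:
            cols[f"sg_{name}"] = solutions[name].sg[idx]
        for name in scenario_set.names:
            for j, var in enumerate(ensemble.model.dependent_vars):
                cols[f"y_{name}_{var}"] = solutions[name].y[idx, j]
        records = pd.DataFrame(cols)

    return DesignScreenResult(
        design=design,
        n_sampled=n,
        n_ill_behaved=int(ill.sum()),
        n_degenerate=int(degenerate.sum()),
        Q=int(valid.sum()),
        Q_prime=int(relaxed.sum()),
        valid_records=records,
    )


def screen_all(
    designs: Sequence[Design],
    scenario_set: ScenarioSet,
    n: int,
    seed: int,
    criteria: ValidityCriteria = DEFAULT_CRITERIA,
    scaffold: Scaffold | None = None,
    keep_records: str = "valid",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Screen a design list; return (Q matrix, filled-circle matrix, records).

    The Q matrix is indexed by crosstalk pattern (rows) and topology label
    (columns); the boolean matrix marks designs with Q > 0, the analogue of
    a filled circle in a pattern-by-topology summary table.
    """
    rows = sorted({pattern_label(d.crosstalk) for d in designs},
                  key=lambda s: (s != "none", s.count("+"), s))
    cols = sorted({d.topology.label for d in designs},
                  key=lambda s: (len(s), s))
    q = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    all_records = []
    for design in designs:
        res = screen_design(
            design, scenario_set, n, seed, criteria, scaffold,
            keep_records=keep_records,
        )
        q.loc[pattern_label(design.crosstalk), design.topology.label] = res.Q
        if len(res.valid_records):
            all_records.append(res.valid_records)
    filled = q > 0
    records = (
        pd.concat(all_records, ignore_index=True) if all_records else pd.DataFrame()
    )
    return q, filled, records


def quadrant_data(
    design: Design,
    scenario_set: ScenarioSet,
    n: int,
    seed: int,
    criteria: ValidityCriteria = DEFAULT_CRITERIA,
    scaffold: Scaffold | None = None,
) -> pd.DataFrame:
    """Per-instantiation knockout predictions for quadrant plots.

    Columns: predicted S/G under the two qualitative (knockout) lines,
    behaved flag, and ``northwest`` — True iff both qualitative clauses of
    the validity screen pass (ccr1 down by more than the margin, ccr2 up by
    more than the margin).
    """
    ensemble = DesignEnsemble(design, scenario_set.rho_wt, scaffold)
    rng = np.random.default_rng(design_seed_sequence(seed, design))
    solutions = ensemble.run(scenario_set, n, rng, criteria)
    names = scenario_set.names
    degenerate = np.any([solutions[s].degenerate for s in names], axis=0)
    ill = np.any([solutions[s].ill_behaved for s in names], axis=0) & ~degenerate
    behaved = ~(ill | degenerate)

    rho = scenario_set.rho_wt
    nw = behaved.copy()
    data: dict[str, np.ndarray] = {}
    for entry in scenario_set.qualitative:
        sg = solutions[entry.name].sg
        data[f"sg_{entry.name}"] = sg
        with np.errstate(invalid="ignore"):
            if entry.direction == "down":
                nw &= sg < (1.0 - criteria.qual_margin) * rho
            else:
                nw &= sg > (1.0 + criteria.qual_margin) * rho
    data["behaved"] = behaved
    data["northwest"] = nw
    df = pd.DataFrame(data)
    df.insert(0, "design", design.id)
    return df


def summarize_metabolite(
    valid_records: pd.DataFrame, metabolite: str, scenario: str
) -> dict[str, float]:
    """Median and interquartile range of a metabolite's relative level.

    Relative level = exp(y) across valid instantiations for one scenario.
    """
    if valid_records is None or len(valid_records) == 0:
        raise ValueError("no valid records to summarize")
    col = f"y_{scenario}_{metabolite}"
    if col not in valid_records.columns:
        raise KeyError(col)
    levels = np.exp(valid_records[col].to_numpy(dtype=float))
    q1, med, q3 = np.percentile(levels, [25, 50, 75])
    return {"median": float(med), "iqr": float(q3 - q1)}
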