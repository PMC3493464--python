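"""Steady-state flux polytope: constraints, vertex enumeration, sampling.

At steady state every mass balance becomes a linear equation over the
reaction fluxes.  Together with a scale-fixing row (total influx = 1), the
wild-type S/G flux-ratio row, and strict positivity of every present flux,
the feasible steady-state flux vectors form a bounded polytope P.  Its
extreme points u_i (extreme pathways) give a concise parametric description:
every feasible flux vector is a convex combination sum_i lambda_i u_i.

Vertices are enumerated as basic feasible solutions: for every choice of
lower bounds held active that completes the equality rows to a full-rank
square system, solve and keep the solutions that satisfy all bounds.  The
problem sizes here (<= 13 fluxes, nullity <= 4) make this exhaustive scheme
exact and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .gma import GMAModel, build_gma
from .scaffold import Design, Scaffold, TopologyConfiguration, base_scaffold


class InfeasiblePolytopeError(RuntimeError):
    """The constraint set has no feasible point."""


class UnboundedPolytopeError(RuntimeError):
    """The constraint set is unbounded (missing normalization row)."""


@dataclass
class FluxConstraintSet:
    """Equality rows (balances, normalization, S/G ratio) plus lower bounds."""

    flux_ids: list[str]
    A_eq: np.ndarray
    b_eq: np.ndarray
    lower: np.ndarray
    row_labels: list[str]

    @property
    def n_fluxes(self) -> int:
        return len(self.flux_ids)

    def index(self, flux_id: str) -> int:
        return self.flux_ids.index(flux_id)


def build_constraints(
    topology: TopologyConfiguration,
    wt_sg_ratio: float,
    scaffold: Scaffold | None = None,
    epsilon: float = 1e-3,
    include_ratio_row: bool = True,
    lower_overrides: Mapping[str, float] | None = None,
) -> FluxConstraintSet:
    """Build the steady-state flux constraints for a topology.

    One balance row per dependent metabolite, a normalization row (influx
    = 1), a ratio row (V_S - rho * V_G = 0) and a lower bound of
    ``epsilon`` (relative to unit influx) on every present flux — a present
    edge with zero flux would duplicate a different topology and break the
    flux-weighted kinetic-order aggregation downstream.
    """
    if wt_sg_ratio <= 0:
        raise ValueError("wt_sg_ratio must be positive")
    scaffold = scaffold or base_scaffold()
    model = build_gma(Design(topology), scaffold)  # structure only, no crosstalk
    flux_ids = [t.reaction for t in model.terms]
    m = len(flux_ids)

    rows, rhs, labels = [], [], []
    for var in model.dependent_vars:
        row = np.zeros(m)
        for k in model.production_terms(var):
            row[k] += 1.0
        for k in model.consumption_terms(var):
            row[k] -= 1.0
        rows.append(row)
        rhs.append(0.0)
        labels.append(f"balance:{var}")

    norm = np.zeros(m)
    norm[flux_ids.index("influx")] = 1.0
    rows.append(norm)
    rhs.append(1.0)
    labels.append("normalization")

    if include_ratio_row:
        ratio = np.zeros(m)
        ratio[flux_ids.index("S_efflux")] = 1.0
        ratio[flux_ids.index("G_efflux")] = -float(wt_sg_ratio)
        rows.append(ratio)
        rhs.append(0.0)
        labels.append("sg_ratio")

    lower = np.full(m, float(epsilon))
    for fid, lo in (lower_overrides or {}).items():
        lower[flux_ids.index(fid)] = float(lo)

    return FluxConstraintSet(
        flux_ids=flux_ids,
        A_eq=np.asarray(rows, dtype=float),
        b_eq=np.asarray(rhs, dtype=float),
        lower=lower,
        row_labels=labels,
    )


@dataclass
class FluxPolytope:
    """Extreme points of a bounded flux polytope."""

    vertices: np.ndarray  # (n_vertices, m)
    flux_ids: list[str]
    dimension: int
    constraints: FluxConstraintSet

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]


def _check_feasible_bounded(cs: FluxConstraintSet) -> None:
    bounds = [(lo, None) for lo in cs.lower]
    m = cs.n_fluxes
    feas = linprog(np.zeros(m), A_eq=cs.A_eq, b_eq=cs.b_eq, bounds=bounds,
                   method="highs")
    if feas.status == 2:
        raise InfeasiblePolytopeError("flux constraint set is infeasible")
    if feas.status != 0 and feas.status != 3:
        raise RuntimeError(f"feasibility LP failed: {feas.message}")
    grow = linprog(-np.ones(m), A_eq=cs.A_eq, b_eq=cs.b_eq, bounds=bounds,
                   method="highs")
    if grow.status == 3:
        raise UnboundedPolytopeError(
            "flux constraint set is unbounded; a normalization row is missing"
        )


def enumerate_vertices(
    cs: FluxConstraintSet, dedup_tol: float = 1e-9
) -> FluxPolytope:
    """Exhaustively enumerate the extreme points of the flux polytope.

    Raises :class:`InfeasiblePolytopeError` / :class:`UnboundedPolytopeError`
    on empty or unbounded sets.  Vertices are deduplicated within
    ``dedup_tol`` (max-norm) and returned in lexicographic order.
    """
    _check_feasible_bounded(cs)
    m = cs.n_fluxes
    rank = int(np.linalg.matrix_rank(cs.A_eq))
    nullity = m - rank
    eye = np.eye(m)

    found: list[np.ndarray] = []
    for active in combinations(range(m), nullity):
        M = np.vstack([cs.A_eq, eye[list(active)]]) if active else cs.A_eq
        rhs = np.concatenate([cs.b_eq, cs.lower[list(active)]]) if active else cs.b_eq
        if np.linalg.matrix_rank(M) < m:
            continue
        x, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        if np.max(np.abs(M @ x - rhs)) > 1e-8:
            continue
        if np.any(x < cs.lower - 1e-9):
            continue
        if not any(np.max(np.abs(x - v)) <= dedup_tol for v in found):
            found.append(x)

    if not found:
        raise InfeasiblePolytopeError("no basic feasible solution found")

    V = np.array(sorted(found, key=tuple))
    dim = 0 if len(V) == 1 else int(
        np.linalg.matrix_rank(V[1:] - V[0], tol=1e-9)
    )
    return FluxPolytope(vertices=V, flux_ids=list(cs.flux_ids), dimension=dim,
                        constraints=cs)


@dataclass
class FluxSample:
    """A wild-type steady-state flux vector drawn from the polytope."""

    values: dict[str, float]
    weights: np.ndarray | None  # convex coefficients over vertices, if applicable

    def as_array(self, flux_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.values[f] for f in flux_ids])


def sample_flux_matrix(
    polytope: FluxPolytope, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` flux vectors as flat-Dirichlet convex combinations of vertices.

    Returns ``(fluxes, weights)`` with shapes (n, m) and (n, n_vertices).
    """
    k = polytope.n_vertices
    if k == 1:
        lam = np.ones((n, 1))
    else:
        lam = rng.dirichlet(np.ones(k), size=n)
    return lam @ polytope.vertices, lam


def _hit_and_run(
    polytope: FluxPolytope, rng: np.random.Generator, n_steps: int
) -> np.ndarray:
    """Approximately uniform sample over P via hit-and-run in the affine hull."""
    cs = polytope.constraints
    from scipy.linalg import null_space

    N = null_space(cs.A_eq)
    x = polytope.vertices.mean(axis=0)
    if N.shape[1] == 0:
        return x
    for _ in range(n_steps):
        d = N @ rng.standard_normal(N.shape[1])
        nrm = np.linalg.norm(d)
        if nrm < 1e-14:
            continue
        d /= nrm
        # x + t d >= lower componentwise
        with np.errstate(divide="ignore"):
            t_bounds = (cs.lower - x) / d
        t_lo = np.max(t_bounds[d > 1e-14], initial=-np.inf)
        t_hi = np.min(t_bounds[d < -1e-14], initial=np.inf)
        if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi < t_lo:
            continue
        x = x + rng.uniform(t_lo, t_hi) * d
    return x


def sample_fluxes(
    polytope: FluxPolytope,
    rng: np.random.Generator,
    method: str = "dirichlet",
    n_steps: int = 200,
) -> FluxSample:
    """Draw one wild-type flux vector from the polytope.

    ``dirichlet`` (default) draws flat-Dirichlet weights over the vertices,
    matching the convex-combination parameterisation literally; the measure
    is not uniform over P, so an approximately uniform ``hit_and_run``
    sampler is offered as an option.
    """
    if method == "dirichlet":
        F, lam = sample_flux_matrix(polytope, rng, 1)
        values = dict(zip(polytope.flux_ids, F[0]))
        return FluxSample(values=values, weights=lam[0])
    if method == "hit_and_run":
        x = _hit_and_run(polytope, rng, n_steps)
        return FluxSample(values=dict(zip(polytope.flux_ids, x)), weights=None)
    raise ValueError(f"unknown sampling method {method!r}")


def validate_flux_sample(
    sample: FluxSample | Mapping[str, float] | np.ndarray,
    cs: FluxConstraintSet,
    tol: float = 1e-9,
) -> bool:
    """True iff all equalities hold within ``tol`` and bounds within ``tol``."""
    if isinstance(sample, FluxSample):
        x = sample.as_array(cs.flux_ids)
    elif isinstance(sample, Mapping):
        x = np.array([sample[f] for f in cs.flux_ids])
    else:
        x = np.asarray(sample, dtype=float)
    if np.max(np.abs(cs.A_eq @ x - cs.b_eq)) > tol:
        return False
    return bool(np.all(x >= cs.lower - tol))


def write_polytope_tsv(polytope: FluxPolytope, path: str | Path) -> None:
    """Dump vertices as TSV (one row per vertex) for inspection."""
    lines = ["\t".join(polytope.flux_ids)]
    for v in polytope.vertices:
        lines.append("\t".join(f"{x:.12g}" for x in v))
    Path(path).write_text("\n".join(lines) + "\n")
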