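"""Symbolic Generalized Mass Action (GMA) models and kinetic-order sampling.

Every reaction in a design is a power-law term

    v_k = gamma_k * prod_j X_j^{f_kj}

over the dependent metabolites and the six enzyme activities.  Enzyme
kinetic orders are fixed at 1; substrate orders are positive; crosstalk
mechanisms add signed effector orders (activation > 0, inhibition < 0).
Rate constants stay symbolic here — they are eliminated later by
normalising to a sampled wild-type steady state.

Kinetic orders are sampled independently and uniformly from per-pair
intervals.  Defaults: substrates and activators in [0.1, 1.0], inhibitors
in [-1.0, -0.1]; substrate inhibition (mechanism M5) replaces the substrate
interval of the targeted term with the inhibitor interval.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .scaffold import (
    ENZYMES,
    MECHANISMS,
    Design,
    Scaffold,
    base_scaffold,
)

#: Variable roles within a power-law term.
ROLE_SUBSTRATE = "substrate"
ROLE_INHIBITOR = "inhibitor"
ROLE_ACTIVATOR = "activator"
ROLE_INHIBITING_SUBSTRATE = "inhibiting_substrate"

_POSITIVE_ROLES = {ROLE_SUBSTRATE, ROLE_ACTIVATOR}
_NEGATIVE_ROLES = {ROLE_INHIBITOR, ROLE_INHIBITING_SUBSTRATE}


class BoundsError(ValueError):
    """A kinetic-order interval violates its sign rule."""


@dataclass(frozen=True)
class PowerLawTerm:
    """One power-law flux: which pool it feeds/drains and who modulates it."""

    reaction: str
    produces: str | None  # dependent metabolite gaining mass (None for effluxes)
    consumes: str | None  # dependent metabolite losing mass (None for the influx)
    enzymes: tuple[str, ...] = ()
    roles: tuple[tuple[str, str], ...] = ()  # (variable, role), canonical order

    @property
    def role_map(self) -> dict[str, str]:
        return dict(self.roles)


@dataclass(frozen=True)
class GMAModel:
    """A symbolic GMA model: ordered variables plus signed term membership."""

    dependent_vars: tuple[str, ...]
    enzymes: tuple[str, ...]
    terms: tuple[PowerLawTerm, ...]
    design: Design | None = None

    def term_index(self, reaction: str) -> int:
        for i, t in enumerate(self.terms):
            if t.reaction == reaction:
                return i
        raise KeyError(reaction)

    def production_terms(self, var: str) -> list[int]:
        return [i for i, t in enumerate(self.terms) if t.produces == var]

    def consumption_terms(self, var: str) -> list[int]:
        return [i for i, t in enumerate(self.terms) if t.consumes == var]

    def validate(self) -> None:
        """Every dependent pool needs at least one producer and one consumer."""
        for v in self.dependent_vars:
            if not self.production_terms(v):
                raise ValueError(f"dependent variable {v} has no production term")
            if not self.consumption_terms(v):
                raise ValueError(f"dependent variable {v} has no consumption term")


def build_gma(design: Design, scaffold: Scaffold | None = None) -> GMAModel:
    """Construct the symbolic GMA model for a design.

    One term per reaction present in the topology (a constant influx into
    caffeoyl CoA, one term per enzymatic step, one efflux per monomer sink).
    Crosstalk mechanisms add signed effector exponents to their target term;
    a mechanism whose target reaction is absent is vacuous and only warned
    about.  Pure function of the design: no numeric parameters yet.
    """
    scaffold = scaffold or base_scaffold()
    dep_vars = design.topology.dependent_variables(scaffold)
    dep_set = set(dep_vars)

    vacuous = design.vacuous_mechanisms()
    for m in sorted(vacuous):
        warnings.warn(
            f"mechanism {m} is vacuous: its target reaction "
            f"{MECHANISMS[m].target_reaction} is absent from configuration "
            f"{design.topology.label}",
            stacklevel=2,
        )

    terms = []
    for rid in design.topology.reaction_ids(scaffold):
        rxn = scaffold.reaction(rid)
        roles: list[tuple[str, str]] = []
        substrate_role = ROLE_SUBSTRATE
        effectors: list[tuple[str, str]] = []
        for m in sorted(design.crosstalk - vacuous):
            mech = MECHANISMS[m]
            if mech.target_reaction != rid:
                continue
            if mech.substrate_inhibition:
                substrate_role = ROLE_INHIBITING_SUBSTRATE
            else:
                effectors.append(
                    (mech.effector, ROLE_ACTIVATOR if mech.sign > 0 else ROLE_INHIBITOR)
                )
        if rxn.substrate is not None:
            roles.append((rxn.substrate, substrate_role))
        roles.extend(effectors)
        terms.append(
            PowerLawTerm(
                reaction=rid,
                produces=rxn.product if rxn.product in dep_set else None,
                consumes=rxn.substrate,
                enzymes=rxn.enzymes,
                roles=tuple(roles),
            )
        )

    model = GMAModel(
        dependent_vars=dep_vars,
        enzymes=scaffold.enzymes,
        terms=tuple(terms),
        design=design,
    )
    model.validate()
    return model


@dataclass(frozen=True)
class KineticOrderBounds:
    """Closed admissible interval per (reaction, variable) pair.

    Enzyme kinetic orders are fixed at 1 and carry no interval.
    """

    intervals: tuple[tuple[tuple[str, str], tuple[float, float]], ...]

    def as_dict(self) -> dict[tuple[str, str], tuple[float, float]]:
        return dict(self.intervals)

    def __getitem__(self, key: tuple[str, str]) -> tuple[float, float]:
        return self.as_dict()[key]

    def __len__(self) -> int:
        return len(self.intervals)


def _check_interval(role: str, lo: float, hi: float, key: tuple[str, str]) -> None:
    if lo > hi:
        raise BoundsError(f"empty interval for {key}: [{lo}, {hi}]")
    if role in _POSITIVE_ROLES and not (0.0 < lo and hi <= 1.0):
        raise BoundsError(
            f"{role} interval for {key} must lie in (0, 1], got [{lo}, {hi}]"
        )
    if role in _NEGATIVE_ROLES and not (-1.0 <= lo and hi < 0.0):
        raise BoundsError(
            f"{role} interval for {key} must lie in [-1, 0), got [{lo}, {hi}]"
        )


def default_bounds(
    model: GMAModel,
    substrate_range: tuple[float, float] = (0.1, 1.0),
    inhibitor_range: tuple[float, float] = (-1.0, -0.1),
    activator_range: tuple[float, float] = (0.1, 1.0),
    m5_range: tuple[float, float] | None = None,
    overrides: Mapping[tuple[str, str], tuple[float, float]] | None = None,
) -> KineticOrderBounds:
    """Build sign-constrained kinetic-order intervals for a model.

    ``m5_range`` controls the apparent kinetic order of an inhibiting
    substrate (defaults to ``inhibitor_range``).  ``overrides`` replaces the
    interval of specific (reaction, variable) pairs; an override violating
    the pair's sign rule raises :class:`BoundsError`.
    """
    role_range = {
        ROLE_SUBSTRATE: substrate_range,
        ROLE_ACTIVATOR: activator_range,
        ROLE_INHIBITOR: inhibitor_range,
        ROLE_INHIBITING_SUBSTRATE: m5_range or inhibitor_range,
    }
    overrides = dict(overrides or {})
    intervals = []
    for term in model.terms:
        for var, role in term.roles:
            key = (term.reaction, var)
            lo, hi = overrides.pop(key, role_range[role])
            _check_interval(role, float(lo), float(hi), key)
            intervals.append((key, (float(lo), float(hi))))
    if overrides:
        raise BoundsError(f"overrides for unknown pairs: {sorted(overrides)}")
    return KineticOrderBounds(tuple(intervals))


@dataclass(frozen=True)
class KineticOrderSample:
    """One realisation of all sampled kinetic orders."""

    values: tuple[tuple[tuple[str, str], float], ...]

    def as_dict(self) -> dict[tuple[str, str], float]:
        return dict(self.values)

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.as_dict()[key]


def sample_kinetic_orders(
    bounds: KineticOrderBounds, rng: np.random.Generator
) -> KineticOrderSample:
    """Draw each kinetic order independently and uniformly from its interval."""
    out = []
    for key, (lo, hi) in bounds.intervals:
        if lo > hi:
            raise BoundsError(f"empty interval for {key}")
        out.append((key, lo if lo == hi else float(rng.uniform(lo, hi))))
    return KineticOrderSample(tuple(out))


# ---------------------------------------------------------------------------
# JSON round trip

def model_to_json(model: GMAModel, bounds: KineticOrderBounds | None = None) -> str:
    doc = {
        "dependent_vars": list(model.dependent_vars),
        "enzymes": list(model.enzymes),
        "terms": [
            {
                "reaction": t.reaction,
                "produces": t.produces,
                "consumes": t.consumes,
                "enzymes": list(t.enzymes),
                "roles": [list(r) for r in t.roles],
            }
            for t in model.terms
        ],
    }
    if bounds is not None:
        doc["bounds"] = [
            {"reaction": k[0], "variable": k[1], "lo": lo, "hi": hi}
            for k, (lo, hi) in bounds.intervals
        ]
    return json.dumps(doc, indent=2)


def model_from_json(text: str) -> tuple[GMAModel, KineticOrderBounds | None]:
    doc = json.loads(text)
    model = GMAModel(
        dependent_vars=tuple(doc["dependent_vars"]),
        enzymes=tuple(doc["enzymes"]),
        terms=tuple(
            PowerLawTerm(
                reaction=t["reaction"],
                produces=t["produces"],
                consumes=t["consumes"],
                enzymes=tuple(t["enzymes"]),
                roles=tuple((v, r) for v, r in t["roles"]),
            )
            for t in doc["terms"]
        ),
    )
    bounds = None
    if "bounds" in doc:
        bounds = KineticOrderBounds(
            tuple(
                ((b["reaction"], b["variable"]), (b["lo"], b["hi"]))
                for b in doc["bounds"]
            )
        )
    return model, bounds
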