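"""Scenario configuration: observed data, perturbation definitions, YAML I/O.

A scenario set bundles the wild-type S/G flux ratio with four perturbation
lines: two quantitative ones (CCoAOMT- and COMT-down-regulated alfalfa,
carrying observed S/G ratios) and two qualitative ones (ccr1 and ccr2
*M. truncatula* knockouts, carrying only a direction of change).  Every
value is tagged with a provenance — ``literature``, ``placeholder`` or
``synthetic`` — and placeholder values trigger a warning on load: the
shipped defaults are stand-ins to be replaced with values from the original
transgenic datasets before any literal comparison with published screens.

A synthetic-scenario generator produces observation sets from a known
ground-truth design so that the full screening pipeline can be exercised
and validated without any external data.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .gma import build_gma, default_bounds, sample_kinetic_orders
from .polytope import build_constraints, enumerate_vertices, sample_fluxes
from .scaffold import Design, Scaffold, base_scaffold
from .steady_state import (
    PerturbationScenario,
    derive_ssystem,
    normalize_instance,
    solve_steady_state,
)

logger = logging.getLogger(__name__)

PROVENANCES = ("literature", "placeholder", "synthetic")
DIRECTIONS = ("down", "up")

#: The four perturbation lines every scenario file must define.
REQUIRED_SCENARIOS = ("CCoAOMT-down", "COMT-down", "ccr1-KO", "ccr2-KO")


class ScenarioSchemaError(ValueError):
    """A scenario file violates the documented schema."""


@dataclass
class ScenarioEntry:
    """One perturbation line with its observation (value or direction)."""

    name: str
    enzyme_multipliers: dict[str, float]
    hierarchical_multipliers: dict[str, float] = field(default_factory=dict)
    observed_sg: float | None = None
    direction: str | None = None
    provenance: str = "placeholder"

    def __post_init__(self) -> None:
        for key, mult in {**self.enzyme_multipliers,
                          **self.hierarchical_multipliers}.items():
            if mult <= 0:
                raise ScenarioSchemaError(
                    f"scenario {self.name!r}: multiplier for {key} must be > 0"
                )
        if self.observed_sg is not None and self.observed_sg <= 0:
            raise ScenarioSchemaError(
                f"scenario {self.name!r}: observed_sg must be > 0"
            )
        if self.direction is not None and self.direction not in DIRECTIONS:
            raise ScenarioSchemaError(
                f"scenario {self.name!r}: direction must be one of {DIRECTIONS}"
            )
        if (self.observed_sg is None) == (self.direction is None):
            raise ScenarioSchemaError(
                f"scenario {self.name!r} must carry exactly one of "
                "observed_sg (quantitative) or direction (qualitative)"
            )
        if self.provenance not in PROVENANCES:
            raise ScenarioSchemaError(
                f"scenario {self.name!r}: provenance must be one of {PROVENANCES}"
            )

    @property
    def is_quantitative(self) -> bool:
        return self.observed_sg is not None

    def to_perturbation(self) -> PerturbationScenario:
        return PerturbationScenario(
            name=self.name,
            enzyme_multipliers=dict(self.enzyme_multipliers),
            hierarchical_multipliers=dict(self.hierarchical_multipliers),
        )


@dataclass
class ScenarioSet:
    """Wild-type S/G ratio plus the four perturbation lines."""

    rho_wt: float
    entries: list[ScenarioEntry]
    rho_provenance: str = "placeholder"

    def __post_init__(self) -> None:
        if self.rho_wt <= 0:
            raise ScenarioSchemaError("rho_wt must be > 0")
        if self.rho_provenance not in PROVENANCES:
            raise ScenarioSchemaError(
                f"rho_wt provenance must be one of {PROVENANCES}"
            )
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ScenarioSchemaError("duplicate scenario names")

    def entry(self, name: str) -> ScenarioEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def quantitative(self) -> list[ScenarioEntry]:
        return [e for e in self.entries if e.is_quantitative]

    @property
    def qualitative(self) -> list[ScenarioEntry]:
        return [e for e in self.entries if not e.is_quantitative]

    def placeholder_values(self) -> list[str]:
        tagged = [e.name for e in self.entries if e.provenance == "placeholder"]
        if self.rho_provenance == "placeholder":
            tagged.insert(0, "rho_wt")
        return tagged


def default_scenario_set() -> ScenarioSet:
    """The shipped default scenario set.

    The CCoAOMT-down multiplier (0.24) reflects the reported ~4.2-fold
    reduction of methyltransferase activity against caffeoyl CoA in the
    down-regulated alfalfa line; everything else quantitative is a flagged
    placeholder to be replaced by values from the original datasets.
    Knockouts are simulated as 5% residual activity, and hierarchical
    regulation of the ccr2 line raises CCR1 and CCoAOMT 1.5-fold.
    """
    return ScenarioSet(
        rho_wt=0.5,
        rho_provenance="placeholder",
        entries=[
            ScenarioEntry(
                name="CCoAOMT-down",
                enzyme_multipliers={"CCoAOMT": 0.24},
                observed_sg=0.75,
                provenance="placeholder",
            ),
            ScenarioEntry(
                name="COMT-down",
                enzyme_multipliers={"COMT": 0.1},
                observed_sg=0.15,
                provenance="placeholder",
            ),
            ScenarioEntry(
                name="ccr1-KO",
                enzyme_multipliers={"CCR1": 0.05},
                direction="down",
                provenance="literature",
            ),
            ScenarioEntry(
                name="ccr2-KO",
                enzyme_multipliers={"CCR2": 0.05},
                hierarchical_multipliers={"CCR1": 1.5, "CCoAOMT": 1.5},
                direction="up",
                provenance="literature",
            ),
        ],
    )


# ---------------------------------------------------------------------------
# YAML I/O

def _entry_to_doc(e: ScenarioEntry) -> dict:
    doc: dict = {"enzyme_multipliers": dict(e.enzyme_multipliers)}
    if e.hierarchical_multipliers:
        doc["hierarchical_multipliers"] = dict(e.hierarchical_multipliers)
    if e.observed_sg is not None:
        doc["observed_sg"] = float(e.observed_sg)
    if e.direction is not None:
        doc["direction"] = e.direction
    doc["provenance"] = e.provenance
    return doc


def scenario_set_to_yaml(sset: ScenarioSet) -> str:
    doc = {
        "rho_wt": float(sset.rho_wt),
        "rho_provenance": sset.rho_provenance,
        "scenarios": {e.name: _entry_to_doc(e) for e in sset.entries},
    }
    return yaml.safe_dump(doc, sort_keys=False)


def save_scenarios(sset: ScenarioSet, path: str | Path) -> None:
    Path(path).write_text(scenario_set_to_yaml(sset))


def _parse_entry(name: str, doc: dict) -> ScenarioEntry:
    if not isinstance(doc, dict):
        raise ScenarioSchemaError(f"scenario {name!r} must be a mapping")
    unknown = set(doc) - {
        "enzyme_multipliers", "hierarchical_multipliers",
        "observed_sg", "direction", "provenance",
    }
    if unknown:
        raise ScenarioSchemaError(
            f"scenario {name!r}: unknown keys {sorted(unknown)}"
        )
    if "enzyme_multipliers" not in doc:
        raise ScenarioSchemaError(
            f"scenario {name!r}: missing key 'enzyme_multipliers'"
        )
    return ScenarioEntry(
        name=name,
        enzyme_multipliers={k: float(v) for k, v in doc["enzyme_multipliers"].items()},
        hierarchical_multipliers={
            k: float(v) for k, v in doc.get("hierarchical_multipliers", {}).items()
        },
        observed_sg=None if doc.get("observed_sg") is None else float(doc["observed_sg"]),
        direction=doc.get("direction"),
        provenance=doc.get("provenance", "placeholder"),
    )


def parse_scenarios(text: str) -> ScenarioSet:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ScenarioSchemaError("scenario file must be a YAML mapping")
    for key in ("rho_wt", "scenarios"):
        if key not in doc:
            raise ScenarioSchemaError(f"missing top-level key {key!r}")
    scenarios = doc["scenarios"]
    if not isinstance(scenarios, dict):
        raise ScenarioSchemaError("'scenarios' must be a mapping of named entries")
    for required in REQUIRED_SCENARIOS:
        if required not in scenarios:
            raise ScenarioSchemaError(f"missing scenario entry {required!r}")
    entries = [_parse_entry(name, sub) for name, sub in scenarios.items()]
    sset = ScenarioSet(
        rho_wt=float(doc["rho_wt"]),
        rho_provenance=doc.get("rho_provenance", "placeholder"),
        entries=entries,
    )
    tagged = sset.placeholder_values()
    if tagged:
        msg = (f"scenario values tagged as placeholders: {tagged}; replace them "
               "with literature values before literal comparisons")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return sset


def load_scenarios(path: str | Path) -> ScenarioSet:
    """Parse and validate a scenario YAML file; warn on placeholder values."""
    return parse_scenarios(Path(path).read_text())


def scenario_hash(sset: ScenarioSet) -> str:
    """Stable content hash of a scenario set (for run manifests)."""
    return hashlib.sha256(scenario_set_to_yaml(sset).encode()).hexdigest()


# ---------------------------------------------------------------------------
# Synthetic ground-truth scenarios

def generate_synthetic_scenario(
    true_design: Design,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    rho_wt: float = 0.5,
    scaffold: Scaffold | None = None,
    qual_margin: float = 0.05,
    epsilon: float = 1e-3,
    max_retries: int = 200,
) -> ScenarioSet:
    """Synthesize an observation set from one instantiation of a known design.

    Samples wild-type fluxes and kinetic orders for ``true_design``, solves
    the four perturbation lines, and emits the predicted S/G ratios as
    observations: quantitative values (optionally perturbed by multiplicative
    lognormal noise of scale ``noise_sd``) for the alfalfa-style
    down-regulation lines, directions for the knockout lines.  Instantiations
    that are ill-behaved in any line, or whose knockout responses fall inside
    the qualitative margin (no scorable direction), are resampled up to
    ``max_retries`` times.
    """
    scaffold = scaffold or base_scaffold()
    template = default_scenario_set()
    model = build_gma(true_design, scaffold)
    cs = build_constraints(true_design.topology, rho_wt, scaffold, epsilon=epsilon)
    polytope = enumerate_vertices(cs)
    bounds = default_bounds(model)

    for _attempt in range(max_retries):
        flux = sample_fluxes(polytope, rng)
        orders = sample_kinetic_orders(bounds, rng)
        inst = normalize_instance(model, flux, orders)
        ssys = derive_ssystem(inst)
        predictions: dict[str, float] = {}
        ok = True
        for entry in template.entries:
            sol = solve_steady_state(
                ssys, entry.to_perturbation(),
                hierarchical=true_design.hierarchical, rho_wt=rho_wt,
            )
            if not sol.ok or sol.sg_ratio is None:
                ok = False
                break
            predictions[entry.name] = sol.sg_ratio
        if not ok:
            continue
        scorable = all(
            abs(predictions[e.name] / rho_wt - 1.0) > qual_margin
            for e in template.qualitative
        )
        if not scorable:
            continue

        entries = []
        for e in template.entries:
            pred = predictions[e.name]
            if e.is_quantitative:
                observed = pred * float(np.exp(rng.normal(0.0, noise_sd))) \
                    if noise_sd > 0 else pred
                entries.append(ScenarioEntry(
                    name=e.name,
                    enzyme_multipliers=dict(e.enzyme_multipliers),
                    hierarchical_multipliers=dict(e.hierarchical_multipliers),
                    observed_sg=observed,
                    provenance="synthetic",
                ))
            else:
                entries.append(ScenarioEntry(
                    name=e.name,
                    enzyme_multipliers=dict(e.enzyme_multipliers),
                    hierarchical_multipliers=dict(e.hierarchical_multipliers),
                    direction="down" if pred < rho_wt else "up",
                    provenance="synthetic",
                ))
        return ScenarioSet(rho_wt=rho_wt, rho_provenance="synthetic",
                           entries=entries)
    raise RuntimeError(
        f"no scorable instantiation of design {true_design.id} found in "
        f"{max_retries} attempts"
    )
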