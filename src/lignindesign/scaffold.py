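"""Pathway scaffold and design enumeration for monolignol biosynthesis.

The scaffold covers the segment of the lignin biosynthetic pathway in
*Medicago* that controls the partitioning of carbon between guaiacyl (G),
5-hydroxyguaiacyl (5HG) and syringyl (S) lignin subunits: from caffeoyl CoA
through the aldehyde/CoA-ester intermediates to the three monomer effluxes.

Two putative enzyme complexes act as metabolic channels:

* the **G channel** (CCR1·CAD), converting feruloyl CoA directly to
  coniferyl alcohol, and
* the **S channel** (COMT·F5H), converting caffeyl aldehyde directly to
  5-hydroxyconiferyl aldehyde.

Six reactions are *optional*: the two channels plus the four free-enzyme
routes through coniferyl aldehyde.  Toggling them yields 2^6 = 64 candidate
topologies, of which only those that neither strand mass in an intermediate
pool nor carry dead edges are admissible; the admissible set has exactly 19
members, labelled A (all six edges) through S (channels only).

A *design* couples a topological configuration with a pattern of metabolite-
level crosstalk between the CCR2/COMT and CCoAOMT/CCR1 branches (mechanisms
M1-M5) and optionally with hierarchical regulation (the *ccr2* knockout also
raising CCR1 and CCoAOMT activity).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

ENZYMES: tuple[str, ...] = ("CCR1", "CCR2", "CCoAOMT", "COMT", "F5H", "CAD")

#: Efflux sinks; lignin subunits are not dynamic pools.
SINKS: tuple[str, ...] = ("G", "5HG", "S")

#: Canonical order of the six toggleable reactions (bit order of topology masks).
OPTIONAL_EDGES: tuple[str, ...] = (
    "free_COMT",
    "S_channel",
    "free_CCR1",
    "G_channel",
    "free_CAD",
    "free_F5H",
)

#: Optional edges incident to coniferyl aldehyde (X4).
_X4_PRODUCERS = ("free_COMT", "free_CCR1")
_X4_CONSUMERS = ("free_CAD", "free_F5H")


@dataclass(frozen=True)
class Metabolite:
    """A pathway species; sinks (lignin subunits) are not dependent variables."""

    id: str
    name: str
    is_dependent: bool = True


@dataclass(frozen=True)
class Reaction:
    """A single enzymatic step or efflux, modelled later as one power-law flux."""

    id: str
    substrate: str | None  # None for the pathway influx
    product: str
    enzymes: tuple[str, ...] = ()
    is_channel: bool = False
    is_optional: bool = False


METABOLITES: tuple[Metabolite, ...] = (
    Metabolite("X1", "caffeoyl CoA"),
    Metabolite("X2", "caffeyl aldehyde"),
    Metabolite("X3", "feruloyl CoA"),
    Metabolite("X4", "coniferyl aldehyde"),
    Metabolite("X5", "coniferyl alcohol"),
    Metabolite("X6", "5-hydroxyconiferyl aldehyde"),
    Metabolite("X7", "sinapaldehyde"),
    Metabolite("G", "guaiacyl lignin subunit", is_dependent=False),
    Metabolite("5HG", "5-hydroxyguaiacyl lignin subunit", is_dependent=False),
    Metabolite("S", "syringyl lignin subunit", is_dependent=False),
)

# 5-hydroxyconiferyl alcohol and sinapyl alcohol are lumped into the 5HG and
# S efflux steps (hence those carry CAD); methylation of caffeoyl CoA is a
# single CCoAOMT-dominated flux and methylation of caffeyl aldehyde a single
# COMT-dominated flux.
REACTIONS: tuple[Reaction, ...] = (
    Reaction("influx", None, "X1"),
    Reaction("ccr2", "X1", "X2", ("CCR2",)),
    Reaction("ccoaomt", "X1", "X3", ("CCoAOMT",)),
    Reaction("free_COMT", "X2", "X4", ("COMT",), is_optional=True),
    Reaction("S_channel", "X2", "X6", ("COMT", "F5H"), is_channel=True, is_optional=True),
    Reaction("free_CCR1", "X3", "X4", ("CCR1",), is_optional=True),
    Reaction("G_channel", "X3", "X5", ("CCR1", "CAD"), is_channel=True, is_optional=True),
    Reaction("free_CAD", "X4", "X5", ("CAD",), is_optional=True),
    Reaction("free_F5H", "X4", "X6", ("F5H",), is_optional=True),
    Reaction("G_efflux", "X5", "G"),
    Reaction("5HG_efflux", "X6", "5HG", ("CAD",)),
    Reaction("comt_5oh", "X6", "X7", ("COMT",)),
    Reaction("S_efflux", "X7", "S", ("CAD",)),
)


@dataclass(frozen=True)
class Scaffold:
    """The fixed reaction scaffold from which all configurations are derived."""

    metabolites: tuple[Metabolite, ...] = METABOLITES
    reactions: tuple[Reaction, ...] = REACTIONS

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def dependent_metabolites(self) -> tuple[Metabolite, ...]:
        return tuple(m for m in self.metabolites if m.is_dependent)

    @property
    def enzymes(self) -> tuple[str, ...]:
        present = {e for r in self.reactions for e in r.enzymes}
        return tuple(e for e in ENZYMES if e in present)

    @property
    def optional_edges(self) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.is_optional)

    @property
    def channels(self) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.is_channel)


def base_scaffold() -> Scaffold:
    """Return the full pathway scaffold (superset of every configuration)."""
    return Scaffold()


@dataclass(frozen=True)
class TopologyConfiguration:
    """One admissible on/off assignment of the six optional reactions.

    ``present_edges`` is a 6-bit tuple over :data:`OPTIONAL_EDGES`.
    """

    present_edges: tuple[int, ...]
    label: str

    def __post_init__(self) -> None:
        if len(self.present_edges) != len(OPTIONAL_EDGES):
            raise ValueError("present_edges must have one bit per optional edge")

    def has(self, edge: str) -> bool:
        return bool(self.present_edges[OPTIONAL_EDGES.index(edge)])

    @property
    def n_edges(self) -> int:
        return int(sum(self.present_edges))

    @property
    def includes_coniferyl_aldehyde(self) -> bool:
        return any(self.has(e) for e in _X4_PRODUCERS + _X4_CONSUMERS)

    @property
    def n_dependent(self) -> int:
        return 7 if self.includes_coniferyl_aldehyde else 6

    def dependent_variables(self, scaffold: Scaffold | None = None) -> tuple[str, ...]:
        scaffold = scaffold or base_scaffold()
        ids = [m.id for m in scaffold.dependent_metabolites]
        if not self.includes_coniferyl_aldehyde:
            ids.remove("X4")
        return tuple(ids)

    def reaction_ids(self, scaffold: Scaffold | None = None) -> tuple[str, ...]:
        scaffold = scaffold or base_scaffold()
        out = []
        for r in scaffold.reactions:
            if r.is_optional and not self.has(r.id):
                continue
            out.append(r.id)
        return tuple(out)

    @property
    def mask(self) -> int:
        """Integer form of the edge bits (bit 0 = first canonical edge)."""
        return sum(b << i for i, b in enumerate(self.present_edges))


def edge_constraints_satisfied(bits: Sequence[int], bidirectional: bool = True) -> bool:
    """Check the admissibility rules for one on/off assignment of edges.

    Rules: caffeyl aldehyde and feruloyl CoA each need an outgoing edge,
    coniferyl alcohol and 5-hydroxyconiferyl aldehyde each an incoming edge
    (otherwise mass strands in an intermediate pool); and coniferyl aldehyde,
    if produced by a free route, must be consumed by one.  With
    ``bidirectional`` (the default) the converse also holds: a consuming free
    route without a producer would be a dead edge indistinguishable from its
    absence.
    """
    c, s, r, g, d, f = (bool(b) for b in bits)
    if not (c or s):  # caffeyl aldehyde out-degree
        return False
    if not (r or g):  # feruloyl CoA out-degree
        return False
    if not (g or d):  # coniferyl alcohol in-degree
        return False
    if not (s or f):  # 5-hydroxyconiferyl aldehyde in-degree
        return False
    produced = c or r
    consumed = d or f
    if produced and not consumed:
        return False
    if bidirectional and consumed and not produced:
        return False
    return True


def _labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    out = []
    for i in range(n):
        if i < len(letters):
            out.append(letters[i])
        else:
            out.append(letters[(i // 26) - 1] + letters[i % 26])
    return out


def enumerate_configurations(
    scaffold: Scaffold | None = None, bidirectional: bool = True
) -> list[TopologyConfiguration]:
    """Enumerate all admissible topological configurations.

    Ordering is canonical and stable: descending number of optional edges,
    ties broken by ascending lexicographic order of the edge-bit tuple.
    Labels A, B, C, ... are assigned in that order; A carries all six edges
    and the channels-only configuration is last (S under the default rules).
    """
    scaffold = scaffold or base_scaffold()
    if len(scaffold.optional_edges) != len(OPTIONAL_EDGES):
        raise ValueError("scaffold must expose exactly the six optional edges")
    admissible = [
        bits
        for bits in product((0, 1), repeat=len(OPTIONAL_EDGES))
        if edge_constraints_satisfied(bits, bidirectional=bidirectional)
    ]
    admissible.sort(key=lambda b: (-sum(b), b))
    labels = _labels(len(admissible))
    return [TopologyConfiguration(bits, lab) for bits, lab in zip(admissible, labels)]


@dataclass(frozen=True)
class CrosstalkMechanism:
    """A metabolite-level activation/inhibition acting on one reaction.

    ``substrate_inhibition`` marks the case where the effector is the
    reaction's own substrate, so the mechanism flips the sign of the
    substrate's apparent kinetic order rather than adding a new factor.
    """

    id: str
    target_reaction: str
    effector: str
    sign: int
    substrate_inhibition: bool = False


MECHANISMS: dict[str, CrosstalkMechanism] = {
    # feruloyl CoA competitively inhibits the CCR2 step
    "M1": CrosstalkMechanism("M1", "ccr2", "X3", -1),
    # caffeyl aldehyde weakly inhibits the 3-O-methylation of caffeoyl CoA
    "M2": CrosstalkMechanism("M2", "ccoaomt", "X2", -1),
    # caffeyl aldehyde activates the 3-O-methylation of caffeoyl CoA
    "M3": CrosstalkMechanism("M3", "ccoaomt", "X2", +1),
    # caffeoyl CoA competitively inhibits the 3-O-methylation of caffeyl aldehyde
    "M4": CrosstalkMechanism("M4", "free_COMT", "X1", -1),
    # caffeyl aldehyde inhibits its own 3-O-methylation (substrate inhibition)
    "M5": CrosstalkMechanism("M5", "free_COMT", "X2", -1, substrate_inhibition=True),
}

#: The four independent inhibition mechanisms whose subsets form the
#: 2^4 = 16 crosstalk patterns of the inhibition family.
INHIBITION_FAMILY: tuple[str, ...] = ("M1", "M2", "M4", "M5")

CROSSTALK_FAMILIES = ("none", "inhibition", "activation")


def _check_pattern(pattern: Iterable[str]) -> frozenset[str]:
    pat = frozenset(pattern)
    unknown = pat - MECHANISMS.keys()
    if unknown:
        raise ValueError(f"unknown crosstalk mechanisms: {sorted(unknown)}")
    if {"M2", "M3"} <= pat:
        raise ValueError("M2 and M3 are opposite signs on the same interaction "
                         "and cannot coexist in one pattern")
    return pat


def enumerate_crosstalk_patterns(family: str) -> list[frozenset[str]]:
    """List the crosstalk patterns of a family in canonical order.

    ``inhibition`` yields the 16 subsets of {M1, M2, M4, M5} (including the
    empty pattern), ``activation`` the two activation-based patterns {M3}
    and {M1, M3}, and ``none`` the single empty pattern.
    """
    if family == "inhibition":
        patterns = [
            frozenset(m for m, bit in zip(INHIBITION_FAMILY, bits) if bit)
            for bits in product((0, 1), repeat=len(INHIBITION_FAMILY))
        ]
        patterns.sort(key=lambda p: (len(p), tuple(sorted(p))))
        return patterns
    if family == "activation":
        return [frozenset({"M3"}), frozenset({"M1", "M3"})]
    if family == "none":
        return [frozenset()]
    raise ValueError(f"unknown crosstalk family {family!r}; "
                     f"expected one of {CROSSTALK_FAMILIES}")


def pattern_label(pattern: frozenset[str]) -> str:
    return "+".join(sorted(pattern)) if pattern else "none"


@dataclass(frozen=True)
class Design:
    """A topological configuration plus a crosstalk pattern.

    ``hierarchical`` switches on hierarchical regulation: perturbations may
    then apply their secondary enzyme-activity changes (for the *ccr2*
    knockout, raising CCR1 and CCoAOMT) in addition to the primary one.
    """

    topology: TopologyConfiguration
    crosstalk: frozenset[str] = field(default_factory=frozenset)
    hierarchical: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "crosstalk", _check_pattern(self.crosstalk))

    def vacuous_mechanisms(self) -> frozenset[str]:
        """Mechanisms whose target reaction is absent from the topology.

        They are retained in the design record but alter nothing in the model
        (e.g. M4/M5 in configurations lacking the free-COMT edge).
        """
        return frozenset(
            m for m in self.crosstalk
            if MECHANISMS[m].target_reaction in OPTIONAL_EDGES
            and not self.topology.has(MECHANISMS[m].target_reaction)
        )

    @property
    def id(self) -> str:
        tag = pattern_label(self.crosstalk)
        suffix = "+hier" if self.hierarchical else ""
        return f"{self.topology.label}:{tag}{suffix}"


def enumerate_designs(
    configs: Sequence[TopologyConfiguration],
    patterns: Sequence[Iterable[str]],
    hierarchical: bool = False,
) -> list[Design]:
    """Cartesian product of configurations and crosstalk patterns.

    Pattern-major order (all topologies for the first pattern, then the
    next), matching a patterns-by-topologies screening matrix.
    """
    return [
        Design(topology=t, crosstalk=frozenset(p), hierarchical=hierarchical)
        for p in patterns
        for t in configs
    ]


def write_configurations_tsv(
    configs: Sequence[TopologyConfiguration], path: str | Path
) -> None:
    """Write one row per configuration: label, six presence bits, counts."""
    header = ["label", *OPTIONAL_EDGES, "n_dependent", "n_edges"]
    lines = ["\t".join(header)]
    for cfg in configs:
        row = [cfg.label, *map(str, cfg.present_edges), str(cfg.n_dependent),
               str(cfg.n_edges)]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
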