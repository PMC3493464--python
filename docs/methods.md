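# Methods

## The question and the modelling strategy

In *Medicago*, the enzymes CCR1·CAD and COMT·F5H appear to organise into two
metabolic channels that feed guaiacyl (G) and syringyl (S) lignin synthesis
directly, bypassing the free intermediate pools. Whether these channels are
permanent or facultative, and whether the CCR2/COMT and CCoAOMT/CCR1 branches
exchange regulatory signals ("crosstalk"), cannot be read off the pathway
diagram. `lignindesign` screens the space of minimal hypotheses
computationally: every admissible on/off combination of the optional
reactions (a *topological configuration*), combined with a pattern of
metabolite-level activation/inhibition mechanisms (a *crosstalk pattern*),
is a *design*. Each design is instantiated many times with randomly drawn
parameters, each instantiation is asked to predict the S/G lignin ratio of
four perturbed lines (CCoAOMT- and COMT-down-regulated alfalfa; ccr1 and
ccr2 *M. truncatula* knockouts), and the design is scored by Q, the number
of instantiations whose predictions match the observations. A design family
that keeps Q > 0 across wide parameter variation is *robust*: its agreement
with the data is a property of the structure, not of a lucky parameter set.

## Pathway scaffold

The scaffold covers the pathway segment that controls S/G partitioning:
caffeoyl CoA (X1), caffeyl aldehyde (X2), feruloyl CoA (X3), coniferyl
aldehyde (X4, optional), coniferyl alcohol (X5), 5-hydroxyconiferyl aldehyde
(X6) and sinapaldehyde (X7), with effluxes into the G, 5HG and S lignin
sinks and six enzyme activities (CCR1, CCR2, CCoAOMT, COMT, F5H, CAD) as
independent variables. 5-hydroxyconiferyl alcohol and sinapyl alcohol are
lumped into the 5HG and S efflux steps (those steps therefore carry CAD);
the 3-O-methylations of caffeoyl CoA and of caffeyl aldehyde are each one
lumped flux dominated by CCoAOMT and COMT respectively. Six reactions are
optional: the G channel (X3→X5), the S channel (X2→X6), and the four free
routes through X4 (free COMT X2→X4, free CCR1 X3→X4, free CAD X4→X5, free
F5H X4→X6).

Admissibility requires that X2 and X3 each have an outgoing edge, X5 and X6
each an incoming edge (no stranded mass), and that X4 — if touched by free
routes at all — has both a producer and a consumer. The producer→consumer
direction alone leaves 22 of the 64 subsets; we also apply the converse
(a consumer without a producer is a dead edge indistinguishable from its
absence), which yields exactly 19 configurations. They are labelled A
(all six optional edges) through S (channels only) in canonical order
(descending edge count, ties by the edge-bit tuple); the only anchored
letters are A, B (= A minus free COMT) and S; the remaining letters are
internal labels and results should be read via the edge sets in
`designs.tsv`.

Crosstalk mechanisms: M1, feruloyl CoA inhibits the CCR2 step; M2/M3,
caffeyl aldehyde inhibits/activates the methylation of caffeoyl CoA
(mutually exclusive); M4, caffeoyl CoA inhibits the free-COMT step; M5,
caffeyl aldehyde inhibits its own methylation (substrate inhibition,
realised as a negative apparent kinetic order of the free-COMT term's
substrate). The inhibition family comprises the 2^4 = 16 subsets of
{M1, M2, M4, M5}; the activation family is {M3} and {M1, M3}. Mechanisms
whose target reaction is absent from a topology are vacuous: recorded, but
altering nothing.

## Model form and parameter sampling

Each reaction is a power-law (GMA) term
`v_k = gamma_k * prod_j X_j^{f_kj}`. Enzyme orders are fixed at 1;
substrate orders are drawn uniformly from [0.1, 1.0]; effector orders from
[0.1, 1.0] (activators) or [-1.0, -0.1] (inhibitors, and the inhibiting
substrate under M5). Uniform sampling is the maximum-entropy choice given
only interval information; all intervals are overridable per
(reaction, variable) pair, with sign rules enforced.

Rate constants never need values: variables are normalised to the sampled
wild-type steady state (Y = X/X_S), so each term is pinned to its
steady-state flux V_kS. The wild-type fluxes are drawn from the steady-state
flux polytope P defined by the mass balances, a scale-fixing row (total
influx = 1; the normalised model is invariant to overall flux scale), the
wild-type S/G flux-ratio row (V_S = rho_wt * V_G, exact in every sample),
and strict positivity V >= 1e-3 on every present flux — a present edge with
zero flux would duplicate a different topology and break the flux-weighted
exponent aggregation. All fluxes are treated as irreversible; per-reaction
bounds are configurable should reversibility information become available.

P is bounded (the pathway is acyclic with unit influx) and its extreme
points are enumerated exactly as basic feasible solutions: with at most 13
fluxes and affine dimension at most 4, the exhaustive active-set search is
exact and cheap, and is cross-checked in the test suite against an
independent rational-arithmetic (exact fraction) enumerator on all 19
default polytopes. Samples are flat-Dirichlet convex combinations of the
vertices — the literal parametric description of P — with an approximately
uniform hit-and-run sampler available as an option, since the Dirichlet
measure is not uniform over P.

## Steady-state solving

Aggregating each pool's parallel production terms into one power law (and
likewise consumption), with exponents combined as flux-weighted means,
yields the S-system equivalent to the GMA model at the operating point. Its
steady state is linear in log space: with G, H the aggregate exponent
matrices over pools and G_E, H_E over enzymes, a perturbation with enzyme
multipliers m solves `(G - H) y = (H_E - G_E) ln m` for the log deviations
y = ln Y. Per-reaction flux factors are `exp(f_k . y) * prod m^{e_k}`, and
the predicted S/G ratio is rho_wt times the S-efflux factor over the
G-efflux factor.

Numerical choices: systems with condition number above 1e12 are flagged
degenerate (excluded and tallied separately — they are not the same thing as
ill-behaved); an instantiation whose solution moves any pool by strictly
more than 1000-fold in any line is ill-behaved and excluded. Knockouts are
simulated as 5% residual activity — a zero multiplier lies outside the
power-law domain. A damped Newton (hybrid Powell) GMA fixed-point finder,
started at the operating point, serves as an independent oracle: it matches
the log-linear solution exactly at the identity perturbation and to second
order in the perturbation size (both verified in the tests; the two solvers
share no code). Local stability of the perturbed steady state is not
checked; the screen is a steady-state analysis throughout.

## Validity criteria and screening statistics

For each design, n instantiations (default 10^4 per design; 10^5 reproduces
the full-scale setting) are drawn from a deterministic per-design random
stream derived from (seed, design), so results do not depend on which other
designs are screened. An instantiation is *valid* when it is well-behaved in
all four lines, the mean squared difference between predicted and observed
S/G over the two quantitative lines is below 0.01 (squared S/G units), and
the knockouts clear the qualitative margins (ccr1 prediction below
0.95·rho_wt, ccr2 above 1.05·rho_wt — predictions within the 5% strip count
as unchanged). Q counts valid instantiations. Q′ relaxes the quantitative
test to a per-line relative error of at most 25%, counted as a union with
the strict test so that Q <= Q′ holds identically (the 25% band alone is not
a superset of the MSE band at small observed values). The qualitative
margins are not relaxed in Q′.

## Scenario configuration and its provenance

Observed values are inputs, not constants. The scenario YAML carries, per
line, the enzyme multipliers, optional hierarchical multipliers (applied
only when a design enables hierarchical regulation — for the ccr2 knockout,
CCR1 and CCoAOMT rise, default 1.5-fold), and either an observed S/G ratio
(quantitative lines) or a direction (qualitative lines), each tagged
`literature`, `placeholder` or `synthetic`. The shipped defaults set the
CCoAOMT-down multiplier to 0.24 (the reported ~4.2-fold activity reduction);
the COMT-down multiplier (0.1), the wild-type ratio (0.5), the hierarchical
magnitudes and both observed S/G values are flagged placeholders that must
be replaced with the original transgenic measurements before any literal
comparison with published screening outcomes. Loading a file with
placeholder tags logs and raises a warning.

## The synthetic-scenario generator

`generate_synthetic_scenario` samples one instantiation of a chosen
ground-truth design, solves the four lines, and emits the predictions as
observations (quantitative values for the down-regulated lines, optionally
with multiplicative lognormal noise; directions for the knockouts).
Instantiations that are ill-behaved or whose knockout responses fall inside
the 5% strip are resampled. This yields observation sets with the exact
structure of the real ones but a known generating design, enabling
end-to-end recovery tests (the true design must score Q > 0) without any
external data. What passing such tests shows is internal consistency of the
pipeline — sampling, solving and scoring — not agreement with real plants:
synthetic observations are noise-free by default, exactly compatible with
the model class, and carry none of the measurement error, tissue
heterogeneity or model misspecification of the experimental S/G data.

A structural caveat the generator makes visible: the channels-only
configuration (S) admits no scorable instantiation, because CCR1 there
appears only in the G channel, whose steady-state flux is pinned by
upstream mass balance — the predicted ccr1 response is identically
wild-type and can never clear the 5% margin.

## Topology graph

Configurations are nodes; two are adjacent when their optional-edge masks
differ in exactly one bit (one gained or lost reaction — a minimal
evolutionary event). Adjacency requires both endpoints admissible. The full
19-node graph has exactly two components: the channels-only configuration is
the unique isolated node, and the other 18 form one component. Connectivity
of a robust subset is read as evolutionary accessibility of its members.

## Default problem sizes

Enumerations and the topology graph are exact and instantaneous. The
data-free property checks and recovery tests run at 10^4 instantiations per
design, the package's desk-scale default; the full-scale setting (10^5 per
design, 1.9 million instantiations over the 19 configurations of one
pattern family arm) is a single CLI flag (`--n 100000`). Vertex enumeration
is cached per (topology, rho_wt, epsilon) within a process.

## Known limitations

* Kinetic-order intervals and the hierarchical up-regulation magnitudes are
  package defaults, not measured values; conclusions that depend on rare
  tails of the ensemble (counts of order 1e-4 and below) are sensitive to
  them, while existence-style conclusions (which design families populate
  the qualitatively correct quadrant at all) are robust across the
  threshold variations exercised in the tests.
* The sampling measure over the flux polytope (flat Dirichlet over vertices)
  is one defensible choice among several; hit-and-run uniform sampling is
  available but not the default.
* Transcriptional regulation, upstream phenylpropanoid reactions, dynamic
  time courses and stability analysis are out of scope.
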