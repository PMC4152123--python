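# Methods

## Interaction graphs

A graph holds uniquely-identified nodes (optionally containing a nested
sub-graph) and typed edges with literature references. Edge identity is the
triple (endpoint pair, directedness, type); for undirected edges the endpoint
pair is unordered. Adding an edge equal to an existing one merges the
reference lists — the graph accumulates evidence rather than multi-edges.
Self-loops are allowed (some genetic interactions are self-interactions) and
collapse the same way. `merge(a, b)` takes the union of nodes by id and of
edges by identity; on a node-attribute conflict the first argument wins and a
warning is logged, which makes merging deterministic and order-stable (and
hence commutative on structure, though not on conflicting attribute values).
Nested graphs are stored by containment (deep copy), never by reference, so a
saved project file is always self-contained.

## Petri nets and hierarchy

A net is a bipartite directed graph of places and transitions; arcs carry
integer multiplicities (>= 1, defaulting to 1 in every input format).
Markings are non-negative integer vectors over the *leaf* places.

Two organisational constructs flatten away before any analysis:

* **Coarse places** contain other places (the containment relation must be a
  forest). An arc between a coarse place and a transition is a macro for one
  arc per contained leaf place, applied recursively and in both directions
  (the replication rule is the same whether the coarse place is the arc's
  source or target). Coarse places carry no tokens of their own and are
  dropped from the flat net. If expansion produces several arcs between the
  same leaf and transition, their multiplicities are summed, so the Pre/Post
  entries stay single-valued.
* **Nested transitions** hold a whole sub-net. Flattening replaces the
  container transition by the contents of its nested net with inner ids
  prefixed `container::inner`; an inner place whose id equals an outer place
  id is unified with it (the boundary through which the module connects), and
  the outer place's attributes and marking win. A container transition is
  purely organisational, so an arc attached directly to one has no defined
  token semantics; flattening rejects it with an explicit error rather than
  guessing (connect the inner net's own elements instead). The `::` separator
  is reserved: user-facing constructors reject ids containing it, which makes
  prefixing collision-proof by construction.

Flattening is idempotent and preserves the leaf-place set and the total
initial token count. A transition is *enabled* when every input place holds
at least the arc multiplicity; firing subtracts Pre and adds Post. There is
no read-arc shorthand — catalysis is modelled with paired input/output arcs,
as in the kinase–substrate template.

## Matrix bundles

`to_matrices` flattens, orders places and transitions lexicographically by id
(deterministic, diff-friendly), and transcribes arc multiplicities into the
Pre and Post integer matrices; the stoichiometry S = Post − Pre is always
derived, never stored. `from_matrices` inverts the construction exactly, so
`to_matrices ∘ from_matrices` is the identity on bundles. The JSON
interchange document (`format_version` 1.0; `place_ids`, `transition_ids`,
`pre`, `post`, `initial_marking`, `rates`, optional `provenance`) is written
with sorted keys, two-space indent and UTF-8, making serialization
byte-reproducible. The schema is this repository's own interchange standard,
designed clean-room for the download-matrices-and-simulate workflow. Markings
and multiplicities are integers (token semantics are discrete); rates are
floating point.

## Stochastic simulation

Propensities follow the combinatorial mass-action convention standard for
stochastic Petri nets: `a_j(x) = c_j * prod_i C(x_i, Pre_ij)`, the rate
constant times the number of distinct reactant combinations. This makes
`a_j = 0` whenever a transition is under-resourced, which is what guarantees
markings never go negative. The simulator is the exact direct method: waiting
time `Δt ~ Exponential(a0)` with `a0 = Σ a_j`, next transition chosen with
probability `a_j / a0` by cumulative-sum search in column order. Each event
consumes exactly two uniform draws from one seeded `numpy` PCG64 generator
per trajectory, so a trajectory is a pure function of (bundle, t_max, seed,
max_events) and reproduces bit-for-bit across processes. A run stops at
`t_max` (without appending an event there), at `max_events` (default 10^6),
or when `a0 = 0`, recorded as an `absorbed` flag. The direct method was
chosen over next-reaction or tau-leaping for exactness and simplicity at the
desk scale this toolkit targets; there are no approximate accelerations.

Ensembles run `n` replicates with consecutive seeds `base_seed .. base_seed
+ n − 1` and resample each trajectory onto a shared time grid by
last-event-carried-forward (the marking is a right-continuous step function),
reporting per-place mean and sample variance (ddof = 1).

### Statistical validation

Three closed-form laws back the simulator's correctness checks:

* immigration–death (`∅ → X` at λ = 10, `X → ∅` at per-capita μ = 1): the
  stationary law is Poisson(λ/μ) = Poisson(10), so stationary mean and
  variance are both 10. The mean is estimated by per-replicate time averages
  over [10, 50] (about 10 relaxation times of burn-in, τ = 1/μ = 1); the
  variance across replicates from states sampled at t = 20, 30, 40, 50 —
  samples ≥ 10 τ apart are effectively independent, and the across-replicate
  estimator avoids the downward bias a within-window time-average variance
  picks up from autocorrelation.
* symmetric isomerization (A ⇌ B, equal rates, 10 tokens): each token is
  independently in A with probability 1/2 at stationarity, so A is
  Binomial(10, 1/2) with mean 5.
* the one-token A ⇌ B chain with equal unit rates, started in A, has
  `P(A at t) = 1/2 + 1/2 e^(−2t)`; the empirical frequency over 5000
  replicates at t = 0.7 is compared within three binomial standard errors.

All tolerances in tests are three Monte-Carlo standard errors computed from
the samples themselves, with fixed seeds so runs are deterministic.

## File formats

* **CSV edge lists** (RFC 4180, UTF-8): required columns `source,target`;
  optional `directed` (`directed`/`undirected`, default undirected), `type`
  (default `physical`), `references` (semicolon-separated). A row with an
  empty target declares an isolated node. Export order is sorted by
  (source, target, type), so writing is deterministic. CSV is flat by nature;
  nested graphs survive only in project JSON and are dropped from CSV with a
  warning.
* **Cytoscape JSON**: the `elements` export shape — either
  `{"nodes": [...], "edges": [...]}` or a flat elements list — with
  `data.id` / `data.source` / `data.target`. Unrecognised `data` fields are
  kept as string attributes; edges default to undirected unless a
  `directed` attribute says otherwise.
* **Snoopy XML**: a declared subset of the discrete/stochastic net classes —
  `Place` and `Transition` node classes (attributes `Name`, `Marking`, and a
  numeric `Rate`/`FunctionList` when present; symbolic rate functions fall
  back to 1.0) and the `Edge` class with `Multiplicity`. Everything else is
  skipped with a logged warning and a summary count, since the full format
  is large and versioned.
* **Project JSON** (`format_version` 1.0): a self-contained document for
  either kind of model, preserving hierarchy, references and attributes.
  Serialization is canonical (sorted keys, fixed indentation), so
  write∘read is a byte-level fixpoint; unknown top-level keys round-trip
  untouched. A major version newer than the library's is rejected
  explicitly.

Readers validate before returning — a reader can only produce an object that
passes model validation — and any truncation of a valid file raises a clean
error.

## Templates and composition

A template is a net fragment whose binding sites (named places/transitions)
are substituted at instantiation, while internal ids receive a caller-chosen
namespace prefix; `compose` merges any fragment into a host net, unifying an
explicit set of shared ids (host attributes win, with a log note) and
prefixing the rest. Both operations are pure and always return validated
nets. The built-in catalogue covers the AND and OR gates, SOURCE, SINK,
REVERSIBLE-BINDING and the KINASE-SUBSTRATE motif. Gates use standard
token-consuming Petri-net semantics (AND: one transition with both inputs;
OR: one transition per input sharing the output); a non-consuming gate
variant is deliberately not provided. The kinase motif is catalyst-preserving
— the kinase is input *and* output of the phosphorylation transition — which
is this repository's canonical encoding of enzymatic conversion.

Template diagrams (arcs as `->`):

```
AND:  in1 -> gate <- in2 ; gate -> out
OR:   in1 -> gate1 -> out ; in2 -> gate2 -> out
SOURCE: produce -> out          SINK: in -> degrade
REVERSIBLE_BINDING: a,b -> bind -> ab ; ab -> release -> a,b
KINASE_SUBSTRATE: kinase <-> phosphorylate ; substrate -> phosphorylate -> product
```

Templates serialize as project-JSON documents with a `template` wrapper
(parameters + defaults + body), the file-based analogue of a shared module
repository.

## Synthetic model generators

`spnlab.testing` provides the seeded random generators the property tests
and the validation script use: small flat nets (≤ 3 places/transitions,
multiplicities ≤ 2 — small enough for exhaustive marking enumeration),
hierarchical nets with containment forests of depth ≤ 3, flat interaction
graphs with mixed edge types and PubMed-style references, arbitrary valid
bundles, and conservation-closed bundles (every transition moves k tokens
from one place to another, so stoichiometry columns sum to zero). They
emulate the *structural* variety of curated pathway models — hierarchy,
stoichiometry, evidence annotations — not the statistics of real interactome
data (degree distributions, hub proteins, literature bias); passing tests
certify the algebra and the simulator, not biological fidelity of any
particular network.

## Problem sizes and numerical choices

The validation battery uses 200 replicates for stationary laws, 5000 for the
transient-distribution check, 100 random nets for the firing oracle, 50 for
flattening and for each round-trip family, and 1000-step firing walks —
sizes at which every Monte-Carlo band is a small multiple of its standard
error while the whole battery completes in seconds. Exponential waiting
times are drawn as `−log1p(−u)/a0` so `u = 0` is safe; empty nets, empty
coarse places and zero-transition bundles are handled as explicit degenerate
cases (empty bundles, absorbed-at-start trajectories). Ties in transition
choice cannot occur (the cumulative-sum search uses strict inequality on a
continuous draw).

## Known limitations

* No inhibitor/read arcs, no timed, coloured or continuous extensions, no
  ODE/hybrid semantics, no tau-leaping.
* No reachability-graph model checking; validation is structural.
* Snoopy import is the declared subset above, not the full format.
* The Cytoscape reader accepts the elements-collection dialect only.
* No networked repository: file exchange replaces sharing, permissions and
  publishing workflows.
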