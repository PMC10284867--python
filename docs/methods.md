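# Methods

## The record language

CMDL text is a sequence of block groups,

```
chemical dbu {
    smiles: "C1CCC2=NCCCN2CC1";
    molar_mass: 152.24 g/mol;
    role: catalyst;
}
```

with eight top-level group types (`chemical`, `fragment`, `polymer_graph`,
`polymer`, `reactor_graph`, `reaction`, `flow_reaction`, `result`) and nested
groups for graph structure (`container`, `node`, `edge`), reactor hardware
(`component`, `connect`), reagents (`reagent`) and flow feeds (`input`,
`solution`).  Values are numbers, quoted strings, identifiers, lists,
`@name`/`@name.path` references, or quantities (`number unit`).  Comments run
from `#` to end of line.  Identifiers are case-sensitive and duplicate
top-level declarations are errors.

The compiler has four stages.  *Tokenize* never fails: unknown characters
become error tokens, and every token carries the whitespace/comment trivia
preceding it so the token stream reconstructs the input byte-for-byte.
*Parse* builds the AST with error recovery — a malformed group produces a
diagnostic and parsing resumes at the next plausible group, so one corrupted
cell cannot hide the rest of a notebook.  *Validate* checks property schemas,
quantity dimensions, and reference resolvability; edge endpoints inside a
graph resolve relative to the container that declares the edge.  *Interpret*
runs only on error-free records and materializes every computation:
stoichiometry tables, polymer edge weights, flow propagation.
Interpretation is deterministic (equal text gives structurally equal
records) and quantities are normalized at parse time to fixed base units
(g, mol, mL, min, mL/min, mol/L, g/mol, g/mL).

## Polymer graphs and edge weights

A polymer is a graph of SMILES fragments carrying non-atomic attachment
points `[R]`, `[Q]`, `[X]`, `[Z]`; symmetric chemically-equivalent points
share one letter (a butanediol initiator is `[R]OCCCCO[R]`).  Edges name a
source and target point; containers group nodes into `linear` (block-like)
or `statistical` (random enchainment) regions and may nest, which is what
distinguishes a grafted side chain from a main-chain block during traversal.
Dangling chain ends (a terminal hydroxyl) are implicit, not nodes.

The edge weight of an edge is the fraction of all covalent bonds in the
stochastic chain belonging to that bond type.  The computation converts the
graph to a composite tree (containers → internal nodes, repeat units with
their DP_n → leaves, edges → counted leaves) and counts bonds:

* self-edge of a repeat unit with DP_n = n and edge quantity q: `q·(n−1)`;
* junction edge (end group → repeat, block → block): `q`, or 0 if either
  side is a failed polymerization (DP_n = 0);
* inside a statistical container whose member DP_n values sum to N, the
  N−1 internal bonds are apportioned by expected random-enchainment
  frequencies, `(N−1)·f_x²` for like pairs and `(N−1)·2·f_x·f_y` for unlike
  pairs with `f_x = dp_x/N`, direction ignored.  As the composition goes
  pure this reduces to the block counts.

Weights are counts normalized by the grand total, so they sum to 1; a graph
implying no bonds at all (every DP_n ≤ 1, no junctions) gets all-zero
weights and a warning rather than an error.  DP_n is interpreted *per arm*
for quantity-compressed edges: a diol with quantity 2 and DP_n 50 has 100
repeat units in total, which makes an edge of quantity q exactly equivalent
to q explicitly expanded branches.  A node with neither a declared DP_n nor
an assignment defaults to 1 (end groups; the one-unit chain).  The counting
rules are verified in the test suite against a brute-force oracle that
writes out every unit of explicit chains (per-block DP_n ≤ 12, q ≤ 4) and
counts bond types directly; agreement is exact, not approximate, because
both sides compute the same integer ratio.

## Graph strings

For language-model I/O a graph serializes to one line: property tags, then
`<graph:name>` / `<stat:container-path>` structure tags, then nodes as
`path(fragment)` with an optional `{dp:n}` annotation (depth-first container
order, lexicographic id within a container), then edges as
`<source.L|target.L|weight>` with weights printed to 4 decimals and an `xQ`
field when the edge quantity exceeds 1.  The structure tags and annotations
are what make `parse(serialize(g)) = g` hold exactly — without them the
container hierarchy, statistical kind, DP_n and quantity would be lost.
Parsing never raises; malformed input returns a typed failure
(`EMPTY`, `UNBALANCED_SMILES`, `BAD_NODE`, `BAD_EDGE`, `UNKNOWN_LETTER`,
`DANGLING_EDGE`) consumed by the QC triage.  Canonical strings used for
novelty and grouping additionally strip weights and DP_n and canonicalize
each fragment through RDKit (placeholders mapped to atom-mapped wildcards
and back), so two records writing the same repeat unit with different atom
orders compare equal.

## Stoichiometry

Moles come from mass/M, volume·ρ/M, or solution volume·concentration; the
quantity must be positive and missing molar mass/density is a typed error.
Equivalents are mole ratios against the reference reagent — the flagged
entry, or by default the unique initiator-role entry, matching the
[M]₀:[I]₀ convention — and the reference row is exactly 1 by construction.
Solvents carry no equivalents but contribute to the total volume used for
concentrations.  Report rendering rounds half-up (2 significant figures for
equivalents, 2 decimals for mmol, matching bench write-up style); internal
values are never rounded.

## Flow reactors

Reactor hardware is a DAG: `input` components (no inflow), `mixer`s,
`reactor` coils (volume required), and `collection` (no outflow).  Streams
are incompressible and instantaneously mixed, and no reaction consumption is
modeled — the stoichiometry computed is that of the combined feed.
Propagation runs in topological order; at every non-input node the
volumetric and per-entity molar flows are the sums over incoming
connections, so conservation holds to round-off (verified at 1e-12 relative
on randomized DAGs).  A node with several outgoing connections splits its
stream equally (the literature shows only merging; splitting still needs a
definition and per-edge fractions can be added later).  Residence time of a
coil is volume / volumetric flow, in minutes; zero flow is a typed error
rather than infinity.  The Sankey export assigns each connection the flow it
actually carries, so link values into a node sum to that node's throughput.
The bundled two-reactor fixture (monomer + catalyst syringes → reactor A;
quench joins before reactor B) defaults to 0.5/0.25/0.75 mL/min and
0.5/0.3 mL coil volumes — representative bench values, configurable per
record.

## Dataset export and aggregation

`export_json` emits a versioned, key-sorted document; import is lossless and
re-export is byte-identical, which the tests assert for every fixture kind.
Training pairs are one row per (monomer, catalyst, result) with conversion
as a fraction, dispersity, and M_n on a log₁₀ scale; incomplete rows are
dropped and counted.  For corpus summaries, repeat units are binned by
assigned DP_n into half-open bins `(lo, hi]` labeled by the upper edge
(default edges 25/50/100, configurable), with `0` reserved for failed
polymerizations and no suffix for non-repeat nodes or missing DP_n.  Sankey
grouping keys node identity on the canonical fragment SMILES plus bin label,
so identical entities from different records merge; a link counts the number
of corpus graphs containing an edge between those two entities (self-edges
mark repeat-unit status and are not links).

## Generation QC

Generated graph strings are triaged into exactly one of six categories in a
fixed precedence — syntax, chemistry, repeat structure, connectivity
ambiguity, then novelty — because each failure makes the later checks
meaningless.  Chemistry uses valence/ring validation of every fragment with
placeholders substituted by wildcards.  The repeat-structure rule requires
every self-propagating node to expose at least two attachment points.  The
ambiguity rule is made concrete here: two self-propagating repeat units
connected by inter-node edges in *both* directions, outside an explicitly
statistical container, admit both a block and a statistical reading; the
report flags the pair and resolves to the AB block by keeping the
lexicographically-first junction direction.  Novelty is structural: the
canonical string (weights stripped, fragments canonicalized) is tested for
membership in the reference corpus.  `preservation_check` compares a
generated graph against its seed and passes iff every attachment-point
letter/count and the whole edge topology are unchanged, while listing
fragment-interior substitutions (which are allowed) in the diff.

## Synthetic fixtures: what they do and do not show

The fixture module emits records for every architecture (homopolymer,
telechelic diol, graft, 3/4-arm star, block and statistical copolymer) and
experiment type (batch and flow ROP) from real monomer/catalyst/initiator
chemistry, plus a sampled dataset: monomer and catalyst uniform over four
monomers and three catalysts, architecture 60/25/15 % homopolymer/diol/star,
target DP_n uniform over {25, 50, 100}, a 5 % failure rate (DP_n = 0,
conversion 0), conversion uniform on [0.85, 1] otherwise, and dispersity
1 + |N(0, 0.1)| — values representative of well-controlled organocatalytic
ROP.  Sampling order is fixed and seeded, so corpora are byte-reproducible.
These fixtures exercise the full pipeline, but they are clean by
construction: they contain no transcription noise, no missing metadata, no
instrument drift, and their property values follow the stated distributions
rather than real structure–property relationships.  Passing tests therefore
demonstrate correctness of the computations and representations, not
predictive value of models trained on such corpora.

## Numerical choices and limitations

Weights are exact rational ratios evaluated in floating point; the
normalization invariant is asserted at 1e-9 and conservation at 1e-12
relative.  Serialized weights print at 4 decimals, so string round trips
compare weights at that precision.  Statistical-container apportionment is
the expected-value model of random enchainment — it ignores reactivity
ratios and sequence drift.  Flow propagation has no dispersion, pressure, or
temperature model.  The QC novelty check is structural only; it does not
score synthesizability or rank by predicted properties.
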