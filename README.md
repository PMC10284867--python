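# cmdl

A compiler, interpreter and toolkit for **Chemical Markdown Language
(CMDL)** — a declarative text format for polymer-chemistry experiment
records, built for groups who want to turn heterogeneous bench and
continuous-flow records into machine-learning-ready datasets without forcing
them into a rigid schema.

A record declares chemicals, polymer structures, reactors, reactions and
measured results as plain text blocks; the interpreter executes the
computations a chemist would otherwise do by hand:

* **Reaction stoichiometry** — moles, equivalents against the initiator
  (so the monomer row *is* [M]₀:[I]₀), and concentrations, from weighed
  masses, volumes with densities, or solution volumes with concentrations.
* **Polymer graphs** — stochastic polymers as graphs of SMILES fragments
  with attachment-point placeholders `[R] [Q] [X] [Z]`.  Assigning a degree
  of polymerization DP_n to each repeat unit yields, for every edge, the
  fraction of the chain's bonds of that bond type (the *edge weight*): a
  repeat unit with DP_n = n contributes n−1 self-bonds and each junction
  contributes its edge quantity q, so a poly(valerolactone) of DP_n = 50
  weighs its end-group junction at 1/50 = 0.02 and its repeat self-edge at
  49/50 = 0.98.  Symmetric architectures (diols, dendrimers) compress q
  identical branches into one edge with quantity q, exactly equivalent to
  the expanded graph.  Statistical blocks apportion their N−1 internal bonds
  by random-enchainment frequencies (N−1)·fₓ² and (N−1)·2fₓf_y.
* **Flow reactors** — hardware as a directed acyclic graph; feeds propagate
  in topological order with exact mass balance, residence time is coil
  volume over volumetric flow, and a Sankey node/link table is exported for
  visualization.
* **Dataset export** — lossless JSON round trips, (monomer, catalyst,
  property) training tables with M_n on a log₁₀ scale, and DP_n-binned
  Sankey aggregation of polymer-graph corpora.
* **Generation QC** — model-generated polymer-graph strings triaged into
  `invalid_syntax`, `invalid_chemistry`, `invalid_repeat_structure`,
  `ambiguous_connectivity` (resolved as the AB block reading),
  `valid_reproduction`, or `valid_novel`, plus an attachment-point
  preservation check between a generated graph and its seed.

See `docs/methods.md` for the models, counting rules and their assumptions.

## Worked example

Generate a complete batch ring-opening-polymerization record (4-methylbenzyl
alcohol initiator, DBU catalyst at 2.5 eq, valerolactone at 50 eq, target
DP_n 50) and run its computations:

```
$ cmdl fixtures --kind batch_rop --out demo
$ cmdl stoich demo/batch_rop.cmdl
mba                  initiator  4e-05 mol  1 eq
dbu                  catalyst   0.0001 mol  2.5 eq
valerolactone        monomer    0.002 mol  50 eq
dcm                  solvent    0.0156011 mol  - eq
```

The initiator row is the reference (exactly 1 eq); DBU computes to 2.5 eq
and the monomer to 50 eq from the emitted masses — the monomer row is the
[M]₀:[I]₀ ratio.  The record's measured result assigns the experimentally
determined DP_n (here 49, from 98 % conversion of 50 eq) to the repeat unit,
and the interpreter turns that into edge weights:

```
$ cmdl weights demo/batch_rop.cmdl --polymer product
<end_group.R|repeat.Q|0.0204>
<repeat.R|repeat.Q|0.9796>
```

1/49 of the bonds join the end group to the first repeat unit; 48/49 are
repeat–repeat bonds.  The same graph serializes to a single canonical line
for language-model consumption, and parses back losslessly:

```
$ cmdl graph-string demo/batch_rop.cmdl --polymer product
<graph:product> end_group([R]OCc1ccc(C)cc1) repeat([R]C(=O)CCCCO[Q]){dp:49} <end_group.R|repeat.Q|0.0204> <repeat.R|repeat.Q|0.9796>
```

Other entry points: `cmdl compile FILE --json-out out.json` (diagnostics +
JSON export), `cmdl flow FILE --sankey sankey.json` (stream states,
residence times), `cmdl pairs DIR --csv pairs.csv` (training table),
`cmdl sankey-data DIR --json summary.json` (corpus aggregation),
`cmdl qc FILE --reference DIR` (generated-structure triage), and
`cmdl fixtures --kind dataset --n 100 --seed 1` (a seeded synthetic corpus
with its ground-truth table).

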