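# Methods

## The data model

Cross-species chromosome painting yields, for each target chromosome, an
ordered series of blocks labeled with the probe (source) chromosome that
hybridized there.  `karyopaint` represents these maps with **ordinal
coordinates only**: blocks are ordered pter→qter by `order_index`, and
adjacency means consecutive indices on one target chromosome.  No
base-pair coordinate system exists at cytogenetic resolution, so none is
modeled.

Region labels follow the compact cytogenetic shorthand used in homology
tables: `<chrom><arm><qualifier>` with qualifier letters p(roximal),
i(nterstitial), d(istal), t(erminal); `p/q…` composites span the
centromere; `+` separates physically distinct blocks; `or` records an
unresolved alternative; `Inv` and `bi-armed` are morphology flags, not
positions.

Unpainted material (heterochromatin, NOR-bearing arms) appears as
explicit **gap rows** so that contiguity is decidable.  Gap rows carry no
homology; they break runs and association adjacency, and extra gap
material on a target chromosome disqualifies whole-chromosome ("intact")
conservation — this is what distinguishes a probe chromosome conserved
as an entire target chromosome from one conserved as a single block on a
larger, NOR-bearing element.

## Counting conventions

* **Conserved region** = maximal run of consecutive blocks sharing one
  source chromosome.  A centromere-spanning composite is one run; blocks
  of the same source separated by another source's block or by a gap row
  are distinct runs.  Two whole-chromosome homologs whose p and q arms
  are listed separately therefore count once, matching how contiguous
  signals are scored on a metaphase.
* **Intact chromosome** = a source chromosome whose blocks all land on
  one target chromosome that carries nothing else (no other source, no
  gap row).  The X is computed like any chromosome but excluded from all
  autosomal counts, as is the Y (for which no paint exists).
* **Syntenic association** = adjacency of two runs with different source
  chromosomes.  A target chromosome built from three sources yields its
  chain of pairwise adjacencies, not all pairs: fusion characters are
  pairwise junction products.  Centric and tandem fusions are not
  distinguished in association identity; morphology context is carried
  as flags for reporting only.
* **Ambiguity.** The `or` entries of painting tables arise because a
  whole-chromosome paint cannot always be assigned to a specific arm:
  in the packaged fixtures every alternative set stays within one source
  chromosome, so chromosome-level statistics (including the `13/3`
  association supported by an arm-ambiguous block) are unaffected.
  Only blocks whose alternatives span *different* source chromosomes —
  possible under the simulator's ambiguity noise — are excluded from
  shared-association claims and from intactness.

The canonical association name preserves the order used in the study for
the four named characters (`13/3`, `9/17`, `18/5`, `16/19`) and is
ascending otherwise.

## Fixture encoding choices

The packaged fixtures are the target-species inversion of the published
MCA-arm-oriented homology table, with block order within each target
chromosome taken from the painting figure.  Two points required a
decision:

* At table granularity the GSO map tallies 23 maximal runs, not the
  printed 24; the figure resolves this as two separate MCA 5-derived
  signals on GSO 1p.  The fixture encodes them as two blocks separated
  by an explicit heterochromatin gap row.
* The order of the MCA 13 and MCA 3q blocks on LCO 8q is encoded with
  MCA 13 proximal, the only order consistent with the `13/3` junction
  being shared by all three species without splitting the MCA 3q signal.

Karyotype morphologies not individually printed (MCA 8/12/14/15/16, the
LCO acrocentric) are pinned by the published fundamental numbers: FN
fixes how many autosomes are bi-armed, and the remaining per-chromosome
assignments are recorded in the fixture comments.  All four FN/2n
constants are recomputed by the test suite.

## ECU space

The 25 chiropteran Evolutionarily Conserved Units are encoded one per
MCA chromosome arm (chromosomes 1–6 carry one ECU per arm, 7–19 one
each), each with its human-segment composition.  `compose_homology`
relates any target map back to ECU/HSA space by arm-resolution matching:
a block whose source is finer than an arm inherits the whole arm's
content flagged `arm-resolution`; a source absent from the lookup yields
an `unmapped` block that is reported, never dropped.  An ECU is
**disrupted** when its content lands on two or more target chromosomes.
Arm-ambiguous blocks cannot create disruption: any consistent resolution
of a whole-chromosome paint places each probe arm exactly once.

## Character placement

Association characters are binary (present/absent per taxon); the probe
species is the outgroup and is absent by definition for every fusion
character.  The placement rule mirrors standard outgroup reasoning on a
fixed topology:

* present in all ingroup taxa → one gain at the ingroup MRCA;
* present in a monophyletic subset → one gain at that clade's MRCA;
* present in one taxon → terminal autapomorphy;
* present in a non-monophyletic subset → independent terminal gains
  (convergence).  A loss is never inferred by the rule.

A separate Fitch engine computes the parsimony minimum and — by
exhaustive enumeration with the root polarized to the outgroup state —
every most-parsimonious reconstruction.  Whenever the rule's placement is
not the unique MPR (e.g. `16/19`: two terminal gains tie with one gain
plus a loss, both at two changes), the report says so rather than hiding
the divergence.  The root polarization matters for the tie count: with a
free root a third, biologically uninterpretable reconstruction (presence
at the root with a change on the outgroup edge) also reaches two
changes.

Characters touching MCA 13, 17 or 18 carry an
`assumed-acrocentric-ancestor` annotation: deducing rearrangements for
these chromosomes assumes the ingroup ancestor had the acrocentric
condition seen in the outgroup.  Retention of individual chromosomes
(plesiomorphy) is reported descriptively — a probe chromosome intact in
the outgroup and in at least one ingroup species — rather than coded as
a matrix character, since absence of rearrangement is not a derived
state.

## Simulator

Chromosomes are ordered tuples of uniquely labeled segments from a root
karyotype plus a centromere index; all events operate at segment
boundaries, so content conservation holds by construction and every tip
projects back onto the root paints with exact ground truth.  Event
semantics: Rb fusion (two acrocentrics → one bi-armed; 2n−2, FN
unchanged), Rb fission (the inverse), tandem fusion (acrocentric donor
joined end-to-end, its centromere inactivated; 2n−2, FN−2), pericentric
inversion (centromere repositioning; morphology class toggles, synteny
unchanged), and whole-arm translocation (fission plus crosswise fusion,
one composite event).

Per-branch event counts are Poisson(rate × branch length) per kind.
Operands are drawn by rejection with a bounded retry budget (default
100); a kind with no feasible operands raises an error rather than
silently renormalizing rates — a simpler scheme with a documented bias
at extreme rates, where the recovery harness counts such replicates as
infeasible and excludes them.  Randomness derives from a single seed via
stable per-branch hashes, so histories replay identically regardless of
traversal order.

The default root mimics the hypothesized ancestral complement discussed
for this bat family: 22 autosome pairs (2n = 46) with 8 bi-armed and 14
acrocentric autosomes (FN = 60), each arm carrying two atomic segments.
No rearrangement rates or branch lengths are known for the real
radiation; the defaults used in tests (unit ingroup branch lengths, a
zero-length outgroup branch so the outgroup observes the root state,
fusion rates of 0.2–3 per branch) are illustrative regimes, not
estimates.

**What the generator does and does not emulate.**  It produces
painting-style maps with realistic block structure, arm-level source
resolution and optional `or`-ambiguity noise.  It does not model
breakpoint reuse, heterochromatin growth, NORs, sequence evolution, or
hybridization failure; gap rows therefore never arise in simulated maps,
and a green recovery test establishes correctness of the analysis chain
on the idealized observation model, not robustness to those artifacts.

## Recovery experiments

Each replicate runs simulate → project → extract associations → build
matrix → place, then scores: placement accuracy (fraction of fusion
events whose junction character was placed on the branch the event
occurred on), the same restricted to single-origin events (junction
pairs created exactly once — with homoplasy, "the true branch" is not
identifiable even in principle, as the study's own `16/19` character
illustrates), false-association rate against the structural ground
truth, and exact recovery of the plesiomorphic set.  At zero noise in a
fusion-only regime the single-origin accuracy is 1.0 and the false
association rate 0; accuracy degrades monotonically across increasing
rate ladders as fissions erase junctions and homoplasy accumulates.

## Numerical and tie-break conventions

* All set-valued outputs are sorted (chromosomes numerically, characters
  by canonical name, nodes by their stable `mrca(...)` ids), making every
  report byte-stable across reruns.
* Exhaustive MPR enumeration is guarded to ≤ 12 internal nodes.
* Fitch ancestral-state sets are computed exactly (min-cost messages in
  both directions), so a state appears at a node iff some MPR uses it.
* Degenerate inputs fail loudly: empty karyotypes, duplicate chromosome
  ids, non-contiguous block orders, unknown morphologies or qualifier
  letters, leaves without character states, and infeasible simulation
  regimes all raise typed errors naming the offending item.

## Known limitations

* Intra-arm breakpoint order beyond the fixture-encoded block order is
  not inferred, and ancestral gene orders are not reconstructed.
* The GSO→HSA map mixes table-derived and figure-derived segment
  positions; sub-arm positions there are approximate.
* The placement rule is tied to a fixed, externally supplied topology;
  no tree search or likelihood model of chromosome evolution is
  provided.
* Whether inversion flags denote pericentric or paracentric events is
  not recorded in the source tables; the flag is carried without
  subtype.
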