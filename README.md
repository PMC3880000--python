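# karyopaint

Comparative chromosome-painting (Zoo-FISH) analysis for karyotype
evolution studies, built around the cross-species painting comparison of
the leaf-nosed bat *Macrotus californicus* (MCA, 2n = 40, FN = 60) with
three nectar-feeding phyllostomids: *Glossophaga soricina* (GSO),
*Anoura cultrata* (ACU) and *Lonchophylla concava* (LCO).

In cross-species painting, whole-chromosome probes of one species are
hybridized onto the metaphases of another, revealing which blocks of each
target chromosome descend from which probe chromosome.  `karyopaint`
encodes such homology maps as ordered cytogenetic blocks, recomputes the
statistics this kind of study reports, polarizes rearrangement characters
against an outgroup on a fixed molecular phylogeny, and validates the
whole chain against a karyotype-evolution simulator with known ground
truth.

## What it computes

* **Karyotype bookkeeping** — diploid number 2n and fundamental number
  FN = Σ autosomal arms (acrocentric = 1 arm, bi-armed = 2), per species.
* **Conserved chromosomal regions** — maximal runs of consecutive painted
  blocks sharing one probe chromosome on a target chromosome.
* **Intact chromosomes** — probe chromosomes conserved as a whole target
  chromosome with nothing else on it.
* **Syntenic associations** — adjacencies of two probe chromosomes on one
  target chromosome (e.g. MCA `13/3`), the cladistic character unit;
  shared-association queries over taxon subsets.
* **ECU composition and disruption** — homology-map composition relates
  target chromosomes back to human (HSA) segments via the 25 chiropteran
  Evolutionarily Conserved Units, and counts ECUs whose content is split
  over two or more target chromosomes.
* **Character placement** — binary association characters placed on the
  rooted tree `(((GSO,ACU),LCO),MCA)` by the outgroup rule (gains at the
  MRCA of the presence set; convergent terminal gains when that set is
  non-monophyletic), cross-checked by a Fitch parsimony engine that
  enumerates all most-parsimonious reconstructions.
* **Simulation** — Robertsonian fusions/fissions, tandem fusions,
  pericentric inversions and whole-arm translocations along a tree, with
  a painting-style observation model and recovery experiments that score
  how reliably the analysis recovers the simulated truth.

## Worked example

The packaged fixtures encode the published homology table and painting
figure.  From Python:

```python
from karyopaint.io import load_paper_dataset
from karyopaint.synteny import (
    count_conserved_regions, extract_syntenic_associations,
)

data = load_paper_dataset()
print(count_conserved_regions(data.maps["GSO"], probes=data.probe_autosomes))
# 24
profile = extract_syntenic_associations(data.maps["GSO"])
print(sorted(profile.intact, key=int))
# ['4', '6', '7', '8', '15', '16']
```

or from the shell:

```
$ karyopaint associations --species GSO
{
  "species": "GSO",
  "associations": ["1/14", "1/2", "13/3", "18/5", "2/12", "3/11", "5/10", "9/17"],
  "ambiguous": [],
  "intact": ["4", "6", "7", "8", "15", "16"]
}
```

The 24 conserved regions mean the 19 MCA autosomal paints light up 24
separate signals on the GSO karyotype; the six intact chromosomes are MCA
autosomes each conserved as a whole GSO chromosome.  The full report
(`karyopaint analyze`) also lists the shared associations per taxon
subset:

```
"shared_associations": {
  "GSO+ACU+LCO":     ["13/3"],
  "ACU+GSO-not-LCO": ["18/5", "9/17"],
  "ACU+LCO-not-GSO": ["16/19"]
}
```

MCA `13/3` is shared by all three nectar feeders and is placed at their
most recent common ancestor; `9/17` and `18/5` unite the two
glossophagines; `16/19`, shared by ACU and LCO but absent from GSO, is
placed as two convergent terminal gains — the placement report flags that
the Fitch oracle ties this with a gain-plus-loss reconstruction at two
changes.

Other subcommands: `validate`, `compose` (ECU-space maps),
`map-characters` (placement JSON + annotated newick), `simulate`, and
`recover` (simulation-based recovery experiments).

## Acceptance script

`scripts/acceptance.py` recomputes, from the packaged fixtures and from
scratch, the per-species conserved-region counts and the ECU-disruption
counts from composed ECU-space maps, writing them as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/karyopaint/
  model.py    domain types (karyotypes, region labels, homology blocks)
  labels.py   cytogenetic-label grammar ("8qt", "12p/qp", "5q or 2qd")
  io.py       TSV/newick readers and writers, packaged fixtures
  synteny.py  region/association/ECU algebra
  phylo.py    character matrices, Fitch/MPR engine, placement rule
  sim.py      karyotype-evolution simulator and recovery experiments
  report.py   report assembly
  cli.py      command-line interface
docs/methods.md   model, conventions and limitations
```
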