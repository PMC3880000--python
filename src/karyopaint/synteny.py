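"""Set and count computations over painting homology maps.

Conventions (documented in docs/methods.md):

* A *conserved region* is a maximal run of consecutive blocks on one target
  chromosome sharing one source chromosome.  A centromere-spanning
  composite block is one run; same-source blocks separated by another
  source's block, or by an explicit gap row, are distinct runs.
* A *syntenic association* is an adjacency of two runs with different
  source chromosomes on one target chromosome (consecutive order indices,
  no gap row between) — the cladistic character unit.  A chromosome whose
  homologs form a chain of three sources yields the chain's pairwise
  adjacencies, not all pairs.
* Blocks whose ``or`` alternatives stay within one source chromosome (arm
  assignment unresolved) still support chromosome-level statistics; blocks
  whose alternatives span different source chromosomes are treated as
  ambiguous and excluded from shared-association claims.
* The X chromosome is computed everywhere but excluded from every
  "autosomal" count.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    ECU,
    HomologyBlock,
    HomologyMap,
    Karyotype,
    RegionLabel,
    SegmentLabel,
    ValidationError,
    chrom_sort_key,
)

SEX_CHROMOSOME_IDS = frozenset({"X", "Y"})

#: association names whose printed member order differs from ascending
PAPER_ASSOCIATION_NAMES = {
    frozenset({"13", "3"}): "13/3",
    frozenset({"9", "17"}): "9/17",
    frozenset({"18", "5"}): "18/5",
    frozenset({"16", "19"}): "16/19",
}


@dataclass(frozen=True)
class SyntenicAssociation:
    """Canonical unordered pairing of two source chromosomes co-resident
    (and adjacent) on one target chromosome, e.g. ``13/3``."""

    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) != 2:
            raise ValidationError(
                f"association needs two distinct members, got {self.members}"
            )

    @classmethod
    def of(cls, a: str, b: str) -> "SyntenicAssociation":
        return cls(frozenset({a, b}))

    @property
    def canonical_name(self) -> str:
        named = PAPER_ASSOCIATION_NAMES.get(self.members)
        if named:
            return named
        return "/".join(sorted(self.members, key=chrom_sort_key))

    def __str__(self) -> str:
        return self.canonical_name

    def __lt__(self, other: "SyntenicAssociation") -> bool:
        return self.canonical_name < other.canonical_name


@dataclass(frozen=True)
class AssociationProfile:
    """Per-species association character state: unambiguous associations,
    chromosome-ambiguous ones (kept separate), and intact source
    chromosomes."""

    species: str
    associations: frozenset[SyntenicAssociation]
    intact: frozenset[str]
    ambiguous: frozenset[SyntenicAssociation] = frozenset()

    def __post_init__(self) -> None:
        members = {m for a in self.associations for m in a.members}
        overlap = members & self.intact
        if overlap:
            raise ValidationError(
                f"{self.species}: chromosome(s) {sorted(overlap)} both "
                "intact and in an association"
            )


@dataclass(frozen=True)
class Run:
    """Maximal same-source run of consecutive blocks on a target
    chromosome."""

    target_chrom: str
    source_chrom: str
    blocks: tuple[HomologyBlock, ...]
    ambiguous: bool  # True if any block is chromosome-ambiguous

    @property
    def first_index(self) -> int:
        return self.blocks[0].order_index

    @property
    def last_index(self) -> int:
        return self.blocks[-1].order_index


def identity_homology(
    karyotype: Karyotype, include_y: bool = False
) -> HomologyMap:
    """The identity map of a species onto itself: one whole-chromosome
    block per chromosome (no Y paint by default)."""
    blocks = tuple(
        HomologyBlock(
            target_chrom=c.id,
            order_index=1,
            target_region=RegionLabel(c.id),
            source_region=RegionLabel(c.id),
        )
        for c in karyotype.chromosomes
        if include_y or c.id != "Y"
    )
    return HomologyMap(
        target_species=karyotype.species,
        source_species=karyotype.species,
        blocks=blocks,
    )


def compute_fundamental_number(karyotype: Karyotype) -> int:
    """FN: diploid count of autosomal arms.  Acrocentric chromosomes count
    one arm, all bi-armed morphology classes count two; sex chromosomes are
    excluded; autosome rows represent pairs and are doubled."""
    return 2 * sum(c.arms for c in karyotype.autosomes)


def runs_by_chromosome(hmap: HomologyMap) -> dict[str, list[Run]]:
    """Group each target chromosome's blocks into maximal same-source runs.

    Gap rows are not runs and break the run on either side.  A block whose
    alternatives span several source chromosomes always forms its own run,
    flagged ambiguous.
    """
    out: dict[str, list[Run]] = {}
    for chrom, blocks in hmap.by_chromosome().items():
        runs: list[Run] = []
        current: list[HomologyBlock] = []
        for b in blocks:
            if b.is_gap:
                if current:
                    runs.append(_close_run(chrom, current))
                    current = []
                continue
            if b.chromosome_ambiguous:
                if current:
                    runs.append(_close_run(chrom, current))
                runs.append(Run(chrom, b.source_chrom, (b,), ambiguous=True))
                current = []
                continue
            if current and current[-1].source_chrom == b.source_chrom \
                    and b.order_index == current[-1].order_index + 1:
                current.append(b)
            else:
                if current:
                    runs.append(_close_run(chrom, current))
                current = [b]
        if current:
            runs.append(_close_run(chrom, current))
        out[chrom] = runs
    return out


def _close_run(chrom: str, blocks: list[HomologyBlock]) -> Run:
    return Run(chrom, blocks[0].source_chrom, tuple(blocks), ambiguous=False)


def _default_probes(hmap: HomologyMap) -> set[str]:
    """Default probe set: every autosomal source chromosome detected."""
    return hmap.source_chromosomes() - SEX_CHROMOSOME_IDS


def count_conserved_regions(
    hmap: HomologyMap, probes: set[str] | None = None
) -> int:
    """Number of conserved chromosomal regions detected by the given probe
    set (default: all autosomal probes)."""
    probes = _default_probes(hmap) if probes is None else set(probes)
    count = 0
    for runs in runs_by_chromosome(hmap).values():
        for run in runs:
            if run.source_chrom in probes:
                count += 1
    return count


def intact_source_chromosomes(
    hmap: HomologyMap, include_sex: bool = False
) -> set[str]:
    """Source chromosomes conserved as intact synteny blocks.

    A source chromosome is intact iff all of its blocks land on a single
    target chromosome and that target chromosome carries nothing else —
    no blocks of another source and no explicit gap row (extra
    heterochromatic/NOR material disqualifies whole-chromosome
    conservation).  Chromosome-level ambiguity disqualifies every candidate
    source it touches.
    """
    targets: dict[str, set[str]] = {}
    disqualified: set[str] = set()
    gapped_targets: set[str] = set()
    target_sources: dict[str, set[str]] = {}
    for b in hmap.blocks:
        if b.is_gap:
            gapped_targets.add(b.target_chrom)
            continue
        if b.chromosome_ambiguous:
            disqualified |= b.source_chromosome_candidates
        for c in b.source_chromosome_candidates:
            targets.setdefault(c, set()).add(b.target_chrom)
        target_sources.setdefault(b.target_chrom, set()).add(b.source_chrom)
    intact: set[str] = set()
    for source, tset in targets.items():
        if source in disqualified or len(tset) != 1:
            continue
        (target,) = tset
        if target in gapped_targets:
            continue
        if target_sources[target] != {source}:
            continue
        intact.add(source)
    if not include_sex:
        intact -= SEX_CHROMOSOME_IDS
    return intact


def extract_syntenic_associations(hmap: HomologyMap) -> AssociationProfile:
    """Derive a species' association profile from its homology map.

    One association is emitted per adjacent pair of runs with different
    source chromosomes; a run adjacent to a chromosome-ambiguous run
    contributes an association per alternative, tagged ambiguous and
    excluded from shared-association reports.
    """
    associations: set[SyntenicAssociation] = set()
    ambiguous: set[SyntenicAssociation] = set()
    for runs in runs_by_chromosome(hmap).values():
        for left, right in zip(runs, runs[1:]):
            if right.first_index != left.last_index + 1:
                continue  # gap row between the runs
            if left.ambiguous or right.ambiguous:
                for a in _candidate_chroms(left):
                    for b in _candidate_chroms(right):
                        if a != b:
                            ambiguous.add(SyntenicAssociation.of(a, b))
                continue
            if left.source_chrom != right.source_chrom:
                associations.add(
                    SyntenicAssociation.of(left.source_chrom, right.source_chrom)
                )
    intact = intact_source_chromosomes(hmap, include_sex=False)
    return AssociationProfile(
        species=hmap.target_species,
        associations=frozenset(associations),
        intact=frozenset(intact),
        ambiguous=frozenset(ambiguous),
    )


def _candidate_chroms(run: Run) -> frozenset[str]:
    if not run.ambiguous:
        return frozenset({run.source_chrom})
    return run.blocks[0].source_chromosome_candidates


def shared_associations(
    profiles: list[AssociationProfile],
    required: set[str],
    excluded: set[str] = frozenset(),
) -> set[SyntenicAssociation]:
    """Associations unambiguously present in every required taxon and
    absent from every excluded taxon."""
    by_species = {p.species: p for p in profiles}
    unknown = (set(required) | set(excluded)) - set(by_species)
    if unknown:
        raise ValidationError(f"unknown taxon code(s) {sorted(unknown)}")
    if len(by_species) < 2:
        raise ValidationError("need at least two profiles")
    if not required:
        raise ValidationError("required taxon set is empty")
    shared: set[SyntenicAssociation] | None = None
    for sp in sorted(required):
        assoc = set(by_species[sp].associations)
        shared = assoc if shared is None else shared & assoc
    assert shared is not None
    for sp in sorted(excluded):
        # absence means: not present even as an ambiguous candidate
        shared -= set(by_species[sp].associations)
        shared -= set(by_species[sp].ambiguous)
    return shared


# ---------------------------------------------------------------------------
# homology composition / ECU space
# ---------------------------------------------------------------------------

def mca_ecu_lookup(ecus: list[ECU], source_species: str = "MCA") -> HomologyMap:
    """Build the probe-species -> ECU lookup map: one block per ECU
    location, target = probe-species region, source = opaque ECU id."""
    blocks: list[HomologyBlock] = []
    per_chrom_counter: dict[str, int] = {}
    order_of_arm = {"p": 0, "whole": 1, "q": 2}
    entries = []
    for ecu in ecus:
        for chrom, arm in ecu.mca_locations:
            entries.append((chrom, arm, ecu))
    entries.sort(key=lambda e: (chrom_sort_key(e[0]), order_of_arm.get(e[1], 3)))
    for chrom, arm, ecu in entries:
        idx = per_chrom_counter.get(chrom, 0) + 1
        per_chrom_counter[chrom] = idx
        region = (
            RegionLabel(chrom)
            if arm == "whole"
            else RegionLabel(chrom, ((arm, None),))
        )
        blocks.append(
            HomologyBlock(
                target_chrom=chrom,
                order_index=idx,
                target_region=region,
                source_region=SegmentLabel(ecu.ecu_id),
            )
        )
    return HomologyMap(
        target_species=source_species, source_species="ECU", blocks=tuple(blocks)
    )


def compose_homology(
    map_x_from_s: HomologyMap, map_s_to_h: HomologyMap
) -> HomologyMap:
    """Compose two homology maps: blocks of species X labeled with
    S-segments inherit the H-content of those segments from a second map
    whose target is S.

    Matching is at arm resolution; a target block finer than an arm
    inherits the whole arm's content flagged ``arm-resolution``.  Source
    ambiguity propagates: alternatives compose to alternative sets.  A
    source segment absent from the second map yields an ``unmapped`` block
    (reported, not dropped).
    """
    if map_x_from_s.source_species != map_s_to_h.target_species:
        raise ValidationError(
            f"cannot compose: first map sources {map_x_from_s.source_species}"
            f", second map targets {map_s_to_h.target_species}"
        )
    pivot_blocks = [b for b in map_s_to_h.blocks if not b.is_gap]

    def lookup(region: RegionLabel) -> list[HomologyBlock]:
        hits = [
            pb
            for pb in pivot_blocks
            if isinstance(region, RegionLabel)
            and pb.target_region.overlaps(region)
        ]
        hits.sort(key=lambda pb: (chrom_sort_key(pb.target_chrom), pb.order_index))
        return hits

    out_blocks: list[HomologyBlock] = []
    counters: dict[str, int] = {}
    for b in map_x_from_s.blocks:
        if b.is_gap:
            out_blocks.append(_renumber(b, counters))
            continue
        hits = lookup(b.source_region)
        alt_sources = tuple(
            pb.source_region
            for alt in b.alternatives
            for pb in lookup(alt)
        )
        if not hits:
            out_blocks.append(
                _renumber(
                    HomologyBlock(
                        target_chrom=b.target_chrom,
                        order_index=b.order_index,
                        target_region=b.target_region,
                        source_region=None,
                        flags=b.flags | {"unmapped"},
                    ),
                    counters,
                )
            )
            continue
        finer = (
            isinstance(b.source_region, RegionLabel)
            and b.source_region.finer_than_arm
        )
        for pb in hits:
            flags = set(b.flags)
            if finer:
                flags.add("arm-resolution")
            out_blocks.append(
                _renumber(
                    HomologyBlock(
                        target_chrom=b.target_chrom,
                        order_index=b.order_index,
                        target_region=b.target_region,
                        source_region=pb.source_region,
                        alternatives=tuple(
                            a for a in alt_sources if a != pb.source_region
                        ),
                        flags=frozenset(flags),
                    ),
                    counters,
                )
            )
    return HomologyMap(
        target_species=map_x_from_s.target_species,
        source_species=map_s_to_h.source_species,
        blocks=tuple(out_blocks),
    )


def _renumber(block: HomologyBlock, counters: dict[str, int]) -> HomologyBlock:
    idx = counters.get(block.target_chrom, 0) + 1
    counters[block.target_chrom] = idx
    if idx == block.order_index:
        return block
    return HomologyBlock(
        target_chrom=block.target_chrom,
        order_index=idx,
        target_region=block.target_region,
        source_region=block.source_region,
        alternatives=block.alternatives,
        flags=block.flags,
    )


def ecu_disruption_count(
    composed_map: HomologyMap, ecus: list[ECU]
) -> tuple[int, list[str]]:
    """Count ECUs whose content is distributed over two or more target
    chromosomes in a map composed to ECU space.

    Blocks are attributed to ECUs through their primary source; arm-level
    ``or`` alternatives never add chromosomes (any consistent resolution of
    a whole-chromosome paint places each probe arm exactly once).
    """
    if composed_map.source_species != "ECU":
        raise ValidationError(
            "ecu_disruption_count expects a map composed to ECU space "
            f"(source species 'ECU'), got {composed_map.source_species!r}"
        )
    known = {e.ecu_id for e in ecus}
    spread: dict[str, set[str]] = {}
    for b in composed_map.blocks:
        if b.is_gap:
            continue
        eid = b.source_region.chromosome_id
        if eid not in known:
            continue
        spread.setdefault(eid, set()).add(b.target_chrom)
    disrupted = sorted(
        (eid for eid, chroms in spread.items() if len(chroms) >= 2),
    )
    return len(disrupted), disrupted


def infer_plesiomorphic_chromosomes(
    profiles: list[AssociationProfile], outgroup: str
) -> set[str]:
    """Probe-species chromosomes proposed as plesiomorphic for the clade:
    intact in the outgroup and in at least one ingroup profile."""
    by_species = {p.species: p for p in profiles}
    if outgroup not in by_species:
        raise ValidationError(f"no profile for outgroup {outgroup!r}")
    out_intact = set(by_species[outgroup].intact)
    ingroup_union: set[str] = set()
    for sp, profile in by_species.items():
        if sp == outgroup:
            continue
        ingroup_union |= set(profile.intact)
    return out_intact & ingroup_union
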