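"""Core cytogenetic domain types.

Coordinates throughout the package are ordinal: a homology map records the
cytogenetic block order pter->qter on each target chromosome, never base
pairs.  Block adjacency means consecutive ``order_index`` on the same target
chromosome with no explicit gap row between.
"""

from __future__ import annotations

from dataclasses import dataclass

ACROCENTRIC = "acrocentric"
SUBTELOCENTRIC = "subtelocentric"
SUBMETACENTRIC = "submetacentric"
METACENTRIC = "metacentric"

MORPHOLOGIES = frozenset(
    {ACROCENTRIC, SUBTELOCENTRIC, SUBMETACENTRIC, METACENTRIC}
)
#: morphology classes that count two arms toward the fundamental number
BI_ARMED = frozenset({SUBTELOCENTRIC, SUBMETACENTRIC, METACENTRIC})

#: qualifier letters of the cytogenetic label grammar
QUALIFIERS = {
    "p": "proximal",
    "i": "interstitial",
    "d": "distal",
    "t": "terminal",
}
QUALIFIER_LETTERS = {v: k for k, v in QUALIFIERS.items()}

#: block flags carried through from painting / morphology context
KNOWN_FLAGS = frozenset(
    {"inverted", "bi-armed", "NOR-adjacent", "arm-resolution", "unmapped"}
)


class ValidationError(ValueError):
    """An invariant of a domain object does not hold."""


@dataclass(frozen=True)
class Chromosome:
    """One chromosome pair (haploid representation) of a karyotype."""

    id: str
    morphology: str
    is_sex: bool = False

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ValidationError(
                f"unknown morphology {self.morphology!r} for chromosome "
                f"{self.id!r}"
            )
        if not self.id:
            raise ValidationError("chromosome id must be non-empty")

    @property
    def arms(self) -> int:
        """Number of arms: acrocentric = 1, any bi-armed class = 2."""
        return 2 if self.morphology in BI_ARMED else 1


@dataclass(frozen=True)
class Karyotype:
    """A species' chromosome complement, one entry per autosome pair and one
    per sex chromosome copy (male fixtures carry X and Y once each)."""

    species: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        if not self.chromosomes:
            raise ValidationError(f"{self.species}: no chromosomes")
        ids = [c.id for c in self.chromosomes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(
                f"{self.species}: duplicate chromosome id(s) {sorted(dupes)}"
            )
        if sum(1 for c in self.chromosomes if c.is_sex and c.id == "X") > 1:
            raise ValidationError(f"{self.species}: more than one X")

    @property
    def autosomes(self) -> tuple[Chromosome, ...]:
        return tuple(c for c in self.chromosomes if not c.is_sex)

    @property
    def sex_chromosomes(self) -> tuple[Chromosome, ...]:
        return tuple(c for c in self.chromosomes if c.is_sex)

    @property
    def diploid_number(self) -> int:
        """2n: autosome rows are pairs, sex rows are single copies."""
        return 2 * len(self.autosomes) + len(self.sex_chromosomes)

    def __getitem__(self, chrom_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(chrom_id)


@dataclass(frozen=True)
class RegionLabel:
    """A cytogenetic region of one chromosome.

    ``parts`` is an ordered tuple of ``(arm, qualifier)`` pairs; the single
    pair ``("whole", None)`` denotes the whole chromosome, and two pairs
    denote a centromere-spanning composite such as ``12p/qp``.
    """

    chromosome_id: str
    parts: tuple[tuple[str, str | None], ...] = (("whole", None),)

    def __post_init__(self) -> None:
        object.__setattr__(self, "parts", tuple(tuple(p) for p in self.parts))
        for arm, qual in self.parts:
            if arm not in ("p", "q", "whole"):
                raise ValidationError(f"bad arm {arm!r} in {self!r}")
            if arm == "whole" and qual is not None:
                raise ValidationError(
                    "whole-chromosome label carries no qualifier"
                )
            if qual is not None and qual not in QUALIFIERS.values():
                raise ValidationError(f"bad qualifier {qual!r} in {self!r}")
        if len(self.parts) > 1 and any(a == "whole" for a, _ in self.parts):
            raise ValidationError("composite label cannot contain 'whole'")

    # -- spec-level accessors -------------------------------------------
    @property
    def arm(self) -> str:
        return self.parts[0][0]

    @property
    def qualifier(self) -> str | None:
        return self.parts[0][1]

    @property
    def spans_centromere(self) -> bool:
        return len(self.parts) > 1 and len({a for a, _ in self.parts}) > 1

    @property
    def is_whole(self) -> bool:
        return self.parts == (("whole", None),)

    def arms_covered(self) -> frozenset[str]:
        if self.is_whole:
            return frozenset({"p", "q"})
        return frozenset(a for a, _ in self.parts)

    def expand(self) -> list["RegionLabel"]:
        """Composite labels expand to an ordered list of simple labels."""
        return [RegionLabel(self.chromosome_id, (p,)) for p in self.parts]

    def overlaps(self, other: "RegionLabel") -> bool:
        """Arm-resolution overlap test (qualifiers are ignored)."""
        if self.chromosome_id != other.chromosome_id:
            return False
        return bool(self.arms_covered() & other.arms_covered())

    @property
    def finer_than_arm(self) -> bool:
        return any(q is not None for _, q in self.parts)

    def __str__(self) -> str:
        if self.is_whole:
            return self.chromosome_id
        body = "/".join(
            a + (QUALIFIER_LETTERS[q] if q else "") for a, q in self.parts
        )
        return f"{self.chromosome_id}{body}"


@dataclass(frozen=True)
class SegmentLabel:
    """A free-form conserved-segment label (e.g. an HSA segment ``5a`` or a
    whole ECU id) used as block source in composed/lookup maps, where the
    p/q arm grammar does not apply."""

    text: str

    @property
    def chromosome_id(self) -> str:
        return self.text

    def __str__(self) -> str:
        return self.text


SourceRegion = RegionLabel | SegmentLabel


@dataclass(frozen=True)
class HomologyBlock:
    """One painted block on a target chromosome.

    A gap row (unlabeled heterochromatin / NOR material) has
    ``source_region is None``; gaps carry no homology but make contiguity
    decidable and break run/association adjacency.
    """

    target_chrom: str
    order_index: int
    target_region: RegionLabel
    source_region: SourceRegion | None
    alternatives: tuple[SourceRegion, ...] = ()
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "alternatives", tuple(self.alternatives))
        object.__setattr__(self, "flags", frozenset(self.flags))
        if self.order_index < 1:
            raise ValidationError(
                f"order_index must be >= 1 (target {self.target_chrom})"
            )
        if self.target_region.chromosome_id != self.target_chrom:
            raise ValidationError(
                f"target region {self.target_region} does not belong to "
                f"chromosome {self.target_chrom}"
            )
        unknown = self.flags - KNOWN_FLAGS
        if unknown:
            raise ValidationError(f"unknown flag(s) {sorted(unknown)}")
        if self.is_gap and self.alternatives:
            raise ValidationError("gap rows cannot carry alternatives")

    @property
    def is_gap(self) -> bool:
        return self.source_region is None

    @property
    def source_chrom(self) -> str | None:
        if self.source_region is None:
            return None
        return self.source_region.chromosome_id

    @property
    def is_ambiguous(self) -> bool:
        """True when the fixture row contained an ``or`` alternative."""
        return bool(self.alternatives)

    @property
    def source_chromosome_candidates(self) -> frozenset[str]:
        """Source chromosomes compatible with this block (primary plus
        alternatives).  Arm-level ambiguity yields a singleton set."""
        if self.is_gap:
            return frozenset()
        return frozenset(
            {self.source_chrom}
            | {a.chromosome_id for a in self.alternatives}
        )

    @property
    def chromosome_ambiguous(self) -> bool:
        """True when the alternatives span more than one source chromosome,
        i.e. even the source chromosome identity is uncertain."""
        return len(self.source_chromosome_candidates) > 1


@dataclass(frozen=True)
class HomologyMap:
    """Ordered painted blocks of one target species, labeled with source
    (probe) species segments."""

    target_species: str
    source_species: str
    blocks: tuple[HomologyBlock, ...]

    def __post_init__(self) -> None:
        blocks = tuple(
            sorted(self.blocks, key=lambda b: (_chrom_key(b.target_chrom), b.order_index))
        )
        object.__setattr__(self, "blocks", blocks)
        self._check_order()

    def _check_order(self) -> None:
        for chrom, blist in self.by_chromosome().items():
            indices = [b.order_index for b in blist]
            expected = list(range(1, len(blist) + 1))
            if indices != expected:
                raise ValidationError(
                    f"{self.target_species} chromosome {chrom}: order_index "
                    f"sequence {indices} is not contiguous from 1"
                )

    def by_chromosome(self) -> dict[str, list[HomologyBlock]]:
        out: dict[str, list[HomologyBlock]] = {}
        for b in self.blocks:
            out.setdefault(b.target_chrom, []).append(b)
        for blist in out.values():
            blist.sort(key=lambda b: b.order_index)
        return out

    def source_chromosomes(self, include_gaps: bool = False) -> set[str]:
        out: set[str] = set()
        for b in self.blocks:
            if b.is_gap:
                continue
            out |= b.source_chromosome_candidates
        return out

    def validate_probes(self, probes: set[str]) -> None:
        """Every probe chromosome must detect at least one homologous
        region in the map."""
        missing = set(probes) - self.source_chromosomes()
        if missing:
            raise ValidationError(
                f"{self.target_species}: probe chromosome(s) "
                f"{sorted(missing)} absent from all blocks"
            )

    def target_chromosomes(self) -> list[str]:
        return sorted({b.target_chrom for b in self.blocks}, key=_chrom_key)


@dataclass(frozen=True)
class ECU:
    """An Evolutionarily Conserved Unit: a chiropteran chromosomal block
    expressed as a combination of human (HSA) chromosome segments, located
    on the probe species' karyotype at arm resolution."""

    ecu_id: str
    hsa_segments: str
    segments: tuple[str, ...]
    mca_locations: tuple[tuple[str, str], ...]  # (chromosome, arm|"whole")

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(
            self, "mca_locations", tuple(tuple(l) for l in self.mca_locations)
        )
        if not self.ecu_id:
            raise ValidationError("ECU id must be non-empty")
        if not self.segments:
            raise ValidationError(f"ECU {self.ecu_id}: no HSA segments")


def _chrom_key(chrom_id: str) -> tuple[int, int, str]:
    """Numeric chromosomes first in numeric order, then X, Y, others."""
    if chrom_id.isdigit():
        return (0, int(chrom_id), "")
    order = {"X": 0, "Y": 1}
    return (1, order.get(chrom_id, 2), chrom_id)


def chrom_sort_key(chrom_id: str):
    """Public stable sort key for chromosome ids ("1" < "2" < ... < "X")."""
    return _chrom_key(chrom_id)
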