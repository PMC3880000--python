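"""Karyotype-evolution simulator with painting-style observation model.

Chromosomes are ordered tuples of uniquely labeled arm segments from a
root (ancestral) karyotype; rearrangement events are drawn per branch from
Poisson laws and applied at segment boundaries, so content is conserved by
construction and every tip can be projected back onto the root paints as a
homology map with known ground truth.

Event semantics (haploid bookkeeping, diploid numbers doubled):

* ``rb_fusion``: centric fusion of two acrocentrics into one bi-armed
  chromosome (2n-2, FN unchanged);
* ``rb_fission``: the reverse (2n+2, FN unchanged);
* ``tandem_fusion``: end-to-end joining of an acrocentric donor onto
  another chromosome's q terminus, donor centromere inactivated
  (2n-2, FN-2);
* ``pericentric_inversion``: centromere repositioning that toggles the
  morphology class (acrocentric <-> bi-armed) without changing synteny;
* ``whole_arm_translocation``: fission of a bi-armed chromosome with
  crosswise fusion of one arm to an acrocentric (composite event).

The default root karyotype mimics the hypothesized phyllostomid ancestral
condition: 22 autosome pairs, 2n = 46 with an FN = 60-consistent mix of
8 bi-armed and 14 acrocentric autosomes.  No rates or branch lengths are
known for the real radiation; defaults are illustrative only.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .model import (
    ACROCENTRIC,
    Chromosome,
    HomologyBlock,
    HomologyMap,
    Karyotype,
    METACENTRIC,
    RegionLabel,
    SUBMETACENTRIC,
    SUBTELOCENTRIC,
    ValidationError,
)
from .phylo import PhylogeneticTree
from .synteny import SyntenicAssociation

RB_FUSION = "rb_fusion"
RB_FISSION = "rb_fission"
TANDEM_FUSION = "tandem_fusion"
PERICENTRIC_INVERSION = "pericentric_inversion"
WHOLE_ARM_TRANSLOCATION = "whole_arm_translocation"

EVENT_KINDS = (
    RB_FUSION,
    RB_FISSION,
    TANDEM_FUSION,
    PERICENTRIC_INVERSION,
    WHOLE_ARM_TRANSLOCATION,
)

DEFAULT_RETRY_BUDGET = 100
ROOT_SPECIES = "ANC"


class SimulationError(RuntimeError):
    """Simulation could not proceed (e.g. retry budget exhausted)."""


Segment = tuple[str, str]  # (root chromosome id, unique piece label)


@dataclass(frozen=True)
class SimChromosome:
    """A chromosome as an ordered pter->qter tuple of root segments with a
    centromere index (``cen`` segments precede the centromere; ``cen == 0``
    means acrocentric)."""

    uid: str
    seq: tuple[Segment, ...]
    cen: int
    is_sex: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError(f"{self.uid}: empty chromosome")
        if not 0 <= self.cen <= len(self.seq):
            raise ValidationError(f"{self.uid}: centromere out of range")

    @property
    def acrocentric(self) -> bool:
        return self.cen in (0, len(self.seq))

    def normalized(self) -> "SimChromosome":
        """Orient so an acrocentric centromere sits at index 0."""
        if self.cen == len(self.seq):
            return replace(self, seq=tuple(reversed(self.seq)), cen=0)
        return self

    @property
    def morphology(self) -> str:
        n = len(self.seq)
        if self.acrocentric:
            return ACROCENTRIC
        ratio = min(self.cen, n - self.cen) / n
        if ratio >= 0.4:
            return METACENTRIC
        if ratio >= 0.25:
            return SUBMETACENTRIC
        return SUBTELOCENTRIC

    @property
    def arms(self) -> int:
        return 1 if self.acrocentric else 2


@dataclass(frozen=True)
class SimKaryotype:
    species: str
    chromosomes: tuple[SimChromosome, ...]

    @property
    def autosomes(self) -> tuple[SimChromosome, ...]:
        return tuple(c for c in self.chromosomes if not c.is_sex)

    def segment_multiset(self) -> dict[Segment, int]:
        counts: dict[Segment, int] = {}
        for c in self.chromosomes:
            for s in c.seq:
                counts[s] = counts.get(s, 0) + 1
        return counts


@dataclass(frozen=True)
class RearrangementEvent:
    branch: str  # child-node id of the tree edge
    kind: str
    operands: tuple[str, ...]  # chromosome uids before the event
    result: tuple[str, ...]  # chromosome uids after the event
    #: root chromosomes adjacent at the new junction, for fusion events
    junction: tuple[str, str] | None = None


def default_root_karyotype(
    n_autosomes: int = 22,
    n_biarmed: int = 8,
    segments_per_arm: int = 2,
    species: str = ROOT_SPECIES,
) -> SimKaryotype:
    """MWA-like ancestral complement: ``n_biarmed`` bi-armed plus
    acrocentric autosomes (default 2n=46, FN=60), one X and one Y."""
    if n_biarmed > n_autosomes:
        raise ValidationError("more bi-armed chromosomes than autosomes")
    chroms = []
    for i in range(1, n_autosomes + 1):
        cid = str(i)
        q = tuple((cid, f"q{j}") for j in range(1, segments_per_arm + 1))
        if i <= n_biarmed:
            p = tuple((cid, f"p{j}") for j in range(segments_per_arm, 0, -1))
            chroms.append(SimChromosome(cid, p + q, cen=len(p)))
        else:
            chroms.append(SimChromosome(cid, q, cen=0))
    x = tuple(("X", f"q{j}") for j in range(1, segments_per_arm + 1))
    xp = tuple(("X", f"p{j}") for j in range(segments_per_arm, 0, -1))
    chroms.append(SimChromosome("X", xp + x, cen=len(xp), is_sex=True))
    chroms.append(SimChromosome("Y", (("Y", "q1"),), cen=0, is_sex=True))
    return SimKaryotype(species=species, chromosomes=tuple(chroms))


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def apply_event(
    karyotype: SimKaryotype,
    kind: str,
    operands: tuple[str, ...],
    rng: np.random.Generator,
    uid_counter: list[int],
    branch: str = "",
) -> tuple[SimKaryotype, RearrangementEvent]:
    """Apply one rearrangement to the named operand chromosomes and return
    the new karyotype plus the event record."""
    by_uid = {c.uid: c for c in karyotype.chromosomes}
    for uid in operands:
        if uid not in by_uid:
            raise SimulationError(f"operand {uid!r} not in karyotype")

    def new_uid() -> str:
        uid_counter[0] += 1
        return f"n{uid_counter[0]}"

    def rebuild(removed: tuple[str, ...], added: list[SimChromosome]):
        chroms = [c for c in karyotype.chromosomes if c.uid not in removed]
        chroms.extend(added)
        return SimKaryotype(karyotype.species, tuple(chroms))

    if kind == RB_FUSION:
        a, b = (by_uid[u].normalized() for u in operands)
        if not (a.acrocentric and b.acrocentric):
            raise SimulationError("rb_fusion requires two acrocentrics")
        fused = SimChromosome(
            new_uid(), tuple(reversed(a.seq)) + b.seq, cen=len(a.seq)
        )
        junction = (a.seq[0][0], b.seq[0][0])
        kary = rebuild(operands, [fused])
        result = (fused.uid,)
    elif kind == RB_FISSION:
        (c,) = (by_uid[operands[0]],)
        if c.acrocentric:
            raise SimulationError("rb_fission requires a bi-armed chromosome")
        left = SimChromosome(
            new_uid(), tuple(reversed(c.seq[: c.cen])), cen=0
        )
        right = SimChromosome(new_uid(), c.seq[c.cen:], cen=0)
        junction = None
        kary = rebuild(operands, [left, right])
        result = (left.uid, right.uid)
    elif kind == TANDEM_FUSION:
        acceptor = by_uid[operands[0]].normalized()
        donor = by_uid[operands[1]].normalized()
        if not donor.acrocentric:
            raise SimulationError("tandem_fusion donor must be acrocentric")
        fused = SimChromosome(
            new_uid(), acceptor.seq + donor.seq, cen=acceptor.cen
        )
        junction = (acceptor.seq[-1][0], donor.seq[0][0])
        kary = rebuild(operands, [fused])
        result = (fused.uid,)
    elif kind == PERICENTRIC_INVERSION:
        c = by_uid[operands[0]].normalized()
        if c.acrocentric:
            if len(c.seq) < 2:
                raise SimulationError(
                    "pericentric inversion needs >= 2 segments"
                )
            new_cen = int(rng.integers(1, len(c.seq)))
        else:
            new_cen = 0
        moved = SimChromosome(new_uid(), c.seq, cen=new_cen)
        junction = None
        kary = rebuild(operands, [moved])
        result = (moved.uid,)
    elif kind == WHOLE_ARM_TRANSLOCATION:
        biarm = by_uid[operands[0]]
        acro = by_uid[operands[1]].normalized()
        if biarm.acrocentric or not acro.acrocentric:
            raise SimulationError(
                "whole_arm_translocation needs a bi-armed and an acrocentric"
            )
        arm_p = SimChromosome("tmp1", tuple(reversed(biarm.seq[: biarm.cen])), 0)
        arm_q = SimChromosome("tmp2", biarm.seq[biarm.cen:], 0)
        moved, kept = (
            (arm_p, arm_q) if rng.integers(2) == 0 else (arm_q, arm_p)
        )
        fused = SimChromosome(
            new_uid(), tuple(reversed(moved.seq)) + acro.seq, cen=len(moved.seq)
        )
        rest = SimChromosome(new_uid(), kept.seq, cen=0)
        junction = (moved.seq[0][0], acro.seq[0][0])
        kary = rebuild(operands, [fused, rest])
        result = (fused.uid, rest.uid)
    else:
        raise SimulationError(f"unknown event kind {kind!r}")

    event = RearrangementEvent(
        branch=branch,
        kind=kind,
        operands=tuple(operands),
        result=result,
        junction=junction,
    )
    return kary, event


def _feasible_operands(
    karyotype: SimKaryotype, kind: str, rng: np.random.Generator
) -> tuple[str, ...] | None:
    autos = list(karyotype.autosomes)
    acros = [c for c in autos if c.acrocentric]
    biarms = [c for c in autos if not c.acrocentric]
    if kind == RB_FUSION:
        if len(acros) < 2:
            return None
        picks = rng.choice(len(acros), size=2, replace=False)
        return (acros[picks[0]].uid, acros[picks[1]].uid)
    if kind == RB_FISSION:
        if not biarms:
            return None
        return (biarms[int(rng.integers(len(biarms)))].uid,)
    if kind == TANDEM_FUSION:
        donors = acros
        if not donors or len(autos) < 2:
            return None
        donor = donors[int(rng.integers(len(donors)))]
        acceptors = [c for c in autos if c.uid != donor.uid]
        acceptor = acceptors[int(rng.integers(len(acceptors)))]
        return (acceptor.uid, donor.uid)
    if kind == PERICENTRIC_INVERSION:
        eligible = [c for c in autos if not c.acrocentric or len(c.seq) >= 2]
        if not eligible:
            return None
        return (eligible[int(rng.integers(len(eligible)))].uid,)
    if kind == WHOLE_ARM_TRANSLOCATION:
        if not biarms or not acros:
            return None
        return (
            biarms[int(rng.integers(len(biarms)))].uid,
            acros[int(rng.integers(len(acros)))].uid,
        )
    raise SimulationError(f"unknown event kind {kind!r}")


# ---------------------------------------------------------------------------
# histories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedHistory:
    tree: PhylogeneticTree
    root_karyotype: SimKaryotype
    node_karyotypes: dict[str, SimKaryotype]
    events: tuple[RearrangementEvent, ...]
    rates: dict[str, float]
    seed: int

    def events_on(self, branch: str) -> list[RearrangementEvent]:
        return [e for e in self.events if e.branch == branch]

    def tip_karyotype(self, tip: str) -> Karyotype:
        return export_karyotype(self.node_karyotypes[tip], tip)

    def true_map(self, tip: str) -> HomologyMap:
        return project_painting(self, tip, resolution="block")

    def true_adjacencies(self, tip: str) -> set[SyntenicAssociation]:
        """Ground-truth associations at a tip straight from the segment
        structure (independent of the painting projection)."""
        out: set[SyntenicAssociation] = set()
        for chrom in self.node_karyotypes[tip].chromosomes:
            if chrom.is_sex:
                continue
            roots = [s[0] for s in chrom.seq]
            for a, b in zip(roots, roots[1:]):
                if a != b:
                    out.add(SyntenicAssociation.of(a, b))
        return out

    def intact_root_chromosomes(self, tip: str) -> set[str]:
        """Root autosomes structurally intact at a tip: all segments on a
        single tip chromosome carrying nothing else."""
        root_ids = {c.uid for c in self.root_karyotype.autosomes}
        root_sizes = {
            c.uid: len(c.seq) for c in self.root_karyotype.chromosomes
        }
        intact = set()
        for rid in root_ids:
            homes = [
                c
                for c in self.node_karyotypes[tip].chromosomes
                for s in c.seq
                if s[0] == rid
            ]
            chroms = {c.uid for c in homes}
            if len(chroms) != 1:
                continue
            home = homes[0]
            if len(home.seq) == root_sizes[rid] and all(
                s[0] == rid for s in home.seq
            ):
                intact.add(rid)
        return intact


def _branch_rng(seed: int, branch: str) -> np.random.Generator:
    """Per-branch substream from a stable hash of the edge id, so subtree
    simulations are reproducible independent of traversal order."""
    h = zlib.crc32(f"{seed}:{branch}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(h)


def simulate_history(
    tree: PhylogeneticTree,
    rates: dict[str, float] | None = None,
    root_karyotype: SimKaryotype | None = None,
    seed: int = 0,
    retry_budget: int = DEFAULT_RETRY_BUDGET,
) -> SimulatedHistory:
    """Simulate rearrangement histories along the tree.

    Per-branch event counts are Poisson with mean ``rate x branch length``
    per kind; events are applied sequentially with operand feasibility
    checks (resampled up to ``retry_budget`` times).  Fully reproducible
    from ``seed``.
    """
    rates = dict(rates or {})
    unknown = set(rates) - set(EVENT_KINDS)
    if unknown:
        raise ValidationError(f"unknown event kind(s) {sorted(unknown)}")
    if any(r < 0 for r in rates.values()):
        raise ValidationError("rates must be >= 0")
    root = root_karyotype or default_root_karyotype()
    node_karyotypes = {tree.root: root}
    events: list[RearrangementEvent] = []
    uid_counter = [0]
    for node in reversed(tree.postorder()):  # preorder: parents first
        if node == tree.root:
            continue
        parent = tree.parent[node]
        kary = node_karyotypes[parent]
        rng = _branch_rng(seed, node)
        bl = tree.branch_length(node)
        kinds: list[str] = []
        for kind in EVENT_KINDS:
            lam = rates.get(kind, 0.0) * bl
            if lam > 0:
                kinds.extend([kind] * int(rng.poisson(lam)))
        rng.shuffle(kinds)
        for kind in kinds:
            operands = None
            for _ in range(retry_budget):
                operands = _feasible_operands(kary, kind, rng)
                if operands is not None:
                    break
            if operands is None:
                raise SimulationError(
                    f"retry budget exhausted: no feasible operands for "
                    f"{kind} on branch {node} (seed {seed})"
                )
            kary, event = apply_event(
                kary, kind, operands, rng, uid_counter, branch=node
            )
            events.append(event)
        node_karyotypes[node] = kary
    return SimulatedHistory(
        tree=tree,
        root_karyotype=root,
        node_karyotypes=node_karyotypes,
        events=tuple(events),
        rates=rates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def _tip_labeling(kary: SimKaryotype) -> list[tuple[str, SimChromosome]]:
    """Stable export labels: autosomes numbered 1..n by decreasing size,
    ties by uid; sex chromosomes keep their names."""
    autos = sorted(kary.autosomes, key=lambda c: (-len(c.seq), c.uid))
    labeled = [(str(i), c) for i, c in enumerate(autos, start=1)]
    labeled.extend(
        (c.seq[0][0], c) for c in kary.chromosomes if c.is_sex
    )
    return labeled


def export_karyotype(kary: SimKaryotype, species: str) -> Karyotype:
    return Karyotype(
        species=species,
        chromosomes=tuple(
            Chromosome(cid, c.morphology, is_sex=c.is_sex)
            for cid, c in _tip_labeling(kary)
        ),
    )


def _arm_qualifiers(n: int) -> list[str | None]:
    if n == 1:
        return [None]
    quals = ["proximal"] + ["interstitial"] * (n - 2) + ["terminal"]
    return quals


def _block_regions(
    chrom_id: str, n_p: int, n_q: int, blocks: int
) -> list[RegionLabel]:
    """Assign parseable region labels to ``blocks`` ordered blocks given
    how many fall on each arm (a block may straddle the centromere)."""
    labels: list[RegionLabel] = []
    if blocks == 1:
        return [RegionLabel(chrom_id)]
    p_quals = list(reversed(_arm_qualifiers(n_p))) if n_p else []
    q_quals = _arm_qualifiers(n_q) if n_q else []
    straddle = blocks - n_p - n_q  # 0 or 1
    for q in p_quals:
        labels.append(RegionLabel(chrom_id, (("p", q),)))
    if straddle:
        labels.append(
            RegionLabel(chrom_id, (("p", "proximal"), ("q", "proximal")))
        )
    for q in q_quals:
        labels.append(RegionLabel(chrom_id, (("q", q),)))
    return labels


def project_painting(
    history: SimulatedHistory,
    tip: str,
    resolution: str = "arm",
    ambiguity_noise: float = 0.0,
    seed: int | None = None,
) -> HomologyMap:
    """Project a tip's true segment composition onto the root paints.

    At ``arm`` resolution maximal runs of segments from one root chromosome
    merge into one block, as contiguous signals do in real painting; at
    ``block`` resolution runs are additionally split at the root p/q arm
    boundary (the true segment map).  With ``ambiguity_noise`` > 0 a block
    may report an ``or`` alternative naming another root chromosome.
    """
    if tip not in history.node_karyotypes:
        raise ValidationError(f"unknown tip {tip!r}")
    if resolution not in ("arm", "block"):
        raise ValidationError(f"unknown resolution {resolution!r}")
    kary = history.node_karyotypes[tip]
    rng = np.random.default_rng(
        zlib.crc32(f"paint:{history.seed}:{tip}:{seed}".encode()) & 0x7FFFFFFF
    )
    root_ids = [c.uid for c in history.root_karyotype.chromosomes]
    root_pieces = {
        c.uid: {piece for _, piece in c.seq}
        for c in history.root_karyotype.chromosomes
    }
    blocks: list[HomologyBlock] = []
    for cid, chrom in _tip_labeling(kary):
        if cid == "Y":
            continue  # no Y paint in the observation model
        chrom = chrom.normalized()
        # group segments into observed blocks
        groups: list[list[tuple[int, Segment]]] = []
        for pos, seg in enumerate(chrom.seq):
            key = seg[0] if resolution == "arm" else (seg[0], seg[1][0])
            if groups and groups[-1][0][2] == key:
                groups[-1].append((pos, seg, key))
            else:
                groups.append([(pos, seg, key)])
        n_p = sum(
            1 for g in groups if g[-1][0] < chrom.cen
        )
        n_q = sum(1 for g in groups if g[0][0] >= chrom.cen)
        regions = _block_regions(cid, n_p, n_q, len(groups))
        for order, (group, region) in enumerate(zip(groups, regions), start=1):
            root_chrom = group[0][1][0]
            pieces = {seg[1] for _, seg, _ in group}
            covered = {p[0] for p in pieces}
            if pieces == root_pieces[root_chrom]:
                source = RegionLabel(root_chrom)
            elif len(covered) == 1:
                source = RegionLabel(root_chrom, ((covered.pop(), None),))
            else:
                source = RegionLabel(
                    root_chrom, (("p", None), ("q", None))
                )
            alternatives: tuple = ()
            if ambiguity_noise > 0 and rng.random() < ambiguity_noise:
                others = [r for r in root_ids if r != root_chrom and r not in ("X", "Y")]
                if others and root_chrom not in ("X", "Y"):
                    alt = others[int(rng.integers(len(others)))]
                    alternatives = (RegionLabel(alt),)
            blocks.append(
                HomologyBlock(
                    target_chrom=cid,
                    order_index=order,
                    target_region=region,
                    source_region=source,
                    alternatives=alternatives,
                )
            )
    return HomologyMap(
        target_species=tip,
        source_species=history.root_karyotype.species,
        blocks=tuple(blocks),
    )


# ---------------------------------------------------------------------------
# recovery experiments
# ---------------------------------------------------------------------------

#: default experiment tree: the study topology with the outgroup branch at
#: length 0, so the outgroup observes the root (ancestral) state
DEFAULT_EXPERIMENT_NEWICK = "(((GSO:1,ACU:1):1,LCO:1):1,MCA:0);"
DEFAULT_OUTGROUP = "MCA"

FUSION_KINDS = frozenset({RB_FUSION, TANDEM_FUSION, WHOLE_ARM_TRANSLOCATION})
MAX_REPLICATES = 10_000


def recovery_experiment(
    rates: dict[str, float],
    replicates: int,
    seed: int,
    tree: PhylogeneticTree | None = None,
    ambiguity_noise: float = 0.0,
    root_karyotype: SimKaryotype | None = None,
) -> dict:
    """Simulate -> project -> analyze -> place, and score recovery.

    Reports the fraction of fusion events whose association character was
    placed on the branch the event occurred on (overall, and restricted to
    single-origin events — junction pairs produced exactly once in the
    replicate, i.e. no homoplasy, where a correct placement is
    identifiable at all), the rate of extracted associations absent from
    the ground-truth adjacency structure, and the fraction of replicates
    whose plesiomorphic set was recovered exactly, stratified by total
    event count.
    """
    from .phylo import build_character_matrix, place_paper_rule
    from .synteny import (
        extract_syntenic_associations,
        infer_plesiomorphic_chromosomes,
    )

    if replicates > MAX_REPLICATES:
        raise ValidationError(
            f"replicates capped at {MAX_REPLICATES} (desk-scale bound)"
        )
    tree = tree or PhylogeneticTree.from_newick(
        DEFAULT_EXPERIMENT_NEWICK, outgroup=DEFAULT_OUTGROUP
    )
    fusion_total = fusion_correct = 0
    single_total = single_correct = 0
    assoc_total = assoc_false = 0
    plesio_hits = 0
    strata: dict[int, dict[str, int]] = {}
    infeasible = 0
    for rep in range(replicates):
        rep_seed = (seed * 100_003 + rep) % (2**31 - 1)
        try:
            history = simulate_history(
                tree, rates=rates, root_karyotype=root_karyotype, seed=rep_seed
            )
        except SimulationError:
            # regime proposed more events than the karyotype supports
            # (e.g. fusions after the acrocentric pool is spent)
            infeasible += 1
            continue
        profiles = []
        for tip in tree.leaves:
            painted = project_painting(
                history, tip, resolution="arm", ambiguity_noise=ambiguity_noise
            )
            profile = extract_syntenic_associations(painted)
            profiles.append(profile)
            truth = history.true_adjacencies(tip)
            extracted = set(profile.associations)
            assoc_total += len(extracted)
            assoc_false += len(extracted - truth)
        matrix = build_character_matrix(profiles, outgroup=tree.outgroup)
        report = place_paper_rule(tree, matrix)
        gains: dict[str, set[str]] = {}
        for p in report.placements:
            gains[p.character] = set(p.nodes)
        fusion_events = [
            e
            for e in history.events
            if e.kind in FUSION_KINDS
            and e.junction is not None
            and e.junction[0] != e.junction[1]
        ]
        pair_counts: dict[str, int] = {}
        for e in fusion_events:
            name = SyntenicAssociation.of(*e.junction).canonical_name
            pair_counts[name] = pair_counts.get(name, 0) + 1
        rep_total = rep_correct = 0
        for event in fusion_events:
            rep_total += 1
            name = SyntenicAssociation.of(*event.junction).canonical_name
            correct = event.branch in gains.get(name, ())
            rep_correct += int(correct)
            if pair_counts[name] == 1:
                single_total += 1
                single_correct += int(correct)
        fusion_total += rep_total
        fusion_correct += rep_correct
        predicted = infer_plesiomorphic_chromosomes(
            profiles, outgroup=tree.outgroup
        )
        truth_plesio = _true_plesiomorphic(history, tree)
        plesio_ok = predicted == truth_plesio
        plesio_hits += int(plesio_ok)
        n_events = len(history.events)
        s = strata.setdefault(
            n_events,
            {"replicates": 0, "fusions": 0, "fusions_correct": 0, "plesio_ok": 0},
        )
        s["replicates"] += 1
        s["fusions"] += rep_total
        s["fusions_correct"] += rep_correct
        s["plesio_ok"] += int(plesio_ok)
    completed = replicates - infeasible
    return {
        "replicates": replicates,
        "completed_replicates": completed,
        "infeasible_replicates": infeasible,
        "rates": dict(rates),
        "ambiguity_noise": ambiguity_noise,
        "fusion_events": fusion_total,
        "placement_accuracy": (
            fusion_correct / fusion_total if fusion_total else 1.0
        ),
        "single_origin_fusions": single_total,
        "single_origin_placement_accuracy": (
            single_correct / single_total if single_total else 1.0
        ),
        "false_association_rate": (
            assoc_false / assoc_total if assoc_total else 0.0
        ),
        "plesiomorphy_recovery": plesio_hits / completed if completed else 1.0,
        "by_event_count": {
            str(k): dict(v) for k, v in sorted(strata.items())
        },
    }


def _true_plesiomorphic(
    history: SimulatedHistory, tree: PhylogeneticTree
) -> set[str]:
    outgroup_intact = history.intact_root_chromosomes(tree.outgroup)
    ingroup_union: set[str] = set()
    for tip in tree.ingroup_leaves:
        ingroup_union |= history.intact_root_chromosomes(tip)
    return outgroup_intact & ingroup_union
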