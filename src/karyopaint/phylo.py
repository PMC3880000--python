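"""Character matrices and placement of rearrangement characters on a tree.

Two engines are provided.  ``place_paper_rule`` applies the outgroup
convention used in comparative painting studies: a fusion association is a
derived character absent from the probe-species outgroup; a character
present in every ingroup species is plotted at the ingroup's most recent
common ancestor, one present in a monophyletic subset at that clade's
ancestor, one present in a single species at its terminal branch, and one
present in a non-monophyletic subset as independent (convergent) terminal
gains — a loss is never inferred.  ``fitch_parsimony`` and
``enumerate_mprs`` form a general minimum-change engine used as the
internal oracle: they report the parsimony minimum and every most
parsimonious reconstruction, so the report can flag characters whose
paper-rule placement is not the unique MPR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import dendropy

from .model import ValidationError
from .synteny import AssociationProfile, SyntenicAssociation


class TreeError(ValueError):
    """Tree input does not satisfy the pipeline's requirements."""


#: chromosomes assumed acrocentric (as in the outgroup) in the last common
#: ancestor of the ingroup when deducing rearrangements
ACROCENTRIC_ANCESTOR_IDS = frozenset({"13", "17", "18"})
ACROCENTRIC_ANNOTATION = "assumed-acrocentric-ancestor"


class PhylogeneticTree:
    """A rooted tree with a designated outgroup leaf.

    Node ids are stable strings: a leaf's id is its taxon label; an
    internal node's id is ``mrca(<sorted leaf labels>)``.  Branches are
    identified by their child node id.
    """

    def __init__(
        self,
        children: dict[str, tuple[str, ...]],
        root: str,
        branch_lengths: dict[str, float],
        outgroup: str | None = None,
    ) -> None:
        self.children = children
        self.root = root
        self.branch_lengths = branch_lengths
        self.outgroup = outgroup
        self.parent: dict[str, str] = {}
        for node, kids in children.items():
            for k in kids:
                self.parent[k] = node
        self._leaves = tuple(
            n for n in self.postorder() if not self.children.get(n)
        )
        if outgroup is not None and outgroup not in self._leaves:
            raise TreeError(f"outgroup {outgroup!r} is not a leaf of the tree")

    # -- construction ----------------------------------------------------
    @classmethod
    def from_newick(
        cls, newick: str, outgroup: str | None = None
    ) -> "PhylogeneticTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        leaves = [l.taxon.label for l in dtree.leaf_node_iter()]
        if len(leaves) < 2:
            raise TreeError("tree must have at least two leaves")
        if len(set(leaves)) != len(leaves):
            raise TreeError("duplicate leaf labels")
        if outgroup is not None:
            if outgroup not in leaves:
                raise TreeError(
                    f"outgroup {outgroup!r} not among leaves {sorted(leaves)}"
                )
            og_node = next(
                l for l in dtree.leaf_node_iter() if l.taxon.label == outgroup
            )
            if og_node.parent_node is not dtree.seed_node:
                dtree.reroot_at_edge(og_node.edge, update_bipartitions=False)
        if len(dtree.seed_node.child_nodes()) > 2 and outgroup is None:
            raise TreeError(
                "unrooted (multifurcating root) input requires an outgroup"
            )
        children: dict[str, tuple[str, ...]] = {}
        lengths: dict[str, float] = {}

        def build(node) -> str:
            kids = node.child_nodes()
            if not kids:
                nid = node.taxon.label
            else:
                kid_ids = [build(k) for k in kids]
                leafset = sorted(
                    l for k in kid_ids for l in _leaves_of(children, k)
                )
                nid = "mrca(" + ",".join(leafset) + ")"
                children[nid] = tuple(kid_ids)
            children.setdefault(nid, ())
            el = node.edge.length
            lengths[nid] = 1.0 if el is None else float(el)
            return nid

        root = build(dtree.seed_node)
        return cls(children, root, lengths, outgroup=outgroup)

    # -- traversal -------------------------------------------------------
    def postorder(self) -> list[str]:
        out: list[str] = []

        def walk(n: str) -> None:
            for k in self.children.get(n, ()):
                walk(k)
            out.append(n)

        walk(self.root)
        return out

    @property
    def leaves(self) -> tuple[str, ...]:
        return self._leaves

    @property
    def ingroup_leaves(self) -> tuple[str, ...]:
        return tuple(l for l in self._leaves if l != self.outgroup)

    def internal_nodes(self) -> list[str]:
        return [n for n in self.postorder() if self.children.get(n)]

    def is_leaf(self, node: str) -> bool:
        return not self.children.get(node)

    def leaves_below(self, node: str) -> frozenset[str]:
        return frozenset(_leaves_of(self.children, node))

    def mrca(self, labels) -> str:
        want = frozenset(labels)
        unknown = want - set(self._leaves)
        if unknown:
            raise TreeError(f"unknown leaf label(s) {sorted(unknown)}")
        best = self.root
        for node in self.postorder():
            below = self.leaves_below(node)
            if want <= below and len(below) < len(self.leaves_below(best)):
                best = node
        return best

    def is_clade(self, labels) -> bool:
        return self.leaves_below(self.mrca(labels)) == frozenset(labels)

    def edges(self) -> list[tuple[str, str]]:
        return [
            (self.parent[n], n) for n in self.postorder() if n != self.root
        ]

    def branch_length(self, child: str) -> float:
        return self.branch_lengths.get(child, 1.0)

    def to_newick(self, node_comments: dict[str, str] | None = None) -> str:
        comments = node_comments or {}

        def render(n: str) -> str:
            comment = comments.get(n, "")
            suffix = f"[&{comment}]" if comment else ""
            if self.is_leaf(n):
                return f"{n}{suffix}"
            inner = ",".join(render(k) for k in self.children[n])
            return f"({inner}){suffix}"

        return render(self.root) + ";"


def _leaves_of(children: dict[str, tuple[str, ...]], node: str) -> list[str]:
    kids = children.get(node, ())
    if not kids:
        return [node]
    return [l for k in kids for l in _leaves_of(children, k)]


# ---------------------------------------------------------------------------
# character matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CharacterMatrix:
    """Binary presence/absence of syntenic-association characters per
    taxon; the outgroup state is 0 for every fusion character (the probe
    karyotype defines absence)."""

    characters: tuple[SyntenicAssociation, ...]
    taxa: tuple[str, ...]
    states: dict[str, dict[str, int]]  # taxon -> character name -> 0/1
    outgroup: str
    annotations: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def state(self, taxon: str, character: SyntenicAssociation | str) -> int:
        name = (
            character.canonical_name
            if isinstance(character, SyntenicAssociation)
            else character
        )
        return self.states[taxon][name]

    def presence_set(self, character: SyntenicAssociation | str) -> frozenset[str]:
        name = (
            character.canonical_name
            if isinstance(character, SyntenicAssociation)
            else character
        )
        return frozenset(
            t for t in self.taxa if self.states[t][name] == 1
        )


def build_character_matrix(
    profiles: list[AssociationProfile], outgroup: str
) -> CharacterMatrix:
    """One binary character per distinct unambiguous association found in
    any ingroup profile; ambiguous (``or``-derived, cross-chromosome)
    associations are excluded; the outgroup is forced absent."""
    by_species = {p.species: p for p in profiles}
    if outgroup not in by_species:
        raise ValidationError(f"missing taxon profile for outgroup {outgroup!r}")
    characters: set[SyntenicAssociation] = set()
    for sp, profile in by_species.items():
        if sp != outgroup:
            characters |= set(profile.associations)
    ordered = tuple(sorted(characters, key=lambda a: a.canonical_name))
    taxa = tuple(sorted(by_species))
    states = {
        t: {
            c.canonical_name: (
                0
                if t == outgroup
                else int(c in by_species[t].associations)
            )
            for c in ordered
        }
        for t in taxa
    }
    annotations: dict[str, tuple[str, ...]] = {}
    if outgroup == "MCA":
        for c in ordered:
            if c.members & ACROCENTRIC_ANCESTOR_IDS:
                annotations[c.canonical_name] = (ACROCENTRIC_ANNOTATION,)
    return CharacterMatrix(
        characters=ordered,
        taxa=taxa,
        states=states,
        outgroup=outgroup,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Fitch / MPR engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitchResult:
    min_changes: int
    #: states each node takes in at least one most parsimonious
    #: reconstruction (exact, via min-cost messages in both directions)
    state_sets: dict[str, frozenset[int]]


def _leaf_states(
    tree: PhylogeneticTree, states: dict[str, int]
) -> dict[str, int]:
    missing = [l for l in tree.leaves if l not in states]
    if missing:
        raise ValidationError(f"leaf (leaves) without state: {missing}")
    bad = {l: s for l, s in states.items() if s not in (0, 1)}
    if bad:
        raise ValidationError(f"non-binary state(s): {bad}")
    return {l: states[l] for l in tree.leaves}


def fitch_character(
    tree: PhylogeneticTree, states: dict[str, int]
) -> FitchResult:
    """Minimum number of 0/1 changes for one character, with the exact set
    of states each node takes across all most parsimonious
    reconstructions."""
    leaf = _leaf_states(tree, states)
    down: dict[str, tuple[float, float]] = {}
    for node in tree.postorder():
        if tree.is_leaf(node):
            s = leaf[node]
            down[node] = (0.0 if s == 0 else float("inf"),
                          0.0 if s == 1 else float("inf"))
        else:
            c0 = c1 = 0.0
            for k in tree.children[node]:
                k0, k1 = down[k]
                c0 += min(k0, k1 + 1)
                c1 += min(k0 + 1, k1)
            down[node] = (c0, c1)
    up: dict[str, tuple[float, float]] = {tree.root: (0.0, 0.0)}
    for node in reversed(tree.postorder()):  # preorder
        kids = tree.children.get(node, ())
        for k in kids:
            sib_cost = [0.0, 0.0]
            for s in (0, 1):
                total = up[node][s]
                for other in kids:
                    if other is k:
                        continue
                    o0, o1 = down[other]
                    total += min(o0 + (s != 0), o1 + (s != 1))
                sib_cost[s] = total
            up[k] = (
                min(sib_cost[0], sib_cost[1] + 1),
                min(sib_cost[0] + 1, sib_cost[1]),
            )
    r0, r1 = down[tree.root]
    best = min(r0, r1)
    sets = {}
    for node in tree.postorder():
        d, u = down[node], up[node]
        sets[node] = frozenset(
            s for s in (0, 1) if d[s] + u[s] == best
        )
    return FitchResult(min_changes=int(best), state_sets=sets)


def fitch_parsimony(
    tree: PhylogeneticTree, matrix: CharacterMatrix
) -> dict[str, FitchResult]:
    """Per-character minimal change counts and ancestral state sets."""
    out = {}
    for c in matrix.characters:
        states = {t: matrix.state(t, c) for t in tree.leaves}
        out[c.canonical_name] = fitch_character(tree, states)
    return out


MAX_ENUM_INTERNAL_NODES = 12


def enumerate_mprs(
    tree: PhylogeneticTree,
    states: dict[str, int],
    root_state: int | None = None,
) -> tuple[int, list[dict[str, int]]]:
    """Exhaustively enumerate all minimal reconstructions of one binary
    character (deterministic node ordering).

    ``root_state`` constrains the root — with an outgroup the root is
    polarized to the outgroup's observed state.  Guarded to trees with at
    most ``MAX_ENUM_INTERNAL_NODES`` internal nodes.
    """
    leaf = _leaf_states(tree, states)
    internals = tree.internal_nodes()
    if len(internals) > MAX_ENUM_INTERNAL_NODES:
        raise ValidationError(
            f"{len(internals)} internal nodes exceed the exhaustive "
            f"enumeration guard ({MAX_ENUM_INTERNAL_NODES})"
        )
    best_cost: float = float("inf")
    best: list[dict[str, int]] = []
    for combo in product((0, 1), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        if root_state is not None and assign[tree.root] != root_state:
            continue
        assign.update(leaf)
        cost = sum(
            assign[p] != assign[c] for p, c in tree.edges()
        )
        if cost < best_cost:
            best_cost = cost
            best = [assign]
        elif cost == best_cost:
            best.append(assign)
    return int(best_cost), best


# ---------------------------------------------------------------------------
# paper placement rule
# ---------------------------------------------------------------------------

ANCESTRAL = "ancestral"
CLADE_SYNAPOMORPHY = "clade_synapomorphy"
TERMINAL_AUTAPOMORPHY = "terminal_autapomorphy"
CONVERGENT = "convergent_terminal_gains"


@dataclass(frozen=True)
class CharacterPlacement:
    character: str
    nodes: tuple[str, ...]  # gain nodes (child end of the gain branch)
    placement_type: str
    changes: int  # changes implied by the placement (gains only)
    fitch_min: int
    mpr_count: int
    unique_mpr: bool
    annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.placement_type == CONVERGENT and len(self.nodes) < 2:
            raise ValidationError(
                f"{self.character}: convergent placement needs >= 2 nodes"
            )


@dataclass(frozen=True)
class PlacementReport:
    outgroup: str
    placements: tuple[CharacterPlacement, ...]

    def __getitem__(self, character: str) -> CharacterPlacement:
        for p in self.placements:
            if p.character == character:
                return p
        raise KeyError(character)

    def to_dict(self) -> dict:
        return {
            "outgroup": self.outgroup,
            "placements": [
                {
                    "character": p.character,
                    "nodes": list(p.nodes),
                    "placement_type": p.placement_type,
                    "changes": p.changes,
                    "fitch_min": p.fitch_min,
                    "mpr_count": p.mpr_count,
                    "unique_mpr": p.unique_mpr,
                    "annotations": list(p.annotations),
                }
                for p in self.placements
            ],
        }


def place_paper_rule(
    tree: PhylogeneticTree, matrix: CharacterMatrix
) -> PlacementReport:
    """Place each character by the outgroup rule (gains only; see module
    docstring), cross-checked against the Fitch/MPR oracle."""
    if tree.outgroup is None:
        raise TreeError("placement requires a tree with a designated outgroup")
    if set(tree.leaves) != set(matrix.taxa):
        raise ValidationError(
            f"matrix taxa {sorted(matrix.taxa)} do not match tree leaves "
            f"{sorted(tree.leaves)}"
        )
    placements = []
    for c in matrix.characters:
        name = c.canonical_name
        present = matrix.presence_set(c) - {tree.outgroup}
        if not present:
            continue  # no all-zero characters
        ingroup = frozenset(tree.ingroup_leaves)
        if present == ingroup:
            nodes = (tree.mrca(ingroup),)
            ptype = ANCESTRAL
        elif len(present) == 1:
            nodes = (next(iter(present)),)
            ptype = TERMINAL_AUTAPOMORPHY
        elif tree.is_clade(present):
            nodes = (tree.mrca(present),)
            ptype = CLADE_SYNAPOMORPHY
        else:
            nodes = tuple(sorted(present))
            ptype = CONVERGENT
        changes = len(nodes)
        states = {t: matrix.state(t, c) for t in tree.leaves}
        fitch = fitch_character(tree, states)
        mpr_min, mprs = enumerate_mprs(
            tree, states, root_state=matrix.state(tree.outgroup, c)
        )
        unique = (
            len(mprs) == 1
            and changes == mpr_min
            and _gain_nodes(tree, mprs[0]) == set(nodes)
        )
        placements.append(
            CharacterPlacement(
                character=name,
                nodes=nodes,
                placement_type=ptype,
                changes=changes,
                fitch_min=fitch.min_changes,
                mpr_count=len(mprs),
                unique_mpr=unique,
                annotations=matrix.annotations.get(name, ()),
            )
        )
    placements.sort(key=lambda p: p.character)
    return PlacementReport(outgroup=tree.outgroup, placements=tuple(placements))


def _gain_nodes(tree: PhylogeneticTree, assignment: dict[str, int]) -> set[str]:
    return {
        child
        for parent, child in tree.edges()
        if assignment[parent] == 0 and assignment[child] == 1
    }


def annotated_newick(
    tree: PhylogeneticTree, report: PlacementReport
) -> str:
    """Newick string with node comments listing gained characters,
    consumable by standard tree viewers."""
    gains: dict[str, list[str]] = {}
    for p in report.placements:
        for node in p.nodes:
            gains.setdefault(node, []).append(p.character)
    comments = {
        node: "gains=" + "|".join(sorted(chars))
        for node, chars in gains.items()
    }
    return tree.to_newick(node_comments=comments)
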