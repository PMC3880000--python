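"""Synteny algebra: fundamental numbers, conserved regions, intact
chromosomes, associations, homology composition and ECU disruption."""

import random

import pytest

from karyopaint.model import (
    BI_ARMED,
    Chromosome,
    HomologyBlock,
    HomologyMap,
    Karyotype,
    RegionLabel,
    ValidationError,
)
from karyopaint.phylo import PhylogeneticTree
from karyopaint.sim import (
    DEFAULT_EXPERIMENT_NEWICK,
    apply_event,
    default_root_karyotype,
    project_painting,
    simulate_history,
)
from karyopaint.synteny import (
    AssociationProfile,
    SyntenicAssociation,
    compose_homology,
    compute_fundamental_number,
    count_conserved_regions,
    ecu_disruption_count,
    extract_syntenic_associations,
    identity_homology,
    infer_plesiomorphic_chromosomes,
    mca_ecu_lookup,
    runs_by_chromosome,
    shared_associations,
)

from conftest import random_karyotype


def study_tree():
    return PhylogeneticTree.from_newick(
        DEFAULT_EXPERIMENT_NEWICK, outgroup="MCA"
    )


# -- fundamental number -----------------------------------------------------

def test_fn_printed_constants(dataset):
    expected = {"MCA": 60, "GSO": 60, "ACU": 56, "LCO": 50}
    for sp, fn in expected.items():
        assert compute_fundamental_number(dataset.karyotypes[sp]) == fn


def test_fn_all_acrocentric():
    k = Karyotype(
        "T",
        tuple(
            [Chromosome(str(i), "acrocentric") for i in range(1, 6)]
            + [
                Chromosome("X", "metacentric", is_sex=True),
                Chromosome("Y", "acrocentric", is_sex=True),
            ]
        ),
    )
    assert compute_fundamental_number(k) == 10


def test_fn_brute_force_oracle():
    rng = random.Random(1)
    for _ in range(1000):
        k = random_karyotype(rng)
        tally = 0
        for c in k.chromosomes:
            if c.is_sex:
                continue
            tally += 2 * (2 if c.morphology in BI_ARMED else 1)
        assert compute_fundamental_number(k) == tally


# -- conserved regions ------------------------------------------------------

def test_region_counts(dataset):
    probes = dataset.probe_autosomes
    expected = {"GSO": 24, "ACU": 29, "LCO": 26}
    for sp, n in expected.items():
        assert count_conserved_regions(dataset.maps[sp], probes=probes) == n


def test_identity_map_regions(dataset):
    ident = identity_homology(dataset.karyotypes["MCA"])
    assert count_conserved_regions(ident) == 19


def _brute_force_regions(hmap, probes):
    """Independent linear scan: walk blocks per chromosome, counting
    transitions of source chromosome, with gaps forcing a break."""
    total = 0
    for chrom, blocks in hmap.by_chromosome().items():
        prev = "::gap::"
        for b in blocks:
            key = "::gap::" if b.is_gap else b.source_chrom
            if key != "::gap::" and key != prev and key in probes:
                total += 1
            prev = key
    return total


def test_region_count_matches_linear_scan_on_simulated_maps():
    tree = study_tree()
    rates = {"rb_fusion": 0.8, "rb_fission": 0.4, "pericentric_inversion": 0.4}
    for seed in range(30):
        history = simulate_history(tree, rates=rates, seed=seed)
        for tip in tree.leaves:
            hmap = project_painting(history, tip)
            probes = hmap.source_chromosomes() - {"X", "Y"}
            assert count_conserved_regions(hmap) == _brute_force_regions(
                hmap, probes
            )


def test_gap_rows_break_runs(dataset):
    runs = runs_by_chromosome(dataset.maps["GSO"])
    # two MCA 5-derived signals on GSO 1p, split by heterochromatin
    gso1 = runs["1"]
    assert [r.source_chrom for r in gso1] == ["5", "5", "10"]


# -- intact chromosomes -----------------------------------------------------

def test_intact_sets(dataset):
    from karyopaint.synteny import intact_source_chromosomes

    expected = {
        "GSO": {"4", "6", "7", "8", "15", "16"},
        "ACU": {"7", "8", "10", "11"},
        "LCO": {"8", "9"},
    }
    intact = {
        sp: intact_source_chromosomes(dataset.maps[sp]) for sp in expected
    }
    assert intact == expected
    # a single chromosome is conserved across all three lineages
    assert set.intersection(*intact.values()) == {"8"}


def test_identity_map_all_intact(dataset):
    from karyopaint.synteny import intact_source_chromosomes

    ident = identity_homology(dataset.karyotypes["MCA"])
    assert intact_source_chromosomes(ident) == dataset.probe_autosomes


def test_forced_fusion_removes_operands_from_intact():
    from karyopaint.synteny import intact_source_chromosomes

    tree = study_tree()
    history = simulate_history(tree, rates={}, seed=0)
    kary = history.root_karyotype
    rng = __import__("numpy").random.default_rng(0)
    fused, event = apply_event(
        kary, "rb_fusion", ("9", "10"), rng, [0], branch="GSO"
    )
    history.node_karyotypes["GSO"] = fused
    painted = project_painting(history, "GSO")
    root_autos = {c.uid for c in kary.autosomes}
    assert intact_source_chromosomes(painted) == root_autos - {"9", "10"}


# -- associations -----------------------------------------------------------

def test_association_canonical_names():
    assert SyntenicAssociation.of("3", "13").canonical_name == "13/3"
    assert SyntenicAssociation.of("13", "3").canonical_name == "13/3"
    assert SyntenicAssociation.of("5", "18").canonical_name == "18/5"
    assert SyntenicAssociation.of("2", "12").canonical_name == "2/12"


def test_terminal_fusion_associations(dataset):
    gso = extract_syntenic_associations(dataset.maps["GSO"])
    names = {a.canonical_name for a in gso.associations}
    assert {"13/3", "9/17", "18/5"} <= names


def test_single_source_targets_yield_no_associations(dataset):
    ident = identity_homology(dataset.karyotypes["MCA"])
    profile = extract_syntenic_associations(ident)
    assert profile.associations == frozenset()
    assert profile.ambiguous == frozenset()


def test_intact_never_in_associations(profiles):
    for p in profiles:
        members = {m for a in p.associations for m in a.members}
        assert not members & p.intact


def test_simulated_associations_equal_truth():
    tree = study_tree()
    rates = {"rb_fusion": 0.6, "tandem_fusion": 0.3}
    for seed in range(30):
        history = simulate_history(tree, rates=rates, seed=seed)
        for tip in tree.leaves:
            painted = project_painting(history, tip)
            profile = extract_syntenic_associations(painted)
            assert set(profile.associations) == history.true_adjacencies(tip)


def test_shared_associations(profiles):
    all3 = shared_associations(profiles, required={"GSO", "ACU", "LCO"})
    assert {a.canonical_name for a in all3} == {"13/3"}
    glosso = shared_associations(
        profiles, required={"ACU", "GSO"}, excluded={"LCO"}
    )
    assert {a.canonical_name for a in glosso} == {"9/17", "18/5"}
    conv = shared_associations(
        profiles, required={"ACU", "LCO"}, excluded={"GSO"}
    )
    assert {a.canonical_name for a in conv} == {"16/19"}


def test_shared_associations_identical_profiles(profiles):
    gso = next(p for p in profiles if p.species == "GSO")
    twin = AssociationProfile(
        species="TWIN", associations=gso.associations, intact=gso.intact
    )
    out = shared_associations([gso, twin], required={"GSO", "TWIN"})
    assert out == set(gso.associations)


def test_shared_associations_monotone(profiles):
    """Enlarging the required set never enlarges the result."""
    subsets = [{"GSO"}, {"GSO", "ACU"}, {"GSO", "ACU", "LCO"}]
    prev = None
    for req in subsets:
        cur = shared_associations(profiles, required=req)
        if prev is not None:
            assert cur <= prev
        prev = cur


def test_shared_associations_unknown_taxon(profiles):
    with pytest.raises(ValidationError, match="unknown taxon"):
        shared_associations(profiles, required={"GSO", "NOPE"})


# -- composition and ECU space ---------------------------------------------

def test_compose_to_ecu_example(dataset):
    """The intact MCA 7 homolog of ACU 10 carries HSA 18:20."""
    composed = compose_homology(
        dataset.maps["ACU"], mca_ecu_lookup(dataset.ecus)
    )
    acu10 = composed.by_chromosome()["10"]
    assert [str(b.source_region) for b in acu10] == ["18:20"]


def test_compose_with_identity_is_identity(dataset):
    ident = identity_homology(dataset.karyotypes["MCA"], include_y=True)
    gso = dataset.maps["GSO"]
    composed = compose_homology(gso, ident)
    assert composed.target_species == gso.target_species
    for orig, comp in zip(gso.blocks, composed.blocks):
        if orig.is_gap:
            assert comp.is_gap
            continue
        assert comp.source_chrom == orig.source_chrom
        assert comp.target_region == orig.target_region


def test_compose_never_invents_content(dataset):
    lookup = mca_ecu_lookup(dataset.ecus)
    allowed = {str(b.source_region) for b in lookup.blocks}
    for sp in ("GSO", "ACU", "LCO"):
        composed = compose_homology(dataset.maps[sp], lookup)
        for b in composed.blocks:
            if b.is_gap:
                continue
            assert str(b.source_region) in allowed


def _content_multisets(hmap):
    out = {}
    for b in hmap.blocks:
        if b.is_gap:
            continue
        out.setdefault(b.target_chrom, []).append(str(b.source_region))
    return {k: sorted(v) for k, v in out.items()}


def test_compose_associative_on_simulated_chains():
    """(A.B).C == A.(B.C) on content multisets, with simulated maps."""
    tree = study_tree()
    for seed in range(10):
        history = simulate_history(
            tree, rates={"rb_fusion": 0.5, "rb_fission": 0.3}, seed=seed
        )
        a = project_painting(history, "GSO")  # GSO <- ANC
        root_k = history.tip_karyotype("MCA")  # identical to root (bl 0)
        b = identity_homology(
            Karyotype("ANC", root_k.chromosomes)
        )  # ANC <- ANC
        c_blocks = []
        for blk in b.blocks:
            c_blocks.append(
                HomologyBlock(
                    target_chrom=blk.target_chrom,
                    order_index=1,
                    target_region=blk.target_region,
                    source_region=RegionLabel(f"{blk.target_chrom}"),
                )
            )
        from karyopaint.model import HomologyMap as HM

        c = HM("ANC", "META", tuple(c_blocks))  # ANC <- META
        left = compose_homology(compose_homology(a, b), c)
        right = compose_homology(a, compose_homology(b, c))
        assert _content_multisets(left) == _content_multisets(right)


def test_unmapped_source_reported_not_dropped(dataset):
    lookup = mca_ecu_lookup([e for e in dataset.ecus if e.ecu_id != "7a"])
    composed = compose_homology(dataset.maps["GSO"], lookup)
    gso11 = composed.by_chromosome()["11"]  # homolog of MCA 8 (ECU 7a)
    assert len(gso11) == 1
    assert "unmapped" in gso11[0].flags
    assert gso11[0].is_gap


def test_ecu_disruption_counts(dataset):
    lookup = mca_ecu_lookup(dataset.ecus)
    expected = {
        "ACU": (4, ["12a-22a+13b", "13a:8b-4c", "16a:19a", "5b"]),
        "LCO": (2, ["12a-22a+13b", "18:20"]),
        "GSO": (0, []),
    }
    for sp, (n, ids) in expected.items():
        composed = compose_homology(dataset.maps[sp], lookup)
        count, disrupted = ecu_disruption_count(composed, dataset.ecus)
        assert (count, disrupted) == (n, ids)


def test_identity_map_zero_disruption(dataset):
    ident = identity_homology(dataset.karyotypes["MCA"])
    composed = compose_homology(ident, mca_ecu_lookup(dataset.ecus))
    count, disrupted = ecu_disruption_count(composed, dataset.ecus)
    assert (count, disrupted) == (0, [])


# -- plesiomorphy -----------------------------------------------------------

def test_plesiomorphic_set(dataset, profiles):
    out = infer_plesiomorphic_chromosomes(profiles, outgroup="MCA")
    assert out == {"4", "6", "7", "8", "9", "10", "11", "15", "16"}
    assert len(out) == 9
    assert "8" in out


def test_plesiomorphy_empty_ingroup(dataset):
    ident = extract_syntenic_associations(
        identity_homology(dataset.karyotypes["MCA"])
    )
    empty = AssociationProfile(
        species="EMPTY", associations=frozenset(), intact=frozenset()
    )
    assert (
        infer_plesiomorphic_chromosomes([ident, empty], outgroup="MCA")
        == set()
    )


def test_plesiomorphy_matches_simulator_ground_truth():
    tree = study_tree()
    rates = {"rb_fusion": 0.6, "rb_fission": 0.2}
    for seed in range(20):
        history = simulate_history(tree, rates=rates, seed=seed)
        profiles = [
            extract_syntenic_associations(project_painting(history, tip))
            for tip in tree.leaves
        ]
        predicted = infer_plesiomorphic_chromosomes(profiles, outgroup="MCA")
        outgroup_intact = history.intact_root_chromosomes("MCA")
        ingroup_union = set()
        for tip in tree.ingroup_leaves:
            ingroup_union |= history.intact_root_chromosomes(tip)
        assert predicted == outgroup_intact & ingroup_union
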