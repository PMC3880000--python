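import random

import pytest

from karyopaint.io import load_paper_dataset
from karyopaint.model import Chromosome, Karyotype, MORPHOLOGIES
from karyopaint.phylo import PhylogeneticTree
from karyopaint.synteny import extract_syntenic_associations, identity_homology


@pytest.fixture(scope="session")
def dataset():
    return load_paper_dataset()


@pytest.fixture(scope="session")
def profiles(dataset):
    """Association profiles for the three painted species plus the probe
    species' identity profile."""
    out = [
        extract_syntenic_associations(dataset.maps[sp])
        for sp in ("GSO", "ACU", "LCO")
    ]
    out.append(
        extract_syntenic_associations(
            identity_homology(dataset.karyotypes["MCA"])
        )
    )
    return out


@pytest.fixture(scope="session")
def study_tree(dataset):
    return dataset.tree


def random_bifurcating_newick(rng: random.Random, n_leaves: int) -> str:
    """Random rooted bifurcating topology over leaves t1..tn."""
    nodes = [f"t{i}" for i in range(1, n_leaves + 1)]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def random_tree(rng: random.Random, n_leaves: int) -> PhylogeneticTree:
    return PhylogeneticTree.from_newick(
        random_bifurcating_newick(rng, n_leaves)
    )


def random_karyotype(rng: random.Random, species: str = "RND") -> Karyotype:
    n = rng.randint(3, 25)
    morphs = sorted(MORPHOLOGIES)
    chroms = [
        Chromosome(str(i), rng.choice(morphs)) for i in range(1, n + 1)
    ]
    chroms.append(Chromosome("X", rng.choice(morphs), is_sex=True))
    if rng.random() < 0.5:
        chroms.append(Chromosome("Y", "acrocentric", is_sex=True))
    return Karyotype(species=species, chromosomes=tuple(chroms))
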