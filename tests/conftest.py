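"""Shared fixtures: a hand-built micro taxonomy and the default synthetic
cohort (session-scoped, seed 42)."""

from __future__ import annotations

import numpy as np
import pytest

from metapep import GeneratorConfig, TaxonomyTree, generate_cohort
from metapep.data_io import TaxonNode


@pytest.fixture(scope="session")
def small_tree() -> TaxonomyTree:
    """root -> 3 domains; Bacteria with two phyla, genera and species;
    Eukaryota with a Chordata lineage down to Homo sapiens."""
    nodes = [
        TaxonNode("root", "root", "root", "root"),
        TaxonNode("Bacteria", "root", "domain", "Bacteria"),
        TaxonNode("Archaea", "root", "domain", "Archaea"),
        TaxonNode("Eukaryota", "root", "domain", "Eukaryota"),
        TaxonNode("Firmicutes", "Bacteria", "phylum", "Firmicutes"),
        TaxonNode("Bacteroidetes", "Bacteria", "phylum", "Bacteroidetes"),
        TaxonNode("Faecalibacterium", "Firmicutes", "genus",
                  "Faecalibacterium"),
        TaxonNode("F_prausnitzii", "Faecalibacterium", "species",
                  "F_prausnitzii"),
        TaxonNode("Bacteroides", "Bacteroidetes", "genus", "Bacteroides"),
        TaxonNode("B_fragilis", "Bacteroides", "species", "B_fragilis"),
        TaxonNode("Euryarchaeota", "Archaea", "phylum", "Euryarchaeota"),
        TaxonNode("M_smithii", "Euryarchaeota", "species", "M_smithii"),
        TaxonNode("Chordata", "Eukaryota", "phylum", "Chordata"),
        TaxonNode("Mammalia", "Chordata", "class", "Mammalia"),
        TaxonNode("Homo", "Mammalia", "genus", "Homo"),
        TaxonNode("Homo_sapiens", "Homo", "species", "Homo_sapiens"),
    ]
    return TaxonomyTree(nodes)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort: 16 subjects x 3 time points, seed 42."""
    return generate_cohort(GeneratorConfig(seed=42))


def random_taxonomy(rng: np.random.Generator,
                    n_nodes: int) -> TaxonomyTree:
    """Random tree: root, a few domain children, then random attachment."""
    nodes = [TaxonNode("t0", "t0", "root", "t0")]
    n_domains = int(rng.integers(2, 4))
    for i in range(1, n_domains + 1):
        name = ["Bacteria", "Archaea", "Eukaryota"][i - 1]
        nodes.append(TaxonNode(f"t{i}", "t0", "domain", name))
    ranks = ["phylum", "class", "order", "family", "genus", "species",
             "no_rank"]
    for i in range(n_domains + 1, n_nodes):
        parent = int(rng.integers(1, i))  # never the root: keeps domains
        rank = ranks[int(rng.integers(len(ranks)))]
        nodes.append(TaxonNode(f"t{i}", f"t{parent}", rank, f"t{i}"))
    return TaxonomyTree(nodes)


def lca_by_path_intersection(taxa, tree: TaxonomyTree) -> str:
    """Brute-force oracle: intersect all root paths, take the deepest."""
    paths = [set(tree.path_to_root(t)) for t in taxa]
    common = set.intersection(*paths)
    return max(common, key=tree.depth)
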