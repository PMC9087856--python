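"""Shared fixtures: small simulated datasets and random-tree helpers."""

from __future__ import annotations

import numpy as np
import pytest

from kmerphylo.simulate import (
    PlantedCore,
    SimulationConfig,
    TaxonSpec,
    simulate_dataset,
)
from kmerphylo.trees import Node, PhyloTree

SMALL_TAXA = (
    TaxonSpec("A1", "SpA", "i1", "symbiotic", "C1"),
    TaxonSpec("A2", "SpA", "i2", "symbiotic", "C1"),
    TaxonSpec("B1", "SpB", "only", "symbiotic", "C1"),
    TaxonSpec("D1", "SpD", "only", "free-living", "C2"),
    TaxonSpec("O1", "SpO", "i1", "free-living", "OUT"),
    TaxonSpec("O2", "SpO", "i2", "free-living", "OUT"),
)


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    defaults = dict(
        seed=seed,
        taxa=SMALL_TAXA,
        genome_length=12_000,
        repeat_fraction=0.25,
        outgroup_repeat_fraction=0.40,
        n_repeat_families=6,
        n_enriched_families=2,
        planted_cores=(PlantedCore("core_all", 200, None),
                       PlantedCore("core_c1", 200, ("C1",))),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """Six-taxon annotated dataset: two ingroup clades, isolate pairs, outgroup."""
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    """D2S distance matrix over the six-taxon WGS sets at k=17."""
    from kmerphylo import count_kmers, distance_matrix, wgs

    rs = {g.genome_id: wgs(g) for g in small_dataset.genomes}
    profiles = {gid: count_kmers(rs[gid], 17) for gid in rs}
    return distance_matrix(profiles, region_sets=rs)


def random_binary_tree(labels, rng: np.random.Generator,
                       min_len: float = 0.1, max_len: float = 2.0) -> PhyloTree:
    """A random unrooted binary topology with positive branch lengths."""
    nodes = [Node(lab, float(rng.uniform(min_len, max_len))) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Node(None, float(rng.uniform(min_len, max_len)), [a, b]))
    return PhyloTree(Node(children=nodes))


def tree_path_distances(tree: PhyloTree):
    """Leaf-to-leaf path-length matrix computed from the rooted structure."""
    dists: dict[tuple[str, str], float] = {}
    depths: dict[int, dict[str, float]] = {}

    def walk(node: Node) -> dict[str, float]:
        if node.is_leaf:
            below = {node.name: 0.0}
        else:
            below = {}
            child_maps = [walk(c) for c in node.children]
            for i in range(len(child_maps)):
                for j in range(i + 1, len(child_maps)):
                    for la, da in child_maps[i].items():
                        for lb, db in child_maps[j].items():
                            key = tuple(sorted((la, lb)))
                            dists[key] = da + db
                    # distances through this node
            for cm in child_maps:
                below.update(cm)
        out = {lab: d + (node.length or 0.0) for lab, d in below.items()}
        depths[id(node)] = out
        return out

    walk(tree.root)
    labels = sorted(tree.leaf_names())
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = dists[(labels[i], labels[j])]
    return labels, mat
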