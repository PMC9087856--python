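"""Core k-mers: words present in every genome of a target group.

Core membership requires presence (count >= 1), not any minimum multiplicity.
Two equivalent constructions are provided: the pairwise-overlap procedure
(shared words of every pair, then their common overlap) and the direct n-way
intersection; they are provably identical and both are exercised in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable, Mapping

from kmerphylo.io_formats import ValidationError
from kmerphylo.kmers import KmerProfile
from kmerphylo.trees import PhyloTree


@dataclass
class CoreKmerSet:
    group_label: str
    members: tuple[str, ...]
    k: int
    words: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.words)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for w in sorted(self.words):
                fh.write(w + "\n")


def _check_group(profiles: Mapping[str, KmerProfile], group: Iterable[str]):
    members = tuple(sorted(group))
    if not members:
        raise ValidationError("core k-mer group is empty")
    missing = [g for g in members if g not in profiles]
    if missing:
        raise ValidationError(f"no profile for group members: {missing}")
    ks = {profiles[g].k for g in members}
    if len(ks) != 1:
        raise ValidationError(f"k mismatch within group: {sorted(ks)}")
    return members, ks.pop()


def core_kmers(profiles: Mapping[str, KmerProfile], group: Iterable[str],
               group_label: str | None = None) -> CoreKmerSet:
    """Direct n-way intersection of the members' distinct-word sets."""
    members, k = _check_group(profiles, group)
    words = reduce(lambda acc, g: acc & profiles[g].counts.keys(),
                   members[1:], frozenset(profiles[members[0]].counts))
    return CoreKmerSet(group_label or "+".join(members), members, k, frozenset(words))


def core_kmers_pairwise(profiles: Mapping[str, KmerProfile], group: Iterable[str],
                        group_label: str | None = None) -> CoreKmerSet:
    """Pairwise shared-word sets, then their common overlap.

    For every pair within the group the shared words are computed; the words
    found in all pairwise comparisons are the core. Identical in outcome to
    :func:`core_kmers` (for a single-member group the core is all its words).
    """
    members, k = _check_group(profiles, group)
    if len(members) == 1:
        return CoreKmerSet(group_label or members[0], members, k,
                           frozenset(profiles[members[0]].counts))
    core: frozenset | None = None
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            shared = profiles[members[i]].counts.keys() & profiles[members[j]].counts.keys()
            core = frozenset(shared) if core is None else core & shared
    return CoreKmerSet(group_label or "+".join(members), members, k, core)


def per_node_core_counts(tree: PhyloTree, profiles: Mapping[str, KmerProfile]
                         ) -> dict[frozenset, int]:
    """Shared-k-mer count for each internal node's leaf set.

    Keys are the leaf-label frozensets of internal nodes (including the root);
    values are the sizes of the core word sets over those leaves. Counts are
    non-increasing from the leaves toward the root, because enlarging a group
    can only shrink an intersection.
    """
    missing = [l for l in tree.leaf_names() if l not in profiles]
    if missing:
        raise ValidationError(f"missing profiles for leaves: {missing}")
    sets = tree.node_leafsets()
    word_sets: dict[int, frozenset] = {}
    counts: dict[frozenset, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            word_sets[id(node)] = frozenset(profiles[node.name].counts)
        else:
            acc = None
            for c in node.children:
                ws = word_sets[id(c)]
                acc = ws if acc is None else acc & ws
            word_sets[id(node)] = acc
            counts[sets[id(node)]] = len(acc)
    return counts


def annotate_tree_with_core_counts(tree: PhyloTree,
                                   profiles: Mapping[str, KmerProfile]) -> str:
    """Newick text with internal node labels carrying shared-k-mer counts."""
    counts = per_node_core_counts(tree, profiles)
    work = tree.copy()
    sets = work.node_leafsets()
    for node in work.postorder():
        if not node.is_leaf:
            node.name = str(counts[sets[id(node)]])
    return work.to_newick()
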