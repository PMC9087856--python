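"""Synthetic annotated genome collections with known truth.

The generator emulates the data regime of a multi-genus dinoflagellate genome
panel: 18 genomes across five ingroup clades plus a two-isolate outgroup,
several same-species isolate pairs, a genic fraction under 10%, repeat content
between roughly 20% and 70% of the assembly, repeat families with
group-differential abundance, and planted clade-conserved elements. Sequences
evolve down a species tree under Jukes–Cantor substitutions (no indels, so
annotation coordinates lift unchanged from the root); repeat copies are
additionally diverged from their family consensus with a Kimura two-parameter
(transition/transversion) process to a per-family target divergence.

All randomness flows from a single seed through named substreams per stage.
Every planted structure is recorded in a truth ledger for use as ground truth.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from kmerphylo.io_formats import Feature, FeatureIndex, GenomeRecord, ValidationError
from kmerphylo.trees import Node, PhyloTree

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {ord("A"): 0, ord("C"): 1, ord("G"): 2, ord("T"): 3}

REPEAT_CLASSES = ("DNA", "LTR", "LINE", "SINE", "RC", "Satellite", "Simple", "Unknown")


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[ord(c)] for c in seq], dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


# ---------------------------------------------------------------------------
# Kimura two-parameter helpers
# ---------------------------------------------------------------------------

def kimura2p(P: float, Q: float) -> float:
    """Kimura 2-parameter distance from transition (P) and transversion (Q)
    proportions: K = −½·ln[(1−2P−Q)·sqrt(1−2Q)]."""
    if not (0 <= P and 0 <= Q):
        raise ValidationError("P and Q must be non-negative")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValidationError(f"Kimura distance undefined for P={P}, Q={Q}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def pq_for_kimura(K: float, ts_tv: float = 2.0) -> tuple[float, float]:
    """Transition/transversion proportions with P = ts_tv·Q and kimura2p = K."""
    if K < 0:
        raise ValidationError("K must be >= 0")
    if K == 0:
        return 0.0, 0.0
    upper = 1.0 / (2.0 * ts_tv + 1.0) - 1e-9

    def f(q: float) -> float:
        return kimura2p(ts_tv * q, q) - K

    q = brentq(f, 1e-12, upper)
    return ts_tv * q, q


def observed_pq(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Realised transition/transversion fractions between two coded sequences."""
    if len(a) != len(b):
        raise ValidationError("sequences differ in length")
    diff = (b.astype(np.int16) - a.astype(np.int16)) % 4
    n = len(a)
    P = float(np.count_nonzero(diff == 2)) / n
    Q = float(np.count_nonzero(diff % 2 == 1)) / n
    return P, Q


def jc_substitution_probability(branch_length: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * branch_length / 3.0))


def jc_distance(p_hat: float) -> float:
    """Invert the observed proportion of differing sites to a JC distance."""
    if p_hat >= 0.75:
        raise ValidationError("observed difference saturates the JC correction")
    return -0.75 * math.log(1.0 - 4.0 * p_hat / 3.0)


def _mutate_jc(arr: np.ndarray, branch_length: float, rng: np.random.Generator) -> np.ndarray:
    if branch_length <= 0:
        return arr.copy()
    p = jc_substitution_probability(branch_length)
    out = arr.copy()
    mask = rng.random(len(arr)) < p
    n = int(mask.sum())
    if n:
        out[mask] = (arr[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return out


def _mutate_kimura(arr: np.ndarray, P: float, Q: float, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(len(arr))
    out = arr.copy()
    trans = u < P
    out[trans] = (arr[trans] + 2) % 4
    tv = (u >= P) & (u < P + Q)
    n = int(tv.sum())
    if n:
        step = 1 + 2 * rng.integers(0, 2, size=n).astype(np.uint8)  # +1 or +3: transversion
        out[tv] = (arr[tv] + step) % 4
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonSpec:
    genome_id: str
    species: str
    isolate: str
    lifestyle: str
    clade: str


def _default_taxa() -> tuple[TaxonSpec, ...]:
    """18 taxa: five ingroup clades (one genus-like clade of 9 with free-living
    members, isolate pairs in three species) plus a two-isolate outgroup."""
    t = TaxonSpec
    return (
        t("SmicA", "S_micro", "A", "symbiotic", "Sym"),
        t("SmicB", "S_micro", "B", "symbiotic", "Sym"),
        t("SmicC", "S_micro", "C", "symbiotic", "Sym"),
        t("StriA", "S_trida", "A", "symbiotic", "Sym"),
        t("StriB", "S_trida", "B", "symbiotic", "Sym"),
        t("Slin", "S_linu", "only", "symbiotic", "Sym"),
        t("Snec", "S_necro", "only", "opportunistic", "Sym"),
        t("Snat", "S_natans", "only", "free-living", "Sym"),
        t("Spil", "S_pilosum", "only", "free-living", "Sym"),
        t("Bmin", "B_minutum", "only", "symbiotic", "Brev"),
        t("Cgor", "C_goreaui", "only", "symbiotic", "Clad"),
        t("Csp15", "C_sp15", "only", "symbiotic", "Clad"),
        t("Csp92", "C_sp92", "only", "symbiotic", "Clad"),
        t("DtreA", "D_trenchii", "A", "symbiotic", "Dur"),
        t("DtreB", "D_trenchii", "B", "symbiotic", "Dur"),
        t("Fkaw", "F_kawagutii", "only", "unknown", "Fug"),
        t("PglaA", "P_glac", "A", "free-living", "OUT"),
        t("PglaB", "P_glac", "B", "free-living", "OUT"),
    )


@dataclass(frozen=True)
class PlantedCore:
    label: str
    length: int
    clades: tuple[str, ...] | None  # None = carried by every genome


@dataclass
class SimulationConfig:
    seed: int = 0
    taxa: tuple[TaxonSpec, ...] = field(default_factory=_default_taxa)
    outgroup_clade: str = "OUT"
    genome_length: int = 30_000

    # branch lengths (expected substitutions per site), jittered ×U(1−j, 1+j).
    # Scaled so that at desk-scale genome lengths the homologous shared-k-mer
    # signal of the deepest pair stays well above the planted-core floor
    # (L·exp(−k·path) >> core element k-mers), keeping distances additive.
    between_clade_branch: float = 0.015
    within_clade_branch: float = 0.006
    terminal_branch: float = 0.008
    isolate_branch: float = 0.001
    outgroup_branch: float = 0.035
    branch_jitter: float = 0.2

    # gene model (genic fraction stays under 10% of the assembly)
    gene_count: int = 2
    exons_per_gene: int = 3
    exon_length: int = 300
    intron_length: int = 200
    dark_gene_fraction: float = 0.3

    # repeat model
    n_repeat_families: int = 12
    consensus_length: int = 350
    repeat_fraction: float = 0.35
    outgroup_repeat_fraction: float = 0.70
    repeat_kimura_range: tuple[float, float] = (0.10, 0.35)
    n_enriched_families: int = 3
    enriched_fold: float = 2.0

    planted_cores: tuple[PlantedCore, ...] = (
        PlantedCore("core_all", 300, None),
        PlantedCore("core_sym", 300, ("Sym",)),
    )

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        if "taxa" in raw:
            raw["taxa"] = tuple(TaxonSpec(**t) if isinstance(t, dict) else t
                                for t in raw["taxa"])
        if "planted_cores" in raw:
            raw["planted_cores"] = tuple(
                PlantedCore(p["label"], p["length"],
                            tuple(p["clades"]) if p.get("clades") else None)
                if isinstance(p, dict) else p
                for p in raw["planted_cores"])
        return cls(**raw)

    def __post_init__(self) -> None:
        if len(self.taxa) < 4:
            raise ValidationError("need at least 4 taxa")
        if not (0.0 <= self.repeat_fraction <= 1.0):
            raise ValidationError("repeat_fraction outside [0, 1]")
        for name in ("between_clade_branch", "within_clade_branch", "terminal_branch",
                     "isolate_branch", "outgroup_branch"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    true_tree: PhyloTree
    genomes: list[GenomeRecord]
    features: dict[str, FeatureIndex]
    metadata: pd.DataFrame
    truth: dict

    @property
    def species_map(self) -> dict[str, str]:
        return dict(zip(self.metadata["genome_id"], self.metadata["species"]))

    def genome(self, genome_id: str) -> GenomeRecord:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def _named_rng(seed: int, label: str) -> np.random.Generator:
    # hash() is salted per process; derive a stable stream from a label digest
    digest = hashlib.sha256(label.encode()).digest()
    words = [int.from_bytes(digest[i:i + 4], "big") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([seed] + words))


def simulate_tree(config: SimulationConfig) -> PhyloTree:
    """A binary species/isolate tree over the configured taxa.

    Isolates of one species attach as short-branch cherries; species join
    within their clade, clades join in a random order, and the outgroup clade
    attaches at the root. Fixed seed gives byte-identical Newick output.
    """
    rng = _named_rng(config.seed, "tree")
    jitter = lambda base: float(base * rng.uniform(1 - config.branch_jitter,
                                                   1 + config.branch_jitter))

    def species_subtree(members: list[TaxonSpec]) -> Node:
        if len(members) == 1:
            return Node(members[0].genome_id, jitter(config.terminal_branch))
        leaves = [Node(m.genome_id, jitter(config.isolate_branch)) for m in members]
        while len(leaves) > 2:
            b = leaves.pop()
            a = leaves.pop()
            leaves.append(Node(None, jitter(config.isolate_branch), [a, b]))
        return Node(None, jitter(config.terminal_branch), leaves)

    def join_all(subtrees: list[Node], branch: float) -> Node:
        order = list(rng.permutation(len(subtrees)))
        items = [subtrees[i] for i in order]
        while len(items) > 1:
            a = items.pop(0)
            b = items.pop(0)
            joined = Node(None, jitter(branch), [a, b])
            items.insert(0, joined)
        return items[0]

    clades: dict[str, list[TaxonSpec]] = {}
    for t in config.taxa:
        clades.setdefault(t.clade, []).append(t)
    if config.outgroup_clade not in clades:
        raise ValidationError(f"no taxa in outgroup clade {config.outgroup_clade!r}")

    clade_nodes = []
    for clade in sorted(clades):
        if clade == config.outgroup_clade:
            continue
        by_species: dict[str, list[TaxonSpec]] = {}
        for t in clades[clade]:
            by_species.setdefault(t.species, []).append(t)
        species_nodes = [species_subtree(by_species[s]) for s in sorted(by_species)]
        clade_nodes.append(join_all(species_nodes, config.within_clade_branch))

    ingroup = join_all(clade_nodes, config.between_clade_branch) if len(clade_nodes) > 1 \
        else clade_nodes[0]
    og_members: dict[str, list[TaxonSpec]] = {}
    for t in clades[config.outgroup_clade]:
        og_members.setdefault(t.species, []).append(t)
    og_nodes = [species_subtree(og_members[s]) for s in sorted(og_members)]
    outgroup = join_all(og_nodes, config.within_clade_branch) if len(og_nodes) > 1 else og_nodes[0]

    half = jitter(config.outgroup_branch)
    ingroup.length = half / 2.0
    outgroup.length = (outgroup.length or 0.0) + half / 2.0
    return PhyloTree(Node(children=[ingroup, outgroup]))


# ---------------------------------------------------------------------------
# genome evolution
# ---------------------------------------------------------------------------

@dataclass
class _RepeatFamily:
    name: str
    rclass: str
    consensus: np.ndarray
    P: float
    Q: float
    target_k: float
    enriched: bool


def _root_layout(config: SimulationConfig, rng: np.random.Generator):
    """Place genes, core slots and base repeat copies on the root sequence."""
    L = config.genome_length
    root = rng.integers(0, 4, size=L, dtype=np.uint8)
    features: list[Feature] = []
    pos = 200

    # genes: exon/intron/exon/... blocks, alternating strands
    for gi in range(config.gene_count):
        gene_id = f"g{gi + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        status = "dark" if rng.random() < config.dark_gene_fraction else "known"
        start = pos
        blocks = []
        for ei in range(config.exons_per_gene):
            blocks.append(("exon", pos, pos + config.exon_length))
            pos += config.exon_length
            if ei < config.exons_per_gene - 1:
                blocks.append(("intron", pos, pos + config.intron_length))
                pos += config.intron_length
        end = pos
        if end > L:
            raise ValidationError("infeasible packing: genes exceed genome length")
        features.append(Feature("sc1", start, end, strand, "gene",
                                {"ID": gene_id, "gene_status": status}))
        tid = f"t_{gene_id}"
        for kind, s, e in blocks:
            if kind == "exon":
                features.append(Feature("sc1", s, e, strand, "exon",
                                        {"Parent": tid, "gene_id": gene_id}))
                features.append(Feature("sc1", s, e, strand, "CDS",
                                        {"Parent": tid, "gene_id": gene_id}))
            else:
                features.append(Feature("sc1", s, e, strand, "intron",
                                        {"Parent": tid, "gene_id": gene_id}))
        pos += 200

    # reserved slots for planted core elements (overwritten post-evolution)
    core_slots: dict[str, tuple[int, int]] = {}
    core_seqs: dict[str, np.ndarray] = {}
    for spec in config.planted_cores:
        core_slots[spec.label] = (pos, pos + spec.length)
        core_seqs[spec.label] = rng.integers(0, 4, size=spec.length, dtype=np.uint8)
        pos += spec.length + 100
    if pos > L:
        raise ValidationError("infeasible packing: core slots exceed genome length")

    # repeat families and base copies up to the target fraction
    families = []
    for fi in range(config.n_repeat_families):
        k_target = float(rng.uniform(*config.repeat_kimura_range))
        P, Q = pq_for_kimura(k_target)
        families.append(_RepeatFamily(
            name=f"rnd-{fi + 1}",
            rclass=REPEAT_CLASSES[fi % len(REPEAT_CLASSES)],
            consensus=rng.integers(0, 4, size=config.consensus_length, dtype=np.uint8),
            P=P, Q=Q, target_k=k_target,
            enriched=fi < config.n_enriched_families,
        ))

    target_bases = int(config.repeat_fraction * L)
    placed = 0
    fi = 0
    while placed < target_bases:
        fam = families[fi % len(families)]
        fi += 1
        copy = _mutate_kimura(fam.consensus, fam.P, fam.Q, rng)
        start, end = pos, pos + len(copy)
        if end + 50 > L:
            raise ValidationError("infeasible packing: repeats exceed genome length")
        root[start:end] = copy
        features.append(Feature("sc1", start, end, "+" if rng.random() < 0.5 else "-",
                                "repeat", {"repeat_type": fam.name,
                                           "repeat_class": fam.rclass}))
        placed += len(copy)
        pos = end + 50

    free_start = pos
    return root, features, core_slots, core_seqs, families, free_start


def evolve_genomes(tree: PhyloTree, config: SimulationConfig) -> SimulatedDataset:
    """Evolve the root genome down the tree and assemble the annotated dataset.

    Substitution-only evolution keeps every feature's coordinates fixed, so
    the root annotation lifts to each leaf. Per-genome extras: outgroup
    genomes receive additional repeat copies up to the outgroup repeat-content
    target, and symbiotic genomes receive extra copies of the enriched
    families (the configured fold-change). Planted core elements are written
    verbatim into their carrier genomes after mutation. Kimura divergence
    attributes are recomputed per leaf against the family consensus and stored
    as percentages, as repeat annotators print them.
    """
    leaf_names = set(tree.leaf_names())
    taxa = {t.genome_id: t for t in config.taxa}
    if leaf_names != set(taxa):
        raise ValidationError("tree leaves do not match configured taxa")

    root, base_features, core_slots, core_seqs, families, free_start = _root_layout(
        config, _named_rng(config.seed, "layout"))
    L = config.genome_length

    evo_rng = _named_rng(config.seed, "evolution")
    leaf_seqs: dict[str, np.ndarray] = {}

    def walk(node: Node, seq: np.ndarray) -> None:
        # deterministic traversal order fixes the substream assignment
        branch_rng = np.random.default_rng(evo_rng.integers(0, 2**31))
        child_seq = _mutate_jc(seq, node.length or 0.0, branch_rng)
        if node.is_leaf:
            leaf_seqs[node.name] = child_seq
        else:
            for c in node.children:
                walk(c, child_seq)

    for c in tree.root.children:
        walk(c, root)
    if not leaf_names:
        raise ValidationError("tree has no leaves")

    genomes: list[GenomeRecord] = []
    features: dict[str, FeatureIndex] = {}
    carriers: dict[str, list[str]] = {spec.label: [] for spec in config.planted_cores}

    extra_bases_outgroup = max(0, int((config.outgroup_repeat_fraction
                                       - config.repeat_fraction) * L))
    base_copies_per_family = sum(
        1 for f in base_features if f.kind == "repeat") // max(1, len(families))

    for gid in sorted(leaf_names):
        taxon = taxa[gid]
        seq = leaf_seqs[gid]
        gfeatures = list(base_features)
        # extras are heritable repeat expansions: isolates of one species
        # share the same per-species substream, hence identical extra copies
        grng = _named_rng(config.seed, f"extras:{taxon.species}")
        pos = free_start

        def place_copy(fam: _RepeatFamily) -> bool:
            nonlocal pos
            copy = _mutate_kimura(fam.consensus, fam.P, fam.Q, grng)
            if pos + len(copy) + 50 > L:
                return False
            seq[pos:pos + len(copy)] = copy
            gfeatures.append(Feature("sc1", pos, pos + len(copy),
                                     "+" if grng.random() < 0.5 else "-", "repeat",
                                     {"repeat_type": fam.name, "repeat_class": fam.rclass}))
            pos += len(copy) + 50
            return True

        if taxon.clade == config.outgroup_clade:
            added = 0
            fi = 0
            while added < extra_bases_outgroup:
                fam = families[fi % len(families)]
                fi += 1
                if not place_copy(fam):
                    raise ValidationError("infeasible packing: outgroup repeat target")
                added += len(fam.consensus)
        elif taxon.lifestyle in {"symbiotic", "opportunistic"}:
            extra_per_family = int(round((config.enriched_fold - 1.0)
                                         * base_copies_per_family))
            for fam in families:
                if not fam.enriched:
                    continue
                for _ in range(extra_per_family):
                    if not place_copy(fam):
                        raise ValidationError("infeasible packing: enriched repeat copies")

        # planted cores overwrite their slots verbatim in carrier genomes
        for spec in config.planted_cores:
            if spec.clades is None or taxon.clade in spec.clades:
                s, e = core_slots[spec.label]
                seq[s:e] = core_seqs[spec.label]
                carriers[spec.label].append(gid)

        # recompute per-copy Kimura divergence against the family consensus
        fam_by_name = {f.name: f for f in families}
        final_features = []
        for f in gfeatures:
            if f.kind == "repeat":
                fam = fam_by_name[f.attributes["repeat_type"]]
                P, Q = observed_pq(fam.consensus, seq[f.start:f.end])
                try:
                    kd = 100.0 * kimura2p(P, Q)
                except ValidationError:
                    kd = float("nan")
                attrs = dict(f.attributes)
                attrs["kimura_divergence"] = f"{kd:.4f}"
                f = Feature(f.scaffold_id, f.start, f.end, f.strand, f.kind, attrs)
            final_features.append(f)

        genome = GenomeRecord(gid, taxon.species, taxon.isolate, taxon.lifestyle,
                              [("sc1", _decode(seq))])
        genomes.append(genome)
        features[gid] = FeatureIndex(final_features, genome.scaffold_lengths)

    metadata = pd.DataFrame([{
        "genome_id": t.genome_id, "species": t.species, "isolate": t.isolate,
        "lifestyle": t.lifestyle, "clade": t.clade,
    } for t in config.taxa if t.genome_id in leaf_names])

    truth = {
        "planted_cores": [{
            "label": spec.label,
            "sequence": _decode(core_seqs[spec.label]),
            "carriers": sorted(carriers[spec.label]),
            "position": core_slots[spec.label],
        } for spec in config.planted_cores],
        "enriched_repeat_types": [f.name for f in families if f.enriched],
        "repeat_families": {f.name: {"class": f.rclass, "target_kimura": f.target_k,
                                     "consensus": _decode(f.consensus)}
                            for f in families},
        "outgroup": [t.genome_id for t in config.taxa
                     if t.clade == config.outgroup_clade],
        "extras_zone_start": free_start,
        "clades": {t.genome_id: t.clade for t in config.taxa},
    }
    return SimulatedDataset(config, tree, genomes, features, metadata, truth)


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> SimulatedDataset:
    """Convenience: simulate the tree, then the genomes, from one config."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    tree = simulate_tree(config)
    return evolve_genomes(tree, config)


# ---------------------------------------------------------------------------
# table-level repeat-type simulation (for the enrichment screen)
# ---------------------------------------------------------------------------

def simulate_repeat_tables(n_types: int = 825,
                           n_group_a: int = 7, n_group_b: int = 2,
                           n_enriched: int = 0, fold: float = 2.0,
                           n_conserved: int = 0, kimura_shift: float = -8.0,
                           noise_sd: float = 0.1, kimura_sd: float = 1.5,
                           seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Per-genome repeat-type metric tables with optional planted effects.

    Proportions are lognormal around a per-type base level (multiplicative
    noise ``noise_sd`` on the log scale); the first ``n_enriched`` types have
    their group-A proportions multiplied by ``fold``. Kimura divergences are
    normal around a per-type base in the 15–40(%) band; the first
    ``n_conserved`` types after the enriched block get ``kimura_shift`` added
    for group A (negative = more conserved). Group sizes default to the 7 vs 2
    symbiotic/free-living design.
    """
    rng = np.random.default_rng(seed)
    genomes_a = [f"A{i + 1}" for i in range(n_group_a)]
    genomes_b = [f"B{i + 1}" for i in range(n_group_b)]
    rows = []
    enriched, conserved = [], []
    for ti in range(n_types):
        rtype = f"type{ti + 1}"
        rclass = REPEAT_CLASSES[ti % len(REPEAT_CLASSES)]
        base_prop = float(np.exp(rng.normal(np.log(1e-3), 0.5)))
        base_kim = float(rng.uniform(15.0, 40.0))
        is_enriched = ti < n_enriched
        is_conserved = n_enriched <= ti < n_enriched + n_conserved
        if is_enriched:
            enriched.append(rtype)
        if is_conserved:
            conserved.append(rtype)
        for gid in genomes_a + genomes_b:
            in_a = gid in genomes_a
            prop = base_prop * float(np.exp(rng.normal(0.0, noise_sd)))
            if is_enriched and in_a:
                prop *= fold
            kim = base_kim + float(rng.normal(0.0, kimura_sd))
            if is_conserved and in_a:
                kim += kimura_shift
            rows.append({"repeat_type": rtype, "repeat_class": rclass,
                         "genome_id": gid, "proportion": prop,
                         "kimura": max(kim, 0.0)})
    table = pd.DataFrame(rows)
    truth = {"group_a": genomes_a, "group_b": genomes_b,
             "enriched": enriched, "conserved": conserved}
    return table, truth
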