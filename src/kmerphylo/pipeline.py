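"""Full-analysis orchestration from a single structured config.

Stages: region curation -> k-mer profiling -> D2S distance matrix ->
neighbour-joining tree (rooted with the outgroup) -> relatedness network ->
core k-mers and per-node counts -> feature mapping of core k-mers ->
repeat-type enrichment. Each stage writes its artefacts under the run
directory and records them (with SHA-256 hashes) in a machine-readable
manifest; a rerun with identical config and seed reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from kmerphylo import core, io_formats, kmers, mapping, network
from kmerphylo import d2s_distance as d2s
from kmerphylo import regions as regions_mod
from kmerphylo import repeat_stats, trees
from kmerphylo.io_formats import ValidationError

log = logging.getLogger("kmerphylo")


@dataclass
class GenomeInput:
    genome_id: str
    fasta: str
    gff: str
    species: str = ""
    isolate: str = ""
    lifestyle: str = "unknown"


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    genomes: list[GenomeInput] = field(default_factory=list)
    simulate: dict | None = None          # SimulationConfig overrides, or None
    region_kind: str = "WGS"
    k: int = kmers.DEFAULT_CORE_K
    canonical: bool = False
    outgroup: list[str] = field(default_factory=list)
    reference_tree: str | None = None
    core_group: list[str] | None = None   # default: all genomes
    mapping_reference: str | None = None  # default: first core-group member
    enrichment_group_a: list[str] = field(default_factory=list)
    enrichment_group_b: list[str] = field(default_factory=list)
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["genomes"] = [GenomeInput(**g) for g in raw.get("genomes", [])]
        return cls(**raw)

    def validate(self) -> None:
        if not self.genomes and self.simulate is None:
            raise ValidationError("config lists no genomes and no simulation block")
        for g in self.genomes:
            for p in (g.fasta, g.gff):
                if not Path(p).exists():
                    raise ValidationError(f"missing input file: {p}")
        ids = [g.genome_id for g in self.genomes]
        declared = set(ids)
        for group in (self.outgroup, self.core_group or [],
                      self.enrichment_group_a, self.enrichment_group_b):
            unknown = set(group) - declared if ids else set()
            if ids and unknown:
                raise ValidationError(f"group references undeclared genomes: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, run_dir: Path, config_echo: dict):
        self.run_dir = run_dir
        self.obj = {"config": config_echo, "stages": []}

    def record(self, stage: str, params: dict, outputs: list[Path], seconds: float):
        self.obj["stages"].append({
            "stage": stage,
            "parameters": params,
            "outputs": {str(p.relative_to(self.run_dir)): _sha256(p) for p in outputs},
            "wall_seconds": round(seconds, 3),
        })
        (self.run_dir / "manifest.json").write_text(json.dumps(self.obj, indent=1, default=str))


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    config.validate()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(run_dir, {k: v for k, v in vars(config).items()
                                   if k != "genomes"})

    def stage(name):
        def wrap(fn):
            t0 = time.monotonic()
            log.info("stage %s: starting", name)
            try:
                params, outputs = fn()
            except Exception:
                log.error("stage %s failed", name)
                raise
            manifest.record(name, params, outputs, time.monotonic() - t0)
            log.info("stage %s: done (%.2fs)", name, time.monotonic() - t0)
        return wrap

    genomes: dict = {}
    features: dict = {}
    metadata_rows = []

    @stage("load")
    def _load():
        outputs = []
        if config.simulate is not None:
            from kmerphylo.simulate import SimulationConfig, simulate_dataset
            sim_cfg = SimulationConfig.from_dict({"seed": config.seed, **config.simulate})
            ds = simulate_dataset(sim_cfg)
            for g in ds.genomes:
                genomes[g.genome_id] = g
                features[g.genome_id] = ds.features[g.genome_id]
            metadata_rows.extend(ds.metadata.to_dict("records"))
            true_path = run_dir / "true_tree.nwk"
            io_formats.write_newick(ds.true_tree, true_path)
            meta_path = run_dir / "metadata.tsv"
            io_formats.write_metadata_table(ds.metadata, meta_path)
            outputs += [true_path, meta_path]
        for gi in config.genomes:
            rec = io_formats.GenomeRecord(
                gi.genome_id, gi.species, gi.isolate, gi.lifestyle,
                io_formats.read_fasta(gi.fasta))
            genomes[gi.genome_id] = rec
            features[gi.genome_id] = io_formats.read_gff3(gi.gff, rec.scaffold_lengths)
            metadata_rows.append({"genome_id": gi.genome_id, "species": gi.species,
                                  "isolate": gi.isolate, "lifestyle": gi.lifestyle})
        return {"n_genomes": len(genomes), "simulated": config.simulate is not None}, outputs

    region_sets: dict = {}

    @stage("regions")
    def _regions():
        outputs = []
        report_rows = []
        for gid in sorted(genomes):
            g, f = genomes[gid], features[gid]
            if config.region_kind == "WGS":
                rs = regions_mod.wgs(g)
            elif config.region_kind == "rmWGS":
                rs = regions_mod.extract_rmwgs(g, f)
            elif config.region_kind == "CDS":
                rs = regions_mod.extract_cds(g, f)
            elif config.region_kind == "intron":
                rs = regions_mod.extract_introns(g, f)
            elif config.region_kind == "repeat":
                rs = regions_mod.extract_repeats(g, f)
            elif config.region_kind == "protein":
                rs = regions_mod.translate_cds(regions_mod.extract_cds(g, f))
            else:
                raise ValidationError(f"unknown region kind {config.region_kind!r}")
            region_sets[gid] = rs
            report_rows.append(rs)
        report = regions_mod.region_size_report(report_rows)
        rpath = run_dir / "region_sizes.tsv"
        report.to_csv(rpath, sep="\t", index=False)
        outputs.append(rpath)
        return {"region_kind": config.region_kind}, outputs

    profiles: dict = {}
    backgrounds: dict = {}

    @stage("profiles")
    def _profiles():
        for gid in sorted(region_sets):
            profiles[gid] = kmers.count_kmers(region_sets[gid], config.k, config.canonical)
            backgrounds[gid] = d2s.letter_frequencies(region_sets[gid])
        return {"k": config.k, "canonical": config.canonical}, []

    matrix_holder: dict = {}

    @stage("distances")
    def _distances():
        matrix = d2s.distance_matrix(profiles, backgrounds)
        matrix_holder["matrix"] = matrix
        mpath = run_dir / f"distances_{config.region_kind}_k{config.k}.phylip"
        io_formats.write_phylip(matrix, mpath)
        return {"k": config.k}, [mpath]

    tree_holder: dict = {}

    @stage("tree")
    def _tree():
        tree = trees.neighbor_joining(matrix_holder["matrix"])
        if config.outgroup:
            tree = trees.root_with_outgroup(tree, config.outgroup)
        tree_holder["tree"] = tree
        tpath = run_dir / "nj_tree.nwk"
        io_formats.write_newick(tree, tpath)
        outputs = [tpath]
        if config.reference_tree:
            ref = io_formats.read_newick(Path(config.reference_tree).read_text())
            smap = {r["genome_id"]: r["species"] for r in metadata_rows}
            rf = trees.normalized_rf(tree, ref, smap)
            rf_path = run_dir / "rf_vs_reference.json"
            rf_path.write_text(json.dumps({"normalized_rf": rf}))
            outputs.append(rf_path)
        return {"outgroup": config.outgroup}, outputs

    @stage("network")
    def _network():
        meta = {r["genome_id"]: {"species": r["species"], "lifestyle": r["lifestyle"]}
                for r in metadata_rows}
        net = network.build_network(matrix_holder["matrix"], meta)
        npath = run_dir / "network.json"
        io_formats.write_network_json(net, npath)
        bpath = run_dir / "network_breakpoints.tsv"
        with open(bpath, "w") as fh:
            fh.write("t\tn_components\n")
            for t, n in network.component_breakpoints(net):
                fh.write(f"{t}\t{n}\n")
        return {}, [npath, bpath]

    core_holder: dict = {}

    @stage("core_kmers")
    def _core():
        group = config.core_group or sorted(profiles)
        cset = core.core_kmers(profiles, group)
        core_holder["set"] = cset
        cpath = run_dir / "core_kmers.txt"
        cset.write(cpath)
        annotated = core.annotate_tree_with_core_counts(tree_holder["tree"], profiles)
        apath = run_dir / "tree_core_counts.nwk"
        apath.write_text(annotated + "\n")
        return {"group": group, "n_core": len(cset)}, [cpath, apath]

    @stage("map_kmers")
    def _map():
        ref_id = config.mapping_reference or (config.core_group or sorted(profiles))[0]
        hits = mapping.locate_kmers(core_holder["set"].words, genomes[ref_id])
        cls = mapping.classify_hits(hits, features[ref_id], strand_specific=True)
        counts = mapping.venn_counts(cls, total_words=len(core_holder["set"]))
        vpath = run_dir / "venn_counts.tsv"
        with open(vpath, "w") as fh:
            for key in sorted(counts):
                fh.write(f"{key}\t{counts[key]}\n")
        return {"reference": ref_id}, [vpath]

    @stage("repeat_enrichment")
    def _enrich():
        if not (config.enrichment_group_a and config.enrichment_group_b):
            return {"skipped": "no enrichment groups configured"}, []
        tables = [repeat_stats.repeat_type_table(genomes[gid], features[gid])
                  for gid in sorted(genomes)]
        table = repeat_stats.combine_tables(tables)
        shared = repeat_stats.shared_repeat_types(
            table, config.enrichment_group_a + config.enrichment_group_b)
        results = []
        for metric in repeat_stats.METRICS:
            results += repeat_stats.enrichment_test(
                table, config.enrichment_group_a, config.enrichment_group_b,
                metric=metric, alpha=config.alpha, types=shared)
        rpath = run_dir / "enrichment.tsv"
        repeat_stats.results_table(results).to_csv(rpath, sep="\t", index=False)
        spath = run_dir / "enrichment_by_class.tsv"
        repeat_stats.summarise_by_class(results).to_csv(spath, sep="\t", index=False)
        return {"n_shared_types": len(shared), "alpha": config.alpha}, [rpath, spath]

    return run_dir
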