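"""Curation of region-specific sequence sets from a genome plus annotations.

Five nucleotide data sets are produced per genome — the whole assembly (WGS),
the repeat-masked assembly (rmWGS), strand-specific coding sequences (CDS),
introns and annotated repeats — plus the translated protein set. Repeat
"deletion" splits scaffolds at merged repeat spans (no chimeric joins), then
discards fragments shorter than ``min_len`` (default 1 kb).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from kmerphylo.io_formats import Feature, FeatureIndex, GenomeRecord, ValidationError

REGION_KINDS = {"WGS", "rmWGS", "CDS", "intron", "repeat", "protein"}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RegionSet:
    """The sequences of one region kind for one genome."""

    genome_id: str
    region_kind: str
    sequences: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.region_kind not in REGION_KINDS:
            raise ValidationError(f"unknown region kind {self.region_kind!r}")

    @property
    def total_bases(self) -> int:
        return sum(len(s) for _, s in self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open intervals."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for start, end in ordered[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def wgs(genome: GenomeRecord) -> RegionSet:
    """The entire assembly as a region set."""
    return RegionSet(genome.genome_id, "WGS", list(genome.scaffolds))


def extract_rmwgs(genome: GenomeRecord, features: FeatureIndex,
                  min_len: int = 1000) -> RegionSet:
    """Delete annotated repeats and drop residual fragments shorter than min_len.

    Each scaffold is split at merged repeat spans into non-repeat fragments
    (never concatenated across a deleted span). Before the length filter the
    retained bases plus the merged repeat bases account for the assembly
    exactly.
    """
    features.validate(genome.scaffold_lengths)
    repeats_by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for f in features.by_kind("repeat"):
        repeats_by_scaffold.setdefault(f.scaffold_id, []).append((f.start, f.end))

    fragments: list[tuple[str, str]] = []
    for sid, seq in genome.scaffolds:
        spans = merge_intervals(repeats_by_scaffold.get(sid, []))
        pos = 0
        pieces: list[tuple[int, int]] = []
        for start, end in spans:
            if start > pos:
                pieces.append((pos, start))
            pos = max(pos, end)
        if pos < len(seq):
            pieces.append((pos, len(seq)))
        for i, (s, e) in enumerate(pieces):
            if e - s >= min_len:
                fragments.append((f"{sid}_frag{i}", seq[s:e]))
    return RegionSet(genome.genome_id, "rmWGS", fragments)


def _cds_groups(features: FeatureIndex) -> dict[str, list[Feature]]:
    """CDS features grouped per transcript (Parent attribute, else ID)."""
    groups: dict[str, list[Feature]] = {}
    for f in features.by_kind("CDS"):
        key = f.attributes.get("Parent") or f.attributes.get("ID")
        if key is None:
            raise ValidationError("CDS feature lacks Parent/ID attribute")
        groups.setdefault(key, []).append(f)
    return groups


def _pick_transcripts(groups: dict[str, list[Feature]]) -> dict[str, list[Feature]]:
    """Where a gene has several transcripts, keep the one with the longest CDS."""
    by_gene: dict[str, list[str]] = {}
    for tid, segs in groups.items():
        gene = segs[0].attributes.get("gene_id", tid)
        by_gene.setdefault(gene, []).append(tid)
    chosen: dict[str, list[Feature]] = {}
    for gene, tids in by_gene.items():
        best = max(sorted(tids), key=lambda t: sum(f.length for f in groups[t]))
        chosen[best] = groups[best]
    return chosen


def extract_cds(genome: GenomeRecord, features: FeatureIndex) -> RegionSet:
    """Sense-strand coding sequence per transcript.

    CDS segments are concatenated in genomic order and reverse-complemented as
    a unit for − strand transcripts.
    """
    features.validate(genome.scaffold_lengths)
    out: list[tuple[str, str]] = []
    for tid, segs in sorted(_pick_transcripts(_cds_groups(features)).items()):
        strands = {f.strand for f in segs}
        if len(strands) > 1:
            raise ValidationError(f"transcript {tid!r} mixes strands {sorted(strands)}")
        scaffolds = {f.scaffold_id for f in segs}
        if len(scaffolds) > 1:
            raise ValidationError(f"transcript {tid!r} spans multiple scaffolds")
        (strand,) = strands
        seq = genome.scaffold_seq(segs[0].scaffold_id)
        parts = [seq[f.start:f.end] for f in sorted(segs, key=lambda f: f.start)]
        cds = "".join(parts)
        if strand == "-":
            cds = reverse_complement(cds)
        out.append((tid, cds))
    return RegionSet(genome.genome_id, "CDS", out)


def extract_introns(genome: GenomeRecord, features: FeatureIndex) -> RegionSet:
    """Each intron individually, on its gene's sense strand.

    Explicit intron features are used when present; otherwise introns are
    derived as the gaps between consecutive exons of each transcript.
    """
    features.validate(genome.scaffold_lengths)
    out: list[tuple[str, str]] = []

    explicit = features.by_kind("intron")
    if explicit:
        for i, f in enumerate(sorted(explicit, key=lambda f: (f.scaffold_id, f.start))):
            seq = genome.scaffold_seq(f.scaffold_id)[f.start:f.end]
            if f.strand == "-":
                seq = reverse_complement(seq)
            name = f.attributes.get("ID", f"intron{i}")
            out.append((name, seq))
        return RegionSet(genome.genome_id, "intron", out)

    groups: dict[str, list[Feature]] = {}
    for f in features.by_kind("exon"):
        key = f.attributes.get("Parent") or f.attributes.get("ID")
        if key is None:
            raise ValidationError("exon feature lacks Parent/ID attribute")
        groups.setdefault(key, []).append(f)
    for tid in sorted(groups):
        exons = sorted(groups[tid], key=lambda f: f.start)
        strands = {f.strand for f in exons}
        if len(strands) > 1:
            raise ValidationError(f"transcript {tid!r} mixes strands")
        (strand,) = strands
        seq = genome.scaffold_seq(exons[0].scaffold_id)
        for i in range(len(exons) - 1):
            gap_start, gap_end = exons[i].end, exons[i + 1].start
            if gap_end < gap_start:
                raise ValidationError(f"overlapping exons in transcript {tid!r}")
            if gap_end == gap_start:
                continue
            intron = seq[gap_start:gap_end]
            if strand == "-":
                intron = reverse_complement(intron)
            out.append((f"{tid}_intron{i}", intron))
    return RegionSet(genome.genome_id, "intron", out)


def extract_repeats(genome: GenomeRecord, features: FeatureIndex) -> RegionSet:
    """One sequence per (overlap-merged) annotated repeat interval, forward strand."""
    features.validate(genome.scaffold_lengths)
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for f in features.by_kind("repeat"):
        by_scaffold.setdefault(f.scaffold_id, []).append((f.start, f.end))
    out: list[tuple[str, str]] = []
    for sid in sorted(by_scaffold):
        seq = genome.scaffold_seq(sid)
        for start, end in merge_intervals(by_scaffold[sid]):
            out.append((f"{sid}:{start}-{end}", seq[start:end]))
    return RegionSet(genome.genome_id, "repeat", out)


def translate_cds(cds: RegionSet) -> RegionSet:
    """Translate sense-strand CDS to protein (standard code).

    A trailing partial codon is dropped with a warning; the terminal stop is
    removed; internal stops are retained as ``*`` and flagged with a warning.
    Empty sequences are skipped.
    """
    if cds.region_kind != "CDS":
        raise ValidationError(f"expected CDS region set, got {cds.region_kind}")
    out: list[tuple[str, str]] = []
    for name, seq in cds.sequences:
        if not seq:
            warnings.warn(f"empty CDS {name!r} skipped")
            continue
        if len(seq) % 3:
            warnings.warn(f"CDS {name!r} length {len(seq)} not divisible by 3; "
                          "trailing remainder dropped")
            seq = seq[: len(seq) - len(seq) % 3]
        if not seq:
            continue
        prot = str(Seq(seq).translate())
        if prot.endswith("*"):
            prot = prot[:-1]
        if "*" in prot:
            warnings.warn(f"CDS {name!r} translates with internal stop codon(s)")
        if prot:
            out.append((name, prot))
    return RegionSet(cds.genome_id, "protein", out)


def gc_content(region_set: RegionSet) -> float:
    """(G+C) / (A+C+G+T) over the set; ambiguity codes excluded entirely."""
    if region_set.region_kind == "protein":
        raise ValidationError("GC content is undefined for protein sequences")
    gc = at = 0
    for _, seq in region_set.sequences:
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValidationError("no unambiguous bases; GC content undefined")
    return gc / (gc + at)


def region_size_report(region_sets: list[RegionSet]):
    """Per-genome, per-region base totals as a tidy DataFrame."""
    import pandas as pd

    rows = [{"genome_id": rs.genome_id, "region_kind": rs.region_kind,
             "n_sequences": len(rs), "total_bases": rs.total_bases}
            for rs in region_sets]
    return pd.DataFrame(rows)
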