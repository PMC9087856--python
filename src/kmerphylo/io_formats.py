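"""Readers and writers for the external formats the pipeline touches.

All readers validate strictly and raise rather than silently repairing
malformed records. Interval coordinates are 0-based half-open internally;
GFF3 (1-based inclusive) is converted at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A record parses but violates a semantic invariant."""


LIFESTYLES = {"symbiotic", "free-living", "opportunistic", "unknown"}
FEATURE_KINDS = {"gene", "exon", "CDS", "intron", "repeat"}
#: feature kinds for which a missing strand is rejected
STRANDED_KINDS = {"gene", "exon", "CDS", "intron"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeRecord:
    """One assembly: scaffolds plus taxon metadata."""

    genome_id: str
    species: str = ""
    isolate: str = ""
    lifestyle: str = "unknown"
    scaffolds: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lifestyle not in LIFESTYLES:
            raise ValidationError(f"unknown lifestyle {self.lifestyle!r} for {self.genome_id}")
        seen: set[str] = set()
        for sid, seq in self.scaffolds:
            if sid in seen:
                raise ValidationError(f"duplicate scaffold id {sid!r} in {self.genome_id}")
            if not seq:
                raise ValidationError(f"empty sequence for scaffold {sid!r} in {self.genome_id}")
            seen.add(sid)

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {sid: len(seq) for sid, seq in self.scaffolds}

    def scaffold_seq(self, scaffold_id: str) -> str:
        for sid, seq in self.scaffolds:
            if sid == scaffold_id:
                return seq
        raise KeyError(scaffold_id)

    @property
    def total_bases(self) -> int:
        return sum(len(seq) for _, seq in self.scaffolds)


@dataclass(frozen=True)
class Feature:
    """One annotated interval, 0-based half-open."""

    scaffold_id: str
    start: int
    end: int
    strand: str  # '+', '-' or '.'
    kind: str    # gene, exon, CDS, intron, repeat
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start},{self.end}) on {self.scaffold_id}")
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.kind in STRANDED_KINDS and self.strand == ".":
            raise ValidationError(f"{self.kind} feature requires an explicit strand")

    @property
    def length(self) -> int:
        return self.end - self.start


class FeatureIndex:
    """All annotated intervals of one genome, validated against scaffold bounds."""

    def __init__(self, features: Iterable[Feature],
                 scaffold_lengths: Mapping[str, int] | None = None):
        self.features: list[Feature] = list(features)
        if scaffold_lengths is not None:
            self.validate(scaffold_lengths)

    def validate(self, scaffold_lengths: Mapping[str, int]) -> None:
        for f in self.features:
            if f.scaffold_id not in scaffold_lengths:
                raise ValidationError(f"feature references unknown scaffold {f.scaffold_id!r}")
            if f.end > scaffold_lengths[f.scaffold_id]:
                raise ValidationError(
                    f"feature [{f.start},{f.end}) exceeds scaffold {f.scaffold_id!r} "
                    f"of length {scaffold_lengths[f.scaffold_id]}")

    def by_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


#: leaf label -> species name
SpeciesMap = dict


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA; ids are the first whitespace token, sequences upper-cased."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(f"{path}:{lineno}: sequence data before first header")
                break
        else:
            return []
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    seq_records = [SeqRecord(Seq(seq), id=str(rid), description="") for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# GFF3 (and a RepeatMasker-out-like table)
# ---------------------------------------------------------------------------

def _parse_gff_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if not part or part == ".":
            continue
        if "=" not in part:
            raise ParseError(f"malformed GFF3 attribute {part!r}")
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _format_gff_attributes(attrs: Mapping[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_gff3(path: str | Path, scaffold_lengths: Mapping[str, int] | None = None) -> FeatureIndex:
    """Read a GFF3 subset into a FeatureIndex (coordinates become 0-based half-open).

    Only rows whose type is one of gene/exon/CDS/intron/repeat are kept;
    RepeatMasker-style types (``similarity``, ``*_repeat_region``) map to
    ``repeat``.
    """
    path = Path(path)
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, col9 = cols
            if ftype in {"similarity", "repeat_region", "dispersed_repeat", "tandem_repeat"}:
                ftype = "repeat"
            if ftype not in FEATURE_KINDS:
                continue
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ValidationError(f"{path}:{lineno}: end < start")
            if strand not in {"+", "-", "."}:
                raise ValidationError(f"{path}:{lineno}: invalid strand {strand!r}")
            try:
                features.append(Feature(
                    scaffold_id=seqid,
                    start=start1 - 1,     # 1-based inclusive -> 0-based half-open
                    end=end1,
                    strand=strand,
                    kind=ftype,
                    attributes=_parse_gff_attributes(col9),
                ))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return FeatureIndex(features, scaffold_lengths)


def write_gff3(index: FeatureIndex, path: str | Path, source: str = "kmerphylo") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in index:
            fh.write("\t".join([
                f.scaffold_id, source, f.kind,
                str(f.start + 1), str(f.end),   # back to 1-based inclusive
                ".", f.strand, ".",
                _format_gff_attributes(f.attributes),
            ]) + "\n")


def read_repeatmasker_table(path: str | Path,
                            scaffold_lengths: Mapping[str, int] | None = None) -> FeatureIndex:
    """Read a tab-separated RepeatMasker-out-like table into repeat features.

    Expected columns: scaffold_id, start (1-based), end, strand, repeat_type,
    repeat_class, kimura_divergence (optional). Header lines starting with
    ``#`` are skipped.
    """
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 columns")
            sid, start_s, end_s, strand, rtype, rclass = cols[:6]
            attrs = {"repeat_type": rtype, "repeat_class": rclass}
            if len(cols) > 6 and cols[6] not in {"", "."}:
                attrs["kimura_divergence"] = cols[6]
            strand = "-" if strand == "C" else strand  # RepeatMasker complement
            features.append(Feature(sid, int(start_s) - 1, int(end_s),
                                    strand if strand in {"+", "-"} else ".",
                                    "repeat", attrs))
    return FeatureIndex(features, scaffold_lengths)


# ---------------------------------------------------------------------------
# Newick (delegates to the tree module, which wraps dendropy for parsing)
# ---------------------------------------------------------------------------

def read_newick(text_or_path: str | Path):
    """Parse a Newick string (or path to a file containing one) into a PhyloTree."""
    from kmerphylo.trees import PhyloTree

    text = str(text_or_path)
    if "(" not in text:
        text = Path(text_or_path).read_text()
    return PhyloTree.from_newick(text)


def write_newick(tree, path: str | Path | None = None) -> str:
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# PHYLIP square distance matrix
# ---------------------------------------------------------------------------

def write_phylip(matrix, path: str | Path) -> None:
    """Serialise a DistanceMatrix in square PHYLIP format, full precision."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.labels)}\n")
        for i, label in enumerate(matrix.labels):
            row = " ".join(repr(float(v)) for v in matrix.values[i])
            fh.write(f"{label}  {row}\n")


def read_phylip(path: str | Path):
    from kmerphylo.d2s_distance import DistanceMatrix
    import numpy as np

    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty PHYLIP file")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise ParseError(f"{path}: bad taxon count line") from exc
    if len(lines) != n + 1:
        raise ParseError(f"{path}: expected {n} matrix rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise ParseError(f"{path}: row has {len(parts) - 1} values, expected {n}")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(labels=labels, values=np.array(rows))


# ---------------------------------------------------------------------------
# network JSON (D3-style nodes/links)
# ---------------------------------------------------------------------------

def write_network_json(network, path: str | Path, t: float | None = None) -> dict:
    """Emit a nodes/links object consumable by D3-style force layouts.

    ``network`` must provide ``to_json_obj()`` (see
    :class:`kmerphylo.network.RelatednessNetwork`); ``t`` optionally restricts
    the links to edges with S >= t. Every link's endpoints are checked against
    the node list.
    """
    obj = network.to_json_obj(t)
    node_ids = {node["id"] for node in obj["nodes"]}
    for link in obj["links"]:
        if link["source"] not in node_ids or link["target"] not in node_ids:
            raise ValidationError(
                f"link {link['source']}--{link['target']} references unknown node")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
    return obj


# ---------------------------------------------------------------------------
# metadata table
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["genome_id", "species", "isolate", "lifestyle"]


def read_metadata_table(path: str | Path) -> pd.DataFrame:
    """Tab-separated taxon table with columns genome_id, species, isolate, lifestyle."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata columns {missing}")
    if df["genome_id"].duplicated().any():
        dups = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValidationError(f"duplicate genome_ids in metadata: {dups}")
    return df


def write_metadata_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def species_map_from_metadata(df: pd.DataFrame) -> dict[str, str]:
    return dict(zip(df["genome_id"], df["species"]))
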