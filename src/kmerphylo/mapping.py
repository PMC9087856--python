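"""Locating k-mers on a reference genome and classifying them against features.

k-mers are exact words, so location uses exact two-strand substring search
(a hit on − means the reverse complement of the genome window equals the
word). Overlap with annotated features follows bedtools ``intersectBed -s``
semantics: one shared base suffices, and under strand-specific mode the hit
strand must match the feature strand. Gene regions use the full gene span
(introns and exons inclusive), split by the gene's known/dark status.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from kmerphylo.io_formats import FeatureIndex, GenomeRecord, ValidationError
from kmerphylo.regions import reverse_complement

FLAGS = ("repeat", "known_gene", "dark_gene")


@dataclass(frozen=True)
class KmerHit:
    word: str
    scaffold_id: str
    start: int  # 0-based
    strand: str  # '+': forward match, '-': reverse-complement match

    @property
    def end(self) -> int:
        return self.start + len(self.word)


@dataclass(frozen=True)
class KmerClassification:
    word: str
    repeat: bool = False
    known_gene: bool = False
    dark_gene: bool = False

    @property
    def unclassified(self) -> bool:
        return not (self.repeat or self.known_gene or self.dark_gene)

    @property
    def flag_set(self) -> frozenset[str]:
        return frozenset(f for f in FLAGS if getattr(self, f))


def locate_kmers(words: Iterable[str], genome: GenomeRecord) -> list[KmerHit]:
    """Every exact occurrence of each word on either strand of the genome.

    Multi-mapping words yield multiple hits; absent words yield none. All
    words must share one length k. The genome is scanned once per strand
    orientation (word-set membership per window), so cost is O(total bases).
    """
    word_set = set(words)
    if not word_set:
        return []
    ks = {len(w) for w in word_set}
    if len(ks) != 1:
        raise ValidationError(f"words of mixed lengths: {sorted(ks)}")
    k = ks.pop()
    hits: list[KmerHit] = []
    for sid, seq in genome.scaffolds:
        for i in range(len(seq) - k + 1):
            window = seq[i:i + k]
            if window in word_set:
                hits.append(KmerHit(window, sid, i, "+"))
            rc = reverse_complement(window)
            if rc in word_set:
                hits.append(KmerHit(rc, sid, i, "-"))
    return hits


def _feature_trees(index: FeatureIndex) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in index:
        flag = None
        if f.kind == "repeat":
            flag = "repeat"
        elif f.kind == "gene":
            status = f.attributes.get("gene_status", "known")
            flag = "dark_gene" if status == "dark" else "known_gene"
        if flag is None:
            continue
        trees.setdefault(f.scaffold_id, IntervalTree()).addi(
            f.start, f.end, (flag, f.strand))
    return trees


def classify_hits(hits: Sequence[KmerHit], feature_index: FeatureIndex,
                  strand_specific: bool = True) -> list[KmerClassification]:
    """Per-word feature membership flags, unioned over all of the word's hits.

    A hit overlaps a feature when their intervals share at least one base and,
    under ``strand_specific``, their strands match. Words with no flagged hit
    are unclassified. The returned list has one entry per distinct word with
    at least one hit, in sorted word order.
    """
    trees = _feature_trees(feature_index)
    flags: dict[str, set[str]] = {}
    for hit in hits:
        flags.setdefault(hit.word, set())
        tree = trees.get(hit.scaffold_id)
        if tree is None:
            continue
        for iv in tree.overlap(hit.start, hit.end):
            flag, fstrand = iv.data
            if strand_specific and fstrand in {"+", "-"} and fstrand != hit.strand:
                continue
            flags[hit.word].add(flag)
    return [KmerClassification(word,
                               repeat="repeat" in fl,
                               known_gene="known_gene" in fl,
                               dark_gene="dark_gene" in fl)
            for word, fl in sorted(flags.items())]


def venn_counts(classifications: Sequence[KmerClassification],
                total_words: int | None = None) -> dict[str, int]:
    """Mutually exclusive cell counts per flag combination.

    Cells are keyed by '+'-joined sorted flag names (e.g. ``repeat``,
    ``known_gene+repeat``) plus ``unclassified``. Aggregates: ``any_feature``
    (words in >= 1 annotated feature) and ``total`` (classified words). If
    ``total_words`` is given (the full query word count, including words
    absent from the reference), ``absent_from_reference`` is reported too.
    """
    cells: Counter[str] = Counter()
    for c in classifications:
        key = "+".join(sorted(c.flag_set)) if c.flag_set else "unclassified"
        cells[key] += 1
    out = {key: 0 for key in _all_cells()}
    out.update(cells)
    out["total"] = len(classifications)
    out["any_feature"] = len(classifications) - out["unclassified"]
    if total_words is not None:
        if total_words < len(classifications):
            raise ValidationError("total_words smaller than classified words")
        out["absent_from_reference"] = total_words - len(classifications)
    return out


def _all_cells() -> list[str]:
    from itertools import combinations

    cells = ["unclassified"]
    for r in (1, 2, 3):
        for combo in combinations(sorted(FLAGS), r):
            cells.append("+".join(combo))
    return cells


def write_hits_bed(hits: Sequence[KmerHit], path) -> None:
    """BED6 output (0-based half-open) of k-mer hits."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.scaffold_id}\t{h.start}\t{h.end}\t{h.word}\t0\t{h.strand}\n")
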