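"""k-mer counting and the distinct/unique k-optimisation sweep.

A profile records the multiset of length-k words of a region set. Windows
containing out-of-alphabet symbols (e.g. ``N``) are skipped, and words never
span sequence boundaries. ``prop_distinct = D/T`` and ``prop_unique = U/D``
where T is the number of counted windows, D the number of distinct words and
U the number of words seen exactly once.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from kmerphylo.io_formats import ValidationError
from kmerphylo.regions import RegionSet, reverse_complement

NUCLEOTIDE_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: k grid for nucleotide regions
NUCLEOTIDE_K_GRID = tuple(range(11, 26, 2))
#: extended grid used when short words are insufficiently distinct (repeats)
REPEAT_K_GRID = tuple(range(11, 52, 2))
#: grid for protein sequences; k=9 is the default protein choice
PROTEIN_K_GRID = (3, 5, 7, 9)
DEFAULT_PROTEIN_K = 9
#: default word length for nucleotide core-k-mer analysis
DEFAULT_CORE_K = 23

_VALID_RUN = {
    "nucleotide": re.compile(f"[{NUCLEOTIDE_ALPHABET}]+"),
    "protein": re.compile(f"[{PROTEIN_ALPHABET}]+"),
}


@dataclass
class KmerProfile:
    genome_id: str
    region_kind: str
    k: int
    alphabet: str                      # 'nucleotide' | 'protein'
    counts: dict[str, int] = field(default_factory=dict)
    canonical: bool = False

    @property
    def T(self) -> int:
        """Total counted windows."""
        return sum(self.counts.values())

    @property
    def D(self) -> int:
        """Distinct words."""
        return len(self.counts)

    @property
    def U(self) -> int:
        """Words occurring exactly once."""
        return sum(1 for c in self.counts.values() if c == 1)

    @property
    def words(self) -> set[str]:
        return set(self.counts)

    def dump(self, path) -> None:
        """Jellyfish-dump-like word<TAB>count text output."""
        with open(path, "w") as fh:
            for word in sorted(self.counts):
                fh.write(f"{word}\t{self.counts[word]}\n")

    @classmethod
    def load(cls, path, genome_id: str, region_kind: str = "WGS",
             alphabet: str = "nucleotide", canonical: bool = False) -> "KmerProfile":
        counts: dict[str, int] = {}
        k = None
        with open(path) as fh:
            for line in fh:
                word, _, count = line.rstrip("\n").partition("\t")
                if k is None:
                    k = len(word)
                elif len(word) != k:
                    raise ValidationError(f"mixed word lengths in {path}")
                counts[word] = int(count)
        return cls(genome_id, region_kind, k or 0, alphabet, counts, canonical)


def count_kmers(region_set: RegionSet, k: int, canonical: bool = False) -> KmerProfile:
    """Count every k-length window of the region set.

    With ``canonical=True`` (nucleotide only) each word is replaced by the
    lexicographic minimum of itself and its reverse complement. Default
    counting is strand-as-given, since CDS/intron sets are strand-specific.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    alphabet = "protein" if region_set.region_kind == "protein" else "nucleotide"
    if canonical and alphabet == "protein":
        raise ValidationError("canonical counting is defined for nucleotides only")
    run_re = _VALID_RUN[alphabet]
    counts: dict[str, int] = {}
    for _, seq in region_set.sequences:
        for match in run_re.finditer(seq):
            run = match.group(0)
            for i in range(len(run) - k + 1):
                word = run[i:i + k]
                if canonical:
                    rc = reverse_complement(word)
                    if rc < word:
                        word = rc
                counts[word] = counts.get(word, 0) + 1
    if not counts:
        warnings.warn(f"no window of length k={k} in {region_set.genome_id} "
                      f"{region_set.region_kind}; empty profile")
    return KmerProfile(region_set.genome_id, region_set.region_kind, k,
                       alphabet, counts, canonical)


def kmer_stats(profile: KmerProfile) -> tuple[float, float]:
    """(prop_distinct, prop_unique) = (D/T, U/D)."""
    T = profile.T
    if T == 0:
        raise ValidationError("empty profile: proportions undefined")
    D = profile.D
    return D / T, profile.U / D


@dataclass
class KSweepResult:
    region_kind: str
    grid: tuple[int, ...]
    #: (genome_id, k) -> (prop_distinct, prop_unique)
    stats: dict[tuple[str, int], tuple[float, float]]
    chosen_k: int | None = None

    def mean_props(self, k: int) -> tuple[float, float]:
        vals = [v for (g, kk), v in self.stats.items() if kk == k]
        if not vals:
            raise KeyError(k)
        pd = sum(v[0] for v in vals) / len(vals)
        pu = sum(v[1] for v in vals) / len(vals)
        return pd, pu


def sweep_k(region_sets: Mapping[str, RegionSet] | Sequence[RegionSet],
            grid: Iterable[int], canonical: bool = False) -> KSweepResult:
    """Evaluate the distinct/unique proportions per genome across a k grid."""
    if not isinstance(region_sets, Mapping):
        region_sets = {rs.genome_id: rs for rs in region_sets}
    grid = tuple(grid)
    if not grid or list(grid) != sorted(set(grid)):
        raise ValidationError("k grid must be non-empty and strictly increasing")
    if not region_sets:
        raise ValidationError("no genomes to sweep")
    kinds = {rs.region_kind for rs in region_sets.values()}
    if len(kinds) != 1:
        raise ValidationError(f"mixed region kinds in sweep: {sorted(kinds)}")
    stats: dict[tuple[str, int], tuple[float, float]] = {}
    for gid in sorted(region_sets):
        for k in grid:
            try:
                stats[(gid, k)] = kmer_stats(count_kmers(region_sets[gid], k, canonical))
            except ValidationError as exc:
                warnings.warn(f"sweep: genome {gid}, k={k} failed: {exc}")
    return KSweepResult(next(iter(kinds)), grid, stats)


def select_optimal_k(sweep: KSweepResult, distinctness_floor: float = 0.5) -> int:
    """The k maximising the mean of the two proportions, subject to a floor.

    Among grid values whose mean prop_distinct across genomes reaches the
    floor, return the k with the highest mean of (prop_distinct+prop_unique)/2
    (ties: smallest k). If no k passes the floor, escalate to the largest grid
    value with a warning — short words are not sufficiently distinct.
    """
    if not sweep.stats:
        raise ValidationError("empty sweep")
    passing = []
    scored = []
    for k in sweep.grid:
        try:
            pd, pu = sweep.mean_props(k)
        except KeyError:
            continue
        score = (pd + pu) / 2.0
        scored.append((k, pd, score))
        if pd >= distinctness_floor:
            passing.append((k, score))
    if not scored:
        raise ValidationError("sweep produced no usable statistics")
    if not passing:
        k_max = max(k for k, _, _ in scored)
        warnings.warn(
            f"no k reaches mean prop_distinct >= {distinctness_floor}; "
            f"falling back to largest grid value k={k_max}")
        sweep.chosen_k = k_max
        return k_max
    best_score = max(s for _, s in passing)
    chosen = min(k for k, s in passing if s == best_score)
    sweep.chosen_k = chosen
    return chosen
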