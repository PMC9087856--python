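"""The D2S dissimilarity between k-mer profiles.

D2S sums, over the words W observed in either of two genomes, the product of
centred counts normalised by their Euclidean magnitude:

    D2S = sum_{w in W} Xc_w * Yc_w / sqrt(Xc_w^2 + Yc_w^2)

where Xc_w = X_w − T_A·p_w^A and Yc_w = Y_w − T_B·p_w^B centre the observed
counts by their expectation under a zero-order (independent-letter)
background model estimated per genome. Terms with both centred counts exactly
zero are skipped. The statistic is transformed into a distance by

    d = min(10, max(0, −ln( D2S_AB / sqrt(D2S_AA · D2S_BB) )))

with a non-positive normalised similarity mapping to the maximal distance 10,
so the network similarity S = 10 − d spans exactly the [0, 10] threshold
range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from kmerphylo.io_formats import ValidationError
from kmerphylo.kmers import (
    NUCLEOTIDE_ALPHABET,
    PROTEIN_ALPHABET,
    KmerProfile,
)
from kmerphylo.regions import RegionSet

MAX_DISTANCE = 10.0

_ALPHABETS = {"nucleotide": NUCLEOTIDE_ALPHABET, "protein": PROTEIN_ALPHABET}


@dataclass
class BackgroundModel:
    """Zero-order letter-frequency null model for one genome's region set."""

    genome_id: str
    alphabet: str
    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValidationError(f"letter frequencies sum to {total}, not 1")
        if any(v < 0 for v in self.frequencies.values()):
            raise ValidationError("negative letter frequency")

    def freq_vector(self) -> np.ndarray:
        letters = _ALPHABETS[self.alphabet]
        return np.array([self.frequencies.get(l, 0.0) for l in letters])


def letter_frequencies(region_set: RegionSet) -> BackgroundModel:
    """Estimate letter frequencies from the unambiguous letters of a region set."""
    alphabet = "protein" if region_set.region_kind == "protein" else "nucleotide"
    letters = _ALPHABETS[alphabet]
    counts = {l: 0 for l in letters}
    for _, seq in region_set.sequences:
        for l in letters:
            counts[l] += seq.count(l)
    total = sum(counts.values())
    if total == 0:
        raise ValidationError(f"no unambiguous letters in {region_set.genome_id} "
                              f"{region_set.region_kind}")
    return BackgroundModel(region_set.genome_id, alphabet,
                           {l: c / total for l, c in counts.items()})


def _letter_count_matrix(words: list[str], alphabet_letters: str) -> np.ndarray:
    """Per-word letter-composition counts, shape (n_words, |alphabet|)."""
    mat = np.zeros((len(words), len(alphabet_letters)), dtype=np.int16)
    for i, word in enumerate(words):
        for j, letter in enumerate(alphabet_letters):
            mat[i, j] = word.count(letter)
    return mat


def _expected_counts(comp: np.ndarray, bg: BackgroundModel, T: int) -> np.ndarray:
    freqs = bg.freq_vector()
    # p_w = prod over letters f^count; 0**0 == 1 keeps absent letters neutral
    pw = np.prod(np.power(freqs[None, :], comp), axis=1)
    return T * pw


def d2s(profile_a: KmerProfile, profile_b: KmerProfile,
        bg_a: BackgroundModel, bg_b: BackgroundModel,
        _comp_cache: dict | None = None) -> float:
    """The D2S statistic over the union of words observed in either profile.

    Symmetric in its arguments. ``_comp_cache`` optionally maps word -> letter
    composition row index into a shared cache, used by :func:`distance_matrix`
    to avoid recomputing word compositions across pairs.
    """
    if profile_a.k != profile_b.k:
        raise ValidationError(f"k mismatch: {profile_a.k} vs {profile_b.k}")
    if profile_a.alphabet != profile_b.alphabet:
        raise ValidationError("alphabet mismatch between profiles")
    if profile_a.T == 0 or profile_b.T == 0:
        raise ValidationError("empty profile in D2S")
    letters = _ALPHABETS[profile_a.alphabet]

    words = sorted(profile_a.counts.keys() | profile_b.counts.keys())
    if _comp_cache is not None:
        rows = []
        for w in words:
            row = _comp_cache.get(w)
            if row is None:
                row = tuple(w.count(l) for l in letters)
                _comp_cache[w] = row
            rows.append(row)
        comp = np.array(rows, dtype=np.int16)
    else:
        comp = _letter_count_matrix(words, letters)

    X = np.fromiter((profile_a.counts.get(w, 0) for w in words), dtype=float,
                    count=len(words))
    Y = np.fromiter((profile_b.counts.get(w, 0) for w in words), dtype=float,
                    count=len(words))
    Xc = X - _expected_counts(comp, bg_a, profile_a.T)
    Yc = Y - _expected_counts(comp, bg_b, profile_b.T)
    denom2 = Xc * Xc + Yc * Yc
    mask = denom2 > 0.0
    return float(np.sum(Xc[mask] * Yc[mask] / np.sqrt(denom2[mask])))


def transform_to_distance(d2s_ab: float, d2s_aa: float, d2s_bb: float) -> float:
    """Clamped −ln of the geometric self-normalised similarity, in [0, 10]."""
    if d2s_aa <= 0 or d2s_bb <= 0:
        raise ValidationError("non-positive self-similarity")
    a = d2s_ab / math.sqrt(d2s_aa * d2s_bb)
    if a <= 0:
        return MAX_DISTANCE
    return min(MAX_DISTANCE, max(0.0, -math.log(a)))


@dataclass
class DistanceMatrix:
    """Labelled symmetric pairwise dissimilarity matrix, d in [0, 10]."""

    labels: list[str]
    values: np.ndarray
    region_kind: str | None = None
    k: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def distance_matrix(profiles: dict[str, KmerProfile],
                    backgrounds: dict[str, BackgroundModel] | None = None,
                    region_sets: dict[str, RegionSet] | None = None) -> DistanceMatrix:
    """All-pairs D2S distances.

    Backgrounds may be supplied directly or estimated from ``region_sets``.
    """
    labels = sorted(profiles)
    if len(labels) < 3:
        raise ValidationError("need at least 3 genomes for a distance matrix")
    ks = {profiles[g].k for g in labels}
    if len(ks) != 1:
        raise ValidationError(f"inconsistent k across profiles: {sorted(ks)}")
    if backgrounds is None:
        if region_sets is None:
            raise ValidationError("provide backgrounds or region_sets")
        backgrounds = {g: letter_frequencies(region_sets[g]) for g in labels}

    cache: dict = {}
    self_sim = {}
    for g in labels:
        try:
            self_sim[g] = d2s(profiles[g], profiles[g], backgrounds[g],
                              backgrounds[g], _comp_cache=cache)
        except ValidationError as exc:
            raise ValidationError(f"self-similarity failed for {g}: {exc}") from exc

    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i], labels[j]
            try:
                ab = d2s(profiles[a], profiles[b], backgrounds[a], backgrounds[b],
                         _comp_cache=cache)
                d = transform_to_distance(ab, self_sim[a], self_sim[b])
            except ValidationError as exc:
                raise ValidationError(f"pair ({a}, {b}) failed: {exc}") from exc
            values[i, j] = values[j, i] = d
    region_kind = profiles[labels[0]].region_kind
    k = profiles[labels[0]].k
    return DistanceMatrix(labels, values, region_kind, k)
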