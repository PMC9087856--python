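# Methods

This note documents the models and procedures implemented in `kmerphylo`, the
parameter choices that matter, and what the synthetic data does and does not
emulate.

## Region curation

Each genome contributes six sequence sets. WGS is the assembly as given.
rmWGS deletes annotated repeats by *splitting* scaffolds at merged repeat
spans — flanks are never concatenated, so no chimeric junction k-mers are
created — and then discards fragments shorter than `min_len` (default
1,000 bp, the conventional short-scaffold cutoff). Before that length filter,
retained bases plus merged repeat bases equal the assembly exactly; this
conservation is asserted in tests. CDS and introns are strand-specific: CDS
segments of a transcript are concatenated in genomic order and
reverse-complemented as a unit on the − strand; each intron is emitted
individually on its gene's sense strand. Where a gene carries several
transcripts the longest CDS is used, to avoid double-counting words.
Overlapping repeat annotations are merged before any arithmetic, as repeat
annotators routinely emit overlapping hits. Ambiguous nucleotides are kept in
the sequences; k-mer windows containing them are skipped during counting.
Proteins are translated with the standard code, dropping a trailing partial
codon (with a warning), removing the terminal stop and flagging internal
stops.

## k-mer profiles and the choice of k

A profile records T (counted windows), D (distinct words) and U (words seen
once). The two optimisation statistics are defined as `prop_distinct = D/T`
and `prop_unique = U/D`: the first measures how far the word spectrum is from
saturating the sequence, the second how dominated it is by single-copy words.
These denominators are a documented choice — the distinct/unique distinction
admits several conventions, and D/T with U/D makes the two proportions
orthogonal (repetitiveness vs. copy-number skew). The selection rule takes,
among grid values whose mean `prop_distinct` across genomes reaches a floor
(default 0.5), the k maximising the mean of the two proportions, breaking
ties toward smaller k; when no k passes the floor the largest grid value is
used with a warning — the escalation path that applies to repeat sequences,
whose short words are insufficiently distinct. Grids: nucleotide 11–25 step
2, repeats 11–51 step 2, protein {3, 5, 7, 9} with k = 9 the default protein
choice, and k = 23 the default for nucleotide core-k-mer work.

Counting is strand-as-given by default because CDS and intron sets are
explicitly strand-specific; canonical (lexicographic min of word and reverse
complement) counting is available for whole-genome work. Words never span
sequence boundaries.

## D2S and the distance transform

For genomes A and B, with word counts X_w, Y_w over the union W of observed
words, expected counts are E[X_w] = T_A·p_w^A where p_w is the product of the
genome's own letter frequencies (a zero-order background model, estimated per
genome per region; the model interface is pluggable but higher-order Markov
backgrounds are out of scope). With centred counts X̃ = X − E[X]:

    D2S(A,B) = Σ_{w∈W} X̃_w Ỹ_w / sqrt(X̃_w² + Ỹ_w²),

skipping terms with both centred counts exactly zero. Restricting the sum to
observed words (rather than the full 4^k lattice) is required for
tractability at k = 23; the deviation this introduces is characterised by an
exhaustive small-k oracle in the test suite (agreement to 1e-9 at k ≤ 3,
where the unobserved-word terms are exactly zero under the restriction).

The statistic is transformed to a dissimilarity by

    d = min(10, max(0, −ln[D2S_AB / sqrt(D2S_AA · D2S_BB)])),

with any non-positive normalised similarity mapped to the maximum d = 10.
The geometric self-normalisation makes identical genomes exactly d = 0; the
clamp makes the similarity S = 10 − d span exactly the [0, 10] threshold
range the network layer exposes. The transform is a documented design choice:
the −ln of a self-normalised similarity is the natural logarithmic distance,
and at moderate divergence it grows approximately linearly with substitution
distance (shared-word mass decays like e^(−k·d_subst)), which is what
neighbour joining needs.

## Trees

Neighbour joining is the standard Saitou–Nei agglomeration, exact on additive
matrices (verified against path-length matrices to 1e-9 and cross-checked
against an independent implementation). Ties in the Q-criterion are broken by
joining the lexicographically smallest label pair, making output
platform-independent. Negative branch lengths are retained — downstream use
is topology-only.

Robinson–Foulds distances are normalised by 2(N−3), the maximum between two
unrooted N-leaf trees; multifurcating inputs are accepted with the same
normalisation. Before comparison, each species whose isolates are
monophyletic in *both* trees is collapsed to a single species leaf, so the
branching order of same-species isolates never contributes; species
non-monophyletic in either tree keep their isolate leaves in both (keeping
the leaf sets comparable). Collapsing is applied before bipartition
extraction, and N is the post-collapse leaf count.

Outgroup rooting requires the outgroup to form a clade of the unrooted
topology and splits the root edge length evenly.

## Networks

S = 10 − d for every pair; a view at threshold t keeps edges with S ≥ t
(closed comparison). Views are nested in t, so component counts are
monotone. Because the analysis is scripted rather than interactive, the
`component_breakpoints` sweep reports every threshold at which the component
partition changes. Exported JSON carries all edges with their S values so a
rendering layer can re-threshold dynamically.

## Core k-mers and feature mapping

Core k-mers of a group are the words present (count ≥ 1 — presence, not
multiplicity) in every member. The pairwise-overlap construction and the
direct n-way intersection are provably identical; both are implemented and
compared in tests. Per-node tree annotation intersects word sets postorder,
so counts are anti-monotone toward the root.

Core k-mers are located on a reference genome by exact two-strand substring
search — k-mers are exact words, so alignment with mismatches would change
the semantics (an intentional strengthening over seed-based search tools). A
− strand hit means the window's reverse complement equals the word. Overlap
with features requires at least one shared base and, in strand-specific mode,
matching strands (bedtools `-s` semantics). Gene regions use the full gene
span (exons and introns), split into known vs. dark by the gene's annotation
status; a word's flags are the union over all its hits; words with no hit on
the reference are tallied separately from unclassified words. The Venn cells
partition the classified words and are recounted in tests.

## Repeat enrichment

Per repeat type, two per-genome metrics are compared between groups:
proportional length (repeat bases / assembly bases) and mean Kimura
divergence (stored in percent, as repeat annotators print it). The decision
tree per type: Shapiro–Wilk on pooled within-group residuals at α = 0.05;
on violation, a log transform (zeros replaced by half the smallest positive
value of the metric); Levene's test (median-centred) chooses Student's vs.
Welch's two-sided t-test; Benjamini–Hochberg adjustment runs across all
tested types, separately per metric, with adjusted p ≤ 0.05 called
significant (Bonferroni is available as an option). Groups as small as n = 2
are allowed — Shapiro runs on the pooled residuals, so the small group never
gates normality alone. Types with zero within-group variance in both groups
are skipped with a reason (or reported p = 1 when all values are identical).

## Synthetic data

The generator emulates the data regime of a multi-genus dinoflagellate
panel: 18 genomes — a nine-genome genus-like clade containing free-living and
symbiotic species and two multi-isolate species, three smaller clades, a
single-taxon clade, and a two-isolate outgroup — with genic fraction under
10%, repeat content ~35% in the ingroup and ~70% in the outgroup, repeat
families with per-family Kimura divergence targets (10–35%), enriched
families at 2-fold abundance in symbiotic genomes, and planted conserved
elements (one universal, one clade-specific) copied verbatim into their
carriers.

Evolution is Jukes–Cantor substitution only (no indels), so annotation
coordinates lift unchanged from the root to every leaf; an indel-free design
was chosen because the D2S statistic is indel-tolerant while indels would
complicate coordinate lifting and truth bookkeeping. Repeat copies are
diverged from their family consensus by a Kimura two-parameter process
(transitions at twice the transversion rate), with the (P, Q) pair solved
numerically from the target divergence; per-copy divergence attributes are
recomputed at each leaf against the consensus. Per-genome repeat "extras"
(the outgroup's higher repeat load; the symbiotic enrichment) are seeded per
*species*, because repeat expansions are heritable: isolates of one species
share them. All randomness flows from one seed through named substreams.

Branch-length defaults (isolate 0.001, terminal 0.008, within-clade 0.006,
between-clade 0.015, outgroup stem 0.035 expected substitutions/site,
jittered ±20%) follow an explicit desk-scale design rule: the homologous
shared-k-mer signal of the deepest genome pair, ≈ L·e^(−k·path), must exceed
the floor of k-mers shared by *all* pairs through the planted universal core
element by several-fold, otherwise distances saturate at the floor and the
outgroup suffers long-branch attraction. At the default L = 30 kb and k = 23
this bounds the deepest path near 0.1 substitutions/site. Real genomes are
four orders of magnitude longer, so the same method tolerates far deeper
divergence there; the shallow desk-scale branches are a property of the test
bed, not of the method.

The table-level repeat simulator (used for enrichment calibration) draws
per-type proportions lognormally with a per-genome log-sd of 0.1 and Kimura
values normally with sd 1.5. These noise defaults come from a power
requirement: with the 7-vs-2 group design, detecting a 2-fold effect after
Benjamini–Hochberg adjustment (≈20% of types planted) needs a per-type
t-statistic near 6, i.e. log-scale noise σ ≲ ln2 / (6·√(1/7+1/2)) ≈ 0.14.

### What the synthetic data does not emulate

No indels, rearrangements or assembly artefacts; uniform base composition
(no GC skew or codon usage structure); genes never overlap repeats by default
(an overlap mode exists for edge-case tests); single-scaffold assemblies;
isolate pairs share their repeat extras exactly (no post-split expansion).
Passing tests therefore demonstrate the correctness and internal consistency
of the pipeline and its statistics under a clean substitution model — not
robustness to assembly noise, rearrangement or composition bias in real
genomes.

## Numerical and degenerate-input choices

Identical genomes give d = 0 exactly; all-zero distance matrices are valid
NJ input (downstream tolerates the degenerate star). D2S terms with both
centred counts zero are skipped (0/0 guard). Empty profiles raise rather
than return NaN. Distance matrices serialise in square PHYLIP format at full
precision (the square dialect avoids triangular ambiguity). GFF3 coordinates
convert to 0-based half-open at the I/O boundary and back on write. Problem
sizes in the test and acceptance workloads (30 kb genomes, 18 taxa, k = 23;
1,000 repeat types for calibration) were chosen as the smallest scales at
which every pipeline property is exercised meaningfully.
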