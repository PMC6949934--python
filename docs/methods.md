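# Methods

`baconscope` re-implements, as a tested library, the computational pipeline
used to discover and characterise ~45-residue BACON-domain tandem repeats in
crAss-like and related gut phage genomes: iterative profile-HMM domain
discovery, gene-sharing contig classification, tandem-array architecture and
neighbourhood analysis, domain phylogeny with duplication-mode inference,
and k-mer Markov host prediction. This note records the models, the
parameters that matter, and the choices made where the design was open.

## ORF calling and translation (`seqio`)

ORFs are called with a simple maximal-ORF scanner on both strands under the
bacterial/archaeal genetic code (table 11; starts ATG/GTG/TTG, stops
TAA/TAG/TGA). An ORF runs from the first start codon after the preceding
in-frame stop to the next in-frame stop, and must encode at least
`min_aa_length` residues (default 30). No coding statistics (GC frame bias,
ribosome-binding models) are used: downstream analyses consume ORF *counts*
only coarsely (the >10-ORF contig filter), and the synthetic generator
plants genes this caller provably finds (see below). Codons containing `N`
are skipped rather than translated to `X`, keeping proteins clean for
profile scoring. Coordinates are 0-based half-open internally; GFF3 export
is 1-based inclusive.

## Profile HMMs (`phmm`)

A profile is the standard match/insert/delete architecture. Construction
from an alignment classifies a column as a match state when its non-gap
fraction is ≥ `match_column_threshold` (default 0.5, unweighted — no
sequence weighting, which is a documented deviation from common
profile-builder defaults). Match emissions are Dirichlet-smoothed counts,
`(counts + α·background)/(n + α)` with α = 1 on a uniform background;
transition probabilities are counted from the rows' implied state paths
with the same pseudocount. Occupancy of column k is the fraction of rows
with a residue there (the quantity shown in sequence-logo renderings of
such profiles).

Search is a Plan7-style *local* Viterbi scan: uniform entry into any match
state (probability 1/L), free exit after any match state, insert emissions
scored as background (zero log-odds — the convention used by the reference
HMMER implementation). The reported score is the log2-odds of the best path
against an i.i.d. background; there is deliberately no forward/E-value
stage, so every reported hit is exactly verifiable against brute-force path
enumeration (the test suite does this exhaustively for small profiles).
Multiple domains per protein are found by mask-and-rescan: the best hit's
envelope is masked (its residues become unalignable, so no later path can
claim or bridge them) and the scan repeats until the best remaining score
drops below `score_threshold_bits` (default 15 bits; the reporting
threshold of the original search tooling is not recoverable, so this is an
explicit free parameter).

Iterative refinement searches all proteins, realigns the hit envelopes on
the profile's match columns (the Viterbi-implied columns; inserted residues
are dropped, so L is stable across rounds), rebuilds the profile from that
alignment, and repeats until the (orf_id, envelope) hit set is identical
between successive rounds — a stricter criterion than hit-count
convergence, and a stable one. HMMER3-ASCII seed profiles (e.g. Pfam
domain models) are read through pyhmmer; only the file parsing is
delegated, never the search.

## Gene-sharing classification (`genenet`)

Contigs with more than 10 ORFs are retained. All-vs-all protein similarity
uses Smith–Waterman with BLOSUM62 and affine gaps (open 11, extend 1)
through Biopython's PairwiseAligner; raw scores are converted to bits with
the Karlin–Altschul formula, `S_bits = (λ·S_raw − ln K)/ln 2`, at the
standard gapped BLOSUM62 constants λ = 0.267, K = 0.041, so the >50-bit
edge threshold lives on the familiar BLAST scale. Because the exact
all-pairs step is quadratic, pairs sharing fewer than two 4-mers are
skipped by default — a seeding heuristic in the same spirit as word-based
search tools; `prefilter=None` restores the exact computation (the test
suite verifies the heuristic drops no family edges on clustered data).

Gene families come from an in-package Markov clustering (MCL)
implementation: self-loops at each node's maximum edge weight,
column-stochastic normalisation, then alternating expansion (matrix
squaring) and inflation (entrywise power 2, renormalise), pruning entries
below 1e−6, to a 1e−9 fixed point; clusters are read from attractor rows.
Node-order invariance is tested.

For every contig pair the number of shared (deduplicated) families k is
scored with the upper-tail hypergeometric probability P(X ≥ k) given the
contigs' family counts and the N families in the dataset. Contigs are then
clustered with Ward.D2 on the Euclidean distances between rows of the raw
p-value matrix (raw p, not −log p, mirroring the procedure this package
re-implements; a −log10 option exists but is off by default). scipy's
`linkage(method="ward")` on a condensed Euclidean distance matrix *is* the
Ward.D2 Lance–Williams recurrence — the tests confirm equality against a
hand-rolled recurrence. The number of clusters is chosen by maximising the
mean silhouette over k = 2..15 (silhouette is used instead of a
multi-index vote because it is the single index the analysis itself
inspects).

## Architecture and neighbourhoods (`arch`)

A tandem array is ≥ 2 hits in one ORF whose inter-envelope gaps never
exceed `max_inter_domain_gap` (default 30 residues ≈ 2/3 of a domain; the
notion of "tandem" is not defined quantitatively anywhere authoritative,
so the bound is surfaced in config). Array positions are numbered 1..m
from the N-terminus. Neighbourhoods collect ±5 ORFs around each
domain-bearing ORF, truncated at contig ends; a neighbourhood whose labels
are all "hypothetical protein" carries no information and is excluded from
association statistics. Tail annotation is keyword-based
({tail, tail fibre/fiber, tail spike, baseplate}, case-insensitive).

Tail association — argued only qualitatively in the analysis this package
re-implements — is formalised here as a permutation test: the statistic is
the difference between the fraction of tandem-array ORFs and the fraction
of single-domain ORFs with ≥ 1 tail neighbour; the null permutes the
tandem/single labels (999 permutations, one-sided, add-one corrected, so
p ∈ [1/(B+1), 1]). Because the statistic is discrete, the add-one p-value
is conservative (sub-uniform) under the null; calibration checks therefore
use standard randomized tie-breaking p-values, which are exactly uniform,
while the reported p stays the conservative one.

## Phylogenetics (`phylo`)

Alignment is progressive: UPGMA guide tree on pairwise 3-mer distances,
then profile–profile Needleman–Wunsch with BLOSUM62 and affine gaps
(column score = count-weighted mean substitution score; deterministic
tie-breaking, input-order independent). Gappy columns are trimmed with the
`gt` convention (retain a column iff non-gap fraction ≥ gt; 0.05 for
concatenated marker-protein alignments, 0.4 for short domain alignments —
the latter provably preserves the four invariant domain residues on
synthetic alignments). Alignments over partially overlapping taxon sets
can be concatenated with gap padding.

Trees are neighbor-joining on Kimura-corrected protein distances,
d = −ln(1 − p − 0.2p²), with pairwise gap deletion (complete deletion
would discard most columns of short trimmed domains) and saturation capped
at d = 10; NJ itself is scikit-bio's implementation, exact on additive
matrices. This distance approach replaces maximum-likelihood tree search
deliberately: ML search is neither desk-verifiable nor reproducible
without its exact tooling, and every conclusion exercised here (clade
purity, ancestral-domain proximity, duplication mode) is topology-level
and recoverable on synthetic data with NJ. Support values come from
ordinary column-resampling bootstrap (percent of replicates containing
each split), written into internal node labels.

Position-in-array clade analysis asks, for each array position class,
whether some edge of the *unrooted* tree separates exactly that class from
all other labelled leaves (rooted-monophyly would structurally fail for
the class spanning the root). Unlabelled leaves (bacterial domains) are
bystanders; the class whose tightest containing clade holds the most
unlabelled leaves is reported as the candidate ancestral position.

Duplication mode is diagnosed from the m×m within-array bit-score matrix
and its offset profile s(d) (mean score of domain pairs d apart). Block
duplication of size b produces elevated similarity at offset b *and its
harmonics* 2b, 3b, …; a candidate b ≥ 2 is accepted when s(b) exceeds the
median of the off-harmonic offsets by more than 2 MADs and exceeds s(1).
Harmonics are excluded from the background because they carry the same
periodic signal: with them included the median itself rises and masks
genuine block signatures (measured on simulated histories, detection fell
to ~50–70% with the naive background versus ≥ 97% with exclusion, at
unchanged specificity on single-duplication histories). Without a
qualifying b, the array is classified as grown by single-domain
duplications; the nearest-neighbour contrast s(1) − mean s(d>1) is also
reported.

## Host prediction (`hostpred`)

One genome per genus is selected by CheckM-style quality, argmax of
C − 5·M (completeness minus five times contamination), ties broken by
coarse-consistency score then lexicographic id. Each representative trains
a fixed-order Markov model of nucleotide composition (both strands,
add-one smoothing); a contig is scored under each model by mean
log-likelihood per scored transition and hosts are ranked, top-1 being the
prediction, with the top-two margin reported. Default order is k = 3
rather than the k = 8 of large-scale host predictors: the scoring contract
is order-independent and k = 3 trains reliably on desk-scale synthetic
genomes. No null model or p-value machinery is included — only the
ranking is used.

## Synthetic data (`synth`)

The generator emits datasets with complete ground truth, and its defaults
*are* the study conditions for the acceptance checks:

- **Lineage structure.** 7 lineages × 8 contigs, 15–30 genes per contig.
  Each gene draws its family from a lineage-private pool (25 families)
  with probability 0.9, otherwise from a 30-family shared pool. This
  mirrors the near-disjoint gene content of real phage lineages (the data
  this emulates spans 13–113 contigs per cluster and 10–200 genes per
  contig); family members are BLOSUM62-conditionally mutated copies
  (rate 0.05) of a family ancestor, comfortably above the 50-bit edge
  threshold.
- **Domains.** A 45-residue ancestral domain with four invariant residues,
  W/N/R/Q at positions 11, 27, 33, 45 (1-based) — an N-terminal
  tryptophan, central asparagine and arginine, and C-terminal glutamine.
  Mutations never touch these positions, in any generated sequence.
- **Arrays.** One domain-bearing ORF per contig; array size 1 or 8
  (p = 0.5 each) by default. Arrays are built by replaying an explicit
  duplication-event history from the lineage's domain: each event copies a
  contiguous block (size 1 for single-domain mode, size b for block mode)
  and inserts it adjacently; after every event all domains accumulate
  substitutions at the divergence rate (default 0.05/site/event), drawn
  from BLOSUM62-conditional exchange probabilities so diverged copies stay
  alignable, as real tandem-repeat domains do. Linkers between planted
  domains are 3–10 residues.
- **Transfers.** With probability 0.1 per contig, a domain-bearing ORF is
  copied in from a different lineage, recorded as a transfer event.
- **Labels.** Informative (non-"hypothetical") labels are sprinkled on 30%
  of ORFs; under the default `tandem_only` policy, tail labels are placed
  only on the ORFs flanking tandem arrays (the planted association), with
  `uniform` and `none` policies for null studies.
- **Nucleotide layer.** Proteins are reverse-translated (fixed codon per
  residue, leading methionine) and laid head-to-tail with C/T-only
  spacers ending in a stop-in-all-frames cassette, which guarantees the
  maximal-ORF caller recovers every planted gene at its exact
  coordinates.
- **Host genomes.** Per-genus dinucleotide transition biases (Dirichlet
  draws) give genomes distinguishable k-mer signatures; phage contigs are
  mutated slices of their host.

What the generator does **not** emulate: codon-level nucleotide evolution,
sequencing error, genome rearrangement, gene loss, real intergenic signal,
and compositional heterogeneity along genomes. Passing tests therefore
demonstrate correctness of the algorithms and recoverability of planted
structure under controlled conditions — not expected performance on real
metaviromes, where divergence, fragmentation and annotation noise are
harsher.

## Problem sizes and determinism

Every stochastic step is seeded; a dataset is byte-identical across runs of
the same configuration. The acceptance script runs, per seed: one full
7×8-contig clustering study (~1.3k ORFs), 200 positive + 200 shuffled
proteins for detection, 100 + 100 replayed histories for duplication-mode
accuracy (single mode at m = 8, the canonical array size; block mode at
m = 6, matching the 5–6-domain arrays where block growth is a live
hypothesis), one 48-leaf position-clade study, the planted tail
association with 999 permutations, 200 null replicates for calibration,
and 24 host-prediction queries over 6 genera — all within a few minutes on
one CPU. The clade study models an ancient, stable array: positions keep
diverging (rate 0.1) after the duplication history ends, while each
position stays nearly fixed (0.015) across a lineage's genomes — the
regime in which array order is conserved and position clades are the
expected outcome.

## Known limitations

- The Viterbi scan has no E-value calibration; the bit threshold trades
  sensitivity against false positives explicitly.
- Profile rebuilding drops insertions relative to the current profile, so
  match length L cannot grow during iterative refinement.
- The progressive aligner is a didactic-grade implementation: adequate for
  45-residue domains and synthetic marker proteins, not a general-purpose
  MSA engine.
- NJ + bootstrap is a distance-based stand-in; statements about real
  ML-tree topologies are outside what this package can check.
- Host prediction reports rankings only; conflicting evidence between
  homology and composition (as occurs in real data) is not adjudicated.
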