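# Methods

`famchar` re-implements, as a single tested library, the analysis pipeline
used in genome-wide gene-family surveys of the ubiquitin-conjugating enzyme
(UBC / E2) family: domain-based member identification, physicochemical and
architectural characterization, distance-based phylogeny with bootstrap
grouping, motif elicitation, promoter cis-element scanning, and expression
quantitation. This note records the models, the parameters that matter, and
the design choices made where the procedure was genuinely open.

## Domain-profile mining

Member identification replaces a profile-HMM search with a
position-specific log-odds profile plus affine-gap Smith–Waterman local
alignment. The profile is built from a seed alignment of the domain: match
columns are those with gap fraction below 50%; the column score for residue
*a* is `log2(((f_a + c·bg_a)/(1 + c)) / bg_a)` with `f_a` the observed
column fraction, `bg` the seed's overall residue frequencies, and
pseudocount weight `c = 1` by default. The smoothing is frequency-based, so
duplicating a sequence in the seed does not change the profile. The
catalytic-cysteine column is read from an annotation row in the seed
alignment and carried on the profile; a member whose aligned residue at
that column is not cysteine is flagged as an E2 enzyme variant (UEV).

Scores are turned into e-values empirically rather than analytically:
local-alignment scores of shuffled sequences follow an extreme-value
(Gumbel) distribution, so the null is fitted (scipy `gumbel_r`) to the
scores of 1000 shuffles that cycle over the actual input sequences,
preserving each one's length and composition; the e-value of a hit is the
fitted tail probability times the number of scanned sequences. The default
cutoff is e ≤ 0.01. Gap penalties are 11 to open and 1 to extend, the
BLOSUM-range convention, since profile scores are on a log2-odds scale of
comparable magnitude. Similarity confirmation against reference family
proteins reuses the same DP core with the reference recast as BLOSUM62
score columns (half-bit units; the bit score is half the raw score).

Filtering: a candidate is *incomplete* when its hit covers less than 60% of
the profile (the completeness notion is a coverage threshold because no
numeric criterion is standard); candidates are *redundant* when pairwise
identity is ≥ 98% over ≥ 95% mutual length coverage (identity from an
edlib global alignment), keeping the longer protein, ties broken by the
lexicographically smaller locus id. Accepted members are named
`<prefix>1..N` ordered by scaffold id under natural numeric ordering, then
start coordinate.

## Physicochemical properties and architecture

Molecular weight is the sum of average residue masses plus one water
(18.0153 Da), reported in kDa. The isoelectric point solves
Henderson–Hasselbalch net charge = 0 by bisection on pH ∈ [0, 14]
(|Q| < 1e-4, ≤ 200 iterations) with the Bjellqvist pKa set (N-term 7.5,
C-term 3.55, D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0) —
the set behind the common web calculators; alternate sets can be passed.

E2 architecture classes follow the standard convention: class I is the bare
catalytic domain, II adds an N-terminal extension, III a C-terminal
extension, IV both. An extension counts when it is at least `extension_min`
residues (default 25 aa; the literature states no number, and published
class splits appear to use motif-level evidence beyond domain spans, so the
threshold is explicit and configurable rather than tuned to reproduce any
particular figure).

Family summaries report means at the precision the published family table
prints: bp/aa means rounded to integers, kDa and pI means truncated (not
rounded) to two decimals — the published aggregates are reproducible from
the printed per-gene values only under truncation, so that convention is
adopted.

## Phylogeny

Distances are p-distances (mismatch fraction) with pairwise deletion of
gapped positions; a pair with no comparable positions is an error. Tree
construction is classic Saitou–Nei neighbor joining: join the pair
minimizing `Q(i,j) = (n-2)·d(i,j) - r_i - r_j`, branch lengths by the
standard formulas, ties broken by the smallest index pair for determinism,
negative length estimates clamped to zero and counted. NJ is exact on
additive matrices, which the tests and acceptance script verify against
independently constructed random additive trees and against scikit-bio's
implementation.

Bootstrap supports resample alignment columns with replacement (default
1000 replicates, seeded), rebuild the NJ tree per replicate, and report the
percentage of replicates containing each original internal bipartition.
Group assignment: a member joins reference group G when the smallest
bipartition side with support strictly greater than the threshold (default
46%) that contains the member and at least one labeled reference contains
references of G only; mixed references or no supported clade leave the
member "unplaced". Multiple-sequence alignment is deliberately outside the
core — the phylogeny operations consume alignments from any source; a
crude center-star aligner is provided for convenience only.

## Motif elicitation

Motifs are found greedily in the MEME tradition, with the occurrence model
selectable between ANR (any number of repetitions; every window is an
independent potential site) and ZOOPS (at most one site per sequence). For
each width in [6, 50], expectation-maximization fits a PWM and occurrence
prior. Starting points matter: up to 32 starts are screened with a
two-iteration EM — prioritizing windows whose exact subsequence recurs
across the input, which are ideal seeds for a shared motif — and the most
promising is refined to convergence (|Δ log-likelihood| < 1e-4, ≤ 100
iterations; the EM objective is non-decreasing and the tests assert it).

Width selection scores a fitted motif as
`sites × Σ_columns (adjRE_col − 0.75)` bits, where `adjRE` is the column's
relative entropy against the 0-order background minus the small-sample
bias `(19)/(2·N·ln2)`; the per-column margin makes uninformative flanking
columns count against a width, so a sharp w-residue signal is reported at
exactly width w. Edge columns under 0.5 adjusted bits are trimmed. Sites
are windows with posterior > 0.5; their positions are probabilistically
erased (weights scaled by 1 − posterior) before the next motif is sought,
so successive motifs describe disjoint signal. The exact-recurrence start
heuristic is tuned to implant-sharp signals; heavily diverged occurrences
rely on the random starts and may need more of them.

## Promoters and cis-elements

The promoter is the 1.5-kb region upstream of the annotated gene start
(used as the transcription-start proxy; no 5'UTR-aware TSS is inferred):
plus strand `[start-1500, start-1]`, minus strand the reverse complement of
`[end+1, end+1500]`, clipped at scaffold bounds with a truncation flag.
Scanning matches IUPAC consensi on both strands via overlapping regex
lookahead; `N` in the promoter matches nothing; minus-strand hits are
reported at the + strand offset of their leftmost base. The bundled element
table carries the commonly named elements (TCA-element, CGTCA/TGACG MeJA
motifs, HSE, LTR, light boxes, circadian `CAANNNNATC`, CAT-box, ABRE, MBS,
GARE/P-box, TGA-element, ERE) grouped into response categories; it is a
plain TSV and fully user-replaceable — the scanning behaviour, not the
table content, is the contract. A category is present in a promoter when
at least one of its elements matches.

## Expression

FPKM is `counts × 10^9 / (length_bp × library_size)`; for bare count
matrices the library size defaults to column sums, which is not identical
to mapped-read totals — flagged, not assumed equivalent. The heat-map
transform is `log10(FPKM + 0.01)` (so FPKM 0 maps to −2), applied once;
the matrix carries a transform-state flag. Row ordering for heat maps uses
average-linkage agglomerative clustering on Euclidean distances (scipy).

Differential expression keeps the published decision rule — fold change at
least 2 AND significance below 0.05 — while replacing the negative-binomial
Wald test with a stated permutation test: counts are CPM-normalized, the
statistic is the difference of condition means on the log2(CPM + 0.5)
scale, labels are permuted exhaustively when at most 1000 reassignments
exist (e.g. C(8,4) = 70 at n = 4 + 4) and 10,000 sampled otherwise, and
p-values are Benjamini–Hochberg adjusted. The adjusted p gates calls by
default; `use_adjusted=False` gates on the raw p instead (both readings
appear in the literature this models; the methods-style adjusted criterion
is the default). Note the exhaustive floor: at n = 4 + 4 the smallest
achievable two-sided p is 2/70 ≈ 0.0286, so adjusted-mode detection across
many genes requires deeper replication.

qPCR relative expression is `2^(−ΔCt)` with ΔCt = Ct(target) −
Ct(reference gene); treated/control ratios are classified up/down by the
inclusive two-fold rule.

## Synthetic data

The generator produces the study conditions end to end, from one integer
seed, byte-identically. Genomes: each gene is designed as a protein
(random extensions around a domain implant where applicable),
reverse-translated with uniformly drawn codons plus a stop, split into
exons with random introns (60–400 bp), and laid out on scaffolds with
1.8–3 kb intergenic gaps (so promoters are full length except where
designed otherwise). Candidate categories mirror the family-mining
bookkeeping of the study this models — defaults of 40 true members, 24
incomplete-domain candidates (25–55% of the consensus retained), 8
redundant duplicates (an exact mutation count keeps identity unambiguously
≥ 99%), 3 UEV members (active-site Cys→Ser), 60 decoys — plus one
designated gene with 6 bp of upstream scaffold. The 150-aa domain
consensus is synthetic (not a natural sequence) but embeds the published
core 15-mer HPNIYSNGSICLDIL and a catalytic Cys at column 86. Cis-elements
are implanted at stated promoter offsets/strands, with degenerate IUPAC
positions made concrete by the seeded RNG. Ground truth for every candidate
and implant is recorded in manifests.

Counts are negative-binomial with variance `μ + α·μ²` (default dispersion
α = 0.05, three replicates, specified log2 fold changes); Ct tables place
the reference gene near Ct 20 with 0.15-cycle noise. What the generator
does **not** emulate: sequencing error, mapping ambiguity, splice isoforms,
GC/length biases, real codon usage, indel divergence between family
members, or promoter background that mimics real nucleotide composition.
Passing tests therefore demonstrate that the algorithms implement their
stated contracts and recover planted truth under realistic noise models —
not that they would reproduce any particular real-genome result.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeds; identical
seeds give identical outputs, including across the alignment (numba-
compiled), EM, bootstrap, and permutation code paths. Negative NJ branches
clamp to zero; EM convergence is |Δll| < 1e-4; bisection tolerance is
|Q| < 1e-4; e-value calibration uses 1000 shuffles.

The test suite and the acceptance script run at desk scale by design:
implant-recovery sweeps use 10 seeds of 35-gene genomes, phylogeny checks
use 4–8-taxon additive matrices and ≤ 200 bootstrap replicates on ≤ 45
taxa, motif recovery uses 20 sequences of 120–200 aa, and the DE operating
characteristics use 2000-gene matrices at n = 4. These sizes were chosen as
the smallest at which the checked properties are statistically unambiguous.

## Known limitations

* The profile scan is a PSSM approximation of a profile HMM: no
  position-specific gap penalties and no forward-algorithm scoring.
* E-value calibration is a single Gumbel fit across the target length mix,
  not length-conditioned Karlin–Altschul statistics.
* The redundancy criterion (98%/95%) is a stand-in definition; published
  family curations rarely state one.
* Group assignment depends on reference coverage: a member whose clade
  contains no reference is "unplaced" rather than assigned by distance.
* The DE permutation test is underpowered below ~4 replicates per
  condition by construction (the p-value floor), unlike parametric NB
  tests; this is the price of making no distributional assumption.
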