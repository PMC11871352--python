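# Methods

This note records the models, conventions and numerical choices behind
each module, what the synthetic data do and do not emulate, and the
known limitations.

## Coordinates and the feature table

All coordinates are 1-based inclusive on the deposited reference strand
(GenBank convention); conversions (Biopython's 0-based half-open
internals, BED export) happen at the boundaries. Strand labels are the
annotation's own L/H names and are never reinterpreted: the deposited
reference strand is taken as L because that is how the source records
label the majority strand, even though the common vertebrate convention
annotates most genes on H. Nothing downstream depends on which physical
strand is "light".

The intergenic column of row *i* is `start(i) − end(i−1) − 1` in table
order, negative for overlaps; the first row is defined as 0 and the
control-region→first-tRNA junction across the circular origin is not
counted. (Published feature tables sometimes print the same junction
values one row earlier, i.e. as the gap *after* each element; the
junction values are identical either way, only the row attribution
differs.)

Incomplete stop codons follow length arithmetic: a protein-coding gene
whose length is ≡1 (mod 3) ends in `T--`, ≡2 (mod 3) in `TA-`, both
completed to TAA by polyadenylation. One shipped table row (nad3,
350 bp) is annotated `T--` in its source despite a 2-residue remainder;
the toolkit reports annotation codons verbatim for coordinate-only
tables, and the amino-acid bookkeeping (⌊size/3⌋ − 1 per complete stop)
is unaffected by the label.

Per-element A+T% uses each element's coding strand and includes
incomplete stop nucleotides, since annotated sizes include them.

## Composition and skew

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C), on the strand as given; a
zero denominator yields a missing value rather than 0. Ambiguity codes
are excluded from numerators and denominators (not fractionally
allocated) — inert for the genomes at hand, which contain none, but
explicit. Full precision is kept internally; rounding to table
precision (1 decimal for percentages) is presentation-only and uses
half-away-from-zero to match how printed tables round.

## Codon usage

The vertebrate mitochondrial code (NCBI table 2) is the default: 60
sense codons, stops {TAA, TAG, AGA, AGG}. Stops — complete or
incomplete — are excluded from all usage counts, so the pooled total
equals the number of encoded amino acids. Non-ATG starts (GTG in cox1)
are counted as their table-2 amino acid, not force-translated to Met:
usage statistics describe the sequence, not the mature protein. RSCU is
count/(family total/family size); a family with zero total reports
missing rather than 0. Both the within-family top codon and the overall
top codon are available (`top_codons`), since "most frequent codon" is
ambiguous between the two readings.

## Control-region structure

The tandem-repeat detector is a transparent lag-correlation method, not
a reimplementation of any published scorer:

1. for each candidate period p, maximal runs of `seq[i] == seq[i+p]`
   seed candidate arrays;
2. nearby seeds of the same period are bridged (gap ≤ p+1) when the
   merged array still clears the identity floor *and* beats the better
   of its parts on an alignment-style score (+2 per matched base, −7
   per edit against the tiled phase-majority consensus) — the score
   test keeps boundary noise from riding along on a long array's high
   global identity;
3. array boundaries then grow by whole (or ±1, i.e. indel-shortened)
   copies and residual partial matches under the same score/identity
   rule, which is what recovers arrays whose terminal copy carries a
   single-base indel;
4. arrays nested inside a longer kept array are suppressed; genuinely
   overlapping arrays of different periods are both reported, longest
   first.

Identity is edit-distance-based (edlib, global mode) against the
consensus tiled to the array length, so one indel costs one position
rather than a frameshift. Copy number is span/period to 1 decimal.
Defaults (periods 2–60, ≥2 copies, ≥80% identity) are deliberately
permissive; at these settings short chance arrays in random sequence
are reported — callers wanting TRF-like selectivity should raise
`min_copies`/`min_identity`.

The conserved-block scanner does IUPAC consensus matching with a
per-block mismatch allowance, reporting the best (fewest-mismatch,
leftmost) window per block. The shipped library is an *approximate*
vertebrate consensus set: the ETAS1 core GYRCAT and the CSB-1 GGACATA
core are classical diagnostics; the CSB-F…B and CSB-2/3 entries are
loose mammalian-style consensuses intended to be edited per taxon
(`--library`), and hits from the shipped library on real genomes should
be treated as candidates, not calls.

## Pairwise Ka/Ks (NG86)

Nei–Gojobori (1986) counting: each codon position contributes one site
split by the fraction of its single-nucleotide changes that are
synonymous, excluding changes into stop codons from the denominators
(so S+N = 3 per codon); differences between codons differing at 2–3
positions are averaged over substitution orderings that avoid stops
(falling back to all orderings, stop steps counted nonsynonymous, in
the rare fully-blocked case). Jukes–Cantor correction
d = −¾ ln(1 − 4p/3) is applied to both proportions; saturation
(p ≥ ¾) and Ks = 0 yield missing values. Gapped or ambiguous codon
pairs are dropped pairwise.

NG86 assumes no transition/transversion bias and equal base
frequencies; under transition bias it is conservative for ω (more
synonymous change than its site counting expects). The neutrality
calibration in the tests therefore simulates inside the estimator's
model (κ = 1, uniform frequencies, ~0.4 substitutions/codon
divergence); which counting estimator a given published figure used is
often unstated, so the method name is carried in output metadata.

## Site models

The substitution process is GY94: rate κ^[transition]·ω^[nonsyn]·π_j
between sense codons one nucleotide apart, π from F3x4 (per-position
nucleotide frequencies of the alignment, pseudocount 0.5, renormalized
over sense codons). Site-class mixtures:

| model | classes | free ω-distribution parameters |
|---|---|---|
| M0 | one ω | ω |
| M1a | ω₀≤1, ω₁=1 | p₀, ω₀ |
| M2a | M1a + ω₂≥1 | p₀, p₁, ω₀, ω₂ |
| M7 | Beta(p,q), K=10 | p, q |
| M8 | p₀·Beta(p,q) + ω_s≥1 | p₀, p, q, ω_s |

The beta is discretized into K = 10 equal-probability categories at
quantile midpoints. Rate matrices are normalized by the
mixture-averaged rate, so branch lengths are expected substitutions per
codon under the fitted mixture. Likelihoods use Felsenstein pruning
over the unrooted tree with transition matrices from a symmetrized
eigendecomposition (the chain is reversible); site patterns are
deduplicated; codon columns containing any gap are removed (complete
deletion), recorded per column.

Optimization is L-BFGS-B over log/logit-transformed κ, branch lengths
and model parameters (ω ∈ [10⁻⁴, 999], proportions kept off exact 0/1,
beta shapes ∈ [0.005, 99]), best of ≥2 restarts with seeded jitter;
non-convergence and boundary hits are flagged on the returned fit, not
silenced. LRTs use 2Δℓ clipped at zero against χ² with df = 2 for
M1a–M2a and M7–M8; other nestings require an explicit df.

Per-site positive-selection evidence is **naive** empirical Bayes:
class posteriors p_k·L(site|ω_k) at the MLEs. The Bayes-empirical-Bayes
refinement (integrating parameter uncertainty) is deliberately out of
scope and all outputs label the method NEB; NEB posteriors near 0.95
should be read cautiously at small sample sizes.

## Supermatrices

Blocks arrive aligned; alignment itself is upstream. The trimmer is a
two-threshold column filter (drop when gap fraction > 0.5 or
majority-residue fraction < 0.5 among non-gap characters), idempotent,
with retained-column provenance — a transparent stand-in for heavier
ambiguity filters, not a reimplementation of them. Concatenation orders
PCG blocks (input order), then rRNAs, then tRNAs; PCGs enter as
nucleotides; a taxon missing from any selected block is a hard error
rather than silent gap padding. Partition maps must tile [1, L] exactly
and every export asserts it. Codon-position subpartitioning and
partition-scheme search are out of scope.

## Synthetic data

The genome generator emulates: the canonical vertebrate element order,
classes, strands and sizes (taken from the shipped soft-shelled-turtle
coordinate table, so fixtures are structurally realistic without
copying any real sequence); target A+T fraction and AT/GC skews on the
reference strand (P(A) = AT·(1+skew)/2 etc.; infeasible combinations
raise); open reading frames with template start/stop codons including
incomplete stops; H-strand elements drawn from the complementary base
distribution before reverse-complementation so reference-strand
composition stays on target; and a control region with planted repeat
arrays and block motifs whose coordinates are returned as ground truth.
Protein-coding genes draw sense codons from a distribution whose base
marginals are fixed-point-corrected for stop-codon exclusion, so coding
regions do not drag the realized skew off target. Defaults: A+T 0.615,
AT skew 0.145, GC skew −0.376 — the measured values of the genomes this
package was built around.

It does **not** emulate: within-genome compositional heterogeneity,
codon-position-specific composition, realistic tRNA/rRNA secondary
structure, overlap sharing between neighbouring genes (elements abut
with configurable spacers), or sequencing error. Tests passing on
synthetic genomes therefore validate the *bookkeeping and detection
machinery*, not biological realism of composition profiles.

The alignment simulator evolves codons under exactly the GY94 process
the inference uses (spectral transition probabilities, not Gillespie
stepping), with per-site ω from a constant, a mixture, or an explicit
list, and records true per-site classes. Both generators are pure
functions of (spec, seed); GenBank output pins the LOCUS date so
identical records are byte-identical.

## Problem sizes in the statistical tests

The suite calibrates the selection machinery at deliberately small
sizes chosen to exercise the asymptotics without excess runtime: the
M1a–M2a null-calibration uses 300 replicates of 3 taxa × 80 codons
(rejection rate compared against α + 3 binomial SE; the χ²(2) reference
is conservative for this boundary case, so the observed rate sits well
below nominal); M0 parameter recovery uses 50 replicates of 6 taxa ×
300 codons with a 3-Monte-Carlo-SE band; NEB false-positive control
uses 10 replicates of 4 taxa × 100 codons. The NG86/brute-force
equivalence check enumerates 1,000 random codon pairs against a
literal, independent transcription of the counting recipe.

## Known limitations

* Site models support one ω distribution across the whole tree: no
  branch or branch-site models.
* NEB replaces BEB (above); the two can differ materially when
  parameter estimates are uncertain.
* The block library is approximate and editable; block calls on real
  control regions are candidates for manual review.
* The repeat detector reports maximal arrays under its own score; exact
  agreement with other tools' array boundaries or copy counts is not
  guaranteed for imperfect arrays.
* F3x4 is the only frequency model; κ is shared across site classes.
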