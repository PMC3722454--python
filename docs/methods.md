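# Methods

`ampliphy` models the computational core of a universal-primer
marker-gene survey: designing degenerate primers from conserved regions
of a multiple alignment, predicting PCR products on template genes,
quantifying pairwise similarity of the amplified fragments, and placing
them on a distance tree with bootstrap support. The worked example
throughout is a panel of six degenerate primers against bifidobacterial
bile salt hydrolase (*bsh*) genes, but every stage is generic.

## Degenerate primer model

A degenerate oligonucleotide is a string over the 15 IUPAC nucleotide
codes; its *degeneracy* is the number of concrete ACGT sequences it
encodes (the product of per-position code sizes — e.g.
`ATGTGCACWGSYGTYCGTTT` encodes 2·2·2·2 = 16 primers). Complementation
maps each code to the code of its complemented base set, so reverse
primers can be stored 5′→3′ on their strand of synthesis, as they are
ordered from a synthesizer. Two codes are *compatible* when their base
sets intersect; this is the annealing model used throughout (a `Y` in a
primer pairs with a `C`, `T`, or any code containing either).

Expansion of a degenerate string is capped (default 65,536 concrete
sequences) because the operation is exponential; all quantitative uses
(degeneracy, Tm bounds, matching) avoid enumeration.

## Conserved-block detection

Each alignment column is profiled: base counts among non-gap residues,
gap fraction, the minimal IUPAC code covering the observed bases, and a
flag for fully identical columns. Conserved blocks are maximal runs of
columns whose gap fraction stays below a threshold (default 0: primer
sites must be gap-free) and whose cumulative consensus degeneracy stays
below a cap (default 64 per block; a separate, looser cap of 256
applies when a block is turned into a primer). Windows are grown
greedily left to right and reported non-overlapping, ties leftmost —
conserved-region selection in practice is done by eye, so determinism
is worth more than optimality here. The default minimum block length is
17 nt, the shortest primer in the packaged panel.

Block coordinates are 1-based inclusive alignment columns; when a
reference row is named, the block start is projected onto ungapped
reference coordinates (a block starting in a reference-gap column
reports the next reference position, with a log entry). This is how
"the site starts at position 46 of the reference gene" is expressed.

Melting temperatures use the Wallace rule, 2(A+T) + 4(G+C) °C, bounded
below by the AT-richest and above by the GC-richest expansion
(equivalently, per-position minima and maxima). The rule is coarse —
for the packaged 17–23-mers it spans roughly 52–76 °C — and is meant as
a plausibility window, not a thermodynamic prediction; nearest-neighbor
models are out of scope.

## In-silico PCR

A primer footprint is accepted on a template when at most
`max_mismatch` positions (default 2) are incompatible, and at most
`three_prime_max_mismatch` (default 0) of the last `three_prime_window`
(default 3) primer bases — the polymerase extension end — are
incompatible. Both strands are scanned: the primer directly against
the plus strand, and its reverse complement against the plus strand
for minus-strand sites (where the primer's 3′ end sits at the
footprint's left edge). Template ambiguity codes participate through
base-set intersection, so sequencing ambiguities do not break matches.
The scan is implemented as a vectorized 4-bit-mask comparison over all
windows.

Products are every (plus-strand forward site, downstream minus-strand
reverse site) pair whose inclusive span lies within
`[min_product, max_product]` (defaults 50–5000 bp). The length counts
both footprints: with the packaged panel's anchors, the forward
footprint at 1–20 and reverse footprint at 505–524 give the 524 bp
screening product, and the internal pair (46–68 forward, 448–464
reverse) gives 419 bp. Templates lacking the conserved sites yield an
empty product list — the negative-control behavior. The `virtual_gel`
table collapses co-migrating duplicate lengths into single bands.

## Pairwise identity

"Similarity" between two fragments is the percent identity of an
optimal end-to-end global alignment with affine gaps (match +1,
mismatch −1, first gap residue −2, each further residue −1), computed
with Biopython's `PairwiseAligner`; the first optimal alignment in the
aligner's deterministic enumeration is used. Identity counts columns
between the terminal-gap overhangs of either row; matches require
identical concrete symbols. Results are *reported* to one decimal
place (the field's convention), but the identity matrix carries full
precision internally: quantizing to 0.1 percentage points before
distance conversion measurably degrades tree resolution on ~500 bp
fragments. Scoring parameters are exposed because published similarity
figures rarely state their alignment model; ±0.5 pp disagreement
between reasonable parameter choices is normal.

## Distances, neighbor joining, bootstrap

Identity converts to distance as p = 1 − identity/100, optionally
Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3) (undefined at
p ≥ 0.75, which raises). The uncorrected p-distance is the default —
the classical default of desktop phylogeny packages for this use —
with JC available where saturation matters; on data simulated under
JC69 the matched correction is the statistically appropriate choice.

Trees are built by Saitou–Nei neighbor joining: join the pair
minimizing Q = (n−2)·d(i,j) − r(i) − r(j), assign branch lengths by the
rate-corrected closed forms, reduce the matrix, and resolve the final
three taxa by the three-point formulas. Two deterministic rules are
fixed: matrix labels are canonically sorted on entry and Q-ties are
broken by the smallest (row, column) pair in that order, making the
tree invariant to input row order; negative branch-length estimates
(possible on non-additive input) are clamped to zero with a log entry.
On additive matrices the algorithm recovers the generating tree
exactly — the property the test suite exercises against a four-point
condition oracle — and its topologies agree with scikit-bio's
independent implementation.

Bootstrap supports resample alignment columns with replacement,
rebuild the distance matrix and NJ tree per replicate, and attach to
each internal edge of the full-data tree the percentage of replicates
containing the same leaf bipartition (canonicalized by the side not
containing the lexicographically first leaf). Pairwise distances over
an alignment count only columns where both rows are gap-free. Supports
are integers 0–100 stored as internal node labels; Newick output
rounds branch lengths to six significant digits.

## Synthetic data

The generator emulates what a universal-primer screen sees: homologous
genes diverged along a known phylogeny that retain conserved primer
footprints. A uniform-random root (default 950 nt, the scale of a
*bsh* coding sequence) evolves down a user-supplied or random tree
under JC69 — each site substitutes with probability
(3/4)(1 − e^(−4t/3)) per branch of length t — and afterwards the
planted footprints (by default the four panel sites at positions 1,
46, 448 and 505) are overwritten in every leaf with an independently
sampled concrete expansion of their IUPAC pattern. Overwriting after
evolution keeps truth coordinates exact and guarantees zero-mismatch
primer sites while flanks diverge; it is adequate for testing
detection and PCR, though real conserved regions would show correlated
(not i.i.d.) residual variation at the degenerate positions. Indels
are off by default so anchors stay exact; an optional per-site indel
process (rate split evenly between geometric-length insertions and
deletions, flanks only) shifts downstream anchors in the truth record.

What passing tests on this generator do show: the binding-site scan,
product arithmetic, identity statistics and NJ recover planted
structure exactly or near-exactly at realistic divergences. What they
do not show: robustness to alignment error, rate heterogeneity across
sites, selection, paralogy, or real indel structure — real marker-gene
data violate all of these to some degree.

## Problem sizes and statistical expectations

Default test and acceptance runs use 8-leaf trees with per-edge
divergence 0.02–0.15 substitutions/site, 950 nt templates, 524 bp
amplicons, 20 pipeline replicates and 200 bootstrap replicates —
desk-scale versions of a survey with ~20 isolates and 1000 replicates.
At these sizes, full-pipeline topology recovery
(simulate → PCR → identity → JC distance → NJ) succeeds in ≈95–100 %
of replicates: an internal edge of 0.02 subs/site corresponds to only
~11 expected substitutions across a 524 bp fragment, so occasional
mis-resolution of the shortest edges is an information limit of the
fragment length, not an algorithmic error (the independent reference
NJ implementation resolves the same instances identically). Clades
separated by ≥10 fixed differences reach ≥95 % bootstrap support at
200 replicates.

## Degenerate inputs and edge cases

Empty sequences, duplicate ids within a collection, gaps outside
alignment contexts, and non-IUPAC characters are rejected with
positioned errors. `U` is transliterated to `T` with a warning.
Primers longer than the template yield no sites; absence of sites
yields an empty product list, never an error. Jukes–Cantor conversion
refuses p ≥ 0.75. NJ requires n ≥ 3; bootstrap requires ≥3 rows and
pairs sharing at least one gap-free column.
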