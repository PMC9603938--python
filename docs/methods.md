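# Methods

`cytobarcode` implements the quantitative core of a chromosomal-barcode
species analysis in black flies (Simuliidae): polytene banding sequences
treated as permutations, inversion-scenario algebra, a rearrangement
registry for species diagnosis, inversion population genetics, and a
from-first-principles COI distance/tree stage.

## Banding sequences as unsigned permutations

A chromosome arm's banding sequence is an ordered list of labeled band
fragments relative to a group-standard reference map. Paracentric
inversions act as reversals of a contiguous interval. The model is
**unsigned**: the cytological notation prints fragments without
orientation marks (a reversed fragment pair "de" is printed "ed", but each
fragment is atomic), so fragment orientation is not tracked and the
signed (Hannenhalli–Pevzner) theory is deliberately out of scope.
Coordinates are 1-based inclusive, matching how cytologists cite limits.

**Breakpoints.** A breakpoint is a neighbor pair of the query whose
fragments are not adjacent in the reference in either orientation. Both
ends are framed by a virtual cap adjacent to *both* reference termini, so
terminal rearrangements are counted and a full-arm reversal — which is the
same arm read from the other end — scores zero. A single reversal changes
only the two boundary adjacencies, so the breakpoint count `b` drops by at
most 2 per step and `ceil(b/2)` is an admissible lower bound on the
inversion distance.

**Minimal-distance search.** `min_inversion_distance` runs
iterative-deepening A* over permutation states with `ceil(b/2)` as the
heuristic; the breakpoint delta of a candidate reversal is computed in
O(1). Moves are enumerated lexicographically by (start, end), making
scenario enumeration deterministic; a per-iteration transposition table
prunes states re-reached at no shallower depth (relaxed to strictly
shallower when several optimal scenarios are requested, so distinct
prefixes survive). The default node budget is 5×10⁶; on exhaustion the
result degrades to the certified interval [`ceil(b/2)`, greedy upper
bound] rather than failing. On the focal 18-fragment IIL instance (b = 9)
the search needs ~6×10⁵ nodes and proves the distance is exactly 7 — the
published 7-step derivation is parsimonious, which the source itself left
open ("several inversion sequences are possible").

**Constrained search.** Requirements are content-addressed: a required
step is the *set of fragment labels* it must invert, since positions shift
between states. The heuristic becomes
`max(ceil(b/2), #unsatisfied requirements)`, still admissible because one
move can both remove two breakpoints and satisfy one requirement.
Unsatisfiable constraints surface as an error when the budget exhausts;
there is no cheaper certificate for unsigned reversals.

**Scenario notation.** The multi-line bracket/slash notation is parsed
with slashes treated as cosmetic breakpoint markers; each line must follow
from the previous by its bracketed inversion, and a trailing bracket-free
line states the end state. Parsing is strict (consistency between
consecutive lines is an error, not a warning) because the notation is the
primary data of record.

## Rearrangement registry and diagnosis

Records carry a name, arm, status (fixed / polymorphic / sex-linked
marker), kind (inversion / transposition / nucleolar expression), a
component count (4 for the overlapping-inversion complex, 1 otherwise),
and the sample frequency. Identity is by canonical name through an
editable alias table shipped as data; the same physical inversion may be a
fixed difference in one taxon and a named polymorphism in another, so
shared-rearrangement queries intersect canonical names regardless of
status or frequency. The fixed-difference total sums component counts over
fixed records — inversions and the nucleolar-organizer transposition alike
(the transposition is registry annotation only; no band-level coordinates
exist for it, so it is not modeled as a permutation operation).

Diagnosis scores each registry taxon as
(matched fixed records) − (fixed records in exactly one profile); ties are
flagged on every tied entry rather than broken silently, because a tie is
a biological statement (the query lacks a diagnostic character).

## Inversion population genetics

Per-larva genotypes are ss / si / ii per polymorphic inversion. The
inverted-homologue frequency is `(2·ii + si) / 2n`. The Hardy–Weinberg
test is the Pearson chi-square against expected counts
`(n p̂², 2n p̂q̂, n q̂²)` with **no continuity correction** and **df = 1**
(three classes, one estimated frequency); this reproduces the focal
worked example (ss=5, si=6, ii=8 → χ² = 2.3578, p = 0.1247) to four
decimals. The reported p is the exact upper tail of χ²(1). Eligibility
("adequate representation") is a named, overridable policy: more than 5
scored larvae. Monomorphic samples return no statistic. Sex linkage of
nucleolar expression is classified by the X-nucleolate / Y-anucleolate
prediction (females homozygously nucleolate, males heterozygous), with
violating larvae listed individually.

## COI stage

K2P distance `d = −½·ln[(1−2P−Q)·√(1−2Q)]` with transitions A↔G, C↔T.
Sites with a gap or N in either member of a pair are excluded from that
pair (pairwise deletion; a complete-deletion switch exists because the
original analysis software's setting is not recorded). Saturated pairs
raise an error instead of returning a silently large distance.

Neighbor joining is the Saitou–Nei agglomeration on
`Q(i,j) = (n−2)d(i,j) − r_i − r_j`, with exact ties broken by the smallest
index pair (original taxon order, internal nodes appended), so output is
deterministic. Negative branch lengths are clamped to zero with the
deficit moved to the sister branch. Additive matrices are recovered
exactly (tested to 1e−9, and cross-checked against an independent NJ
implementation).

Bootstrap: alignment columns resampled with replacement, K2P+NJ per
replicate, per-branch bipartition percentages mapped onto the full-data
tree (as the common display convention does, not a majority-rule
consensus). Replicates in which any pair saturates are skipped and
counted; supports are percentages of successful replicates. Supports below
50% are suppressed in rendered newick but retained in the data.

## Synthetic data

The generators define the study conditions rather than tune to them:

- **Genotypes** — 19 larvae (9 female / 10 male), the four observed
  autosomal inversion frequencies (0.58, 0.10, 0.74, 0.71), genotypes
  binomial(2, q) independent across larvae and inversions (exact HWE),
  nucleolar states perfectly Y-linked unless an exception rate is set.
- **Banding scrambles** — k uniform random non-identity reversals with the
  ground-truth scenario returned, giving distance-≤-k witnesses.
- **Alignments** — 8 sequences × 658 bp by default, evolved
  site-independently along a newick tree under K80 with transition/
  transversion ratio R = 2 (κ = 2R = 4), a conventional value for insect
  mitochondrial COI; the data give none. The default tree is two shallow
  four-leaf clusters separated by a deep split — the shape of a barcode
  set with a focal species and near relatives.

Streams derive from (seed, component index), so outputs are byte-stable
and adding one generator call never perturbs another's draws.

What the generators deliberately do **not** emulate: linkage
disequilibrium between inversions, rate heterogeneity across sites, base
composition bias, sequencing error, or alignment uncertainty (alignment is
an input precondition). Passing tests therefore demonstrate correctness of
the estimators and searches under their own model assumptions, not
robustness to real-data violations of them.

## Numerical and testing choices

- Distance recovery checks use Kimura's large-sample variance of the K2P
  estimator (error propagation over the multinomial site counts), averaged
  over 5 replicate alignments against the replicate-mean standard error;
  the binomial SE of the raw difference proportion understates the
  estimator's spread.
- The HWE type-I-error property draws 2000 multinomial samples of n = 100
  at allele frequency 0.4 and requires the rejection rate at α = 0.05 to
  fall in [0.03, 0.08], the tolerance appropriate to the chi-square
  approximation at that sample size.
- The reversal-distance search is validated against a plain breadth-first
  enumeration of all permutations of length ≤ 8 (an independent oracle
  precomputed once per length).
- Problem sizes in the shipped analyses — 18-fragment arms, 19-larva
  tables, 8 × 658 alignments, 1000 bootstrap replicates — are the study's
  own scales; every driver finishes in seconds.

## Known limitations

- Unsigned reversals only; no translocations, fissions, or transposition
  moves in the permutation algebra.
- The exact search is exponential; beyond ~20 fragments or distances much
  above 8 expect budget exhaustion and interval results.
- The NJ implementation targets small barcode sets (tens of taxa); it is
  O(n³) with dense matrices and no rapid-NJ heuristics.
- Percent identity is defined on aligned pairs only; database search
  (BLAST/BOLD) semantics are out of scope.
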