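# Methods

This note documents the modelling choices, parameters, numerical details
and limitations of `histac`. It states no empirical claims beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Problem setting and label semantics

Histone lysine acetylation is detected experimentally (largely by MS) with
limited sensitivity: absence of evidence is weak evidence of absence. Each
lysine therefore carries one of three labels — `P` (observed acetylable),
`N` (not observed; a semi-reliable negative), `U` (unknown). Training
coerces `U` to `N` (the semi-supervised convention), and evaluation in
`semi_supervised` mode treats only sensitivity and the false-negative rate
as reliable; specificity and FPR are reported but flagged, since many `N`
sites may simply be unobserved positives. Standard definitions are used
throughout (sensitivity = tp/(tp+fn), fnr = 1 − sensitivity, asserted in
tests); reported metric pairs therefore always sum consistently.

## Peptide representation

- **Flank = 12** residues either side of the lysine (window ≤ 25 aa),
  truncated at termini. Rationale: acetyltransferase–substrate contacts
  rarely exceed 14–20 aa, so a 25-residue window covers the recognition
  context with margin.
- **Adjacent-lysine merging, max_gap = 3**: runs of lysines whose
  successive positions differ by ≤ 3 *and* share a label are merged into
  one peptide spanning flank-left of the first to flank-right of the last.
  Runs with discordant labels never merge. The operation is idempotent.
- Numbering is 1-based on the mature protein (initiator Met stripped),
  matching H3K4/H4K91-style site names.

## Distance

Smith–Waterman local alignment under BLOSUM62 with gap open 10 / extend
0.5 (penalties unrecoverable from first principles; these are the common
protein defaults and are configurable). Scores map to distances by

- `min_self` (default): d = 1 − S(a,b)/min(S(a,a), S(b,b));
- `geometric_mean_self` (alternative): d = 1 − S(a,b)/√(S(a,a)·S(b,b));

both clipped to [0,1], d(x,x)=0, symmetric. The length-normalized variant
divides the cross-score by min(len a, len b) and the self-scores by their
own lengths before the same transform. The exact transform behind any
particular published cut height is not identifiable from a score
definition alone, which is why both are config-selectable; all cut heights
in this package are on the `min_self` scale unless stated.

A caution encoded in the tests: the distance is *not* monotone under
appending shared context to both peptides (the self-score denominator can
grow faster than the cross-score; random instances violate it routinely).
The true invariant is on scores: S(x+c, y+c) ≥ max(S(x,y), S(c,c)).
Triangle inequality is likewise not asserted.

## Clustering and cut selection

Complete-linkage agglomeration is implemented directly (O(n³), exact) with
a deterministic tie-break: among minimal-distance pairs, merge the
lexicographically smallest leaf-id-sorted cluster pair. scipy's
implementation serves as an independent oracle in the tests, never as the
implementation. Merge heights are monotone non-decreasing; any cluster at
cut height h has diameter ≤ h.

Candidate cuts are 0 plus midpoints between consecutive distinct merge
heights (avoiding on-the-knot ambiguity). Each candidate partition is
scored by the Quinlan gain ratio of P/N labels (information gain divided
by split information, 0 by convention for zero gain or single-cluster
partitions). Selection: maximal gain ratio, then fewest clusters, then
larger height; an all-zero profile returns the single-cluster cut flagged
degenerate. Note a structural consequence: among label-pure partitions the
rule always prefers the coarsest one (split information grows with cluster
count), so a pure two-cluster cut dominates a pure three-cluster cut even
when finer structure exists in the tree.

## Insertion behaviour (what is and is not guaranteed)

The high-cutoff predictor inserts query peptides into the training tree
and reads off co-membership. Two facts are theorems and are
machine-checked on arbitrary random instances:

1. merge heights are monotone and cluster diameter ≤ cut height;
2. the complete-linkage distance between two clusters weakly increases
   when either absorbs new points.

Full preservation of training-side memberships at a fixed height is **not**
a theorem: arbitrary insertions can both split and join pre-existing
clusters (counterexamples are easy to generate, and the tests document
this). Preservation does hold — and is asserted on 100 random instances —
in the separated regime the method assumes: sub-class diameters below the
cut, separations above it, and queries that either join one sub-class or
stay far from all. Outside that regime `predict_high_cutoff` detects the
rearrangement at runtime and flags every affected record
(`training-membership-changed`) rather than failing; the flag appears in
real cross-species runs and should be read as "the high-cutoff geometry is
being stretched by these queries".

## Classifier

Reference sub-classes: label-pure clusters with ≥ 2 members at the
selected cut. Decision: score = α·min over N-sub-classes of D(x, s′) −
β·min over P-sub-classes − I, with D the complete-linkage (max-member)
distance; score > 0 ⇒ P, ties to N (conservative: the semi-supervised
setting makes false positives less interpretable than false negatives).
Defaults α = β = 1. The intercept is grid-fitted (step 0.01 over the
observed training score range) minimizing training FNR, tie-broken toward
maximal specificity.

## Nucleosome geometry

- ε-N positions are the NZ atoms of lysines, read from a PDB structure
  via Biopython; sites are located on chains purely by exact flanking-
  peptide matching (up to 8 residues each side, greedily shrunk near
  termini but never below 8 total flanking residues; ambiguous multi-hit
  windows exclude the site for that chain). PDB residue numbers are never
  trusted for mapping.
- Region fitting: the five site groups (acetylable: {H3K37, H3K56, H4K31,
  H4K44, H4K59}, {H4K77, H4K79}, {H4K91}; un-acetylable: {H3K115,
  H3K122}, {H2BK40, K43, K105, K113, K117, K122}) are each fitted with an
  ellipsoid (x−c)ᵀA(x−c) = 1 over the pooled ε-N atoms of both symmetric
  octamer copies. The H2BK31 pair is deliberately not a group (no
  evaluated status). Membership and polarity are config-overridable.
- Fit: with ≥ 9 points, the general 9-parameter quadric is solved by
  least squares and the center recovered as −M⁻¹b/2. A centroid-centered
  6-parameter fit was considered and rejected: the centroid of a finite
  random surface sample is offset from the true center by ~r/√n, which
  alone produces up to ~10% radii error on 30 noiseless points; the
  quadric fit is exact there. With 6–8 points (underdetermined quadric)
  the 6-parameter centroid-centered form is used instead; with < 6 pooled
  atoms the group falls back to a flagged sphere through the RMS radius
  (floor 1 Å). Eigenvalues are clamped at 1e−8 before reassembly; radii
  are eigenvalue^(−1/2).
- Point-to-region distance: minimum Euclidean distance to a Fibonacci-
  lattice surface sample mapped through A^(−1/2) (default n = 4096; the
  seed only rotates the lattice offset, so results are deterministic and
  coverage quasi-uniform). The sampling error is bounded by
  ~2π·max_radius/√n and the tests verify 1% agreement with a 10⁶-point
  brute-force oracle.
- Site-to-region distance takes the min over the site's symmetric copies
  (either copy's proximity is biologically equivalent in the two-fold
  symmetric octamer).

## Hierarchy

Level 1 (high cutoff, default height 0.364): final; membership-based, no
score. Level 2: max–min peptide score for everything level 1 left
unpredicted. Level 3: applies only to level-2 positives with a structure
mapping (a config switch `level3_rescues_negatives` extends it to
negatives, default off, matching the conservative reading that structure
*adjusts* positives); its score uses the same α/β but its own intercept
(`spatial_intercept`, default 0) because region distances are in Å, not on
the [0,1] peptide-distance scale. Unmapped sites keep their level-2 label
with a `no-structure` note. Merged runs yield one decision, expanded to
per-lysine records by default.

## Synthetic data

The generators produce data with exactly the structure the method assumes,
which bounds what passing tests show about real data:

- `generate_histone_family`: lysine windows are mutated copies of class
  consensus motifs (default 5% per-residue substitution, never touching
  the central K, never creating lysines; sites spaced 28 residues so
  default windows do not overlap). Real histone tails violate several of
  these idealizations (overlapping windows, compositional bias, shared
  evolutionary history), so motif-recovery rates measured here are upper
  bounds.
- `generate_epsilon_cloud` / `make_synthetic_nucleosome`: ε-N points on
  configurable ellipsoid shells with *radial* Gaussian noise (default
  region geometry at nucleosome scale, radii 4–14 Å, disc radius ~45 Å,
  two-fold symmetric chains; catalog-site pairs are placed on their
  group's single shell, mirroring the fact that a region contains the
  symmetric pair). It is a geometric stand-in, not a crystal structure:
  no excluded volume, no DNA, no correlated side-chain packing.
- Noise tolerances were fixed from the generator's realistic regime:
  noiseless ellipsoid recovery is exact to machine precision; 0.5 Å radial
  noise on nucleosome-scale radii supports ~5% radii error (50 points).
  On unit-scale radii the same absolute noise is 50% relative noise and no
  fitter recovers 10% — tolerance claims are therefore stated at
  nucleosome scale.
- `generate_asa_table`: label-independent by default (shift_sd = 0),
  mirroring the reported absence of ASA–acetylability association;
  `shift_sd` exists for power checks of the rank-sum test.

## Bundled reconstruction and problem sizes

The bundled FASTA/TSV files reconstruct the human/Arabidopsis histone
inventory under the published constraints (lysine counts per variant,
inter-species difference positions, per-variant acetylated-site counts);
residues not pinned by those constraints are synthetic
(`data/PROVENANCE.md`). Consequently the acceptance script's quantities
are faithful recomputations of the *method* on a faithful-scale input, not
database-exact reproductions. Sizes used: 41 merged human training
peptides, 228 Arabidopsis query lysines, permutation counts 500–2000
(chosen as comfortable Monte-Carlo resolution for p-values in the 0.001–1
range), 4096 surface samples per region distance.

## Known limitations

- Cut heights depend on the score→distance transform; comparisons of
  absolute heights across transforms are meaningless.
- The empirical p-value convention is (r+1)/(n+1); exhaustive enumeration
  (used automatically in tests for tiny n) reports the exact fraction.
- Permutation of labels re-runs label-dependent merging, so the sub-class
  count statistic is recomputed on a slightly different peptide set per
  permutation — intended, as merging is part of the pipeline under test.
- The spatial level is only as good as the structure and the mapping;
  N-terminal tails are typically unresolved in crystal structures, so
  tail sites are effectively peptide-only even with a real structure.
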