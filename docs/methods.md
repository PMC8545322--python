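# Methods

## The problem and the approach

Given two multiple sequence alignments (MSAs) M1 and M2 of the same large
set of homologous protein sequences, which one is more accurate?  Benchmark
alignments cannot answer this for alignments of tens of thousands of
sequences, so the package uses an internal, structure-based signal instead:
residue pairs that form 3D contacts tend to coevolve, and a more accurately
aligned family shows that coevolution more clearly.  The pipeline

1. fits a Potts model to each alignment by pseudo-likelihood maximisation
   and summarises each column pair by its average-product-corrected (APC)
   Frobenius norm — the direct-coupling (DC) score;
2. for each reference structure, ranks the DC scores of the residue pairs
   that are scored in *both* alignments and measures, with the
   initial-segment statistic described below, how strongly the top of the
   ranking is enriched in true sidechain contacts (distance <= z);
3. takes the per-structure score difference dS = S1 - S2 as that
   structure's vote, filters structures whose alignment looks internally
   inconsistent (the distance-discrepancy test), and reports the mean dS
   and the two-tailed equiprobable binomial P of the vote split, both with
   and without the filtered structures.

Only the *ordering* of DC scores is ever used, so the comparison is
invariant to any monotone transform of the coupling scores, and the two
per-structure arrays always share their length L and contact count D —
the property that makes S1 and S2 directly comparable.

## Scored columns and comparable pair sets

Match-state formats (A2M, Stockholm with `#=GC RF`) declare which columns
are modelled; for flush FASTA alignments, columns with more than 50% null
characters (`-`, `.`) are excluded (strict inequality, so exactly half
null is kept).  For one structure, the comparable residue set R contains
the residues mapped to scored columns in both alignments; candidate pairs
are those with at least m = 5 intervening residues (sequence separation
b - a >= m + 1), measured in residue space because the constraint exists
to suppress trivial backbone-driven contacts.  Ties in DC score are broken
by residue-pair lexicographic order so runs are reproducible.

## The congruence statistic

For one ranked array of L pairs with D distinguished elements (contacts,
themselves ranked by closeness, rank 1 = smallest sidechain distance), the
statistic scans initial segments.  For the segment of length X ending at
the k-th distinguished element it computes:

* an enrichment p-value: the hypergeometric tail
  `p_enrich = Pr(#contacts among first X >= k)`;
* an ordering p-value: the probability that the closeness ranks of those k
  contacts agree with their array order as well as observed, measured by
  the Spearman D-statistic `sum (i - sigma(i))^2`.  For k <= 8 the null is
  enumerated exactly over all k! permutations (the normal approximation is
  anticonservative at small k: a perfect order of 3 has exact p = 1/6 but
  approximate p = 0.079); beyond 8 the usual normal approximation
  `z = rho * sqrt(k - 1)` is used.

The two components are combined through the exact joint tail of their
product: `p(X) = Pr{ p_enrich(X, d') * p_order(d', sigma') <= u_obs }`,
enumerated over the hypergeometric distribution of d' and the ordering
atoms.  Both components are strongly discrete, and a chi-square (Fisher)
combination that treats them as continuous uniforms overstates the
combined p by orders of magnitude at extreme configurations (for the
perfect arrangement of 5 contacts atop a 20-pair array the exact null
probability is 1/(C(20,5) * 5!) = 5.4e-7, while the Fisher combination
gives ~8e-6); the exact joint tail reproduces such atoms exactly.  The
enumeration runs in log space, so scores up to several hundred are
representable without underflow.

The minimum over candidate segment ends is corrected by a Bonferroni
factor of L: although the minimum is always attained at a segment ending
in a distinguished element (enrichment and ordering components only
improve when a segment is trimmed back to its last contact), the selection
effectively ranges over all L possible lengths, and a factor of D alone is
measurably anticonservative under permutation.  The union bound makes the
final P conservative by a configuration-dependent factor (between 1 and
about 6 in simulations); since both alignments are scored with the same
statistic at the same L and D, this conservatism largely cancels in dS.

`S = -log10 P`.  With D = 0 the statistic is defined as S = 0.

Calibration, verified in the test suite: under random placement and
ordering the fraction of arrays reaching P <= alpha stays below alpha
(checked at alpha = 0.05 and 0.01 with 10^4 simulated arrays at L = 200,
D = 20), the exhaustive null at L = 8, D = 3 is never understated, and the
fixed-X combined p matches a 10^6-draw permutation oracle to well within
5% relative error on the -log10 scale.

## Direct-coupling engine

A 21-state Potts model (20 amino acids + one gap/other state) is fitted to
the scored columns by weighted pseudo-likelihood maximisation, as in
standard pairwise maximum-entropy contact prediction.  Sequences are
reweighted by 1/(number of neighbours at >= 80% identity over scored
columns, nulls counting as mismatches); the 0.7/0.9 alternates are exposed.
The penalty is L2: `0.01 ||h||^2 + lambda * (L - 1) ||e||^2` with
lambda = 0.2 by default (0.1/0.3 exposed).  Optimisation starts from zero
parameters and runs L-BFGS to a gradient infinity-norm below 1e-3 or at
most 150 iterations; most iterations use float32 arithmetic (the two large
matrix products dominate the cost) with a float64 polish phase to reach
the tolerance, since the float32 objective noise floor stalls the line
search around max|grad| ~ 5e-3.  Non-convergence is recorded in the model
metadata rather than raised.  DC scores are Frobenius norms of the
zero-sum-gauged 20x20 amino-acid coupling blocks (the gap state is
excluded from the norm), followed by APC.  Precomputed L x L score
matrices from external DCA tools can be supplied instead; asymmetries up
to 1e-6 are averaged away, larger ones rejected.

## Structures

Contacts use the minimum heavy-atom sidechain distance, where "sidechain"
means C-beta outward (so alanine contributes its C-beta) and glycine falls
back to its C-alpha; hydrogens are ignored.  The default contact cutoff is
z = 4 A (inclusive), with 5 and 6 A as robustness alternates.  Alternate
locations keep the highest-occupancy atom; residues without a C-alpha are
skipped with a warning.  Residues are renumbered by ordinal chain position,
keeping the author numbering for reports.

A chain is placed in an alignment by scanning every record's ungapped
sequence for a contiguous window matching the chain sequence with at most
5% mismatches; ambiguous placements are an error that an explicit
structure-to-record mapping resolves.

## Misaligned-structure filter

For each alignment, the residues of structure i aligned to residues of
*all* other structures form R_i (same size for every structure).  The
pairwise discrepancy dD_ij is the mean absolute difference of C-alpha
distances over all residue pairs of R_i; dD_i is its mean over j.  The
filter iteratively removes structures with dD_i >= mean + 2 SD (sample SD,
n-1 denominator; the candidate's own value is included in the statistics
it is tested against) and recomputes mean/SD until stable.  The dD matrix
itself is frozen after the first computation; only the summary statistics
iterate.  If all retained values are equal (SD = 0) nothing is removed.
Exclusion decisions never see the S-scores.  The union of the two
alignments' exclusion sets is dropped from the "with exclusion" summary;
every structure still appears, flagged, in the per-structure table.
Optionally a greedy diversity selection first reduces the structure set to
chains sharing at most 65% identity over their co-aligned residues, with
a warning when fewer than 10 survive.

## Synthetic validation harness

The generator plants a sparse Potts model on a compact self-avoiding bead
chain (bond length 3.8 A, excluded volume 3.4 A, confinement radius
3 * n^(1/3) A): the contact graph is the n_contacts spatially closest bead
pairs at chain separation >= 6, all within 8 A, and only those pairs carry
non-zero couplings.  Fields are Normal(0, 0.5) per amino-acid state;
contact blocks are Normal(0, 0.5) 20x20 matrices in zero-sum gauge.  The
coupling scale is chosen so that planted covariation is clearly detectable
at the simulated alignment depths used here (hundreds of sequences); the
block Frobenius norms this produces sit at the strong end of what fitted
models of real families show, compensating for the reduced depth.
Sampling is plain Gibbs at the model's temperature, by default one
independent chain per sequence with 500 burn-in sweeps (a single thinned
chain is available); gold alignments are gap-free by construction, the
only nulls entering through corruption.  The sampled alignment together
with the bead chain (carrying one sampled record's residue identities)
forms a gold standard whose single reference structure is exact.  The
8 A masking radius doubles as the contact cutoff z when scoring these
synthetic comparisons, so the distinguished pairs coincide with the
model's coupled pairs.

Corruption inserts, in a seeded random subset of records, 1 + Poisson(1)
gap blocks of 1..max_shift nulls at random positions, shifting the
downstream residues out of register; rows are padded to a common width.
The distance of a corrupted alignment from its gold standard is the
SP-score: the fraction of the gold standard's co-aligned residue pairs
that are co-aligned identically in the test alignment.

What this emulates — and what it does not: the synthetic families have
independent sequences (no phylogeny), site-independent composition, no
insertions in the gold standard, and exactly sparse couplings realised by
a single structure.  Real families violate all four, so passing the
validation loop shows the machinery recovers planted signal and that the
score tracks alignment accuracy under controlled corruption; it does not
by itself certify accuracy claims on any particular real superfamily.

## Numerical and degenerate-case choices

* Binomial vote: `P = min(1, 2 * sum_{j>=max(n1,n2)} C(n,j)/2^n)`; dS = 0
  votes for neither side; an empty vote reports P = 1 with a flag.
* A single retained structure reports SD = 0 with a degenerate flag.
* Identity denominators: dereplication and structure diversity use
  positions where both sequences carry residues; reweighting uses all
  scored columns with nulls as mismatches (each record always counts in
  its own neighbourhood).
* Sequence-set mismatches between the two alignments are warned about and
  resolved by intersecting the ungapped-sequence multisets; dereplication
  is a separate, explicit step (CLI `--purge`) so it cannot silently
  desynchronise the two alignments.
* Comparisons need two usable structures (the discrepancy filter three);
  the synthetic loop runs with a single, exact reference structure via an
  explicit configuration switch.
* Problem sizes in the test suite (hundreds of sequences, tens of
  columns, a handful of planted models) are chosen as the smallest scales
  at which the recovered signal is unambiguous; the generator's defaults
  (5000 sequences) match the scale a real study would simulate.

## Known limitations

* The scan P is a union bound, conservative by a small
  configuration-dependent factor; absolute S values are therefore
  slightly deflated, while score *differences* between alignments — the
  quantity the method reports — are much less affected.
* One conformation per structure: proteins with large conformational
  changes contribute whichever contacts their deposited model shows.
* The binomial vote treats structures as independent; related reference
  chains share evolutionary history, so reported significances overstate
  somewhat (a fixed note in every report says so).
* dD values are comparable only within one alignment, never between
  alignments; the report prints them per alignment without cross-MSA
  comparison.
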