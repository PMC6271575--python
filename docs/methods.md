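# Methods

## Fingerprint encoding

Compounds are described by six binary structural features in a fixed
rank order: cyc₁₂₃ (1–3 rings), O₀₃₄₅ (0 or 3–5 oxygens), NP
(nonplanar), S= (thiono sulphur), N₁₃ (1 or 3 nitrogens), Cl₃ (exactly
3 chlorines). The rank reflects expected importance for LC retention;
position 1 is most important. The encoding rules are total on valid
counts: values outside the labelled ranges (≥4 rings, 6+ oxygens, 0/2/4+
nitrogens, ≠3 chlorines) encode to 0, since only the labelled ranges are
defined as positive. This default matters for compounds outside the
benchmark set and is the one genuinely open choice in the encoder.

## Similarity and its weight schemes

The similarity index r_ij = Σₖ tₖ aₖᵏ weights a positional match by
aₖᵏ, with base weights aₖ ∈ [0, 1] (default: equal weights aₖ = 0.5).
The self-similarity Σₖ aₖᵏ is the matrix diagonal and must not exceed 1,
otherwise indices leave [0, 1]; `WeightScheme` enforces this at
construction (with equal weights the constraint is aₖ ≲ 0.5 for long
vectors, satisfied by the default). The same index applies between
feature columns after transposing the item × feature table ("property
space"), with weights running along the molecule axis.

The thresholded pair diagram bins every unordered pair at
0.75 / 0.50 / 0.25 on the raw matrix. These are similarity bins, not
statistical partial correlations: a Pearson correlation between 6-bit
rows is ill-defined for a constant vector (the all-ones compound would
correlate 1.0 with everything), while the weighted-match index handles
it without artefacts — on the benchmark set the index reproduces every
spot value the reference analysis prints for its "correlation" matrix
(0.984 for identical 6-bit vectors, 0.986 for the thiono-S/Cl₃ feature
pair in property space), so that is what the module computes. True
Pearson correlations appear only in the PCA.

## Stabilization, grouping, entropy

Max–min composition (**R**∘**S**)ᵢⱼ = maxₖ min(rᵢₖ, sₖⱼ) is iterated,
R(n+1) = R(n)∘R, to a fixed point. Entries only grow, and the fixed
point is exactly the best-path closure: the stabilized r_ij is the
maximum over chains i→…→j of the weakest link. The closure converges in
at most n compositions; the tests cross-check it against a brute-force
enumeration of all simple paths for n ≤ 7. Thresholding the stabilized
matrix at b gives disjoint classes; classes are reported in order of
first member appearance, and all tie-breaking everywhere is input order.

The class matrix takes off-diagonal entries from the **raw** matrix
(largest raw similarity across two classes) and the weight scheme's
self-similarity on the diagonal. Entropy is the sum of binary Shannon
entropies H(x) = −x ln x − (1−x) ln(1−x) over **all N² entries,
diagonal included**, in natural-log units, with 0·ln 0 := 0. These two
conventions — raw-matrix class entries with self-similarity diagonal,
full-matrix summation — are the unique combination that reproduces the
benchmark's published eight-level entropy staircase (32.49, 20.01,
15.13, 10.70, 6.77, 3.71, 1.47, 0.08 at b = 1.00 … 0.10); plausible
alternatives (upper-triangle-only summation, closure-based class
entries, diagonal = 1) do not, which is why they are hard-wired rather
than configurable.

Entropy is monotone in b (coarser partitions lose entropy), partitions
nest as b falls, and h = 0 when all entries are crisp — all verified as
property tests over seeded random fingerprint sets.

## Level scans and equipartition

A scan classifies at each level of a list (or, with auto-levels, at
every distinct stabilized off-diagonal value — every level where the
partition can change; note that simultaneous merges make some class
counts unreachable, e.g. identical vectors collapse three-at-once so the
benchmark scan never shows 8 classes). h_max is the entropy of the
all-singletons classification (b = 1), i.e. of the raw matrix. The
equipartition criterion scores a scan by Σ (h(b) − h_max·b)² and
`select_by_equipartition` returns the candidate weight scheme minimizing
it, ties broken by first occurrence.

## Distance and weight learning

The distance between two similarity matrices treats each entry pair
(r, s) as Bernoulli parameters and sums the symmetrized
Kullback–Leibler form (r − s)[ln(r/s) − ln((1−r)/(1−s))] over all
ordered entries — nonnegative, symmetric, zero iff equal. Endpoints are
guarded by clipping at 1e-12; the elementwise form is pluggable for
experimentation.

`learn_weights` is a seeded stochastic hill climb: the first weight a₁
is held constant (it sets the scheme's scale — the reference is assumed
to share it), the remaining weights receive Gaussian perturbations of
scale `step_size` (default 0.05) clipped to [0, 1], infeasible
candidates (self-similarity > 1) are skipped, and a move is accepted
iff it lowers the distance to the reference. The accepted-step trace is
therefore monotone nonincreasing and identical seeds give identical
runs. The synthetic reference generator pins a₁ = 0.5 and rescales the
hidden effective weights to keep the self-similarity below 1, so that
recovery is actually achievable with a₁ fixed; on the default recovery
setup (12 items, 6 bits) 2000 iterations reduce the starting distance
by well over 90 %.

## Dendrograms

Threshold-mode trees merge exactly at the distinct stabilized levels —
equivalent to single linkage under the max–min closure (asserted in the
tests) but possibly multifurcating when several pairs tie. Node heights
are 1 − merge similarity. Standard single/complete linkage on
d = 1 − r is delegated to scipy. Exports: Newick with branch lengths,
and a NEXUS DISTANCES block with d = 1 − r (raw matrix) for
split-network viewers; the 1 − r transform is a convention of this
package, stated in the file header.

## PCA

Ordination uses the plain Pearson correlation matrix of the feature
columns (eigenvalues sum to the number of variables), not the weighted
similarity. Eigenvectors are oriented so each one's largest-magnitude
element is positive; published loading tables are compared by magnitude
to stay sign-convention-free. The factor profile is 100 × squared
loading (rows sum to 100). Scores project columns standardized with the
n−1 denominator onto the eigenvectors; the standardization denominator
does not affect the eigenstructure, only the score scale, and n−1 keeps
per-factor score variances equal to the eigenvalues.

## QSPR retention models

The response is the relative retention (R_t − R_t°)/R_t° against the
least-retained compound (methamidophos, R_t° = 2.78 min). Five model
specs are named eq1–eq5: logP + (D′−D) with and without the internal
standard TPP, logP + D′ without TPP, and quadratic D′ fits with and
without TPP. Fits are OLS via statsmodels; the reported bundle is
r = √R², s = √(SSE/(n−p−1)), F with (p, n−p−1) dof, AEV = 1 − r²
(asserted as an identity), and MAPE = 100·mean(|y−ŷ|/|y|) over
observations with y ≠ 0 (the reference compound's ratio is exactly 0
and is excluded from the percentage error). Under this rule the
computed MAPEs come out 1–2 points below the reference analysis's
printed MAPEs (e.g. 7.47 % vs 8.77 % for eq1) while every other
statistic matches to printed precision; the printed MAPEs' exact
denominator convention is not recoverable, so MAPE is reported but not
used for validation. Likewise the intercept printed for eq2 (−0.299) is
not reproduced (OLS gives −0.229) although eq2's r, s, F and slopes all
match — treated as a typo in the source of that coefficient.

## Periodic table and the P/D/R series

Groups are the leading five bits (columns, ascending binary order),
periods the trailing bit (two rows). P is the decimal reading of the
vector, a bijection on 6-bit space; cells therefore contain only
identical-vector compounds. The series walks compounds ordered by group
then period (ties: input order) and assigns D(p) = P(p+1) − P(p) and
R(p) = P(p+1)/P(p) to the earlier compound; R is undefined (None) when
P(p) = 0. The extended table fixture (POPs, phenylureas,
sulphonylureas) carries group/period keys only — vectors are decoded
from the keys and no structural descriptors are invented for those
compounds.

## Synthetic data

`generate_vectors` draws i.i.d. Bernoulli(density) bits with a seeded
generator; default density 0.5 matches the maximum-entropy regime of
the 6-bit scheme and the roughly balanced bit frequencies of the
benchmark set. What random sets do not emulate: the strong nestedness
of real fingerprints (the benchmark's vectors are nearly a chain under
bitwise ≤, which is why its classification is so clean), or any
correlation between bits. Property tests on random sets therefore
exercise the algebraic invariants (closure, nesting, monotonicity), not
the chemistry.

## Problem sizes and numerics

All packaged analyses are 9 compounds × 6 bits; property tests use up
to 12 items and the path-enumeration oracle up to 7. Recovery runs use
2000 hill-climb iterations. Floating-point comparisons against printed
values use the print precision (±0.01 for entropies, 1e-6–1e-7 for
eigenvalues/loadings, 5e-4 for three-decimal correlations). Degenerate
inputs: zero-variance PCA columns raise with the column named; grouping
rejects unstabilized matrices; P = 0 yields an undefined ratio rather
than an exception.

## Known limitations

- The encoder covers the six-feature scheme only; it does not perceive
  rings, planarity or tautomers from structure files.
- Fractal dimensions D, D′ are consumed as inputs; computing them is
  out of scope.
- Split decomposition itself is not implemented — only the NEXUS
  distance export that split-network tools read.
- The equipartition criterion compares candidate schemes on a common
  level grid; comparing scans with different auto-level grids conflates
  grid density with staircase shape.
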