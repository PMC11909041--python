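# Methods

## Data-generating model

All validation runs draw data from a common-factor model. A condition
fixes the number of factors `m`, variables per factor `p_c`, a dominant
loading range, a cross-loading standard deviation, a sign pattern, a
factor-correlation matrix `Φ`, and a sample size `n`. One replicate
realizes a loading matrix `Λ` (dominant loadings uniform in the range,
every other entry Normal(0, cross_sd)), forms

    R_P = Λ Φ Λ′ + Ψ,    Ψ = 1 − diag(Λ Φ Λ′)

and samples `X = Z U` with `R_P = U′U` (upper Cholesky) and `Z` i.i.d.
standard normal, so indicators have unit population variance. A draw is
rejected and `Λ` redrawn when `R_P` has an eigenvalue ≤ 0 or any
communality exceeds 0.90; the redraw loop is capped at 1,000 attempts
(a hard error then indicates misconfiguration, not bad luck — the
rejection region is negligible for the ranges used here).

Under the `half_negative` sign pattern the first `⌊p_c/2⌋` variables of
each factor are wholly negated (exactly one when `p_c = 3`), emulating
reverse-keyed items. Negating the full row rather than the dominant
loading alone is inert distributionally (cross-loadings are symmetric
about zero) but matches the "reversed variable" interpretation.

"Varying" conditions redraw per replicate: variables per factor uniform
on {3..12}, dominant loadings U(0.30, 0.80), factor correlations
U(0.00, 0.70) independently per pair (non-positive-definite `Φ` draws are
rejected). The main factorial grid uses sample sizes 500 and 1000 and
cross-loading sd 0.05.

What the generator does *not* emulate: ordinal/dichotomous indicators,
skew, local dependence, or network-generated (non-factor) data. Passing
tests therefore demonstrate recovery when a factor model holds — they say
nothing about loadings computed on data with a different generating
mechanism.

## Network estimation

Pearson correlations (denominator n−1) feed a graphical lasso over 100
log-spaced penalties from `λ_max` (largest absolute off-diagonal sample
correlation) down to `0.1·λ_max`; the 0.1 floor gives slightly sparser
networks than the 0.01 used by some implementations, deliberately. The
EBIC

    −n(log det Θ − tr(SΘ)) + E log n + 4γE log p

selects the penalty (`E` = nonzero upper-triangle entries of `Θ`;
likelihood written without its additive constant, shared across the grid).
Selection starts at γ = 0.50; if the chosen network leaves any node with
all edges below 1e−12, selection repeats at γ = 0.25 and then γ = 0 (= BIC),
keeping the γ = 0 result regardless. The glasso path does not depend on γ,
so it is fitted once and re-scored. Edges are partial correlations
`w_ij = −θ_ij/√(θ_ii θ_jj)`.

Solver: scikit-learn's coordinate-descent graphical lasso, unpenalized
diagonal, dual-gap tolerance 1e−3, 100 iterations. The dual-gap criterion
is stricter in kind than the average-parameter-change thresholds common in
other glasso implementations; 1e−3 was validated against 1e−4/200
(maximum partial-correlation deviation ≈ 1e−3, edge sets differing by at
most two borderline edges across a full path) and is ~7× faster, which is
what keeps the replicated designs at desk scale. Failed fits at individual
penalties are dropped; a path with no successful fit raises an error
naming the last penalty. A correlation matrix with no off-diagonal mass
short-circuits to the empty network.

Walktrap community detection (python-igraph, absolute weights) is provided
for end-to-end use on real data only; every validation run passes the true
simulated memberships, isolating loading quality from detection quality.

## Original loadings: sign procedure semantics

The two-stage sign heuristic evaluates, for each node of a community
sub-network, whether negating that node's row/column in the *initial*
matrix of edge signs would raise the total sign sum; favourable flips are
applied to the loadings but do not feed back into later decisions, and the
test uses a strict increase (ties keep signs). Nodes are visited in
ascending index order in a single pass per stage; stage 2 flips only the
node's cross-loading entries. Finally each column is negated unless its
sum is strictly positive. The no-feedback semantics are load-bearing:
with an evenly split community every node's within-block sign sum is
negative, every flip looks favourable, and the whole community flips
together — mixed keying is lost. That failure mode is the documented
behaviour of this formulation and is preserved as the baseline; a
feedback-updating greedy would "fix" it and misrepresent the method.

The standardization denominator `Σ_i l_ic` sums the full column (assigned
and cross rows), read literally from the defining formula; this was
validated against the published cross-loading example.

## Revised loadings

The sign loop flips the lowest-index node whose within-community
connection sum is negative, updates the sub-network, and repeats until no
negative sums remain (cap: 100·p flips per community, then a warning and
the current state). A community whose sign-vector sum is negative is
recoded wholesale; a zero sum keeps the current signs. Within sums use
the signed post-flip weights — the sign step exists precisely to orient
them positively. Singleton communities get zero loadings with a warning.
`ζ = 2` throughout; logs are natural (`ζ·p_c > 1` required, else a
configuration error). The column-`c` denominator is built from community
`c`'s assigned within sums and divides every row of the column, including
cross-loadings from other communities (validated against the published
cross-loading example). Edgeless communities yield zero columns.

## Scores, congruence, alignment

Network scores are `z(X)·O` (z-scoring with denominator n−1); Pearson
correlations between score columns estimate the correlations between
factors. Scores are not re-standardized before correlating (correlation
is scale-free). Tucker congruence is the cosine of the vectorized loading
matrices (fair ≥ 0.85, good ≥ 0.95). Alignment matches estimated to
target columns by optimal assignment on absolute column congruences
(Hungarian; greedy matching can mis-pair under high factor correlations),
congruence rather than raw correlation because the two matrices live on
different scales; a matched column's sign is the sign of its congruence,
and the same permutation/signs are applied congruently to the estimated
factor-correlation matrix. Factor-correlation accuracy is the mean
absolute error over the `m(m−1)/2` unique off-diagonal elements.

## Problem sizes of the shipped runs

The replicated designs are scaled to single-CPU desk scale as the
package's own defaults; full-scale counts are noted for reference.

* Worked examples (mixed-sign, cross-loading): n = 100,000, exact printed
  `Λ` matrices as inputs.
* Community-size simulation: 25 replicates (full scale: 100) × sample
  sizes {250, 1000, 10,000, 100,000}; pooled correlations stabilize to
  ±0.03 by 25 replicates.
* Factorial-slice contrast: 2 factors × {3, 6, 12} variables × loadings
  0.55 × φ = 0.30 × n = 1000, both sign patterns, 20 replicates. The
  published full-grid means (960 cells × 100 replicates) are not
  recoverable from any slice; the slice reproduces the qualitative
  contrast (revised ≈ 0.95 congruence under reverse keying, original
  collapsed, gap > 0.4).
* Mapping sweep (effect-size guidelines): the design leaves the per-
  replicate sample size open; n = 1000 (the upper end of the main grid)
  with a default of 5 replicates per condition (full scale: 500).

## Known limitations

* All guarantees assume factor-generated continuous data; behaviour under
  network-generated or ordinal data is out of scope.
* The original method's sign procedure is order-dependent by construction;
  determinism is guaranteed only for a fixed node order.
* `estimate_network` is permutation-equivariant up to solver tolerance
  (coordinate descent visits columns in order); sign-flip equivariance is
  exact.
* EBIC selection on very small n (< 100) with dense true graphs can pick
  the sparsest grid end; the γ fallback mitigates but does not remove
  empty-node outcomes.
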