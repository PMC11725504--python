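# Methods

## Model

`trajalign` treats each gene in each trajectory as a univariate time series
of expression distributions along normalized pseudotime, and frames the
comparison of two trajectories as pairwise sequence alignment solved by
dynamic programming. Three ingredients define the optimization.

### Distributional interpolation

Pseudotime is min–max normalized to [0, 1]. For a gene g with expression
g(t_i) over n cells, every interpolation point t′ on an m-point equispaced
grid receives kernel weights `w_i = exp(−(t_i − t′)²/window_size²)` and a
Gaussian summary:

- mean: `Σ w_i g(t_i) / Σ w_i`
- s.d.: `c_t′ · sqrt( n Σ w_i (ḡ − g(t_i))² / ((n−1) Σ w_i) )`, with the
  deviations taken about the **global** (unweighted) gene mean ḡ and the
  weighted cell density `c_t′ = Σ w_i / n` damping the variance where few
  cells contribute.

Centering deviations on the global mean is deliberate, if unusual: where the
local level departs from the gene's overall level, the estimated σ inflates,
which makes the match cost conservative in fast-changing regions. A locally
centered variant would give smaller σ there; we implement the global form
exactly and note the consequence below under *simulator design*. 50 points
are drawn from each point's Gaussian (seeded per (seed, gene, grid point),
so results are independent of gene processing order); these samples are the
data the scoring encodes.

**Extreme cases.** Runs of adjacent interpolation points spanning more than
0.2 of the axis in which fewer than 3 cells (per kernel window) express the
gene get mean 0 and a common σ of 10% of that trajectory's minimum estimated
σ; a gene expressed in fewer than 3 cells of one trajectory inherits 10% of
the *other* trajectory's minimum σ everywhere. If both sides are degenerate,
a floor of σ = 0.001 (the datum precision ε) keeps encoding lengths finite.
Corrections are applied after interpolation, and corrected points are
re-sampled; densities are not re-scaled.

### The match cost

The cost of matching reference point R_j and query point Q_i compares two
hypotheses for their pooled sampled data D: a single shared Gaussian
(match, A) versus one Gaussian per side (mismatch, Φ). Each encoding length
is the Wallace–Freeman two-part message for a Gaussian (d = 2, lattice
constant κ₂ = 5/(36√3), uniform priors of width R_μ = 15 over μ and
R_σ = 3 over log σ, datum precision ε = 0.001, natural logarithms — nits).
Both lengths are normalized per datum; the match hypothesis states only one
model and is averaged over stating R_j's or Q_i's Gaussian, which makes

`Δ = I(A, D)_entropy − I(Φ, D)_entropy`

exactly symmetric in the two sides. The ε terms appear in every length with
the same total datum count and cancel arithmetically in Δ. A vectorized
implementation evaluates Δ for all (i, j) pairs of one gene from per-point
sufficient statistics; it is unit-tested cell-for-cell against the scalar
definition.

### The five-state machine and DP

States Ω = {M, W, V, D, I}. W/V are DTW-style warps (many-to-one /
one-to-many) and **pay the match cost**; D/I are pure gaps. The transition
machine has 23 allowed transitions (I→W and D→V are prohibited, as each
would imply a single M) priced at −ln Pr(x|y). Costs are invariant under
the reference/query swap (I↔D, W↔V) and every state's outgoing mass is 1,
leaving three free parameters, default (Pr(M|M), Pr(I|I), Pr(M|I)) =
(0.99, 0.1, 0.7). The symmetry and row constraints do not pin down every
transition; the remaining freedom is closed by equality classes:

- from M, the four non-match transitions share (1 − Pr(M|M))/4;
- from I (mirrored from D), M gets Pr(M|I), self gets Pr(I|I), and the two
  remaining targets split the leftover equally;
- warp states are treated gap-like: self Pr(I|I), back to M Pr(M|I), and
  the three remaining targets split the leftover equally.

This is one of several parameterizations satisfying the stated constraints;
it keeps warps non-sticky, which sharpens match/mismatch boundaries.

The DP fills five (|Q|+1)×(|R|+1) matrices with the Gotoh-style recurrences
(M from the diagonal; W/V from the row/column with match cost; D/I without),
gap borders accumulate I(I|I)/I(D|D) from the initial-state cost, and the
printed all-zero initialization of the match-type borders is replaced by the
only well-founded reading (0 at the origin via the initial-state costs,
∞ elsewhere on the borders). The first alignment state is priced from
initial probabilities (Pr(M), Pr(I), Pr(D)) = (0.99, 5·10⁻⁵, 5·10⁻⁵); a
uniform −ln(1/3) setting is available via `AlignmentConfig.uniform_initial`.
Ties in every minimization break in the fixed order M > W > V > D > I for
reproducibility. Backtracking yields the five-state string; the landscape
L(i,j) = min_x Hist_x(i,j) and its argmin states feed the aggregate
alignment.

**Symmetry caveat.** Swapping reference and query preserves the optimal
cost, and the mirrored (I↔D, W↔V) string of the swapped alignment is always
an equal-cost optimum — but not necessarily the character-identical string
the unswapped run returns. This is unavoidable: gap runs such as "ID" and
"DI" cost exactly the same by the machine's symmetry, the co-optimal set is
closed under mirroring, and no five-state string containing a gap or warp
is its own mirror image. Tests therefore verify mirror co-optimality with
an independent path-scoring oracle.

## Downstream statistics

- **Alignment similarity**: percentage of M/V/W characters.
- **Aggregate alignment**: from the terminal landscape cell, repeatedly take
  the modal argmin state across genes (ties again M > W > V > D > I,
  restricted to steps that stay on the grid) and move by that state's step.
  On a single gene-level alignment this reproduces the gene's own string in
  practice (the argmin state along the optimal path can in principle differ
  from the path state, since suffix costs are state-dependent).
- **String distances**: Levenshtein (via edlib) normalized by the longer
  string — the default, since it distinguishes all five states — or Hamming
  on the |R|+|Q| binary match/mismatch encodings. Identical strings are
  deduplicated before the pairwise computation; a battery of thousands of
  alignments typically contains only tens of unique strings.
- **Clustering**: agglomerative, average linkage, on the precomputed
  distance matrix. Auto mode scans thresholds 0.01…1.0 in 0.01 steps,
  reports the full mean-silhouette curve, and suggests the locally optimal
  threshold with the fewest clusters within 0.05 of the best silhouette —
  the curve is always emitted because threshold choice trades resolution
  against interpretability and deserves inspection.
- **Significance of expression distances**: the null distribution pools MML
  distances between disjoint random 50-cell subset pairs drawn within each
  group (50 iterations per gene per group); the observed statistic per gene
  is the distance between random 50-cell subsets of the two groups, so that
  under a true null it is exchangeable with the null draws and p-values are
  uniform (verified by a KS test in the suite). Full-set distances would
  not be exchangeable, because the model-statement terms of the encoding
  scale as 1/X. Right-tail p-values use an add-one guard and are BH
  corrected; the distance-change comparison between two conditions is a
  Mann–Whitney U test.

## The simulator

Each simulated gene trajectory has 300 cells equispaced on [0, 1].

- **Matching**: a mean function μ(t) ~ GP(c·1, 0.25·K_RBF) with
  c ~ U[0.5, 9], RBF lengthscale 0.5; reference and query are independent
  draws μ(t) + σε with σ ~ U[0.05, 1].
- **Divergence**: branch covariance `K_CP(t,t′) = s(t)s(t′)K_RBF(t,t′)`
  with sigmoid s(·) of steepness 50 at t_CP ∈ {0.25, 0.5, 0.75} — zero
  covariance before the change point, RBF after — two branch functions
  f₁, f₂ ~ GP(μ, K_CP), and noise σ = 0.3.
- **Convergence**: divergence pairs with the time axis reversed.
- **Negative control**: independent mean functions with constant levels at
  least 3 apart — no shared process.

**Expected ranges.** Branching can begin slightly before t_CP; the
nondivergent segment is expected to last at least until the first time i
where K_CP's variance exceeds 0.01. Expected match lengths span the integer
hull of [m·i, m·t_CP], mismatch lengths the complement.

**Clear-divergence filter (simulator design).** Raw change-point draws often
produce *ambiguous* ground truth: branches that cross each other, revisit
the base path's value range at a different time (which a value-based aligner
rightly matches), or whose excursions are so large that the global-mean-
centered σ estimates inflate and blur the boundary. Accepted pairs must
therefore (1) have a mean branch gap below 0.25 noise s.d. before t_CP −
0.05; (2) place the branches on opposite sides of the base function's entire
value band for t ≥ t_CP + 0.1, each escaping the band by more than 2 noise
s.d.; and (3) keep that escape below 1.5 log-expression units. The base GP's
output scale (0.25) is kept below the branch kernel's (1.0) so such
escapes are reachable; candidates are drawn in batches with cached Cholesky
factors and resampled until accepted (acceptance is roughly 0.1–10%
depending on the change point). Under these conditions per-pattern template
accuracies land between ~96% and 100%.

**What the simulator does not emulate.** Expression values are Gaussian
around smooth means — no zero inflation, no count noise, no uneven cell
density, no batch structure, and the two trajectories share an exact
pseudotime scale. Passing the battery shows the aligner recovers known
match/mismatch structure under its own generative assumptions; it does not
certify pseudotime estimates or normalization choices on real data. The
real-data perturbation design (bin-wise reference/query splits with deleted
or shifted leading bins, `perturb_split_real_style`) reproduces the
structure of a real-data robustness experiment on any trajectory, including
simulated ones.

Battery clustering at Levenshtein threshold 0.22 recovers one pure cluster
per pattern (mis-clustering 0%). Because the filter yields clean strings
(~20 unique across 3,500 alignments), no additional noise mini-clusters
form, and the cluster count equals roughly the number of patterns rather
than the larger counts seen with noisier generators.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_interp_points` (m) | heuristic, clamp [5, 50] | alignment resolution; explicit user value always wins |
| `window_size` | 0.1 | kernel bandwidth on normalized pseudotime |
| `state_probs` | (0.99, 0.1, 0.7) | Pr(M\|M), Pr(I\|I), Pr(M\|I) — expected run lengths of matches/gaps |
| `initial_probs` | (0.99, 5e-5, 5e-5) | cost of the first alignment state |
| `n_samples_per_point` | 50 | data per interpolation point entering the encoding |
| `R_mu`, `R_sigma`, `epsilon` | 15, 3, 0.001 | prior ranges and datum precision of the encoding |
| `sigma_floor` | 0.001 | lower bound on model σ |

The m heuristic is a Freedman–Diaconis rule on the pseudotime distribution
(minimum over the two trajectories) — a transparent stand-in for fancier
optimal-binning, justified because resolution, not the binner, drives the
alignment, and an explicit m overrides it.

## Numerical choices and limitations

- ∞ is used as the cost sentinel; it propagates safely through `min` and
  additions in the DP borders.
- Model σ values are floored at 0.001 before encoding so all lengths are
  finite.
- The DP is exact (no banding); runtime is O(m²) per gene after the
  vectorized cost matrix, ~2–3 ms per gene at m = 15.
- Branched (tree-shaped) trajectories, adaptive kernel bandwidths, and
  restricting interpolation to nearest neighbors are out of scope.
- Cells sharing a pseudotime value are all used as-is; no jitter is added,
  and batch origin is ignored at interpolation.
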