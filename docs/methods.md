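# Methods

## Sketching and Jaccard estimation

A genome (one FASTA file, possibly many contigs) is decomposed per contig
into windows of k consecutive bases; windows containing any non-ACGT symbol
are skipped, and k-mers never span contig boundaries. Each window is
represented by the lexicographically smaller of the k-mer and its reverse
complement, so sketches are strand-independent. Canonical k-mers are packed
two bits per base (which caps k at 31) and hashed with a MurmurHash3-style
64-bit finalizer applied to the packed word XORed with a mixed seed
(default 42). The finalizer is a bijection on 64-bit words for every seed:
distinct k-mers cannot collide, and the bottom-σ hash values are a uniform
random subset of the k-mer set. Duplicated k-mers collapse before
truncation, so a sketch is shorter than σ only when the genome has fewer
than σ distinct canonical k-mers.

The Jaccard estimator is the merged ("containment-free") form: the σ
smallest values of the union of two sketches act as a uniform sample of the
k-mer union, and ĵ is the fraction of that sample present in both sketches.
When σ is at least the union size this is exactly the Jaccard index, a
property the tests exploit as an oracle.

Parameter resolution: k may be given directly or derived from the
random-match probability q by k = ⌈log₄(g(1−q)/q) − 0.5⌉, clamped below at
1. The length g is the largest genome of the set being sketched (for a
single pair, the longer of the two). σ may be given directly or as a
fraction s of the arithmetic mean genome length of the set. Defaults in
the production pipeline are q = 10⁻⁹ and s = 0.5, the values recommended
for genus-level genome collections.

## Distance transforms

With p̂ = 1 − (2ĵ/(ĵ+1))^(1/k):

* PC: d = −ln(1−p); EI: d = −b₁ ln(1−p/b₂); EI+Γ:
  d = a·b₁·[(1−p/b₂)^(−1/a) − 1], with b₁ = 1 − Σ πᵣ² and
  b₂ = 1 − Σ πᵣˣ πᵣʸ. The EI+Γ form is read as the *product* a·b₁: only
  this reading converges to the EI form as a → ∞ and reduces to the
  standard F81+Γ estimator. For the equal-frequency case (b = 0.75) it is
  the exact closed-form inverse of the Jukes–Cantor+Γ expected p(d) curve,
  verified to 10⁻⁹ in the tests.
* δ = −b₁ ln(1 + ln(1−p)/b₂) is kept as `delta_v11`: it is EI applied to a
  PC distance as if it were a p-distance, a historical implementation
  accident whose behaviour the equivalence fitter explains (it is well
  approximated by EI+Γ with a ≈ 1.1–1.2 on p ≤ 0.35).

Frequency handling in matrices: `global` mode pools per-genome base counts
(weighted by unambiguous length) into one composition, giving a single
b₁ = b₂ for all pairs; `per_pair` mode uses the mean of the two genomes' b₁
values and the cross-composition b₂. Global is the default — compositions
within a genus are similar and a common b keeps the matrix metric-like.

Missingness is explicit: ĵ = 0 carries no signal (p̂ would be 1) and
p̂ ≥ b₂ puts the logarithm/power out of domain. Scalar transforms return
NaN in those cases; `DistanceMatrix` records a reason code (`j_zero`,
`p_exceeds_b2`, `imputed`) per entry. Imputation replaces every missing
d_uv by min over third taxa x of d_xu + d_xv — the tight upper bound the
triangle inequality allows — reading only the original matrix (no
chaining), and fails loudly, naming the pair, when no third taxon resolves
it.

### The equivalence fitter

`fit_equiv_a` minimizes the unweighted sum of squared differences between
the EI+Γ curve and a target d(p) curve over the grid p = 0.001 … 0.35
(step 0.001), by bounded scalar minimization on ln a ∈ [ln 0.01, ln 100]
(`xatol` 10⁻¹⁰, deterministic). The 0.35 ceiling is where sketch-based p̂
stops being reliable, so fitting beyond it would weight a regime the
estimator never sees; results are invariant to halving the grid step to
well below 10⁻³. `fit_a_to_points` is the same objective on scattered
(p, d) points with optional per-point b (for fits pooled across
composition regimes), and `fit_bias_compensated_a` fits EI+Γ evaluated at
βp against EI+Γ(a_target) at p, quantifying how much the shape parameter
must grow to absorb a multiplicative overestimation of p̂ (β ≈ 1.15 is what
sketch estimators exhibit when indels are present).

## Sequence simulation

The substitution model is GTR: Q_ij = r_ij π_j (i ≠ j), rows summing to
zero, scaled so −Σ π_i Q_ii = 1; branch lengths therefore count expected
substitutions per site, and d counts substitution events only (indels are
extra). Transition probabilities use the symmetric similarity transform and
an exact eigendecomposition. Site-rate heterogeneity is continuous: each
site draws ρ ~ Γ(α, mean 1) once and keeps it for its whole history
(inserted sites draw fresh rates); `analytic_p` replaces each eigen-term
e^{λd} by the Γ average (1 − λd/α)^(−α), so simulation and analytic curve
agree in expectation by construction — the tests check agreement within
three binomial standard errors at 10⁵ sites.

Indels: insertion and deletion events each arrive as Poisson with mean
(indel rate) × d × L per branch, positions uniform, lengths Zipf(1.5)
truncated to [1, 50000] sampled by inverse CDF. Deletions are applied
first (marking gaps against the parent), then insertions (gaps in the
parent row); within one branch the order is a convention with no
statistical consequence at these event densities. Site rates do not
modulate indels. Defaults (rate 0.01 per substitution, Zipf 1.5, max
50000) are the regime the validation experiments assume.

Pairs are simulated down a single branch of length d with the ancestor as
one endpoint — equivalent under reversibility to two d/2 branches, which
the tests verify distributionally. `evolve_along_tree` applies the same
branch mechanics down a Newick tree from a stationary root.

Because the 142 maximum-likelihood GTR parameter sets behind the original
benchmarks are external deposits, the package ships a small synthetic
library of six representative exchangeability vectors (transition-biased,
as ML fits to prokaryote genera typically are) and draws Γ shapes
uniformly from the observed range [0.162, 0.422] (mean 0.314). Benchmark
conclusions (homogeneous GTR fits a large shape, GTR+Γ a small one; fitted
pooled shapes land near 0.3) are insensitive to the specific vectors.

## Accuracy statistics

The regression of p̂ on p is through the origin (β = Σ p p̂ / Σ p²); R²
uses the conventional mean-centered total sum of squares. p_r>0.99 scans a
p_max grid (default 0.10 … 0.55, step 0.005) and returns the largest value
whose subset Ψ(p_max) shows correlation exceeding 0.99 by a one-sided
Fisher z-test at the 1% level (subsets with fewer than four usable pairs
are skipped). ĵ = 0 pairs are excluded from regressions but counted in the
cumulative zero-ĵ fraction. Topology recovery is the percentage of
replicates with unrooted Robinson–Foulds distance zero.

## Tree search

Neighbor joining (scikit-bio backend; the three-taxon case is solved in
closed form) initializes a best-improvement NNI hill-climb on the balanced
minimum-evolution length, computed from Pauplin's 2^(1−t_uv) weights. The
ratchet then runs a fixed number of rounds: multiply all distances by
symmetric U(1−ε, 1+ε) noise (ε = 0.2), climb on the noisy matrix, re-climb
and re-score on the original, keep the best score seen. Defaults are 16
rounds: from an NJ start on matrices of the quality this pipeline
produces, the climb converges almost immediately and additional rounds
almost never change the result, so a short schedule keeps full benchmark
sweeps cheap while `rounds` stays configurable for harder matrices. The
search is fully deterministic given its seed. Final branch lengths are
ordinary least squares on the path-incidence system, clamped at zero.
Canonical Newick output (rooted for writing at the neighbor of the
lexicographically smallest leaf, children ordered by smallest descendant
label) makes reruns byte-identical.

## Scales used by the tests and benchmarks

The package's default benchmark configurations use 10⁵-base sequences and
tens of replicates per condition; the published protocol (5 × 10⁶ bases,
200 pairs per divergence step, 20-step grid) is reachable via
`paper_scale=True` and the explicit length/replication arguments. All
statistics involved scale with sequence length in the expected binomial
way, so the reduced runs probe the same properties with proportionally
wider sampling error. What the synthetic benchmarks do *not* emulate:
repeat content and horizontal transfer (real genomes share k-mers for
reasons other than vertical descent), assembly artifacts, contamination,
and genuinely heterogeneous compositions across lineages — conclusions
about real data should lean on the production pipeline's explicit
missing-data handling rather than on the simulator's clean regime. At
desk scale a single Zipf-tailed indel can be a visible fraction of a
10⁵-base genome, so simulated length ratios are far noisier than at 5 Mb;
directional claims about indel-driven length divergence hold, exact
published ratios require full scale.

## Degenerate inputs and numerical conventions

Genomes with no unambiguous residue fail at sketching with a clear error;
identical genomes produce an all-zero matrix, which the pipeline rejects
at the tree stage rather than emitting an arbitrary topology. Jaccard
ties cannot occur (hashes are injective in the k-mer); NJ's occasional
negative branch estimates are clamped to zero. BME comparisons use a
10⁻¹² strict-improvement margin so floating-point ties cannot cycle the
hill-climb. PHYLIP matrices are written tab-separated at 17 significant
digits, which round-trips doubles exactly and makes write→read→write
byte-stable.
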