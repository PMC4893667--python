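# Methods

## Problem and model

`osessl` implements content-based image retrieval over a database that is
described only by an `N x N` symmetric nonnegative dissimilarity matrix
`A` (for example, morphologic dissimilarities between segmented gland
shapes in histopathology). The pipeline has an expensive offline stage and
a cheap online stage.

**Offline (database construction).** Dissimilarities become heat-kernel
affinities `W(i,j) = exp(-A(i,j)/sigma)`. If class labels are known for a
subset of the database, `W` is refined with `gamma = W(i,j)`:

- same known class: `gamma * (1 + gamma)`
- different known classes: `gamma * (1 - gamma)`
- either label unknown: `gamma` (unchanged)

so refined entries stay in `[0, 2]`, vanish with `gamma`, and with no
labels the refinement is exactly the identity. As the affinities approach
1 the refined matrix approaches a block class-indicator structure, which
is what makes supervision effective in the large-`sigma` regime (see
*Bandwidth* below). The refinement form is isolated in
`embedding.label_refinement` so it can be swapped.

The database embedding solves the graph-Laplacian generalized
eigenproblem `(D - W) y = lambda D y`, `D(i,i) = sum_j W(i,j)`, keeping
the `d` smallest eigenpairs after excluding zero eigenvalues (one per
connected component; a disconnected graph is a warning, not an error).
This stage is `O(N^3)`.

**Online (query).** A query contributes only its dissimilarity column
`A(., q)`. Its affinities `W(i,q)` place it in the embedding by the
Nystrom extension of the random-walk operator:

    y_q[k] = sum_i W(i,q) y_i[k] / ((1 - lambda_k) * sum_i W(i,q))

This normalization is the unique weighted-sum form consistent with the
in-sample identity `D^-1 W y = (1 - lambda) y`, so extrapolating the
affinity column of a database image returns that image's stored
coordinates exactly; the test suite enforces this to 1e-10 and treats it
as the correctness contract of the module. The cost per query is
`O(N d)`. Query labels are never used online. Retrieval ranks the
database by Euclidean distance to `y_q`, ties broken by database index.

Baselines share the same interface: ranking by raw `A(., q)`
(high-dimensional), by Euclidean distance after projecting dissimilarity
rows onto top-`d` principal components (PCA), after a
locality-preserving linear projection (LPP), and the unsupervised
spectral embedding (GE), which is exactly the label-refined pipeline with
zero known labels.

## Parameters

- `sigma` (heat-kernel bandwidth, units of the dissimilarity). The
  library default is the median off-diagonal entry of `A`
  (`median_sigma`), which is scale-free. Two regimes matter:
  - *Manifold regime* (`sigma` well below the scale of global structure):
    the embedding recovers intrinsic geometry. For the Swiss-Roll
    experiments we fix `sigma = 0.5` — below the `2*pi` winding gap and
    above the sample spacing at `N >= 500`; there the first embedding
    coordinate tracks the roll parameter with rank correlation ~0.99.
    In this regime affinities are small, so the label refinement (a
    second-order correction in `gamma`) has almost no effect.
  - *Global regime* (`sigma` of the order of the median dissimilarity or
    larger): affinities are moderate-to-large and the label refinement is
    strong. The semi-supervised and metric-comparison experiments run
    here, with `sigma = median(A)`.
- `d` (embedding dimensionality): 2 throughout the synthetic
  experiments; for `Z` well-separated classes roughly `Z - 1` dimensions
  carry the class structure.
- `n`, `m` (protocol fractions): database size as a fraction of all
  images (`N = n * N_all`, the query always excluded) and known-label
  fraction of the database (`M = round(m * N)`), both realized by
  stratified sampling with largest-remainder rounding so per-class counts
  deviate from the target ratio by at most one sample.
- `b`: number of reported hits; evaluation uses the full ranking.

## Numerical choices

- Zero-eigenvalue tolerance: `lambda <= 2e-10` (the generalized spectrum
  lies in `[0, 2]`).
- Eigenvectors: unit `D`-norm (`y^T D y = 1`), sign fixed so the
  largest-magnitude entry is positive; `scipy.linalg.eigh` with
  `subset_by_index` computes only the leading pairs.
- Extrapolation guard: `|1 - lambda_k| < 1e-10` raises an eigenvalue
  singularity error; a query whose affinities all underflow to zero
  raises an isolation error.
- Input hygiene: asymmetries and diagonal residue up to `1e-9` are
  averaged away; anything larger is a format error naming the offending
  cell.
- LPP: features are the centered rows of `A`; the denominator matrix
  `X^T D X` is always rank-deficient after centering and receives a ridge
  of `1e-9 * trace/N` (logged); near-zero eigenvalues (null-space
  directions that project every sample to 0) are discarded as trivial.
  LPP loading vectors are unit-normalized but not mutually orthogonal —
  generalized eigenvectors are `X^T D X`-conjugate, not orthonormal;
  orthonormality is enforced only for the PCA basis.
- AUPRC: precision `p(alpha) = Phi(alpha)/alpha` and recall
  `r(alpha) = Phi(alpha)/R` at every cutoff `alpha`, integrated by
  trapezoid over the achieved `(r, p)` points with a horizontal extension
  from the first point back to recall 0. Relevance is "same class as the
  query". Reported spreads are sample (n-1) standard deviations.
- Silhouette: the standard Rousseeuw per-point `(b - a)/max(a, b)` with
  Euclidean distance in whichever space a metric evaluates
  (dissimilarity rows for the high-dimensional baseline, embedding
  coordinates otherwise); cross-checked against scikit-learn.

## Synthetic data: what it emulates, what it does not

`make_swiss_roll` generates the classic nonlinear manifold
(`t` uniform on `[1.5*pi, 4.5*pi]`, ambient `(t cos t, h, t sin t)`,
isotropic Gaussian noise, default `noise_sd` used in experiments 0.25)
with classes as contiguous equal-count bands of `t`, so class structure
follows geodesic rather than ambient geometry; an interleaved-band option
makes the unsupervised problem harder. `make_blobs` generates Gaussian
clusters with explicit per-class sizes — the experiments use 93/748/47 to
mirror a heavily imbalanced three-class (benign / grade 3 / grade 4)
gland database — with centers on a circle of radius `separation`
(default 1.5, chosen so the unsupervised retrieval baseline sits well
below ceiling, the regime in which label information can matter, as it
does in real grading data).

Dissimilarity is exact ambient Euclidean distance. Real morphologic
dissimilarities are noisy, possibly non-metric, and live in much higher
ambient dimension; passing tests here demonstrates the correctness and
the qualitative behavior of the algorithms (label benefit, database-size
sensitivity, metric ordering), not clinical performance numbers.

## Experiment designs and problem sizes

Two query protocols are used. The leave-one-out protocol
(`build_database` / `run_experiment`, as in the benchmark the method was
designed for) redraws a stratified database for every query and is used
where the comparison needs it, e.g. extrapolation versus full
re-embedding, where "full" means the `n = 1.0, m = 0.0` reference. The
holdout protocol (`holdout_split` / `holdout_experiment`) draws one
stratified database per replicate and uses every excluded image as an
out-of-sample query; it embeds each database once and is used for the
multi-seed sweeps. Queries are always out of sample and their labels are
never revealed.

Problem sizes in the shipped tests and acceptance script: database-size
sensitivity on a 500-point two-class roll with 200 queries per condition;
label benefit (`m = 0.85` vs `0`) on 2000-point rolls and 888-point
imbalanced blobs over 20 seeds; metric ordering on 600-point rolls over
20 seeds; eigensolver agreement on 200 random instances with `N <= 20`;
online-cost scaling timed at `N` of 200 vs 800 (a pure `O(N d)` weighted
sum; the measured ratio is compared against the linear prediction of 4).

## Known limitations

- The dissimilarity is consumed as-is; no metric repair or denoising.
- Supervision can reduce out-of-sample retrieval quality when the
  unsupervised problem is already near ceiling: collapsing classes to
  tight clusters makes boundary queries all-or-nothing. The label benefit
  is a property of the realistic (non-saturated) difficulty regime.
- `LinearProjection` baselines center the dissimilarity rows; a query
  column is assumed to be commensurate with database rows.
- Incremental database updates are out of scope: adding images means
  re-running the offline construction.
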