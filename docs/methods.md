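# Methods

## Data model

All stages operate on a `ModalityBundle`: a set of cells × genes layers
sharing one cell and one gene index. `spliced` and `unspliced` are
required, non-negative, and validated for identical dimensions; optional
layers hold k-NN moments (`moments_spliced`, `moments_unspliced`) and RNA
velocity (`velocity`, the one layer allowed to be negative). On disk the
bundle is a MatrixMarket directory (genes × cells, 1-based, with TSV
metadata sidecars), a loom-layout HDF5 file, or an h5ad container. Layer
alignment is verified by gene/cell *name*, never assumed from storage
order; a layer-specific gene order (sidecar `<layer>_genes.tsv`, or a loom
`Gene_<layer>` row attribute) triggers realignment by gene id.

## Splicing-kinetics simulator

Cells are placed on a milestone trajectory (chain, bifurcation, or
three-phase cycle), each cell drawn on an edge with probability
proportional to edge length and a uniform within-edge fraction. Gene `g`
follows

    du/dt = α_g(t) − β_g u,      ds/dt = β_g u − γ_g s,

with transcription `α_g(t)` switched on while the cell's root path
traverses the gene's active edges (constitutive genes always on). The
latent solution is propagated segment-by-segment with the exact closed
form for piecewise-constant `α`, so the stored ground truth solves the ODE
to solver precision (verified against LSODA in the tests); the true
velocity `v = βu − γs` is stored alongside. Cells start from the
steady state of their constitutive genes, non-constitutive genes from
zero.

Counts are sampled by per-molecule capture: `N ~ Poisson(latent)` thinned
by `Binomial(N, p)` (a pure-Poisson alternative is available). Default
capture efficiencies `p_s = 0.3`, `p_u = 0.1` give realistic few-count
sparsity and a strictly sparser unspliced layer, as in real data where
poly(A) selection depletes intronic molecules. Default rates
(`α ∈ [3, 9]`, `β ∈ [0.4, 0.7]`, `γ ∈ [0.2, 0.35]` per unit pseudotime,
edge length 4) put steady-state spliced abundance at 10–40 molecules and
let transitions play out over roughly one edge. Count sampling uses a
dedicated child RNG stream of the seed so that `add_batch_effects` with
unchanged expected counts and the same seed reproduces the data
bit-for-bit.

Batch effects multiply both layers' expected counts identically (per-gene
log-fold shifts and/or a depth factor) before re-sampling, preserving the
within-batch u/s phase relationship. Condition labels mark a
`balance`-fraction of cells and shift signal genes multiplicatively in a
stated layer subset, enabling "complementary signal" designs where one
layer carries information the other lacks.

Two study fixtures are packaged:

* `complementary_signal_bundle` (400 cells × 80 genes, bifurcation) —
  an early-stimulation design: 12 signal genes shifted by log-FC 1.5 in
  unspliced but only 0.4 in spliced (mature transcripts have not yet
  accumulated), balanced labels. A spliced-only analysis sees a faint echo
  of the class signal; integrated analyses see the full response.
* `complementary_bifurcation_bundle` (300 cells × 80 genes) — branch
  identity carried mainly by nascent transcription: branch-specific genes
  are strongly induced (`α ∈ [20, 35]`) but slowly spliced
  (`β ∈ [0.25, 0.35]`), so over a short branch (length 1, backbone 4)
  unspliced rises ~linearly in time while spliced accumulates only
  ~quadratically; capture is `p_u = 0.25`, `p_s = 0.3`.

What the simulator does **not** model: gene-regulatory feedback, per-cell
kinetic heterogeneity, doublets, ambient contamination, or empirical
overdispersion beyond capture thinning. Passing tests therefore show the
machinery is correct and the qualitative orderings hold under clean
kinetics — not that they hold on any given real dataset.

## Preprocessing

QC keeps a gene iff it is expressed (S+U > 0) in ≥ 5 cells *and* carries
≥ 5 total joint counts, and keeps a cell iff < 20 % of its spliced counts
map to mitochondrial genes (prefix match). Size factors are computed on
the joint S+U counts — one factor per cell dividing both layers, so
normalization cannot distort the phase space; `library_size` is the
default, with a simplified pooled option (ring pools of 20 cells
deconvolved by least squares) standing in for full pooling normalization.
With `batch_rescale`, factors are centered within batch and multiplied by
the per-batch median ratio of per-gene average counts against the
shallowest batch, downsampling deeper batches toward it. Highly variable
genes use the dispersion flavor: variance/mean of log1p data, z-scored in
20 equal-count mean bins, flagged iff `0.012 < mean < 5` and normalized
dispersion ≥ 0.25. Geometric sketching scales a PCA embedding to the unit
box, binary-searches the grid resolution so the occupied equal-volume
hypercube count ≈ the target sketch size, and samples occupied boxes
round-robin — rare populations are sampled at least at their share of
occupied space.

## Joint batch correction

Correcting spliced and unspliced independently can tilt the per-gene u/s
phase portrait that velocity fitting depends on, so correction happens on
a combined representation: either the summed log matrix
`M = log(S+U+1)` with the spliced ratio `R = S/(S+U)` carried through
unchanged and inverted as `S_c = exp(M_c∘R) − 1`, `U_c = exp(M_c∘(1−R)) − 1`
(both clipped at 0; `R := 0` where `S+U = 0`, forcing both corrected
entries to 0), or the cell-wise concatenation of both log1p layers
corrected in one call. Correctors are pluggable `(matrix, batches) →
matrix` callables registered by name; the built-in `location_scale`
corrector standardizes each gene per batch and restores the pooled
moments. Three quality metrics: kBET (χ² goodness-of-fit of size-10
neighborhood batch composition vs global, rejection rate at α = 0.05;
neighborhoods are the cell plus its 9 nearest neighbors, zero-expectation
categories are merged, a single batch scores 0 by definition), LISI
(Gaussian-kernel neighbor weights calibrated to perplexity 30 by
bisection, inverse Simpson's index of batch probabilities ∈ [1, #batches]),
and phase-space preservation (per gene and batch, Pearson correlation of
pairwise cell distances in the (s, u) plane before vs after correction,
averaged over batches; zero-variance genes return NaN and are excluded).

## Velocity

Moments are means over the size-k Euclidean neighborhood (cell plus k−1
nearest, k = 10) in the top-50 PCs of the spliced layer — a row-stochastic
smoothing. The steady-state estimator fits, per gene, the zero-intercept
least-squares slope of `Mu` on `Ms` restricted to cells in the upper 95 %
and lower 5 % quantiles of `Ms`, and sets `V = Mu − γ̂ Ms`. On noiseless
steady states the slope equals `γ/β` exactly. Genes with all-zero `Ms`
get `γ̂ = 0` (so `V = Mu`). The estimator deliberately replaces a full
dynamical-model fit: integration consumes velocity only as an input
layer, so any consistent estimator exercises the downstream machinery.

## Integration strategies

Every strategy returns a k-NN graph (k = 10, unit connectivity weights or
similarity weights, zero diagonal) with rows aligned to the input cell
order; distance ties break toward the lower cell index for
reproducibility. Most strategies consume the normalized log spliced and
unspliced layers; the Markov-blending strategy consumes spliced moments
plus velocity.

* **Baselines** — PCA(50) + k-NN on: spliced alone; the horizontal
  concatenation (n × 2d); the element-wise sum (n × d). A summed matrix
  with no variance raises a clean degenerate-input error.
* **Markov blending** — the expression operator `P_s` is the uniform
  random walk on the k-NN graph; the velocity operator `P_v` scores each
  neighbor by the similarity (cosine, correlation, or standardized dot
  product) between the cell's velocity vector and the displacement to the
  neighbor, pushed through an exponential kernel and normalized
  (zero-velocity cells fall back to uniform). The blend
  `P = λP_v + (1−λ)P_s` is symmetrized and its k strongest entries per
  row become the graph. `λ` has no canonical default and is a required
  configuration value (0.5 in the CLI).
* **Similarity network fusion** — locally adaptive heat kernel
  `W_ij = exp(−d²_ij/(μ ε_ij))` with
  `ε_ij = (mean_d(i,N_i) + mean_d(j,N_j) + d_ij)/3`; cross-diffusion
  `P₁ ← S₁ P₂ S₁ᵀ` (and symmetrically) for 20 rounds using the k-NN
  truncated row-normalized kernel as carrier, each round symmetrized with
  the self-affinity re-added (the stabilized canonical update; a bare
  re-normalized update oversharpens onto local cliques). The fused
  affinity's unnormalized Laplacian `L_u = D − A` is eigendecomposed; the
  embedding spans the bottom `K_eigs` eigenvectors with the constant mode
  projected out (robust to the degenerate null space of a disconnected
  fused graph).
* **Grassmann joint embedding** — per modality, heat kernel
  `exp(−d²/2t²)` (t defaults to the median pairwise distance), k-NN
  truncated and max-symmetrized; normalized Laplacian
  `L_n = D^{−1/2}(D−W)D^{−1/2}` with eigenvalues in [0, 2]; the merged
  operator `L_mod = Σ L_n^m − α Σ U^m U^{m⊤}` trades modality structure
  (first term) against subspace agreement (second); embedding = bottom
  `K_eigs` eigenvectors.
* **Alternating diffusion** — per modality: spectral clustering, per-
  cluster truncated SVD keeping ≥ 90 % variance (local denoising), then a
  row-normalized adaptive Gaussian operator; diffusion times from the
  spectral-entropy elbow (smallest `t` whose entropy decrement falls below
  5 % of the total decay up to `t_max = 16`), reduced by their ratio;
  `P_j = P₁^{t₁} P₂^{t₂}`, itself powered by the same rule; embedding =
  top `K_eigs` eigenvectors by eigenvalue magnitude (real parts).
* **Principal vectors** — SVD of the cross-product of the two top-`n_pv`
  PCA loading matrices pairs up directions ordered by non-increasing
  cosines of principal angles; `principal_vectors` projects the first
  modality onto its own side, `consensus` onto the geodesic midpoint
  (slerp at the half-angle; antipodal pairs keep the first-modality side).
* **Weighted nearest neighbors** — within- and cross-modality neighbor-
  average predictions of each cell's PCA profile; per-cell modality
  ratios `(err_cross − err_within)/σ_i` (σ = distance to nearest
  neighbor) softmaxed into weights summing to 1; joint similarity =
  weight-blended exponential kernels; graph = top-k joint similarities.
* **Shared factor model** — `X^m = Z W^{m⊤} + ε^m` by alternating least
  squares with ridge `1e−8`, random `Z` init from the seed; the penalized
  objective is non-increasing by construction and iteration stops at
  relative change < 1e−9. The variational sparsity priors of the original
  factor-analysis formulation are out of scope; plain ALS suffices for a
  Gaussian likelihood.

## Trajectory evaluation

Cluster-graph connectivity is PAGA-like: observed inter-cluster edge mass
over its expectation under uniform random placement of the same total
mass, capped at 1 (the exact reference statistic is not published; this
normalization is documented as our choice). Edges above a threshold
(default 0.05) are kept and oriented by ascending median cluster
pseudotime from each root. Diffusion pseudotime uses the symmetrized
graph with anisotropic (α = 1) density normalization, the top 20
nontrivial components ψ_k weighted by λ_k/(1−λ_k), min–max scaled; the
density normalization recovers trajectory geometry independent of
sampling density and measurably improves agreement with the latent time
on simulated data. Cells are placed on the edge entering their cluster
(root-cluster cells on the strongest outgoing edge, occupying its first
half) with min–max-normalized within-cluster pseudotime as the fraction;
milestones with no surviving edge are flagged, self-looped, and sit at a
finite distance cap (the milestone count) so scores remain defined.

Scoring against a reference: geodesic cell distances on the milestone
network (unit edge lengths plus within-edge offsets; same-edge pairs use
the direct offset difference), compared by Spearman correlation over all
pairs or a seeded sample (`C_corr`); per-gene random-forest regressions
(100 trees, out-of-bag R² floored at 0) of expression on cell-to-milestone
distances, compared by Pearson correlation of the score vectors
(`F_corr`; constant vectors return 0 with a flag); and
`TI_corr = 2·C_corr·F_corr/(C_corr+F_corr)` with negative inputs clipped
to 0 first (the harmonic mean is undefined across signs). Ten random
root cells are drawn from the annotated root cluster per evaluation.

## Classification evaluation

Label propagation on the symmetrized graph: one-hot training rows, zero
test rows; iterate `y′ ← D⁻¹W y′`, row-normalize, clamp training rows;
converged when the largest entry change < δ = 0.001 (cap 10 000
iterations, then an error naming δ). The fixed point on the unlabeled
block coincides with the closed-form harmonic solution
`(I − P_uu)^{−1} P_ul y_l`, which the tests verify to 1e−6 on random
graphs. Components containing no labeled cell are flagged unreachable and
assigned uniform probabilities (and still count in the metrics). Splits
are stratified; ten random training initializations re-sample the split
each time (the train fraction, default 0.5, is a configuration value).
Metrics are computed by hand and cross-checked against scikit-learn in
tests: F1 on the positive class (second sorted label) or macro for
multiclass; balanced accuracy = (sensitivity + specificity)/2, multiclass
mean per-class sensitivity; AUC by the rank-sum (Mann–Whitney)
formulation on soft probabilities, one-vs-rest macro for multiclass.
Argmax ties break to the lower class index. Aggregation: per (dataset,
task, metric) the method score is the median over replicates, min–max
scaled across methods within the dataset (an all-tied dataset scores 0.5
for every method, flagged), averaged across datasets, ranked descending.

## Reproduction protocols and problem sizes

The packaged headline comparisons (`modalfuse.reproduce`) use 400-cell /
80-gene classification datasets (10 simulation seeds, 10 splits each) and
300-cell / 80-gene bifurcation datasets (3 simulation seeds, 10 roots, 8
highest-variance genes in the forest scoring) — sizes chosen so the full
reproduction runs in minutes on a laptop core while keeping the
qualitative contrasts well outside split-to-split noise for the
classification task. Similarity network fusion is tuned over its
benchmark grid (k ∈ {20, 30}, μ ∈ {0.5, 0.8}, K_eigs ∈ {10, 20}) per
dataset on the task score, mirroring the benchmark protocol in which
every method's hyperparameters are tuned; the spliced-only baseline has
no hyperparameters.

A known limitation follows from the scale: in the trajectory task the
fused graph and the spliced-only baseline score within the root-to-root
noise of the diffusion-pseudotime pipeline (≈ ±0.03 in median TI
correlation), so the fused-vs-baseline ordering is a statistical tie on
any single simulated dataset — self-fusion experiments show the fusion
iterations cost about as much fine-grained ordering as the second
modality adds at these counts. The classification contrast, by
comparison, is large and stable. Other numerical choices: PCA uses full
SVD for determinism; eigendecompositions use symmetric solvers wherever
the operator is symmetric or has a symmetric conjugate; all randomness
flows through explicit integer seeds.
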