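# Methods

## Problem setting

The package addresses transductive node classification in sparsely labeled
attributed networks, with protein–protein interaction (PPI) networks as
the motivating case: given a graph over N nodes, an M × N non-negative
attribute matrix **X**, and class memberships **Y** (q × N, binary) known
for only a small fraction n′/N of nodes (typically 2–10%), predict the
classes — or a ranking of classes — for the remaining nodes. At such label
fractions most unlabeled nodes have no labeled neighbor, so methods that
propagate labels only along observed edges degrade badly; the approach here
combines attribute reconstruction, label reconstruction, and smoothness
over a *constructed* similarity graph in a single factorization.

## Latent graphs

Three N × N non-negative symmetric similarity graphs are built from
different views of the data:

1. **Interaction graph** — the observed network, binarized
   (weight 1 iff an edge exists).
2. **Even-step random walk with restart (ERWR)** — walks on the squared
   adjacency **P** = colnorm(**E·E**) only land an even number of hops
   away, scoring nodes that share many interaction partners even when not
   adjacent. The accumulated weight after T steps with restart probability
   a is R = Σ_{t=1..T} a(1−a)^t **P**^t. Defaults: a = 0.1, T = 10
   (the tail factor 0.9¹⁰ ≈ 0.35 still carries mass; longer horizons add
   little but cost). Column normalization breaks symmetry, so the result
   is symmetrized as (R + Rᵀ)/2 — the downstream graph Laplacian requires
   a symmetric weight matrix, and symmetrization also makes the
   row-versus-column reading of "probability i reaches j" immaterial.
   Columns of **E·E** with zero sum (nodes without two-hop neighbors)
   carry no mass and are left zero with a warning.
3. **Prediction-similarity graph** — a probabilistic classifier
   (multinomial logistic regression by default; any estimator with
   `fit`/`predict_proba` can be passed) is trained on the labeled nodes'
   features; the graph weight between two nodes is the cosine similarity
   of their q-dimensional class-probability vectors. Confidences are
   computed for *all* nodes, labeled ones included, because the
   integration step needs similarities among labeled nodes.

### Graph integration

The graphs are combined as Ê = Σᵢ wᵢ E⁽ⁱ⁾ with **w** on the probability
simplex. **w** is fit on the labeled submatrices Ē⁽ⁱ⁾ against the ideal
similarity target ȲᵀȲ (entry (i,l) counts classes shared by labeled nodes
i and l):

    min_w ‖Σᵢ wᵢ Ē⁽ⁱ⁾ − ȲᵀȲ‖²_F + λ‖w‖²,   Σwᵢ = 1, wᵢ ≥ 0,   λ = 0.01.

Because t (the number of graphs) is tiny, this convex QP is solved
*exactly* by active-set enumeration: for each of the 2ᵗ−1 support subsets
the equality-constrained KKT system is solved in closed form and the best
non-negative candidate is kept. A vectorized brute-force simplex grid
search is shipped alongside as an independent oracle; the tests check the
solver beats every grid point at resolution 0.001. Graphs enter the
combination unscaled — the weights absorb scale differences in the *fit*,
though not in the downstream Laplacian (see Limitations).

## Regularized factorization

All three couplings share one coefficient matrix V (N × K, rows z_j):

    O(U, B, V) = ‖X − UVᵀ‖²_F
               + α Σ_{ij} W_ij (Y − BVᵀ)²_ij
               + β Tr(Vᵀ L V),       L = D − Ê,  D_jj = Σ_l Ê_jl,

with U (M × K) the feature basis, B (q × K) the label basis, and W a
q × N confidence mask: for labeled nodes W = 0.01 where Y = 1 and W = 1
where Y = 0; unlabeled columns are 0. The asymmetry deliberately pushes
BVᵀ hard toward 0 at known absences while only loosely toward 1 at known
memberships. Tr(VᵀLV) = ½ Σ_{jl} ‖z_j − z_l‖² Ê_jl penalizes
representations that vary across strong latent edges.

On the label term's norm: the masked misfit is the **W-weighted** squared
Frobenius norm (each squared residual scaled once by its weight). This is
the form whose gradient the multiplicative updates below majorize; reading
the mask as inside the square would square the weights and forfeit the
monotonicity guarantee.

Minimization alternates multiplicative updates (ε = 10⁻¹² floors every
denominator):

    U ← U ⊙ (XV) ⊘ (UVᵀV)
    B ← B ⊙ ([W⊙Y]V) ⊘ ([W⊙BVᵀ]V)
    V ← V ⊙ (XᵀU + α[W⊙Y]ᵀB + βÊV) ⊘ (VUᵀU + α[W⊙BVᵀ]ᵀB + βDV)

Each pass is non-increasing in O (verified over randomized instances to
1e−9 relative slack); with α = β = 0 the U and V updates coincide exactly
with plain NMF, and the test suite checks trajectory equality to 1e−10.

### Initialization and label reset

K is set to q so each coefficient column is identified with one class.
V starts from the labels: labeled rows copy their binary membership
vectors; every unlabeled row is set to the empirical class priors among
labeled memberships. After each pass the labeled rows of V are reset to
their one-hot values, so the supervision survives the fit exactly; since
the updates are multiplicative, zeros in those rows are invariant anyway
and the reset only rescales the active entries.

U is warm-started by projection, U = X·V_init (floored at 10⁻⁶ and
rescaled by its maximum), anchoring each basis column to the feature mass
of the class its coefficient column represents. This choice is deliberate:
with uniform-random U the column↔class alignment is decided by the
(unsupervised) reconstruction term, and on benchmark fixtures roughly one
fit in ten converged to a *label-permuted* local minimum — perfect block
structure, cyclically wrong class identities — that the few reset rows
could not escape. B starts uniform (0, 1) from the run's seeded generator.
A `v_init="random"` mode initializes U, V uniformly instead (drawn in the
same order as the plain-NMF fitter, so the unregularized reduction is
bit-comparable).

### Stopping, defaults, determinism

Iteration stops when the relative objective change falls below
tol = 10⁻⁶ or after max_iter = 200 passes; on the bundled benchmarks the
relative change falls below 10⁻⁴ within ~30–45 passes. Defaults α = 10,
β = 5 (both terms matter over a broad plateau; accuracy degrades toward
the unsupervised and unsmoothed corners), λ = 0.01, restart 0.1. All
randomness flows from explicit integer seeds through `numpy` generators;
identical seeds reproduce fits bit-for-bit.

### Prediction readouts

Single-label: argmax over each unlabeled V row, ties to the lowest class
index; an all-zero row (no signal) falls back to the most frequent labeled
class with a warning. Multi-label: classes sorted by descending row score
(stable in class index), evaluated by coverage (mean depth down the
ranking needed to collect all true labels, minus 1) and ranking loss (mean
fraction of (true, false) class pairs ordered wrongly; ties count as
errors, so all-tied scores give loss 1). Both depend only on score order
and are invariant to monotone transforms. Node-pair interaction strength
is the cosine of two V rows.

## Synthetic benchmark generator

The generator emulates the structure of curated PPI benchmarks: a
planted-partition graph (within-class edge probability 0.05, across 0.005
at N = 300 — mean degree ≈ 6 with strong but imperfect assortativity),
binary indicator features (mirroring categorical protein attributes such
as chromosome, essentiality, phenotype, motifs), and an optional
multi-label mode (primary class from the partition, up to two extra
memberships with probability 0.2 each). Informative features fire with
probability 1 − noise_rate on their class and noise_rate elsewhere;
the default feature budget (20 features, 40% informative, noise 0.2) is
calibrated so a features-only logistic regression at a 5% label split
scores ≈ 0.74 — the difficulty band reported for attribute-only baselines
on the yeast benchmark this emulates. A `kddcup_like` preset reproduces
that benchmark's scale (1,243 nodes, ≈1,806 expected edges, 14 classes,
multi-label).

What the generator does **not** emulate: the real class-frequency skew,
correlated/hierarchical feature schemas, hub-dominated degree
distributions, or missing-at-random feature blocks. Passing recovery
tests therefore demonstrate correct mechanics and the expected qualitative
behavior under assortativity, not field performance on real PPI data.

## Pipeline composition on small-q fixtures

The recovery benchmarks integrate the interaction and ERWR graphs. The
prediction-similarity graph is constructed and tested, but it is excluded
from the default *benchmark* pipeline for a documented reason: with q = 3,
class-probability vectors live on a 2-simplex where cosine similarity has
a high floor, so the graph is near-complete (mean weighted degree ~150 of
300). The weight learner — which sees the classifier's own training nodes,
where confidences are nearly one-hot and the restricted submatrix nearly
matches the target — then hands it most of the mass, and the resulting
Laplacian term (β × degree ≫ the data terms) smooths every representation
toward the global class prior. Cross-fitting the labeled nodes'
confidences (leave-one-out) softens but does not cure this. The
construction is most useful when q is large enough, and the classifier
confident enough, for the cosine floor to sit well below within-class
similarity; users choose the graph set per dataset via
`PipelineConfig.graphs`.

## Numerical choices and degenerate inputs

- Multiplicative-update denominators floored at 10⁻¹²; NaN/Inf in any
  factor aborts with the iteration number.
- Laplacian construction rejects asymmetry beyond 1e−10.
- The weight-learning QP rejects solutions violating the simplex beyond
  1e−8 (cannot occur with the exact enumeration, but the contract is
  checked).
- Uniform label splits warn — not fail — when a class loses all labeled
  representatives; the factorization then cannot assign that class to any
  unlabeled node, which is the honest transductive behavior.
- Tie-breaks everywhere (argmax, rankings, coverage ranks) resolve to the
  lowest class index, making every readout deterministic.

## Known limitations

- Simplex weights absorb scale differences in the integration *fit* but
  not in the Laplacian: a dense graph in the combination can still
  dominate smoothing. Per-graph normalization was deliberately not
  applied (the combination is fit on the graphs as constructed); the
  composition knob is the supported control.
- The method is transductive: nodes absent at fit time cannot be scored.
- Convergence to a *global* minimum is not guaranteed (multiplicative
  updates reach a local minimum); the projection warm start removes the
  label-permutation failure mode observed with random starts but other
  local minima remain, particularly when a class has ≤1 labeled anchor.
- Objective monotonicity is verified empirically over randomized
  instances rather than proven; the label-row reset can in principle
  perturb monotonicity, though in practice the recorded traces are
  strictly non-increasing (the reset only rescales entries the updates
  left structurally intact).
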