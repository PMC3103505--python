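# Methods

`tractnet` implements a structural brain-network discrimination pipeline for
two-group (control vs. dysmyelinated) mouse studies: diffusion-tensor
tractography → weighted connectome construction → backbone extraction → six
weighted graph measures → max-t permutation group comparison → leave-one-out
LDA classification in per-measure representation spaces. This note documents
the models, the numerical choices, and what the synthetic data do and do not
emulate.

## Connectome construction

A fiber trajectory connects the two gray-matter regions containing its
endpoints (an endpoint rule, not a passes-through rule). The arc weight
between regions *i* and *j* is

    w(a_ij) = 1/(n_i + n_j) · Σ_{f ∈ F_ij} (1/N_f) Σ_steps 1/MD(step)

where F_ij is the set of connecting trajectories, N_f the number of steps of
fiber *f*, MD the local mean diffusivity sampled at each step, and n_i the
number of superficial (surface) voxels of region *i*. Mean diffusivity falls
when myelin and membranes restrict water mobility, so 1/MD acts as an
indirect per-fiber integrity index; the weight is an "effective number of
connecting fibers" normalized by the interface size of the two regions.
Variants: `mean_fa` replaces the inner mean of 1/MD by the mean fractional
anisotropy along the fiber; `count` uses 1 per fiber. Surface voxels are
6-connected boundary voxels of the region's label volume; matrix-only
pipelines supply n_i explicitly (default 1).

The connectivity backbone keeps the maximum spanning tree (maximal total
weight, so every node remains reachable through its strongest routes) and
then adds the remaining edges in strictly decreasing weight order until the
average node degree 2|E|/n first reaches the target (default 4, hence
exactly 2n edges on a sufficiently dense n-node input). Equal-weight ties
are broken by ascending node-index order, making extraction deterministic.
A disconnected input is reduced to its largest component with a warning.

## Tractography

Deterministic trackers on a voxel grid of diffusion tensors, with
nearest-neighbor (voxel-wise) field lookup:

* **FACT** follows the principal eigenvector e1 of the current voxel.
* **TEND** (tensor deflection) propagates v_out ∝ D·v_in.
* **TL** (tensorline) blends the two by the local anisotropy,
  v_out ∝ FA·e1 + (1 − FA)·D·v_in.

Eigenvector sign is chosen to keep dot(v_new, v_old) ≥ 0. One bidirectional
streamline starts at each seed-voxel center; seeds are all voxels with
FA > 0.12 (brute-force seeding). Defaults: 25 µm step, 200 mm maximum trace
length (split evenly between the two directions), ±80° per-step curvature
threshold. Termination: sub-threshold FA, excessive turn, leaving the
volume, or reaching the length cap. On spatially constant, axially
symmetric fields the three trackers coincide exactly (e1 is a fixed point of
D·v), which the tests exploit. Interpolation beyond nearest-neighbor lookup
and probabilistic tracking are out of scope.

## Graph measures

All measures operate on symmetric nonnegative weight matrices.

* **Clustering C** (per node, averaged): geometric mean of triangle weights,
  C_i = [1/(k_i(k_i−1))] Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}, with ŵ = w/max(w)
  by default so C_i ∈ [0, 1]; `scaled=False` leaves weights untouched, which
  reproduces magnitudes ≫ 1 on strongly weighted networks. Nodes of degree
  < 2 contribute 0.
* **Characteristic path length L**: arc length l_ij = 1/w_ij (stronger
  connections are "shorter"); geodesics by dense Floyd–Warshall (the C
  implementation in scipy; Dijkstra above 400 nodes); L is the mean over
  ordered pairs. Disconnected inputs are rejected (E_glob is the measure
  that tolerates them, contributing 0 per disconnected pair).
* **Global / local efficiency**: E_glob = mean of 1/l over ordered pairs;
  E_loc averages E_glob of each node's first-neighbor subgraph (node
  excluded; fewer than two neighbors contributes 0).
* **Modularity Q** on weight fractions: Q = Σ_c (e_cc − a_c²). Partitions
  are found by Newman's spectral method: recursive leading-eigenvector
  bisection of the modularity matrix B = W − kkᵀ/2m (generalized form for
  subgroups), each bisection refined by a Kernighan–Lin-style pass that
  greedily flips single nodes, keeps the best intermediate state, and stops
  when a pass yields no improvement above a relative tolerance (passes are
  capped at 100 to guard against float-noise cycling). Groups are left
  intact when no split increases Q.
* **Small-worldness σ = γ/λ**, γ = C/⟨C_rand⟩, λ = L/⟨L_rand⟩, over an
  ensemble (default 20) of random references that preserve the degree
  sequence (double-edge swaps, default 5× the edge count) and the weight
  multiset (weights reassigned uniformly at random to the surviving edges).
  Swaps run in windows of 100 with rollback of any window that disconnects
  the graph, so null draws are connected by construction; a residual
  disconnected draw is resampled (bounded retries). σ > 1 indicates
  small-world organization; with a zero-swap (self-referenced) null,
  γ = λ = σ = 1 exactly.

A caveat quantified during development: on a 150-node degree-4 backbone a
degree-preserving random reference carries only a handful of triangles, so
per-draw C_rand has a coefficient of variation near 0.35 (Poisson counting
noise) and the 20-draw σ estimate inherits a ~8% standard error. σ is
therefore the noisiest of the six measures at the default ensemble size, and
group effects on σ smaller than roughly 15–20% are not reliably detectable
in a 6 vs 6 design. Raising `ensemble_size` reduces this error as 1/√m at
proportional cost.

## Group comparison

For each measure, subjects contribute one value per tracking variant. Per
variant a pooled-variance two-sample t statistic is computed; the test
statistic is max|t| over variants, whose permutation distribution (group
labels reassigned across subjects) controls the family-wise error over the
simultaneous per-variant comparisons. All C(12, 6) = 924 assignments are
enumerated when feasible (≤ 20,000; always for 6 vs 6), otherwise a seeded
Monte-Carlo sample is drawn; the identity assignment is counted in numerator
and denominator, so p ≥ 1/924 > 0 and the test is exactly valid. The test
is two-sided (|t|) since both increases (L) and decreases (the other
measures) are of interest. Zero pooled variance with zero mean difference
yields t = 0 (all permutations tie, p = 1).

## Representation spaces and classification

For measure X, subject *i* is the point whose N coordinates are the X values
from the N tracking variants (N = 3: "length, width, depth"); M measures
concatenate to an M·N-dimensional space with a deterministic layout
(measures in declared order, variants within measure). Classification is
leave-one-out LDA: pooled within-class covariance with diagonal ridge
loading λ·trace(Σ)/d (λ = 1e−6 — with 11 training points in up to 18
dimensions the pooled covariance is singular and some regularization is
unavoidable), equal class priors (the design is balanced 6 vs 6), posterior
P(control|x) from the linear log-odds, prediction at posterior > 0.5
(a posterior exactly at threshold counts as an error and is logged). The
"mean boundary hyperplane" averages per-fold coefficient vectors after
normalizing each to a unit normal. Forward sequential selection ranks
measures by single-measure LOO accuracy (ties broken by the canonical order
C, L, Q, E_glob, E_loc, σ) and appends the next-ranked measure's coordinates
while the combined accuracy strictly improves; the combined accuracy
therefore never falls below the best single measure. Percent correct is
rounded to two decimals.

## Synthetic cohorts

The generator emulates the statistical design of a 6 vs 6 control/mutant
study without any imaging data. The shared base graph is a weighted
planted-partition graph: 150 nodes in 6 equal modules, within-module edge
probability 0.3, between-module 0.02, log-normal weights
(median `base_weight`, log-sd 0.25). Weights are coupled to topology:
within-module edges are boosted ×2, and a fraction 0.15 of between-module
edges receives the same boost, emulating the strong long-range projection
tracts (e.g. callosal fibers) that keep healthy connectomes topologically
short-pathed. Without this coupling the backbone samples edges independently
of module structure and the case-group effects below become erratic; with
it, healthy backbones are strongly clustered *and* efficiently bridged,
which is the regime real structural connectomes occupy.

The case ("shiverer-like") group shares one altered base — appropriate for a
genetically homogeneous mutant line: `rewire_frac` (default 0.1) of the
edges rewired by degree-preserving double-edge swaps (weights travel with
edges; one swap rewires two edges, so ⌈frac·E/2⌉ swaps are performed, with
connectivity enforced by retry), then all weights multiplied by
(1 − `attenuation`) (default 0.3). Each subject then receives independent
multiplicative log-normal edge jitter (`subject_noise`, default 0.05), and
each of the three tracking-variant replicas another (`algo_jitter`, default
0.05; at 0.05 the variants' upper-triangle weights correlate above 0.9, as
intended for three algorithms reconstructing the same anatomy).

Mechanistically, uniform attenuation never changes which edges the backbone
selects and cancels exactly in the scaled measures (C, Q, γ, λ, σ); it
drives L up and E_glob/E_loc down. Rewiring relocates strong within-module
edges to essentially random (mostly between-module) positions; in the
backbone these displace the weakest selected edges, lowering clustering and
modularity. The same displaced edges act as shortcuts, so rewiring *raises*
topological efficiency — with the projection-tract coupling above, healthy
networks already possess efficient bridges and the shortcut gain stays well
below the attenuation loss, keeping the E_glob and L effect directions
stable. All randomness derives from one `numpy.random.SeedSequence`: one
child for the base graph, one for the case rewiring, one per subject (split
into jitter and variant streams), making cohorts bit-reproducible.

What the generator does **not** emulate: real mouse neuroanatomy or atlas
geometry, scanner noise, tractography biases (crossing fibers, distance
bias), unequal region sizes, or between-subject topological variability
beyond weight jitter. Passing tests on these cohorts demonstrate that the
pipeline recovers effects of the modeled kind at realistic sizes — not
performance on real DW-MRI data.

Tensor phantoms for the tracking stage place axially symmetric anisotropic
tensors (principal axis along the local bundle tangent) inside cylindrical
polyline bundles in an isotropic background. Eigenvalues are obtained in
closed form from the target FA: for λ = (x, 1, 1)·c,
FA = (x − 1)/√(x² + 2), hence x = (1 + FA·√(3 − 2FA²))/(1 − FA²), scaled to
the target MD (defaults: FA 0.8 inside, MD 7·10⁻⁴ mm²/s everywhere, 80 µm
voxels). Bundle end-caps (first/last `cap_length` mm) are labeled as
distinct parcellation regions; overlapping caps are rejected.

## Problem sizes and determinism

Default analyses run at the study scale (150 nodes, 6 vs 6 subjects, 3
variants, ensemble 20, exact 924-permutation tests); a full pipeline
replicate takes a few seconds on one core, and the replicate-based checks in
the test suite use 25–50 cohorts. All stochastic stages take explicit seeds;
two runs from the same configuration produce byte-identical summaries. The
exact permutation denominator, backbone tie-breaking, and representation-
space coordinate layout are all deterministic by construction.

## Known limitations

* The σ ensemble noise described above makes small σ effects statistically
  invisible at the default ensemble size.
* Scaled clustering divides by the single largest weight, so C is sensitive
  to the weight distribution's extreme order statistic; `scaled=False` is
  available when absolute magnitudes are wanted.
* The spectral modularity optimizer is a heuristic; on small graphs it
  matches exhaustive search in the tests, but global optimality is not
  guaranteed in general.
* LDA posteriors far in the tails saturate to 0/1 in double precision; the
  decision rule is unaffected.
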