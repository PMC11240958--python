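# Methods

## Overview

`molnet` treats a molecule library as four weighted networks, one per
dissimilarity (Euclidean in descriptor space, Tanimoto and Hamming on
fingerprints, Levenshtein on SMILES), and pushes each through the same
chain: dense distance matrix → similarity transform → TMFG planar filter →
weighted centralities → two community detections → partition comparison →
per-descriptor non-parametric tests. This note records the model choices,
defaults, numerical conventions and known limitations.

## Descriptor assembly

Each molecule is summarised by 12 descriptors in fixed order: molecular
mass (amu), MMFF94 energy (kcal/mol, reference-normalised), Crippen cLogP
and molar refractivity, geometric eccentricity of a 3D conformer (in
[0, 1]), Kier kappa-1/2/3, synthetic-accessibility score, TPSA (Å²), and
the Shannon entropies of the 2D and 3D autocorrelation vectors. Raw
per-molecule quantities come from an RDKit adapter; 3D-dependent values
(MMFF energy, eccentricity, 3D autocorrelation) use a single ETKDGv3
conformer embedded with a fixed, configurable seed, so descriptor tables
are reproducible bit-for-bit. We deliberately do not average over
conformer ensembles; the conformer seed is part of the analysis
configuration.

Two post-processing steps are bespoke:

* **MMFF normalisation.** Raw MMFF94 energies are not comparable across
  non-isomeric compounds, so a reference energy is subtracted. Default
  reference: the minimum energy in the input set (`min-reference`), which
  makes the column non-negative and dataset-relative; an
  `index-reference(i)` strategy is available when an external reference
  structure is meaningful. Pairwise differences are preserved exactly
  under any reference choice.
* **Autocorrelation entropies.** The 2D (192-long) and 3D (80-long)
  autocorrelation vectors are collapsed to scalars via Shannon entropy of
  the absolute-value-normalised vector, `p_i = |v_i| / Σ|v_j|`,
  `H = −Σ p_i log p_i`. Natural log by default (`--entropy-base`
  configurable); the absolute-value normalisation is our choice of how to
  turn a signed vector into a distribution. H is scale- and
  permutation-invariant, which is what a complexity summary should be.

Fingerprints default to Morgan (circular, radius 2, L = 2048 bits) — the
field standard substrate for Tanimoto similarity; kind and length are
configurable. Invalid SMILES rows are excluded with a logged warning
rather than aborting the run, since public CSVs routinely contain a few
unparsable entries.

## Distances

Euclidean distances are computed after per-column z-scoring by default:
the 12 descriptors live on wildly different scales (mass ~600, TPSA ~150,
eccentricity ~0.9), and without standardisation the metric is effectively
a mass/energy metric. A `scaling="none"` flag restores raw-unit
distances. Constant columns are dropped with a warning before z-scoring.
Tanimoto follows `T = A·B/(|A|²+|B|²−A·B)`, `d = 1 − T`, and requires at
least one set bit per fingerprint; Hamming is the raw differing-bit
count (an integer, at most L). Levenshtein uses unit costs
(insertion/deletion/substitution) on the stored SMILES strings; the
edit-distance kernel is `edlib`'s banded dynamic programme, checked in
the tests against a textbook DP implementation. An optional
canonicalisation pre-pass (default off) recomputes canonical SMILES
before comparing; it is off because edit distances between raw strings
and between canonical forms are both defensible and the difference is a
user-level choice. All matrices are dense; the O(n²) Levenshtein pass
logs progress every 200 rows and takes ~1 min for n ≈ 1500.

## Similarity transform and TMFG

Edge weights must increase as distance decreases. Default transform:
`s = 1 − d/d_max` with `d_max` the largest off-diagonal distance — linear,
bounded in [0, 1] (good for modularity), and order-reversing. An
`inverse` mode `s = 1/(1+d)` is provided; it compresses large distances
more aggressively. Degenerate inputs (all distances zero) are rejected.

The TMFG is built greedily: the four vertices with the largest total
similarity form a K4 (4 triangular faces); each remaining vertex is
inserted into the face maximising `s(v,a)+s(v,b)+s(v,c)`, adding 3 edges
and replacing 1 face with 3. The result always has `3n − 6` edges, is
planar by construction (verified independently in the tests with a
planarity algorithm) and connected. Ties in seed selection and insertion
gain are broken toward the smallest vertex index, then the oldest face,
making the construction deterministic. Each edge carries **two**
attributes: `weight` (similarity — used by weighted degree, modularity,
eigenvector centrality) and `length` (the original distance — used by
shortest paths and betweenness). This dual attribution resolves the
ambiguity of running both "strong connection" and "short path" analyses
on one graph. An MST builder (Kruskal, on lengths) is included as the
sparser alternative filter.

## Node metrics

* Weighted degree: `d_i = Σ_j w_ij`.
* Shortest paths and betweenness run on edge *lengths* — "shortest" is
  only meaningful on a dissimilarity. Betweenness is the unnormalised
  node form `C_B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st` counting multiplicities
  (each unordered pair once), delegated to networkx and cross-checked
  against explicit path enumeration on small graphs.
* Burt constraint uses similarity-weighted tie proportions
  `p_ij = w_ij/Σ_k w_ik` and the open-neighbourhood form
  `C_i = Σ_j (p_ij + Σ_{k≠i,j} p_ik p_kj)²`. It is invariant to a global
  rescaling of the weights. Isolated nodes get NaN with a warning.
* Eigenvector centrality is the Perron vector of the similarity
  adjacency, computed by power iteration with a positive diagonal shift
  (same eigenvector; makes the leading eigenvalue strictly dominant even
  on bipartite graphs, whose ±λ spectrum otherwise makes plain power
  iteration oscillate). Deterministic all-ones start, tolerance 1e−10 on
  the max-norm of successive iterates, cap 10⁵ iterations,
  non-convergence is an error reporting the residual. The vector is
  rescaled so `max_i x_i = 1`: the most central molecule always scores
  exactly 1, and the reported λ is the Rayleigh quotient (fixed-point
  residual ≤ 1e−8·λ is asserted in the tests).

## Community detection

Modularity is the weighted form
`Q = (1/2m) Σ_ij [A_ij − k_i k_j/2m] δ(c_i,c_j)` on similarity weights;
the one-block partition scores exactly 0.

The **leading-eigenvector** method is implemented directly: recursive
two-way splits by the sign of the principal eigenvector of the
generalised modularity matrix `B^(g) = B_g − diag(row sums of B_g)`,
with `B = A − kkᵀ/2m`. A branch stops when the leading eigenvalue is
≤ 1e−10, when the eigenvector has one sign, or when the split's
modularity gain `sᵀB^(g)s/4m` is ≤ 1e−12. Determinism: the eigenvector
sign is anchored on its largest-magnitude component and zero components
join the non-negative side; labels are renumbered by first appearance.

The **Leiden** method delegates to the published `leidenalg`
implementation (RB-configuration quality, resolution parameter 1.0 =
modularity; configurable), with an explicit seed and `n_iterations=-1`
(iterate until the quality stops improving). Its contract — seeded
determinism, internally connected communities, quality at least that of
the leading-eigenvector split — is asserted in the tests. Both methods
require a connected graph (TMFG and MST always are; anything else is an
explicit error).

## Partition comparison

All five agreement metrics are computed from one r×s contingency table:
VOI (nats) = H₁+H₂−2I; NMI = 2I/(H₁+H₂) with the conventions NMI = 1 for
two single-block partitions and 0 when exactly one entropy is zero;
split–join in the van Dongen form `(n−Σ_A max_B|A∩B|) + (n−Σ_B max_A|A∩B|)`;
RI and ARI from pair counts, with the degenerate ARI denominator (only
possible for identical all-singleton or single-block pairs) guarded to
return the exact-match indicator. Identical partitions return exact
identity values (VOI snapped to 0.0 rather than the ~1e−16 float residue
of H₁+H₂−2I). A single-community partition therefore forces NMI = 0 and
ARI = 0 against any other partition — the behaviour the edit-distance
network exhibits when one detection method cannot split it. The default
pipeline comparison is leading-eigenvector vs Leiden per network, and
the choice is recorded in the output metadata.

## Non-parametric test battery

For each of the 12 descriptors and a given community partition, three
k-sample tests are run (groups below the size floor, default 2, are
dropped with a warning; a single-community partition skips the battery
with an explicit marker):

* **Kruskal–Wallis** (location): tie-corrected H, chi-square with k−1
  dof (scipy's implementation of exactly this statistic).
* **Conover squared-ranks** (scale): rank |x − group mean| over the
  pooled sample, compare group sums of squared ranks;
  `T = [Σ S_i²/n_i − N S̄²]/D²` with `S̄` the mean squared rank and
  `D² = [Σ R⁴ − N S̄²]/(N−1)`; chi-square, k−1 dof. Location shifts of
  any single group leave T unchanged.
* **Gehan** (generalized Wilcoxon, log-rank family): every observation
  scores `U = #{beaten} − #{beating}` over the pooled sample (all values
  treated as fully observed events — no censoring arises for molecular
  descriptors); the k-group statistic is
  `(N−1)·Σ G_i²/n_i / Σ U_j²`, chi-square with k−1 dof.

All three are reported with raw p-values, matching the convention of
reporting one statistic + p per descriptor and test; an optional
Benjamini–Hochberg flag adjusts across the battery. Chi-square
approximations are calibrated under null simulation (3 groups × 30
normals, 2000 reps) to rejection rates in [0.03, 0.07] at α = 0.05, and
a permutation-p oracle is used in the tests for small-sample scale
comparisons. Degenerate input (all values tied) returns statistic 0,
p = 1, with a warning.

## Synthetic planted-cluster generator

The generator emulates a molecule library with K compound classes. Per
cluster: a descriptor centroid drawn uniformly inside realistic
per-column ranges (mass 200–800 amu, TPSA 50–250 Å², eccentricity
0.8–1.0, …), a Bernoulli(0.3) fingerprint template (L = 256), and a
random template string over a SMILES-like alphabet (length 40). A
molecule is its centroid plus diagonal Gaussian noise (sd = 2% of the
column range by default), the template with independent bit flips at
rate ε = 0.02, and the template string with independent substitutions at
rate ρ = 0.05 (substitution-only, so the expected edit distance is
linear in ρ; an indel mode exists). Defaults were fixed once as a
low-noise, well-separated regime: at these settings the within-cluster
mean distance is far below the between-cluster mean for all four
metrics, which the tests assert. Pseudo-SMILES are not chemically valid
— they exist to exercise the Levenshtein stage; real-molecule inputs go
through the CSV reader instead. Fixed seed ⇒ byte-identical output.

What the generator does **not** emulate: correlated descriptors,
heavy-tailed or hub-structured within-class variation (real chemical
series have a core-scaffold-plus-analogs structure), chemically valid
strings, or class-size imbalance. Passing tests on synthetic data
therefore demonstrate the pipeline's correctness and its behaviour under
idealised cluster structure, not performance claims about any real
compound library.

## A structural caveat: modularity on a TMFG subdivides geometric clusters

One empirical finding from this package's own test battery deserves
emphasis. On the **fingerprint** and **string** networks, TMFG + Leiden
(or leading-eigenvector) recovers planted clusters essentially exactly
(ARI = 1.0 at ε = 0.02). On the **Euclidean** network of Gaussian
descriptor clusters it reliably does not (ARI ≈ 0.5–0.65): each planted
cluster is split into two or three sub-communities, and the split
partition has genuinely *higher* modularity than the planted one. The
mechanism is structural, not a bug, and has two halves:

* every k-node subset of a TMFG is itself planar (≤ 3k−6 internal
  edges), so a 50-node community can never be internally dense, and
  planar graphs always have O(√k) separators — cheap balanced cuts;
* a Gaussian point cloud gives the TMFG locally geometric structure, so
  those cheap cuts exist along spatial bisections, and resolution-1
  modularity takes them.

Bit-flip noise escapes because its distances are nearly additive
(d_ij ≈ f_i + f_j with f the per-molecule flip count), which makes
low-noise molecules hubs; hub stars have no cheap balanced cuts, so the
planted partition is the modularity optimum. The practical reading:
community counts from modularity methods on TMFGs of *continuous*
descriptor spaces should be treated as upper bounds on the number of
real classes, and the recovered partitions as refinements. This is why
the package reports planted-recovery ARI per metric rather than
asserting a single number across all four networks.

## Numerical conventions and degenerate inputs

Tolerances: eigensolver branch-stop 1e−10 / ΔQ 1e−12
(leading-eigenvector), power iteration 1e−10 (eigenvector centrality),
oracle-agreement bound 1e−12 for the partition metrics. Distance
matrices validate symmetry, zero diagonal and non-negativity on
construction; Tanimoto additionally validates the [0, 1] bound.
Rejected degenerate inputs: empty energy vectors, all-zero entropy
vectors, all-zero fingerprints (Tanimoto), all-identical molecules
(similarity transform), n < 3 (TMFG), disconnected graphs (eigenvector
centrality, community detection). Softly handled: invalid SMILES
(excluded + warning), constant descriptor columns (dropped + warning
before z-scoring), undersized test groups (dropped + warning), all-tied
test values (statistic 0, p = 1, warning), single-community partitions
(battery skipped with marker).

## Problem sizes used in the shipped analyses

The test-suite and acceptance analyses run on synthetic sets of 60–200
molecules, 50 random TMFG instances with n ∈ [4, 100], 1000 random
partition pairs (n ≤ 12), and 2000-replicate null simulations (3 × 30
observations) — sizes chosen so the full battery re-runs in minutes on a
single CPU while keeping every estimate's Monte-Carlo error well inside
the asserted bands. The pipeline itself is routinely run at n ≈ 1500
(the BACE-1 library size); the O(n²) Levenshtein stage and the dense
eigensolves remain the slowest steps there.

## Known limitations

* No PMFG or threshold filters; TMFG and MST only.
* Dense O(n²) distance storage; no nearest-neighbour approximations.
* Chi-square approximations for the three tests (permutation p-values
  available but not the default); no pairwise post-hoc comparisons.
* The Gehan test is implemented for fully observed values only — no
  censoring support.
* Leading-eigenvector uses dense eigensolves; fine to a few thousand
  nodes, not for 10⁵-node graphs.
* The generator's realism limits listed above.
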