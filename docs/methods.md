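# Methods

## Signal matrix and preprocessing

A 4D BOLD image and a 3D brain mask yield the m×n matrix S: rows are time
points, columns are in-mask voxel time series.  Voxels are ordered by a
fixed raster convention (first grid axis fastest) stored explicitly as
`voxel_index`, so spatial reconstruction is an exact inverse of the
flattening regardless of array-layout conventions.  Preprocessing inside
the package is deliberately minimal — per-voxel linear detrending (the
in-repo analog of scanner drift removal; motion and slice-time correction
are assumed done upstream) followed by standardization to zero mean, unit
variance.  Columns whose detrended variance falls below 1e-12 cannot be
standardized and are dropped, with their coordinates recorded.
Normalization is idempotent to numerical precision.

## Sparse coding

Each voxel's code solves `min_α ½‖s − Dα‖² + λ‖α‖₁` by cyclic coordinate
descent on the precomputed Gram matrix (covariance updates), so a sweep
costs O(k²) per signal independent of m.  All columns of a matrix are
swept simultaneously as vectorized updates; because the columns are
independent problems, columns whose largest coefficient change falls below
1e-10 are frozen out of subsequent sweeps (exact, not approximate).
Convergence is declared when every column is below that tolerance, capped
at 10,000 sweeps.  Solutions are verified in the test suite against an
exhaustive sign-pattern enumeration oracle on small instances, against
scikit-learn's lasso (different objective scaling, rescaled accordingly),
and against the subgradient optimality conditions on every returned code.
Coefficients are unconstrained in sign; λ is one global scalar.

λ defaults to `median(‖s_i‖₂)/√m` — for standardized columns this is ≈ 1 —
a dimension-aware default that keeps the per-voxel problem scale-free;
it is overridable everywhere.

## Dictionary learning

D (m×k, atoms in the ℓ2 unit ball) is trained by online mini-batch
learning: per epoch the columns are visited in a seeded shuffled order in
batches of 256; each batch is sparse-coded against the current D, the
sufficient statistics A ← A + ααᵀ, B ← B + sαᵀ are accumulated, and one
block-coordinate-descent pass updates each atom as
`u_j = (b_j − D a_j)/max(A_jj, 1e-12) + d_j`, `d_j ← u_j / max(1, ‖u_j‖)`.
This never increases the quadratic surrogate ½tr(DᵀDA) − tr(DᵀB), and the
unit-ball constraint holds after every update (asserted in tests through a
per-update callback).  Atoms are initialized from k distinct data columns
projected to the unit ball (seeded, deterministic).

Epoch-end maintenance handles two pathologies:

* **Dead atoms** — atoms never used during the epoch are replaced by the
  epoch's worst-reconstructed batch signals (renormalized), their
  statistics zeroed.
* **Duplicate atoms** — when two atoms' |cosine| exceeds 0.9 the less-used
  one is re-seeded the same way.  Near-duplicates are actively harmful
  here: they split one network's coefficient mass over several α rows,
  which dilutes the row's z-scores and lets pure-noise voxels cross the
  two-sided |z| threshold.  The 0.9 bound sits far above the chance
  correlation between distinct network time courses (≈ 0.4 at the default
  simulation settings) and is configurable.

Both replacements happen before the epoch-end full coding, so the final
coefficient matrix always corresponds to the final dictionary.  Defaults:
k = 400 (fully configurable; the desk-scale analyses here use k = 50),
5 epochs, batch 256.  The recommended over-complete regime k > m, k ≪ n is
warned about, not enforced.  Fixed seeds give bitwise-reproducible
trajectories.  The full-data objective is recorded at each epoch end;
across epochs it is non-increasing in practice, asserted in tests with 1%
slack because the mini-batch trajectory is stochastic.

## Voxel sampling

Dictionary training cost is linear in n, but large networks are carried by
many voxels, so a uniform random subset (without replacement, seeded)
suffices to learn D.  The sampled path trains on `round(ratio·n)` columns
and then sparse-codes the full matrix, so spatial maps always cover every
voxel.  λ is resolved on the full matrix so both paths solve the same
coding problem; `ratio = 1` reduces bitwise to plain training.  Uniform
sampling is the default and only built-in strategy; the config field
leaves room for energy- or spatially-stratified alternatives.

## Network maps and template matching

Each α row is z-scored over mask voxels (population sd) and binarized
two-sided at |z| > 2 — two-sided because dictionary sign is indeterminate;
negating an atom and its row leaves the binary map unchanged.  Rows with
zero sd become empty components, not errors.  Candidate maps are scored
against binary templates with Jaccard overlap by default (Dice and
|A∩T|/|T| as options) and assigned one-to-one greedily: repeatedly take
the highest-overlap unassigned pair until templates are exhausted or the
best score drops below 0.05.  Ties break toward the lower component
index.  Greedy matching is deterministic and adequate when overlaps are
well separated, which planted-network data guarantees.

Group consensus per template stacks the matched subject maps, computes the
voxelwise proportion, and binarizes at ≥ 0.5 (majority).  Overlap tables
report the group overlap per dataset×template and the individual
mean ± population sd.

## Synthetic data

The generator emulates the structure the decomposition assumes: K
spatially compact, mutually disjoint networks, each with its own
unit-variance time course (white noise smoothed by a 3-TR moving average —
resting-state-like slow fluctuations, no hemodynamic model), mixed
linearly into voxels with additive white Gaussian noise of sd 1/SNR.
Defaults: 24³ grid, ellipsoidal mask at 0.95 of the half-extent
(≈ 6,200 voxels), K = 10, 120 time points, SNR 5, 5 subjects, 1-voxel
jitter.

Design choices worth recording:

* **Blob geometry.**  Networks are grown by stochastic radial accretion —
  each step annexes a random boundary voxel among those nearest the seed —
  giving compact bodies with irregular boundaries.  Mean size is 180
  voxels (sampled ±15%).  Compactness and size are chosen so the planted
  geometry survives single-voxel misregistration: a unit shift of such a
  blob retains Jaccard ≈ 0.6 with itself, whereas stringy random-walk
  shapes drop to ≈ 0.35 and would be unidentifiable under jitter that
  real RSN templates tolerate easily.
* **Disjoint placement.**  Blobs are carved from the still-free region
  (inside the mask eroded by the jitter margin), so pairwise overlap is
  exactly zero and no voxel mixes two network time courses.  Overlapping
  placements create genuine mixture atoms and boundary clipping, making
  the planted ground truth itself ambiguous.  Seeds require clearance of
  about one blob radius so late placements are not squeezed.
* **Subject jitter.**  Per-subject spatial variability is modeled as local
  boundary displacement of depth ≤ `jitter`: boundary voxels of the
  template persist with probability 0.7 and adjacent outside voxels join
  with probability 0.3, independently per subject.  Every displaced voxel
  stays within `jitter` voxels of the template.  A rigid whole-network
  translation was rejected: anatomy varies locally, and with only five
  subjects a rigid-shift consensus inherits any chance alignment of the
  shifts, so the group map is not systematically better than individuals.
  Under boundary jitter the majority vote converges to the template, which
  is exactly the group-versus-individual sharpening the pipeline is meant
  to exhibit.

What passing tests on this generator do **not** show: robustness to
hemodynamic variability, physiological or spatially correlated noise,
inter-site heterogeneity, registration errors beyond one voxel, or
networks with graded (non-binary) membership — none of which are
simulated.

## Study scale and numerical choices

The simulation analyses in the tests and acceptance script run at desk
scale — 24³ grid, ≈ 6,200 mask voxels, k = 50 atoms, 5 subjects — chosen
so the whole study re-runs in minutes on one CPU while preserving the
regime that matters (k well above the number of planted networks, n ≫ k).
Coordinate-descent tolerance 1e-10 on coefficient changes; nonzero
threshold 1e-10; unit-ball slack 1e-10; zero-variance cutoff 1e-12;
division guard ε = 1e-12 in the atom update.  All randomness flows from
explicit integer seeds (per-subject seeds derive from the dataset seed via
a seed sequence); reruns with the same config and seed are byte-identical
in every CSV/JSON output.

## Known limitations

Greedy (not globally optimal) assignment; no cluster-extent correction or
spatial smoothing of maps; templates must already live on the analysis
grid (no resampling); the α-row z-threshold is a convention (z > 2), not
an inference procedure; wall-clock speedup from sampling is
hardware-dependent and intentionally not an assertion surface.
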