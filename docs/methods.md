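# Methods

## Problem setting

A robot-assisted training session produces three synchronized streams at
50 Hz: surgeon-side-console kinematics (SSC), patient-side instrument and
camera kinematics (SI), and eight binary system events (camera control,
master clutches, instrument-following states, energy activation, head
in/out). Five surgical tasks performed back to back form one
*pseudo-procedure*; the goal is to recover the task boundaries and identities
from system data alone, off-line and unsupervised.

## Synthetic pseudo-procedures

Real recordings of this kind are proprietary, so the `synthio` module
generates trials with the same statistical skeleton. What it emulates:

- **Durations.** Each task's duration is drawn
  `Normal(mean·time_scale, sd·time_scale)` with per-task means/sds of
  (1329.2 ± 733.9, 2159.7 ± 492.6, 1999.3 ± 1097.5, 617.6 ± 126.7,
  1474.7 ± 276.3) seconds, truncated below at
  `max(5/rate, 1 s)·time_scale` so every task occupies at least a few
  frames. `time_scale` shrinks a ~7600 s procedure to desk scale without
  touching the dynamics; the duration *statistics* are fixed study
  conditions, not tuning knobs.
- **Kinematics.** Each task has an emission mean in kinematic space; the
  five means sit at mutually orthogonal directions scaled so every pair is
  `separation × noise_sd` apart (directions fixed by an internal constant,
  independent of the trial seed). Within a task, each channel follows an
  AR(1) process toward the task mean with stationary sd `noise_sd` and a
  per-task smoothness coefficient (defaults 0.90–0.97; dissection tasks
  drift more slowly than suturing). The latent state carries across task
  boundaries, so transitions are smooth rather than stepwise.
- **Events.** Each of the 8 channels fires independently per frame with
  probability `rate/50`, with per-second rates that differ across tasks, so
  event features alone carry task identity.

Default dimensions are 12 (SSC) + 24 (SI): the clustering algorithms see
only the kernel structure of the features, not the raw dimensionality, and
smaller streams keep desk-scale tests fast; the real 56/156 dimensions are
reachable through the config.

What the generator does **not** emulate: da Vinci joint-space geometry or
tool identities, correlated event bursts, camera pose, inter-task pauses,
non-stationarity within a task, or surgeon-specific styles. Passing tests
therefore demonstrate correctness of the algorithms and the claimed
qualitative ordering on data with clean task structure — not clinical
performance on real procedures.

Two regimes matter for testing: `separation = 6` (a per-frame Bayes
classifier on the true parameters exceeds 0.95 accuracy, so failures are
attributable to the algorithms, not the data), and `separation = 1.5` with
distinct per-task smoothness (per-frame marginals overlap, so per-frame
methods like GMM degrade while alignment-based methods retain temporal
structure).

## Preprocessing

Raw 50 Hz streams are reduced to 1 Hz by default: kinematics by window
means, events by an any-on rule, ground-truth labels by window majority
vote with ties to the earlier task. The reduction makes a full-scale
procedure ~7600 frames — a tractable frame kernel — and makes the default
maximum segment length of 30 frames (30 s) small relative to task durations
of minutes, which is the regime where segment clustering is meaningful.

Kinematic channels of the requested streams are concatenated, z-scored
(population sd; constant channels map to zero), and vector-quantized per
trial with k-means into `N_s = 15` symbols (10 seeded restarts). Frames are
re-embedded as their symbol centroid rather than a one-hot code, so the
Gaussian kernel yields graded between-symbol similarity; fewer symbols give
a visibly blockier kernel. Event channels are appended raw. The kernel
bandwidth σ defaults to the median pairwise distance over a seeded
subsample of ≤ 2000 frames (median heuristic), excluding zero distances.

## Segment clustering

**DTAK.** The similarity between segments `Q_i`, `Q_j` is a dynamic time
alignment kernel computed on the frame kernel `F` with the (1,2,1)-weighted
recursion `u(p,q) = max(u(p−1,q)+f, u(p−1,q−1)+2f, u(p,q−1)+f)`,
`u(0,0) = 2f(0,0)`, normalized by `τ = u(n_a−1, n_b−1)/(n_a+n_b)`. With
unit-diagonal kernels `τ(Q,Q) = 1` and `τ ∈ (0,1]`.

**ACA.** Coordinate descent on
`J = Σ_k Σ_m g_{k,m} D²(Q_m, z_k)` with
`D²(Q_m, z_k) = τ_mm − (2/M_k) Σ_j g_{kj} τ_mj + (1/M_k²) Σ g_{kj1} g_{kj2} τ_{j1 j2}`:

1. *Assignment*: batch reassignment of segments to the nearest kernel-space
   centroid until stable. An empty cluster is re-seeded with the segment
   farthest from its own centroid — a move that provably lowers J.
2. *Boundary search*: with centroids frozen, a DP over end frames
   (`V(v) = min_{l,k} V(v−l) + D²([v−l,v), z_k)`, `l ∈ [l_min, l_max]`)
   finds globally optimal boundaries and labels. Candidate-segment DTAK
   values against all current segments are computed incrementally (one DP
   row per candidate length), making the step `O(N · l_max · ΣM segment
   frames)` per iteration; the inner kernels are numba-compiled.

Both steps are non-increasing in J (the previous segmentation is always a
feasible DP path, and centroid updates can only lower within-cluster
scatter), so the iteration history is monotone to floating precision.
Convergence: ΔJ < 1e-7 or 50 iterations. DP ties prefer the longer segment,
then the smaller cluster index, fixing determinism. `l_min` defaults to 3
frames (never a meaningful constraint at 1 Hz, but it guarantees
well-conditioned segments); `l_max = 30`.

**HACA.** Level 1 runs ACA with `2K` clusters (finer motifs, regrouped
later) and `l_max = 20` frames. Level 2 treats the level-1 segments as
units, builds the reduced kernel `F2[a,b] = dtak(F, Q_a, Q_b)`, and re-runs
ACA with `K` clusters. The level-2 maximum segment length (default 30) is
enforced **in original frames** as a cap on the total span of merged
level-1 segments, preserving the intended `l_max^(1) < l_max^(2)` ordering
on the frame axis. The alternative — counting level-1 segments as units —
is degenerate: whenever it permits segments of ~`M₁/K` units, the objective
admits a trivial global optimum of exactly `K` segments, each its own
cluster, with `J = 0` for *any* boundary placement (kernel k-means scatter
vanishes when every cluster is a singleton), and segmentation quality
collapses. Single level-1 segments are always admissible so a feasible
solution exists. The reported HACA energy is the frame-level objective of
the expanded segmentation, which is comparable across restarts (per-restart
reduced kernels differ in size, so level-2 objectives are not) and with
plain ACA.

**Baselines.** GMM: diagonal covariance with a 1e-6 variance floor (full
covariance is singular-prone on ~32-d centroid-embedded features), seeded
k-means initialization, maximum-posterior frame labels cut at component
changes; energy = total negative log-likelihood. Spectral clustering:
normalized symmetric Laplacian of the Gaussian similarity graph, bottom-K
eigenvectors row-normalized, seeded k-means; energy = embedded-space
inertia. Restart protocol: every algorithm is run with five seeded
initializations and the minimum-energy solution kept.

## Evaluation

Frame-level only. `C[i,j]` counts frames in predicted cluster `i` and true
task `j`; accuracy is `max_P tr(CP)/N` via the Hungarian algorithm
(equivalently the best of all `K!` matchings — the test suite checks this
exhaustively). Per-task precision/recall/F1 reuse the accuracy-optimal
matching; a task with no true frames is reported as missing and excluded
from macro-F1. Per-task "performance" tables report recall and are labeled
as such. The proportional baseline averages normalized task durations over
training trials (leave-one-out by default), cumulates, scales to the target
length and rounds to monotone boundaries with ≥ 1 frame per task.

## Problem sizes

Desk-scale runs use `time_scale = 0.13` (~1000 frames at 1 Hz, tasks of
60–330 s) — large enough that `l_max = 30` segments are short relative to
tasks, small enough that a full four-algorithm sweep over several trials
completes in seconds per trial. Generator-fidelity checks draw 200 trials at
`time_scale = 1` with a 1 Hz sampling rate, which measures the duration
distributions through the full generation path at negligible cost.

## Known limitations

- The objective's degenerate `M = K` optimum means ACA is only meaningful
  when `l_max` is small relative to `N/K`; the package does not guard
  against deliberately degenerate configurations.
- Very short tasks (duration near the truncation floor at small
  `time_scale`) can vanish under 50× downsampling; the majority-vote label
  reduction then yields fewer than K true tasks and per-task metrics report
  the missing task as NaN.
- Symbolization is per trial; cluster identities are not comparable across
  trials, matching the unsupervised, per-procedure setting.
- Spectral clustering uses a dense eigensolver, quadratic memory in N; at
  the default 1 Hz reduction this is ≤ ~7600² even at full scale.
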