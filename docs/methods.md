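# Methods

## The SAR optimizer

SAR models a box-constrained search with `M` agents on `[lb, ub]^N`. The state
is a position matrix `X` (M×N), a memory matrix of the same shape holding
abandoned positions, per-row fitness caches, and per-agent counters of
consecutive unsuccessful searches (`usn`). The clue matrix `Z` is the vertical
stack of positions then memory (2M×N); all moves reference it.

Per iteration, each agent `j` generates and greedily accepts two candidates:

1. **Social phase.** Draw a clue row `k ≠ j`, one `r1 ~ U[−1, 1]` shared across
   dimensions, per-dimension `r2 ~ U[0, 1]`, and a forced dimension `irand`.
   Dimensions with `r2 < SE` (or `i = irand`) move to
   `Z_k + r1 (X_j − Z_k)` if the clue is fitter than the agent, else to
   `X_j + r1 (X_j − Z_k)`; other dimensions keep `X_j`. The forced dimension
   guarantees the candidate differs from `X_j` somewhere.
2. **Individual phase.** Draw clue rows `k, m` with `j, k, m` distinct and one
   `r3 ~ U[0, 1]`; the candidate is `X_j + r3 (Z_k − Z_m)`.

Out-of-box coordinates are midpoint-repaired: a coordinate above `ub_i`
becomes `(x_i + ub_i)/2`, below `lb_i` becomes `(x_i + lb_i)/2` (the current
coordinate is in the box, so the repaired value is too). An improving
candidate replaces `X_j` and the displaced position is written to a uniformly
random memory row; otherwise `usn_j` grows, and once it exceeds `mu_max` the
agent restarts uniformly in the box (the memory row is left untouched —
restarts discard the agent, not its clues). "Improving" is the
epsilon-constrained comparison: with both violations within `eps` (or exactly
equal) fitness decides, otherwise the smaller violation wins; all comparisons
are strict, so exact ties never replace an incumbent. With zero violations
this is plain strict fitness comparison.

The memory matrix is initialized as a copy of the initial population together
with its fitness cache, so initialization costs exactly `M` evaluations and a
full run with `T` iterations costs `M(1 + 2T)` plus one evaluation per
restart.

## mSAR: opposition-based learning

The opposite of `x` is `lb + ub − x`. mSAR applies an **opposite-population
selection** (replace each agent by its opposite iff strictly fitter) once
after initialization and once at the top of every iteration, then moves each
agent according to a three-phase schedule over the `T` iterations: social
phase while `t < T/3`, individual phase while `T/3 ≤ t < 2T/3`, and an
opposition jump (greedy acceptance of the opposite point, with memory saving)
for the final third. Restart checks and best-so-far bookkeeping follow each
agent's move; every acceptance is greedy, so the convergence curve is monotone
under the configured sense.

Two published descriptions of when OBL applies disagree (initialization-only
versus per-iteration with the schedule); the pseudocode being the most
specific statement, `per_iteration + schedule` is the default, and
`OblConfig` exposes `init_only`, `disabled`, `schedule_enabled` and a
`final_third_supplement` flag (run the social/individual sweep *in addition
to* the opposition jump in the last third) to cover the other readings. With
OBL disabled and the schedule off, `run_msar` is bitwise identical to
`run_sar` at equal seed. In the final third the opposition jump alone rarely
improves an agent that already survived opposite-selection, so progress there
comes mostly from the restart mechanism — a deliberate consequence of
following the published schedule; the supplement flag restores directed moves
if wanted.

A configured `mutation_ratio_p` (0.5) is carried in `SarConfig` for
completeness with the reference parameter table but drives no operator: the
published description assigns it no equation.

## Thresholding objectives

Histograms are 256-bin probability vectors per channel (`numpy.bincount` over
the 8-bit range, normalized). A pixel of value `g` belongs to class
`c = #{thresholds ≤ g}`, i.e. class `j` covers gray levels
`[th_j, th_{j+1} − 1]`.

**Otsu.** `σ_B² = Σ_j ω_j (μ_j − μ_T)²`, computed from cumulative sums;
empty classes contribute zero. `exhaustive_otsu` enumerates all single
thresholds or pairs (vectorized) and can return the exact argmax *plateau*:
when the histogram has empty stretches, moving a threshold across unoccupied
bins changes no class and the optimum is a set of exactly tied threshold
vectors, not a point. Tests and the acceptance script therefore measure
recovery as distance to the nearest plateau member.

**Fuzzy entropy.** `nTh` ordered triplets `(q_i, u_i, v_i)` forming one
strict chain in `[0, 255]` define S-shaped ramps

```
S(k; q, u, v) = 0                         k ≤ q
              = (k−q)² / ((v−q)(u−q))     q ≤ k ≤ u
              = 1 − (k−v)² / ((v−q)(v−u)) u ≤ k ≤ v
              = 1                         k ≥ v
```

Region memberships are consecutive differences `1 − S_1, S_1 − S_2, …,
S_nTh`, so region 0 is Z-shaped (dark), the last region S-shaped (bright),
interior regions Π-shaped, and the memberships sum to one at every gray level
by telescoping — exactly, up to a clip of −1e−17-scale rounding residue. The
objective is the summed Shannon entropy of the region distributions
(natural log, `0 ln 0 := 0`, zero-mass regions contribute 0). The published
description prints the memberships and region probabilities but not the
entropy expression itself; the standard fuzzy-entropy definition from the
cited literature is used, as written above. Crisp thresholds solve
`S(T) = 1/2` in closed form:
`T = q + sqrt((v−q)(u−q)/2)` when `(q+v)/2 ≤ u`, else
`T = v − sqrt((v−q)(v−u)/2)`.

**Agent decoding.** Otsu agents are `nTh` reals in `[0, 255]`: sorted,
rounded, clamped to `[1, 254]`, duplicates bumped upward (cascading, with a
backward pass at the cap). Fuzzy agents are `3·nTh` reals: the whole vector is
sorted into consecutive triplets, exact ties nudged apart by one ulp. The
fuzzy objective is evaluated on the continuous parameters; integerization
happens only when rendering thresholds.

## Segmentation pipeline

Per channel: histogram → optimizer maximizes the chosen criterion over agent
vectors (the optimizer sees only the histogram, so cost is independent of
image size) → best agent decoded → quantized rendering in which each class is
painted with its mean gray level (interval midpoint for empty classes). The
class-mean convention is what makes PSNR/SSIM/FSIM against the original
meaningful. RGB channels are treated independently, no colorspace conversion;
channel `c` of a run seeded `s` uses seed `s + c`.

## Fidelity metrics

* **PSNR** `= 20 log10(255 / RMSE)`, RMSE over all pixels and channels
  jointly; identical images are reported as infinite with a flag.
* **SSIM** uses whole-image statistics,
  `(2μ₁μ₂ + c_a)(2σ₁₂ + c_b) / ((μ₁² + μ₂² + c_a)(σ₁² + σ₂² + c_b))` with
  `c_a = (0.01·255)²`, `c_b = (0.03·255)²`, channels averaged; the common
  sliding-window form is available behind `windowed=True` (scikit-image).
* **FSIM** weights pointwise similarity of two feature maps by phase
  congruency: `FSIM = Σ S_PC·S_G·PC_m / Σ PC_m` with `PC_m = max(PC₁, PC₂)`,
  `S_PC = (2 PC₁PC₂ + T₁)/(PC₁² + PC₂² + T₁)` (T₁ = 0.85) and
  `S_G = (2 G₁G₂ + T₂)/(G₁² + G₂² + T₂)` (T₂ = 160, Scharr gradients).
  Phase congruency is computed from a log-Gabor bank (4 scales × 4
  orientations, min wavelength 6, multiplier 2, σ_onf 0.55) in the plain
  energy-over-amplitude form `PC = Σ_o E_o / (ε + Σ_o Σ_n A_{no})` with
  `ε = 1e−4` — no noise-compensation or sigmoid weighting stages. RGB inputs
  are reduced to luminance (ITU-R 601). Constant (featureless) image pairs,
  where every PC weight vanishes, fall back to the unweighted mean similarity
  so identical constants still score 1.
* **run_std** is the population standard deviation `sqrt(Σ(x−μ)²/n)` used to
  summarize repeated runs.

## Rank statistics

`friedman_mean_ranks` ranks algorithms 1..A per problem (ascending for
minimization, average ranks on ties), averages per algorithm, and derives the
final ordering as ordinal ranks of the mean ranks with ties broken by column
order — the convention under which published rank rows print distinct integers
for algorithms with equal mean ranks. The Friedman chi-square and p-value are
reported alongside (scipy). `wilcoxon_rank_sum` is the two-sided Mann-Whitney
rank-sum test: exact enumeration when `n + m ≤ 12` without ties, otherwise the
tie-corrected normal approximation; `H = 1` iff `p < alpha` (default 0.05).
The rank-sum (independent samples) variant, not signed-rank, matches the
two-independent-samples framing of the comparisons this module serves.

## Benchmark suite

Ten bound-constrained functions on `[−100, 100]^D`
(D ∈ {2, 5, 10, 15, 20}): bent cigar; modified Schwefel; Lunacek
bi-Rastrigin; expanded Rosenbrock-plus-Griewank; three hybrids (3/4/5
subcomponents over a seeded variable partition with proportions
[0.3, 0.3, 0.4], [0.2, 0.2, 0.3, 0.3], [0.1, 0.2, 0.2, 0.2, 0.3]); three
compositions (3/4/5 components with distance-based weights, standard sigmas,
lambdas and biases). Target offsets are 100, 1100, 700, 1900, 1700, 1600,
2100, 2200, 2400, 2500. **Shift vectors are drawn uniformly in [−80, 80] and
rotations are Haar-random orthogonal matrices (sign-fixed QR), both from a
user seed: the official competition data files are not bundled, so absolute
values on this suite are not comparable with results computed on those
files.** The suite exists to exercise and compare optimizers under controlled,
bitwise-reproducible conditions; `suite_manifest` records every construction
parameter as JSON.

## Synthetic test images

`generate_cell_image` renders a bright background (default level 220),
non-overlapping dark disks (cytoplasm, 130) with inner nucleus disks (40,
nucleus area fraction 0.5), and Gaussian pixel noise (σ = 8) clipped to
[0, 255] — levels and noise chosen so each channel histogram has three
well-separated modes with unequal masses, the regime histogram-based
thresholding addresses. Mode levels may be set per RGB channel; the generator
validates a 3σ separation between adjacent levels so the histogram stays
genuinely multimodal. Ground truth carries the mode means and the exhaustive
2-threshold Otsu optimum (full argmax plateau) of each realized channel.

What this emulates — and what it does not: the fidelity target is the
*histogram* (multimodality, separated modes, unequal masses, noise), not cell
morphology, staining gradients, illumination fields, or overlapping cells.
Passing tests on these images shows the optimizer recovers exhaustively
verifiable optima of realistic multimodal histograms; it does not certify
segmentation quality on real micrographs, whose histograms can have
overlapping modes where the Otsu/fuzzy criteria themselves blur.

## Numerical notes

* All randomness flows from one `numpy` Generator per run with a fixed draw
  order (per agent: social k, r1, r2 vector, irand, memory row; then
  individual k, m, r3, memory row; then restart draws), so equal seeds give
  bitwise-identical runs.
* Opposite-point reflection `lb + ub − x` is an exact involution in real
  arithmetic; in IEEE doubles the round trip is exact when the reflection is
  exactly representable (always for bounds symmetric about zero; on the
  half-integer lattice of [0, 255]) and within one ulp of the bound scale
  otherwise — for values far below the bound scale an exact float preimage
  does not exist at all. Tests assert exactness where it is attainable and
  the one-ulp bound in general.
* Ties: fitness comparisons are strict everywhere (an equal candidate never
  replaces an incumbent); Otsu argmax plateaus are handled as sets; fuzzy
  decode separates exact parameter ties by one ulp.
* The `restart` threshold `mu_max` defaults to 15 consecutive failures —
  small enough to matter within 350 iterations, and configurable.
* Degenerate inputs: empty histogram classes contribute zero to both
  objectives; zero-mass fuzzy regions contribute zero entropy; empty
  rendering classes paint their interval midpoint; constant image pairs give
  PSNR = ∞ (flagged) and FSIM's unweighted fallback.

## Problem sizes used in tests and the acceptance script

Optimizer-attainment checks run mSAR at the reference settings (M = 50,
T = 350) — 30 seeded runs on a 10k-pixel trimodal histogram for the Otsu
pair-optimum rate, and 10 seeds × 3 channels on a 256×256 synthetic image for
threshold recovery. Exhaustive oracles cover all 254 single thresholds and all
32,131 pairs. These sizes were chosen as the smallest that exercise the full
method end to end; larger images change only the histogram's sampling noise,
not the optimization problem, because the pipeline optimizes over the
histogram.

## Known limitations

* Absolute benchmark values depend on the synthetic shift/rotation instance
  (see above); only rank-based post-processing of externally supplied result
  tables is instance-independent.
* The epsilon-constrained comparison is implemented with a constant `eps`
  (default 0); no decay schedule is provided because none is specified.
* FSIM here follows the plain energy-over-amplitude phase congruency; scores
  are comparable within this package but not numerically interchangeable with
  implementations that include noise compensation.
* The comparison metaheuristics named in the packaged reference table (LFD,
  HHO, SCA, EO, GSA, AOA) are not implemented; the table is input data for
  the rank statistics.
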