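# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `aglnet`.

## Finite-state grammar engine

A grammar is a directed labeled automaton (states, syllable-labeled arcs,
one entry state, ≥1 exit states). A sequence is grammatical iff some
entry-to-exit path emits exactly its syllables. Acceptance uses subset
construction (the full reachable state set per position), so ambiguous
grammars — several arcs with the same syllable leaving one state — are
handled exactly; unknown syllables empty the reachable set and force
rejection. The empty sequence is always rejected.

The packaged default grammar is a Reber-style two-branch topology with
loops over the alphabet {pok, kun, dem, tik, guk} (5 states, 11 arcs). It
is a synthetic stand-in: it was constructed so that the canonical example
sequences classify correctly ("pok kun dem dem tik" grammatical,
"pok kun tik guk pok" ungrammatical) and so that the language contains 48
strings of length 2–5 — enough for the default 22-sequence study list
plus 24 novel grammatical test items. Any user grammar can be substituted
via a JSON specification.

Design choices:

* **Study list.** 22 unique sequences are sampled round-robin across
  length strata (so all lengths are represented), each pass is ordered by
  nondecreasing length, and the pass is presented 3 times (66 total).
  How the original paradigm sampled its study sequences is not public;
  both the count and the repetition factor are parameters.
* **Foils.** Off-path substitution replaces one syllable with one that no
  reachable state allows at that position, which guarantees rejection
  analytically and preserves length (used for the length-matched test
  list). Syllable deletion shortens by one and retries positions until
  the result is rejected and still ≥2 syllables, else errors.
* **Enumeration** is capped at length 12 (loop explosion guard) and
  ordered by length, then lexicographically.

## ROI time-series simulator

Four ROIs (defaults IFG, INS, CN, PCu) evolve as a structural VAR(1):

    η_t = (I − A)⁻¹ (Φ η_{t−1} + c_t + ζ_t),  ζ_t ~ N(0, diag(σ²)),

with A the contemporaneous directed coefficients (zero diagonal), Φ the
lag-1 coefficients, and c_t a box-car task mean shift (`task_gain` during
task scans, 0 during fixation, identical across ROIs). Stationarity
requires spectral radius of (I − A)⁻¹Φ < 1 and is enforced. The
stationary covariance solves the discrete Lyapunov equation
V = BVB′ + Q with B = (I−A)⁻¹Φ and Q = (I−A)⁻¹ diag(σ²) (I−A)⁻ᵀ; tests
verify simulated covariances against this closed form.

The schedule mirrors a blocked grammaticality-judgment run: 8 task blocks
of 26 s (one 2 s instruction scan + six 4 s trials) interleaved with 16 s
fixation, fixation first and last, TR = 2 s → 176 scans. 20 warm-up
samples are discarded. A constant `baseline_level` (default 100, scanner
units) is added to all scans so percent signal change is well defined; it
does not affect covariances. Groups get per-subject Gaussian jitter
(default sd 0.02) on the nonzero coefficients, truncated to preserve
stationarity (≤100 retries), with per-subject seeds spawned
deterministically from the master seed.

What the generator does **not** emulate: hemodynamic convolution (an
optional realism extension; the connectivity model operates on extracted
ROI series directly), voxel-level structure, motion or physiological
artifacts, heavier-tailed noise, or task-dependent *connectivity* changes
(the task enters as a mean shift only). Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to hemodynamic or artifact-induced
distortions in real BOLD data.

The behavioral generator draws (accuracy, WM score) from a Gaussian
copula with a planted correlation (default .564 for demonstrations) and
an independent age column, so the age-controlled partial correlation
recovers the planted value in population. Accuracies are clipped to
[0, 1]; defaults (accuracy .57 ± .08, WM 6 ± 1.1, age 21 ± 2) echo the
scale of AGL judgment accuracies and letter-number-sequencing scores.

## Percent signal change

PSC[t, r] = (signal − baseline)/baseline × 100 with baseline[r] the mean
of ROI r over all fixation scans of the run (run-wise rather than
block-wise baselines: lower variance; block-wise is not currently
implemented as the run-wise convention suffices for the shipped
analyses). Mean PSC over fixation scans is exactly 0 by construction.
Instruction scans count as task scans by default (configurable).

## Unified SEM

Variables are the stacked pair x = η_t (lagged block, exogenous with
freely estimated covariance) and y = η_{t+1}. With B = (I − A)⁻¹:

    Σ_xx = S_xx,   Σ_yx = BΦS_xx,   Σ_yy = B(ΦS_xxΦ′ + Ψ)B′,

Ψ = diag(ψ). Free parameters: the p(p+1)/2 exogenous covariances, the p
residual variances, and the masked entries of A (off-diagonal only) and
Φ. Degrees of freedom: p(2p+1) moments minus free parameters (clamped at
0 and flagged saturated).

**Lagged covariance.** Per subject, ROI columns are standardized over the
scans passing the condition filter, and (t, t+1) pairs are formed only
within contiguous same-condition segments — no pair spans a condition or
block boundary. Because series are standardized first, the pooled matrix
is on the correlation scale, reconciling "covariance matrix" and
"correlation matrix" descriptions of the same construction. The default
filter keeps task scans only: the box-car task shift is common to all
ROIs, and mixing task with fixation scans would convert that shared mean
structure into spurious positive covariance everywhere. Pooling is
pair-count weighted; n_effective = Σ pairs − n_subjects (one sample-mean
degree of freedom per subject; the convention entering every (N−1) term).

**Estimation.** L-BFGS-B on F with analytic gradients
(∂F = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹) ∂Σ]), regression-based starting values
(Φ̂ from OLS of y on x, A = 0, ψ from the conditional variances,
S_xx from the sample), positivity bounds on variances, convergence
tolerance 1e−8 on F with up to 5 jittered restarts. Non-PD candidate
Σ gets a large penalty, which the line search backs away from. Standard
errors come from the inverse expected information
I_ab = (N−1)/2 · tr(Σ⁻¹∂Σ_aΣ⁻¹∂Σ_b).

**Fit indices.** RMSEA = √(max(χ²−df,0)/(df(N−1))); SRMR = RMS of
standardized residual covariances (diagonal included); NNFI and CFI use
the independence model over all 2p variables as the null
(df_null = 2p(2p+1)/2 − 2p). One deliberate convention: when the null
model's own RMSEA is below 0.158 — the standard bound below which
incremental indices are uninformative — NNFI and CFI are reported as 1.
Rationale: if independence already fits (e.g. white-noise data), the
incremental-index denominators are pure sampling noise and the search
would chase noise paths; with this convention the null network is
correctly recovered as empty. The bound is an effect-size criterion, so
it is insensitive to the large pooled N.

**Modification indices.** For every fixed path, the univariate score
(Lagrange-multiplier) statistic s_j²/(I_jj − I_jf I_ff⁻¹ I_fj), evaluated
at the restricted optimum — the expected χ² drop from freeing that one
path. Ranking is by MI descending; exact ties break contemporaneous
before lagged, then row-major, which (with the deterministic optimizer)
makes the whole search trace reproducible bit-for-bit.

**Search.** Baseline model: the p autoregressive lagged paths free
(standard uSEM practice; an empty baseline is available). Iterate
free-top-MI → refit (warm-started from the previous solution, so χ² is
provably nonincreasing) until all four criteria hold, no candidates
remain, or `max_steps` (20) is reached. Then a single prune of free paths
with |z| < 1.96 and one refit — a single pass rather than an iterative
prune loop, for determinism. The edge report maps A[i, j] to a directed
contemporaneous edge j→i (row = target) and Φ[i, j] to a lagged edge;
since inputs are standardized, the reported weights are standardized βs.

**Calibration design.** The χ²-calibration test draws independent
8-vectors from the implied covariance of the sparse true model (N = 800,
500 replicates) and checks the 0.05-level rejection rate of (N−1)F
against χ²(df). Independent draws are used because the reference
distribution assumes i.i.d. observations; consecutive-scan pairs from a
single run overlap (scan t appears in two pairs), so the time-series
route is not a clean null for this distributional check — there the
statistic is the usual SEM approximation, as in practice.

**Recovery conditions.** The planted-network benchmark uses the packaged
6-edge truth (contemporaneous chain IFG→INS→CN→PCu with negative CN→PCu
and PCu→IFG feedback, lagged IFG→CN and INS→PCu, AR 0.3 on all nodes;
|weights| 0.35–0.5), 20 subjects × 176 scans, between-subject sd 0.02 —
sample sizes mirroring a realistic single-group study. Over 20 replicate
groups the search recovers the planted set with sensitivity ≥ 0.9 and ≤1
false edge in ≥90% of replicates.

## Behavioral statistics

One-sample t = (m − μ₀)/(s/√n) with df = n − 1; two-sample defaults to
the pooled equal-variance test (df = n₁+n₂−2, matching a reported df of
41 for groups of 20 and 23), with Welch available. Partial correlation is
computed from residuals of regressions on the covariate and equals the
closed form (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)); df = n − 3.
Reconstructions from rounded printed group summaries are expected to
deviate ≤3% from statistics computed on unrounded data.

## Pipeline

`run_pipeline` drives simulate → pool → search → report for any number of
groups from one YAML config. All randomness derives from the master seed
via SHA-256 of "seed:stage-label" (keeping every derived seed below
2³¹), so reruns are bit-identical; the manifest records the config hash,
derived seeds, package version, per-group edges, fit, stop reason, and
behavioral statistics.

## Known limitations

* Group-level pooling assumes a common network; there is no
  GIMME-style subject-level path heterogeneity.
* The ML χ² treats pooled pairs as independent observations; overlapping
  pairs make it mildly liberal in the time-series regime (the fit-index
  thresholds, not the χ² p-value, drive the search for exactly this
  reason).
* No hemodynamic forward model; results on real BOLD depend on the
  adequacy of extracting ROI averages directly.
* The default grammar reproduces the paradigm's statistical structure,
  not any specific published diagram.
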