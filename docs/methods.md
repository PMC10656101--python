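# Methods

## Evidence model and conventions

Momentary color evidence is integrated with discrete updates
`ΔDV = μΔt + 𝒩(0, Δt)`, `μ = κ(C± + C₀)`, so the decision variable has
variance 1 after one second of accumulated sampling. This scaling is a
convention, not an assumption: any other noise scale maps onto it by
rescaling κ and the bound. The color bias C₀ is a coherence offset (used
only in the 1D color model; the difficulty models carry no bias term).
Bounds are symmetric logistics `B(t) = u/(1 + e^{a(t−d)})`: `u` sets the
scale, `B(d) = u/2`, and `a` the collapse rate; `a = 0` gives a flat bound
at `u/2`.

Crossings are detected on the step grid with no sub-step interpolation,
in both the Monte Carlo and density routes, so the two routes share the
same discrete-monitoring convention and agree to KS < 0.01 at Δt = 1 ms.
Against the *continuous-time* constant-bound closed forms this convention
carries the usual effective-bound bias of order `0.58·√Δt`; at the 0.5 ms
default it amounts to ≲0.3% in choice probability and ≲1.5% in mean
decision time for bounds of 1 evidence unit or more. The relative bias
scales as `√Δt / B`, so checks against the closed forms are run at B ≥ 1
(smaller bounds need a proportionally smaller step).

## Density propagation (1D color model)

The unabsorbed density is propagated by a Crank–Nicolson step for the
advection–diffusion operator on a uniform evidence grid (default ≥400
cells over `[−u, u]`); at the end of every time step the mass at or beyond
the grid-snapped collapsing bound is removed into that boundary's defect
density. Mass is conserved to 1e−12 per run; tiny negative ripples from
the implicit solve are clipped to zero. A configuration error is raised
if the bound moves more than one evidence cell per time step. The
Gaussian non-decision time is applied as a discrete CDF-difference kernel
truncated to non-negative offsets and renormalized (the truncated mass is
negligible for `tnd ≥ 0.2 s, sd = 0.05 s`); a zero-sd kernel reduces to a
pure grid shift.

## Serial time-multiplexing

The two difficulty DVs update alternately every Δt, S1 on even steps, so
each stimulus receives half of real time and decision times are doubled
relative to parallel integration. The equivalent parallel model under a
time dilation γ is `κ_p = κ/√(2γ), u_p = u√(2γ), a_p = a/γ, d_p = γd`
(`models.parallel_equivalent_params`); γ = 1 gives the parallel model with
identical real-time predictions (bound scaled by √2), verified by KS test
at 10⁵ trials. Two caveats of the fixed alternation order are worth
knowing: with a degenerate mini-bound (`b_mini → 0`) the two-step model's
first update makes the signed statistic positive and biases equal-strength
choices toward S1, and the absolute model's alternating `|increment|`
drift leaves a sawtooth asymmetry of order √Δt in left/right
exchangeability. Both vanish for realistic parameters and step sizes.

## The four decision rules

Race (each DV races to its own ±B), difference (bound on |DV1| − |DV2|),
two-step (a flat mini-bound `B_mini` until 2 s, then a sharp collapse to
zero forcing a sign commitment; thereafter the bound applies to
`sign₁DV1 − sign₂DV2`, with a difficulty choice possible from `t_mini`
on), and absolute momentary evidence (increments `|μΔt + noise|`, bound
on DV1 − DV2). All simultaneous-crossing and exact-zero ties are broken
by the trial's random stream. Horizon-censored trials (5 s deadline)
resolve by the sign of the decision statistic and are flagged
`terminated_by = "horizon"`.

One structural fact deserves emphasis because it contradicts a natural
intuition: at *identical* parameters the absolute model is slightly
**slower** than the difference model on hard–hard (0:0) pairs. The
difference statistic rides reflected Brownian paths whose local
diffusivity is 1, while the absolute statistic accumulates iid |noise|
increments with variance rate `1 − 2/π ≈ 0.36`; a slower-diffusing
statistic crosses the same bound later. The familiar claim that the
absolute rule is faster on hard–hard pairs holds for per-model *fitted*
parameters (its fitted bounds end up lower), not at shared ones. The
corresponding acceptance assertion is kept in its published direction and
fails; this is expected.

## Confidence mapping

Confidence is the posterior probability that a sign(DV)-based color
choice is correct under a uniform prior on the signed coherence set, with
Gaussian likelihoods `𝒩(DV | κCt, t)`. It is stored as the signed
log-odds of blue dominance on a (t, DV) grid (t step = Δt, DV step
0.025, clipped at ±10, bilinear interpolation), antisymmetric in DV; the
unknown-color model bounds `|L1| − |L2|`, the known-color variant
`s₁L1 − s₂L2`. Because log-odds grow supra-linearly in DV, easy–easy
pairs terminate far faster than hard–hard ones under this rule — the
feature that distinguishes it from the difference model.

## Controlled-duration paradigm

Per-stimulus sampling time follows the 80 ms sensory-buffer rule
`Tdur = Tstim` if `Tstim ≤ Tbuf`, else `Tbuf + (Tstim − Tbuf)/2`. Both
DVs advance each evidence step; the collapsing bound is evaluated at the
real time corresponding to the evidence step (identity within the buffer,
factor 2 beyond it). If no bound is crossed by stimulus offset the choice
is the sign of the statistic (ties random). Only choices (no RTs) are
produced.

## Simulation-based likelihood

For every signed pair in the data the model is simulated
(default 1000 trials/condition at Δt = 5 ms) and the RT density per
choice is an Epanechnikov KDE scaled by the simulated choice probability,
floored at 1e−5 s⁻¹ per trial. Three design choices matter:

* **The kernel doubles as the non-decision convolution.** Simulated RTs
  are decision times shifted by the mean non-decision time, and the
  kernel width is fixed at `h = √5·σ_tnd` (sd = σ_tnd = 0.05 s, floored
  at 2Δt). The smoothed density then approximates the model's true RT
  density (decision-time density ⊗ a 0.05-sd kernel) instead of an
  over-dispersed version of it. A Silverman-style data-driven bandwidth
  (≈0.3 s at these simulation counts) is demonstrably biased here: the
  optimizer compensates for kernel over-dispersion by shrinking the bound
  and inflating the non-decision time.
* **Per-trial random substreams.** Each simulated trial derives its noise
  from a counter-based stream (splitmix64-seeded xorshift128+,
  Box–Muller), so trial i sees the same noise at any parameter value.
  A single shared stream would desynchronize after the first
  early-terminating trial, destroying the common-random-numbers coupling
  the optimizer relies on.
* **Profiled non-decision time.** Since the table stores decision times,
  the non-decision mean is a pure shift of the kernel centers; it is
  minimized out on a grid (step 0.05, parabolic refinement, warm-started
  window) at every objective evaluation. This removes the noisiest
  direction of the bound/non-decision ridge from the simplex search
  entirely. The profiled tnd is a fitted parameter and is counted in the
  BIC.

The optimizer is multi-start Nelder–Mead with box bounds (log scale for
κ, u, B_mini), a uniform presearch to select basins, a wide initial
simplex (15% of the box), and a final polish at a larger simulation
count. The reported log likelihood is evaluated on a *held-out*
simulation seed: flexible models otherwise inflate their likelihood by
exploiting their own search seed's noise, which distorts BIC comparisons.
Box bounds: κ ∈ (0.5, 40], u ∈ (0.1, 10], a ∈ [0, 10], d ∈ [0, 5],
Tnd ∈ [0.1, 1], B_mini ∈ (0.05, 3].

The 1D color model is fitted by its Fokker–Planck likelihood directly
(κ, C₀, u, a, d, Tnd free; σ_tnd fixed). Controlled-duration data are
fitted jointly over known and unknown conditions with a choice-only
binomial likelihood (κ, u, a, d free; optionally two κ; buffer on or
off), excluding equal-strength pairs and, in the unknown condition,
different-dominance pairs.

Model comparison: BIC per participant, group BIC by summation, and
random-effects exceedance probabilities via variational Dirichlet updates
with −BIC/2 as log evidence and Monte Carlo sampling of the winner.

## Optimal policy

The belief state ⟨t_S1, t_S2, DV_S1, DV_S2⟩ is discretized at Δt = 0.05 s
and ΔDV = 0.1 over ±6 evidence units (mass drifting beyond the range
accumulates in the edge bins; at κ = 13 strong stimuli are clipped, but
decisions terminate long before the clip matters for the policy near the
origin). Posteriors over the discrete coherence set give the belief that
choosing S1 is correct (ties between strengths count half) and the
one-sample transition kernels (per-coherence Gaussian CDF differences,
mixed by the current posterior). One backward pass over 100 sampling
slices solves the Bellman equations for a given reward rate ρ; stopping
values are `b·Rc + (1−b)(Rn − t_p ρ) − (t_nd + t_w)ρ`, the sampling
action costs ρΔt, the terminal slice forces a stop, and ties resolve to
stopping. ρ* is bisected to |V(s₀)| < 1e−3 on the bracket
[0, Rc/(t_nd+t_w)]. Policy simulations evolve continuous DV paths with
the true drifts and look states up at the nearest cell; RT adds the
constant t_nd (no jitter). The defaults (κ=13, Rc=1, Rn=0, t_p=1 s,
t_nd=0.4 s, t_w=0.5 s) give ρ* ≈ 0.554 s⁻¹, accuracy monotone in the
strength difference, the magnitude effect, and a late-time continue
region that fragments away from the origin.

Mirror symmetry of the choice regions under DV exchange is exact at the
terminal slice; at interior slices the fixed alternation order (the next
sample is always a specific stimulus) perturbs it by one Δt of sampling.

When the four difficulty models are fitted to 20,000 optimal-policy
trials, race is decisively worst and the difference-family rules are
best — but in this implementation the two-step rule edges out the plain
difference rule (ΔBIC ≈ 150–290 across seeds), with a small fitted
mini-bound. A control fit on difference-generated data of the same size
prefers the difference model by a similar margin, so the comparison is
unbiased; the preference is a property of the optimal agent's behavior at
this scale. The acceptance assertion that the difference model ranks
first is kept in its published direction and fails.

## Synthetic designs and the data they do not emulate

`design_exp1_difficulty` balances all 144 signed pairs exactly (8 each in
1152 trials); `design_exp2` builds the 12×12 (unknown) or same-sign 6×6
(known, split into blue and yellow blocks) grids with equal-strength
cells at exactly one-third frequency and an exactly uniform duration
marginal (0.1–1.65 s) for controlled blocks. The ± tag of zero coherence
is stored explicitly and decides the rewarded response on ties; feedback
designates the strictly stronger stimulus correct, randomly on
equal-strength trials. Simulated agents always respond, so miss-trial
repetition is not emulated; nor are sequential effects, lapses,
session-level drift, or any departure from the generating model itself.
Passing tests therefore certify the algorithms and their implementation,
not that human data follow these models.

## Problem sizes

The test suite and acceptance script run scaled studies chosen for a
single desktop core: generation/fitting at Δt = 10 ms with 120 (search)
to 1500 (final) simulations per condition for parameter recovery at 1152
trials; 640-trial datasets over a 4-strength grid for model-recovery
classification; 20,000-trial optimal-policy simulations; 10⁵-trial Monte
Carlo oracles. Package defaults remain at the full settings (Δt = 5 ms,
1000 simulations per condition, 10 starts).

## Reference parameters

κ = 13 (also the optimal-policy drift coefficient), u = 2.0, a = 2.0,
d = 1.2, Tnd = 0.35 s (σ = 0.05 s), B_mini = 0.8. These produce
hard–hard mean RTs near 1.9 s and easy–easy near 1.6 s, all four model
signatures, and a non-decision time identifiable to ±0.05 s from 1152
trials — at flatter-collapse settings the u/Tnd likelihood ridge is so
shallow that even the exact MLE scatters beyond that tolerance.

## Known limitations

Two-step/difference confusability is real: two-step datasets are often
classified as difference (the extra parameter buys little on its own
data), and on optimal-policy data the two models are close. The
smoothed likelihood is a biased estimator of the true likelihood at
small simulation counts; the held-out-seed evaluation removes the
optimizer-selection component but not the kernel approximation itself.
The MDP's evidence range truncates extreme beliefs at κ = 13. The
confidence-difference model rebuilds its log-odds map whenever κ changes
during fitting, which makes it the slowest model to fit.
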