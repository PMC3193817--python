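# Methods

## The kinetic model

The receptor is a continuous-time Markov chain on ten states. The resting
branch binds up to three agonist molecules — R ⇌ AR ⇌ A2R ⇌ A3R with
forward constants k1–k3 (mM⁻¹·s⁻¹) and backward l1–l3 (s⁻¹) — and the
fully occupied receptor gates into the open state, A3R ⇌ A3Ro (k4/l4, both
s⁻¹; gating is conformational, not binding). The desensitized branch
mirrors it: D ⇌ AD ⇌ A2D ⇌ A3D with binding m1–m3 (mM⁻¹·s⁻¹) and
unbinding n1–n3 (s⁻¹), plus the rapidly desensitizing state A3Df
(A3D ⇌ A3Df via m4/n4). Vertical desensitization/resensitization edges
connect the branches: R⇌D (d1/r1), AR⇌AD (d2/r2), A2R⇌A2D (d3/r3),
A3R⇌A3D (d4/r4) and, critically for the fast current decay, the open
state itself: A3Ro → A3Df with d5 and reopening A3Df → A3Ro with r5.

Two direction assignments deserve a note because they are fixed by the
physiology rather than by the naming pattern: **d5** is the exit from the
open state into the rapidly desensitizing state (it controls decay
acceleration), and **n4** is the drain from A3Df into the slowly
recovering bound pool A3D (it controls how much of the response is
trapped beyond the 30-s washout). Their reverses, r5 (reopening) and m4
(A3D → A3Df, 0.001 s⁻¹), are the only assignments consistent with both
the first-order units of every constant involved and the observed roles
of d5/n4 in decay and recovery.

Occupancies evolve by mass action, `dp/dt = Q(c) p`. `Q(c)` uses the
column convention: entry (j, i) is the propensity of i → j — the rate
constant multiplied by the agonist concentration c (in mM) for the six
binding steps k1–k3, m1–m3, unscaled otherwise — and each diagonal entry
is minus its column sum, so columns sum to zero and total occupancy is
conserved exactly. The current readout is the A3Ro occupancy ("fraction
of active receptors"); an optional linear scale converts it to pA with
the inward-negative sign convention.

Two packaged rate sets ship as YAML documents (`data/control.yaml`,
`data/mbcd.yaml`). They differ in exactly six constants: k4 75 → 40 s⁻¹
(slower gating → smaller peak), d5 9 → 13 s⁻¹ and n4 0.44 → 0.68 s⁻¹
(faster desensitization entry and hand-off → faster slow decay, poorer
recovery), and n1–n3 roughly doubled (0.01/0.02/0.03 →
0.019/0.038/0.057 s⁻¹).

## Simulation

Agonist application is piecewise constant (fast-step perfusion; no
exchange time constant is applied by default). Within each protocol
segment the generator is constant, so the simulator integrates segment by
segment with LSODA (analytic Jacobian = Q, rtol 1e-8, atol 1e-10) on a
uniform output grid, 1 kHz by default. The initial condition is the exact
zero-agonist steady state — effectively all receptors in R, with a D
fraction d1/(d1+r1) ≈ 1e-6 — which is the infinite-time limit of a
pre-pulse wash; a finite `pre_equilibration` option exists for protocols
that need one. The steady state is obtained by replacing one balance
equation of `Q v = 0` with the normalization row Σv = 1 and solving
directly; the residual and non-negativity are checked, and sampling-grid
round-off is clipped so no evaluation point leaves its segment.

Because the per-segment problem is linear, an exact solution by repeated
multiplication with `expm(Q Δt)` is available
(`propagate_expm_oracle`). It is computed by an entirely independent code
path and serves as the numerical oracle in the tests: LSODA and the
matrix exponential agree to < 1e-6 occupancy over full paired-pulse
protocols on both rate sets, mass is conserved to 1e-9 over 60 s, and
halving the solver tolerances moves reported peaks by < 1e-6.

## Trace analysis

* **Baseline / peak** — baseline is the mean of the last 100 ms (default,
  configurable) before the response window; the peak is the largest
  absolute deflection from baseline in the window, with the sign
  recorded. Flat traces are reported as peak 0 with a `no_response` flag.
* **10–90% rise time** — first crossings of 10% and 90% of the
  peak-minus-baseline magnitude, linearly interpolated between samples;
  rises completed within two sampling intervals are flagged
  resolution-limited. For a monoexponential onset this reproduces the
  closed form τ·ln 9.
* **Biexponential decay** — least squares (lmfit, Levenberg–Marquardt) of
  `A_f·exp(−t/τ_f) + A_s·exp(−t/τ_s)` on the deflection magnitude from
  the peak to the end of the agonist application. Components are ordered
  so τ_fast < τ_slow after the fit; initial guesses are τ_f = 10% and
  τ_s = 60% of the window with the starting amplitude split 60/40. A
  constant offset term is **off by default**: over a 2-s application a
  slow exponential and a constant are numerically degenerate, and
  including the offset sends τ_slow to unphysical values (∼10⁴ s) with a
  compensating amplitude. Fits with τ_f ≈ τ_s (within 5%) or a component
  amplitude below 1% of the peak are flagged effectively
  monoexponential. Calibration: noiseless self-fits recover parameters to
  < 0.1%; with 2% additive noise the median τ_slow error over 200
  replicates is < 5%.
* **Recovery** — 100 × second peak / first peak for a paired-pulse
  protocol; values above 100% are flagged, above 200% rejected.
* **Group statistics** — unpaired Student's t-test or Mann-Whitney,
  two-sided, reported as mean ± SEM with n. Rank-sum ties are mid-ranked;
  the exact null distribution is used for tie-free groups of n ≤ 20,
  otherwise the tie-corrected normal approximation. Two groups with zero
  pooled spread are returned as p = 1.

With these definitions the two packaged rate sets yield, under the
standard protocol (0.01 mM, 2-s pulses, 30-s interval, 1 kHz): control —
peak 0.531, rise 37 ms, τ_fast 0.141 s, τ_slow 3.05 s, recovery 24.4%;
MβCD — peak 0.379, rise 41 ms, τ_fast 0.139 s, τ_slow 1.93 s, recovery
19.1%. The condition contrast (peak ↓, τ_slow ↓, recovery ↓, rise and
τ_fast within 15%) is asserted as a property test.

## Rate-constant fitting

The optimizer replaces manual tuning. A fit specification names the free
constants (with positive finite bounds), the fixed base set, the target
features — any of peak amplitude, rise time, τ_fast, τ_slow, recovery — and
per-feature weights. The loss is the weighted sum of squared *relative*
deviations, making pA, seconds and percent commensurable; simulation or
fit failures inside the objective return a large finite penalty
(1e6) so derivative-free search can continue.

Search runs in log parameter space (constants span eight orders of
magnitude) with Nelder–Mead from the starting values, restarting from a
seeded jitter around the incumbent while the evaluation budget lasts;
seeded differential evolution is available as an alternative. Results are
deterministic given the specification (including its seed). A fit whose
final loss exceeds the tolerance (default 1e-4) is flagged not
converged — which is also how physically unreachable targets surface.
Only the parameter subsets with a clear physiological handle ({k4} for
amplitude; {d5, n4, n1–n3} for desensitization/recovery) are recommended;
freeing anything else warns, since 26 constants are not identifiable from
one macroscopic trace. Parameter recovery is verified from five seeded
perturbed starts: {k4, d5, n4} return to their generating values within
10% (in practice to ~1e-6 relative).

## Synthetic populations

Each synthetic cell is `holding − scale·occupancy(t) + noise`: the shared
kinetic trace for the cell's condition, scaled so its peak equals the
cell's latent peak current, shifted by the holding current and corrupted
by i.i.d. Gaussian noise (default σ = 5 pA at 10 kHz; optional 50 Hz hum
and linear drift are off by default). Latent peaks are lognormal —
positive by construction — with mean set to the group target and
between-cell SD = SEM·√n, the only calibration that reproduces the
printed SEM at the printed n. Capacitance is normal truncated at 5 pF;
the holding offset is normal with a 9-pA per-cell SD. The four presets
encode the reported group statistics: WT control 338 ± 26 pA (n = 33,
32 ± 2 pF), KI control 520 ± 58 pA (29 ± 2 pF), and the post-MβCD groups
with the reported ~30%/44% amplitude reductions, reduced capacitance and
a −85 pA holding level. Cell i of a population draws from the independent
stream seeded by (population seed, i), so any cell is reproducible in
isolation.

The generator emulates amplitude statistics, kinetics and stationary
recording noise. It does **not** emulate series-resistance or space-clamp
error, solution-exchange filtering, rundown within a recording, or any
correlation between amplitude and kinetics — so pipeline tests validate
the analysis chain and the model's condition contrasts, not robustness to
those artefacts.

A note on detection power: with between-cell SD = SEM·√n, the WT/KI
amplitude contrast (338 vs 520 pA, n = 33 each) has a standardized mean
difference of ≈ 2.86 standard errors, i.e. two-sided t-test power ≈ 0.86
at α = 0.05 (simulation: 177/200 replicates). Sample-mean calibration
checks are therefore pooled across replicate populations rather than
asserted on a single 33-cell draw, which would miss a 2-SEM band ~10% of
the time by construction.

## Problem sizes and defaults

Simulations sample at 1 kHz (protocol integration) by default; synthetic
acquisition defaults to 10 kHz with a 0.5-s pre-pulse baseline. Test and
pipeline runs that sweep many protocols or populations use 2–5 ms
sampling and 1 kHz acquisition with shortened tails — feature estimates
at these grids agree with finer ones within the tolerances asserted in
the resampling tests. The paired-pulse reproduction run uses the full
1 kHz default.

## Known limitations

- Macroscopic (mean-field) description only; no stochastic single-channel
  simulation, voltage dependence or permeation model.
- The allosteric extension describing very slow desensitization by
  ambient nucleotides is deliberately out of scope; the model targets
  short pulse applications.
- The biexponential decay description is an empirical summary; its time
  constants are fit-window dependent (window = peak to end of
  application, documented above).
- The feature-targeted loss is a surrogate for by-hand optimization; no
  posterior uncertainty over rate constants is computed.
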