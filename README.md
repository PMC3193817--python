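# p2x3kin

Kinetic modelling and patch-clamp trace analysis of **P2X3 receptor**
currents in trigeminal sensory neurons.

P2X3 is a fast-activating, fast-desensitizing ATP-gated cation channel of
sensory ganglia and a key transducer of nociceptive (including migraine-
related) signalling. Its hallmark in whole-cell recordings is a rapidly
rising inward current evoked by α,β-meATP that decays biexponentially
during the agonist pulse and recovers from desensitization only slowly
(tens of seconds). This package provides, in one place:

- the **cyclic ten-state Markov model** of receptor operation — sequential
  binding of three agonist molecules (R ⇌ AR ⇌ A2R ⇌ A3R), gating of the
  fully occupied receptor into the open state A3Ro, entry into a rapidly
  desensitizing state A3Df, and a parallel desensitized branch
  (D ⇌ AD ⇌ A2D ⇌ A3D) reached by vertical transitions from each resting
  state — with packaged rate-constant sets for the *control* condition and
  after *cholesterol depletion with methyl-β-cyclodextrin (MβCD)*;
- a mass-action ODE **simulator** for piecewise-constant agonist protocols
  (`dp/dt = Q(c) p`, with `Q(c)` the concentration-dependent generator
  matrix), plus an exact matrix-exponential propagator used as an
  independent numerical oracle;
- the standard **trace analyses**: peak amplitude vs. baseline, 10–90%
  rise time, biexponential desensitization fit (τ_fast, τ_slow),
  paired-pulse recovery, current density (pA/pF), and two-group statistics
  (unpaired t-test / Mann-Whitney) reported as mean ± SEM with n;
- a reproducible, seeded **rate-constant optimizer** that replaces manual
  tuning: derivative-free search in log space against target trace
  features;
- a **synthetic-data generator** emulating whole-cell recordings
  (per-cell lognormal amplitude variability, truncated-normal capacitance,
  holding-current offset, additive Gaussian recording noise) for the four
  groups wild-type/knock-in × control/MβCD.

## Worked example

```python
import p2x3kin as pk

control = pk.load_rate_set("control")
mbcd = pk.load_rate_set("MbCD")

# two 2-s pulses of 10 uM (0.01 mM) agonist, 30 s apart
for rates in (control, mbcd):
    res = pk.simulate_paired_pulse(rates, 0.01, 2.0, 30.0)
    feats = pk.simulated_features(rates)
    print(f"{rates.label:8s} peak={res.first_peak:.3f} "
          f"recovery={res.recovery_percent:.2f}% "
          f"tau_fast={feats['tau_fast']*1e3:.0f} ms "
          f"tau_slow={feats['tau_slow']:.2f} s")
```

prints

```
control  peak=0.531 recovery=24.36% tau_fast=141 ms tau_slow=3.05
MbCD     peak=0.379 recovery=19.13% tau_fast=139 ms tau_slow=1.93
```

Reading: under control rate constants just over half of the receptors are
open at the first peak, and after a 30-s washout a second identical pulse
recovers 24% of the first response — desensitized receptors are trapped in
the slowly unbinding A3D pool. The MβCD rate set (slower gating `k4`
75→40 s⁻¹, faster desensitization entry `d5` 9→13 s⁻¹ and `n4`
0.44→0.68 s⁻¹, doubled unbinding `n1`–`n3`) lowers the peak by ~29%,
shortens the slow decay by ~37% and impairs recovery, while the onset and
fast decay are essentially unchanged — the electrophysiological fingerprint
of lipid-raft disruption.

The same analyses run from the shell:

```sh
p2x3kin simulate --rates control --pairs 2 --out out/ctrl   # trace + summary
p2x3kin compare-conditions                                  # feature deltas
p2x3kin reproduce-fig5 --out out/fig5                       # both conditions + plot
p2x3kin synth --preset KI_control --n 33 --seed 1 --out out/ki
```

## Layout

- `src/p2x3kin/kinetic_model.py` — scheme, rate sets, generator, steady state
- `src/p2x3kin/simulator.py` — ODE integration, paired-pulse protocol, expm oracle
- `src/p2x3kin/trace_analysis.py` — peaks, rise time, biexponential fits, statistics
- `src/p2x3kin/fitting.py` — feature-targeted rate-constant optimization
- `src/p2x3kin/synthetic_data.py` — noisy population generator
- `src/p2x3kin/pipeline.py`, `cli.py` — workflows and the `p2x3kin` command
- `docs/methods.md` — model description, numerical choices, limitations
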