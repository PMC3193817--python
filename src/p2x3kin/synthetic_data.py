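"""Synthetic whole-cell recordings of agonist-evoked P2X3 currents.

Each synthetic cell is the kinetic-model open-state trace scaled to a
per-cell latent peak current (inward-negative pA), shifted by a holding
current and corrupted with additive white Gaussian recording noise.
Population structure mirrors the group statistics reported for mouse
trigeminal neurons: wild-type control peaks 338 +/- 26 pA (SEM, n = 33)
versus 520 +/- 58 pA for the Ca_V2.1 R192Q knock-in, capacitances near
32 +/- 2 pF (WT) falling to ~20 pF after cholesterol depletion, and
holding currents around -50 pA (control) to -85 pA (after MbCD).

Per-cell amplitudes are lognormal (positive by construction) with the
between-cell standard deviation derived from the target SEM as
``sd = sem * sqrt(n)``; capacitance is normal truncated at 5 pF.  Every
draw is reproducible from the population seed: cell ``i`` uses the
independent stream seeded by ``(seed, i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinetic_model import RateSet, load_rate_set
from .simulator import CurrentTrace, PulseProtocol, simulate

__all__ = [
    "PopulationSpec",
    "POPULATION_PRESETS",
    "preset_population",
    "generate_cell",
    "generate_population",
    "base_kinetic_trace",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Targets and acquisition settings for one recorded cell group."""

    condition: str = "WT_control"
    n_cells: int = 33
    peak_mean_pA: float = 338.0
    peak_sem_pA: float = 26.0
    capacitance_mean_pF: float = 32.0
    capacitance_sem_pF: float = 2.0
    rate_set: str = "control"
    concentration_mM: float = 0.01
    pulse_duration_s: float = 2.0
    baseline_s: float = 0.5
    tail_s: float = 1.0
    noise_sigma_pA: float = 5.0
    hum_amplitude_pA: float = 0.0  # mains interference, off by default
    hum_frequency_hz: float = 50.0
    drift_pA_per_s: float = 0.0  # slow baseline drift, off by default
    sampling_rate_hz: float = 10_000.0
    holding_mean_pA: float = -50.0
    holding_sd_pA: float = 9.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("peak_sem_pA", "capacitance_sem_pF", "noise_sigma_pA",
                     "holding_sd_pA"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.peak_mean_pA <= 0:
            raise ValueError("peak_mean_pA must be > 0")

    @property
    def peak_sd_pA(self) -> float:
        """Between-cell SD implied by the target SEM at the target n."""
        return self.peak_sem_pA * np.sqrt(self.n_cells)

    @property
    def capacitance_sd_pF(self) -> float:
        return self.capacitance_sem_pF * np.sqrt(self.n_cells)

    def protocol(self) -> PulseProtocol:
        return PulseProtocol.single_pulse(
            self.concentration_mM,
            self.pulse_duration_s,
            baseline=self.baseline_s,
            tail=self.tail_s,
            sampling_interval=1.0 / self.sampling_rate_hz,
        )


#: group statistics for the four recorded conditions (pA, pF); the two
#: MbCD peak targets apply the reported ~30% (WT) and ~44% (KI) reductions
POPULATION_PRESETS: dict[str, dict] = {
    "WT_control": dict(
        peak_mean_pA=338.0, peak_sem_pA=26.0,
        capacitance_mean_pF=32.0, capacitance_sem_pF=2.0,
        rate_set="control", holding_mean_pA=-50.0,
    ),
    "KI_control": dict(
        peak_mean_pA=520.0, peak_sem_pA=58.0,
        capacitance_mean_pF=29.0, capacitance_sem_pF=2.0,
        rate_set="control", holding_mean_pA=-50.0,
    ),
    "WT_MbCD": dict(
        peak_mean_pA=237.0, peak_sem_pA=26.0,
        capacitance_mean_pF=20.0, capacitance_sem_pF=2.0,
        rate_set="MbCD", holding_mean_pA=-85.0,
    ),
    "KI_MbCD": dict(
        peak_mean_pA=291.0, peak_sem_pA=30.0,
        capacitance_mean_pF=23.0, capacitance_sem_pF=2.0,
        rate_set="MbCD", holding_mean_pA=-85.0,
    ),
}


def preset_population(name: str, **overrides) -> PopulationSpec:
    """A :class:`PopulationSpec` for one of the four recorded conditions."""
    if name not in POPULATION_PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(POPULATION_PRESETS)}"
        )
    params = dict(POPULATION_PRESETS[name], condition=name)
    params.update(overrides)
    return PopulationSpec(**params)


def base_kinetic_trace(spec: PopulationSpec) -> CurrentTrace:
    """The noiseless open-state occupancy trace shared by all cells."""
    rates = load_rate_set(spec.rate_set)
    return simulate(rates, spec.protocol(), keep_states=False)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment match: X ~ LogNormal(mu, sigma) with E X = mean, SD X = sd
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _draw_latents(spec: PopulationSpec, rng: np.random.Generator) -> dict:
    mu, sigma = _lognormal_params(spec.peak_mean_pA, spec.peak_sd_pA)
    peak = float(rng.lognormal(mu, sigma))
    cap_sd = spec.capacitance_sd_pF
    if cap_sd > 0:
        lo = (5.0 - spec.capacitance_mean_pF) / cap_sd
        cap = float(
            stats.truncnorm.rvs(
                lo, np.inf, loc=spec.capacitance_mean_pF, scale=cap_sd,
                random_state=rng,
            )
        )
    else:
        cap = spec.capacitance_mean_pF
    holding = float(rng.normal(spec.holding_mean_pA, spec.holding_sd_pA))
    return {"peak_pA": peak, "capacitance_pF": cap, "holding_pA": holding}


def generate_cell(
    spec: PopulationSpec,
    cell_index: int,
    base_trace: CurrentTrace | None = None,
) -> CurrentTrace:
    """One synthetic whole-cell recording.

    The trace is ``holding - scale * occupancy + noise`` where ``scale``
    maps the simulated peak occupancy onto the cell's latent peak current.
    Reproducible: the same spec and cell index always give the same trace.
    """
    if base_trace is None:
        base_trace = base_kinetic_trace(spec)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, cell_index)))
    latents = _draw_latents(spec, rng)
    occ = base_trace.value
    occ_peak = float(occ.max())
    scale = latents["peak_pA"] / occ_peak
    noise = (
        rng.normal(0.0, spec.noise_sigma_pA, size=occ.size)
        if spec.noise_sigma_pA > 0
        else np.zeros(occ.size)
    )
    value = latents["holding_pA"] - scale * occ + noise
    if spec.hum_amplitude_pA > 0:
        phase = rng.uniform(0.0, 2 * np.pi)
        value = value + spec.hum_amplitude_pA * np.sin(
            2 * np.pi * spec.hum_frequency_hz * base_trace.time + phase
        )
    if spec.drift_pA_per_s != 0:
        value = value + spec.drift_pA_per_s * base_trace.time
    metadata = {
        "condition": spec.condition,
        "rate_set": spec.rate_set,
        "cell_index": cell_index,
        "seed": spec.seed,
        "units": "pA",
        "latent": latents,
        "noise_sigma_pA": spec.noise_sigma_pA,
        "pulse_window_s": (spec.baseline_s, spec.baseline_s + spec.pulse_duration_s),
    }
    return CurrentTrace(time=base_trace.time.copy(), value=value, metadata=metadata)


def generate_population(
    spec: PopulationSpec,
    base_trace: CurrentTrace | None = None,
) -> tuple[list[CurrentTrace], pd.DataFrame]:
    """All cells of one group plus a manifest of their latent parameters.

    The manifest records, per cell, the latent peak, capacitance and holding
    current together with the condition label and seed.  With a single cell
    the sample SEM is undefined and the manifest carries a flag.
    """
    if base_trace is None:
        base_trace = base_kinetic_trace(spec)
    traces = [
        generate_cell(spec, i, base_trace=base_trace) for i in range(spec.n_cells)
    ]
    rows = []
    for i, tr in enumerate(traces):
        latent = tr.metadata["latent"]
        rows.append(
            {
                "cell_id": f"{spec.condition}_{i:03d}",
                "cell_index": i,
                "condition": spec.condition,
                "rate_set": spec.rate_set,
                "latent_peak_pA": latent["peak_pA"],
                "capacitance_pF": latent["capacitance_pF"],
                "holding_pA": latent["holding_pA"],
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.attrs["seed"] = spec.seed
    manifest.attrs["sem_undefined"] = spec.n_cells < 2
    return traces, manifest
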