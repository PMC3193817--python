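"""Feature extraction from agonist-evoked current traces.

Implements the quantities used to characterise P2X3 receptor currents in
whole-cell recordings: peak amplitude relative to a pre-pulse baseline,
10-90% rise time of the onset, biexponential time constants of the
desensitizing decay (tau_fast < tau_slow), paired-pulse recovery and
current density (peak / capacitance).  Group comparisons use the unpaired
t-test or the Mann-Whitney rank-sum test and report mean +/- SEM with n.

All functions accept any object exposing ``time`` and ``value`` arrays
(e.g. :class:`~p2x3kin.simulator.CurrentTrace`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lmfit import Model
from scipy import stats

__all__ = [
    "TraceFeatures",
    "PeakResult",
    "RiseTimeResult",
    "BiexpFit",
    "GroupComparison",
    "AnalysisError",
    "FitError",
    "peak_and_baseline",
    "rise_time_10_90",
    "fit_biexponential",
    "recovery_ratio",
    "current_density",
    "compare_groups",
    "extract_features",
]


class AnalysisError(ValueError):
    """A trace does not admit the requested measurement."""


class FitError(RuntimeError):
    """Curve fit failed to converge; carries the initial guesses."""

    def __init__(self, message: str, initial_guesses: dict | None = None):
        super().__init__(message)
        self.initial_guesses = initial_guesses or {}


@dataclass(frozen=True)
class PeakResult:
    baseline: float
    peak_amplitude: float  # magnitude of the extremum relative to baseline
    peak_time: float
    sign: int  # -1 inward (downward), +1 outward
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class RiseTimeResult:
    seconds: float
    resolution_limited: bool = False


@dataclass(frozen=True)
class BiexpFit:
    amp_fast: float
    tau_fast: float
    amp_slow: float
    tau_slow: float
    offset: float
    r_squared: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class TraceFeatures:
    """The per-trace summary reported for each recording."""

    peak_amplitude: float
    rise_time_10_90: float
    tau_fast: float
    tau_slow: float
    amp_fast: float
    amp_slow: float
    fit_r2: float
    recovery_percent: float | None = None
    current_density: float | None = None
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "peak_amplitude": self.peak_amplitude,
            "rise_time_10_90": self.rise_time_10_90,
            "tau_fast": self.tau_fast,
            "tau_slow": self.tau_slow,
            "amp_fast": self.amp_fast,
            "amp_slow": self.amp_slow,
            "fit_r2": self.fit_r2,
            "recovery_percent": self.recovery_percent,
            "current_density": self.current_density,
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    method: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "group_a": {"mean": self.mean_a, "sem": self.sem_a, "n": self.n_a},
            "group_b": {"mean": self.mean_b, "sem": self.sem_b, "n": self.n_b},
        }


def _arrays(trace) -> tuple[np.ndarray, np.ndarray]:
    return np.asarray(trace.time, float), np.asarray(trace.value, float)


def peak_and_baseline(
    trace,
    response_window: tuple[float, float],
    baseline_window: float = 0.1,
) -> PeakResult:
    """Baseline from the pre-pulse segment and peak deflection magnitude.

    The baseline is the mean of the samples in the ``baseline_window``
    seconds immediately preceding the response window (all pre-window
    samples if fewer are available; 0 with a flag if there are none).
    """
    t, v = _arrays(trace)
    t_start, t_end = response_window
    in_window = (t >= t_start) & (t <= t_end)
    if not in_window.any():
        raise AnalysisError("response window contains no samples")
    flags: list[str] = []
    pre = (t < t_start) & (t >= t_start - baseline_window)
    if not pre.any():
        pre = t < t_start
    if pre.any():
        baseline = float(v[pre].mean())
        noise_sd = float(v[pre].std())
    else:
        baseline, noise_sd = 0.0, 0.0
        flags.append("no_baseline_samples")
    deflection = v[in_window] - baseline
    idx = int(np.argmax(np.abs(deflection)))
    peak = float(abs(deflection[idx]))
    sign = int(np.sign(deflection[idx])) or 1
    if peak <= max(3.0 * noise_sd, 0.0) and peak < 1e-12:
        flags.append("no_response")
        peak = 0.0 if peak < 1e-12 else peak
    elif noise_sd > 0 and peak <= 3.0 * noise_sd:
        flags.append("no_response")
    return PeakResult(
        baseline=baseline,
        peak_amplitude=peak,
        peak_time=float(t[in_window][idx]),
        sign=sign,
        flags=tuple(flags),
    )


def rise_time_10_90(
    trace,
    baseline: float,
    peak_amplitude: float,
    onset_window: tuple[float, float] | None = None,
) -> RiseTimeResult:
    """Time between the first 10% and 90% crossings of the rising phase.

    Crossing times are linearly interpolated between samples.  If both
    thresholds are crossed within two sampling intervals the measurement is
    flagged as resolution-limited.
    """
    t, v = _arrays(trace)
    if onset_window is not None:
        m = (t >= onset_window[0]) & (t <= onset_window[1])
        t, v = t[m], v[m]
    if peak_amplitude <= 0:
        raise AnalysisError("no onset detected: peak amplitude is zero")
    magnitude = np.abs(v - baseline)
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0

    def first_crossing(level: float) -> float:
        above = magnitude >= level
        if not above.any():
            raise AnalysisError(
                f"no onset detected: trace never reaches {level:.4g}"
            )
        i = int(np.argmax(above))
        if i == 0:
            return float(t[0])
        frac = (level - magnitude[i - 1]) / (magnitude[i] - magnitude[i - 1])
        return float(t[i - 1] + frac * (t[i] - t[i - 1]))

    t10 = first_crossing(0.10 * peak_amplitude)
    t90 = first_crossing(0.90 * peak_amplitude)
    rise = t90 - t10
    return RiseTimeResult(seconds=rise, resolution_limited=bool(rise <= 2 * dt))


def _biexp(x, amp_fast, tau_fast, amp_slow, tau_slow, offset):
    return (
        amp_fast * np.exp(-x / tau_fast)
        + amp_slow * np.exp(-x / tau_slow)
        + offset
    )


def fit_biexponential(
    trace,
    fit_window: tuple[float, float] | None = None,
    baseline: float = 0.0,
    with_offset: bool = False,
    min_samples: int = 20,
) -> BiexpFit:
    """Least-squares biexponential fit of the desensitizing decay.

    The decaying quantity is the deflection magnitude ``|value - baseline|``
    over ``fit_window`` (default: from the global extremum to the end of the
    trace).  Components are ordered so ``tau_fast < tau_slow``; the result
    is flagged ``effectively_monoexponential`` when the two time constants
    agree within 5% or one component amplitude is below 1% of the peak.

    The constant offset is off by default: over a short agonist application
    a slow exponential and a constant are nearly degenerate, which destroys
    the tau_slow estimate.
    """
    t, v = _arrays(trace)
    y_full = np.abs(v - baseline)
    if fit_window is None:
        start = float(t[int(np.argmax(y_full))])
        fit_window = (start, float(t[-1]))
    m = (t >= fit_window[0]) & (t <= fit_window[1])
    if m.sum() < min_samples:
        raise AnalysisError(
            f"fit window holds {int(m.sum())} samples; need >= {min_samples}"
        )
    x = t[m] - t[m][0]
    y = y_full[m]
    span = float(x[-1])
    y0 = float(y[0])

    model = Model(_biexp)
    params = model.make_params(
        amp_fast=dict(value=0.6 * y0, min=0.0),
        tau_fast=dict(value=0.10 * span, min=1e-6),
        amp_slow=dict(value=0.4 * y0, min=0.0),
        tau_slow=dict(value=0.60 * span, min=1e-6),
        offset=dict(value=0.0, vary=with_offset),
    )
    guesses = {name: float(p.value) for name, p in params.items()}
    result = model.fit(y, params, x=x)
    if not result.success:
        raise FitError(
            f"biexponential fit did not converge: {result.message}",
            initial_guesses=guesses,
        )
    p = result.params
    amp_f, tau_f = float(p["amp_fast"]), float(p["tau_fast"])
    amp_s, tau_s = float(p["amp_slow"]), float(p["tau_slow"])
    if tau_f > tau_s:
        amp_f, tau_f, amp_s, tau_s = amp_s, tau_s, amp_f, tau_f
    ss_res = float(np.sum(result.residual**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    flags: list[str] = []
    peak = max(y0, amp_f + amp_s)
    if abs(tau_s - tau_f) <= 0.05 * tau_s or min(amp_f, amp_s) < 0.01 * peak:
        flags.append("effectively_monoexponential")
    return BiexpFit(
        amp_fast=amp_f,
        tau_fast=tau_f,
        amp_slow=amp_s,
        tau_slow=tau_s,
        offset=float(p["offset"]),
        r_squared=r2,
        flags=tuple(flags),
    )


def recovery_ratio(first_peak: float, second_peak: float) -> float:
    """Paired-pulse recovery: ``100 * second_peak / first_peak`` (percent)."""
    if first_peak <= 0:
        raise AnalysisError("recovery undefined: first peak must be > 0")
    return 100.0 * second_peak / first_peak


def current_density(peak_pA: float, capacitance_pF: float) -> float:
    """Peak current normalized by cell capacitance (pA/pF)."""
    if capacitance_pF <= 0:
        raise AnalysisError(
            f"capacitance must be > 0 pF, got {capacitance_pF}"
        )
    return peak_pA / capacitance_pF


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: str = "t-test",
) -> GroupComparison:
    """Two-sided comparison of two independent feature groups.

    ``method`` is ``"t-test"`` (unpaired Student's t-test) or ``"rank-sum"``
    (Mann-Whitney).  Rank-sum ties are mid-ranked; the exact null
    distribution is enumerated for tie-free samples with n <= 20 per group,
    otherwise the normal approximation with tie correction is used.  Two
    groups with zero pooled spread are reported as p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("each group needs n >= 2")
    summary = dict(
        mean_a=float(a.mean()),
        sem_a=float(stats.sem(a)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sem_b=float(stats.sem(b)),
        n_b=int(b.size),
    )
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return GroupComparison(statistic=0.0, p_value=1.0, method=method, **summary)
    if method == "t-test":
        res = stats.ttest_ind(a, b)
        return GroupComparison(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            method=method,
            **summary,
        )
    if method == "rank-sum":
        has_ties = np.unique(pooled).size < pooled.size
        exact = (not has_ties) and a.size <= 20 and b.size <= 20
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        return GroupComparison(
            statistic=float(res.statistic),
            p_value=float(min(res.pvalue, 1.0)),
            method=method,
            **summary,
        )
    raise ValueError(f"unknown method {method!r}; use 't-test' or 'rank-sum'")


def extract_features(
    trace,
    pulse_start: float,
    pulse_end: float,
    baseline_window: float = 0.1,
    capacitance_pF: float | None = None,
    second_peak: float | None = None,
    with_offset: bool = False,
) -> TraceFeatures:
    """Run the full single-trace analysis for one agonist application.

    Peak and baseline come from :func:`peak_and_baseline`; the decay is
    fitted from the peak to the end of the agonist application
    (``pulse_end``).  ``second_peak`` (same units as the trace) adds the
    paired-pulse recovery; ``capacitance_pF`` adds the current density.
    """
    pk = peak_and_baseline(trace, (pulse_start, pulse_end), baseline_window)
    flags = list(pk.flags)
    rise = rise_time_10_90(
        trace, pk.baseline, pk.peak_amplitude, onset_window=(pulse_start, pk.peak_time)
    )
    if rise.resolution_limited:
        flags.append("rise_time_resolution_limited")
    fit = fit_biexponential(
        trace, fit_window=(pk.peak_time, pulse_end), baseline=pk.baseline,
        with_offset=with_offset,
    )
    flags.extend(fit.flags)
    recovery = None
    if second_peak is not None:
        recovery = recovery_ratio(pk.peak_amplitude, second_peak)
        if recovery > 200:
            raise AnalysisError(f"recovery {recovery:.1f}% outside [0, 200]")
        if recovery > 100:
            flags.append("recovery_above_100")
    density = None
    if capacitance_pF is not None:
        density = current_density(pk.peak_amplitude, capacitance_pF)
    return TraceFeatures(
        peak_amplitude=pk.peak_amplitude,
        rise_time_10_90=rise.seconds,
        tau_fast=fit.tau_fast,
        tau_slow=fit.tau_slow,
        amp_fast=fit.amp_fast,
        amp_slow=fit.amp_slow,
        fit_r2=fit.r_squared,
        recovery_percent=recovery,
        current_density=density,
        flags=tuple(flags),
    )
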