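"""Sweep drivers and synthetic fixtures.

A "condition" is one cell of the experimental design: (patch area,
presynaptic current I0, signal frequency, exogenous noise power D).
:func:`run_condition` simulates a seeded batch of runs for one cell and
reduces it to firing-rate, power and SNR statistics; the sweep drivers
map it over a frequency grid (signal-frequency sensitivity) or a noise
grid (stochastic-resonance curve, with the optimum noise power D_opt).

Every cell derives its own seed from the sweep master seed, so a sweep
is bit-reproducible and each row equals a direct `run_condition` call
with the same seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from . import _kernels
from .channel_kinetics import MembranePatch, steady_state_counts
from .membrane_sim import SimConfig, SimulationTrace, iter_traces
from .noise_and_stimulus import NoiseSpec, StimulusSpec
from .spike_spectral_analysis import (
    PSDEstimate,
    SpikeTrain,
    adjacent_psd_correlation,
    averaged_psd,
    detect_spikes,
    firing_rate_stats,
    pulse_train,
    snr,
    total_power,
)

logger = logging.getLogger(__name__)

#: Default signal-frequency grid (Hz): spans the studied 10-500 Hz band
#: and contains the 150 Hz sensitivity peak.
DEFAULT_FREQUENCIES = (10.0, 50.0, 100.0, 150.0, 200.0, 300.0, 400.0, 500.0)

#: Default noise-power grid (mV^2): spans 0.7-25 and contains the
#: optimum levels 2, 7 and 12 reported for the impaired conditions.
DEFAULT_NOISE_POWERS = (0.7, 2.0, 4.0, 7.0, 12.0, 18.0, 25.0)


@dataclass
class ConditionResult:
    """Reduced statistics for one experimental cell."""

    area: float
    i0: float
    frequency: float
    d: float | None
    n_runs: int
    n_failed: int
    rate_mean: float
    rate_se: float
    snr: float
    snr_se: float
    background: float
    rho: float | None
    total_power_mean: float
    seed: int
    psd: PSDEstimate | None = None

    def to_row(self) -> dict[str, Any]:
        return {
            "area": self.area, "i0": self.i0, "frequency": self.frequency,
            "d": np.nan if self.d is None else self.d,
            "n_runs": self.n_runs, "n_failed": self.n_failed,
            "rate_mean": self.rate_mean, "rate_se": self.rate_se,
            "snr": self.snr, "snr_se": self.snr_se,
            "background": self.background,
            "rho": np.nan if self.rho is None else self.rho,
            "total_power_mean": self.total_power_mean, "seed": self.seed,
        }


def run_condition(
    area: float,
    i0: float,
    frequency: float = 150.0,
    amplitude: float = 0.5,
    d: float | None = None,
    n_runs: int = 100,
    master_seed: int = 0,
    dt: float = 0.01,
    duration: float = 1.0,
    bin_width: float = 0.5,
    omega_c: float = 2.5e3,
    keep_psd: bool = False,
) -> ConditionResult:
    """Simulate one cell and reduce it to rates, power and SNR.

    ``d=None`` (or 0) disables the exogenous noise.  Divergent runs are
    excluded from the statistics and counted in ``n_failed``.
    """
    t_start = time.perf_counter()
    stimulus = StimulusSpec(frequency=frequency, amplitude=amplitude, i0=i0)
    noise = None if (d is None or d == 0) else NoiseSpec(d=d, omega_c=omega_c)
    config = SimConfig(patch=MembranePatch(area=area), stimulus=stimulus,
                       noise=noise, i0=i0, dt=dt, duration=duration,
                       n_runs=n_runs, master_seed=master_seed)
    trains: list[SpikeTrain] = []
    n_failed = 0
    for trace in iter_traces(config):
        if trace.failed:
            n_failed += 1
            continue
        trains.append(detect_spikes(trace))
    if n_failed:
        logger.warning("condition (area=%g, i0=%g, f=%g, d=%s): %d/%d runs "
                       "diverged and were excluded", area, i0, frequency, d,
                       n_failed, n_runs)
    pulses = [pulse_train(tr, bin_width) for tr in trains]
    rate_mean, rate_se = firing_rate_stats(trains)
    power_mean = float(np.mean([total_power(p) for p in pulses]))
    psd = averaged_psd(pulses)
    est = snr(psd, frequency)
    rho = est.rho
    logger.info("condition (area=%g, i0=%g, f=%g, d=%s): %d runs in %.1f s",
                area, i0, frequency, d, len(trains),
                time.perf_counter() - t_start)
    return ConditionResult(
        area=area, i0=i0, frequency=frequency, d=d,
        n_runs=len(trains), n_failed=n_failed,
        rate_mean=rate_mean, rate_se=rate_se,
        snr=est.snr, snr_se=est.se, background=est.background, rho=rho,
        total_power_mean=power_mean, seed=master_seed,
        psd=psd if keep_psd else None,
    )


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for the sweep drivers.

    Frequencies are swept without exogenous noise; noise powers are
    swept at a fixed signal frequency.  ``n_runs`` applies per cell.
    """

    areas: tuple[float, ...] = (200.0, 300.0, 600.0)
    currents: tuple[float, ...] = (2.0, 4.0, 7.0)
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    noise_powers: tuple[float, ...] = DEFAULT_NOISE_POWERS
    amplitude: float = 0.5
    n_runs: int = 100
    master_seed: int = 0
    dt: float = 0.01
    duration: float = 1.0

    def __post_init__(self) -> None:
        if not self.areas or not self.currents:
            raise ValueError("areas and currents must be non-empty")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("frequencies must be positive")
        if any(d < 0 for d in self.noise_powers):
            raise ValueError("noise powers must be >= 0")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")


@dataclass
class SweepResult:
    """Long-format result table plus a per-condition summary."""

    table: pd.DataFrame
    summary: pd.DataFrame
    spec: SweepSpec


def _cell_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), 7, index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_frequency_sweep(spec: SweepSpec) -> SweepResult:
    """SNR versus signal frequency for every (area, I0), no exogenous noise.

    The summary records, per condition, the grid argmax of the SNR and
    its value — the bell-shaped frequency sensitivity reduced to its
    peak.
    """
    rows = []
    idx = 0
    for area in spec.areas:
        for i0 in spec.currents:
            for f in spec.frequencies:
                res = run_condition(
                    area=area, i0=i0, frequency=f, amplitude=spec.amplitude,
                    d=None, n_runs=spec.n_runs,
                    master_seed=_cell_seed(spec.master_seed, idx),
                    dt=spec.dt, duration=spec.duration)
                rows.append(res.to_row())
                idx += 1
    table = pd.DataFrame(rows)
    summary_rows = []
    for (area, i0), grp in table.groupby(["area", "i0"]):
        if grp["snr"].notna().any():
            best = grp.loc[grp["snr"].idxmax()]
            summary_rows.append({"area": area, "i0": i0,
                                 "f_opt": best["frequency"],
                                 "snr_max": best["snr"],
                                 "snr_max_se": best["snr_se"]})
        else:
            summary_rows.append({"area": area, "i0": i0, "f_opt": np.nan,
                                 "snr_max": np.nan, "snr_max_se": np.nan})
    return SweepResult(table=table, summary=pd.DataFrame(summary_rows),
                       spec=spec)


def run_noise_sweep(spec: SweepSpec, frequency: float = 150.0) -> SweepResult:
    """SNR and firing rate versus exogenous noise power D.

    The signal is fixed (150 Hz, 500 uV by default); the summary gives
    the optimum noise power D_opt (grid argmax of the SNR) per
    condition — the stochastic-resonance peak.
    """
    rows = []
    idx = 0
    for area in spec.areas:
        for i0 in spec.currents:
            for d in spec.noise_powers:
                res = run_condition(
                    area=area, i0=i0, frequency=frequency,
                    amplitude=spec.amplitude, d=d, n_runs=spec.n_runs,
                    master_seed=_cell_seed(spec.master_seed, idx),
                    dt=spec.dt, duration=spec.duration)
                rows.append(res.to_row())
                idx += 1
    table = pd.DataFrame(rows)
    summary_rows = []
    for (area, i0), grp in table.groupby(["area", "i0"]):
        if grp["snr"].notna().any():
            best = grp.loc[grp["snr"].idxmax()]
            summary_rows.append({"area": area, "i0": i0, "d_opt": best["d"],
                                 "snr_max": best["snr"],
                                 "snr_max_se": best["snr_se"]})
        else:
            summary_rows.append({"area": area, "i0": i0, "d_opt": np.nan,
                                 "snr_max": np.nan, "snr_max_se": np.nan})
    return SweepResult(table=table, summary=pd.DataFrame(summary_rows),
                       spec=spec)


def make_fixtures(kind: str, params: dict[str, Any] | None = None,
                  seed: int = 0):
    """Seeded synthetic inputs with analytically known statistics.

    Kinds:

    - ``poisson_trains``: homogeneous Poisson spike trains (params:
      rate [spikes/s], n_runs, record_length [s], min_isi [ms]) —
      known mean rate, flat expected spectrum.
    - ``periodic_train``: one perfectly periodic train (params:
      frequency [Hz], record_length [s]) — spectral mass only at the
      harmonics.
    - ``clamped_ensemble``: voltage-clamped channel-ensemble occupancy
      trajectories (params: v [mV], area [um^2], duration [s],
      dt [ms], stride) — known binomial stationary law.
    - ``analytic_crossing_trace``: a voltage trace crossing 0 mV upward
      at prescribed times (params: crossing_times [ms],
      record_length [s], dt [ms]) — known spike times by construction.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "poisson_trains":
        rate = params.get("rate", 20.0)
        n_runs = params.get("n_runs", 100)
        record_length = params.get("record_length", 1.0)
        min_isi = params.get("min_isi", 0.5)
        trains = []
        for _ in range(n_runs):
            n = rng.poisson(rate * record_length)
            times = np.sort(rng.uniform(0.0, record_length * 1000.0, n))
            if times.size:
                keep = np.concatenate([[True], np.diff(times) >= min_isi])
                times = times[keep]
            trains.append(SpikeTrain(times, record_length))
        return trains
    if kind == "periodic_train":
        f = params.get("frequency", 100.0)
        record_length = params.get("record_length", 1.0)
        period = 1000.0 / f
        times = np.arange(0.0, record_length * 1000.0 - 1e-9, period)
        return SpikeTrain(times, record_length)
    if kind == "clamped_ensemble":
        v = params.get("v", -65.0)
        area = params.get("area", 300.0)
        duration = params.get("duration", 0.5)
        dt = params.get("dt", 0.01)
        stride = params.get("stride", 100)
        patch = MembranePatch(area=area)
        state = steady_state_counts(v, patch, rng)
        n_steps = int(round(duration * 1000.0 / dt))
        kernel_seed = int(rng.integers(2 ** 31))
        na_traj, k_traj, n_clamped = _kernels.run_clamped(
            state.na_counts, state.k_counts, float(v), float(dt),
            n_steps, int(stride), kernel_seed)
        return {"na_traj": na_traj, "k_traj": k_traj,
                "n_clamped": int(n_clamped), "patch": patch, "v": v,
                "dt": dt, "stride": stride}
    if kind == "analytic_crossing_trace":
        crossing_times = np.asarray(params.get("crossing_times",
                                               [100.0, 300.0, 500.0]))
        record_length = params.get("record_length", 1.0)
        dt = params.get("dt", 0.01)
        n = int(round(record_length * 1000.0 / dt))
        t = np.arange(n) * dt
        v = np.full(n, -65.0)
        for tc in crossing_times:
            # linear ramp through 0 mV exactly at tc, slope 50 mV/ms
            mask = np.abs(t - tc) <= 1.0
            v[mask] = np.clip(50.0 * (t[mask] - tc), -65.0, 50.0)
        return SimulationTrace(t=t, v=v, v_total=v.copy(), dt=dt)
    raise ValueError(f"unknown fixture kind {kind!r}")
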