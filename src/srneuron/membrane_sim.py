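"""Stochastic membrane-patch simulation.

The membrane is the usual HH circuit — capacitance in parallel with Na,
K and leak branches plus a constant presynaptic current I0 — with the
macroscopic conductances replaced by gamma * N_open / area from the
finite channel ensembles.  The exogenous sinusoid and noise are series
voltage sources: the gating rates and the ionic driving forces see the
total voltage V_tot = V + V_ES + V_noise, while the capacitive
forward-Euler update applies to the physiological voltage V (the source
supplies its own displacement current).

Runs start at the deterministic resting potential of the unperturbed
model with channel states drawn from the clamped stationary law there;
no transient is discarded — records are analysed whole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import optimize

from . import _kernels
from .channel_kinetics import (
    HHParams,
    MembranePatch,
    steady_state_counts,
    steady_state_gates,
)
from .noise_and_stimulus import NoiseSpec, StimulusSpec, lorentzian_noise, sinusoid

logger = logging.getLogger(__name__)

#: |V| beyond which a run is declared numerically divergent (mV).
BLOWUP_LIMIT = 200.0


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to reproduce a batch of runs.

    dt in ms (default 0.01 = 10 us), duration in s (default 1).
    ``mode`` selects stochastic channel ensembles ("stochastic"), their
    expected-value (master-equation) limit ("expected"), or the classic
    m^3 h / n^4 ODE model ("deterministic").
    """

    patch: MembranePatch
    stimulus: StimulusSpec | None = None
    noise: NoiseSpec | None = None
    hh: HHParams = field(default_factory=HHParams)
    i0: float = 0.0
    dt: float = 0.01
    duration: float = 1.0
    n_runs: int = 1
    master_seed: int = 0
    mode: str = "stochastic"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.mode not in ("stochastic", "expected", "deterministic"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * 1000.0 / self.dt))


@dataclass
class SimulationTrace:
    """One simulated record.

    ``v`` is the physiological membrane voltage (spike detection runs on
    it); ``v_total`` is v plus the series perturbations — the voltage
    the channel gates saw.  Both are sampled on ``t`` (ms).
    """

    t: np.ndarray
    v: np.ndarray
    v_total: np.ndarray
    dt: float
    run_index: int = 0
    failed: bool = False
    n_clamped: int = 0

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.v) == len(self.v_total)):
            raise ValueError("t, v and v_total must have equal length")

    @property
    def record_length(self) -> float:
        """Record length in seconds."""
        return len(self.v) * self.dt * 1e-3


def resting_potential(config: SimConfig) -> float:
    """Resting voltage of the deterministic unperturbed model (~ -65 mV).

    Solves the steady-state current balance without any stimulation
    (I0, signal and noise all absent) for V in [-90, -35] mV.  Every
    run starts from this rest with stationary channel states; the
    constant presynaptic current switches on at t = 0, and its onset
    transient is part of the record, as is the convention for
    step-current protocols.
    """
    hh = config.hh
    patch = config.patch
    gbar_na = hh.gamma_na * patch.density_na / 10.0
    gbar_k = hh.gamma_k * patch.density_k / 10.0

    def balance(v: float) -> float:
        m, h, n = steady_state_gates(v)
        return (-gbar_na * m ** 3 * h * (v - hh.v_na)
                - gbar_k * n ** 4 * (v - hh.v_k)
                - hh.g_leak * (v - hh.v_leak))

    return float(optimize.brentq(balance, -90.0, -35.0, xtol=1e-10))


def _drive(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Series perturbation V_ES + V_noise sampled on the step grid."""
    n = config.n_steps
    out = np.zeros(n)
    if config.stimulus is not None:
        out += sinusoid(config.stimulus, config.dt, n)
    if config.noise is not None and config.noise.d > 0:
        out += lorentzian_noise(config.noise, config.dt, n, rng)
    return out


def _run_seeds(config: SimConfig, run: int) -> tuple[np.random.Generator, int]:
    """Independent per-run RNG streams derived from the master seed."""
    ss = np.random.SeedSequence([int(config.master_seed), run])
    ss_kernel, ss_numpy = ss.spawn(2)
    kernel_seed = int(ss_kernel.generate_state(1)[0] % (2 ** 31))
    return np.random.default_rng(ss_numpy), kernel_seed


def iter_traces(config: SimConfig) -> Iterator[SimulationTrace]:
    """Lazily yield the ``n_runs`` traces of a batch.

    Memory-friendly alternative to :func:`simulate` for large batches:
    each trace can be reduced (e.g. to its spike train) and dropped.
    Divergent runs are yielded with ``failed=True`` and a warning, so
    callers can exclude them without losing the run accounting.
    """
    v0 = resting_potential(config)
    hh = config.hh
    patch = config.patch
    f_na = hh.gamma_na / (10.0 * patch.area)
    f_k = hh.gamma_k / (10.0 * patch.area)
    gbar_na = hh.gamma_na * patch.density_na / 10.0
    gbar_k = hh.gamma_k * patch.density_k / 10.0
    t = np.arange(config.n_steps) * config.dt

    for run in range(config.n_runs):
        rng, kernel_seed = _run_seeds(config, run)
        drive = _drive(config, rng)
        n_clamped = 0
        if config.mode == "deterministic":
            m0, h0, n0 = steady_state_gates(v0)
            v, v_tot, blow = _kernels.run_deterministic(
                v0, m0, h0, n0, drive, config.dt, config.i0,
                gbar_na, gbar_k, hh.cm, hh.g_leak, hh.v_na, hh.v_k, hh.v_leak)
        elif config.mode == "expected":
            na, k = (arr.astype(np.float64) for arr in
                     _expected_occupancies(v0, patch))
            v, v_tot, n_clamped, blow = _kernels.run_expected(
                v0, na, k, drive, config.dt, config.i0, f_na, f_k,
                hh.cm, hh.g_leak, hh.v_na, hh.v_k, hh.v_leak)
        else:
            state = steady_state_counts(v0, patch, rng)
            v, v_tot, n_clamped, blow = _kernels.run_stochastic(
                v0, state.na_counts, state.k_counts, drive, config.dt,
                config.i0, f_na, f_k, hh.cm, hh.g_leak,
                hh.v_na, hh.v_k, hh.v_leak, kernel_seed)
        if n_clamped:
            logger.warning("run %d: transition probabilities clamped at %d "
                           "steps; dt is too large", run, n_clamped)
        if blow:
            logger.warning("run %d diverged at step %d (|V| > %g mV); "
                           "flagged as failed", run, blow, BLOWUP_LIMIT)
        yield SimulationTrace(t=t, v=v, v_total=v_tot, dt=config.dt,
                              run_index=run, failed=bool(blow),
                              n_clamped=int(n_clamped))


def _expected_occupancies(v0: float, patch: MembranePatch):
    from .channel_kinetics import expected_state

    return expected_state(v0, patch)


def simulate(config: SimConfig) -> list[SimulationTrace]:
    """Run the batch and return all traces (see :func:`iter_traces`)."""
    return list(iter_traces(config))


def _sustained_firing(config: SimConfig, i0: float,
                      window: float = 0.5, min_spikes: int = 2) -> bool:
    """Does the deterministic model fire >= min_spikes in the final window (s)?"""
    from .spike_spectral_analysis import detect_spikes

    cfg = replace(config, i0=i0, mode="deterministic", n_runs=1)
    trace = next(iter_traces(cfg))
    if trace.failed:
        return False
    train = detect_spikes(trace)
    t_min = (cfg.duration - window) * 1000.0
    return int((train.times >= t_min).sum()) >= min_spikes


def find_firing_threshold(
    config: SimConfig,
    tolerance: float = 0.05,
    bracket: tuple[float, float] = (0.0, 15.0),
) -> float:
    """Repetitive-firing current threshold I0th (uA/cm^2) by bisection.

    The deterministic model behaves as an oscillator once the constant
    current exceeds a threshold; "sustained firing" is operationalised
    as at least two spikes in the final 500 ms of a 1 s record started
    from rest.
    """
    lo, hi = bracket
    if _sustained_firing(config, lo):
        raise ValueError("lower bracket already fires; widen the bracket")
    if not _sustained_firing(config, hi):
        raise ValueError("upper bracket does not fire; widen the bracket")
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if _sustained_firing(config, mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
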