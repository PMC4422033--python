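"""From voltage traces to spike trains, spectra and SNR.

The analysis chain mirrors the standard stochastic-resonance workflow
for neuronal time encoding:

1. spikes are detected as upward threshold crossings of the
   physiological voltage (0 mV default, 2 ms dead time);
2. each record is reduced to a pulse train U(t) of uniform 100 mV
   pulses, one bin per spike, discarding spike shape;
3. one-sided rectangular-window periodograms of U(t) are averaged over
   the R runs of a batch (1 Hz spacing for 1 s records);
4. the SNR at the forcing frequency f_s is the averaged PSD at f_s over
   the mean of the averaged PSD 1 Hz below and above, with a standard
   error propagated through the ratio of the three correlated means.

An SNR of 1 means the signal is undetectable in the spike timing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .membrane_sim import SimulationTrace

#: Pulse amplitude used for U(t), mV.
PULSE_AMPLITUDE = 100.0


@dataclass
class SpikeTrain:
    """Spike times in ms (strictly increasing) within a record of
    ``record_length`` seconds."""

    times: np.ndarray
    record_length: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (np.diff(self.times) <= 0).any():
            raise ValueError("spike times must be strictly increasing")
        if self.times.size and (
                self.times[0] < 0
                or self.times[-1] > self.record_length * 1000.0):
            raise ValueError("spike times outside the record")

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    @property
    def rate(self) -> float:
        """Spikes per second over the record."""
        return self.n_spikes / self.record_length


@dataclass
class PulseTrain:
    """Binned Dirac-pulse representation U(t) of a spike train."""

    samples: np.ndarray
    bin_width: float

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.bin_width

    @property
    def record_length(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class PSDEstimate:
    """Run-averaged one-sided periodogram with per-frequency errors.

    ``per_run`` (R x n_freq) is retained so that covariances between
    frequency bins — needed for the SNR error — can be estimated.
    """

    freqs: np.ndarray
    mean_psd: np.ndarray
    se_psd: np.ndarray
    n_runs: int
    per_run: np.ndarray

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class SNREstimate:
    """SNR at the forcing frequency with a propagated standard error.

    ``background`` is the mean PSD at f_s +- 1 bin; ``rho`` the
    across-run correlation between the two background bins (None when
    degenerate).  ``valid`` is False when the background is zero (a
    silent batch), in which case snr/se are NaN.
    """

    f_s: float
    snr: float
    se: float
    background: float
    rho: float | None
    n_runs: int
    valid: bool = True


def detect_spikes(trace: SimulationTrace, threshold: float = 0.0,
                  dead_time: float = 2.0) -> SpikeTrain:
    """Detect spikes as upward crossings of ``threshold`` on V.

    Crossings closer than ``dead_time`` (ms) after an accepted spike are
    ignored; with a 0 mV threshold this is far above subthreshold
    fluctuations and well below spike peaks, so detection is insensitive
    to the exact values.
    """
    v = np.asarray(trace.v)
    if not np.isfinite(v).all():
        raise ValueError("trace contains non-finite voltages")
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    last = -np.inf
    for idx in crossings:
        t = trace.t[idx]
        if t - last >= dead_time:
            times.append(t)
            last = t
    return SpikeTrain(np.asarray(times), trace.record_length)


def pulse_train(train: SpikeTrain, bin_width: float = 0.5) -> PulseTrain:
    """Convert a spike train to U(t): one 100 mV bin per spike.

    The default 0.5 ms bin (2 kHz sampling) gives 1 Hz spectral spacing
    on a 1 s record with a 1 kHz Nyquist frequency.  Two spikes sharing
    a bin violates the dead-time precondition and raises.
    """
    n_bins = int(round(train.record_length * 1000.0 / bin_width))
    samples = np.zeros(n_bins)
    if train.n_spikes:
        idx = np.minimum((train.times / bin_width).astype(int), n_bins - 1)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("two spikes fell in one bin; "
                             "bin_width must be below the dead time")
        samples[idx] = PULSE_AMPLITUDE
    return PulseTrain(samples, bin_width)


def total_power(pulse: PulseTrain) -> float:
    """Time-averaged power of U(t) over the record (mV^2).

    Proportional to the spike count: each spike contributes
    amplitude^2 / n_bins.  Only ratios of this quantity are
    normalisation-independent.
    """
    return float(np.mean(pulse.samples ** 2))


def averaged_psd(pulses: list[PulseTrain]) -> PSDEstimate:
    """Average one-sided periodograms over the runs of a batch.

    Plain rectangular-window periodogram per run (no detrending, no
    segmenting), FFT-based; per-frequency mean and standard error over
    runs.  Requires >= 2 runs of identical length and bin width.
    """
    if len(pulses) < 2:
        raise ValueError("need at least 2 runs for an averaged PSD")
    n = len(pulses[0].samples)
    bw = pulses[0].bin_width
    if any(len(p.samples) != n or p.bin_width != bw for p in pulses):
        raise ValueError("all pulse trains must share length and bin width")
    data = np.stack([p.samples for p in pulses])
    freqs, pxx = signal.periodogram(data, fs=pulses[0].fs, window="boxcar",
                                    detrend=False, scaling="density", axis=-1)
    mean = pxx.mean(axis=0)
    se = pxx.std(axis=0, ddof=1) / np.sqrt(len(pulses))
    return PSDEstimate(freqs=freqs, mean_psd=mean, se_psd=se,
                       n_runs=len(pulses), per_run=pxx)


def _bin_index(psd: PSDEstimate, f: float) -> int:
    idx = int(round((f - psd.freqs[0]) / psd.df))
    if idx < 0 or idx >= len(psd.freqs) or abs(psd.freqs[idx] - f) > 1e-9:
        raise ValueError(f"frequency {f} Hz is not on the spectral grid")
    return idx


def snr(psd: PSDEstimate, f_s: float) -> SNREstimate:
    """SNR at the forcing frequency and its propagated standard error.

    snr = PSD(f_s) / mean(PSD(f_s - 1 bin), PSD(f_s + 1 bin)), on the
    run-averaged spectrum.  The error follows from first-order
    propagation for a ratio of three correlated means, using the
    across-run covariance of the PSD samples at the three bins.
    """
    ip = _bin_index(psd, f_s)
    ilo, ihi = ip - 1, ip + 1
    if ilo < 0 or ihi >= len(psd.freqs):
        raise ValueError("f_s +- 1 bin must lie on the spectral grid")
    peak = psd.mean_psd[ip]
    background = 0.5 * (psd.mean_psd[ilo] + psd.mean_psd[ihi])
    lo_runs = psd.per_run[:, ilo]
    hi_runs = psd.per_run[:, ihi]
    rho = _safe_corr(lo_runs, hi_runs)
    if background <= 0:
        return SNREstimate(f_s=f_s, snr=np.nan, se=np.nan, background=0.0,
                           rho=rho, n_runs=psd.n_runs, valid=False)
    value = peak / background
    cov = np.cov(np.stack([psd.per_run[:, ip], lo_runs, hi_runs]), ddof=1)
    grad = np.array([1.0 / background,
                     -value / (2.0 * background),
                     -value / (2.0 * background)])
    var = grad @ cov @ grad / psd.n_runs
    return SNREstimate(f_s=f_s, snr=float(value), se=float(np.sqrt(max(var, 0.0))),
                       background=float(background), rho=rho,
                       n_runs=psd.n_runs, valid=True)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float | None:
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def adjacent_psd_correlation(psd: PSDEstimate, f_s: float) -> dict[str, float | None]:
    """Across-run Pearson correlations between the PSD samples at the
    peak and background bins.

    Keys: "lo_hi" for (f_s-1, f_s+1) — the pair entering the SNR error —
    plus "peak_lo" and "peak_hi".  Degenerate (zero-variance) samples
    yield None.
    """
    if psd.n_runs < 10:
        raise ValueError("need >= 10 runs for a meaningful correlation")
    ip = _bin_index(psd, f_s)
    peak = psd.per_run[:, ip]
    lo = psd.per_run[:, ip - 1]
    hi = psd.per_run[:, ip + 1]
    return {
        "lo_hi": _safe_corr(lo, hi),
        "peak_lo": _safe_corr(peak, lo),
        "peak_hi": _safe_corr(peak, hi),
    }


def firing_rate_stats(trains: list[SpikeTrain]) -> tuple[float, float]:
    """Mean and standard error of the per-run firing rate (spikes/s)."""
    if len(trains) < 2:
        raise ValueError("need >= 2 runs for a standard error")
    rates = np.array([tr.rate for tr in trains])
    return float(rates.mean()), float(rates.std(ddof=1) / np.sqrt(len(rates)))
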