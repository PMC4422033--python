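"""Exogenous voltage perturbations: sinusoidal signal and Lorentzian noise.

Both act as voltage sources in series with the membrane: they offset the
voltage seen by the channel gates and by the ionic driving forces
without being integrated by the membrane capacitance.

The noise is a zero-mean Gaussian process whose power spectral density
is Lorentzian, A / (omega_c^2 + (2 pi f)^2): flat below the cutoff
angular frequency omega_c and rolling off as 1/f^2 above it.  It is
produced by passing white Gaussian noise through a discrete single-pole
low-pass filter with the exact pole exp(-omega_c * dt) and is calibrated
so that the stationary variance of the delivered (filtered) series is
exactly the noise power D, in mV^2 — D is the experimental knob, so its
meaning must be exact at the point of injection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class StimulusSpec:
    """Deterministic sinusoidal perturbation plus constant presynaptic drive.

    amplitude in mV (default 0.5 mV = 500 uV), frequency in Hz, phase in
    rad; i0 is the constant presynaptic current in uA/cm^2.
    """

    frequency: float
    amplitude: float = 0.5
    phase: float = 0.0
    i0: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Lorentzian-filtered Gaussian voltage noise.

    d: noise power (stationary variance of the delivered series), mV^2.
    omega_c: cutoff angular frequency of the Lorentzian, rad/s.
    seed: used when no external Generator is supplied.
    """

    d: float
    omega_c: float = 2.5e3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("noise power d must be >= 0")
        if self.omega_c <= 0:
            raise ValueError("omega_c must be > 0")


def sinusoid(spec: StimulusSpec, dt: float, n_steps: int) -> np.ndarray:
    """Sample the sinusoid on the simulation grid.

    ``series[k] = amplitude * sin(2 pi f * k dt + phase)`` with dt in ms.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be > 0")
    t_s = np.arange(n_steps) * (dt * 1e-3)
    return spec.amplitude * np.sin(2.0 * np.pi * spec.frequency * t_s
                                   + spec.phase)


def lorentzian_noise(
    spec: NoiseSpec,
    dt: float,
    n_steps: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Generate one stationary realisation of the voltage noise (mV).

    White Gaussian innovations are filtered by x[k] = a x[k-1] + w[k]
    with the exact pole a = exp(-omega_c dt); the innovation variance
    D (1 - a^2) makes the stationary variance of x exactly D.  The
    filter is started from a stationary draw and a warm-up of at least
    five correlation times is generated and discarded, so the returned
    series is stationary from the first sample.

    ``dt`` is in ms; ``rng`` falls back to ``spec.seed``.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be > 0")
    if spec.d == 0.0:
        return np.zeros(n_steps)
    if rng is None:
        rng = spec.seed
    rng = np.random.default_rng(rng)

    dt_s = dt * 1e-3
    a = np.exp(-spec.omega_c * dt_s)
    sigma_w = np.sqrt(spec.d * (1.0 - a * a))
    n_warm = max(int(np.ceil(5.0 / (spec.omega_c * dt_s))), 1)

    w = rng.standard_normal(n_steps + n_warm) * sigma_w
    x0 = rng.normal(0.0, np.sqrt(spec.d))
    x, _ = signal.lfilter([1.0], [1.0, -a], w, zi=np.array([a * x0]))
    return x[n_warm:]


def lorentzian_psd(freqs: np.ndarray, d: float, omega_c: float) -> np.ndarray:
    """Theoretical one-sided PSD (mV^2/Hz) of the noise at `freqs` (Hz).

    The amplitude constant is fixed by the variance normalisation:
    integrating A / (omega_c^2 + (2 pi f)^2) one-sided over f must give
    D, hence A = 4 D omega_c.
    """
    a_const = 4.0 * d * omega_c
    return a_const / (omega_c ** 2 + (2.0 * np.pi * np.asarray(freqs)) ** 2)
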