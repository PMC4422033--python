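"""Voltage-gated channel ensembles as Markov chains.

A Na channel is the combination of three identical activation particles
(m) and one inactivation particle (h); a K channel has four activation
particles (n).  With independent particles the single-channel chain
collapses onto occupancy counts over 8 Na states (i open m-particles,
h open/closed) and 5 K states (i open n-particles).  The ensemble is
advanced with a channel-state-tracking scheme: at every fixed time step
the number of channels leaving each state through each transition is
drawn jointly from a multinomial, so channel number is conserved exactly
and no count can go negative.

Rate functions are the standard squid-axon set in the modern convention
(resting potential near -65 mV).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from . import _kernels


class GatingRates(NamedTuple):
    """The six voltage-dependent transition rates, in 1/ms."""

    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float
    alpha_n: float
    beta_n: float


@dataclass(frozen=True)
class HHParams:
    """Membrane and single-channel constants.

    Units: cm uF/cm^2; g_leak mS/cm^2; reversal potentials mV;
    single-channel conductances pS.  The defaults reproduce the
    macroscopic maxima 120 (Na) and 36 (K) mS/cm^2 at channel densities
    of 60 and 18 per um^2 (20 pS each).
    """

    cm: float = 1.0
    g_leak: float = 0.3
    v_na: float = 50.0
    v_k: float = -77.0
    v_leak: float = -54.4
    gamma_na: float = 20.0
    gamma_k: float = 20.0

    def __post_init__(self) -> None:
        for name in ("cm", "g_leak", "gamma_na", "gamma_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class MembranePatch:
    """A membrane patch: area (um^2) and channel densities (1/um^2)."""

    area: float
    density_na: float = 60.0
    density_k: float = 18.0

    def __post_init__(self) -> None:
        if self.area <= 0 or self.density_na <= 0 or self.density_k <= 0:
            raise ValueError("patch area and densities must be positive")

    @property
    def n_na(self) -> int:
        return round(self.area * self.density_na)

    @property
    def n_k(self) -> int:
        return round(self.area * self.density_k)


@dataclass
class ChannelEnsembleState:
    """Integer occupancy counts of the 8 Na and 5 K channel states.

    ``na_counts[i, j]`` is the number of Na channels with i open
    m-particles (0..3) and h-particle state j (0 closed, 1 open);
    ``k_counts[i]`` the number of K channels with i open n-particles.
    """

    na_counts: np.ndarray
    k_counts: np.ndarray

    def __post_init__(self) -> None:
        self.na_counts = np.asarray(self.na_counts, dtype=np.int64)
        self.k_counts = np.asarray(self.k_counts, dtype=np.int64)
        if self.na_counts.shape != (4, 2) or self.k_counts.shape != (5,):
            raise ValueError("na_counts must be 4x2 and k_counts length 5")
        if (self.na_counts < 0).any() or (self.k_counts < 0).any():
            raise ValueError("occupancy counts must be non-negative")

    @property
    def n_na(self) -> int:
        return int(self.na_counts.sum())

    @property
    def n_k(self) -> int:
        return int(self.k_counts.sum())

    @property
    def n_open_na(self) -> int:
        """Conducting Na channels: all three m-particles and h open."""
        return int(self.na_counts[3, 1])

    @property
    def n_open_k(self) -> int:
        """Conducting K channels: all four n-particles open."""
        return int(self.k_counts[4])

    def copy(self) -> "ChannelEnsembleState":
        return ChannelEnsembleState(self.na_counts.copy(), self.k_counts.copy())


def rate_functions(v: float) -> GatingRates:
    """Evaluate the six gating rates at membrane voltage ``v`` (mV).

    The removable singularities of alpha_m (at -40 mV) and alpha_n (at
    -55 mV) are replaced by their analytic limits.
    """
    v = float(v)
    if not np.isfinite(v):
        raise ValueError(f"non-finite membrane voltage {v!r}; "
                         "the simulation has likely diverged")
    return GatingRates(*_kernels.rates_scalar(v))


def steady_state_gates(v: float) -> tuple[float, float, float]:
    """Per-particle open probabilities (m_inf, h_inf, n_inf) at voltage v."""
    r = rate_functions(v)
    return (
        r.alpha_m / (r.alpha_m + r.beta_m),
        r.alpha_h / (r.alpha_h + r.beta_h),
        r.alpha_n / (r.alpha_n + r.beta_n),
    )


def na_state_probabilities(v: float) -> np.ndarray:
    """Stationary 4x2 occupancy law of a Na channel under clamp at v.

    Product of a Binomial(3, m_inf) over activation particles and a
    Bernoulli(h_inf) for the inactivation particle.
    """
    m, h, _ = steady_state_gates(v)
    pm = stats.binom.pmf(np.arange(4), 3, m)
    return pm[:, None] * np.array([1.0 - h, h])[None, :]


def k_state_probabilities(v: float) -> np.ndarray:
    """Stationary length-5 occupancy law of a K channel: Binomial(4, n_inf)."""
    _, _, n = steady_state_gates(v)
    return stats.binom.pmf(np.arange(5), 4, n)


def expected_state(v: float, patch: MembranePatch) -> tuple[np.ndarray, np.ndarray]:
    """Expected (non-integer) stationary occupancies (na 4x2, k length 5).

    Returned as plain float arrays rather than a ChannelEnsembleState,
    since the expected counts are fractional.
    """
    na = na_state_probabilities(v) * patch.n_na
    k = k_state_probabilities(v) * patch.n_k
    return na, k


def steady_state_counts(
    v: float,
    patch: MembranePatch,
    rng: np.random.Generator | int | None = None,
) -> ChannelEnsembleState:
    """Draw channel counts from the clamped stationary law at voltage v.

    Na counts are a multinomial over the 8-state product-binomial law,
    K counts a multinomial over the 5-state binomial law; the sums equal
    the patch channel numbers by construction.
    """
    if patch.n_na <= 0 or patch.n_k <= 0:
        raise ValueError("patch must contain at least one channel of each kind")
    rng = np.random.default_rng(rng)
    p_na = na_state_probabilities(v).ravel()
    p_k = k_state_probabilities(v)
    na = rng.multinomial(patch.n_na, p_na / p_na.sum()).reshape(4, 2)
    k = rng.multinomial(patch.n_k, p_k / p_k.sum())
    return ChannelEnsembleState(na, k)


def ensemble_step(
    state: ChannelEnsembleState,
    v_gate: float,
    dt: float,
    seed: int | None = None,
) -> tuple[ChannelEnsembleState, bool]:
    """Advance both ensembles one step of length ``dt`` (ms) at gating
    voltage ``v_gate`` (mV).

    Returns the new state and a flag marking whether any per-state exit
    probability was clamped (a sign that dt is too large for the
    voltage reached).  ``seed`` reseeds the underlying RNG; leave None
    to continue its current stream.
    """
    if not np.isfinite(v_gate):
        raise ValueError("non-finite gating voltage")
    new = state.copy()
    if seed is not None:
        _kernels.seed_rng(int(seed))
    clamped = _kernels.step_ensembles(new.na_counts, new.k_counts,
                                      float(v_gate), float(dt))
    return new, bool(clamped)
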