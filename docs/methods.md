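# Methods

## The model

`srneuron` simulates a patch of excitable membrane as a stochastic
Hodgkin–Huxley (HH) circuit: a specific capacitance C_m in parallel with
Na, K and leak branches and a constant presynaptic current I0.  Na and K
conductances are not the macroscopic m³h / n⁴ expressions but arise from
finite ensembles of two-state gating particles: an Na channel conducts
when its three m-particles and its h-particle are all permissive, a K
channel when its four n-particles are.  With independent particles the
per-channel Markov chain collapses onto occupancy counts over 8 Na
states (i = open m-particles × h state) and 5 K states (i = open
n-particles), with transition rates

    (i,j) → (i±1,j) at (3−i)α_m / i·β_m,   (i,j) → (i,1−j) at α_h / β_h
    i → i±1 at (4−i)α_n / i·β_n

evaluated at the gating voltage.  The rate functions are the standard
squid-axon set in the modern convention (rest ≈ −65 mV; V_Na = 50,
V_K = −77, V_L = −54.4 mV; ḡ_Na = 120, ḡ_K = 36, g_L = 0.3 mS/cm²;
C_m = 1 µF/cm²).  This choice is anchored by the deterministic
repetitive-firing threshold, which the package recovers at
I0th ≈ 6.3 µA/cm².  Removable singularities of α_m (−40 mV) and α_n
(−55 mV) are replaced by their analytic limits within 10⁻⁶ mV.

A patch of area A µm² at densities 60 Na/µm² and 18 K/µm² carries
N_Na = 60A and N_K = 18A channels of 20 pS each, so the macroscopic
maxima are recovered exactly in the all-open limit.  Channel noise —
the endogenous noise — scales as 1/√N, i.e. decreases with patch area.

## Channel-state tracking

The ensembles advance on the same fixed grid as the voltage
(dt = 10 µs).  For every source state the numbers of channels taking
each outgoing transition in one step are drawn *jointly* from a
multinomial over {r₁dt, …, r_k dt, stay}, realised as a chain of
conditional binomials.  This guarantees conservation and
non-negativity by construction, unlike independent per-transition
binomials.  Per-state total exit probabilities stay ≪ 1 at dt = 10 µs
for physiological voltages; should they exceed 1 (they never do in the
studied regimes) they are renormalised and the event is counted and
logged.  Voltage-clamped occupancy histograms converge to the
product-binomial stationary law, and 50-channel ensembles agree with an
exact continuous-time (Gillespie) realisation of the same chain; both
are enforced by tests.  Replacing every draw by its mean gives the
expected-value mode — one forward-Euler step of the 13-state master
equation — whose trajectories track the deterministic m³h/n⁴ ODE model
to < 0.5 mV.

## Exogenous signal and noise, and how they couple

The stimulation signal is a weak sinusoid V_ES(t) = A sin(2πf t)
(A = 500 µV; f = 10–500 Hz) and the exogenous noise V_noise(t) is a
zero-mean Gaussian process with Lorentzian PSD ∝ 1/(ω_c² + (2πf)²),
ω_c = 2.5×10³ rad/s.  The noise is white Gaussian innovations through a
single-pole low-pass with the exact pole a = exp(−ω_c dt); the
innovation variance D(1−a²) makes the stationary variance of the
*delivered* series exactly the noise power D (mV²), which is the
experimental knob.  The filter is started from a stationary draw and a
warm-up of five correlation times is discarded.

Both act as voltage sources in series with the membrane.  Read
literally, a current balance written for V_m + V_ES + V_noise as one
state would make the total voltage autonomous and the stimulus
ineffectual; the only coupling under which a series perturbation does
anything is that the gating rates and the ionic driving forces see
V_tot = V + V_ES + V_noise while the capacitive update integrates the
physiological V (the source supplies its own displacement current):

    C_m dV/dt = −g_Na(V_tot−V_Na) − g_K(V_tot−V_K) − g_L(V_tot−V_L) + I0

with g_Na = γ_Na N_open_Na / A and g_K = γ_K N_open_K / A.  Forward
Euler at dt = 10 µs; the ensembles are stepped with the same V_tot.

Runs start at the resting potential of the unstimulated model (≈ −65 mV,
found by root-finding on the steady-state current balance) with channel
counts drawn from the clamped stationary law; I0 steps on at t = 0 and
the onset transient is part of the analysed record (1 s, no burn-in
discard).  Runs whose voltage leaves ±200 mV are flagged, logged and
excluded from statistics (none occur in the studied regimes).

## Analysis chain

Spikes are upward crossings of 0 mV on V with a 2 ms dead time — far
above subthreshold fluctuations, below all spike peaks, so the exact
values are uncritical.  Each record is reduced to a pulse train U(t):
one 100 mV bin per spike on a 0.5 ms grid (2 kHz sampling → 1 Hz
spectral spacing on 1 s records, 1 kHz Nyquist).  Per-run one-sided
rectangular-window periodograms (no detrending, no segmenting) are
averaged over the R runs of a batch; per-frequency standard errors come
from the across-run spread, and the per-run spectra are retained.

The SNR at the forcing frequency is

    SNR = PSD(f_s) / ½[PSD(f_s−1) + PSD(f_s+1)]

on the run-averaged spectrum; its standard error follows from
first-order propagation for a ratio of three correlated means, using
the measured across-run covariance of the three bins.  SNR = 1 means
the signal leaves no trace in the spike timing.  In our runs the
across-run correlation between adjacent periodogram bins is small
(|ρ| ≲ 0.25), as periodogram theory predicts; the propagation formula
is agnostic to its value.  A batch with zero background (no spikes in
any run) yields a flagged, undefined SNR rather than an error — this
happens for the largest patch under severe impairment.

The total power of U(t) is its time-averaged mean square, proportional
to the spike count (5 mV² per spike/s under this discretisation).  Its
absolute scale depends on the pulse-width convention, which is not
identifiable from uniform-height "Dirac" pulses alone; only power
*ratios* between conditions are treated as meaningful.

## Sweeps and replicate counts

The frequency sweep (no exogenous noise) uses the grid
{10, 50, 100, 150, 200, 300, 400, 500} Hz; the noise sweep (signal
fixed at 150 Hz / 500 µV) uses D ∈ {0.7, 2, 4, 7, 12, 18, 25} mV².
Both grids are configurable; the defaults bracket the studied ranges
and contain the reported optima.  D_opt is the grid argmax of SNR(D).
Replicate defaults follow the study design: R = 100 per condition
without exogenous noise, R = 300 with it (the periodogram average needs
more runs once the noise contributes background variance).  Every run
derives an independent RNG stream from (master_seed, run index) via
SeedSequence spawning — numba's internal RNG for the channel draws,
a numpy Generator for noise and initial conditions — so any batch,
sweep cell or table is bit-reproducible from its seed, and sweep rows
equal direct single-condition calls with the same cell seed.

Noise-generator verification is statistics-limited in a different way:
the Fisher information of an AR(1) pole gives SE(f_c) ≈ 3.6 Hz per 10⁶
samples, so pinning the Lorentzian half-power frequency (≈ 398 Hz) to
±1 Hz requires ≈ 2.4×10⁸ samples; the corresponding test averages
periodograms over 2400 seeded 1 s records and fits by Whittle maximum
likelihood (the correct estimator under χ² periodogram noise).

The acceptance script (`scripts/acceptance.py`) recomputes the six
headline cells at R = 300 each.  For the healthy-neuron cell
(600 µm², I0 = 7) the study design used R = 100; the script runs R = 300
there as well, purely to halve the SNR estimator's standard error.  The
desk-scale test suite uses R = 150 for rate checks and R = 30–100 per
sweep point, stated in each test.

## Known limitations

- Above the repetitive-firing onset (I0 between ≈ 6.3 and the Hopf point
  near 9.8 µA/cm²) the deterministic model is bistable, and channel
  noise makes trajectories drop out of the limit cycle into the
  coexisting stable rest for tens of milliseconds before noise kicks
  them back.  Suprathreshold firing rates therefore fall below the
  deterministic rate and *decrease* with patch area (less noise = slower
  re-entry), and the healthy-neuron SNR at 150 Hz comes out ≈ 5.0 rather
  than the reference ≈ 6.8.  Subthreshold (impaired) conditions, where
  all stochastic-resonance conclusions live, do not visit the bistable
  regime and reproduce closely.
- The generator emulates an isopotential patch with ideal series
  voltage sources; real stimulation couples through tissue and membrane
  geometry, so passing tests say nothing about dosimetry, electrode
  coupling or multicompartment effects.
- Independent-particle kinetics only: no coupled inactivation schemes,
  no temperature (Q10) scaling, no Langevin/diffusion channel-noise
  approximation.
- The periodogram is the plain single-record estimator by design
  (matching the study's estimator); no Welch/multitaper variance
  reduction, so per-bin errors shrink only with R.
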