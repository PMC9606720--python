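# Methods

`neuroforward` computes extracellular electric (LFP) and magnetic (MEG-like)
signals from two descriptions of the same cortical population: a spiking
network of adaptive exponential integrate-and-fire (AdEx) neurons, and its
first-order mean-field (population rate) reduction. The package's purpose is
the *forward model* — the map from neuronal activity to measurable fields —
validated on slow-wave (up/down state) activity, where the two descriptions
can be compared quantitatively.

## Network models

**Point AdEx network.** 10,000 neurons (80% excitatory, 20% inhibitory),
Erdős–Rényi connectivity with pairwise probability p = 0.05, conductance-based
synapses with exponential decay (τ_e = τ_i = 5 ms) and quantal increments
q_e = 1.5 nS, q_i = 5 nS at reversal potentials E_e = 0, E_i = −80 mV.
Membrane: C = 200 pF, g_L = 10 nS, E_L = −63 mV, exponential spike initiation
at V_T = −50 mV with slope Δ_T = 2 mV (excitatory) / 0.5 mV (inhibitory),
reset −65 mV, refractory 5 ms. Spike-frequency adaptation acts on excitatory
cells only (b = 60 pA, τ_w = 500 ms, a = 0).

Integration is forward Euler at dt = 0.1 ms. The exponential term is
evaluated with its argument clipped at the spike-detection voltage (0 mV for
the point model), and a spike is registered when V crosses that detection
value; because the exponential upstroke traverses the last few millivolts in
far less than a millisecond, the registered spike time is insensitive to the
exact cut. A unit test checks that halving dt leaves the stationary
population rate statistically unchanged, and that a constant-current
response matches a dt/10 reference within one spike.

**Synaptic latency.** Recurrent spikes arrive with a uniform 1 ms latency
(configurable, including zero). The latency matters for the slow-wave
regime: with strictly instantaneous recurrence, a nascent population surge
recruits inhibition within a single synaptic time step and up-state onsets
are quenched at a small fraction of the amplitude that the mean-field
reduction — whose excitatory→inhibitory loop responds on the population time
scale T — predicts for the same parameters. A ~1 ms conduction/synaptic
latency is physiologically conservative for a 1 mm² patch and restores
quantitative agreement between the two routes.

**External drive and state initiation.** Nothing in the network equations
initiates up states; a weak external excitatory drive is required. Every
neuron receives an independent Poisson stream through 400 external synapses
(per-afferent rate 0.32 Hz for excitatory targets and 30% of that for
inhibitory targets), acting through the same q_e synapses as recurrent
input. The total drive rate is additionally modulated by a single slow
Ornstein–Uhlenbeck process shared by all neurons (relative SD 0.3,
τ = 300 ms), representing global background fluctuations; its excursions
trigger up-state onsets, while spike-triggered adaptation terminates them.
Drive asymmetry (excitatory cells receiving more external input than
inhibitory ones) widens the adaptation range over which an ignited up state
survives and thereby sets the up-state duration; the shipped values place
the alternation at ~1 Hz with up states of roughly half a second, the
deep-sleep slow-wave regime. These drive parameters are the principal free
inputs of the study conditions; they were fixed once and are pinned in the
default configuration.

**Two-compartment variant.** For the magnetic field, excitatory cells get a
passive apical dendrite (C_D = 10 pF, g_LD = 2 nS) coupled to the soma by an
axial conductance g_A = 400 nS; inhibitory cells remain point neurons.
Synapses distribute across compartments with the measured bias — 30% of
excitatory synapses perisomatic and 70% dendritic, 60/40 for inhibitory —
and the spiking thresholds follow the two-compartment parameter set
(detection at −40 mV, reset −55 mV for excitatory; −47.5/−65 mV for
inhibitory). The dendrite is stiff (time constant C_D/(g_LD+g_A) ≈ 24 µs),
so it is advanced with the exact exponential update of its linear ODE per
step instead of Euler; the soma stays on Euler. With g_A → 0, all synapses
somatic and a deterministic drive, the soma reproduces the point model's
trajectory exactly (tested). Its slow-wave drive point differs from the
point network's (rate 0.32 Hz, inhibitory fraction 0.15, OU relative SD
0.5): the altered thresholds and the dendritic filtering shift the ignition
boundary, so the regime is pinned separately.

## Mean-field model

The reduction follows the Markovian population framework: rates ν_e, ν_i
relax toward a transfer function F with time constant T (default 5 ms), and
mean adaptation W integrates b·ν_e with decay τ_w. F is the semi-analytic
conductance-based form: shot-noise (Campbell) formulas give the subthreshold
moments (μ_V, σ_V, τ_V) of a neuron bombarded by Poisson input at rates
K_e ν_e and K_i ν_i (K = 400/100 from the network), and the rate is
F = erfc((V_eff − μ_V)/(√2 σ_V)) / (2 τ_V), with the effective threshold
V_eff a full second-order polynomial in the normalized moments.

The ten polynomial coefficients are not universal constants; they are
regenerated by `fit_transfer_function`, which simulates a grid of single
AdEx neurons under stationary Poisson bombardment (the grid spans
ν_e ∈ [0.1, 50] Hz, ν_i ∈ [0, 70] Hz and W ∈ [0, 480] pA, 10 s per point,
adaptation frozen and W injected as a constant current), inverts the erfc
formula at every grid point with measurable output, and fits V_eff by least
squares. The shipped coefficient file records the grid, seed and fit
residual (≈1–3 Hz RMS). Fit quality at the low-rate corner is what decides
whether the mean-field's down state is truly silent, hence the grid is
densest there. The erfc normalization (ceiling 1/τ_V) was chosen so that the
measured saturating branch of the single-neuron response remains invertible
and inside the fit domain; fit and evaluation use the same form throughout.

Under the default drive (rate 0.528 Hz through the same K_ext = 400,
inhibitory fraction 0.3, no noise), the deterministic system follows a
relaxation limit cycle: ignition to a transient high-rate burst, a
sub-second adapting plateau, collapse to silence, recovery as W decays —
slow waves at ~1.4 Hz with essentially cycle-invariant amplitude and
duration. An optional OU term on the drive adds cycle-to-cycle variability.

## LFP: unitary-kernel synthesis

Each presynaptic spike contributes a Gaussian uLFP template of width σ
(3.15 ms excitatory, 2.1 ms inhibitory), constant delay d = 10.4 ms,
amplitude A₀(z) at the source decaying radially as exp(−r/λ) with
λ = 200 µm, and peak time retarded by r/v_a (v_a = 200 mm/s). The
spike-based route evaluates this per neuron and spike. The rate-based route
replaces the per-source decay by its average over a disk of radius 2λ —
analytically (1 − 3e⁻²)/2 ≈ 0.297, independent of λ — and drops the
propagation term, then convolves each population's spike flux n_p·ν_p with
the resulting template. Both routes agree for Poisson populations
distributed over that disk (tested within Monte-Carlo error); for a uniform
1×1 mm² sheet the true sheet average is ~20% below the disk factor, which is
part of the approximation the population kernel makes.

The depth-amplitude table A₀(z) at the four tabulated depths (−400, 0, 400,
800 µm) ships in `data/kernels_default.yaml`. It is a representative table,
not a verbatim transcription of the published human uLFP measurements: it
preserves their structure (inhibitory somatic peak of a few microvolts,
weaker excitatory amplitudes of opposite polarity, dipolar sign change
toward the surface) with the overall scale calibrated once so that the
shipped slow-wave configuration reproduces the reference up-state LFP
amplitude at the surface electrode. Replace the file with measured values
for quantitative work on other preparations.

## MEG: current-dipole and volume-conductor model

The primary source is the population axial current. For the mean-field
route, the stationary voltages of the two passive compartments under the
momentary conductance moments (μ_G = ν τ q per synapse, with the
per-compartment synapse counts K^j and W on the soma) are solved exactly as
a 2×2 linear system per time point; I_A = g_A(V_D − V_S), and
Q_s = n_e L I_A with the effective dipole length L (shipped default 322 µm,
calibrated once against the reference up-state field; the anatomical
soma-to-apical separation is of this order). Only tangential dipoles are
modeled; the sensor sits 3 cm radially, and B = (μ0/4π) Q×r/|r|³.

Secondary (volume-conduction) currents use the surface-integral identity
over conductivity discontinuities: Q_c = −Σᵢ (σ′ᵢ−σ″ᵢ)∫Φ dSᵢ. The default
conductor has a single gray-matter/CSF interface (0.3 / 2.1 S/m) at the
surface depth, discretized 21×21 with midpoint quadrature; Φ on the
interface comes from the spatially resolved rate-based kernel (per-point
sheet-averaged decay). In the gyrus-wall geometry the cortical depth axis is
tangential to the scalp, so interface normals are parallel to the dipole
axis and the secondary dipole adds to the primary one; it contributes ~10%
of the total field in the shipped configuration, consistent with axial
currents dominating. For the spiking route the network's mean axial current
is used directly, with no conduction term (homogeneous medium).

## State detection

Up states are maximal excursions beyond baseline ± 3 SD of the base-state
fluctuation. The baseline is the histogram mode (the down state dominates
slow-wave signals) and the base SD comes from samples within one median
absolute deviation of it; detection is sign-aware, states shorter than
100 ms are discarded and gaps shorter than 50 ms merged (both configurable).
Amplitude is the per-state extremum relative to baseline; duration is
onset-to-offset. Across-state SDs use the sample (n−1) convention by
default. Detection is invariant under affine rescaling of the signal.

## Problem sizes and determinism

The validation pipeline uses 30 s of mean-field activity and 25 s of spiking
activity (2,000–3,000 ms discarded as burn-in), which yields 15–40 detected
states per run; these sizes keep a full validation run in the tens of
minutes on one core while leaving the state statistics stable at the few
percent level. All stochastic stages (connectivity, drive, initial
conditions, fits) consume named seeds, and every output can be regenerated
bit-identically from its provenance record.

## Known limitations

* Random (Erdős–Rényi) connectivity only; no structured topology.
* The A₀ depth table is representative, not measured (see above); per-region
  or per-layer kernel specialization is not implemented.
* The far-field dipole formula assumes sensor distance ≫ source extent; a
  warning is emitted otherwise. Conductivity is isotropic and
  frequency-independent; no realistic head model (the whole-brain example
  uses the diagonal per-region gain).
* The mean-field is first order: no rate covariances or finite-size
  corrections, so its cycle-to-cycle variability is entirely drive-driven.
* The synthetic connectome is a statistical stand-in (log-normal weights,
  uniform tract lengths) for empirical tractography.
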