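# Model and methods

`ebpb` simulates the spiking circuit that couples the *ellipsoid body* (EB)
and the *protocerebral bridge* (PB) of the fruit-fly central complex — the
network believed to hold the fly's internal heading estimate as a localized
"bump" of activity and to move that bump when the animal turns in darkness.
This note documents the model, its assumptions, the free parameters and how
they were set, the synthetic protocols, and the known limitations.

## Anatomy and wiring

Regions. The PB has 18 glomeruli (R0–R8, L0–L8); the EB is divided into 16
wedges which run `L1, R1, R2 … R8, L8, L7 … L2` around the torus.  Adjacent
wedge pairs form eight **dual regions** (`L1R1, R2R3, R4R5, R6R7, R8L8,
L7L6, L5L4, L3L2`), the innervation unit of PB→EB neurons.  The tiling is
the only one consistent with the anatomically named duals (R2R3, L23, R8L8);
a config switch (`dual_offset`) exposes the alternative one-wedge-shifted
tiling for sensitivity checks.

Neuron types.  53 region-level types in four classes:

* **EIP** (18): dendrites in three consecutive EB wedges, axon in one PB
  glomerulus.  EIP0 and EIP17 are atypical, innervating the single seam
  wedges R8 and L8.
* **PEI** (16): dendrite in one glomerulus of R0–R7/L0–L7, axon in one dual
  region of the EB C ring.  EIP↔PEI form a *symmetric* feedback circuit:
  every EIP→PEI connection is reciprocated.
* **PEN** (16): the PEI innervation copied with the PB site shifted one
  glomerulus outward (dendrites R1–R8/L1–L8), axons in the P ring.  EIP→PEN
  feedback returns one dual region over — an *asymmetric shifter*: the
  right-hemisphere PENs (PEN0–7) and left-hemisphere PENs (PEN8–15) each
  form a closed chain that advances the bump one dual per hop, in opposite
  directions, closing over all eight duals through the atypical types at
  the R8L8 seam.
* **Ring neurons** (R_EIP, R_PEI, R_PEN): GABAergic, arborizing over all 16
  wedges.  R_EIP receives direct excitation from every EIP type and
  inhibits all EIPs (global winner-take-all); R_PEI and R_PEN are driven
  externally and silence the PEI (C ring) or PEN (P ring) populations,
  gating which ring operates.

Synapses are inferred from region overlap — an axonal arbor contacts every
dendritic arbor sharing a region — with maximal conductance G = w·(number of
shared regions), where w is a per-(pre-class, post-class) base weight.  Two
exceptions: (i) the seam connections PEN8→EIP0 and PEN7→EIP17 (one shared
wedge each) are tripled so the bump can cross R8L8; (ii) ring-neuron
synapses use a uniform G = w per target type.  Exception (ii) is a
deliberate design choice: scaling ring inhibition with the target's
dendritic footprint would give the single-wedge types EIP0/EIP17 one third
of the typical inhibition on top of their tripled excitation, and in
simulation the seam then captures every bump.  Uniform ring inhibition
keeps the seam passive, consistent with the observation that the atypical
innervation does not visibly distort EB activity at R8/L8.

The full wedge/glomerulus assignment is generated algorithmically.  It is
uniquely determined (an exhaustive search over the parameterized wiring
family confirms uniqueness) by: the cue-mapping anchor (a cue in wedge R2's
field is delivered to PB R5 and L3), the PEI11→EIP12 (two shared wedges,
R2R3) and PEI11→EIP4 (one wedge, R2) overlap examples, the worked shifter
chains EIP5→PEN5→EIP6→PEN6→EIP7 and EIP12→PEN10→EIP11→PEN9→EIP10, the seam
connections, reciprocity of the C ring, asymmetry of the P ring, and
closure of both chains over all eight duals.  In the resulting wiring the
clockwise cycle runs through EIP1–7 plus the atypical EIP17 and the
counterclockwise one through EIP10–16 plus EIP0; EIP8 and EIP9 (axons at
R0/L0, where no PEN dendrites exist) take part only in the feedback ring.

## Neuron and synapse dynamics

Leaky integrate-and-fire with conductance-based synapses:

    C_m dV/dt = −g_L (V − V_L) − Σ g·s·(V − E) + I_inject

with C_m = 0.1 nF (0.01 nF for R_EIP), τ_m = C_m/g_L = 15 ms, V_L = −70 mV,
threshold −50 mV, reset −70 mV, refractory period 2 ms (the refractory
value is a package choice; it prevents step-size-dependent burst artifacts
and network behaviour is insensitive to it in the 1–3 ms range).

Receptors: ACh (τ = 20 ms, E = 0), GABA_A (τ = 5 ms, E = −70 mV) with
first-order gating ds/dt = −s/τ + Σδ(t−t_k); NMDA (τ = 100 ms, E = 0) with
saturating gating ds/dt = −s/τ + α(1−s)Σδ, α = 0.63, and voltage-dependent
conductance g(V) = G/(1 + [Mg]·e^(−0.062V/3.57)), [Mg] = 1.0 (the
magnesium concentration enters the model as the printed dimensionless
factor 1.0; the exponential form makes the conductance rise steeply with
depolarization).  Internal excitation (EIP, PEI, PEN and EIP→R_EIP) is
NMDA; ring-neuron output is GABA_A; all external inputs are cholinergic.

Integration: exponential decay for gating variables and forward Euler for
membranes at dt = 0.1 ms (config).  Within a step the order is: external
inputs → gating decay and spike increments → pool conductance sums →
currents → membrane update and threshold.  Multiple external events in one
step are applied sequentially for NMDA (k spikes take s to 1−(1−α)^k(1−s)).
Synaptic delays are zero by default.  Membrane potentials start at rest.

Each type is a pool of 10 identical neurons; type-to-type connections are
all-to-all between pools with the same per-contact conductance, so the
conductance a postsynaptic neuron receives from a pool is G times the sum
of presynaptic gating variables.  The engine exploits this exactly: one
outgoing gating variable per neuron, aggregated at pool level (a 53×53
weight matrix), which makes the compiled (numba) inner loop O(N) per step.
Doubling the pool size with halved per-contact conductances leaves
population rates approximately unchanged.

## Stimuli and tasks

The 16 wedges map homogeneously onto 360° of azimuth, anchored so that a
cue at 40° falls in wedge R2.  The circular *orientation* of that map is
not fixed by any single anchor; the package orients it (azimuth =
90° − 22.5°·position) so that unilateral right-PB drive moves the bump
clockwise and left-PB drive counterclockwise, the measured behaviour of the
simulated circuit.  Under this convention all directional observables
(rotation–direction mapping, tracking, drift) are reproduced; the
"clockwise/counterclockwise" names attached to the two PEN chains are
purely a drawing convention and carry no physical content.

* **Visual cue**: 50 Hz Poisson per neuron at 2.1 nS onto the two bilateral
  PB glomeruli whose PEI neurons converge on the cued wedge's dual region
  (bilateral, so that no shifter hemisphere is favoured).
* **Body rotation**: 3150 Hz at 0.3 nS onto all glomeruli of one PB side.
  The rate is the *total over the upstream group feeding each pool* and is
  delivered as independent 315 Hz trains per neuron; this is the only
  reading under which the drive is subthreshold (steady-state V ≈ −54.5 mV)
  as described, rather than a 19 nS suprathreshold barrage.  Right side ↔
  counterclockwise body rotation at 58.5°/s.
* **Ring gating**: 200 Hz at 10 nS onto R_PEN during forward walking /
  cue-on periods and onto R_PEI during rotations.  Each drive ceases 150 ms
  before its movement-state transition so the two rings overlap briefly and
  the bump transfers smoothly.  R_EIP receives *no* external drive by
  default: it is driven by EIP feedback, which is what makes the inhibition
  track total excitation and enforce a single winning bump (a tonic
  200 Hz/10 nS drive saturates the small-capacitance R_EIP at its
  refractory-limited rate and destroys the competition; the option remains
  in config).
* **Lesions**: −0.5 nA injected into a ring class for the whole trial.
* **Random walk**: alternating forward segments (0.2–2 s uniform) and
  rotations (fair-coin direction, uniform 0–90° at 58.5°/s), 1 s cue then
  darkness.

Task conditions: (1) static cue for 1 s then off; (2) cue stays on and
sweeps at 22.5°/s (one wedge per second; a 45°/s variant sweeps 8 s per
direction), PB targets switching at wedge-boundary crossings; (3) cue off
at 1 s followed by scripted rotations.  Circuit variants: C ring
(EIP+PEI+R_EIP), P ring (EIP+PEN+R_EIP — the global inhibition is required
in both rings), full (all six classes).

## Analysis

Rates are pooled spike trains convolved with a causal exponential kernel,
d = 721.5 ms (500 ms half-life, mimicking a slow calcium indicator), and
divided by pool size.  Wedge activity is the mean rate of the EIP pools
covering the wedge.  Every 100 ms a circular Gaussian with baseline is fit
to the 16-point profile (the profile is rotated so its argmax is centred,
avoiding the wrap); the fit counts as a bump when its amplitude is at least
1.0 kernel-rate units, at least half the baseline, and its FWHM is below
180°.  FWHM = 2√(2 ln 2)σ.  Derived metrics: mean absolute circular
deviation from the expected azimuth; bump speed as the least-squares slope
of the nearest-angle-unwrapped centre (samples jumping > 90° between fits
are discarded); loss-of-tracking when the centre is > 45° from the cue, or
the fit fails, for more than 1 s; drift coefficient a from a least-squares
fit of y = √(ax) (linear regression of y on √x through the origin).
The deviation of a moving-cue trial is evaluated from 1 s after cue onset
to trial end.  Note that the kernel itself contributes ≈ v·d of measured
lag for a cue moving at v (≈ 0.28 rad at 22.5°/s) — this is a property of
the calcium-like read-out, not of the spiking dynamics, and it dominates
the tracking-deviation statistic.

## Free parameters and calibration

The eight per-channel base weights are the model's free parameters.
`calibrate_weights` (coordinate descent, multiplicative steps, seeded)
tunes them against the circuit contracts: condition-1 persistence with
FWHM ≈ 58.4°, tracking at 22.5°/s with loss of tracking at 45°/s, no shift
of the C ring under unilateral drive, and a correctly-directed ≈ 58.5°/s
shift at the standard drive.  The shipped defaults (nS per shared region)
are

    EIP→PEI 2.3   PEI→EIP 1.63   EIP→PEN 2.2   PEN→EIP 3.5
    EIP→R_EIP 0.2   R_EIP→EIP 7.0   R_PEI→PEI 2.5   R_PEN→PEN 2.5

Notable consequences of this operating point: the C-ring bump width is
pinned at 58.6° by the dual-region geometry across a broad weight range;
the P-ring bump is wider (≈ 1.5 rad) and less stable, as expected from its
displaced feedback; the rotation gain is ≈ 56–62°/s with the correct
direction on both sides.  When the gating-variable saturation is removed,
the compensating global NMDA down-scale that still yields an initial bump
is ≈ 0.12 for this weight set (the window is narrow, and the bump is lost
at rotation onset regardless) — the analogous compensation constant is
calibration-dependent, and other weight sets place it near 0.08–0.09.

## Known limitations

* **Seam inhomogeneity.**  The atypical single-wedge types make the R8L8
  seam a shallow barrier for bump motion despite the tripled seam
  connections: shifting is slower into the seam and faster away from it.
  Per-rotation path-integration errors are therefore several times larger
  than the ideal, and in the random-walk task the trial-averaged deviation
  approaches its circular ceiling within tens of seconds; the fitted drift
  coefficients land near 0.06–0.09 for both the full model and the P-ring
  variant, and the full-vs-P-ring ordering is not robust across seed
  batches at this operating point.
* **Mg-block removal.**  Removing the magnesium block multiplies NMDA drive
  ≈ 3.5× at subthreshold voltages while R_EIP's GABA output grows only
  linearly with its rate; at this operating point the network then runs
  away into a uniform active state instead of keeping a (slightly changed)
  bump.
* **Persistent C-ring pinning.**  In variants where the C ring is never
  gated off (R_PEI lesioned or absent), the unilateral drive still moves
  the bump slowly instead of being fully pinned; making the C ring sticky
  enough to pin would push the tracking deviation out of its tolerance.
* The synthetic protocols idealize real data in the usual ways: Poisson
  input spike trains, identical neurons within a pool, no synaptic delays
  or plasticity, a single fixed retinotopic mapping, and a calcium-like
  read-out reduced to an exponential kernel.  Passing tests demonstrate
  the circuit-level computations under these conditions, not quantitative
  agreement with physiological recordings.
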