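# Methods

## Scope and model

`dendroplast` simulates long-term plasticity induction in passive spiny
dendrites driven by two calcium sources per spine: ligand- and
voltage-gated NMDA receptors (only at presynaptically activated spines)
and voltage-gated calcium channels (VGCCs, at every spine). The working
hypothesis is that homosynaptic outcomes reflect NMDA + VGCC calcium while
heterosynaptic outcomes at nonactivated spines are produced purely by
depolarization-driven VGCC calcium, so their spatial pattern is inherited
from the voltage attenuation profile of the dendritic tree. All membrane
mechanisms outside the spines are passive by default (an optional uniform
HCN/Ih density is provided); there are no Na⁺/K⁺ spiking channels, so the
model isolates the cable-theoretic contribution.

Assumptions baked into the default configuration:

* a single simultaneous presynaptic event per activated synapse, with
  deterministic release of one vesicle (no Tsodyks–Markram dynamics, no
  release failures) — the protocols studied are one-shot cluster
  activations;
* plasticity thresholds and channel densities identical across spines;
* θ_P > θ_D (the cortical/hippocampal ordering), enforced at
  configuration time;
* synaptic weights are frozen during an induction event and read out from
  ρ afterwards; on the induction timescale (τ_ρ = 70 s vs. 300 ms
  protocols) ρ moves by only a few percent, so the *label* (potentiate /
  depress / no change), not the magnitude, is the model's output;
* no calcium diffusion between spine and shaft, and no internal stores:
  each head's pool is private.

## Parameters

Passive and geometric (morphology units: μm, Ω·cm, kΩ·cm², μF/cm²):

| parameter | value | notes |
|---|---|---|
| R_a | 150 Ω·cm | dendrite, soma and spine neck |
| E_pas | −77 mV | resting potential of the passive model |
| dendritic R_m | 44 kΩ·cm², run as 22 | halved by spine compensation |
| dendritic C_m | 1 μF/cm², run as 2 | doubled to keep τ_m |
| somatic R_m, C_m | 30 kΩ·cm², 1 μF/cm² | no compensation at the soma |
| soma | 718 × 23 μm cylinder | diameter fitted so R_N = R_m/(π d L) ≈ 57.8 MΩ, the sink of a full L5 arbor |
| dendrite | 200 μm × 0.75 μm, 50 segments | ball-and-stick |
| tree branch | 50 μm × 0.75 μm, 10 segments | order-3 symmetric tree, tips at 200 μm |
| spine head | 0.4 μm sphere | area π d² ≈ 0.503 μm², volume π d³/6 |
| spine neck | L = 0.66 μm, d = 0.0746 μm | d fitted so R_neck = 4 R_a L/(π d²) = 226.6 MΩ; the commonly quoted 0.07 μm is this value rounded and would give ≈257 MΩ |
| spine R_m | 10.7 kΩ·cm², *not* halved | compensation models spines that are absent, not ones modeled explicitly |

Synapse and calcium (transcribed from the published Blue Brain
glutamatergic synapse mechanism, with the four modifications noted):

| parameter | value | notes |
|---|---|---|
| AMPA τ_rise/τ_decay, E | 0.2 / 1.7 ms, 0 mV | dual-exponential, peak-normalized |
| AMPA g_max | 1.5 nS neutral; 1 (DOWN) – 2 (UP) nS | modification: initialized at the unstable point ρ = 0.5 |
| NMDA τ_rise/τ_decay, E | 0.29 / 43 ms, −3 mV | |
| NMDA g_max | 1.31 nS | modification: human-synapse estimate |
| Mg block | 1/(1 + (mg/K₀) e^(−γv)), mg = 1 mM, K₀ = 2.552 mM, γ = 0.072 /mV | |
| NMDA Ca fraction | P_f = 4·ca_o/(4·ca_o + 120/1.38)·0.6 ≈ 0.0505, driven to +40 mV | calcium bookkeeping only; the electrical NMDA current already flows through its own reversal, so adding the Ca component to the membrane current would double-count |
| VGCC | 20 pS × 20 /μm² × head area ≈ 0.2 nS | modification: R-type kinetics, aggregate HVA conductance |
| VGCC gates | m²h; m∞: v½ = −5.9 mV, k = 9.5 mV, τ = 1 ms; h∞: v½ = −39 mV, k = −9.2 mV, τ = 27 ms | ohmic to the Nernst E_Ca from the instantaneous pool |
| Ca pool | γ = 0.04, τ_ca = 12.213 ms, min 70 nM, ca_o = 2 mM, volume = head sphere | modification: geometry from the explicit neck + spherical head |
| effective Ca | deff/dt = (ca_i − min) − eff/τ_eff, τ_eff = 278.318 ms | dimensionless A.U., the scale on which θ_D/θ_P live |
| plasticity | γ_p = 216.2, γ_d = 101.5, τ_ρ = 70 s, ρ* = 0.5 | Graupner–Brunel bistable rule |
| thresholds | (θ_D, θ_P) = (0.5, 1) default; (0.2, 0.4) for the branched sandwiches | A.U. |

The kinetic constants above follow the mechanism's publication and are
collected in one place (`channels.py`) so a user with the archived
mechanism source can diff them directly.

## Protocol generator

`protocols.py` is the input generator: every experiment is built
programmatically (no data files). Background spines sit at every 10 μm of
path distance (none at a branch's 0 μm point; 20 spines on the
ball-and-stick, 75 on the tree); clusters are n spines attached to the
midpoint segment of the named branch, each with its own neck and head,
activated simultaneously at t = 50 ms in a 300 ms window; a distributed
variant spreads them uniformly along the branch. Sweeps enumerate
row-major over the declared axes and runs are bitwise deterministic, so a
preset id plus its parameters fully reproduces any figure-style output.

What this generator does *not* emulate about real inputs: stochastic
vesicle release and short-term dynamics, temporally extended or repeated
(frequency-coded) stimulation, heterogeneous spine geometries and
thresholds, and background synaptic bombardment. Passing results therefore
demonstrate the cable-and-threshold mechanism under clean one-shot
conditions, not quantitative predictions for noisy in-vivo input streams.

## Numerics

* Units inside the solver: mV, ms, nA, μS, nF — chosen so μS·mV = nA and
  nF·mV/ms = nA with no stray conversion factors; morphology-unit
  conversions happen once at graph construction.
* Spatial discretization: one compartment per electrical segment, two per
  spine. Axial conductance between neighbors is the series sum of the two
  half-segment resistances; the neck's fitted resistance is split into
  equal halves on its two edges so the head-to-shaft resistance
  reproduces the closed form exactly; the spherical head is isopotential.
* Time stepping: Crank–Nicolson (half-step backward Euler + extrapolation)
  on the tree system via Hines-ordered elimination, which is exact and
  O(N) per step. Channel gates advance by exponential relaxation with
  rates at the pre-step voltage (staggered convention); synaptic waveforms
  are evaluated analytically at the step midpoint; the voltage-dependent
  Mg block is handled with one predictor–corrector pass. The scheme
  converges at second order on the recorded traces.
* Step size: dt = 0.0125 ms by default. At this step, halving dt changes
  every recorded voltage by < 0.04 mV even through NMDA-plateau onset; at
  0.025 ms the onset samples move by ~0.17 mV, above the package's 0.1 mV
  stability target, which is why the finer step is the default. All
  categorical outcomes are identical at both steps. Recordings are
  sampled every 0.1 ms.
* Spine compartments are solved in the same implicit system as the shaft
  (no subcycling): the ~226 MΩ neck makes explicit coupling stiff.
* Initialization: v = E_pas, gates at their steady state for E_pas,
  calcium at its floor, ρ = 0.5. With Ih enabled, a 200 ms unrecorded
  settling run precedes t = 0 so traces start from the shifted resting
  state.
* Degenerate inputs: zero-size clusters are legal (flat traces); empty
  calcium traces, θ_P ≤ θ_D, non-positive geometry, and probes at unknown
  sites raise typed errors. Threshold comparisons are inclusive (≥), a
  documented tie-break.
* The small resting VGCC flux at −77 mV leaves a baseline effective
  calcium of ~2.5 × 10⁻⁴ A.U. — three orders of magnitude below θ_D —
  visible in all-quiet runs.

## Classifier choice

Figure-style outcome grids use the peak rule: label by the maximum of the
effective calcium against (θ_D, θ_P). The alternative ρ-rule (integrate
the bistable dynamics along the trace, label by the sign of Δρ with a
10⁻⁴ dead band) agrees with the peak rule everywhere below θ_P and for
strongly driven spines, but can relabel a borderline peak-rule P as D when
a brief excursion above θ_P rides on a long tail inside the depression
window (time-above-θ_D outweighing γ_p/γ_d); in the reference
27-synapse experiment this happens at the colocated nonactivated spine
(peak 1.35 A.U.). The disagreement is structural — only (P→D), never
involving N — and is asserted as such in the test suite.

## Conventions for summary milestones

`results.py` reduces sweeps to milestones ("smallest cluster size whose X
spines are labelled Y"). The distal set of an input site is every
nonactivated spine on descendant branches plus same-branch spines beyond
the cluster; the sister set is the stimulated branch's sibling subtree; a
set's outcome is its modal label with ties broken upward (N < D < P). The
NMDA-spike criterion is a package definition — activation-site (activated
spine head) voltage ≥ −40 mV sustained for ≥ 20 ms contiguously — with
both constants exposed, since plateau phenomenology has no universal
quantitative definition.

Milestones on a coarse cluster-size grid are knife-edge quantities: a
spine set whose peak calcium lands within a few percent of a threshold can
change label under tiny parameter perturbations, and an outcome window
narrower than the grid step (e.g. a depression window crossed entirely
between two tested sizes) is invisible to the sweep. The per-spine peak
calcium tables, not just the labels, are therefore part of every output.

## Known limitations

* Passive dendrites only; active dendritic conductances (Na⁺, K⁺, Ca²⁺
  spikes, SK) would reshape both attenuation and calcium and are out of
  scope. The distance-scaled Ih profile is not built in; `IhParams` only
  covers a constant density (2 pS/μm² reproduces the qualitative
  asymmetry), and a user-supplied density profile can be attached by
  editing the per-compartment `ih_gbar` array on the graph.
* One aggregate high-voltage-activated VGCC type with R-type kinetics; no
  per-subtype mix, no GHK flux.
* Early-phase induction only: no protein-synthesis-dependent late phase,
  no metaplasticity (thresholds are constants), and no
  "post-potentiative neutral zone" at extreme calcium.
* Idealized morphologies (uniform diameters, symmetric tree); SWC import
  exists for exchanging section trees but tapering and 3D effects are not
  modeled.
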