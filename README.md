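# dendroplast

Dendritic cable simulations of calcium-based heterosynaptic plasticity.

When a cluster of co-active synapses on a dendritic branch fires an NMDA
spike, the resulting plateau depolarization spreads through the tree and
opens voltage-gated calcium channels (VGCCs) at spines that received no
input at all. Under the calcium control hypothesis — no change below the
depression threshold θ_D, depression between θ_D and θ_P, potentiation
above θ_P — that spillover calcium produces *heterosynaptic* plasticity
whose spatial pattern is set by the strongly asymmetric voltage attenuation
of dendrites: depolarization spreads far in the distal (sealed-end)
direction and dies quickly toward the somatic current sink. `dendroplast`
is a self-contained compartmental simulator built to map out these effects:
which spines potentiate, depress, or stay unchanged as a function of
cluster size, branch order, and threshold choice.

It is aimed at computational neuroscientists who want to reproduce and
extend this class of experiments without a full simulation platform: the
entire model — passive cable, two-compartment spines, AMPA/NMDA receptor
kinetics with Mg²⁺ block, R-type VGCC gating, spine calcium dynamics, and
the bistable plasticity rule — lives in plain Python/numpy with a
numba-accelerated implicit tree solver.

## Model summary

* **Morphologies.** A ball-and-stick model (200 μm, 0.75 μm dendrite in 50
  segments; isopotential soma enlarged to 718 μm so its input resistance
  R_N = R_m/A ≈ 58 MΩ matches a full layer-5 pyramidal cell) and a
  symmetric order-3 bifurcating tree (15 branches of 50 μm, every
  root-to-tip path 200 μm). Passive: R_a = 150 Ω·cm, E_pas = −77 mV,
  dendritic R_m = 44 kΩ·cm² halved and C_m = 1 μF/cm² doubled to stand in
  for unmodeled spine membrane.
* **Spines.** Explicit neck (fitted to R_neck = 226.6 MΩ) plus spherical
  head (0.4 μm); each head carries one glutamatergic synapse and a VGCC
  population of 20 pS × 20 channels/μm² × π d² ≈ 0.2 nS.
* **Synapse.** Dual-exponential AMPA (1.5 nS neutral, plastic between 1
  and 2 nS) and NMDA (1.31 nS) conductances; sigmoidal Mg²⁺ unblock;
  effective spine calcium c(t) integrates NMDA- and VGCC-carried calcium
  current and is compared against θ_D < θ_P.
* **Plasticity.** Graupner–Brunel bistable efficacy ρ with
  τ dρ/dt = −ρ(1−ρ)(ρ*−ρ) + γ_p(1−ρ)·[c>θ_P] − γ_d ρ·[c>θ_D]; the synaptic
  weight maps linearly to ρ. Outcomes are labelled P/D/N from the peak of
  the effective calcium (a ρ-integrating classifier is also provided).
* **Solver.** Hines-ordered elimination on the compartment tree (exact,
  linear cost), Crank–Nicolson time stepping at dt = 0.0125 ms with
  staggered channel gates and a predictor–corrector for the
  voltage-dependent Mg block.

See `docs/methods.md` for parameter tables, numerical choices and
limitations.

## Worked example

Place a nonactivated spine every 10 μm along the ball-and-stick dendrite,
fire 27 colocated synapses at 100 μm, and classify every spine at
(θ_D, θ_P) = (0.5, 1):

```python
from dendroplast import protocols as pr, analysis as an

spec = pr.preset_fig3()           # 27 synapses at 100 um, spines every 10 um
res = pr.run_experiment(spec)
tab = an.outcome_table(res, spec.plasticity)
print(tab[~tab.activated][["path_distance_um", "peak_ca", "label"]])
```

The nonactivated spines between 60 and 140 μm come out as:

```
 path_distance_um  peak_ca label
           60.000    0.041     N
           70.000    0.090     N
           80.000    0.282     N
           90.000    0.564     D
          100.000    1.350     P
          110.000    1.332     P
          120.000    1.326     P
          130.000    1.330     P
          140.000    1.342     P
activated cluster (100 um): peak_ca = 3.901, label = P
```

Reading the numbers: the activated cluster (peak effective calcium 3.90,
far above θ_P = 1) and *every* spine distal to it potentiate, because the
NMDA plateau barely attenuates toward the sealed distal end and opens the
distal VGCCs wide. One spine, 10 μm on the proximal side, lands in the
depression window (0.564 ∈ [0.5, 1)); 20 μm proximal and beyond, the
voltage has already attenuated so much toward the somatic sink that calcium
stays below θ_D and nothing changes. The plateau itself qualifies as an
NMDA spike (−40 mV crossed for 34.3 ms at the activated head).

The same machinery drives the other presets: `fig2` (attenuation probes),
`fig4` (branch-order × cluster-size grid on the tree), `fig5`/`fig6`
(sandwiching an inactive spine between two clusters). A CLI wraps the
common tasks:

```bash
dendroplast run fig3                 # traces (HDF5) + outcome CSV
dendroplast sweep fig4               # 4x4 grid of outcome CSVs
dendroplast classify run.h5 --thetas 0.3 0.8   # relabel cached calcium
dendroplast validate                 # physics invariant suite
```

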