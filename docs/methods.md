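# Methods

## Scope

`dendrofit` models thick-tufted layer-5b (L5b) neocortical pyramidal
cells as multi-compartment conductance-based neurons, scores simulated
firing against experimental feature statistics, and searches channel
densities with a multi-objective evolutionary algorithm. The cell has
two interacting spiking zones — a perisomatic Na⁺ zone and a distal
apical Ca²⁺ zone — and the package's protocols probe both and their
interaction (BAC firing).

## Cell model

### Morphology and discretization

A morphology is a tree of unbranched sections (soma, axon-initial
segment, basal, apical) with 3-D points and diameters, read from
7-column SWC or generated synthetically. The axon is reduced to its
initial segment (60 µm retained by default) because the spike-initiation
zone is collapsed into the perisomatic compartment; the rest of the axon
is deleted on load.

Each section splits into ⌈L/20 µm⌉ equal compartments. Membrane areas
are frustum lateral surfaces of the piecewise-linear radius profile
(exact under re-splitting, so total area is conserved to round-off when
the grid is refined). Axial resistances integrate R_a·ds/(πr²)
analytically over the taper; couplings are assembled between compartment
centers in parent-before-child (Hines) order. The soma is one
isopotential compartment; a single-point SWC soma uses the sphere
convention (area πd²), a multi-point outline the frustum rule. Soma
axial resistance is neglected (the soma is electrically fat relative to
any neurite), and path distances are measured from the soma with the
soma contributing zero extent.

### Passive properties

C_m = 1 µF/cm² for soma and axon, 2 µF/cm² for dendrites; R_a =
100 Ω·cm; E_leak = −90 mV; leak densities are free parameters per
region. The factor 2 compensates dendritic spine membrane, and the same
doubling is applied internally to *all* dendritic conductance densities,
exactly once, at model build time; every reported or serialized density
is the un-doubled value. An optional non-uniform variant replaces the
uniform apical leak with a sigmoid R_m profile (34 963 → 5 357 Ω·cm²,
half-distance 406 µm, steepness 50 µm, area-preserving factor 1.16) and
a matching E_leak gradient (−90 → −80 mV).

### Conductances

Ten HH-style currents: transient and persistent Na⁺ (Na_t, Na_p), I_h,
muscarinic I_m, slow- and fast-inactivating K⁺ (K_p, K_t), Kv3.1,
high- and low-voltage-activated Ca²⁺ (Ca_HVA, Ca_LVA), and the
Ca²⁺-gated SK current. Each follows I = ḡ·mˣ·hʸ·(V−E) with the
literature kinetics kept in their published form; two corrections are
layered on top rather than folded into coefficients:

* time constants of channels characterized at 21 °C divide by
  q10^((T_sim−21)/10), q10 = 2.3, T_sim = 34 °C;
* channels recorded without junction-potential correction (K_p, K_t,
  Ca_LVA) carry a −10 mV shift of their voltage dependence.

Reversal potentials: E_Na = 50 mV, E_K = −85 mV, E_h = −45 mV. E_Ca
defaults to a fixed 132 mV (the Nernst value at resting [Ca²⁺]ᵢ and
2 mM [Ca²⁺]ₒ at 34 °C); a dynamic Nernst mode is available. The
difference between the two on every quantity in the desk battery is
negligible because [Ca²⁺]ᵢ excursions move E_Ca by only a few mV while
the driving force is >150 mV. SK has a single Ca²⁺-dependent gate,
z∞ = 1/(1+(0.43 µM/[Ca²⁺])^4.8), with a fixed 1 ms activation time
constant (its kinetics are effectively instantaneous and not separately
characterized). Rate expressions with removable singularities (the
x/(1−e^(−x/y)) form) evaluate the analytic limit near the singular
voltage rather than risking NaN.

### Ca²⁺ dynamics

A submembrane shell (depth 0.1 µm) integrates
d[Ca]/dt = −γ·I_Ca/(2F·d) − ([Ca]−Ca_inf)/τ_decay with Ca_inf =
10⁻⁴ mM. γ (the inverse buffer binding ratio) and τ_decay are free
parameters, independently for the somatic and apical pools. The model
is deliberately simple — clearance acts equally at all concentrations —
which is also its main limitation: it cannot represent buffer or pump
saturation, and the acceptable τ_decay range is known to trade off
against burst strength.

### Spatial distribution rules

All channels are uniform within their region except:

* **I_h**: apical density follows the exponential profile
  g(x) = g₀·(A + B·e^(Cx/x_end))/(A+B) with A = −0.8696, B = 2.0870,
  C = 3.6161 and g₀ = 1 pS/µm² at the soma (the normalization makes the
  printed somatic base density exact at x = 0); basal and somatic I_h
  are uniform at g₀. I_h is fixed, not fitted — it underwrites the
  resting-potential gradient along the apical tree (~10 mV/mm) and
  sag/rebound behavior.
* **Ca_LVA / Ca_HVA**: an apical "hot" zone at 685–885 µm path distance
  carries 100× (LVA) and 10× (HVA) the density found elsewhere on the
  apical tree; parameter values always refer to the hot zone. For
  morphologies whose main bifurcation sits elsewhere an alternative
  placement anchors a 200 µm zone starting 35 µm proximal to the main
  bifurcation. The main bifurcation is identified as the apical branch
  point whose second-largest child subtree is longest (oblique side
  branches score low), ties resolving distally.

## Numerical scheme

The cable equation is advanced by a θ-method (Crank–Nicolson, θ = 0.5
by default) solved directly on the tree by Hines-ordered elimination;
gates use the exact exponential (Rush–Larsen) update staggered with the
voltage solve, and the Ca²⁺ pool uses its own exact update after the
voltage step. The inner loop is JIT-compiled (numba). Default
dt = 0.025 ms. Divergence (|V| > 200 mV or NaN) aborts the run and
flags the model as failed — the optimizer maps this to sentinel
objectives.

Initialization holds all stimuli off and integrates 1000 ms of rest
(backward Euler at 0.1 ms) so I_h-dependent resting gradients and the
Ca²⁺/SK steady state are established before t = 0; the settled state is
cached per model and re-used across protocol phases.

Accuracy: passive analytics (τ_m = R_mC_m, R_in of a sphere, charge
balance, transfer-impedance reciprocity, subthreshold linearity) are
exact to <1%. At the 0.025 ms default the somatic AP peak carries a
~2 mV discretization error (the Na_t activation τ approaches 0.05 ms at
spike threshold); halving dt within the convergent regime
(≤0.0125 ms) moves the peak by <0.5 mV. The coarse-step error is well
below the 5–7 mV experimental SD of the AP-peak feature and was left as
is to keep the published step size.

## Synthetic reference morphology

The generator emulates a reduced thick-tufted L5b cell: a 25×20 µm
soma, a 60 µm axon-initial stub, an apical trunk whose main bifurcation
sits at 650 µm, two 300 µm tuft branches (tips at 950 µm), eight
oblique side branches (300 µm) leaving the trunk between 150 and
600 µm, and eight basal dendrites (250 µm). It is deterministic given
spec and seed; the seed only rotates branch azimuths and never changes
any path length. About 220 compartments result at the 20 µm cap.

Diameters are not published for the reference reconstruction, so the
generator's defaults were fixed once by matching the reduced cell's
passive/functional fingerprints to those printed for the reference
cell: with the published parameter set the synthetic cell has
R_in ≈ 30 MΩ (reference cell: 41.9), soma→700 µm transfer impedance
≈ 7.5 MΩ steady and ≈ 3.1 MΩ for a 5 ms pulse (13.1 and 1.2), and —
the property prioritized in the calibration — the BAC dissociation: a
brief somatic pulse alone evokes exactly one AP and no distal Ca²⁺
spike, while the same pulse coincident with a distal EPSP ignites a
Ca²⁺ spike (~35 ms at its −55 mV base) and a somatic burst. A reduced
cylinder-and-branches cell cannot reproduce every fingerprint of a full
arbor simultaneously; the residuals (smaller BAP amplitudes, a
two-spike instead of three-spike coincident burst, deeper AHPs, narrower
APs) are of the same kind the full model shows when transferred across
real reconstructions. Tests against the synthetic cell therefore check
the qualitative dissociations and the quantities that are
morphology-robust; they do not certify feature-level agreement on real
cells.

## Feature extraction and scoring

Spikes are positive-going crossings of −20 mV with a 1 ms lockout,
linearly interpolated between samples. AP half-width is measured at
half height between the spike-onset voltage (where dV/dt first exceeds
20 mV/ms) and the peak. ISI-based features use population (N) SD for
the ISI-CV; the adaptation index is the mean of
(ISIᵢ₊₁−ISIᵢ)/(ISIᵢ₊₁+ISIᵢ). Fast and slow AHP depths are the voltage
minima within and after the first 5 ms of each inter-peak interval, and
the slow-AHP time is reported as a fraction of the ISI. First-spike
latency runs from step onset to the first crossing. The dendritic Ca²⁺
spike is measured at its −55 mV base (the longest contiguous excursion
above that level), and BAP amplitudes at 620/800 µm are peak minus the
local resting potential (which differs distally because of I_h).

The three step amplitudes are normalized per cell: the current
producing the 15 Hz reference frequency is interpolated from the f–I
curve, and the low/high amplitudes are 78% and 190% of it.

Errors are |value−mean|/SD against the shipped statistics table
(`data/feature_stats.csv`: 10 features × 3 amplitudes for step firing,
10 BAC features). Features with zero experimental SD (the two AP
counts) are hard constraints: error 0 on an exact match, a 250 SD
sentinel otherwise, so any violation dominates the Pareto comparison.
Missing values (e.g. no spikes) score the same sentinel.

The 30 step-feature errors collapse to 8 objectives and the 10 BAC
errors to 5 by group means (step: frequency / adaptation / ISI-CV /
burst ISI / latency / {AP peak, half-width} / fast AHP / {slow AHP
depth, time}; BAC: {Ca peak, width} / {both AP counts} / burst ISI /
{AHP, AP peak, half-width} / {both BAP amplitudes}); step-group members
average across the three amplitudes. The exact grouping is an
implementation choice — only the 8/5 objective counts are fixed — and
is fully configurable.

## Optimization

The 22 free parameters (somatic ḡ for eight channels, somatic γ,
τ_decay and leak; axonal, basal and apical leak; apical ḡ for Na_t,
Kv3.1, Ca_HVA, Ca_LVA, SK, I_m; apical γ, τ_decay) live in the bounded
space of the published limits; normalized values report x/upper so 1 is
the upper bound. The search is an elitist non-dominated sorting
evolutionary algorithm: uniform-in-bounds seeded initialization, binary
tournament on (rank, crowding distance), simulated binary crossover
(η = 15, p = 0.9), bounded polynomial mutation (η = 20, p = 1/n), and
environmental selection over the merged parent+offspring pool. The
variation-operator constants follow the standard NSGA-II reference
settings and sit in the run configuration. Evaluation is sequential,
so a seed fixes the entire run bit-for-bit; every generation is
archived. Evaluator exceptions or divergences quarantine the individual
at sentinel objectives.

*Acceptable* models have every per-feature error (not the grouped
objectives) within the SD cutoff — default 3 SD, with 2 SD as the
strict variant. Acceptable sets yield per-parameter min/max ranges (raw
and normalized) and range-comparison reports (overlap, shift) between
sets.

The two-stage fit reproduces the staged strategy needed because a
single 13-objective joint fit converges poorly: stage 1 fits the BAC
target; its acceptable models are re-scored on the step target and the
best of them (smallest maximal per-feature error — the scalarization is
configurable) donates its dendritic parameters (the apical partition
plus basal leak), which are frozen; stage 2 reoptimizes the perisomatic
parameters (somatic set plus axonal leak) against both targets.

Full-scale runs (population 1000 × 500 generations) are supported by
the same code path; the validation surface uses a ball-and-stick
ground-truth harness (5 somatic parameters, features generated by the
forward model itself, synthetic SDs of 5% with absolute floors,
population 64 × 50 generations) where the engine must recover models
within 2 SD on every feature.

## Protocol battery

* **BAC protocol**: EPSP-like current (0.5 nA, 0.5/5 ms rise/decay) at
  620 µm; brief somatic pulse (1.9 nA, 5 ms); both coincident (EPSP
  5 ms after the pulse); intense dendritic input (2.5 nA) alone.
* **Step protocol**: 2 s somatic steps at the three normalized
  amplitudes; f–I assembly.
* **Critical frequency**: trains of five 5 ms pulses, 40–200 Hz in
  10 Hz steps; peak distal voltage (hot-zone site) per frequency; the
  critical frequency is the first all-or-none jump (>15 mV per step).
  The pulse amplitude is calibrated per model as the *largest* amplitude
  evoking exactly one AP in isolation, because weaker pulses fail to
  trigger APs when later pulses fall into the AHP of preceding spikes
  and the protocol presumes an AP per pulse.
* **Up/Down coincidence window**: somatic pulse + EPSP at 700 µm with
  Δt ∈ [−40, 40] ms (5 ms grid); Up state adds 0.42 nA DC for 200 ms at
  200 µm. The printed 0.5 nA somatic pulse is used when it is
  suprathreshold at rest; otherwise the calibrated single-AP amplitude
  is substituted (the protocol requires a BAP on every trial). The
  window is the contiguous Δt range whose peak distal voltage exceeds
  the midpoint of the across-grid spread; no window is reported when the
  spread stays under 15 mV.
* **I_h attenuation**: −50 pA/200 ms somatic step; steady-state
  deflection along the apical path and somatic sag ratio, with I_h
  intact and blocked. Blocking zeroes I_h everywhere, is idempotent,
  and restores exactly on unblock.
* **Morphology transfer**: rebuilds a parameter set on a new
  reconstruction, rescales step amplitudes by the R_in ratio, places the
  hot zone by the configured rule (failing loudly when the apical tree
  cannot host it), and re-scores both targets.

## Design choices on open points

* Initial-population sampling is uniform-in-bounds (seeded); no Latin
  hypercube by default.
* Acceptance filters on raw per-feature errors, not grouped objectives.
* ISI windows for AHP features run between consecutive AP *peaks*;
  ISIs for interval features use threshold-crossing times.
* The soma outline is converted to an equivalent compartment by the
  frustum rule (sphere rule for single-point somata); any
  area-preserving convention would do, this one matches the neurite
  treatment.
* `trunk_length`, when supplied to the generator, must equal
  `bifurcation_distance`: the trunk is defined as the path from soma to
  the main bifurcation.

## Problem sizes used by tests and the acceptance script

Simulated protocols run at dt = 0.025 ms on the ~220-compartment
synthetic cell; optimizer validation uses the ball-and-stick harness at
population 64 × 50 generations (≈3 300 evaluations) plus cheap analytic
objectives for the determinism/elitism/sorting properties; sorting is
cross-checked against a brute-force oracle on instances up to 200
individuals. Full-scale fits are out of the desk-scale surface by
design.

## Known limitations

* The synthetic reference cell is a reduced arbor: feature-level
  agreement with the experimental statistics table is partial (see
  above), and conclusions about real cells require real
  reconstructions.
* Ca²⁺ handling is the linear shell model; no saturating buffer/pump.
* No NMDA spikes, no dendritic Na⁺ spikelets, no basal-dendrite BAP
  fitting, and no multi-compartment axonal initiation variant: these
  are outside the model's scope.
* The Up-state battery on the synthetic cell can abolish rather than
  merely narrow the coincidence window (the DC depolarizes this smaller
  cell relatively more); the Down-state window and the BAP-depression
  prediction are robust.
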