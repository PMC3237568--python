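# Methods

## Model structure and assumptions

The network couples four mechanistic layers under mass-action kinetics
(concentrations in nM, time in minutes; rates `k·∏[reactants]`, both sides
of every reaction limited to molecularity two):

1. **Receptor layer.** EGF binds EGFR (Kd 0.5 nM), ligand-bound monomers
   dimerize, and the dimer trans-phosphorylates (`k_rtk` 10 min⁻¹) into the
   active receptor RP, reversibly dephosphorylated at 1 min⁻¹. Only EGFR
   homodimers are represented; ErbB2/3/4 heterodimers, ligand depletion by
   synthesis, and receptor recycling are out of scope. Internalization
   removes ligand-bound receptor species — including scaffolded complexes,
   whose cargo is degraded with the receptor, as in classic receptor-level
   models — and is tagged so the sustained-activation variant can delete it.
2. **Ras/ERK arm.** RP docks Shc; phospho-Shc recruits the cytosolic
   Grb2:SOS pre-complex; receptor-bound SOS catalyses Ras GDP→GTP exchange
   (two-step, Km ≈ 180 nM so exchange is partially saturated in RasGDP).
   Ras-GTP hydrolyses through a dominant first-order route (3 min⁻¹) plus a
   weak RasGAP-catalysed route, and also inside its encounter complex with
   Raf (0.8 min⁻¹) so Raf binding cannot shelter Ras-GTP from inactivation.
   Active ERK phosphorylates receptor-bound SOS, dissolving the Grb2-SOS
   module (negative feedback). Raf phosphorylation is attributed directly
   to a Ras-GTP molecule (its immediate activator being unresolved), and
   each MAPK tier is an explicit two-step enzymatic conversion with a
   constitutive first-order dephosphorylation plus a weak dedicated
   phosphatase.
3. **PI3K/AKT arm.** RP independently docks Grb2, which recruits Gab1;
   phospho-Gab1 recruits PI3K, and the receptor:Grb2:p-Gab1:PI3K module
   converts PIP2 to PIP3 (PTEN reverses it). AKT is recruited by PIP3 and
   activated by PDK1 within the membrane complex; p-AKT decays by a
   first-order route (0.4 min⁻¹) plus weak PP2A catalysis.
4. **ROS/ASK1/MKK/p38 arm and crosstalk.** The active PI3K module also
   activates Rac; Rac-GTP drives ROS production (NADPH-oxidase style,
   zeroth order in ROS), cleared first-order (≈ 0.05 min⁻¹, the slowest
   timescale in the model — ROS is the stored "apoptotic potential") plus a
   weak scavenger. ROS activates ASK1, which drives MKK and p38 through
   fast two-step tiers. Active AKT phosphorylates **both** inactive ASK1
   and activated p-ASK1 into an inhibited pool ASK1i (recovery
   0.2 min⁻¹). Acting on both forms makes the suppression depth roughly
   quadratic in p-AKT while the release speed is set by the recovery rate
   alone: this is what lets sustained p-p38 sit at basal under high ROS yet
   rebound within tens of minutes of AKT decay. The crosstalk catalysis is
   fast and low-occupancy (k_cat 100 min⁻¹) so that p-AKT is not
   sequestered in crosstalk complexes.

Basal (pre-stimulus) activity comes from small constitutive leak reactions
(Ras exchange, Raf, AKT, ASK1; ~10⁻⁴–10⁻³ min⁻¹), so every readout has a
strictly positive basal value and fold changes are well defined.

## Parameters

Units: second-order constants 1/(nM·min), first-order constants 1/min.
Receptor association/dissociation constants are at literature scale for
EGF/EGFR kinetics; the downstream constants are this package's own
calibration, chosen so that the transient-stimulation envelope holds (p-ERK
peak ≤ 5 min, basal return ≤ 50 min, delayed p-p38 peak ≥ 15 min; early
sustained p-p38 transient ≤ 5 min) together with the sensitivity ranking
structure below. All values live in `builder.DEFAULT_PARAMS`; each reaction
row carries a `source` field (`core` for the mechanistic network,
`reconstructed` for padding).

Two regimes were set deliberately:

* the Raf tier operates at a high activated fraction (~50–60% of Raf
  phosphorylated at the transient peak) while the MEK and ERK tiers sit at
  moderate fractions — this places the largest p-ERK sensitivities on the
  MEK and Raf totals and attenuates the upstream (receptor/SOS/Ras)
  elasticities;
* helper enzymes introduced for bookkeeping (RasGAP, the ROS scavenger,
  the five explicit phosphatases) carry a minor share of their step's flux
  beside a dominant constitutive route, so they do not dominate the
  sensitivity spectrum.

The printed structural cardinalities (160 species / 243 reactions /
145 parameters / 28 nonzero initials) are met exactly by padding the
mechanistic core (~80 species, ~95 reactions) with inert reserve chains:
zero-initial species reacting only among themselves, flagged
`reconstructed`. They carry no flux and leave the dynamics untouched; they
stand in for complex intermediates whose full inventory is not publicly
recoverable. "Reaction rows" counts elementary rows (a reversible row is
one reaction with kf and kr); "kinetic parameters" counts distinct named
rate constants, with names shared across reactions counted once.

## Scenarios and events

* Pre-equilibration holds the stimulus at 0 nM and integrates until
  max|dx/dt| < 10⁻⁷ nM/min (≤ 5000 min); the result is the basal reference
  for fold changes and basal-return statistics.
* *Transient* stimulation is a one-time bolus (reference dose 100 nM EGF)
  consumed by binding and internalization — the pulse duration is not an
  input but emerges from ligand consumption.
* *Sustained* activation clamps EGF (zero derivative) and removes the
  internalization reactions.
* *Acute inactivation* runs the sustained scenario 360 min to steady
  state, then, as an instantaneous event, resets every phosphorylated or
  dimerized receptor species to its basal value — returning scaffolded
  adaptors to their free pools so no cytosolic mass is lost — and scales
  the trans-phosphorylation constant by 10⁻⁴ (a basal leak), mimicking a
  saturating inhibitor. Reported times place the event at t = 0; the
  default post-event horizon is 24 h.
* Knockout variants delete all reactions carrying the targeted tag
  (`crosstalk:AKT-ASK1`, `internalization`) or the ROS species with every
  reaction touching it; species orphaned by a removal are dropped.

## Sensitivity analysis

`S = [(A₊ − A₋)/A₀]/(2δ)`, a central, normalized finite difference of the
time-integrated readout (trapezoidal, 60-min transient window), where the
perturbed systems scale one species' initial amount by (1 ± δ), δ = 0.1,
and are re-equilibrated before stimulation. S is dimensionless and
invariant to concentration rescaling. The one-sided-versus-central choice
and the window are checked by a step-halving tolerance (δ = 0.1 vs 0.05
agree within 10% on toy models). Scanned over the 28 nonzero-initial
species for p-ERK, p-AKT and p-p38, the model yields: MEK and Raf as the
top non-trivial p-ERK ranks; Grb2, PIP2, Gab1, PI3K, PDK1, SOS and PTEN
among the top p-AKT ranks; AKT as the single most negative and ASK1, MKK,
RacGDP as the largest positive p-p38 sensitivities.

## Calibration

Selected rate constants are fitted to tidy (time, readout, value) tables by
multi-start bounded least squares in log-parameter space
(`scipy.optimize.least_squares`, trust-region reflective): log-uniform
starts within bounds from a seeded generator, the model's current values as
the first start, a large finite residual when a simulation fails, and
Gauss–Newton standard errors mapped back by the delta rule. This is a
deliberately simple ensemble — not a posterior, and not the hybrid
ensemble scheme referenced in the source literature, which is out of scope.

## Synthetic data

`synthetic.generate_timecourse_dataset` emulates sampled phospho-protein
time courses: a sparse time grid and multiplicative log-normal noise with
unit mean and a stated CV (default 0.1), chosen over additive Gaussian
noise because blot-style readouts are positive and scale-proportional.
It does not emulate densitometry artifacts, batch effects, detection
limits, or biological cell-to-cell variability — so passing recovery tests
demonstrate estimator correctness under the stated noise model, not
robustness to real experimental structure. The sequential first-order
cascade with its exact (Bateman) solution serves as the simulator's
correctness oracle; seeded random mass-action networks drive the
round-trip and conservation property tests. All generators are pure
functions of their arguments including the seed.

## Numerics

LSODA (scipy `solve_ivp`) with an analytic Jacobian assembled from the
stoichiometry; rtol 10⁻⁶, atol 10⁻⁹ nM by default (configurable). Timed
events restart the integrator at the discontinuity rather than relying on
step rejection. Tightening tolerances tenfold changes the scenario readouts
by well under 0.1%. Conservation laws are computed as the integer left null
space of the stoichiometry matrix (rational arithmetic via sympy; a
`within` restriction keeps the computation cheap on the full network), and
moiety totals drift by less than 10⁻⁶ relative over a simulated day.
`peak_time` breaks ties toward the earliest grid point; `time_to_basal`
reports the earliest post-peak time within a stated fraction (default 5%)
of the excursion and signals "never returned" explicitly.

Problem sizes used by the test and acceptance runs: 60-min transient and
120-min sustained scenarios on a 0.1-min grid; a 30-h acute-inactivation
run; a 24-h conservation check; a 2 × 28 + 1-simulation sensitivity scan;
and a 20-replicate, 20-start, 3-parameter recovery study on a 4-species
cascade.

## Known limitations

* The reaction inventory is a reconstruction: mechanisms and cardinalities
  are faithful, but individual rate constants are package calibrations,
  not literature measurements, and the padded rows are explicitly inert.
* ROS → ERK/AKT pro-survival signalling is absent by design, as is
  everything downstream of p-p38 (apoptosis execution).
* Sustained p-p38 sits near, not exactly at, its pre-stimulus basal value
  (within ~1.5×); after receptor inhibition with the crosstalk removed,
  p-p38 stays high for hours but ultimately decays as ROS production
  ceases — statements about "persistently high" p-p38 are therefore
  evaluated on the first hour after the event.
* Compartment volumes are implicit (all concentrations share one scale);
  no stochastic (SSA) or spatial simulation is provided.
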