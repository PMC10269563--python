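# Methods

## Model structure

The simulated system is a batch wine fermentation by a cold-tolerant
yeast. Extracellular state (biomass dry weight DW in g/L and metabolite
concentrations in mM) evolves by ODEs whose right-hand side is obtained
from a linear program: at each integration step the intracellular network
is assumed at quasi-steady state (`S·v = 0`, fluxes in mmol/(gDW·h)) and
a phase-specific objective is maximized under kinetic exchange bounds;
then `dC_m/dt = v_m·DW` for every extracellular species and
`dDW/dt = μ·DW` with μ the biomass flux (0 in lag and stationary,
−k_d·DW in decay).

The fermentation is divided into five phases with estimated boundaries
`0 < T_L < T_E < T_S < T_D ≤ t_end` (half-open intervals, left-closed).
Objectives per phase:

| phase | objective | biomass reaction |
|---|---|---|
| lag | max ATPase (maintenance ATP hydrolysis) | off |
| exponential | max growth | standard composition |
| N-limited growth | max growth with carbohydrate accumulation | carb-enriched variant |
| stationary, decay | max ATP + protein synthesis, jointly | off |

The "ATP + protein" combination is a weighted sum with each weight set to
the reciprocal of that flux's standalone optimum under the current
bounds; the scalarization was an open design choice and this
normalization prevents unit dominance. On the bundled network the two
terms are exactly commensurate (protein polymerization costs 4.3 ATP per
residue, which equals its normalized weight ratio), so the combination is
tie-broken by the parsimonious stage: with growth off and no nitrogen
demand the parsimonious optimum takes no amino acids unless a forced
product (e.g. 2-phenylethanol from the phenylalanine-like pool) makes the
uptake route the shortest one.

Every LP is solved in two stages (parsimonious FBA): the objective is
maximized, then fixed to its optimum within a relative tolerance of 1e-9
and the total absolute flux Σ|v| is minimized. The LPs are held as
persistent GLPK problems and warm-started between steps, which keeps a
full accurate simulation of a 300–600 h fermentation at 1–3 s. The
integrator (LSODA, rtol 1e-6 / atol 1e-9 by default) restarts at each
phase boundary because objectives and constraints switch discontinuously
there; concentrations are clipped at zero (all kinetic bounds vanish
continuously as their substrate goes to zero, so the clip is inactive up
to integration error).

## Kinetic exchange constraints

Equalities: glucose and fructose (Michaelis–Menten with noncompetitive
ethanol inhibition, constants vmax_G/k_G, vmax_F/k_F, K_Ei), dissolved
oxygen (first order, k_O2), and every fermentation product
(`v_Pj = −X_A·k_Pj·(v_Glx+v_F)`). One-sided lower bounds: ammonium
(Michaelis–Menten) and amino acids (mass action) — the LP may take less.
Arginine uptake is mass action during lag through N-limited growth and
exactly zero from the stationary phase onward, which leaves residual
arginine at the end of fermentation.

Acetate changes role at T_S: during growth it is a proportional product;
from the stationary phase it follows a first-order uptake equality
`v_ac = −k_ac·Ac`. This realizes the observed stationary-phase acetate
consumption, which the engine routes through acetyl-CoA synthetase into
the mevalonate pathway (its excretion, standing in for lipid sinks, is
opened for the stationary and decay phases only).

X_A is an activity coefficient on product formation (default 1 in the
bundled presets). Because the product equalities are hard constraints,
values below 1 shrink the redox sinks without shrinking the sources and
can make the LP infeasible on the small network; X_A is therefore left
at 1 and exposed for genome-scale models.

## Dynamic biomass and GAM

Protein mass fraction follows remaining YAN through a saturating curve
`p(YAN) = p_min + (p_max−p_min)·YAN/(YAN+k_p)` (p_min 0.25, k_p 50 mg
N/L; p_max calibrated per condition so the initial must gives 0.66 at
12 °C and 0.41 at 25 °C). The exact functional form was an open design
choice; a two-parameter saturating curve is smooth, monotone and matches
both calibration points. RNA is 0.05·protein, DNA 0.01 and lipid 0.05
are fixed, and carbohydrates absorb the remainder. The carb-enriched
variant used during N-limited growth shifts +0.20 mass fraction from
protein (via the same ρ) to carbohydrate.

GAM (mmol ATP per gDW formed — the literature reports the number with an
h⁻¹ in the unit, but it enters the biomass pseudoreaction per gram) is
`GAM_F + Σ fraction_i × cost_i` with polymerization costs shipped as
package data (protein 29.3, RNA 1.2, DNA 4.2, carbohydrate 6.2 mmol
ATP/g; package defaults adapted from published cost estimates). GAM_F is
the estimable residual; the preset values are backed out from total GAM
of 137 (12 °C) and 99.8 (25 °C) at the initial compositions. The biomass
pseudoreaction consumes monomers summing to 1 g per unit flux
(glutamate for protein, a C5N nucleotide monomer for RNA/DNA, anhydrous
hexose-phosphate for carbohydrate, a palmitate-like lipid) plus
GAM-total ATP, and is rewritten along the trajectory as YAN falls.

## The toy network

A deliberately small (~70 metabolites, ~95 reactions, cytoplasm +
mitochondrion, exchanges drain directly from the cytoplasm) but
carbon/nitrogen-balanced caricature of wine-yeast metabolism. It
realizes, with correct stoichiometric signatures: lumped glycolysis, the
oxidative PPP (2 NADPH per hexose-P) and a reversible non-oxidative lump
to erythrose-4-phosphate, the erythritol branch (added through the same
curation operation used for external models), pyruvate decarboxylation
and NADH-dependent ethanol formation, NADP-dependent acetate formation,
acetate activation (ATP→AMP, with adenylate kinase and
pyrophosphatase), the mevalonate route (3 acetyl-CoA and 2 NADPH per
mevalonate), the TCA oxidative branch to 2-oxoglutarate (no
2-oxoglutarate dehydrogenase, so succinate cannot form oxidatively
except via the shunt), the cytosolic reductive branch
OAA→malate→fumarate→succinate, the malate/2-oxoglutarate antiporter, the
GABA shunt (net 2-OG → succinate + CO₂ + 1 NADPH), Ehrlich routes to
isobutanol, isoamyl alcohol and 2-phenylethanol with parallel NADH- and
NADPH-dependent reductions, the ethanol–acetaldehyde and
glycerol-3-phosphate shuttles, respiration (P/O 1.5, active only while
the initial dissolved O₂ lasts), and protein synthesis/degradation
pseudo-fluxes for the stationary objective and turnover.

Elemental bookkeeping covers carbon and nitrogen exactly (checked for
every non-boundary reaction); cofactors carry inert pseudo-elements so
CoA and phosphate stay conserved, while hydrogen/oxygen are deliberately
loose in the lumped reactions.

Because hexose uptake and all major products are equality-constrained,
the network needs free overflow routes or the LP is generically
infeasible; it ships four, all real yeast overflow metabolites:
acetaldehyde export (carbon valve), 2,3-butanediol (NADH sink via
pyruvate), mannitol (strong NADH sink from hexose-phosphate) and
arabitol (pentose-side valve). Parsimonious FBA keeps them silent when
the balance closes without them. A structural consequence worth knowing:
the ethanol yield coefficient has a redox ceiling near 1.66 mol/mol
hexose on this network — above it no flux distribution exists, and the
estimator reports a finite penalty for such candidates.

## Scenario presets (the simulated study conditions)

Both presets share the initial must: 100 g/L each of glucose and
fructose (555 mM), ammonium 2 mM, three amino-acid pools (glutamate-,
leucine- and phenylalanine-like; 1.2/0.6/0.5 mM) plus arginine 1 mM
(YAN ≈ 115 mg N/L), dissolved O₂ 0.25 mM, inoculum 0.05 gDW/L. The
temperatures differ in the sign pattern reported for such fermentations:
the cold preset has longer phases (T_L..t_end 15/100/200/420/600 h vs
5/40/90/210/300 h), slower uptake kinetics (vmax_G 2.0 vs 3.5
mmol/(gDW·h)), higher GAM, higher initial protein content, a higher
erythritol yield (k_P 0.006 vs 0.002) and much weaker stationary acetate
uptake (k_ac 0.002 vs 0.010 L/(gDW·h)). Ethanol and glycerol yields
(1.55/0.19 cold, 1.58/0.18 standard) sit inside the redox corridor.
These values were chosen once as realistic wine-fermentation magnitudes
(final ethanol ≈ 80 g/L, biomass 1.5–5 g/L, residual sugar in the cold
run — a sluggish cold fermentation).

Synthetic measurements sample every state variable on a uniform grid
(24 points) and apply independent, mean-preserving multiplicative
lognormal noise with a chosen CV (the instrument-like choice: errors
scale with signal and concentrations stay positive). The generator
returns the noise-free trajectory as ground truth for recovery tests.

What the generator does not emulate: biological replicate variability,
sampling-time jitter, variable-specific detection limits or
heteroscedastic floors, CO₂ off-gas measurements, and transcriptome-like
data. Passing recovery tests therefore show the estimator works on data
of the assumed noise structure, not that real bioreactor data are this
kind.

## Estimation

`J(θ)` interpolates the simulated trajectory to the sampling times
(monotone cubic) and normalizes each variable's residuals by the mean of
its observed readouts (a per-variable scalar — the matrix form collapses
to this when weights are variable-wise). Failed simulations contribute a
large finite penalty so the global search continues. Fitting runs in a
fast integration mode (RK23, looser tolerances, LP solves only in the
growth phases — in lag/stationary/decay every exchange flux is already
determined by the kinetics and the parsimonious nitrogen uptake is zero;
state agreement with the accurate mode is ~1e-3 relative).

The search is scipy's differential evolution (seeded, bounded,
polish-free), satisfying the contract any population-based global
optimizer must meet here: reproducible given the seed, never leaving the
box, final J no worse than the best initial sample. Budgets below two
population sweeps fall back to the best of a seeded space-filling
sample. Phase-time candidates violating the ordering are rejected with a
penalty proportional to the violation rather than reparameterized as
increments — with subset fitting (typically only T_S free) the box can
be placed inside the ordering interval, and the penalty handles the
remaining edge.

The bundled recovery experiment (cold preset, 5 % noise, fixed seed,
2,500 evaluations, free parameters vmax_G, k_P[ethanol], T_S) recovers
all three within 15 % of truth; glucose R² of the refit exceeds 0.98.

## Flux ratios

`S_i = 100·∫v_i·DW dt / H` with `H = |∫(v_Glx+v_F)·DW dt|`, trapezoidal
quadrature on accepted steps, windows growth [T_L,T_S], stationary
[T_S,T_D], decay [T_D,t_end]. A printed variant of the decay formula
integrates the whole run; the `whole_run` option reproduces it, the
default treats the window label as authoritative. The denominator is the
accumulated hexose consumption as a positive quantity so production
ratios are positive and uptake ratios negative (the hexose exchange
entries themselves sum to −100 by construction). Differential selection
between two conditions takes reactions with max(|S_a|,|S_b|) > 0.1
(absolute values; the magnitude cut is applied to |S|) and |log₂ fold| >
1, flagging sign-inconsistent pairs instead of folding them.

## Numerical choices and limitations

* LP determinism: a fixed GLPK pivoting rule plus the parsimonious stage
  makes repeated solves bit-identical; the pFBA objective-fixing slack is
  max(1e-9·|z|, 1e-12), visible as ~1e-8 absolute in flux values at
  optima of order 10.
* Steady-state residual max|S·v| stays below ~1e-10 at every accepted
  step on both presets (asserted at 1e-8).
* The dynamic biomass column is refreshed whenever the protein fraction
  moves by more than 1e-5 (or GAM_F changes), a discretization far below
  integration error.
* Phase-boundary trajectory points are recorded once, labeled with the
  closing phase; ratio windows therefore carry an O(Δt) edge effect at
  their boundaries.
* The toy network's purpose is structural fidelity, not quantitative
  imitation of any particular must; genome-scale values (e.g. absolute
  flux-ratio magnitudes, the 12 °C GABA-shunt share of succinate) are
  not expected to match it. On the toy network the 12 °C stationary
  phase produces succinate through the reductive branch (no NADPH pull),
  while at 25 °C acetate-driven mevalonate synthesis activates the
  GABA shunt — the inter-temperature direction, not the exclusivity, is
  reproduced.
* Temperatures are fitted independently; no Arrhenius-type coupling of
  parameters across conditions.
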