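# Model and methods

`symbiosim` simulates metabolic symbiosis in a growing tumour: oxygenated
cells at the tumour rim oxidise exogenous lactate imported through MCT1
(the "reverse Warburg" effect), while hypoxic interior cells run glycolysis
and export that lactate through MCT4.  The model couples three spatial
scales on a 2D lattice — a Boolean regulatory network inside every cell, a
stoichiometric metabolic layer, and steady-state reaction–diffusion fields —
plus a cellular automaton for division, death and contact inhibition.

## Intra-cellular scale: Boolean regulatory network

Every cell carries a copy of a Boolean network (`src/symbiosim/data/
default_network.net`, plain text, editable).  Input nodes are driven by the
microenvironment: a bound input is active iff its substance's local
concentration is at or above an activation threshold (the comparison is
inclusive so the boundary case is deterministic).  Inhibitor-input nodes
(GLUT1I, MCT1I, MCT4I) are set stochastically by drug exposure.  Internal
and output nodes update *asynchronously*: each phenotype step performs
`n_sweeps` (default 1) passes in which every free node is recomputed once,
in a freshly drawn random order, against the immediately visible state.
Knockout/enrichment fixes a node at 0/1 for the whole run; forced nodes are
never updated.

The shipped network is a curated ~30-node summary of a MAPK–HIF–metabolism
logic, not a literature-complete reconstruction.  Its load-bearing rules:

* `HIF1 := NOT Oxygen_supply`; `PDK := HIF1 OR MYC`.  PDK (pyruvate
  dehydrogenase kinase) diverts pyruvate from the mitochondria, so
  glucose-fuelled OXPHOS is suppressed in signalling-active or hypoxic
  cells — the Warburg switch.
* `Lactate_oxidation := Oxygen_supply AND Lactate_supply AND MCT1` is the
  MCT1-dependent lactate-intake branch; it both fuels
  `mitoATP := Oxygen_supply AND (Lactate_oxidation OR (Glucose_supply AND
  GLUT1 AND NOT PDK))` and defines the "lactate-metabolic" classification
  used by the symbiosis index.
* `glycoATP := Glucose_supply AND GLUT1 AND (HIF1 OR NOT Lactate_oxidation)`:
  hypoxic cells always glycolyse; oxygenated cells prefer lactate oxidation
  when it is available (this preference is what lets a clean division of
  labour, rather than a mixed phenotype, emerge at the rim).
* p53 axis: `p53 := NOT MDM2`, with MDM2 held off by MYC-induced p14ARF, so
  p53 is active in wild-type tumour cells.  p53 loss acts through two
  mechanisms: apoptosis stops (`Apoptosis := p53 AND (DNA_damage OR
  Starvation)`) and GLUT1 is de-repressed
  (`GLUT1 := (MYC OR HIF1 OR NOT p53) AND NOT GLUT1I`).
* `Starvation := NOT (Glucose_supply AND GLUT1) AND NOT Lactate_oxidation`
  is deliberately defined over supply and transporter nodes, which are
  stable within a phenotype step, rather than over the ATP bits: with the
  bit-based definition, a mid-sweep pathway switch (e.g. a rim cell turning
  hypoxic) transiently shows "no ATP" and triggers spurious p53 apoptosis.
  For the same reason a daughter cell's fresh network state is settled with
  four sweeps against its local environment at birth, before any fate is
  read from it.

Fate precedence is Apoptosis > Proliferation > Growth_Arrest, with
Growth_Arrest the default when no fate node is active: death must dominate,
and the source logic does not specify tie-breaks.

## Metabolic layer

Rates follow Monod kinetics switched by the two pathway bits the network
provides (glycoATP, mitoATP); writing `m(C,K) = C/(K+C)`:

    R_O2   = mu_O2 * m(C_O2,K_O2) * (mitoATP + K_glyco*glycoATP)
    R_G    = (mu_O2/6) * m(C_O2,K_O2)*m(C_G,K_G)*mitoATP
             + (mu_O2/6)*(A0/2) * m(C_G,K_G)*glycoATP
    R_ATP  = A0*(mu_O2/6) * [m(C_O2,K_O2)*m(C_G,K_G)*mitoATP + m(C_G,K_G)*glycoATP]
    R_L,p  = 2*(mu_O2/6)*(A0/2)*m(C_G,K_G)*glycoATP
    R_L,c  = 2*(mu_O2/6)*m(C_O2,K_O2)*m(C_L,K_L)*mitoATP
    R_H+   = beta*A0*(mu_O2/6)*m(C_G,K_G)*glycoATP

These encode the textbook stoichiometry — 6 O2 per glucose and A0 (28–36)
ATP per glucose under OXPHOS; 2 ATP, 2 lactate and 2 protons per glucose
under glycolysis; 3 O2 per lactate for reverse-Warburg oxidation — and are
built so both pathways reach the same saturating ATP rate (cells adjust
nutrient throughput to their energy demand).  A glycolytic cell still draws
`K_glyco` (0.5) of the maximal oxygen rate for biosynthesis.  A cell with
both bits set contributes both terms additively.  Proliferation requires an
ATP rate of at least 80% of the saturating maximum `A0*mu_O2/6`
(`atp_gate_fraction`).  Extracellular pH is −log10 of the steady-state
proton field; protons are produced only, damped by the buffering
coefficient `beta` = 0.001 (which puts tumour-core pH near 6.4–6.9).

Units: oxygen in %O2, glucose and lactate in mM, protons in molar, time in
hours.  The rate equations are molar-balanced, so the metabolism module
returns mM/h and the microenvironment converts the oxygen sink to %O2/h
with a solubility constant of 0.013 mM per %O2 (Henry's law at 37°C),
declared in `config.py`.

## Extra-cellular scale

Each substance obeys a diffusion–reaction equation whose diffusion time
scale (seconds) is far below the phenotype time scale (hours), so every
field is relaxed to steady state `D∇²C = R` between phenotype updates:
5-point finite differences, Dirichlet edges pinned at the boundary value,
red–black SOR (ω from the optimal-SOR formula), concentrations clamped at
≥ 0, and the residual tolerance 1e-6 by default.  Because sinks are Monod
functions of the field itself, an outer fixed-point loop re-evaluates them
against the updated fields (3 passes per phenotype step) — the source text
is silent here; this bounds cost and stabilises the coupling.  A direct
sparse solve of the identical discretisation is kept as the test oracle,
never as the engine.  Growth factors (TGFA) use first-order consumption
γ_C·C and zero-order production γ_P at live cell sites; drugs are
substances with first-order cellular uptake that reach cells by diffusion
only.  Metabolically inactive and necrotic cells consume nothing.

## Cellular scale

Each phenotype step (1 h): drug boundary doses are updated from the
schedule, fields are equilibrated, then cells act in a freshly shuffled
order.  A cell first checks necrosis — both oxygen AND glucose below their
critical values (0.1 %O2, 0.1 mM) kills it in place; necrotic cells keep
their site forever and count in the total.  Otherwise the network is driven
and the fate read out; Proliferation additionally requires the ATP gate.  A
proliferative cell older than `t_division` (24 h) divides into a uniformly
chosen empty Moore neighbour (8-neighbourhood, which reproduces compact
circular tumours); the daughter inherits tag and perturbations with age 0,
and both ages reset.  Without an empty neighbour the cell turns quiescent
(contact inhibition) and waits `t_q` (3 h) before re-checking its
environment.  Apoptotic cells are removed, and their sites freed, within
the same step.  The initial tumour is a filled disc of 100 cells at the
domain centre with ages drawn uniformly in [0, t_division); mixed
populations are randomly interleaved at the configured ratio (1:1 for
competition runs).

## Symbiosis index and accounting

Occupied sites split into oxygenated/hypoxic regions by the same oxygen
threshold that drives the cells' Oxygen_supply input (1.5 %O2), keeping the
metric consistent with the dynamics.  Over *active* cells per region,
φ_L is the lactate-metabolic fraction (mitoATP via the MCT1 intake branch)
and φ_G the glycolytic fraction; then

    MSI = (φ_L(A_oxy) − φ_G(A_oxy)) / (φ_L(A_oxy) + φ_G(A_oxy))

when φ_L(A_oxy) > φ_G(A_oxy) and φ_L(A_hypo) < φ_G(A_hypo), else MSI = 0
(also when either region holds no active cell: no active cells, no
measurable symbiosis).  Fractions are over active cells because the index
is about which pathway working cells use.  Paired effect maps report
100·(C_wt − C_ko)/C_ko along the centre cross-section over time, masked
where C_ko = 0.

## Therapy

A drug inhibits its transporter with per-step probability
`e_max·C/(IC50+C)` (e_max = 0.85), drawn independently per cell and step —
memoryless re-draws are consistent with reversible inhibitor binding.
Schedules (windows in days): `continuous`; `alternating` (lactate-intake
blocker first, then the glucose-uptake blocker, swapping every period);
`simultaneous_periodic` (both on for one period, both off for the next);
`control` (both continuous at half dose).  Doses are expressed as multiples
of IC50 (1–1000), matching how dose–response grids are usually reported.

## Sensitivity analysis

Twenty parameters — diffusivities, activation thresholds, half-saturations,
mu_O2, boundary nutrient levels, necrosis criticals, TGFA gammas — are
varied ±20% around baseline with an equal-width-bin Latin hypercube
(40 bins; LHS needs more than 4k/3 bins for k parameters), one uniform
sample per bin, columns shuffled independently.  PRCC: rank-transform all
columns, residualise the target parameter's and the output's ranks on the
other parameters' ranks by least squares, correlate the residuals; p-values
from the t-approximation with n − 2 − (k − 1) degrees of freedom,
significance at p < 0.05.  Constant columns yield missing coefficients.

## Parameters, provenance and scale

The source literature's full parameter table is supplementary material that
is not available here, so every numeric default is this package's own
supplementary-derived choice, declared once in `config.py` /
`scenarios.py`: D (site²/h, 20 µm sites) 18000 (O2), 4500 (glucose/drugs),
5000 (lactate), 20000 (protons), 900 (TGFA); boundaries 6 %O2 / 5 mM
glucose / 1 mM lactate / pH 7.4; K_O2 = 0.45 %O2, K_G = 0.04 mM,
K_L = 0.3 mM, A0 = 30.  Activation thresholds: oxygen 1.5 %O2, lactate
0.8 mM, TGFA 1e-6.  The glucose activation threshold is 1.2 mM: the
low-nutrient scenarios require that a 1 mM boundary supply cannot sustain
glycolysis inside the tumour (that is what eliminates the MCT1- population
in the glucose-poor/lactate-rich competition), while 1.2 mM is comfortably
below the 5 mM baseline; interstitial tumour glucose is of this order.

Two preset scales exist.  `paper` (100×100 lattice, 25 days, mu_O2 =
4.3 mM/h) reproduces the full study geometry: hypoxia emerges when the
tumour radius reaches ≈18 sites, around day 14–17.  `desk` (50×50, 16
days, mu_O2 = 16 mM/h) is the configuration the test-suite and examples
use; the higher consumption rate keeps the oxygen-penetration depth
proportional to the halved domain, so the same normoxic → hypoxic →
symbiotic progression plays out at roughly a third of the run time.  At
either scale the progression is: lactate-fuelled OXPHOS everywhere early
(ambient lactate sits above its threshold), interior oxygen falls with
tumour size, a hypoxic glycolytic core appears and the MSI jumps from 0 to
≈1 and stays there; knocking out MCT1 yields a purely glycolytic tumour
with MSI ≡ 0, an OXPHOS population of at most a few percent of the
glycolytic one, and delayed hypoxia.

## What the simulations do and do not show

All inputs are generated: there are no measured fields or real expression
data, so passing tests demonstrate internal consistency of the mechanism —
emergent division of labour, its loss under MCT1 knockout, nutrient-driven
competition, schedule-dependent drug response — not quantitative agreement
with any tumour.  The Boolean layer is binary (no expression levels), the
lattice is 2D with at most one cell per site, there is no vasculature,
motility, mechanics, immune or stromal compartment, and pH feeds back on
nothing.  Necrotic cells are retained indefinitely.  Numerical choices that
matter: solver tolerance 1e-6 (residual, relative to the field scale),
clamping at zero concentration, 3 outer sink re-evaluations, one network
sweep per phenotype step, inclusive threshold comparisons, and per-replicate
seeds derived deterministically from (base seed, replicate index).
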