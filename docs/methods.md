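# Methods

## Model

`tnbcqsp` implements a quantitative-systems-pharmacology (QSP) model of
triple-negative breast cancer (TNBC) under checkpoint immunotherapy
(atezolizumab, an anti-PD-L1 antibody) and chemotherapy (nab-paclitaxel),
with explicit tumor-associated macrophage (TAM) dynamics.  The default
configuration couples four physiological compartments — central (blood),
peripheral tissue, tumor, and tumor-draining lymph node — plus
sub-compartments for immune synapses and the APC endosome/surface, into a
system of 152 ordinary differential equations with 45 repeated-assignment
rules.

### Cancer and vasculature

Each cancer clone grows by a modified Gompertz law,
dC_i/dt = k_growth · C_i · ln(C_max / C_total), toward a dynamic carrying
capacity C_max maintained by tumor vasculature: capacity grows with an
angiogenic factor c_vas (calibrated against VEGF-A, secreted by cancer
cells and M2 macrophages, induced by low-dose chemotherapy), and is lost
to endogenous endothelial turnover (∝ C_max · (C_total·V_cell)^(2/3))
and to nab-paclitaxel.  Clones die by apoptosis, chemotherapy (Hill in
tumor drug concentration, capped by the drug-accessible cell number),
phagocytosis by M1 macrophages, and effector-T-cell killing.  The two
cell-mediated kill rates saturate in the effector:target ratio
(E/(E + K·C)) and the Teff:Treg ratio, and are damped by the inhibition
Hills for TGF-β, PD-1 engagement, MDSC products, and (for phagocytosis)
IL-10 plus the combined CD47/PD-1 checkpoint Hill.  Two clones are
carried: the initial clone and a chemo-resistant clone with 100× the
nab-paclitaxel EC50, induced from the first by a TGF-β-gated first-order
flux.  Dead cells from apoptosis/chemo/T-kill enter per-clone dead pools
(phagocytosed cells are engulfed, leaving no debris) and clear first-
order while still occupying tumor volume.  Tumor volume is the cellular
volume (live + dead cancer, T, macrophages) divided by the intracellular
volume fraction 0.37 (≈2% vascular and ≈61% interstitial space); the
reported diameter is sphere-equivalent.

### Lymphocytes

Three lineages have independent naive clonotype-average pools in
central/peripheral/lymph-node compartments: CD8→Teff (neoantigen-
specific, diversity 1.11e6), CD4→Th (neoantigen-specific, 1.16e6), and
CD4→Treg (self-antigen-specific).  Naive cells arrive by zero-order
thymic export divided by diversity, self-renew with saturating kinetics
in peripheral organs and lymph node, and exchange between compartments;
transport and renewal constants are solved analytically so the healthy
steady state reproduces measured blood densities (naive CD4 8.6e5,
naive CD8 5.1e5 cell/mL).  In the lymph node, activation consumes naive
cells at k_act · H_APC · H_Ag; activated cells undergo N_aT divisions
(N_aT = N_TCR + N_costim·H_CD28 + N_IL2·H_IL2, a linear sum of signal
components), yielding a 2^N_aT-fold output.  Mature cells egress,
recirculate, and infiltrate the tumor at a rate gated by
C_total²/(C_total² + K_rec) (chemoattractant requirement); the same
constant drives clearance of tumor-resident immune cells as the tumor is
eradicated.  Intratumoral Teff suffer extra death from Treg (IL-10-
mediated, weighted by the Treg fraction) and cancer contact (PD-1-
gated); Th convert to Treg under TGF-β and arginase-I with a flux
first-order in Th, so differentiation conserves Th + Treg.

### Antigen presentation

Immature APCs relax toward a density-proportional baseline, mature under
IL-12 with IL-10 inhibition, and migrate to the lymph node.  Two
aggregated antigen channels (neoantigen, self-antigen) are deposited at a
rate equal to the cancer-death flux, taken up into the APC endosome
(receptor-mediated uptake concentrates antigen ~800-fold over the
interstitial concentration), processed to peptides, loaded on the
channel's MHC pool, and exocytosed.  MHC cycles between endosomal and
surface membranes without synthesis or degradation, so each channel's
MHC is exactly conserved.  Surface pMHC drives TCR engagement through the
smaller root of the binding quadratic and a kinetic-proofreading factor
(k_off/(k_off+φ)) · (k_p/(k_p+k_off))^N, giving the activation Hill
H_Ag; H_APC is the saturating fraction of naive T cells that can engage
a mature APC.

### Checkpoint synapses

Five synapse sub-compartments carry 2-D binding networks
(molecule/µm²): Teff–cancer per clone (PD-1 vs PD-L1/PD-L2, bivalent
anti-PD-L1, cis PD-L1:CD80), macrophage–cancer per clone (the same plus
trans CD47:SIRPα with bivalent anti-CD47), and naive T–APC in the lymph
node (the PD-1 network plus the CD28/CTLA-4 vs CD80/CD86 competition,
including zipper-like multivalent CTLA-4:CD80 complexes and dormant
bivalent anti-CTLA-4).  3-D affinities convert to 2-D through the
synapse confinement thickness d_syn; the contact area is widened 3-fold
in lieu of explicit diffusive entry.  IFN-γ drives saturating PD-L1/2
synthesis up to a fold-limit over baseline.  Inhibition Hills (exponent
2) of the bound-receptor densities give H_PD1 (per cell pair), H_CD28,
H_SIRPα, and the combined phagocytosis checkpoint
H_Mac,C = 1 − (1−H_SIRPα)(1−H_PD1,M).  Only cis PD-L1:CD80 binding is
modeled (no trans); the cis heterodimer still presents CD80 to CD28 at
full affinity but to CTLA-4 with a weakening factor.

### Myeloid cells and cytokines

CCL2 (secreted by cancer cells) recruits M1 macrophages and MDSCs in
proportion to tumor volume.  Macrophages polarize reversibly — M2→M1
under IL-12 + IFN-γ, M1→M2 under TGF-β + IL-10 — conserving the total.
MDSCs secrete arginase-I and NO; their combined Teff inhibition is
H_MDSC = 1 − (1−H_ArgI)(1−H_NO), mirroring the phagocytosis-checkpoint
composition (both mediators suppress killing independently).  Every
soluble mediator follows V·dc/dt = Σ k_sec,i·N_i − k_deg·c·V with a
fixed source map (IL-12 ← M1 + mature APCs at 10× the macrophage rate;
IL-10 ← M2 + Treg; TGF-β ← M2 + cancer; IFN-γ/IL-2 ← activated T cells).

### Pharmacokinetics

Antibodies follow a four-compartment model with volumetric exchange on
free-fraction concentrations [A]/γ, a lymphatic chain tumor→node→blood,
and linear central clearance.  Transport rates derive from the
Stokes-Einstein radius (a_e = 0.483·MW^0.386; 47.4 Å for a 145 kDa IgG)
and permeability-surface-area products (2e-8 cm/s central–peripheral,
3e-7 cm/s for leaky tumor vessels, 28.4 cm²/cm³ capillary area).
Nab-paclitaxel follows a linear three-compartment plasma model; tumor
concentration is plasma × a partition ratio.  Doses are zero-order
infusions (1 h antibody, 30 min chemotherapy); mg/m² doses scale with
per-patient body surface area.

## Virtual trials

Virtual patients are Latin-hypercube samples of ~30 parameter
distributions (growth/angiogenesis rates, checkpoint densities,
trafficking and secretion rates, chemo sensitivity, PK variability,
pre-treatment diameter).  Each patient grows from one seed cell until
first crossing the sampled diameter (solver event); patients that never
reach it within 1500 days are eliminated, and survivors are filtered
against measured pre-treatment ranges.  Treatment is then simulated for
400 days with tumor diameter recorded every 8 weeks.  Response follows
RECIST 1.1 (PR ≤ −30% vs baseline; PD ≥ +20% over nadir with a 5 mm
absolute guard, toggleable; CR below 2 mm; SD otherwise once 8 weeks
from baseline; progression takes precedence over response) or irRC
(PR ≤ −50%, PD ≥ +25% over nadir).  Duration of response runs from
first PR/CR to PD, censored at the horizon, reported in 30-day months;
ORR/DOR summaries use percentile bootstrap with a resample size matching
the clinical study being compared.  New-lesion events are not modeled,
so classification uses size only.

## Calibration

Parameter provenance is tagged in the shipped table
(`reported` / `literature` / `calibrated` / `assumed`).  Calibrated
values were set by the model's own documented procedures, in order:

1. **Naive T homeostasis** — solved in closed form for the healthy
   steady state (scratch-free, exact).
2. **Phagocytosis submodule** — with a Hill exponent of 2 fixed for all
   checkpoint inhibitions, the half-max constants PD1_50 and SIRPα_50
   were set so that sampled phagocytosis activity (1 − H_Mac,C) rises
   ≈8-fold under saturating anti-CD47 and 2–3-fold for PD-1-negative
   macrophages, matching the in-vitro assays these parameters represent.
3. **Baseline dynamics** — macrophage recruitment/turnover and the
   T-cell activation chain were tuned so the median-parameter untreated
   run shows intratumoral M1 density crossing 1e5 cell/mL near day 2 and
   CD8 near day 14, and the tumor-microenvironment composition at the
   median pre-treatment size (3 cm) approximates measured medians
   (CD8 ~1.7e7, macrophages ~2.2e6, MDSC ~1.7e5 cell/mL, M1/M2 ~0.45,
   IL-10 ~20, IFN-γ ~13, CCL2 ~2200 pg/mL).
4. **Population statistics** — distribution medians were adjusted (they
   may differ from the fixed-parameter defaults, as survivorship through
   initialization shifts population medians) so the virtual-population
   medians match the same targets, and treatment-related parameters
   (chemo kill rate, resistance induction, PD-L2:PD-L1 ratio) so ORR and
   DOR of the monotherapy arms approximate the reported trial results.
   The PD-L2 ratio is a genuine resistance dial here: PD-1:PD-L2
   engagement persists under anti-PD-L1 and caps the achievable
   unleashing of T-cell killing.

## Numerical choices

- Stiff integration by LSODA at absolute/relative tolerances 1e-9/1e-6
  (the solver configuration used for all trial simulations); oracle
  comparisons in tests tighten tolerances instead of loosening
  assertions.
- The right-hand side is generated as straight-line code from the
  declarative registry and JIT-compiled once per model *structure*;
  parameters enter as a vector, so one compiled kernel serves every
  virtual patient.
- States are clipped at zero inside the derivative evaluation (fluxes
  cannot be driven by negative populations); outputs are clipped at
  zero and a post-hoc guard raises if any state falls below −1e-6
  relative.
- Ratio denominators carry a 1e-6 guard; the Gompertz logarithm guards
  both numerator and denominator; tumor volume has a 1e-6 mL floor
  (an isolated micro-tumor still occupies a small tissue context).
- Rules form a DAG (cycle detection at assembly) and are emitted in
  dependency order, so evaluation order cannot affect derivatives.
- Tumor drug concentration neglects dilution by tumor-volume growth
  (volume doubling is slow against PK turnover).
- Dosing uses piecewise integration with solver restarts at infusion
  boundaries; bolus doses are state jumps.

## Problem sizes

Shipped analyses use sizes that keep a full run on one CPU comfortable:
phagocytosis panels of 100–400 samples, PRCC with 200–1000 LHS samples,
and virtual trials of ~100–200 sampled patients (of which roughly a
third survive initialization at the default distributions; the original
analysis used ~1000).  All sizes are arguments.

## What the synthetic data does and does not show

The virtual population emulates inter-patient variability by independent
parameter sampling: covariances between parameters (e.g. jointly
regulated cytokine axes) are absent, so extreme combinations occur that
real patients would not show, and population ranges are wider than
measured ranges.  Tumors are single, spherical, spatially well-mixed
lesions; new metastatic lesions, toxicity-driven discontinuation, and
imaging detectability limits are not modeled, which inflates stable
disease relative to progressive disease exactly as size-only
classification predicts.  Passing tests therefore demonstrate internal
consistency and agreement with the calibration targets, not predictive
validity on new patients.

## Known limitations

- The three-compartment nab-paclitaxel model is linear; saturable
  distribution present in the population PK literature is not included
  (the parameter file is the extension point).
- Helper-T subsets (Th1/Th2/Th17), NK cells, B cells, and fibroblasts
  are out of scope.
- The CTLA-4 zipper network truncates at 2:2 complexes; anti-CTLA-4 and
  anti-CD47 antibodies are carried with full PK/binding machinery but no
  default regimen doses them.
- Per-lineage tumor-resident death rates and a CD8-specific activation
  rate were introduced to reproduce the measured CD4/CD8 asymmetries in
  both naive depletion and infiltrate composition; the printed equations
  use generic symbols for these rates.
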