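# tnbcqsp

A quantitative-systems-pharmacology (QSP) model of triple-negative breast
cancer (TNBC) immunotherapy with explicit tumor-associated macrophage
(TAM) dynamics, for modelers studying checkpoint blockade and
chemo-immunotherapy combinations in silico.

The model couples four physiological compartments (blood, peripheral
tissue, tumor, tumor-draining lymph node) with immune-synapse and
APC-endosome sub-compartments into 152 stiff ODEs plus 45 algebraic
rules: Gompertzian cancer growth toward a vasculature-driven carrying
capacity dC/dt = k·C·ln(C_max/C_total); naive/activated T-cell
homeostasis with a 2^N proliferation program; antigen processing with
kinetic-proofreading TCR activation; mass-action checkpoint binding
networks (PD-1:PD-L1/2 with bivalent anti-PD-L1, cis PD-L1:CD80,
CD28/CTLA-4 vs CD80/86 competition, CD47:SIRPα) yielding inhibition
Hills such as H_Mac,C = 1 − (1−H_SIRPα)(1−H_PD1,M); M1/M2 macrophage
polarization and MDSC-derived suppression; and four-compartment antibody
plus three-compartment nab-paclitaxel pharmacokinetics.  On top sit
virtual-patient generation by Latin-hypercube sampling, in-silico
clinical trials with RECIST 1.1 / irRC response classification,
bootstrap ORR and duration-of-response summaries with Kaplan-Meier
curves, and LHS-PRCC global sensitivity analysis.

## Worked example

`examples/01_baseline_dynamics.py` grows an untreated tumor from one
seed cell at the default (median) parameters:

```
model: 152 ODE states, 45 rules, 224 parameters
M1 macrophages reach 1e5 cell/mL on day 1.9
CD8 T cells reach 1e5 cell/mL on day 15.4
tumor reaches 3 cm on day 500
  CD8_density: 1.59e+07
  Treg_density: 1.05e+07
  Mac_density: 2.13e+06
  M1_M2_ratio: 0.453
  MDSC_density: 1.69e+05
  IL10: 22.1
  IFNg: 14.7
  CCL2: 2.2e+03
```

Pro-inflammatory macrophages are recruited by CCL2 within days of tumor
seeding; CD8 effector cells follow after antigen release, APC maturation
and lymph-node priming; by the median pre-treatment size (3 cm) the
microenvironment composition (densities in cell/mL, cytokines in pg/mL)
sits at the measured medians the model was calibrated to, with the
M1/M2 balance near 0.45.

The other examples run the phagocytosis checkpoint panel (anti-CD47
blockade restores phagocytosis ≈8-fold, PD-1-negative TAMs 2–3-fold), a
single combination-therapy course with RECIST classification, a small
virtual trial, and the PRCC sensitivity analysis.  A thin CLI wraps the
same functions (`tnbcqsp build|simulate|trial|sensitivity|panel`).

## Layout

- `src/tnbcqsp/framework.py` — declarative model registry and compiled
  stiff ODE integration
- `src/tnbcqsp/modules/` — cancer/vasculature, lymphocytes, antigen
  presentation, checkpoint synapses, myeloid cells, pharmacokinetics
- `src/tnbcqsp/trial.py`, `stats.py`, `panel.py`, `sensitivity.py` —
  virtual trials, statistics, checkpoint panel, LHS-PRCC
- `src/tnbcqsp/data/` — default parameter table and virtual-patient
  distributions (editable CSV)
- `docs/methods.md` — model equations, assumptions, calibration, and
  limitations
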