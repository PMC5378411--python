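# vegfpkpd

Whole-body compartmental model of VEGF-family ligand distribution and
VEGFR1/VEGFR2 activation in a healthy human.

Angiogenic signaling by the VEGF family is shaped by much more than
ligand–receptor affinity: the splice isoforms VEGF121, VEGF165 and VEGF189
(and PlGF1/PlGF2) differ in whether they bind heparan-sulfate sites in the
extracellular matrix and basement membranes (M), and whether they engage
the co-receptor Neuropilin-1 (NRP1) directly or only via pre-formed
NRP1–VEGFR1 complexes. Soluble VEGFR1 (sR1) acts as a ligand trap that
itself binds matrix and NRP1. Matrix-immobilized ligand can activate
surface VEGFR2 with a distinct site-specific phosphorylation profile
(pY1214/migration vs pY1175/proliferation), because immobilized complexes
are not internalized and phosphatase activity differs between the cell
surface and Rab4/5 / Rab11 endosomes. `vegfpkpd` puts all of this in one
mechanistic framework for systems-pharmacology questions: where is each
isoform in the body, what occupies VEGFR1 and VEGFR2, and how do sR1, PlGF
and matrix density shift signaling?

## Model

Three well-mixed compartments (calf muscle, main body mass, blood/plasma)
exchange soluble species via vascular permeability, lymphatic drainage and
plasma clearance. Within each tissue, a mass-action network generated
automatically from the kinetic tables couples the five ligands L to
receptors (R1, R2), NRP1 (N1), sR1 and matrix sites M in the ECM and
basement membranes, including ternary complexes M·L·R (endothelial
basement membrane only, 25 nm accessibility) and M·L·sR1. The state
evolves as

    dy/dt = c + L y + S f(y),   f_r = kon_r · y_a · y_b − koff_r · y_p

with c the secretion/production inputs, L the linear trafficking/transport
operator, and S the stoichiometry matrix; endothelial receptors cycle
surface → Rab4/5 → (surface | Rab11 → surface) with ligation- and
NRP1-dependent rates. VEGFR2 phosphorylation at Y951/Y1175/Y1214 is
first order (k_phos = 1 s⁻¹ when ligated, 0 otherwise) against site- and
location-specific dephosphorylation, and pY travels with its carrier
through every binding and trafficking flux. Steady states are solved by
damped Newton iteration with an analytic Jacobian (LSODA integration as
globalizer); ligand secretion and receptor production rates are calibrated
by a damped quasi-Newton root solve to plasma concentration and surface
receptor-density targets. See `docs/methods.md` for assumptions, unit
conventions, parameter provenance and limitations.

## Worked example

```python
from vegfpkpd import load_parameter_set, build_model
from vegfpkpd.calibration import fit_rates
from vegfpkpd.experiments import ligation_summary, distribution_summary, phospho_summary

params = load_parameter_set()
model = build_model(params)
fit = fit_rates(model)          # 9 rates -> 9 physiological targets
ss = fit.steady_state
lig, dist, ph = ligation_summary(ss), distribution_summary(ss), phospho_summary(ss)
```

prints (via the corresponding report calls):

```
fit converged in 13 iterations; q_VEGF=0.0750, q_PlGF=0.0041, q_sR1=0.5803 molecules/cell/s
surface occupancy: VEGFR1 0.9%, VEGFR2 5.4%
VEGF121 share of ligand on VEGFR1: 54%
plasma VEGF bound to sR1: 76%
tissue sR1 matrix-bound:  90%
pY1214/pY1175 by isoform: V121=0.91, V165=1.01, V189=1.02
```

Reading: after calibration to 1.5/10/100 pM plasma VEGF/PlGF/sR1 and
1800/5800/70000 surface receptors per endothelial cell, receptor
occupancies are low (ligand, not receptor, is limiting in vivo); VEGF121 —
the only VEGF isoform that binds NRP1-coupled VEGFR1 — dominates VEGFR1
ligation even at 8% of production; most plasma VEGF rides on the sR1 decoy
and most tissue sR1 is itself matrix-sequestered; and the migratory-vs-
proliferative signaling ratio pY1214/pY1175 rises with isoform length,
because matrix-tethered and NRP1-recycled complexes spend more time at the
cell surface where Y1214 dephosphorylation is slow.

The same analyses are available from the CLI:

```sh
vegfpkpd validate            # kinetic-table audit: KD typos, cycle closure
vegfpkpd calibrate           # fit secretion/production rates to targets
vegfpkpd report              # distribution / ligation / phospho / flux tables
vegfpkpd sweep --target sr1  # perturbation sweeps (plgf | sr1 | ebm)
vegfpkpd ablate              # matrix-ligand-receptor ablation cases
vegfpkpd isoform --isoform VEGF165   # single-isoform scenario
vegfpkpd sensitivity         # ±2% super-sensitivity scan
```

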