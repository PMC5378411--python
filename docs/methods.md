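# Methods

## Model overview

`vegfpkpd` is a deterministic compartmental pharmacokinetic/pharmacodynamic
model of the VEGF ligand family in a healthy 70 kg human. The body is three
well-mixed compartments — calf muscle (gastrocnemius + soleus), the main
body mass (remaining tissue, treated as skeletal muscle), and blood (5 L,
60% plasma). Five pre-dimerized ligands are tracked: VEGF121, VEGF165,
VEGF189, PlGF1 and PlGF2, together with soluble VEGFR1 (sR1), endothelial
surface receptors VEGFR1/VEGFR2 and the co-receptor NRP1, and
heparan-sulfate binding sites (M) in three interstitial sub-volumes
(extracellular matrix, endothelial basement membrane, parenchymal basement
membrane).

The state vector holds molar amounts of every *species instance* — a
molecular composition placed in a compartment and subcellular location
(interstitial fluid, one of the matrix locations, EC surface, Rab4/5 or
Rab11 endosomes, or plasma). Amounts, not concentrations, are the primary
state: concentrations are derived views using the appropriate reference
volume (available interstitial fluid, plasma, total tissue, or EC surface
area), which avoids unit errors at compartment boundaries. The full model
has ≈280 chemical states plus ≈120 companion phospho states.

## Reaction network

The network is generated automatically from the binding-parameter table:
every non-empty (reaction label, isoform) entry becomes one reversible
mass-action reaction per compartment and legal location. Isoform
differences are carried entirely by the table and by five boolean binding
traits per ligand (VEGFR1, VEGFR2, matrix, direct NRP1 bridging,
NRP1-coupled-VEGFR1 binding). The species set is the closure of the
monomers under these reactions plus trafficking moves, so the registry and
the network can never disagree. kon/koff are authoritative; the KD column
is used only for the consistency audit (`validate_kinetics`), which flags
four rows of the shipped table where the printed KD disagrees with
koff/kon by more than 10%.

Rate-constant unit handling reduces every bimolecular rate to amount space
(`flux = khat · a_i · a_j`) with `khat = kon_volumetric / V_context`:

* soluble encounters use the available interstitial fluid volume (tissue)
  or plasma volume (blood);
* membrane–membrane encounters (receptor coupling, endosomal re-binding,
  and EBM-immobilized-ligand ↔ surface-receptor binding) use the surface
  convention, `kon_surface = kon_M × 1000 × ESAV`, equivalent to dividing
  by total tissue volume;
* EBM ↔ surface reactions are additionally scaled by the accessible
  fraction `min(reach / thickness, 1)` with a 25 nm reach — only
  basement-membrane-bound ligand within reach of the cell surface can
  engage receptors. Soluble ligand binding to matrix sites is not scaled
  (the fluid permeates the basement membranes).

Matrix–ligand–receptor (M·L·R) ternary complexes form only at the
EBM/surface interface; M·L·sR1 complexes form throughout the interstitium.
M·L·R complexes are surface-tethered and never internalize; dissociation
from the matrix releases a normal L·R complex that traffics normally.
Matrix sites are strictly conserved per location.

Three ablation switches reproduce the matrix-complex perturbation cases:
`no_mlr_cell` (no M·L·R on cells), `no_mlr_sr1` (no M·L·sR1 in either bond
order, and no ligand capture by immobilized sR1), and their conjunction
("no MLR"). A fourth switch optionally lets PlGF2 bind NRP1-coupled
VEGFR1/sR1 (experimentally unproven; off by default, reusing PlGF2's
VEGFR1 kinetics when enabled).

### Detailed-balance audit

For every three-species cycle reachable by two binding orders the audit
reports the ratio of KD products along the two paths. All matrix/sR1
cycles close to 1 exactly as parameterized. The NRP1-coupling cycles do
*not* close (ratios ≈ 3.75–250): NRP1 presentation deliberately enhances
ligand capture in this model family. The audit reports these rather than
"correcting" them — they are the mechanism, not a typo.

## Trafficking and phosphorylation

Receptors are produced at the surface, internalized to Rab4/5, recycled
directly or via Rab11, and degraded from either endosomal pool, with rates
depending on receptor class, ligation, and (for VEGFR2) NRP1 content —
NRP1-containing complexes route preferentially through Rab11. Free ligand
or sR1 released inside an endosome is degraded with the endosome contents
(no back-transport; the simplest closure). Complexes keep their integrity
through recycling. VEGFR1 trafficking is structurally present but all
reporting exposes surface VEGFR1 only.

Baseline receptor production is the closed-form rate that puts the
no-ligand steady state of the three-pool trafficking system exactly at the
target surface density; the calibrated per-tissue multiplier then
compensates ligand-induced degradation, matching the "change from
no-ligand steady state" convention of the production-rate table.

Phosphorylation of VEGFR2 at Y951/Y1175/Y1214 is first-order and
site-independent: rate 0 for unoccupied receptor, 1 s⁻¹ for ligated
receptor; dephosphorylation varies by site and location (Y1175 faster at
the surface, Y1214 faster in Rab4/5). Phospho amounts are companion states
that travel proportionally with every carrier flux (binding, unbinding,
trafficking, degradation). Because the chemistry never depends on the
phospho states, the steady-state phospho distribution satisfies a small
linear system that is solved exactly after the chemistry converges; the
same fluxes define the transient phospho right-hand side used in the toy
models. Y951 is tracked structurally but defaults to Y1175's
dephosphorylation rates and is excluded from headline reports.

## Transport and clearance

Free ligands, free sR1 and L·sR1 complexes move between tissue fluid and
plasma by bidirectional vascular permeability (flux ∝ concentration
difference on fluid-phase concentrations; species-specific,
size-scaled permeabilities, PlGF = VEGF) and by lymphatic drainage (tissue
→ blood only, proportional to interstitial fluid concentration,
size-independent, including L·sR1). A single first-order clearance per
species family acts in plasma. Matrix- and cell-bound species are
immobile. The flux audit integrates every process rate at steady state
into per-compartment, per-family flow tables (pmol/day) and verifies
conservation to 0.5%.

## Numerics

The right-hand side is affine-plus-bilinear, `dy/dt = c + L y + S f(y)`,
with an analytic sparse Jacobian. Steady states are found by damped Newton
iteration with line search and non-negativity clipping; matrix-site
conservation replaces the residual rows of the free-site states (the
binding subsystem is singular along those directions). Cold starts
(no-ligand receptor distribution, free matrix sites) are globalized by
LSODA integration in expanding windows (10⁵…10⁸ s) with Newton polish
between windows; warm starts go straight to Newton, which is what makes
the nested calibration and sweep solves fast (tens of ms each).
Convergence requires max |dy_i| / (|y_i| + atol) < 10⁻⁹ with
atol = 10⁻³ molecules. Integration uses rtol 10⁻⁶; the Newton polish makes
all reported quantities insensitive to rtol. Tiny negative excursions are
clipped in reporting only.

Calibration solves the 9-unknown/9-target root problem (three secretion
rates, six receptor-production multipliers vs three plasma concentrations
and six surface densities) by damped Newton on log-rates (damping 0.5,
finite-difference Jacobian, step clipped to e²) with warm-started steady
solves; zero plasma targets pin the corresponding secretion rate at zero
and drop out of the root problem. Typical convergence: ~10 iterations,
well under a minute on one CPU. Plasma targets are interpreted as *free*
ligand and free sR1 (the assays are assumed not to detect sR1-bound
ligand); per-tissue surface targets are supported for synthetic-target
studies.

## Parameter provenance and the role of defaults

All binding kinetics, production fractions, calibration targets, the
25 nm accessibility reach, blood volumes and the 1 s⁻¹ phosphorylation
rate are printed values, transcribed as-is. The geometric detail
(tissue volumes, ESAV, fluid fractions, basement-membrane thicknesses,
myonuclear-domain size), matrix-site densities, trafficking rates,
site-specific dephosphorylation rates, and transport numbers live in a
supplement that is not reproduced here; the shipped configuration marks
every such value `default (supplement unavailable)` and sets it once to a
standard value for human skeletal muscle from the prior compartment-model
literature this model family builds on. Two structural constraints from
the printed tables inform those defaults: dephosphorylation must be of the
same order as the printed 1 s⁻¹ phosphorylation (otherwise every ligated
receptor is fully phosphorylated on all sites and the documented
surface-vs-endosome differential vanishes), and the printed
receptor-production multipliers (≈32–54× for VEGFR2, ≈1.2–1.5× for
VEGFR1/NRP1 at their steady occupancies) pin the ratio of ligand-induced
to constitutive receptor turnover.

Consequences for interpretation: structural results — network closure,
conservation, cycle ratios, calibration recovery, sign and ordering
contracts (isoform-specific pY1214/pY1175 ordering, monotone sR1
dose–response, VEGF165-only closest to baseline, transport directions for
VEGF and PlGF) — do not depend on the defaults and are tested tightly.
Absolute percentages (receptor occupancies, immobilized-ligand fractions,
interstitial concentrations, knockout fold-changes, the super-sensitivity
magnitude) shift with the unprinted magnitudes; the calibrated model lands
within a factor ≈2–4 of the reference values for these, and the acceptance
suite records them at a ±15% tolerance, several of which therefore fail
honestly under the shipped defaults. The net direction of free-sR1
vascular exchange is similarly parameterization-dependent and comes out
tissue→blood here.

## Problem sizes and runtimes

The baseline steady state (≈400 states including phospho) solves in under
a second warm, a few seconds cold. Full calibration ≈25 s. The acceptance
script — calibration, all summaries, the PlGF/sR1/EBM sweeps, the ±2%
sensitivity scan and a 5-draw calibration-recovery study — completes in a
few minutes on one CPU; the test suite adds a 20-draw recovery study
(~6 min). Sweep granularity defaults to 9–10 multiplier points including
zero.

## Known limitations

No spatial gradients (well-mixed compartments); no proteolytic release or
degradation of growth factors; no VEGF/PlGF heterodimers, VEGF-B, or
monocyte/macrophage receptors; no downstream kinase cascades; "pR2 on at
least one site" is not resolvable because sites are tracked independently
(the Y1175+Y1214 sum is used as the aggregate phosphorylation readout);
endosomal encounter volumes reuse the surface convention for lack of
endosomal geometry.
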