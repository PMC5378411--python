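"""Mass-action reaction-network generation.

Every non-empty entry of the binding tables becomes, per compartment and
legal location, one reversible reaction. Rates are converted once into
*amount space*: the forward flux of reaction r is ``khat * a_i * a_j``
(mol/s) where ``khat = kon_volumetric / V_context`` and the context volume
depends on where the encounter happens:

=================  =====================================================
context            volume
=================  =====================================================
fluid              available interstitial fluid of the tissue
plasma             plasma volume
surface            total tissue volume (ESAV convention for membrane pairs)
endosome           total tissue volume (same convention as the surface)
ebm_access         total tissue volume (both partners membrane-immobilized);
                   on-rate additionally scaled by the fraction of the EBM
                   within reach of surface receptors
=================  =====================================================

Surface-unit rate constants ((mol/cm^2)^-1 s^-1) are first converted to
volumetric via ``kon_M = kon_surf / (1000 * ESAV)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (BindingParameterTable, KineticEntry, ParameterSet,
                         TISSUES)
from .species import (ENDOSOME_LOCATIONS, LIGAND_SYMBOL, MATRIX_LOCATIONS,
                      Species, SpeciesRegistry, comp)


@dataclass(frozen=True)
class AblationFlags:
    """Switches for the matrix-ligand-receptor perturbation cases.

    no_mlr_cell
        forbid ternary complexes of matrix, ligand and EC surface receptor.
    no_mlr_sr1
        forbid ternary complexes of matrix, ligand and sR1 (either bond
        order), including ligand capture by matrix-immobilized sR1.
    allow_plgf2_nrp1_coupled
        let PlGF2 bind pre-formed NRP1-VEGFR1 / NRP1-sR1 (off by default;
        experimentally unproven), reusing its VEGFR1 kinetics.
    disable_all_binding
        diagnostic switch: no binding reactions at all (monomers only).
    """
    no_mlr_cell: bool = False
    no_mlr_sr1: bool = False
    allow_plgf2_nrp1_coupled: bool = False
    disable_all_binding: bool = False


BASELINE = AblationFlags()
NO_MLR = AblationFlags(no_mlr_cell=True, no_mlr_sr1=True)
SR1_ONLY = AblationFlags(no_mlr_cell=True)
CELL_ONLY = AblationFlags(no_mlr_sr1=True)


@dataclass(frozen=True)
class SymReaction:
    """A reaction instance on symbolic species (pre-registry)."""
    label: str
    isoform: str | None
    a: Species
    b: Species
    product: Species
    context: str
    entry: KineticEntry = field(compare=False)


@dataclass(frozen=True)
class Reaction:
    """Compiled reversible reaction over registry indices."""
    a: int
    b: int
    product: int
    khat: float  # mol^-1 s^-1 (amount space), forward
    koff: float  # s^-1
    label: str
    isoform: str | None
    compartment: str
    location: str
    context: str


def ebm_accessible_fraction(reach_nm: float, ebm_thickness_nm: float) -> float:
    """Fraction of EBM-bound ligand within reach of cell-surface receptors."""
    if ebm_thickness_nm <= 0:
        raise ValueError("EBM thickness must be > 0")
    if reach_nm < 0:
        raise ValueError("reach must be >= 0")
    return min(reach_nm / ebm_thickness_nm, 1.0)


def convert_kd_volume_to_surface(kd_molar: float, esav: float) -> float:
    """KD in mol/cm^2 from KD in M: kd * (1 L / 1000 cm^3) / ESAV."""
    if esav <= 0:
        raise ValueError("ESAV must be > 0")
    return kd_molar * 1e-3 / esav


def _tissue_candidates(params: ParameterSet, tissue: str,
                       options: AblationFlags) -> list[SymReaction]:
    T = params.kinetics
    out: list[SymReaction] = []
    if options.disable_all_binding:
        return out

    def S(loc, *mono):
        return Species(tissue, loc, comp(*mono))

    def add(label, iso, a, b, p, ctx, entry=None):
        e = entry if entry is not None else T.get(label, iso)
        if e is None:
            return
        out.append(SymReaction(label=label, isoform=iso, a=a, b=b, product=p,
                               context=ctx, entry=e))

    for name in params.ligands:
        L = LIGAND_SYMBOL[name]
        add("L-R1", name, S("fluid", L), S("surface", "R1"),
            S("surface", L, "R1"), "fluid")
        add("L-R2", name, S("fluid", L), S("surface", "R2"),
            S("surface", L, "R2"), "fluid")
        add("L-N1", name, S("fluid", L), S("surface", "N1"),
            S("surface", L, "N1"), "fluid")
        add("L-sR1", name, S("fluid", L), S("fluid", "sR1"),
            S("fluid", L, "sR1"), "fluid")
        for loc in MATRIX_LOCATIONS:
            add("L-M", name, S("fluid", L), S(loc, "M"), S(loc, L, "M"), "fluid")
        if not options.no_mlr_cell:
            # immobilized ligand <-> surface receptors: EBM only, reach-limited
            add("(M-L)-R1", name, S("ebm", L, "M"), S("surface", "R1"),
                S("ebm_surface", L, "M", "R1"), "ebm_access")
            add("(M-L)-R2", name, S("ebm", L, "M"), S("surface", "R2"),
                S("ebm_surface", L, "M", "R2"), "ebm_access")
            add("M-(L-R1)", name, S("ebm", "M"), S("surface", L, "R1"),
                S("ebm_surface", L, "M", "R1"), "ebm_access")
            add("M-(L-R2)", name, S("ebm", "M"), S("surface", L, "R2"),
                S("ebm_surface", L, "M", "R2"), "ebm_access")
        if not options.no_mlr_sr1:
            for loc in MATRIX_LOCATIONS:
                add("(M-L)-sR1", name, S(loc, L, "M"), S("fluid", "sR1"),
                    S(loc, L, "M", "sR1"), "fluid")
                add("M-(L-sR1)", name, S(loc, "M"), S("fluid", L, "sR1"),
                    S(loc, L, "M", "sR1"), "fluid")
                add("(L-sR1)-M", name, S("fluid", L, "sR1"), S(loc, "M"),
                    S(loc, L, "M", "sR1"), "fluid")
                add("(M-sR1)-L", name, S(loc, "M", "sR1"), S("fluid", L),
                    S(loc, L, "M", "sR1"), "fluid")
        add("(N1-L)-R2", name, S("surface", L, "N1"), S("surface", "R2"),
            S("surface", L, "N1", "R2"), "surface")
        add("N1-(L-R2)", name, S("surface", "N1"), S("surface", L, "R2"),
            S("surface", L, "N1", "R2"), "surface")
        add("(L-R1)-N1", name, S("surface", L, "R1"), S("surface", "N1"),
            S("surface", L, "N1", "R1"), "surface")
        add("(L-sR1)-N1", name, S("fluid", L, "sR1"), S("surface", "N1"),
            S("surface", L, "N1", "sR1"), "fluid")
        add("(N1-R1)-L", name, S("fluid", L), S("surface", "N1", "R1"),
            S("surface", L, "N1", "R1"), "fluid")
        add("(N1-sR1)-L", name, S("fluid", L), S("surface", "N1", "sR1"),
            S("surface", L, "N1", "sR1"), "fluid")
        if options.allow_plgf2_nrp1_coupled and name == "PlGF2":
            e = T.get("L-R1", "PlGF2")
            add("(N1-R1)-L", name, S("fluid", L), S("surface", "N1", "R1"),
                S("surface", L, "N1", "R1"), "fluid", entry=e)
            add("(N1-sR1)-L", name, S("fluid", L), S("surface", "N1", "sR1"),
                S("surface", L, "N1", "sR1"), "fluid", entry=e)

    add("N1-R1", None, S("surface", "R1"), S("surface", "N1"),
        S("surface", "N1", "R1"), "surface")
    add("sR1-N1", None, S("fluid", "sR1"), S("surface", "N1"),
        S("surface", "N1", "sR1"), "fluid")
    for loc in MATRIX_LOCATIONS:
        add("sR1-M", None, S("fluid", "sR1"), S(loc, "M"),
            S(loc, "M", "sR1"), "fluid")

    # endosomal replicas: same rates as on the surface, no matrix species
    endo: list[SymReaction] = []
    for r in out:
        if any("M" in s.composition for s in (r.a, r.b, r.product)):
            continue
        for eloc in ENDOSOME_LOCATIONS:
            endo.append(SymReaction(
                label=r.label, isoform=r.isoform,
                a=Species(tissue, eloc, r.a.composition),
                b=Species(tissue, eloc, r.b.composition),
                product=Species(tissue, eloc, r.product.composition),
                context="endosome", entry=r.entry))
    return out + endo


def _blood_candidates(params: ParameterSet,
                      options: AblationFlags) -> list[SymReaction]:
    out = []
    if options.disable_all_binding:
        return out
    for name in params.ligands:
        e = params.kinetics.get("L-sR1", name)
        if e is None:
            continue
        L = LIGAND_SYMBOL[name]
        out.append(SymReaction(
            label="L-sR1", isoform=name,
            a=Species("blood", "plasma", comp(L)),
            b=Species("blood", "plasma", comp("sR1")),
            product=Species("blood", "plasma", comp(L, "sR1")),
            context="plasma", entry=e))
    return out


def _seeds(params: ParameterSet, tissue: str) -> set[Species]:
    seeds = set()
    for name in params.ligands:
        seeds.add(Species(tissue, "fluid", comp(LIGAND_SYMBOL[name])))
    seeds.add(Species(tissue, "fluid", comp("sR1")))
    for loc in MATRIX_LOCATIONS:
        seeds.add(Species(tissue, loc, comp("M")))
    for rc in ("R1", "R2", "N1"):
        seeds.add(Species(tissue, "surface", comp(rc)))
    return seeds


def _closure(seeds: set[Species],
             candidates: list[SymReaction]) -> tuple[set[Species], list[SymReaction]]:
    """Fixpoint: activate reactions whose reactants exist; surface species
    spawn endosomal counterparts (trafficking moves)."""
    present = set(seeds)
    active: list[SymReaction] = []
    pending = list(candidates)
    changed = True
    while changed:
        changed = False
        for sp in list(present):
            if sp.location == "surface" and "M" not in sp.composition:
                for eloc in ENDOSOME_LOCATIONS:
                    e = Species(sp.compartment, eloc, sp.composition)
                    if e not in present:
                        present.add(e)
                        changed = True
        still = []
        for r in pending:
            # reversible: reachable from either side (complexes internalized
            # into endosomes must be able to dissociate there)
            if (r.a in present and r.b in present) or r.product in present:
                active.append(r)
                for s in (r.a, r.b, r.product):
                    if s not in present:
                        present.add(s)
                        changed = True
            else:
                still.append(r)
        pending = still
    return present, active


def _sym_model(params: ParameterSet, options: AblationFlags | None):
    options = options or BASELINE
    all_species: set[Species] = set()
    all_reactions: list[SymReaction] = []
    for tissue in TISSUES:
        sp, rx = _closure(_seeds(params, tissue),
                          _tissue_candidates(params, tissue, options))
        all_species |= sp
        all_reactions.extend(rx)
    blood_seeds = {Species("blood", "plasma", comp(LIGAND_SYMBOL[n]))
                   for n in params.ligands}
    blood_seeds.add(Species("blood", "plasma", comp("sR1")))
    sp, rx = _closure(blood_seeds, _blood_candidates(params, options))
    all_species |= sp
    all_reactions.extend(rx)
    return all_species, all_reactions


def enumerate_model_species(params: ParameterSet,
                            options: AblationFlags | None = None) -> SpeciesRegistry:
    sp, _ = _sym_model(params, options)
    return SpeciesRegistry(sp)


def _khat(entry: KineticEntry, context: str, params: ParameterSet,
          compartment: str) -> float:
    kon = entry.kon
    if context == "plasma":
        if entry.units != "volumetric":
            raise ValueError("plasma reactions must be volumetric")
        return kon / params.blood.plasma_volume_L
    geom = params.geometry[compartment]
    if entry.units == "surface":
        kon = kon / (1000.0 * geom.esav_cm2_per_cm3)
    if context == "fluid":
        return kon / geom.available_fluid_volume_L
    if context in ("surface", "endosome"):
        return kon / geom.total_volume_L
    if context == "ebm_access":
        # both partners immobilized at the membrane: surface (ESAV)
        # convention, on-rate scaled by the EBM accessible fraction
        return kon * geom.ebm_accessible_fraction / geom.total_volume_L
    raise ValueError(f"unknown reaction context {context!r}")


@dataclass
class ReactionNetwork:
    registry: SpeciesRegistry
    reactions: list[Reaction]
    params: ParameterSet = field(repr=False, default=None)
    options: AblationFlags = BASELINE

    def stoichiometry(self) -> dict[int, list[tuple[int, int]]]:
        """Species index -> [(reaction index, coefficient)]; -1 per reactant,
        +1 for the product of each reversible reaction's forward direction."""
        sto: dict[int, list[tuple[int, int]]] = {}
        for ri, r in enumerate(self.reactions):
            sto.setdefault(r.a, []).append((ri, -1))
            sto.setdefault(r.b, []).append((ri, -1))
            sto.setdefault(r.product, []).append((ri, +1))
        return sto

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        sp = self.registry.species
        for r in self.reactions:
            rows.append({
                "reactant_a": sp[r.a].label(), "reactant_b": sp[r.b].label(),
                "product": sp[r.product].label(), "khat_per_mol_s": r.khat,
                "koff_per_s": r.koff, "label": r.label, "isoform": r.isoform,
                "compartment": r.compartment, "location": r.location,
                "context": r.context})
        return pd.DataFrame(rows)


def build_network(params: ParameterSet,
                  compartment: str | None = None,
                  options: AblationFlags | None = None,
                  registry: SpeciesRegistry | None = None) -> ReactionNetwork:
    """Generate the mass-action network (all compartments, or one)."""
    options = options or BASELINE
    sp, sym = _sym_model(params, options)
    if registry is None:
        registry = SpeciesRegistry(sp)
    reactions = []
    for r in sym:
        if compartment is not None and r.product.compartment != compartment:
            continue
        for s in (r.a, r.b, r.product):
            if s not in registry:
                raise KeyError(f"reaction references species not in registry: "
                               f"{s.label()}")
        reactions.append(Reaction(
            a=registry.idx(r.a), b=registry.idx(r.b),
            product=registry.idx(r.product),
            khat=_khat(r.entry, r.context, params, r.product.compartment),
            koff=r.entry.koff, label=r.label, isoform=r.isoform,
            compartment=r.product.compartment, location=r.product.location,
            context=r.context))
    reactions.sort(key=lambda r: (r.compartment, r.location, r.label,
                                  r.isoform or "", r.a, r.b))
    return ReactionNetwork(registry=registry, reactions=reactions,
                           params=params, options=options)


# --- thermodynamic cycle audit -------------------------------------------

#: 3-species cycles: path A = (step1, step2), path B = (step3, step4);
#: detailed balance requires KD1*KD2 == KD3*KD4.
_CYCLES = (
    ("M,L,R1", ("L-M", "(M-L)-R1"), ("L-R1", "M-(L-R1)")),
    ("M,L,R2", ("L-M", "(M-L)-R2"), ("L-R2", "M-(L-R2)")),
    ("M,L,sR1", ("L-M", "(M-L)-sR1"), ("L-sR1", "M-(L-sR1)")),
    ("M,sR1,L", ("sR1-M", "(M-sR1)-L"), ("L-sR1", "(L-sR1)-M")),
    ("N1,L,R2", ("L-N1", "(N1-L)-R2"), ("L-R2", "N1-(L-R2)")),
    ("N1,R1,L", ("N1-R1", "(N1-R1)-L"), ("L-R1", "(L-R1)-N1")),
    ("N1,sR1,L", ("sR1-N1", "(N1-sR1)-L"), ("L-sR1", "(L-sR1)-N1")),
)


@dataclass(frozen=True)
class CycleReport:
    cycle: str
    isoform: str
    path_a: tuple[str, str]
    path_b: tuple[str, str]
    ratio_from_rates: float
    ratio_from_printed_kd: float

    @property
    def balanced(self) -> bool:
        return abs(self.ratio_from_rates - 1.0) <= 0.10


def check_thermodynamic_cycles(network: "ReactionNetwork | BindingParameterTable",
                               esav: float | None = None) -> list[CycleReport]:
    """Audit detailed balance over every 3-species binding cycle.

    Ratios are computed from kon/koff-derived KDs (and, for reference, from
    the printed KD columns), with surface-unit entries converted to
    volumetric via the ESAV rule so both paths are commensurate. A ratio of
    1 means the two binding orders are thermodynamically equivalent;
    deviations mark either table typos or deliberate affinity enhancement
    (the NRP1-coupling cycles).
    """
    if isinstance(network, ReactionNetwork):
        table = network.params.kinetics
        if esav is None:
            esav = next(iter(network.params.geometry.values())).esav_cm2_per_cm3
    else:
        table = network
    if esav is None:
        esav = 1.0

    def kd_vol(entry: KineticEntry, printed: bool) -> float:
        kd = entry.kd if printed else entry.kd_from_rates
        if entry.units == "surface":
            kd = kd * 1000.0 * esav
        return kd

    def lookup(label, iso):
        e = table.get(label, iso)
        if e is None:
            e = table.get(label, None)  # coupling rows have no isoform
        return e

    reports = []
    isoforms = sorted({iso for (_, iso) in table.entries if iso})
    for name, path_a, path_b in _CYCLES:
        for iso in isoforms:
            es = [lookup(lbl, iso) for lbl in path_a + path_b]
            if any(e is None for e in es):
                continue
            num = kd_vol(es[0], False) * kd_vol(es[1], False)
            den = kd_vol(es[2], False) * kd_vol(es[3], False)
            num_p = kd_vol(es[0], True) * kd_vol(es[1], True)
            den_p = kd_vol(es[2], True) * kd_vol(es[3], True)
            reports.append(CycleReport(
                cycle=name, isoform=iso, path_a=path_a, path_b=path_b,
                ratio_from_rates=num / den,
                ratio_from_printed_kd=num_p / den_p))
    return reports
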