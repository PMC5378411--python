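"""Endothelial receptor trafficking and VEGFR2 site-specific phosphorylation.

Receptors are produced at the cell surface, internalized into early
(Rab4/5) endosomes, recycled directly or via Rab11 recycling endosomes, and
degraded from either endosomal pool. Rates depend on the receptor class the
complex carries, its ligation status, and (for VEGFR2) whether NRP1 is part
of the complex — NRP1-containing VEGFR2 complexes route preferentially
through the Rab11 pathway. Matrix-tethered complexes (M·L·R) do not
internalize; free ligand or sR1 released inside endosomes is degraded with
the endosome contents.

Phosphorylation of VEGFR2 (sites Y951/Y1175/Y1214) is first order and
site-independent: zero for unoccupied receptor, fast (1 s^-1) for ligated
receptor; dephosphorylation rates vary by site and subcellular location.
Phospho amounts are companion states that travel with their carrier
species proportionally through every flux.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (N_AVOGADRO, ParameterSet, TISSUES, TraffickingRates)
from .species import SpeciesRegistry

TRAFFIC_KINDS = ("production", "internalization", "rab45_to_surface",
                 "rab45_to_rab11", "rab11_to_surface", "degradation",
                 "cargo_degradation")


@dataclass(frozen=True)
class LinearProcess:
    """First-order process: d(dst)/dt += rate * y[src]; d(src)/dt -= same.

    dst None means pure loss (degradation, clearance).
    """
    kind: str
    src: int
    dst: int | None
    rate: float
    compartment: str = ""


@dataclass(frozen=True)
class ConstProcess:
    """Zeroth-order input: d(dst)/dt += rate (mol/s)."""
    kind: str  # 'secretion' | 'production'
    dst: int
    rate: float
    family: str = ""  # ligand family / receptor class
    compartment: str = ""


def receptor_production_for_target(rates: TraffickingRates,
                                   target_surface_per_cell: float) -> float:
    """Closed-form production rate (molecules/cell/s) that yields the target
    surface density at the no-ligand steady state of the three-pool
    (surface, Rab4/5, Rab11) trafficking system."""
    d4 = rates.rab45_to_surface + rates.rab45_to_rab11 + rates.degradation_rab45
    d11 = rates.rab11_to_surface + rates.degradation_rab11
    e4_per_s = rates.internalization / d4 if d4 > 0 else 0.0
    e11_per_s = rates.rab45_to_rab11 * e4_per_s / d11 if d11 > 0 else 0.0
    net_loss = (rates.internalization
                - rates.rab45_to_surface * e4_per_s
                - rates.rab11_to_surface * e11_per_s)
    return target_surface_per_cell * net_loss


def no_ligand_surface_level(production_per_cell: float,
                            rates: TraffickingRates) -> float:
    """Inverse of :func:`receptor_production_for_target`."""
    unit = receptor_production_for_target(rates, 1.0)
    return production_per_cell / unit


def no_ligand_pool_distribution(rates: TraffickingRates) -> tuple[float, float]:
    """(Rab4/5, Rab11) amounts per unit surface amount at no-ligand SS."""
    d4 = rates.rab45_to_surface + rates.rab45_to_rab11 + rates.degradation_rab45
    d11 = rates.rab11_to_surface + rates.degradation_rab11
    e4 = rates.internalization / d4 if d4 > 0 else 0.0
    e11 = rates.rab45_to_rab11 * e4 / d11 if d11 > 0 else 0.0
    return e4, e11


def _species_rates(params: ParameterSet, sp) -> TraffickingRates | None:
    rc = sp.receptor_class
    if rc is None:
        return None
    ligated = sp.ligand is not None
    nrp1 = "N1" in sp.composition and rc == "R2"
    return params.trafficking.rates_for(rc, ligated, nrp1)


def build_trafficking_processes(
        params: ParameterSet,
        registry: SpeciesRegistry) -> tuple[list[LinearProcess], list[ConstProcess]]:
    """All trafficking moves plus receptor production for the full registry."""
    from .species import Species, comp  # local to avoid cycle at import time

    linear: list[LinearProcess] = []
    const: list[ConstProcess] = []
    cargo_k = params.trafficking.endosomal_cargo_degradation

    for i, sp in enumerate(registry):
        if sp.compartment == "blood" or "M" in sp.composition:
            continue  # plasma species and matrix-tethered complexes do not traffic
        rates = _species_rates(params, sp)
        tissue = sp.compartment
        if sp.location == "surface" and rates is not None:
            dst = registry.idx(Species(tissue, "rab45", sp.composition))
            linear.append(LinearProcess("internalization", i, dst,
                                        rates.internalization, tissue))
        elif sp.location == "rab45":
            if rates is not None:
                surf = registry.idx(Species(tissue, "surface", sp.composition))
                r11 = registry.idx(Species(tissue, "rab11", sp.composition))
                linear.append(LinearProcess("rab45_to_surface", i, surf,
                                            rates.rab45_to_surface, tissue))
                linear.append(LinearProcess("rab45_to_rab11", i, r11,
                                            rates.rab45_to_rab11, tissue))
                linear.append(LinearProcess("degradation", i, None,
                                            rates.degradation_rab45, tissue))
            else:  # released ligand / sR1 / L·sR1 cargo
                linear.append(LinearProcess("cargo_degradation", i, None,
                                            cargo_k, tissue))
        elif sp.location == "rab11":
            if rates is not None:
                surf = registry.idx(Species(tissue, "surface", sp.composition))
                linear.append(LinearProcess("rab11_to_surface", i, surf,
                                            rates.rab11_to_surface, tissue))
                linear.append(LinearProcess("degradation", i, None,
                                            rates.degradation_rab11, tissue))
            else:
                linear.append(LinearProcess("cargo_degradation", i, None,
                                            cargo_k, tissue))

    # receptor production at the surface: baseline closed-form rate hitting
    # the target at the no-ligand SS, scaled by the calibrated multiplier
    for tissue in TISSUES:
        geom = params.geometry[tissue]
        for rc in ("R1", "R2", "N1"):
            free_rates = params.trafficking.rates_for(rc, False, False)
            target = params.targets.surface_target(rc, tissue)
            p0 = receptor_production_for_target(free_rates, target)
            mult = params.secretion.receptor_production_multiplier[rc][tissue]
            dst = registry.idx(Species(tissue, "surface", comp(rc)))
            const.append(ConstProcess(
                "production", dst,
                p0 * mult * geom.ec_count / N_AVOGADRO, rc, tissue))
    return linear, const


def build_secretion_processes(params: ParameterSet,
                              registry: SpeciesRegistry) -> list[ConstProcess]:
    """Ligand secretion by parenchymal cells and sR1 secretion by ECs, into
    the tissue interstitial fluid (same per-cell rates in both tissues)."""
    from .species import LIGAND_SYMBOL, Species, comp

    const = []
    for tissue in TISSUES:
        geom = params.geometry[tissue]
        for name, lig in params.ligands.items():
            q = (params.secretion.q_vegf if lig.family == "VEGF"
                 else params.secretion.q_plgf)
            rate = q * lig.production_fraction * geom.myonuclear_domain_count \
                / N_AVOGADRO
            dst = registry.idx(Species(tissue, "fluid", comp(LIGAND_SYMBOL[name])))
            const.append(ConstProcess("secretion", dst, rate, lig.family, tissue))
        dst = registry.idx(Species(tissue, "fluid", comp("sR1")))
        const.append(ConstProcess(
            "secretion", dst,
            params.secretion.q_sr1 * geom.ec_count / N_AVOGADRO, "sR1", tissue))
    return const


def trafficking_fluxes(y: np.ndarray, model) -> np.ndarray:
    """Trafficking + production contribution to dy/dt (carrier block)."""
    dy = np.zeros_like(y)
    for p in model.linear_processes:
        if p.kind not in TRAFFIC_KINDS:
            continue
        f = p.rate * y[p.src]
        dy[p.src] -= f
        if p.dst is not None:
            dy[p.dst] += f
    for c in model.const_processes:
        if c.kind == "production":
            dy[c.dst] += c.rate
    return dy


def vegfr1_trafficking_fluxes(y: np.ndarray, model) -> np.ndarray:
    """Trafficking contribution restricted to VEGFR1-carrying species.

    VEGFR1 trafficking shares the structural form of VEGFR2 trafficking
    (with R1-specific rates) and is simulated in full, but reporting
    operations expose only cell-surface VEGFR1.
    """
    dy = np.zeros_like(y)
    reg = model.registry.species
    for p in model.linear_processes:
        if p.kind not in TRAFFIC_KINDS or "R1" not in reg[p.src].composition:
            continue
        f = p.rate * y[p.src]
        dy[p.src] -= f
        if p.dst is not None:
            dy[p.dst] += f
    for c in model.const_processes:
        if c.kind == "production" and c.family == "R1":
            dy[c.dst] += c.rate
    return dy


# --- phosphorylation ------------------------------------------------------

_LOC_MAP = {"surface": "surface", "ebm_surface": "surface",
            "rab45": "rab45", "rab11": "rab11"}


class PhosphoSystem:
    """Per-site linear system for phospho amounts on R2 carriers.

    Given carrier amounts y, the phospho state p (one value per carrier per
    tyrosine) obeys dp/dt = A(y) p + b(y): phosphorylation of ligated
    carriers, site/location-specific dephosphorylation, and proportional
    co-transport of phospho with every carrier flux.
    """

    def __init__(self, model):
        self.model = model
        self.carriers = model.registry.r2_carriers()
        self.pos = {ci: k for k, ci in enumerate(self.carriers)}
        reg = model.registry.species
        self.locations = [_LOC_MAP[reg[i].location] for i in self.carriers]
        self.ligated = np.array([reg[i].ligand is not None
                                 for i in self.carriers])

    def assemble(self, y: np.ndarray, site: str):
        ph = self.model.params.phosphorylation
        n = len(self.carriers)
        A = np.zeros((n, n))
        b = np.zeros(n)
        kdp = ph.k_dephos[site]
        for k, ci in enumerate(self.carriers):
            A[k, k] -= kdp[self.locations[k]]
            if self.ligated[k]:
                A[k, k] -= ph.k_phos_ligated
                b[k] += ph.k_phos_ligated * y[ci]
            else:
                A[k, k] -= ph.k_phos_free
                b[k] += ph.k_phos_free * y[ci]
        for p in self.model.linear_processes:
            ks = self.pos.get(p.src)
            if ks is None:
                continue
            A[ks, ks] -= p.rate
            kd = self.pos.get(p.dst) if p.dst is not None else None
            if kd is not None:
                A[kd, ks] += p.rate
        for r in self.model.reactions:
            ka, kb = self.pos.get(r.a), self.pos.get(r.b)
            kp = self.pos.get(r.product)
            # forward: carrier reactant -> product, per-carrier rate khat*y[other]
            if ka is not None and kp is not None:
                rate = r.khat * y[r.b]
                A[ka, ka] -= rate
                A[kp, ka] += rate
            if kb is not None and kp is not None:
                rate = r.khat * y[r.a]
                A[kb, kb] -= rate
                A[kp, kb] += rate
            # reverse: product -> the R2-carrying reactant
            if kp is not None:
                A[kp, kp] -= r.koff
                kc = ka if ka is not None else kb
                if kc is not None:
                    A[kc, kp] += r.koff
        return A, b

    def steady_state(self, y: np.ndarray) -> dict[str, np.ndarray]:
        """Solve A p = -b per site at the carrier steady state y."""
        out = {}
        for site in self.model.params.phosphorylation.k_dephos:
            A, b = self.assemble(y, site)
            if len(b) == 0:
                out[site] = b
                continue
            out[site] = np.linalg.solve(A, -b)
        return out

    def rhs(self, y: np.ndarray, p_by_site: dict[str, np.ndarray]):
        out = {}
        for site, p in p_by_site.items():
            A, b = self.assemble(y, site)
            out[site] = A @ p + b
        return out


def phosphorylation_fluxes(y: np.ndarray, p_by_site: dict[str, np.ndarray],
                           model) -> dict[str, np.ndarray]:
    """dp/dt per site for the companion phospho states (transient form)."""
    return PhosphoSystem(model).rhs(y, p_by_site)
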