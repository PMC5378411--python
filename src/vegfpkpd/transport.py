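"""Intercompartmental transport, plasma clearance, and flux auditing.

Soluble species (free ligands, free sR1, ligand·sR1 complexes) move between
each tissue's interstitial fluid and plasma by bidirectional vascular
permeability (flux proportional to the concentration difference) and by
lymphatic drainage (tissue -> blood only, proportional to the interstitial
fluid concentration, protein-size-independent). Clearance removes soluble
species from plasma first order. Matrix- and cell-bound species are
immobile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterSet, TISSUES
from .species import Species, SpeciesRegistry
from .trafficking import LinearProcess

TRANSPORT_KINDS = ("permeability", "lymph", "clearance")

#: monomer -> family used for transport parameters and audit grouping
_FAMILY_OF = {"V121": "VEGF", "V165": "VEGF", "V189": "VEGF",
              "P1": "PlGF", "P2": "PlGF", "sR1": "sR1"}


def transport_family(sp: Species) -> str | None:
    """Transport parameter family of a soluble species (None if immobile)."""
    if not sp.is_soluble:
        return None
    has_sr1 = "sR1" in sp.composition
    lig = sp.ligand
    if lig is not None and has_sr1:
        return "L_sR1"
    if lig is not None:
        return _FAMILY_OF[lig]
    if has_sr1:
        return "sR1"
    return None


def build_transport_processes(params: ParameterSet,
                              registry: SpeciesRegistry) -> list[LinearProcess]:
    out: list[LinearProcess] = []
    tp = params.transport
    vp_cm3 = params.blood.plasma_volume_L * 1000.0
    for tissue in TISSUES:
        geom = params.geometry[tissue]
        vt_cm3 = geom.available_fluid_volume_L * 1000.0
        s_cm2 = geom.ec_surface_area_cm2
        lymph = tp.lymph_flow_L_per_s[tissue] / geom.available_fluid_volume_L
        for i in registry.select(compartment=tissue, location="fluid"):
            sp = registry.species[i]
            fam = transport_family(sp)
            if fam is None:
                continue
            j = registry.idx(Species("blood", "plasma", sp.composition))
            kp = tp.permeability_cm_per_s[fam]
            out.append(LinearProcess("permeability", i, j,
                                     kp * s_cm2 / vt_cm3, tissue))
            out.append(LinearProcess("permeability", j, i,
                                     kp * s_cm2 / vp_cm3, tissue))
            out.append(LinearProcess("lymph", i, j, lymph, tissue))
    for j in registry.select(compartment="blood"):
        fam = transport_family(registry.species[j])
        if fam is None:
            continue
        out.append(LinearProcess("clearance", j, None,
                                 tp.clearance_per_s[fam], "blood"))
    return out


def transport_fluxes(y: np.ndarray, model) -> np.ndarray:
    """Transport + clearance contribution to dy/dt."""
    dy = np.zeros_like(y)
    for p in model.linear_processes:
        if p.kind not in TRANSPORT_KINDS:
            continue
        f = p.rate * y[p.src]
        dy[p.src] -= f
        if p.dst is not None:
            dy[p.dst] += f
    return dy


# --- flux audit -----------------------------------------------------------

_PMOL_PER_DAY = 1e12 * 86400.0  # mol/s -> pmol/day


@dataclass
class FluxAudit:
    """Per-compartment, per-family steady-state process totals (pmol/day).

    Families count monomer content: a VEGF·sR1 complex contributes to both
    the VEGF and sR1 families. `net_complex_association` is the net rate of
    ligand·sR1 complex formation in the compartment (reported for reference;
    it cancels inside each family's conservation sum).
    """
    table: pd.DataFrame
    residuals: pd.DataFrame = field(default=None)

    def ec_consumed_fraction(self, compartment: str, family: str) -> float:
        row = self.table.loc[(compartment, family)]
        prod = row["production"]
        return row["ec_consumption"] / prod if prod > 0 else np.nan

    def net_permeability(self, compartment: str, family: str) -> float:
        return self.table.loc[(compartment, family), "net_permeability_in"]


def _family_content(sp: Species) -> dict[str, int]:
    out: dict[str, int] = {}
    for m in sp.composition:
        fam = _FAMILY_OF.get(m)
        if fam is not None:
            out[fam] = out.get(fam, 0) + 1
    return out


def audit_fluxes(model, y: np.ndarray, check_converged: bool = True) -> FluxAudit:
    """Integrate each process's instantaneous rate at steady state into a
    per-compartment, per-family flow table (pmol/day)."""
    if check_converged and not model.is_steady(y):
        raise ValueError("flux audit requires a converged steady state")
    reg = model.registry
    compartments = list(model.params.geometry) + ["blood"]
    families = ("VEGF", "PlGF", "sR1")
    cols = ("production", "ec_consumption", "net_permeability_in",
            "lymph_out", "lymph_in", "clearance", "net_complex_association")
    acc = {(c, f): dict.fromkeys(cols, 0.0)
           for c in compartments for f in families}

    def bump(comp, fam_content, col, mol_s):
        for fam, n in fam_content.items():
            acc[(comp, fam)][col] += n * mol_s * _PMOL_PER_DAY

    for c in model.const_processes:
        if c.kind == "secretion":
            sp = reg.species[c.dst]
            bump(sp.compartment, _family_content(sp), "production", c.rate)
    for p in model.linear_processes:
        f = p.rate * y[p.src]
        sp = reg.species[p.src]
        fams = _family_content(sp)
        if p.kind in ("degradation", "cargo_degradation"):
            bump(sp.compartment, fams, "ec_consumption", f)
        elif p.kind == "clearance":
            bump("blood", fams, "clearance", f)
        elif p.kind == "lymph":
            bump(sp.compartment, fams, "lymph_out", f)
            bump("blood", fams, "lymph_in", f)
        elif p.kind == "permeability":
            if sp.compartment == "blood":  # extravasation: into the tissue
                tissue = reg.species[p.dst].compartment
                bump(tissue, fams, "net_permeability_in", f)
                bump("blood", fams, "net_permeability_in", -f)
            else:
                bump(sp.compartment, fams, "net_permeability_in", -f)
                bump("blood", fams, "net_permeability_in", f)
    for r in model.reactions:
        prod_sp = reg.species[r.product]
        if r.label == "L-sR1":
            net = r.khat * y[r.a] * y[r.b] - r.koff * y[r.product]
            for fam in _family_content(prod_sp):
                acc[(prod_sp.compartment, fam)]["net_complex_association"] += \
                    net * _PMOL_PER_DAY

    rows = []
    for (c, f), d in acc.items():
        rows.append({"compartment": c, "family": f, **d})
    table = pd.DataFrame(rows).set_index(["compartment", "family"])

    res_rows = []
    for (c, f), row in table.iterrows():
        inflow = row["production"] + row["net_permeability_in"] + row["lymph_in"]
        outflow = row["ec_consumption"] + row["lymph_out"] + row["clearance"]
        scale = max(abs(inflow), abs(outflow), 1e-30)
        res_rows.append({"compartment": c, "family": f,
                         "net": inflow - outflow,
                         "relative": (inflow - outflow) / scale})
    residuals = pd.DataFrame(res_rows).set_index(["compartment", "family"])
    return FluxAudit(table=table, residuals=residuals)


def render_flow_profile(audit: FluxAudit) -> str:
    """Text rendering of the steady-state net flow profile (pmol/day)."""
    lines = ["Steady-state net flows (pmol/day)"]
    for (c, f), row in audit.table.iterrows():
        lines.append(
            f"  {c:>10s} {f:>5s}: production {row['production']:9.3f}  "
            f"EC consumption {row['ec_consumption']:9.3f}  "
            f"net permeability in {row['net_permeability_in']:9.3f}  "
            f"lymph out {row['lymph_out']:9.3f}  "
            f"clearance {row['clearance']:9.3f}")
    return "\n".join(lines)


def global_mass_balance(model, y: np.ndarray) -> pd.DataFrame:
    """Whole-body conservation per family: production vs degradation+clearance."""
    reg = model.registry
    prod = {}
    loss = {}
    for c in model.const_processes:
        sp = reg.species[c.dst]
        for fam, n in _family_content(sp).items():
            prod[fam] = prod.get(fam, 0.0) + n * c.rate
        if c.kind == "production":
            prod[c.family] = prod.get(c.family, 0.0) + c.rate
    for p in model.linear_processes:
        if p.dst is not None:
            continue
        f = p.rate * y[p.src]
        sp = reg.species[p.src]
        for fam, n in _family_content(sp).items():
            loss[fam] = loss.get(fam, 0.0) + n * f
        for rc in ("R1", "R2", "N1"):
            if rc in sp.composition:
                loss[rc] = loss.get(rc, 0.0) + f
    rows = []
    for fam in sorted(set(prod) | set(loss)):
        pr, lo = prod.get(fam, 0.0), loss.get(fam, 0.0)
        rows.append({"family": fam, "production": pr, "loss": lo,
                     "relative_residual": (pr - lo) / max(pr, 1e-300)})
    return pd.DataFrame(rows).set_index("family")
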