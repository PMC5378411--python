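"""Toy model fixtures with closed-form steady states.

Each fixture is a genuine :class:`~vegfpkpd.engine.Model` instance — built
from hand-specified species, reactions and affine processes — solved by the
same Newton/LSODA engine as the full model, and paired with an independent
closed-form expectation for its steady state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import Model
from .network import BASELINE, Reaction
from .parameters import load_parameter_set
from .species import Species, SpeciesRegistry, comp
from .trafficking import ConstProcess, LinearProcess


@dataclass
class ToyModelSpec:
    name: str
    model: Model
    y0: np.ndarray
    expected: dict[str, float] = field(default_factory=dict)
    state_names: tuple[str, ...] = ()


def _minimal_params():
    # a full ParameterSet is only needed for volumes/phospho defaults the
    # toy engines consult; the packaged default serves
    return load_parameter_set()


def binding_equilibrium_quadratic(total_l: float, total_r: float,
                                  kd: float) -> float:
    """Closed-form bound complex at equilibrium of L + R <-> LR.

    Solves c^2 - (L_T + R_T + KD) c + L_T R_T = 0 for the physical root.
    """
    b = total_l + total_r + kd
    disc = b * b - 4.0 * total_l * total_r
    return 0.5 * (b - math.sqrt(disc))


def make_binding_toy(total_l_mol: float = 1.0e-14, total_r_mol: float = 1.0e-15,
                     kd_M: float = 1.0e-10, volume_L: float = 1.0,
                     kon: float = 1.0e7) -> ToyModelSpec:
    """(a) single-compartment L + R <-> LR with conserved totals."""
    params = _minimal_params()
    reg = SpeciesRegistry([
        Species("blood", "plasma", comp("V165")),
        Species("blood", "plasma", comp("sR1")),
        Species("blood", "plasma", comp("V165", "sR1")),
    ])
    il = reg.idx(Species("blood", "plasma", comp("V165")))
    ir = reg.idx(Species("blood", "plasma", comp("sR1")))
    ic = reg.idx(Species("blood", "plasma", comp("V165", "sR1")))
    khat = kon / volume_L
    koff = kon * kd_M
    rx = [Reaction(a=il, b=ir, product=ic, khat=khat, koff=koff,
                   label="L-sR1", isoform="VEGF165", compartment="blood",
                   location="plasma", context="plasma")]
    # closed binding system: both totals conserved -> two constraint rows
    conservation = [(il, [il, ic], total_l_mol), (ir, [ir, ic], total_r_mol)]
    model = Model(params, reg, rx, [], [], conservation, BASELINE)
    y0 = np.zeros(3)
    y0[il], y0[ir] = total_l_mol, total_r_mol
    kd_amount = koff / khat  # mol in this volume
    bound = binding_equilibrium_quadratic(total_l_mol, total_r_mol, kd_amount)
    return ToyModelSpec(
        name="binding_quadratic", model=model, y0=y0,
        expected={"bound_mol": bound, "free_l_mol": total_l_mol - bound,
                  "free_r_mol": total_r_mol - bound},
        state_names=("L", "LR", "R"))  # registry canonical order


def make_clearance_toy(infusion_mol_s: float = 1.0e-15,
                       k_clear: float = 3.0e-4,
                       volume_L: float = 3.0) -> ToyModelSpec:
    """(b) constant infusion Q into plasma with first-order clearance k:
    steady concentration Q/(k V)."""
    params = _minimal_params()
    reg = SpeciesRegistry([Species("blood", "plasma", comp("V121"))])
    i = 0
    linear = [LinearProcess("clearance", i, None, k_clear, "blood")]
    const = [ConstProcess("secretion", i, infusion_mol_s, "VEGF", "blood")]
    model = Model(params, reg, [], linear, const, [], BASELINE)
    return ToyModelSpec(
        name="secretion_clearance", model=model, y0=np.zeros(1),
        expected={"steady_amount_mol": infusion_mol_s / k_clear,
                  "steady_conc_M": infusion_mol_s / (k_clear * volume_L)},
        state_names=("L_plasma",))


def two_pool_phospho_ratio(k_int: float, k_rec: float,
                           kdp_surf: dict[str, float],
                           kdp_endo: dict[str, float],
                           k_phos: float = 1.0) -> float:
    """(c) analytic steady pY1214/pY1175 for a ligated carrier cycling
    between surface and one endosomal pool (no degradation).

    Carrier distribution: S/E = k_rec/k_int. Per-site phospho on each pool
    solves the 2x2 linear transfer system exactly.
    """
    s = k_rec / (k_int + k_rec)
    e = 1.0 - s

    def site(kdp_s, kdp_e):
        # unknowns pS, pE:
        # 0 = kphos(S - pS) - kdp_s pS - kint pS + krec pE
        # 0 = kphos(E - pE) - kdp_e pE - krec pE + kint pS
        a11 = -(k_phos + kdp_s + k_int)
        a12 = k_rec
        a21 = k_int
        a22 = -(k_phos + kdp_e + k_rec)
        b1, b2 = -k_phos * s, -k_phos * e
        det = a11 * a22 - a12 * a21
        p_s = (b1 * a22 - a12 * b2) / det
        p_e = (a11 * b2 - b1 * a21) / det
        return p_s + p_e

    return site(kdp_surf["Y1214"], kdp_endo["Y1214"]) / \
        site(kdp_surf["Y1175"], kdp_endo["Y1175"])


def make_phospho_toy(k_int: float = 1.0e-3, k_rec: float = 1.0e-3,
                     amount: float = 1.0e-15) -> ToyModelSpec:
    """Surface/Rab4-5 two-pool ligated VEGFR2 with site-specific
    dephosphorylation; expected pY1214/pY1175 from the closed form."""
    params = _minimal_params()
    tissue = "main_body"
    reg = SpeciesRegistry([
        Species(tissue, "surface", comp("V165", "R2")),
        Species(tissue, "rab45", comp("V165", "R2")),
    ])
    isurf = reg.idx(Species(tissue, "surface", comp("V165", "R2")))
    iendo = reg.idx(Species(tissue, "rab45", comp("V165", "R2")))
    linear = [
        LinearProcess("internalization", isurf, iendo, k_int, tissue),
        LinearProcess("rab45_to_surface", iendo, isurf, k_rec, tissue),
    ]
    conservation = [(isurf, [isurf, iendo], amount)]
    model = Model(params, reg, [], linear, [], conservation, BASELINE)
    kdp = params.phosphorylation.k_dephos
    expected_ratio = two_pool_phospho_ratio(
        k_int, k_rec,
        {s: kdp[s]["surface"] for s in ("Y1175", "Y1214")},
        {s: kdp[s]["rab45"] for s in ("Y1175", "Y1214")},
        params.phosphorylation.k_phos_ligated)
    y0 = np.zeros(2)
    y0[isurf] = amount
    return ToyModelSpec(
        name="two_pool_phospho", model=model, y0=y0,
        expected={"ratio_pY1214_pY1175": expected_ratio},
        state_names=("LR2_rab45", "LR2_surface"))  # registry canonical order


def generate_toy_fixtures() -> dict[str, ToyModelSpec]:
    """All toy fixtures, keyed by name."""
    return {t.name: t for t in (make_binding_toy(), make_clearance_toy(),
                                make_phospho_toy())}
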