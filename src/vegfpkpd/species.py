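"""Molecular species bookkeeping.

A *species instance* is a molecular composition (a set of monomers: one
ligand at most, plus receptors/co-receptors/matrix site) placed in a
compartment and subcellular location. The full state vector of the model is
the ordered list of these instances (amounts in moles), plus companion
phospho-amount states for VEGFR2-containing instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

MONOMERS = ("V121", "V165", "V189", "P1", "P2", "R1", "R2", "N1", "sR1", "M")
LIGAND_MONOMERS = ("V121", "V165", "V189", "P1", "P2")

#: config/ligand-table name -> composition monomer symbol
LIGAND_SYMBOL = {"VEGF121": "V121", "VEGF165": "V165", "VEGF189": "V189",
                 "PlGF1": "P1", "PlGF2": "P2"}
SYMBOL_LIGAND = {v: k for k, v in LIGAND_SYMBOL.items()}

TISSUE_LOCATIONS = ("fluid", "ecm", "ebm", "pbm", "surface", "ebm_surface",
                    "rab45", "rab11")
MATRIX_LOCATIONS = ("ecm", "ebm", "pbm")
ENDOSOME_LOCATIONS = ("rab45", "rab11")


def comp(*monomers: str) -> tuple[str, ...]:
    """Canonical composition tuple (sorted, no duplicates)."""
    ms = tuple(sorted(monomers))
    assert len(set(ms)) == len(ms), f"duplicate monomer in {monomers}"
    for m in ms:
        assert m in MONOMERS, f"unknown monomer {m}"
    return ms


@dataclass(frozen=True, order=True)
class Species:
    compartment: str  # 'calf' | 'main_body' | 'blood'
    location: str  # tissue locations | 'plasma'
    composition: tuple[str, ...]

    def __post_init__(self):
        if "M" in self.composition and self.location in (
                "plasma", "rab45", "rab11", "fluid", "surface"):
            raise ValueError(
                f"matrix-containing species cannot live in {self.location}")

    @property
    def ligand(self) -> str | None:
        for m in self.composition:
            if m in LIGAND_MONOMERS:
                return m
        return None

    @property
    def ligand_name(self) -> str | None:
        lig = self.ligand
        return SYMBOL_LIGAND[lig] if lig is not None else None

    def contains(self, monomer: str) -> bool:
        return monomer in self.composition

    @property
    def receptor_class(self) -> str | None:
        """Receptor class whose trafficking rates govern this complex."""
        for rc in ("R2", "R1", "N1"):
            if rc in self.composition:
                return rc
        return None

    @property
    def is_cell_associated(self) -> bool:
        return self.location in ("surface", "ebm_surface", "rab45", "rab11")

    @property
    def is_soluble(self) -> bool:
        """Free-diffusing in fluid: eligible for transport."""
        return self.location in ("fluid", "plasma")

    def key(self) -> tuple:
        return (self.compartment, self.location, self.composition)

    def label(self) -> str:
        return f"{self.compartment}:{self.location}:{'·'.join(self.composition)}"


class SpeciesRegistry:
    """Deterministically ordered set of species instances."""

    def __init__(self, species: Iterable[Species]):
        self.species: list[Species] = sorted(set(species))
        self.index: dict[Species, int] = {s: i for i, s in enumerate(self.species)}

    def __len__(self):
        return len(self.species)

    def __iter__(self):
        return iter(self.species)

    def __contains__(self, sp: Species):
        return sp in self.index

    def idx(self, sp: Species) -> int:
        try:
            return self.index[sp]
        except KeyError:
            raise KeyError(f"species not in registry: {sp.label()}") from None

    def select(self, **criteria) -> list[int]:
        """Indices of species matching simple predicates.

        Supported criteria: compartment, location (str or tuple), contains
        (monomer str or tuple: all must be present), ligand (symbol, or True
        for any ligand, False for none).
        """
        out = []
        for i, s in enumerate(self.species):
            if "compartment" in criteria and s.compartment != criteria["compartment"]:
                continue
            if "location" in criteria:
                locs = criteria["location"]
                locs = (locs,) if isinstance(locs, str) else locs
                if s.location not in locs:
                    continue
            if "contains" in criteria:
                need = criteria["contains"]
                need = (need,) if isinstance(need, str) else need
                if not all(m in s.composition for m in need):
                    continue
            if "ligand" in criteria:
                want = criteria["ligand"]
                if want is True and s.ligand is None:
                    continue
                if want is False and s.ligand is not None:
                    continue
                if isinstance(want, str) and s.ligand != want:
                    continue
            out.append(i)
        return out

    def r2_carriers(self) -> list[int]:
        """Cell-associated VEGFR2-containing instances (phospho carriers)."""
        return [i for i, s in enumerate(self.species)
                if s.contains("R2") and s.is_cell_associated]


def enumerate_species(params, options=None) -> SpeciesRegistry:
    """Closure of the monomer set under all reactions and trafficking moves.

    Thin wrapper over the reaction-network generator so that the registry and
    the network are always constructed from the same rules.
    """
    from .network import enumerate_model_species
    return enumerate_model_species(params, options)
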