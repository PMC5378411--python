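"""Parameter loading and validation for the whole-body VEGF-family model.

All model inputs live in a single structured YAML configuration (the default
one ships with the package). Loading resolves every table entry into typed
records carrying value, units and a provenance string, and fails hard —
naming the offending table cell — on missing or inconsistently-tagged
entries.

Internally the model works in SI-adjacent units: amounts in moles, volumes
in liters, areas in cm^2, time in seconds. The loader converts the
human-readable config units (cm^3, nm, molecules/cell/s) once, here.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

N_AVOGADRO = 6.02214076e23

LIGANDS = ("VEGF121", "VEGF165", "VEGF189", "PlGF1", "PlGF2")
VEGF_ISOFORMS = ("VEGF121", "VEGF165", "VEGF189")
PLGF_ISOFORMS = ("PlGF1", "PlGF2")
RECEPTOR_CLASSES = ("R1", "R2", "N1")
TISSUES = ("calf", "main_body")
PHOSPHO_SITES = ("Y951", "Y1175", "Y1214")
ENDOSOME_LOCATIONS = ("rab45", "rab11")

#: reaction labels of Tables 1-3 (per-isoform rows)
REACTION_LABELS = (
    "L-R1", "L-R2", "L-N1", "L-sR1", "L-M",
    "(M-L)-R1", "(M-L)-R2", "(M-L)-sR1",
    "M-(L-R1)", "M-(L-R2)", "M-(L-sR1)",
    "(L-sR1)-M", "(M-sR1)-L",
    "(N1-L)-R2", "N1-(L-R2)",
    "(L-R1)-N1", "(L-sR1)-N1",
    "(N1-R1)-L", "(N1-sR1)-L",
)
COUPLING_LABELS = ("N1-R1", "sR1-N1", "sR1-M")

VALID_UNIT_TAGS = ("volumetric", "surface")


class ParameterError(ValueError):
    """Raised when the configuration is missing or inconsistent."""


@dataclass(frozen=True)
class LigandIsoform:
    name: str
    family: str  # VEGF | PlGF
    production_fraction: float
    binds_r1: bool
    binds_r2: bool
    binds_matrix: bool
    binds_nrp1_direct: bool
    binds_nrp1_coupled_r1: bool

    def __post_init__(self):
        if self.binds_nrp1_direct and self.binds_nrp1_coupled_r1:
            raise ParameterError(
                f"{self.name}: binds_nrp1_direct and binds_nrp1_coupled_r1 "
                "are mutually exclusive")
        if not self.binds_r1:
            raise ParameterError(f"{self.name}: all isoforms bind VEGFR1")
        if self.family == "PlGF" and self.binds_r2:
            raise ParameterError(f"{self.name}: PlGF isoforms do not bind VEGFR2")
        if not 0.0 <= self.production_fraction <= 1.0:
            raise ParameterError(f"{self.name}: production fraction outside [0,1]")


@dataclass(frozen=True)
class CompartmentGeometry:
    """Geometry of one tissue compartment (volumes in liters, areas in cm^2)."""

    name: str
    total_volume_L: float
    available_fluid_volume_L: float
    esav_cm2_per_cm3: float
    ec_surface_area_cm2: float
    ec_count: float
    myonuclear_domain_count: float
    ebm_volume_L: float
    ecm_volume_L: float
    pbm_volume_L: float
    ebm_thickness_nm: float
    ebm_accessible_fraction: float
    provenance: str = ""

    def __post_init__(self):
        for f in ("total_volume_L", "available_fluid_volume_L", "ec_surface_area_cm2",
                  "ebm_volume_L", "ecm_volume_L", "pbm_volume_L"):
            if getattr(self, f) <= 0:
                raise ParameterError(f"geometry {self.name}: {f} must be > 0")
        if not 0.0 < self.ebm_accessible_fraction <= 1.0:
            raise ParameterError(
                f"geometry {self.name}: EBM accessible fraction outside (0,1]")

    def matrix_location_volume_L(self, loc: str) -> float:
        return {"ecm": self.ecm_volume_L, "ebm": self.ebm_volume_L,
                "pbm": self.pbm_volume_L}[loc]


@dataclass(frozen=True)
class BloodGeometry:
    total_volume_L: float
    plasma_volume_L: float
    provenance: str = ""

    def __post_init__(self):
        if self.plasma_volume_L <= 0 or self.total_volume_L <= 0:
            raise ParameterError("blood volumes must be > 0")


@dataclass(frozen=True)
class KineticEntry:
    label: str
    isoform: str | None  # None for the single-valued coupling rows
    kon: float
    koff: float
    kd: float
    units: str  # 'volumetric' | 'surface'
    provenance: str = ""

    @property
    def kd_from_rates(self) -> float:
        return self.koff / self.kon


@dataclass(frozen=True)
class Discrepancy:
    label: str
    isoform: str | None
    stated_kd: float
    kd_from_rates: float

    @property
    def relative_error(self) -> float:
        return abs(self.kd_from_rates - self.stated_kd) / self.stated_kd


@dataclass
class BindingParameterTable:
    entries: dict[tuple[str, str | None], KineticEntry]

    def get(self, label: str, isoform: str | None = None) -> KineticEntry | None:
        return self.entries.get((label, isoform))

    def has(self, label: str, isoform: str | None = None) -> bool:
        return (label, isoform) in self.entries


@dataclass(frozen=True)
class TraffickingRates:
    internalization: float
    rab45_to_surface: float
    rab45_to_rab11: float
    rab11_to_surface: float
    degradation_rab45: float
    degradation_rab11: float

    def __post_init__(self):
        for f, v in self.__dict__.items():
            if v < 0:
                raise ParameterError(f"trafficking rate {f} must be >= 0")


@dataclass
class TraffickingParameters:
    by_class: dict[str, dict[str, TraffickingRates]]  # class -> status -> rates
    endosomal_cargo_degradation: float
    provenance: str = ""

    def rates_for(self, receptor_class: str, ligated: bool, nrp1: bool) -> TraffickingRates:
        statuses = self.by_class[receptor_class]
        if ligated and nrp1 and "ligated_nrp1" in statuses:
            return statuses["ligated_nrp1"]
        return statuses["ligated" if ligated else "free"]


@dataclass
class PhosphorylationParameters:
    k_phos_ligated: float
    k_phos_free: float
    k_dephos: dict[str, dict[str, float]]  # site -> location -> rate (s^-1)
    provenance: str = ""


@dataclass
class TransportParameters:
    permeability_cm_per_s: dict[str, float]  # species family -> cm/s
    lymph_flow_L_per_s: dict[str, float]  # tissue -> L/s
    clearance_per_s: dict[str, float]  # species family -> s^-1
    provenance: str = ""


@dataclass
class MatrixSiteDensities:
    density_M: dict[str, float]  # location -> mol/L of local BM/ECM volume
    provenance: str = ""

    def __post_init__(self):
        for loc, d in self.density_M.items():
            if d <= 0:
                raise ParameterError(f"matrix density {loc} must be > 0")


@dataclass
class SecretionConfig:
    """Ligand secretion and receptor production controls.

    q_* are per-cell molecular rates (same in both tissue compartments);
    receptor multipliers scale the closed-form baseline production that hits
    the target surface density at the no-ligand steady state.
    """

    q_vegf: float  # molecules / myonuclear domain / s
    q_plgf: float
    q_sr1: float  # molecules / EC / s
    receptor_production_multiplier: dict[str, dict[str, float]]  # class -> tissue -> x
    provenance: str = ""

    def copy(self) -> "SecretionConfig":
        return SecretionConfig(
            q_vegf=self.q_vegf, q_plgf=self.q_plgf, q_sr1=self.q_sr1,
            receptor_production_multiplier={
                c: dict(t) for c, t in self.receptor_production_multiplier.items()},
            provenance=self.provenance)


@dataclass
class CalibrationTargets:
    plasma_free_pM: dict[str, float]  # VEGF, PlGF, sR1
    #: R1, R2, N1 -> either one value for both tissues or {tissue: value}
    surface_receptors_per_cell: dict[str, float | dict[str, float]]
    provenance: str = ""

    def surface_target(self, receptor: str, tissue: str) -> float:
        v = self.surface_receptors_per_cell[receptor]
        return v[tissue] if isinstance(v, dict) else v

    def __post_init__(self):
        vals = list(self.plasma_free_pM.values())
        for v in self.surface_receptors_per_cell.values():
            vals.extend(v.values() if isinstance(v, dict) else [v])
        for v in vals:
            if v < 0:
                raise ParameterError("targets must be >= 0")


@dataclass
class ParameterSet:
    ligands: dict[str, LigandIsoform]
    geometry: dict[str, CompartmentGeometry]  # tissue name -> geometry
    blood: BloodGeometry
    kinetics: BindingParameterTable
    trafficking: TraffickingParameters
    phosphorylation: PhosphorylationParameters
    transport: TransportParameters
    matrix_sites: MatrixSiteDensities
    secretion: SecretionConfig
    targets: CalibrationTargets
    ebm_reach_nm: float
    raw_config: dict = field(repr=False, default_factory=dict)

    def content_hash(self) -> str:
        blob = json.dumps(self.raw_config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def with_secretion(self, secretion: SecretionConfig) -> "ParameterSet":
        new = copy.copy(self)
        new.secretion = secretion
        raw = copy.deepcopy(self.raw_config)
        raw.setdefault("secretion", {})
        raw["secretion"]["q_vegf_molec_per_md_s"] = secretion.q_vegf
        raw["secretion"]["q_plgf_molec_per_md_s"] = secretion.q_plgf
        raw["secretion"]["q_sr1_molec_per_ec_s"] = secretion.q_sr1
        raw["secretion"]["receptor_production_multiplier"] = {
            c: dict(t) for c, t in secretion.receptor_production_multiplier.items()}
        new.raw_config = raw
        return new

    def serialize(self) -> dict:
        return copy.deepcopy(self.raw_config)


def default_config_path() -> Path:
    return Path(resources.files("vegfpkpd").joinpath("data/default_config.yaml"))


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise ParameterError(f"missing parameter: {where}, {key}")
    return mapping[key]


def _load_geometry(name: str, g: Mapping) -> CompartmentGeometry:
    where = f"geometry.{name}"
    v_total_cm3 = float(_require(g, "total_volume_cm3", where))
    esav = float(_require(g, "esav_cm2_per_cm3", where))
    if esav <= 0:
        raise ParameterError(f"{where}: ESAV must be > 0")
    area = esav * v_total_cm3
    ec_count = area / float(_require(g, "ec_surface_area_per_cell_cm2", where))
    md_count = (float(_require(g, "myocyte_volume_fraction", where)) * v_total_cm3
                / float(_require(g, "myonuclear_domain_volume_cm3", where)))
    ebm_thick_nm = float(_require(g, "ebm_thickness_nm", where))
    ebm_vol_cm3 = area * ebm_thick_nm * 1e-7
    pbm_vol_cm3 = (float(_require(g, "myocyte_sa_per_cm3_tissue_cm2", where))
                   * v_total_cm3
                   * float(_require(g, "pbm_thickness_nm", where)) * 1e-7)
    ecm_vol_cm3 = float(_require(g, "ecm_volume_fraction", where)) * v_total_cm3
    return CompartmentGeometry(
        name=name,
        total_volume_L=v_total_cm3 / 1000.0,
        available_fluid_volume_L=(
            float(_require(g, "available_fluid_fraction", where)) * v_total_cm3 / 1000.0),
        esav_cm2_per_cm3=esav,
        ec_surface_area_cm2=area,
        ec_count=ec_count,
        myonuclear_domain_count=md_count,
        ebm_volume_L=ebm_vol_cm3 / 1000.0,
        ecm_volume_L=ecm_vol_cm3 / 1000.0,
        pbm_volume_L=pbm_vol_cm3 / 1000.0,
        ebm_thickness_nm=ebm_thick_nm,
        ebm_accessible_fraction=1.0,  # placeholder; set after reach is known
        provenance=str(g.get("provenance", "")),
    )


def _required_kinetic_cells(ligands: dict[str, "LigandIsoform"]):
    """(label, isoform) cells that the printed tables fill (non-"-")."""
    out = []
    for name, lig in ligands.items():
        rules = {
            "L-R1": lig.binds_r1,
            "L-R2": lig.binds_r2,
            "L-N1": lig.binds_nrp1_direct,
            "L-sR1": lig.binds_r1,  # sR1 shares VEGFR1 binding properties
            "L-M": lig.binds_matrix,
            "(M-L)-R1": lig.binds_matrix,
            "(M-L)-R2": lig.binds_matrix and lig.binds_r2,
            "(M-L)-sR1": lig.binds_matrix,
            "M-(L-R1)": lig.binds_matrix,
            "M-(L-R2)": lig.binds_matrix and lig.binds_r2,
            "M-(L-sR1)": lig.binds_matrix,
            "(L-sR1)-M": lig.binds_nrp1_coupled_r1,
            "(M-sR1)-L": lig.binds_nrp1_coupled_r1,
            "(N1-L)-R2": lig.binds_nrp1_direct and lig.binds_r2,
            "N1-(L-R2)": lig.binds_nrp1_direct and lig.binds_r2,
            "(L-R1)-N1": lig.binds_nrp1_coupled_r1,
            "(L-sR1)-N1": lig.binds_nrp1_coupled_r1,
            "(N1-R1)-L": lig.binds_nrp1_coupled_r1,
            "(N1-sR1)-L": lig.binds_nrp1_coupled_r1,
        }
        out.extend((label, name) for label, req in rules.items() if req)
    return out


def load_parameter_set(config_source: str | Path | Mapping | None = None) -> ParameterSet:
    """Load and validate a full model parameterization.

    Parameters
    ----------
    config_source
        Path to a YAML file, an already-parsed mapping, or None for the
        packaged default configuration.
    """
    if config_source is None:
        config_source = default_config_path()
    if isinstance(config_source, (str, Path)):
        with open(config_source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = copy.deepcopy(dict(config_source))

    # --- ligands ---
    lig_block = _require(cfg, "ligands", "config")
    ligands = {}
    for name in LIGANDS:
        entry = _require(lig_block, name, "ligands")
        ligands[name] = LigandIsoform(
            name=name,
            family=str(_require(entry, "family", f"ligands.{name}")),
            production_fraction=float(_require(entry, "production_fraction",
                                               f"ligands.{name}")),
            binds_r1=bool(_require(entry, "binds_r1", f"ligands.{name}")),
            binds_r2=bool(_require(entry, "binds_r2", f"ligands.{name}")),
            binds_matrix=bool(_require(entry, "binds_matrix", f"ligands.{name}")),
            binds_nrp1_direct=bool(_require(entry, "binds_nrp1_direct",
                                            f"ligands.{name}")),
            binds_nrp1_coupled_r1=bool(_require(entry, "binds_nrp1_coupled_r1",
                                                f"ligands.{name}")),
        )
    for family, members in (("VEGF", VEGF_ISOFORMS), ("PlGF", PLGF_ISOFORMS)):
        s = sum(ligands[m].production_fraction for m in members)
        if abs(s - 1.0) > 1e-9:
            raise ParameterError(
                f"{family} production fractions sum to {s:.6f}, expected 1")

    # --- EBM reach & geometry ---
    reach_nm = float(_require(_require(cfg, "ebm_accessibility", "config"),
                              "reach_nm", "ebm_accessibility"))
    geom_block = _require(cfg, "geometry", "config")
    geometry = {}
    for tissue in TISSUES:
        g = _load_geometry(tissue, _require(geom_block, tissue, "geometry"))
        frac = min(reach_nm / g.ebm_thickness_nm, 1.0)
        geometry[tissue] = CompartmentGeometry(
            **{**g.__dict__, "ebm_accessible_fraction": frac})
    blood_cfg = _require(geom_block, "blood", "geometry")
    blood = BloodGeometry(
        total_volume_L=float(_require(blood_cfg, "total_volume_cm3",
                                      "geometry.blood")) / 1000.0,
        plasma_volume_L=float(_require(blood_cfg, "plasma_volume_cm3",
                                       "geometry.blood")) / 1000.0,
        provenance=str(blood_cfg.get("provenance", "")),
    )

    # --- kinetics ---
    kin = _require(cfg, "kinetics", "config")
    kin_prov = str(kin.get("provenance", ""))
    entries: dict[tuple[str, str | None], KineticEntry] = {}
    rows = _require(kin, "rows", "kinetics")
    for label in REACTION_LABELS:
        row = _require(rows, label, "kinetics.rows")
        units = str(_require(row, "units", f"kinetics.rows.{label}"))
        if units not in VALID_UNIT_TAGS:
            raise ParameterError(
                f"kinetics.rows.{label}: inconsistent units tag {units!r}")
        for isoform, triple in _require(row, "per_isoform",
                                        f"kinetics.rows.{label}").items():
            if isoform not in LIGANDS:
                raise ParameterError(
                    f"kinetics.rows.{label}: unknown isoform {isoform}")
            if triple is None or len(triple) != 3:
                raise ParameterError(
                    f"missing parameter: Table 1-3, {label}, {isoform}")
            kon, koff, kd = (float(x) for x in triple)
            entries[(label, isoform)] = KineticEntry(
                label=label, isoform=isoform, kon=kon, koff=koff, kd=kd,
                units=units, provenance=kin_prov)
    couplings = _require(kin, "couplings", "kinetics")
    for label in COUPLING_LABELS:
        c = _require(couplings, label, "kinetics.couplings")
        units = str(_require(c, "units", f"kinetics.couplings.{label}"))
        if units not in VALID_UNIT_TAGS:
            raise ParameterError(
                f"kinetics.couplings.{label}: inconsistent units tag {units!r}")
        entries[(label, None)] = KineticEntry(
            label=label, isoform=None,
            kon=float(_require(c, "kon", f"kinetics.couplings.{label}")),
            koff=float(_require(c, "koff", f"kinetics.couplings.{label}")),
            kd=float(_require(c, "kd", f"kinetics.couplings.{label}")),
            units=units, provenance=str(couplings.get("provenance", kin_prov)))
    table = BindingParameterTable(entries=entries)
    # completeness: every non-"-" cell of the printed tables must be present;
    # coverage is derivable from the isoform binding flags
    for label, iso in _required_kinetic_cells(ligands):
        if not table.has(label, iso):
            raise ParameterError(f"missing parameter: Table 1-3, {label}, {iso}")

    # --- trafficking ---
    tr = _require(cfg, "trafficking", "config")
    by_class = {}
    for rc in RECEPTOR_CLASSES:
        statuses = {}
        for status, rates in _require(tr, rc, "trafficking").items():
            statuses[status] = TraffickingRates(**{
                k: float(_require(rates, k, f"trafficking.{rc}.{status}"))
                for k in ("internalization", "rab45_to_surface", "rab45_to_rab11",
                          "rab11_to_surface", "degradation_rab45",
                          "degradation_rab11")})
        if "free" not in statuses or "ligated" not in statuses:
            raise ParameterError(f"trafficking.{rc}: need 'free' and 'ligated' rates")
        by_class[rc] = statuses
    trafficking = TraffickingParameters(
        by_class=by_class,
        endosomal_cargo_degradation=float(
            _require(tr, "endosomal_cargo_degradation", "trafficking")),
        provenance=str(tr.get("provenance", "")))

    # --- phosphorylation ---
    ph = _require(cfg, "phosphorylation", "config")
    k_dephos = {}
    for site in PHOSPHO_SITES:
        locs = _require(_require(ph, "k_dephos_per_s", "phosphorylation"), site,
                        "phosphorylation.k_dephos_per_s")
        k_dephos[site] = {loc: float(_require(locs, loc,
                                              f"phosphorylation.k_dephos.{site}"))
                          for loc in ("surface", "rab45", "rab11")}
    phospho = PhosphorylationParameters(
        k_phos_ligated=float(_require(ph, "k_phos_ligated_per_s", "phosphorylation")),
        k_phos_free=float(_require(ph, "k_phos_free_per_s", "phosphorylation")),
        k_dephos=k_dephos, provenance=str(ph.get("provenance", "")))

    # --- transport ---
    tp = _require(cfg, "transport", "config")
    transport = TransportParameters(
        permeability_cm_per_s={k: float(v) for k, v in
                               _require(tp, "permeability_cm_per_s",
                                        "transport").items()},
        lymph_flow_L_per_s={k: float(v) / 1000.0 for k, v in
                            _require(tp, "lymph_flow_cm3_per_s",
                                     "transport").items()},
        clearance_per_s={k: float(v) for k, v in
                         _require(tp, "clearance_per_s", "transport").items()},
        provenance=str(tp.get("provenance", "")))
    for fam in ("VEGF", "PlGF", "sR1", "L_sR1"):
        if fam not in transport.permeability_cm_per_s:
            raise ParameterError(f"missing parameter: transport.permeability, {fam}")
        if fam not in transport.clearance_per_s:
            raise ParameterError(f"missing parameter: transport.clearance, {fam}")
    if abs(transport.permeability_cm_per_s["PlGF"]
           - transport.permeability_cm_per_s["VEGF"]) > 1e-30:
        # invariant from the transport assumptions: same permeability for PlGF
        raise ParameterError("transport: PlGF permeability must equal VEGF permeability")

    # --- matrix sites ---
    ms = _require(cfg, "matrix_sites", "config")
    matrix = MatrixSiteDensities(
        density_M={k: float(v) for k, v in
                   _require(ms, "density_M", "matrix_sites").items()},
        provenance=str(ms.get("provenance", "")))

    # --- secretion & targets ---
    sec = _require(cfg, "secretion", "config")
    secretion = SecretionConfig(
        q_vegf=float(_require(sec, "q_vegf_molec_per_md_s", "secretion")),
        q_plgf=float(_require(sec, "q_plgf_molec_per_md_s", "secretion")),
        q_sr1=float(_require(sec, "q_sr1_molec_per_ec_s", "secretion")),
        receptor_production_multiplier={
            rc: {t: float(v) for t, v in
                 _require(_require(sec, "receptor_production_multiplier",
                                   "secretion"), rc,
                          "secretion.receptor_production_multiplier").items()}
            for rc in RECEPTOR_CLASSES},
        provenance=str(sec.get("provenance", "")))
    tg = _require(cfg, "calibration_targets", "config")
    targets = CalibrationTargets(
        plasma_free_pM={k: float(v) for k, v in
                        _require(tg, "plasma_free_pM", "calibration_targets").items()},
        surface_receptors_per_cell={
            k: float(v) for k, v in
            _require(tg, "surface_receptors_per_cell",
                     "calibration_targets").items()},
        provenance=str(tg.get("provenance", "")))

    return ParameterSet(
        ligands=ligands, geometry=geometry, blood=blood, kinetics=table,
        trafficking=trafficking, phosphorylation=phospho, transport=transport,
        matrix_sites=matrix, secretion=secretion, targets=targets,
        ebm_reach_nm=reach_nm, raw_config=cfg)


def validate_kinetics(table: BindingParameterTable,
                      rel_tol: float = 0.10) -> list[Discrepancy]:
    """Report entries whose printed KD disagrees with koff/kon by > rel_tol.

    Reporting only: network construction always uses kon/koff, which are
    authoritative when the printed KD column carries a typo.
    """
    out = []
    for (label, isoform), e in table.entries.items():
        if e.kd <= 0 or e.kon <= 0:
            continue
        derived = e.kd_from_rates
        if abs(derived - e.kd) / e.kd > rel_tol:
            out.append(Discrepancy(label=label, isoform=isoform,
                                   stated_kd=e.kd, kd_from_rates=derived))
    out.sort(key=lambda d: (d.label, d.isoform or ""))
    return out
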