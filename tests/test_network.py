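import numpy as np
import pytest

from vegfpkpd.engine import Model, simulate
from vegfpkpd.network import (BASELINE, NO_MLR, build_network,
                              check_thermodynamic_cycles,
                              convert_kd_volume_to_surface,
                              ebm_accessible_fraction)
from vegfpkpd.species import MONOMERS


class TestUnitConversions:
    def test_kd_volume_to_surface(self):
        assert convert_kd_volume_to_surface(0.0, 1000.0) == 0.0
        assert convert_kd_volume_to_surface(1.0e-10, 1000.0) == \
            pytest.approx(1.0e-16)
        # sR1-N1 at the configured ESAV
        assert convert_kd_volume_to_surface(1.8e-9, 70.0) == \
            pytest.approx(1.8e-9 * 1e-3 / 70.0)
        with pytest.raises(ValueError):
            convert_kd_volume_to_surface(1e-10, 0.0)

    def test_ebm_accessible_fraction(self):
        assert ebm_accessible_fraction(25.0, 50.0) == 0.5
        assert ebm_accessible_fraction(25.0, 20.0) == 1.0  # capped
        assert ebm_accessible_fraction(0.0, 40.0) == 0.0
        with pytest.raises(ValueError):
            ebm_accessible_fraction(25.0, 0.0)


def test_composition_conservation_exhaustive(params):
    net = build_network(params)
    sp = net.registry.species
    for r in net.reactions:
        union = sorted(sp[r.a].composition + sp[r.b].composition)
        assert union == sorted(sp[r.product].composition)


def test_no_cross_compartment_reactions(params):
    net = build_network(params)
    sp = net.registry.species
    for r in net.reactions:
        assert sp[r.a].compartment == sp[r.b].compartment \
            == sp[r.product].compartment


def test_reaction_set_reproducible(params):
    a = build_network(params)
    b = build_network(params)
    key = lambda r: (r.label, r.isoform, r.compartment, r.location, r.a, r.b)
    assert [key(r) for r in a.reactions] == [key(r) for r in b.reactions]


def test_plasma_network_is_ligand_sr1_only(params):
    net = build_network(params, compartment="blood")
    assert len(net.reactions) == 5  # one L+sR1 <-> L·sR1 per isoform
    for r in net.reactions:
        assert r.label == "L-sR1"
        sp = net.registry.species[r.product]
        assert sp.location == "plasma"
        assert set(sp.composition) <= {"V121", "V165", "V189", "P1", "P2",
                                       "sR1"}


def test_no_mlr_removes_matrix_receptor_reactions(params):
    net = build_network(params, options=NO_MLR)
    sp = net.registry.species
    for r in net.reactions:
        prod = sp[r.product]
        if "M" in prod.composition:
            # only binary matrix species remain: L·M and sR1·M
            assert not ({"R1", "R2"} & set(prod.composition))
            assert not ("sR1" in prod.composition
                        and prod.ligand is not None)


def test_ebm_reactions_scaled_by_accessible_fraction(params, raw_config):
    import copy
    from vegfpkpd.parameters import load_parameter_set
    raw = copy.deepcopy(raw_config)
    raw["ebm_accessibility"]["reach_nm"] = 0.0
    with pytest.raises(Exception):
        # reach 0 makes the accessible fraction 0, outside (0, 1]
        load_parameter_set(raw)
    # at reach 25 / thickness 40 the fraction is 0.625 and multiplies khat
    net = build_network(params)
    ebm_rx = [r for r in net.reactions if r.context == "ebm_access"]
    assert ebm_rx
    geom = params.geometry[ebm_rx[0].compartment]
    r = next(r for r in ebm_rx if r.label == "(M-L)-R2"
             and r.isoform == "VEGF165")
    expected = 1.0e7 * geom.ebm_accessible_fraction / geom.total_volume_L
    assert r.khat == pytest.approx(expected)
    assert geom.ebm_accessible_fraction == pytest.approx(25.0 / 40.0)


def test_stoichiometry_map(params):
    net = build_network(params, compartment="blood")
    sto = net.stoichiometry()
    for ri, r in enumerate(net.reactions):
        assert (ri, -1) in sto[r.a]
        assert (ri, -1) in sto[r.b]
        assert (ri, +1) in sto[r.product]


def test_binding_only_subsystem_conserves_monomers(params, rng):
    """With trafficking/transport/secretion stripped and koff kept, the pure
    binding subsystem conserves the total amount of every monomer."""
    net = build_network(params)
    m = Model(params, net.registry, net.reactions, [], [], [], BASELINE)
    y0 = rng.uniform(0.0, 1e-13, m.n)

    def totals(y):
        t = dict.fromkeys(MONOMERS, 0.0)
        for i, sp in enumerate(net.registry.species):
            for mono in sp.composition:
                t[mono] += y[i]
        return t

    sol = simulate(m, y0, (0.0, 2.0e4))
    assert sol.success
    t0, t1 = totals(y0), totals(sol.y[:, -1])
    for mono in MONOMERS:
        assert t1[mono] == pytest.approx(t0[mono], rel=1e-6)


class TestCycleClosure:
    def test_matrix_cycles_balance(self, params):
        """Both binding orders through a matrix site multiply to the same KD
        product (e.g. VEGF165: 6.1e-8 x 1.0e-10 either way)."""
        reports = check_thermodynamic_cycles(params.kinetics, esav=70.0)
        matrix = [r for r in reports if r.cycle.startswith("M")]
        assert matrix
        for r in matrix:
            assert r.ratio_from_rates == pytest.approx(1.0, rel=1e-9), r

    def test_vegf121_sr1_matrix_cycle(self, params):
        reports = check_thermodynamic_cycles(params.kinetics, esav=70.0)
        r = next(r for r in reports
                 if r.cycle == "M,sR1,L" and r.isoform == "VEGF121")
        assert r.ratio_from_rates == pytest.approx(1.0, rel=1e-9)

    def test_nrp1_enhancement_cycles_reported_not_silent(self, params):
        """NRP1-coupling cycles deliberately violate detailed balance
        (presentation enhances affinity); the audit must surface them."""
        reports = check_thermodynamic_cycles(params.kinetics, esav=70.0)
        n1_lr2 = next(r for r in reports
                      if r.cycle == "N1,L,R2" and r.isoform == "VEGF165")
        assert not n1_lr2.balanced
        assert n1_lr2.ratio_from_rates > 1.0

    def test_empty_table_empty_report(self):
        from vegfpkpd.parameters import BindingParameterTable
        assert check_thermodynamic_cycles(
            BindingParameterTable(entries={}), esav=70.0) == []


def test_network_export_table(params):
    df = build_network(params, compartment="blood").to_dataframe()
    assert set(df.columns) >= {"reactant_a", "reactant_b", "product",
                               "khat_per_mol_s", "koff_per_s", "location"}
    assert len(df) == 5
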