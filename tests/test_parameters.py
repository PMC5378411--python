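import pytest

from vegfpkpd.parameters import (LIGANDS, ParameterError, load_parameter_set,
                                 validate_kinetics, BindingParameterTable)


def test_default_config_carries_printed_values(params):
    """Headline fitted rates and geometry stated in the main text."""
    assert params.secretion.q_vegf == pytest.approx(0.2830)
    assert params.secretion.q_plgf == pytest.approx(0.0146)
    assert params.secretion.q_sr1 == pytest.approx(0.0893)
    assert params.blood.plasma_volume_L == pytest.approx(3.0)
    assert params.blood.total_volume_L == pytest.approx(5.0)
    assert params.targets.plasma_free_pM == {"VEGF": 1.5, "PlGF": 10.0,
                                             "sR1": 100.0}
    assert params.targets.surface_receptors_per_cell == {
        "R1": 1800.0, "R2": 5800.0, "N1": 70000.0}
    e = params.kinetics.get("L-R2", "VEGF165")
    assert (e.kon, e.koff, e.kd) == (1.0e7, 1.0e-3, 1.0e-10)


def test_production_fractions_sum_to_one(params):
    for family, members in (("VEGF", ("VEGF121", "VEGF165", "VEGF189")),
                            ("PlGF", ("PlGF1", "PlGF2"))):
        s = sum(params.ligands[m].production_fraction for m in members)
        assert s == pytest.approx(1.0)


def test_isoform_binding_flags(params):
    for name in LIGANDS:
        lig = params.ligands[name]
        assert lig.binds_r1
        assert not (lig.binds_nrp1_direct and lig.binds_nrp1_coupled_r1)
    assert not params.ligands["PlGF1"].binds_r2
    assert not params.ligands["PlGF2"].binds_r2
    assert params.ligands["VEGF121"].binds_nrp1_coupled_r1
    assert params.ligands["VEGF189"].binds_matrix


@pytest.mark.parametrize("label, isoform", [
    ("L-R2", "VEGF165"), ("L-R1", "PlGF2"), ("(M-sR1)-L", "PlGF1")])
def test_missing_entry_error_names_the_cell(raw_config, label, isoform):
    import re
    del raw_config["kinetics"]["rows"][label]["per_isoform"][isoform]
    with pytest.raises(ParameterError,
                       match=f"{re.escape(label)}.*{isoform}"):
        load_parameter_set(raw_config)


def test_bad_units_tag_is_an_error(raw_config):
    raw_config["kinetics"]["rows"]["L-R2"]["units"] = "furlongs"
    with pytest.raises(ParameterError, match="units"):
        load_parameter_set(raw_config)


def test_unequal_plgf_vegf_permeability_rejected(raw_config):
    raw_config["transport"]["permeability_cm_per_s"]["PlGF"] = 9.9e-8
    with pytest.raises(ParameterError, match="permeability"):
        load_parameter_set(raw_config)


def test_round_trip_is_lossless(params):
    reloaded = load_parameter_set(params.serialize())
    assert reloaded.content_hash() == params.content_hash()
    for key, e in params.kinetics.entries.items():
        e2 = reloaded.kinetics.entries[key]
        assert (e2.kon, e2.koff, e2.kd) == (e.kon, e.koff, e.kd)


class TestValidateKinetics:
    def test_consistent_entry_not_flagged(self, params):
        flagged = {(d.label, d.isoform)
                   for d in validate_kinetics(params.kinetics)}
        assert ("L-R2", "VEGF165") not in flagged

    def test_known_typos_flagged(self, params):
        """Hand-derived: koff/kon for PlGF1 (M-sR1)-L is 3.5e-4/1.5e6 =
        2.33e-10 M, vs the printed 2.3e-11 M; likewise (N1-sR1)-L."""
        disc = {(d.label, d.isoform): d
                for d in validate_kinetics(params.kinetics)}
        for label in ("(M-sR1)-L", "(N1-sR1)-L"):
            d = disc[(label, "PlGF1")]
            assert d.kd_from_rates == pytest.approx(2.333e-10, rel=1e-3)
            assert d.stated_kd == pytest.approx(2.3e-11)

    def test_empty_table(self):
        assert validate_kinetics(BindingParameterTable(entries={})) == []


def test_provenance_retained(params):
    assert "Table" in params.kinetics.get("L-R1", "VEGF165").provenance
    assert params.geometry["calf"].provenance
    assert "supplement" in params.trafficking.provenance
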