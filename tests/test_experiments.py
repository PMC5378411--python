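import numpy as np
import pytest

from vegfpkpd.engine import build_model, solve_steady_state
from vegfpkpd.experiments import (ALL_SYMS, VEGF_SYMS, distribution_summary,
                                  ligation_summary, phospho_summary,
                                  sweep_plgf, sweep_sr1)
from vegfpkpd.parameters import load_parameter_set


@pytest.fixture(scope="module")
def reports(calibrated):
    model, fit = calibrated
    ss = fit.steady_state
    return (distribution_summary(ss), ligation_summary(ss),
            phospho_summary(ss))


def test_fractions_bounded_and_compositions_sum(reports):
    dist, lig, _ph = reports
    for rep in (dist, lig):
        for key, v in rep.outputs.items():
            if v is None or not ("frac" in key or "occupancy" in key):
                continue
            assert -1e-9 <= v <= 1 + 1e-9, key
    # per-breakdown compositions close to 100%
    s = sum(dist[f"fig3a_plasma_free_vegf_frac_{sym}"] for sym in VEGF_SYMS)
    assert s == pytest.approx(1.0, abs=1e-3)
    for rc in ("R1", "R2"):
        s = sum(lig[f"fig4e_{rc}_ligand_frac_{sym}"] or 0.0
                for sym in ALL_SYMS)
        assert s == pytest.approx(1.0, abs=1e-3)
    for sym in ALL_SYMS:
        s = sum(dist[f"fig3b_main_body_{sym}_frac_{k}"]
                for k in ("free", "ec", "matrix", "sr1"))
        assert s == pytest.approx(1.0, abs=1e-3)


def test_sweep_identity_at_unit_multiplier(calibrated):
    model, fit = calibrated
    rep = sweep_plgf(model, fit.steady_state, multipliers=(1.0,))
    for key, v in rep.outputs.items():
        if key.endswith("_rel") and v is not None:
            assert v == 1.0, key  # bit-identical: same solve path


def test_plgf_knockout_leaves_vegf_r1_binding(calibrated):
    model, fit = calibrated
    rep = sweep_plgf(model, fit.steady_state, multipliers=(0.0, 1.0))
    assert rep["0x_r1_plgf_abs"] == pytest.approx(0.0, abs=1e-25)
    assert rep["0x_r1_vegf_rel"] == pytest.approx(1.0, abs=0.1)


def test_sr1_dose_response_monotone_and_r1_biased(calibrated):
    model, fit = calibrated
    mult = (0.0, 0.5, 1.0, 2.0, 5.0)
    rep = sweep_sr1(model, fit.steady_state, multipliers=mult)
    r1 = [rep[f"{v:g}x_r1_ligation_rel"] for v in mult]
    r2 = [rep[f"{v:g}x_r2_ligation_rel"] for v in mult]
    assert all(np.diff(r1) < 0), r1  # more sR1, less R1 ligation
    assert all(np.diff(r2) < 0), r2
    # the trap hits VEGFR1 harder than VEGFR2
    assert r1[-1] < r2[-1]
    assert r1[0] > r2[0]


def test_phospho_ratio_symmetry_under_equal_dephosphorylation(raw_config):
    for site in raw_config["phosphorylation"]["k_dephos_per_s"]:
        for loc in raw_config["phosphorylation"]["k_dephos_per_s"][site]:
            raw_config["phosphorylation"]["k_dephos_per_s"][site][loc] = 0.5
    params = load_parameter_set(raw_config)
    model = build_model(params)
    ss = solve_steady_state(model)
    rep = phospho_summary(ss)
    assert rep["fig5c_ratio_pY1214_pY1175"] == pytest.approx(1.0, rel=1e-9)
    for sym in VEGF_SYMS:
        r = rep[f"fig5c_ratio_pY1214_pY1175_{sym}"]
        if r is not None:
            assert r == pytest.approx(1.0, rel=1e-9)


def test_degenerate_no_ligand_state_reports_absent_not_nan(raw_config):
    raw_config["secretion"]["q_vegf_molec_per_md_s"] = 0.0
    raw_config["secretion"]["q_plgf_molec_per_md_s"] = 0.0
    params = load_parameter_set(raw_config)
    model = build_model(params)
    ss = solve_steady_state(model)
    dist = distribution_summary(ss)
    lig = ligation_summary(ss)
    for rep in (dist, lig):
        for key, v in rep.outputs.items():
            assert v is None or np.isfinite(v), key
    assert dist["fig3a_plasma_free_vegf_frac_V165"] is None
    assert lig["fig4_surface_occupancy_R1"] == pytest.approx(0.0, abs=1e-12)


def test_ordering_contracts_robust_to_parameter_jitter(params):
    """The qualitative contracts (pY1214/pY1175 isoform ordering, monotone
    sR1 dose-response) survive ±10% multiplicative jitter of every
    supplement-derived default (trafficking, dephosphorylation, transport,
    matrix densities)."""
    import copy
    from vegfpkpd.calibration import fit_rates
    rng = np.random.default_rng(42)

    def jitter():
        return float(np.exp(rng.uniform(np.log(0.9), np.log(1.1))))

    raw = copy.deepcopy(params.raw_config)
    for rc in ("R1", "R2", "N1"):
        for status in raw["trafficking"][rc]:
            for k in raw["trafficking"][rc][status]:
                raw["trafficking"][rc][status][k] *= jitter()
    for site in raw["phosphorylation"]["k_dephos_per_s"]:
        for loc in raw["phosphorylation"]["k_dephos_per_s"][site]:
            raw["phosphorylation"]["k_dephos_per_s"][site][loc] *= jitter()
    for fam in raw["transport"]["clearance_per_s"]:
        raw["transport"]["clearance_per_s"][fam] *= jitter()
    for loc in raw["matrix_sites"]["density_M"]:
        raw["matrix_sites"]["density_M"][loc] *= jitter()
    p2 = load_parameter_set(raw)
    model = build_model(p2)
    fit = fit_rates(model)
    ph = phospho_summary(fit.steady_state)
    assert ph["fig5c_ratio_pY1214_pY1175_V121"] < \
        ph["fig5c_ratio_pY1214_pY1175_V165"] < \
        ph["fig5c_ratio_pY1214_pY1175_V189"]
    mult = (0.0, 1.0, 5.0)
    sr = sweep_sr1(model, fit.steady_state, multipliers=mult)
    lig = [sr[f"{v:g}x_r1_ligation_rel"] for v in mult]
    assert all(np.diff(lig) < 0)


def test_mlr_ablation_sign_contracts(params):
    """Four matrix-complex cases, each re-fit to the same targets: the
    baseline self-comparison is exactly zero; keeping sR1-matrix-ligand
    complexes (sR1 Only) stores more total tissue ligand than No MLR; and
    keeping cell-side matrix complexes (Cell Only) raises receptor ligation
    relative to No MLR."""
    from vegfpkpd.experiments import run_mlr_ablation
    reps = run_mlr_ablation(params)
    base = reps["baseline"].outputs
    for k, v in base.items():
        if k.startswith("pct_change"):
            assert v == pytest.approx(0.0, abs=1e-6), k
    assert reps["sr1_only"]["pct_change_total_vegf"] > \
        reps["no_mlr"]["pct_change_total_vegf"]
    assert reps["sr1_only"]["pct_change_total_plgf"] > \
        reps["no_mlr"]["pct_change_total_plgf"]
    for rc in ("r1", "r2"):
        assert reps["cell_only"][f"pct_change_{rc}_ligation_frac"] > \
            reps["no_mlr"][f"pct_change_{rc}_ligation_frac"]


def test_nrp1_routing_rab45_accumulation(calibrated):
    """VEGF121-bound VEGFR2 (no NRP1 bridge) sits in early endosomes more
    than VEGF165-bound VEGFR2, which recycles via Rab11."""
    _model, fit = calibrated
    rep = phospho_summary(fit.steady_state)
    assert rep["fig4c_r2_V121_frac_rab45"] > rep["fig4c_r2_V165_frac_rab45"]
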