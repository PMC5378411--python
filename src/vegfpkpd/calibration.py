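"""Calibration of secretion/production rates and the ±2% sensitivity scan.

Nine rates — q_VEGF, q_PlGF, q_sR1 and the VEGFR1/VEGFR2/NRP1 production
multipliers in each tissue — are fit simultaneously to nine steady-state
targets: free plasma VEGF, PlGF and sR1 concentrations, and the surface
receptor densities per EC in each tissue. The system is strongly nonlinear
(ligand-induced receptor degradation couples every rate to every target),
so the root problem is solved by a damped quasi-Newton iteration on
log-rates with warm-started steady-state solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import Model, SteadyStateResult, build_model, solve_steady_state
from .parameters import (CalibrationTargets, ParameterSet, SecretionConfig,
                         TISSUES)

#: order of unknowns / targets in the root problem
RATE_KEYS = ("q_vegf", "q_plgf", "q_sr1",
             "m_R1_calf", "m_R1_main_body", "m_R2_calf", "m_R2_main_body",
             "m_N1_calf", "m_N1_main_body")
TARGET_KEYS = ("plasma_VEGF_pM", "plasma_PlGF_pM", "plasma_sR1_pM",
               "surf_R1_calf", "surf_R1_main_body", "surf_R2_calf",
               "surf_R2_main_body", "surf_N1_calf", "surf_N1_main_body")

_VEGF_SYMS = ("V121", "V165", "V189")
_PLGF_SYMS = ("P1", "P2")


class CalibrationError(RuntimeError):
    def __init__(self, msg, residuals=None):
        super().__init__(msg)
        self.residuals = residuals


def _secretion_from_vector(base: SecretionConfig, x: np.ndarray) -> SecretionConfig:
    sec = base.copy()
    sec.q_vegf, sec.q_plgf, sec.q_sr1 = x[0], x[1], x[2]
    mult = sec.receptor_production_multiplier
    mult["R1"]["calf"], mult["R1"]["main_body"] = x[3], x[4]
    mult["R2"]["calf"], mult["R2"]["main_body"] = x[5], x[6]
    mult["N1"]["calf"], mult["N1"]["main_body"] = x[7], x[8]
    return sec


def _vector_from_secretion(sec: SecretionConfig) -> np.ndarray:
    m = sec.receptor_production_multiplier
    return np.array([sec.q_vegf, sec.q_plgf, sec.q_sr1,
                     m["R1"]["calf"], m["R1"]["main_body"],
                     m["R2"]["calf"], m["R2"]["main_body"],
                     m["N1"]["calf"], m["N1"]["main_body"]])


def model_outputs(model: Model, ss: SteadyStateResult) -> dict[str, float]:
    """The nine calibration observables of a steady state.

    Plasma targets refer to free ligand / free sR1 (the calibration assumes
    no sR1-bound ligand is detected by the plasma assays).
    """
    reg = model.registry
    vp = model.params.blood.plasma_volume_L
    vegf = plgf = sr1_free = 0.0
    for i in reg.select(compartment="blood"):
        sp = reg.species[i]
        if sp.composition == ("sR1",):
            sr1_free += ss.y[i]
        elif sp.ligand is not None and "sR1" not in sp.composition:
            if sp.ligand in _VEGF_SYMS:
                vegf += ss.y[i]
            else:
                plgf += ss.y[i]
    out = {"plasma_VEGF_pM": vegf / vp * 1e12,
           "plasma_PlGF_pM": plgf / vp * 1e12,
           "plasma_sR1_pM": sr1_free / vp * 1e12}
    for rc in ("R1", "R2", "N1"):
        for tissue in TISSUES:
            out[f"surf_{rc}_{tissue}"] = ss.surface_per_cell(tissue, rc)
    return out


def _targets_vector(targets: CalibrationTargets) -> np.ndarray:
    t = [targets.plasma_free_pM["VEGF"], targets.plasma_free_pM["PlGF"],
         targets.plasma_free_pM["sR1"]]
    for rc in ("R1", "R2", "N1"):
        for tissue in TISSUES:
            t.append(targets.surface_target(rc, tissue))
    return np.array(t)


@dataclass
class FitResult:
    secretion: SecretionConfig
    outputs: dict[str, float]
    residuals: np.ndarray
    iterations: int
    steady_state: SteadyStateResult = field(repr=False, default=None)


def fit_rates(model_or_params, targets: CalibrationTargets | None = None,
              rel_tol: float = 0.005, damping: float = 0.5,
              max_iter: int = 60, x0: SecretionConfig | None = None) -> FitResult:
    """Fit the 9 secretion/production rates to the 9 steady-state targets.

    Deterministic: damped Newton on log-rates, fixed start at the config's
    rates (or unit multipliers), finite-difference Jacobian, warm-started
    nested steady-state solves.
    """
    if isinstance(model_or_params, Model):
        model = model_or_params
    else:
        model = build_model(model_or_params)
    params: ParameterSet = model.params
    targets = targets or params.targets
    tvec = _targets_vector(targets)
    base = (x0 or params.secretion).copy()

    # zero targets force the corresponding rate to zero and leave the root
    # problem (ligand rates only; receptor targets are physically positive)
    x = _vector_from_secretion(base)
    fixed_zero = np.zeros(9, dtype=bool)
    for k in range(3):
        if tvec[k] == 0.0:
            fixed_zero[k] = True
            x[k] = 0.0
    x[(x <= 0) & ~fixed_zero] = 1.0
    free = ~fixed_zero

    warm = {"y": None}

    def outputs_for(xv: np.ndarray) -> np.ndarray:
        model.set_secretion(_secretion_from_vector(base, xv))
        ss = solve_steady_state(model, y0=warm["y"])
        warm["y"] = ss.y
        outputs_for.last_ss = ss
        o = model_outputs(model, ss)
        return np.array([o[k] for k in TARGET_KEYS])

    def residual(xv: np.ndarray) -> np.ndarray:
        o = outputs_for(xv)
        r = np.zeros(9)
        for k in range(9):
            if fixed_zero[k]:
                continue
            r[k] = np.log(max(o[k], 1e-300) / tvec[k])
        return r

    r = residual(x)
    best = (np.max(np.abs(np.expm1(r[free]))), x.copy(), r.copy())
    it = 0
    for it in range(1, max_iter + 1):
        rel = np.max(np.abs(np.expm1(r[free])))
        if rel < rel_tol:
            break
        nfree = int(np.sum(free))
        J = np.zeros((nfree, nfree))
        h = 0.02
        free_idx = np.where(free)[0]
        for col, k in enumerate(free_idx):
            xp = x.copy()
            xp[k] = x[k] * np.exp(h)
            rp = residual(xp)
            J[:, col] = (rp[free_idx] - r[free_idx]) / h
        try:
            step = np.linalg.solve(J, -r[free_idx])
        except np.linalg.LinAlgError:
            raise CalibrationError("singular calibration Jacobian",
                                   residuals=r) from None
        step = np.clip(step, -2.0, 2.0)  # at most e^2 per iteration
        x_new = x.copy()
        x_new[free_idx] = x[free_idx] * np.exp(damping * step)
        r_new = residual(x_new)
        x, r = x_new, r_new
        rel_new = np.max(np.abs(np.expm1(r[free])))
        if rel_new < best[0]:
            best = (rel_new, x.copy(), r.copy())
    else:
        rel = np.max(np.abs(np.expm1(r[free])))
        if rel >= rel_tol:
            raise CalibrationError(
                f"calibration did not converge: max relative residual "
                f"{best[0]:.3%}", residuals=best[2])
    o = outputs_for(x)
    ss = outputs_for.last_ss
    return FitResult(secretion=_secretion_from_vector(base, x),
                     outputs=dict(zip(TARGET_KEYS, o)),
                     residuals=r, iterations=it, steady_state=ss)


def sensitivity_scan(model: Model, ss: SteadyStateResult,
                     delta: float = 0.02) -> pd.DataFrame:
    """±delta one-at-a-time perturbation of each secretion/production rate.

    Returns (output x input) matrix of |% change in output| per % change in
    input, averaged over the + and − perturbations.
    """
    base_sec = model.params.secretion.copy()
    x0 = _vector_from_secretion(base_sec)
    base_out = np.array([model_outputs(model, ss)[k] for k in TARGET_KEYS])
    mat = np.zeros((9, 9))
    if delta == 0.0:
        return pd.DataFrame(mat, index=TARGET_KEYS, columns=RATE_KEYS)
    for j in range(9):
        changes = []
        for sign in (+1.0, -1.0):
            x = x0.copy()
            x[j] = x0[j] * (1.0 + sign * delta)
            model.set_secretion(_secretion_from_vector(base_sec, x))
            pss = solve_steady_state(model, y0=ss.y)
            out = np.array([model_outputs(model, pss)[k] for k in TARGET_KEYS])
            changes.append(np.abs(out / base_out - 1.0))
        mat[:, j] = 0.5 * (changes[0] + changes[1]) / delta
    model.set_secretion(base_sec)
    return pd.DataFrame(mat, index=TARGET_KEYS, columns=RATE_KEYS)
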