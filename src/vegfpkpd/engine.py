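"""Right-hand-side assembly and steady-state solution of the full model.

The state vector holds amounts (moles) of every species instance. The
chemistry is bilinear (mass-action binding), everything else — trafficking,
transport, secretion, production, clearance — is affine, so

    dy/dt = c + L y + S f(y),      f_r(y) = khat_r y_a y_b - koff_r y_p

with a sparse stoichiometry matrix S and an analytic Jacobian. Steady
states are found by damped Newton iteration (warm-startable), falling back
to stiff time integration (LSODA) from cold starts. Matrix binding sites
are conserved quantities: their Newton residual rows are replaced by the
site-conservation constraints.

Phospho amounts are passive companions of their VEGFR2 carriers: carrier
dynamics never depend on them, so at steady state they satisfy a small
linear system solved exactly after the chemistry has converged.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sps
from scipy.integrate import solve_ivp

from .network import AblationFlags, BASELINE, Reaction, build_network
from .parameters import N_AVOGADRO, ParameterSet, SecretionConfig
from .species import Species, SpeciesRegistry, comp
from .trafficking import (ConstProcess, LinearProcess, PhosphoSystem,
                          build_secretion_processes,
                          build_trafficking_processes,
                          no_ligand_pool_distribution)
from .transport import build_transport_processes

#: default absolute tolerance: 1e-3 molecules
ATOL_MOL = 1e-3 / N_AVOGADRO
STEADY_TOL = 1e-9


class ConvergenceError(RuntimeError):
    def __init__(self, msg, residual=None):
        super().__init__(msg)
        self.residual = residual


class Model:
    """Compiled ODE model: registry + reactions + affine processes."""

    def __init__(self, params: ParameterSet, registry: SpeciesRegistry,
                 reactions: list[Reaction],
                 linear_processes: list[LinearProcess],
                 const_processes: list[ConstProcess],
                 conservation: list[tuple[int, list[int], float]],
                 options: AblationFlags = BASELINE):
        self.params = params
        self.registry = registry
        self.reactions = reactions
        self.linear_processes = linear_processes
        self.const_processes = const_processes
        #: (free-site index, member indices incl. free site, conserved total)
        self.conservation = conservation
        self.options = options
        self.n = len(registry)
        self._compile()
        self.phospho = PhosphoSystem(self)

    # -- compilation -------------------------------------------------------

    def _compile(self):
        n, nr = self.n, len(self.reactions)
        self.ia = np.array([r.a for r in self.reactions], dtype=int)
        self.ib = np.array([r.b for r in self.reactions], dtype=int)
        self.ip = np.array([r.product for r in self.reactions], dtype=int)
        self.khat = np.array([r.khat for r in self.reactions])
        self.koff = np.array([r.koff for r in self.reactions])
        rows = np.concatenate([self.ia, self.ib, self.ip])
        cols = np.concatenate([np.arange(nr)] * 3)
        data = np.concatenate([-np.ones(nr), -np.ones(nr), np.ones(nr)])
        self.S = sps.csr_matrix((data, (rows, cols)), shape=(n, nr))
        trip = []
        for p in self.linear_processes:
            trip.append((p.src, p.src, -p.rate))
            if p.dst is not None:
                trip.append((p.dst, p.src, p.rate))
        if trip:
            r, c, d = zip(*trip)
            self.L = sps.csr_matrix((d, (r, c)), shape=(n, n))
        else:
            self.L = sps.csr_matrix((n, n))
        self._rebuild_const()
        # fixed structure of the flux Jacobian (nr x n)
        self._jf_rows = np.concatenate([np.arange(nr)] * 3)
        self._jf_cols = np.concatenate([self.ia, self.ib, self.ip])

    def _rebuild_const(self):
        c = np.zeros(self.n)
        for p in self.const_processes:
            c[p.dst] += p.rate
        self.c = c

    def set_secretion(self, secretion: SecretionConfig):
        """Swap secretion/production rates without recompiling the network."""
        self.params = self.params.with_secretion(secretion)
        keep = [p for p in self.const_processes
                if p.kind not in ("secretion", "production")]
        _, prod = build_trafficking_processes(self.params, self.registry)
        sec = build_secretion_processes(self.params, self.registry)
        self.const_processes = keep + prod + sec
        self._rebuild_const()

    # -- dynamics ----------------------------------------------------------

    def fluxes(self, y: np.ndarray) -> np.ndarray:
        return self.khat * y[self.ia] * y[self.ib] - self.koff * y[self.ip]

    def rhs(self, y: np.ndarray) -> np.ndarray:
        return self.c + self.L @ y + self.S @ self.fluxes(y)

    def jac(self, y: np.ndarray) -> sps.csr_matrix:
        nr = len(self.reactions)
        data = np.concatenate([self.khat * y[self.ib],
                               self.khat * y[self.ia],
                               -self.koff])
        jf = sps.csr_matrix((data, (self._jf_rows, self._jf_cols)),
                            shape=(nr, self.n))
        return self.L + self.S @ jf

    def normalized_residual(self, y: np.ndarray, atol: float = ATOL_MOL) -> float:
        return float(np.max(np.abs(self.rhs(y)) / (np.abs(y) + atol)))

    def is_steady(self, y: np.ndarray, tol: float = 1e-6) -> bool:
        return self.normalized_residual(y) < tol

    # -- initial condition -------------------------------------------------

    def default_initial_state(self) -> np.ndarray:
        """No-ligand-like start: matrix sites free, receptors at their
        closed-form no-ligand pool distribution, everything else zero."""
        y0 = np.zeros(self.n)
        for free_idx, _, total in self.conservation:
            y0[free_idx] = total
        for tissue, geom in self.params.geometry.items():
            for rc in ("R1", "R2", "N1"):
                rates = self.params.trafficking.rates_for(rc, False, False)
                target = self.params.targets.surface_target(rc, tissue)
                mult = self.params.secretion.receptor_production_multiplier[rc][tissue]
                surf = target * mult * geom.ec_count / N_AVOGADRO
                e4, e11 = no_ligand_pool_distribution(rates)
                y0[self.registry.idx(Species(tissue, "surface", comp(rc)))] = surf
                y0[self.registry.idx(Species(tissue, "rab45", comp(rc)))] = e4 * surf
                y0[self.registry.idx(Species(tissue, "rab11", comp(rc)))] = e11 * surf
        return y0

    # -- views -------------------------------------------------------------

    def amount(self, y: np.ndarray, **criteria) -> float:
        return float(sum(y[i] for i in self.registry.select(**criteria)))

    def conc_pM_fluid(self, y: np.ndarray, tissue: str, **criteria) -> float:
        v = (self.params.blood.plasma_volume_L if tissue == "blood"
             else self.params.geometry[tissue].available_fluid_volume_L)
        loc = "plasma" if tissue == "blood" else "fluid"
        a = self.amount(y, compartment=tissue, location=loc, **criteria)
        return a / v * 1e12

    def surface_per_cell(self, y: np.ndarray, tissue: str, receptor: str) -> float:
        idxs = self.registry.select(compartment=tissue,
                                    location=("surface", "ebm_surface"),
                                    contains=receptor)
        a = sum(y[i] for i in idxs)
        return a * N_AVOGADRO / self.params.geometry[tissue].ec_count


@dataclass
class SteadyStateResult:
    y: np.ndarray
    phospho: dict[str, np.ndarray]  # site -> amounts over model.phospho.carriers
    model: Model = field(repr=False, default=None)
    residual_norm: float = np.nan
    method: str = ""
    time_integrated: float = 0.0
    wall_time_s: float = 0.0
    params_hash: str = ""

    @property
    def registry(self) -> SpeciesRegistry:
        return self.model.registry

    def amount(self, **criteria) -> float:
        return self.model.amount(self.y, **criteria)

    def conc_pM_fluid(self, tissue: str, **criteria) -> float:
        return self.model.conc_pM_fluid(self.y, tissue, **criteria)

    def surface_per_cell(self, tissue: str, receptor: str) -> float:
        return self.model.surface_per_cell(self.y, tissue, receptor)

    def phospho_amount(self, site: str, **criteria) -> float:
        sel = set(self.model.registry.select(**criteria))
        return float(sum(p for ci, p in zip(self.model.phospho.carriers,
                                            self.phospho[site]) if ci in sel))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        params = self.model.params
        for i, sp in enumerate(self.registry.species):
            if sp.compartment == "blood":
                conc = self.y[i] / params.blood.plasma_volume_L * 1e12
                unit = "pM_plasma"
            else:
                conc = self.y[i] / params.geometry[sp.compartment].total_volume_L \
                    * 1e12
                unit = "pM_tissue"
            rows.append({"compartment": sp.compartment, "location": sp.location,
                         "species": "·".join(sp.composition),
                         "amount_mol": self.y[i], "concentration": conc,
                         "units": unit})
        return pd.DataFrame(rows)


def build_model(params: ParameterSet,
                options: AblationFlags | None = None) -> Model:
    """Assemble the full whole-body model from a parameter set."""
    options = options or BASELINE
    net = build_network(params, options=options)
    registry = net.registry
    linear, prod = build_trafficking_processes(params, registry)
    linear = linear + build_transport_processes(params, registry)
    const = prod + build_secretion_processes(params, registry)
    conservation = []
    for tissue in params.geometry:
        for loc in ("ecm", "ebm", "pbm"):
            free_idx = registry.idx(Species(tissue, loc, comp("M")))
            locs = (loc, "ebm_surface") if loc == "ebm" else (loc,)
            members = registry.select(compartment=tissue, location=locs,
                                      contains="M")
            total = (params.matrix_sites.density_M[loc]
                     * params.geometry[tissue].matrix_location_volume_L(loc))
            conservation.append((free_idx, members, total))
    return Model(params, registry, net.reactions, linear, const,
                 conservation, options)


def assemble_rhs(model: Model):
    """Side-effect-free rhs over the carrier state vector, plus its sparsity
    pattern (for external integrators)."""
    def rhs(t, y):
        return model.rhs(y)
    pattern = (model.jac(np.ones(model.n)) != 0)
    return rhs, pattern


# --- steady-state solving -------------------------------------------------

def _newton(model: Model, y0: np.ndarray, max_iter: int = 80,
            tol: float = STEADY_TOL) -> tuple[np.ndarray, bool]:
    cons_rows = {free: (members, total)
                 for free, members, total in model.conservation}
    scale = np.maximum(np.abs(y0), ATOL_MOL)

    def residual(y):
        r = model.rhs(y)
        for free, (members, total) in cons_rows.items():
            r[free] = sum(y[m] for m in members) - total
        return r

    def jac(y):
        J = model.jac(y).toarray()
        for free, (members, _) in cons_rows.items():
            J[free, :] = 0.0
            for m in members:
                J[free, m] = 1.0
        return J

    y = y0.copy()
    r = residual(y)
    rn = np.max(np.abs(r) / np.maximum(scale, np.abs(y) + ATOL_MOL))
    for _ in range(max_iter):
        if not np.isfinite(rn):
            return y, False
        try:
            dy = np.linalg.solve(jac(y), -r)
        except np.linalg.LinAlgError:
            return y, False
        t_step, ok = 1.0, False
        for _ in range(30):
            y_new = np.maximum(y + t_step * dy, 0.0)
            r_new = residual(y_new)
            rn_new = np.max(np.abs(r_new)
                            / np.maximum(scale, np.abs(y_new) + ATOL_MOL))
            if rn_new < rn or rn_new < tol:
                ok = True
                break
            t_step *= 0.5
        if not ok:
            return y, False
        y, r, rn = y_new, r_new, rn_new
        if model.normalized_residual(y) < tol and rn < max(tol, 1e-7):
            return y, True
    return y, model.normalized_residual(y) < tol


def solve_steady_state(model: Model, y0: np.ndarray | None = None,
                       rtol: float = 1e-6, steady_tol: float = STEADY_TOL,
                       max_time: float = 1e8,
                       require_converged: bool = True) -> SteadyStateResult:
    """Find the steady state: damped Newton from a warm start, with stiff
    time integration (LSODA) as the globalizer from cold starts."""
    t_start = time.perf_counter()
    cold = y0 is None
    y = model.default_initial_state() if cold else np.asarray(y0, float).copy()
    method = "newton"
    integrated = 0.0

    y_n, ok = _newton(model, y)
    if not ok:
        method = "lsoda+newton"
        t_end = 1e5
        y_run = y.copy()
        while integrated < max_time:
            sol = solve_ivp(lambda t, z: model.rhs(z), (0.0, t_end), y_run,
                            method="LSODA", jac=lambda t, z: model.jac(z).toarray(),
                            rtol=rtol, atol=ATOL_MOL)
            if not sol.success:
                raise ConvergenceError(
                    f"LSODA failed: {sol.message}",
                    residual=model.normalized_residual(y_run))
            y_run = np.maximum(sol.y[:, -1], 0.0)
            integrated += t_end
            y_n, ok = _newton(model, y_run)
            if ok:
                break
            t_end *= 10.0
        else:
            ok = False
    if not ok:
        resid = model.normalized_residual(y_n)
        if require_converged and resid > 1e-6:
            raise ConvergenceError(
                f"no steady state within {max_time:.0e} s of simulated time; "
                f"normalized residual {resid:.2e}", residual=resid)
    y_ss = np.maximum(y_n, 0.0)
    resid = model.normalized_residual(y_ss)
    phospho = model.phospho.steady_state(y_ss)
    return SteadyStateResult(
        y=y_ss, phospho=phospho, model=model, residual_norm=resid,
        method=method, time_integrated=integrated,
        wall_time_s=time.perf_counter() - t_start,
        params_hash=model.params.content_hash())


def simulate(model: Model, y0: np.ndarray, t_span: tuple[float, float],
             rtol: float = 1e-6, **kw):
    """Transient integration of the carrier block (LSODA)."""
    return solve_ivp(lambda t, y: model.rhs(y), t_span, y0, method="LSODA",
                     jac=lambda t, y: model.jac(y).toarray(), rtol=rtol,
                     atol=ATOL_MOL, **kw)
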