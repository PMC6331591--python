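"""Finite-volume solver for drug transport through gel, epithelium and
stroma, coupled to a well-mixed blood compartment and local metabolite
(diphosphate) kinetics.

Model
-----
Let c(x, t) be the drug concentration in a stack of layers.  Within each
layer

    dc/dt = D d2c/dx2 - k c

with layer-specific diffusivity D and first-order sink k (dilution in the
gel, transport to blood in the stroma).  At layer interfaces the
concentration jumps by the partition coefficient (c_down = phi * c_up)
while the diffusive flux is continuous.  Both outer faces are zero-flux
(luminal symmetry plane at the top, deep tissue at the bottom), unless a
Dirichlet surface condition is requested.

The jump conditions are handled by solving for the continuous potential
u = c / S, where S is the cumulative solubility of a layer (product of
the partition coefficients crossed to reach it).  The system becomes a
heterogeneous-capacity diffusion problem

    S du/dt = d/dx (D S du/dx) - k S u

which a cell-centred finite volume with harmonic-mean face conductances
discretizes conservatively.  Time stepping is Crank-Nicolson with a short
backward-Euler start-up to damp oscillations from discontinuous initial
data.

The blood compartment obeys

    VB dCB/dt = kB * A * integral(c_stroma dx) - kL * VB * CB

with coated area A = area_factor * W * L; it is driven one-way by the
stromal field and integrated with the trapezoidal rule so the discrete
mass ledger closes to round-off.

The metabolite field (per tissue volume) follows, at every tissue node,

    dc_m/dt = k_on * relu(c_eq - c_m) - k_off * relu(c_m - c_eq),
    c_eq = vf * n_eq * c,

i.e. formation drives the metabolite toward its equilibrium ratio with the
parent drug on the fast 1/k_on time scale, while elimination below
equilibrium proceeds on the slow 1/k_off time scale (long intracellular
half-life).  Formation does not deplete the parent drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .params import Discretization, ParamError, TransportParams

__all__ = [
    "Layer",
    "SimulationResult",
    "SolverError",
    "simulate",
    "solve_multilayer",
    "volume_average",
    "mass_balance",
    "COMPARTMENTS",
    "SPECIES",
]

SECONDS_PER_HOUR = 3600.0
UM_PER_CM = 1e4
ML_PER_L = 1e3

COMPARTMENTS = ("gel", "epithelium", "stroma", "blood")
SPECIES = ("TFV", "TFV-DP")

# Relative negativity beyond which the step is declared unstable rather
# than clipped.
_NEG_TOL = 1e-6


class SolverError(RuntimeError):
    """Raised when the linear solve diverges or concentrations blow up."""


@dataclass(frozen=True)
class Layer:
    """One slab of the composite diffusion domain (low-level API)."""

    name: str
    D_cm2_s: float        # diffusivity, cm^2/s
    thickness_um: float   # slab thickness, um
    n_cells: int
    solubility: float = 1.0   # cumulative partition factor vs. first layer
    sink_per_hr: float = 0.0  # first-order loss rate, 1/hr
    c_init: float = 0.0       # initial concentration, ng/mL

    def __post_init__(self) -> None:
        if self.D_cm2_s <= 0 or self.thickness_um <= 0 or self.solubility <= 0:
            raise ParamError(f"layer {self.name!r}: D, thickness and "
                             "solubility must be positive")
        if self.n_cells < 2:
            raise ParamError(f"layer {self.name!r}: need >= 2 cells")
        if self.sink_per_hr < 0 or self.c_init < 0:
            raise ParamError(f"layer {self.name!r}: sink and initial "
                             "concentration must be non-negative")

    @property
    def dx_cm(self) -> float:
        return self.thickness_um / UM_PER_CM / self.n_cells


@dataclass
class SimulationResult:
    """Space-time concentration fields from one model run.

    ``grids`` maps layer name to cell-centre coordinates in um measured
    from the luminal symmetry plane.  Concentration arrays are
    (n_times, n_cells); ``blood_tfv`` is (n_times,).  ``cum_dilution_ng``
    and ``cum_clearance_ng`` are the cumulative drug masses lost to gel
    dilution and to clearance from blood, accumulated with the same
    quadrature as the time-stepping scheme.
    """

    times: np.ndarray
    grids: dict[str, np.ndarray]
    tfv_gel: np.ndarray
    tfv_epi: np.ndarray
    tfv_stroma: np.ndarray
    dp_epi: np.ndarray
    dp_stroma: np.ndarray
    blood_tfv: np.ndarray
    cum_dilution_ng: np.ndarray
    cum_clearance_ng: np.ndarray
    params: TransportParams
    disc: Discretization
    cell_widths_um: dict[str, float] = field(default_factory=dict)

    def field_for(self, compartment: str, species: str) -> np.ndarray:
        """Return the stored field for a compartment/species pair."""
        key = (compartment, species)
        table = {
            ("gel", "TFV"): self.tfv_gel,
            ("epithelium", "TFV"): self.tfv_epi,
            ("stroma", "TFV"): self.tfv_stroma,
            ("epithelium", "TFV-DP"): self.dp_epi,
            ("stroma", "TFV-DP"): self.dp_stroma,
            ("blood", "TFV"): self.blood_tfv,
        }
        if key not in table:
            raise ValueError(
                f"species {species!r} is not defined in compartment "
                f"{compartment!r}")
        return table[key]


class _ComposedGrid:
    """Capacity/conductance assembly for the composite finite volume."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)
        dx, S, D_hr, sink, c0 = [], [], [], [], []
        self.slices: dict[str, slice] = {}
        start = 0
        for lay in self.layers:
            n = lay.n_cells
            dx += [lay.dx_cm] * n
            S += [lay.solubility] * n
            D_hr += [lay.D_cm2_s * SECONDS_PER_HOUR] * n
            sink += [lay.sink_per_hr] * n
            c0 += [lay.c_init] * n
            self.slices[lay.name] = slice(start, start + n)
            start += n
        self.n = start
        self.dx = np.array(dx)
        self.S = np.array(S)
        self.D = np.array(D_hr)
        self.sink = np.array(sink)
        self.c_init = np.array(c0)
        # capacity per unit area: S * dx
        self.beta = self.S * self.dx
        # interior face conductances (harmonic mean of half-cell resistances)
        r = self.dx / (2.0 * self.D * self.S)
        self.g_face = 1.0 / (r[:-1] + r[1:])

    def operator(self, left_bc: tuple[str, float]) -> tuple[sp.csr_matrix, np.ndarray]:
        """Tridiagonal transport operator T and constant source s such that
        beta * du/dt = T u + s."""
        n = self.n
        main = np.zeros(n)
        lower = np.zeros(n - 1)
        upper = np.zeros(n - 1)
        g = self.g_face
        main[:-1] -= g
        main[1:] -= g
        lower[:] = g
        upper[:] = g
        s = np.zeros(n)
        kind, value = left_bc
        if kind == "dirichlet":
            g0 = 2.0 * self.D[0] * self.S[0] / self.dx[0]
            u_bc = value / self.S[0]
            main[0] -= g0
            s[0] += g0 * u_bc
        elif kind != "no_flux":
            raise ParamError(f"unknown boundary condition {kind!r}")
        main -= self.sink * self.beta
        T = sp.diags([lower, main, upper], [-1, 0, 1], format="csc")
        return T, s


def _step_matrices(grid: _ComposedGrid, T: sp.csc_matrix, dt: float):
    """Prefactored Crank-Nicolson and backward-Euler step operators."""
    B = sp.diags(grid.beta / dt)
    lu_cn = spla.splu((B - 0.5 * T).tocsc())
    rhs_cn = (B + 0.5 * T).tocsr()
    B2 = sp.diags(grid.beta / (0.5 * dt))
    lu_be = spla.splu((B2 - T).tocsc())
    return lu_cn, rhs_cn, lu_be, B2


def solve_multilayer(
    layers: Sequence[Layer],
    dt: float,
    output_times: np.ndarray,
    left_bc: tuple[str, float] = ("no_flux", 0.0),
    n_startup_steps: int = 2,
) -> tuple[np.ndarray, dict[str, np.ndarray], "_ComposedGrid", np.ndarray]:
    """Integrate the composite diffusion system (low-level entry point).

    Returns ``(times, fields, grid, sink_integrals)`` where ``fields`` maps
    layer name to a (n_times, n_cells) concentration array and
    ``sink_integrals`` maps layer name to the cumulative sink loss per unit
    area (ng/cm^2) at the output times.
    """
    output_times = np.asarray(output_times, dtype=float)
    grid = _ComposedGrid(layers)
    T, s = grid.operator(left_bc)
    lu_cn, rhs_cn, lu_be, B2 = _step_matrices(grid, T, dt)

    out_steps = np.round(output_times / dt).astype(int)
    if np.max(np.abs(out_steps * dt - output_times)) > 1e-6:
        raise ParamError("output_times must align with multiples of dt")
    n_steps = out_steps[-1]

    u = grid.c_init / grid.S
    c_scale = max(np.max(np.abs(grid.c_init)),
                  abs(left_bc[1]) if left_bc[0] == "dirichlet" else 0.0, 1.0)

    n_out = output_times.size
    fields = {lay.name: np.empty((n_out, lay.n_cells)) for lay in layers}
    sink_cum = {lay.name: np.zeros(n_out) for lay in layers}
    sink_run = {lay.name: 0.0 for lay in layers}
    # per-step sink increments also returned densely for blood coupling
    stroma_like = {lay.name for lay in layers if lay.sink_per_hr > 0}

    out_map = {step: i for i, step in enumerate(out_steps)}

    def record(step_idx: int, u_now: np.ndarray) -> None:
        i = out_map[step_idx]
        c = u_now * grid.S
        for lay in layers:
            sl = grid.slices[lay.name]
            fields[lay.name][i] = np.maximum(c[sl], 0.0)
            sink_cum[lay.name][i] = sink_run[lay.name]

    if 0 in out_map:
        record(0, u)

    step_sink_increments = {lay.name: np.zeros(n_steps) for lay in layers}

    for step in range(1, n_steps + 1):
        u_old = u
        if step <= n_startup_steps:
            # two backward-Euler half steps (Rannacher start-up)
            u_half = lu_be.solve(B2 @ u_old + s)
            u = lu_be.solve(B2 @ u_half + s)
            # implicit-Euler sink quadrature matching the scheme
            u_quad = 0.5 * (u_half + u)
        else:
            u = lu_cn.solve(rhs_cn @ u_old + s)
            u_quad = 0.5 * (u_old + u)

        umin = u.min()
        if not np.all(np.isfinite(u)) or umin < -_NEG_TOL * c_scale:
            raise SolverError(
                f"solver failure at time step {step} (t = {step * dt:.4g} "
                f"hr): min concentration {umin * grid.S.min():.3g}")
        np.clip(u, 0.0, None, out=u)

        for lay in layers:
            if lay.sink_per_hr == 0.0:
                continue
            sl = grid.slices[lay.name]
            inc = lay.sink_per_hr * dt * float(
                np.sum(grid.beta[sl] * u_quad[sl]))
            sink_run[lay.name] += inc
            step_sink_increments[lay.name][step - 1] = inc

        if step in out_map:
            record(step, u)

    times = output_times.copy()
    # stash per-step increments for callers that integrate coupled ODEs
    grid.step_sink_increments = step_sink_increments  # type: ignore[attr-defined]
    grid.out_steps = out_steps  # type: ignore[attr-defined]
    return times, fields, grid, sink_cum


def _metabolite_series(
    c_field: np.ndarray, times: np.ndarray, vf: float, n_eq: float,
    k_on: float, k_off: float, dt: float,
) -> np.ndarray:
    """Integrate the local metabolite ODE driven by the stored parent field.

    The rate law is asymmetric first-order relaxation toward the
    equilibrium level c_eq = vf * n_eq * c_parent: rate constant k_on when
    below equilibrium (formation) and k_off when above (elimination).  The
    parent field is sampled at ``times``; classical RK4 with linear
    interpolation of the drive within each step is ample, since the output
    grid already resolves the 1/k_on time scale (k_on * h << 1).
    """
    out = np.zeros_like(c_field)
    keq = vf * n_eq

    def rate(cm: np.ndarray, ceq: np.ndarray) -> np.ndarray:
        gap = ceq - cm
        return np.where(gap >= 0.0, k_on * gap, k_off * gap)

    for i in range(1, times.size):
        h = times[i] - times[i - 1]
        ceq0 = keq * c_field[i - 1]
        ceq1 = keq * c_field[i]
        ceq_mid = 0.5 * (ceq0 + ceq1)
        y = out[i - 1]
        k1 = rate(y, ceq0)
        k2 = rate(y + 0.5 * h * k1, ceq_mid)
        k3 = rate(y + 0.5 * h * k2, ceq_mid)
        k4 = rate(y + h * k3, ceq1)
        out[i] = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return np.maximum(out, 0.0)


def simulate(params: TransportParams, disc: Discretization) -> SimulationResult:
    """Run the full gel/epithelium/stroma/blood model.

    Raises
    ------
    ParamError
        If the parameters or discretization are invalid.
    SolverError
        If the linear solve produces non-finite values or concentrations
        drop below the negativity tolerance (message names the time step).
    """
    if not isinstance(params, TransportParams):
        raise ParamError("params must be a TransportParams instance")
    if not isinstance(disc, Discretization):
        raise ParamError("disc must be a Discretization instance")

    layers = [
        Layer("gel", params.Dg, params.hg,
              disc.n_cells(params.hg, disc.dx_gel),
              solubility=1.0, sink_per_hr=params.kD, c_init=params.C0),
        Layer("epithelium", params.De, params.he,
              disc.n_cells(params.he, disc.dx_epi),
              solubility=params.phi_ge),
        Layer("stroma", params.Ds, params.hs,
              disc.n_cells(params.hs, disc.dx_stroma),
              solubility=params.phi_ge * params.phi_es,
              sink_per_hr=params.kB),
    ]
    times, fields, grid, sink_cum = solve_multilayer(
        layers, disc.dt, disc.output_times)

    area_cm2 = params.area_factor * params.W * params.L
    vb_ml = params.VB * ML_PER_L

    # Blood: driven by the per-step stromal sink mass, trapezoidal in the
    # clearance term so the ledger closes exactly.
    inc = grid.step_sink_increments["stroma"] * area_cm2  # ng per step
    n_steps = inc.size
    dt = disc.dt
    cb = 0.0
    cleared = 0.0
    out_steps = grid.out_steps
    blood = np.zeros(times.size)
    clearance_cum = np.zeros(times.size)
    out_map = {step: i for i, step in enumerate(out_steps)}
    if 0 in out_map:
        blood[out_map[0]] = 0.0
    a = 1.0 + 0.5 * dt * params.kL
    b = 1.0 - 0.5 * dt * params.kL
    for step in range(1, n_steps + 1):
        cb_new = (b * cb + inc[step - 1] / vb_ml) / a
        cleared += params.kL * vb_ml * 0.5 * dt * (cb + cb_new)
        cb = cb_new
        if step in out_map:
            i = out_map[step]
            blood[i] = cb
            clearance_cum[i] = cleared

    dp_epi = _metabolite_series(
        fields["epithelium"], times, params.vf_e, params.n_eq,
        params.k_on, params.k_off, dt)
    dp_stroma = _metabolite_series(
        fields["stroma"], times, params.vf_s, params.n_eq,
        params.k_on, params.k_off, dt)

    grids = {}
    x0 = 0.0
    widths = {}
    for lay in layers:
        dx_um = lay.thickness_um / lay.n_cells
        grids[lay.name] = x0 + dx_um * (np.arange(lay.n_cells) + 0.5)
        widths[lay.name] = dx_um
        x0 += lay.thickness_um

    return SimulationResult(
        times=times,
        grids=grids,
        tfv_gel=fields["gel"],
        tfv_epi=fields["epithelium"],
        tfv_stroma=fields["stroma"],
        dp_epi=dp_epi,
        dp_stroma=dp_stroma,
        blood_tfv=blood,
        cum_dilution_ng=sink_cum["gel"] * area_cm2,
        cum_clearance_ng=clearance_cum,
        params=params,
        disc=disc,
        cell_widths_um=widths,
    )


def volume_average(result: SimulationResult, compartment: str,
                   species: str = "TFV") -> np.ndarray:
    """Volume-averaged concentration time series for one compartment.

    For tissue/gel layers this is the cell-width-weighted spatial mean of
    the stored field (exact for the uniform grids produced by
    :func:`simulate`); for blood it returns the stored series.
    """
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}; expected one "
                         f"of {COMPARTMENTS}")
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of "
                         f"{SPECIES}")
    arr = result.field_for(compartment, species)
    if compartment == "blood":
        return arr.copy()
    return arr.mean(axis=1)


def mass_balance(result: SimulationResult, params: TransportParams | None = None):
    """Drug-mass ledger at every output time.

    Returns a dict of arrays (ng): mass in gel, epithelium, stroma and
    blood, the cumulative dilution and clearance losses, their total, the
    initial gel mass, and the relative closure error.  Metabolite mass is
    excluded (formation is modelled as non-depleting).
    """
    p = params if params is not None else result.params
    area_cm2 = p.area_factor * p.W * p.L

    def layer_mass(field: np.ndarray, name: str) -> np.ndarray:
        dx_cm = result.cell_widths_um[name] / UM_PER_CM
        return area_cm2 * dx_cm * field.sum(axis=1)

    gel = layer_mass(result.tfv_gel, "gel")
    epi = layer_mass(result.tfv_epi, "epithelium")
    stroma = layer_mass(result.tfv_stroma, "stroma")
    blood = result.blood_tfv * p.VB * ML_PER_L
    total = (gel + epi + stroma + blood
             + result.cum_dilution_ng + result.cum_clearance_ng)
    hg_cm = p.hg / UM_PER_CM
    initial = p.C0 * area_cm2 * hg_cm
    denom = initial if initial > 0 else 1.0
    return {
        "times": result.times.copy(),
        "gel_ng": gel,
        "epithelium_ng": epi,
        "stroma_ng": stroma,
        "blood_ng": blood,
        "dilution_loss_ng": result.cum_dilution_ng.copy(),
        "clearance_loss_ng": result.cum_clearance_ng.copy(),
        "total_ng": total,
        "initial_ng": initial,
        "relative_error": (total - initial) / denom,
    }
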