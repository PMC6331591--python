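"""Physical parameters and solver discretization settings.

Units follow the conventions of the source data tables: concentrations in
ng/mL, lengths of tissue layers in micrometres, canal dimensions in cm,
diffusivities in cm^2/s, first-order rate constants in 1/hr, blood volume
of distribution in litres.  Conversion to the internal solver unit system
(cm / hr / ng/mL) is centralized in :mod:`mucosim.transport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TransportParams",
    "Discretization",
    "default_params",
    "default_discretization",
    "ParamError",
]


class ParamError(ValueError):
    """Raised when a parameter set violates its physical constraints."""


# Default levels of the three host-variability parameters.  The middle
# entry of each list is the standard (single-run) value.
HE_LEVELS_UM = (100.0, 175.0, 250.0, 325.0, 400.0)
HE_LEVELS_7_UM = (100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0)
KD_LEVELS_PER_HR = (0.386, 0.515, 0.686, 0.915, 1.220)
KB_LEVELS_PER_HR = (0.067, 0.089, 0.119, 0.159, 0.212)


@dataclass(frozen=True)
class TransportParams:
    """Transport and physiology constants for the gel/mucosa/blood model.

    Attributes
    ----------
    C0 : float
        Initial drug concentration in the gel layer, ng/mL.
    Dg, De, Ds : float
        Diffusion coefficients in gel, epithelium and stroma, cm^2/s.
    phi_ge, phi_es : float
        Equilibrium partition coefficients at the gel/epithelium and
        epithelium/stroma interfaces (downstream/upstream concentration
        ratio), dimensionless.
    hg, he, hs : float
        Layer thicknesses of gel, epithelium and stroma, micrometres.
    W, L : float
        Width and length of the coated canal surface, cm.
    kD : float
        First-order dilution/leakage rate constant in the gel, 1/hr.
    kB : float
        Stroma-to-blood transport rate constant, 1/hr.
    kL : float
        Clearance rate constant from blood, 1/hr.
    VB : float
        Blood volume of distribution, litres.
    vf_e, vf_s : float
        Volume fraction of cells in epithelium and stroma.
    k_on, k_off : float
        Formation and elimination rate constants of the intracellular
        diphosphate metabolite, 1/hr.
    n_eq : float
        Equilibrium ratio of metabolite to parent drug in cells.
    EC50 : float
        Prophylactic threshold concentration of the metabolite, ng/mL.
    area_factor : float
        Multiplier on the coated area W*L feeding the blood compartment
        (set to 2.0 to count both apposed canal walls; default 1.0).
    """

    C0: float = 1e7
    Dg: float = 6e-6
    De: float = 7e-8
    Ds: float = 4e-7
    phi_ge: float = 0.75
    phi_es: float = 1.0
    hg: float = 400.0
    he: float = 250.0
    hs: float = 2800.0
    W: float = 3.35
    L: float = 13.0
    kD: float = 0.686
    kB: float = 0.119
    kL: float = 1.41
    VB: float = 75.0
    vf_e: float = 0.95
    vf_s: float = 0.1
    k_on: float = 0.693
    k_off: float = 0.00413
    n_eq: float = 0.1
    EC50: float = 224.0
    area_factor: float = 1.0

    def __post_init__(self) -> None:
        errors = []
        for name in ("Dg", "De", "Ds", "hg", "he", "hs", "W", "L", "VB",
                     "phi_ge", "phi_es", "EC50", "area_factor"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                errors.append(f"{name} must be strictly positive "
                              f"(got {getattr(self, name)!r})")
        for name in ("C0", "kD", "kB", "kL", "k_on", "k_off", "n_eq"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                errors.append(f"{name} must be non-negative "
                              f"(got {getattr(self, name)!r})")
        for name in ("vf_e", "vf_s"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                errors.append(f"{name} must lie in [0, 1] (got {v!r})")
        if errors:
            raise ParamError("; ".join(errors))

    def replace(self, **kwargs) -> "TransportParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "TransportParams":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ParamError(f"unknown transport parameter(s): "
                             f"{', '.join(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class Discretization:
    """Spatial/temporal resolution of the finite-volume solver.

    ``output_times`` must be contained in [0, t_end], include t = 24 hr and
    align (to rounding) with multiples of ``dt``.
    """

    dx_gel: float = 5.0
    dx_epi: float = 5.0
    dx_stroma: float = 5.0
    dt: float = 0.01
    t_end: float = 96.0
    output_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    MIN_NODES_PER_LAYER = 8

    def __post_init__(self) -> None:
        if self.output_times is None:
            object.__setattr__(
                self, "output_times",
                np.round(np.arange(0.0, self.t_end + 1e-9, 0.1), 10))
        out = np.asarray(self.output_times, dtype=float)
        object.__setattr__(self, "output_times", out)
        errors = []
        for name in ("dx_gel", "dx_epi", "dx_stroma", "dt", "t_end"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                errors.append(f"{name} must be strictly positive")
        if out.ndim != 1 or out.size == 0:
            errors.append("output_times must be a non-empty 1-D sequence")
        else:
            if np.any(np.diff(out) <= 0):
                errors.append("output_times must be strictly increasing")
            if out[0] < 0:
                errors.append("output_times must start at or after 0")
            if self.t_end < out[-1] - 1e-9:
                errors.append("t_end must be >= max(output_times)")
            if not np.any(np.isclose(out, 24.0, atol=1e-6)):
                errors.append("output_times must include t = 24 hr")
            if self.dt > 0:
                steps = out / self.dt
                if np.max(np.abs(steps - np.round(steps))) > 1e-6:
                    errors.append(
                        "output_times must align with multiples of dt")
        if errors:
            raise ParamError("; ".join(errors))

    def n_cells(self, thickness_um: float, dx_um: float) -> int:
        n = int(round(thickness_um / dx_um))
        return max(n, self.MIN_NODES_PER_LAYER)

    def to_dict(self) -> dict:
        return {
            "dx_gel": self.dx_gel,
            "dx_epi": self.dx_epi,
            "dx_stroma": self.dx_stroma,
            "dt": self.dt,
            "t_end": self.t_end,
            "output_times": [float(t) for t in self.output_times],
        }


def default_params() -> TransportParams:
    """Standard parameter set.

    The three host-variability parameters take the median of their default
    level lists (he = 250 um, kD = 0.686 1/hr, kB = 0.119 1/hr).
    """
    return TransportParams(
        he=HE_LEVELS_7_UM[3],
        kD=KD_LEVELS_PER_HR[2],
        kB=KB_LEVELS_PER_HR[2],
    )


def default_discretization(t_end: float = 96.0,
                           output_interval: float = 0.1) -> Discretization:
    """Default solver resolution: 5 um cells, dt = 0.01 hr."""
    times = np.round(np.arange(0.0, t_end + 1e-9, output_interval), 10)
    return Discretization(t_end=t_end, output_times=times)


def make_output_times(t_end: float, interval: float) -> np.ndarray:
    return np.round(np.arange(0.0, t_end + 1e-9, interval), 10)
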