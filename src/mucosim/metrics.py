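"""Summary pharmacokinetic metrics and the percent-protected measure."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKMetrics",
    "PDMetrics",
    "pk_metrics",
    "percent_protected",
    "pd_metrics",
    "ec50_convert",
    "MetricsError",
]

# Plateau tolerance (percentage points) used to locate the time of maximum
# protection on a near-flat maximum.
T_LAG_TOLERANCE_PP = 0.1


class MetricsError(ValueError):
    """Raised on metric contract violations (bad series, missing samples)."""


@dataclass(frozen=True)
class PKMetrics:
    """Cmax (ng/mL), tmax (hr), AUC (ng*hr/mL) over [0, t_end], C24 (ng/mL)."""

    Cmax: float
    tmax: float
    AUC: float
    C24: float


@dataclass(frozen=True)
class PDMetrics:
    """Percent-protected time course with its two summary metrics."""

    pp_series: np.ndarray
    times: np.ndarray
    t_lag: float
    PPmax: float


def pk_metrics(series, times, t_end: float | None = None) -> PKMetrics:
    """Summary PK metrics of one volume-averaged concentration series.

    Cmax/tmax come from the discrete maximum (first occurrence on ties);
    AUC is the trapezoidal rule over [0, t_end]; C24 is an exact lookup of
    the t = 24 hr sample — a missing sample is a contract error, never an
    interpolation.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.ndim != 1 or times.ndim != 1 or series.size != times.size:
        raise MetricsError("series and times must be 1-D and equally long")
    if series.size < 2:
        raise MetricsError("need at least two samples")
    if np.any(np.diff(times) <= 0):
        raise MetricsError("times must be strictly increasing")
    if t_end is None:
        t_end = float(times[-1])
    if t_end > times[-1] + 1e-9:
        raise MetricsError(f"t_end = {t_end} beyond last sample {times[-1]}")

    i24 = np.flatnonzero(np.isclose(times, 24.0, rtol=0.0, atol=1e-6))
    if i24.size == 0:
        raise MetricsError("series has no sample at t = 24 hr")

    imax = int(np.argmax(series))
    mask = times <= t_end + 1e-9
    auc = float(np.trapezoid(series[mask], times[mask]))
    return PKMetrics(
        Cmax=float(series[imax]),
        tmax=float(times[imax]),
        AUC=auc,
        C24=float(series[i24[0]]),
    )


def percent_protected(dp_field, ec50: float, weights=None,
                      interpolate: bool = True) -> np.ndarray:
    """Percent of a tissue volume at or above the prophylactic threshold.

    Parameters
    ----------
    dp_field : array, shape (n_times, n_nodes)
        Metabolite concentration over time and space, ng/mL tissue, sampled
        at equally spaced cell centres across the layer.
    ec50 : float
        Threshold concentration, ng/mL; must be positive.
    weights : array, optional
        Per-node volume weights.  Supplying weights selects the plain
        node-fraction estimate (no sub-cell interpolation).
    interpolate : bool
        When True (default) the protected volume is measured on a
        piecewise-linear reconstruction between cell centres, locating the
        threshold crossing inside cells.  This removes the one-node-width
        quantization of the plain node count; both estimates agree to
        within one node width.

    Returns
    -------
    ndarray of percentages in [0, 100], one per time sample.
    """
    field = np.atleast_2d(np.asarray(dp_field, dtype=float))
    if field.size == 0:
        raise MetricsError("empty concentration field")
    if not np.isfinite(ec50) or ec50 <= 0:
        raise MetricsError(f"ec50 must be positive (got {ec50!r})")
    if np.any(field < 0):
        raise MetricsError("concentration field contains negative values")
    n = field.shape[1]
    if weights is not None or not interpolate or n == 1:
        if weights is None:
            w = np.full(n, 1.0 / n)
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
                raise MetricsError("weights must be non-negative, one per node")
            w = w / w.sum()
        return np.clip(100.0 * ((field >= ec50) @ w), 0.0, 100.0)

    # piecewise-linear reconstruction between cell centres; the outer half
    # cells take their centre value
    a = field - ec50
    left, right = a[:, :-1], a[:, 1:]
    frac = np.where((left >= 0) & (right >= 0), 1.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where((left >= 0) & (right < 0), left / (left - right), frac)
        frac = np.where((left < 0) & (right >= 0), right / (right - left), frac)
    edge = 0.5 * ((field[:, 0] >= ec50).astype(float)
                  + (field[:, -1] >= ec50).astype(float))
    return np.clip(100.0 * (frac.sum(axis=1) + edge) / n, 0.0, 100.0)


def pd_metrics(pp_series, times, plateau_tol: float = T_LAG_TOLERANCE_PP) -> PDMetrics:
    """Summaries of a percent-protected time course.

    PPmax is the series maximum.  t_lag is the earliest time at which the
    series comes within ``plateau_tol`` percentage points of PPmax: the
    metabolite decays so slowly that the maximum sits on a near-plateau,
    making a strict argmax numerically unstable.
    """
    pp = np.asarray(pp_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if pp.ndim != 1 or pp.size == 0 or pp.shape != times.shape:
        raise MetricsError("pp_series and times must be equal-length 1-D")
    if np.any((pp < -1e-9) | (pp > 100 + 1e-9)):
        raise MetricsError("pp_series must lie within [0, 100]")
    ppmax = float(pp.max())
    idx = int(np.flatnonzero(pp >= ppmax - plateau_tol)[0])
    return PDMetrics(pp_series=pp.copy(), times=times.copy(),
                     t_lag=float(times[idx]), PPmax=ppmax)


def ec50_convert(value_fmol_per_mg: float, molar_mass_g_per_mol: float,
                 density_g_per_ml: float = 1.0) -> float:
    """Convert a tissue threshold from fmol/mg to ng/mL.

    fmol/mg * (g/mol) -> 1e-15 mol/mg * g/mol = 1e-15 g/mg = 1e-3 ng/g;
    multiplying by tissue density (g/mL) yields ng/mL.
    """
    for name, v in (("value", value_fmol_per_mg),
                    ("molar_mass", molar_mass_g_per_mol),
                    ("density", density_g_per_ml)):
        if not np.isfinite(v) or v < 0 or (name != "value" and v == 0):
            raise MetricsError(f"{name} must be positive (got {v!r})")
    return value_fmol_per_mg * molar_mass_g_per_mol * density_g_per_ml * 1e-3
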