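"""Equilibrium thermodynamics from state populations.

The two-state free energy of closing at temperature T is
ΔG_close = −kB·T·ln(p_cl/p_op); it is negative when the closed state is
favoured.  Across temperatures, ΔG = ΔH − TΔS yields the enthalpy and
entropy of the transition, either by ordinary least squares of ΔG on T
(Gibbs fit) or of ln(p_op/p_cl) on 1/T (van't Hoff fit).  Both fits agree
exactly when the populations derive from constant ΔH and ΔS.

The published convention for this system reports CLOSING quantities
(ΔH, ΔS < 0); the opening convention is available by flag and every fit is
tagged with the convention used.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Sequence, Tuple

import numpy as np
from scipy import stats

from .constants import EU_PER_KCAL_PER_MOL_K, KB_KCAL_PER_MOL_K
from .errors import FitError, ValidationError
from .io_formats import TimeSeriesTable
from .state_classifier import StateDefinition, classify


class ThermoRecord(NamedTuple):
    T: float  # K
    p_cl: float
    p_op: float
    dG: float  # kcal/mol, in the fit's convention


@dataclass(frozen=True)
class ThermoFit:
    """Populations, per-temperature ΔG and the fitted ΔH/ΔS."""

    records: Tuple[ThermoRecord, ...]
    dH: float  # kcal/mol
    dS_eu: float  # cal mol^-1 K^-1
    t_m: float  # K where the fitted dG crosses zero
    dH_stderr: float
    dS_stderr_eu: float
    residuals: Tuple[float, ...]
    convention: str  # 'closing' | 'opening'
    kB: float = KB_KCAL_PER_MOL_K

    @property
    def dS(self) -> float:
        """Entropy in kcal mol⁻¹ K⁻¹."""
        return self.dS_eu / EU_PER_KCAL_PER_MOL_K


def free_energy_difference(
    p_cl: float, p_op: float, T: float, convention: str = "closing"
) -> float:
    """Two-state free-energy difference in kcal/mol.

    ``closing``: ΔG = −kB·T·ln(p_cl/p_op) (negative when closing is
    favoured).  ``opening`` flips the sign.
    """
    if p_cl <= 0 or p_op <= 0:
        raise ValidationError(f"probabilities must be positive, got {p_cl}, {p_op}")
    if T <= 0:
        raise ValidationError(f"temperature must be positive, got {T}")
    dg = -KB_KCAL_PER_MOL_K * T * np.log(p_cl / p_op)
    if convention == "closing":
        return float(dg)
    if convention == "opening":
        return float(-dg)
    raise ValueError(f"unknown convention {convention!r}")


def _check_points(T: np.ndarray) -> None:
    if len(T) < 2:
        raise FitError(f"need at least 2 temperatures, got {len(T)}")
    if np.ptp(T) == 0:
        raise FitError("all temperatures are equal; slope is undefined")


def fit_gibbs(points: Sequence[Tuple[float, float]]) -> Tuple[float, float, float, dict]:
    """OLS of ΔG on T: intercept = ΔH, slope = −ΔS.

    Returns (ΔH kcal/mol, ΔS eu, T_m K, diagnostics).  T_m = ΔH/ΔS is the
    temperature where the fitted line crosses zero.
    """
    pts = np.asarray(points, dtype=float)
    T, dG = pts[:, 0], pts[:, 1]
    _check_points(T)
    res = stats.linregress(T, dG)
    dH = float(res.intercept)
    dS = -float(res.slope)  # kcal/mol/K
    t_m = dH / dS if dS != 0 else float("inf")
    fitted = res.intercept + res.slope * T
    diag = {
        "dH_stderr": float(res.intercept_stderr),
        "dS_stderr_eu": float(res.stderr) * EU_PER_KCAL_PER_MOL_K,
        "residuals": tuple(float(x) for x in (dG - fitted)),
        "r_value": float(res.rvalue),
    }
    return dH, dS * EU_PER_KCAL_PER_MOL_K, float(t_m), diag


def fit_vant_hoff(
    points: Sequence[Tuple[float, float, float]], convention: str = "closing"
) -> Tuple[float, float, dict]:
    """OLS of ln(p_op/p_cl) on 1/T.

    The slope is −ΔH_open/kB and the intercept ΔS_open/kB; closing
    parameters are the negatives.  Returns (ΔH kcal/mol, ΔS eu,
    diagnostics) in the requested convention.
    """
    pts = np.asarray(points, dtype=float)
    T, p_cl, p_op = pts[:, 0], pts[:, 1], pts[:, 2]
    _check_points(T)
    if np.any(p_cl <= 0) or np.any(p_op <= 0):
        raise ValidationError("probabilities must be positive")
    x = 1.0 / T
    y = np.log(p_op / p_cl)
    res = stats.linregress(x, y)
    dH_open = -float(res.slope) * KB_KCAL_PER_MOL_K
    dS_open = float(res.intercept) * KB_KCAL_PER_MOL_K
    sign = 1.0 if convention == "opening" else -1.0
    if convention not in ("closing", "opening"):
        raise ValueError(f"unknown convention {convention!r}")
    diag = {
        "dH_stderr": float(res.stderr) * KB_KCAL_PER_MOL_K,
        "dS_stderr_eu": float(res.intercept_stderr)
        * KB_KCAL_PER_MOL_K
        * EU_PER_KCAL_PER_MOL_K,
        "r_value": float(res.rvalue),
    }
    return sign * dH_open, sign * dS_open * EU_PER_KCAL_PER_MOL_K, diag


def thermo_fit_from_populations(
    points: Sequence[Tuple[float, float, float]], convention: str = "closing"
) -> ThermoFit:
    """Full thermodynamic extraction from (T, p_cl, p_op) records."""
    records = tuple(
        ThermoRecord(T, p_cl, p_op, free_energy_difference(p_cl, p_op, T, convention))
        for T, p_cl, p_op in points
    )
    dH, dS_eu, t_m, diag = fit_gibbs([(r.T, r.dG) for r in records])
    return ThermoFit(
        records=records,
        dH=dH,
        dS_eu=dS_eu,
        t_m=t_m,
        dH_stderr=diag["dH_stderr"],
        dS_stderr_eu=diag["dS_stderr_eu"],
        residuals=diag["residuals"],
        convention=convention,
    )


def equilibration_trace(
    series: TimeSeriesTable,
    defs: StateDefinition,
    checkpoints: Sequence[float],
    convergence_tol: float = 0.01,
) -> Tuple[List[Tuple[float, float]], bool]:
    """Running closed-state occupancy p_cl(0..t) at each checkpoint time.

    Transition-state frames are attributed to the residence containing
    them (the same bookkeeping the segmentation uses), so the trace
    converges to the segmentation's p_cl.  Returns the trace and a
    convergence flag: True when the last two checkpoints differ by less
    than ``convergence_tol``.
    """
    checkpoints = list(checkpoints)
    if not checkpoints:
        raise ValidationError("need at least one checkpoint")
    t0, t1 = series.time[0], series.time[-1]
    for c in checkpoints:
        if c < t0 or c > t1 + series.step / 2:
            raise ValidationError(f"checkpoint {c} ns outside trajectory span")
    seg = classify(series, defs)
    # per-frame basin attribution from the residence tiling
    closed_frac = np.zeros(series.n_frames)
    for r in seg.residences:
        if r.label != "closed":
            continue
        i0 = np.searchsorted(series.time, r.start - series.step / 2, side="left")
        i1 = np.searchsorted(series.time, r.end - series.step / 2, side="left")
        closed_frac[i0:i1] = 1.0
    cum = np.cumsum(closed_frac)
    trace: List[Tuple[float, float]] = []
    for c in checkpoints:
        n = int(np.searchsorted(series.time, c, side="right"))
        n = max(n, 1)
        trace.append((float(c), float(cum[n - 1] / n)))
    converged = (
        len(trace) >= 2 and abs(trace[-1][1] - trace[-2][1]) < convergence_tol
    )
    return trace, converged
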