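"""Rates, transition-path times and barrier heights from lifetimes.

The two-state rates are the reciprocal mean lifetimes, k− = 1/τ_cl (opening)
and k+ = 1/τ_op (closing).  The mean transition-path times are identified
with the mean failed-excursion durations: t_tp(o→c) = τ_ctc and
t_tp(c→o) = τ_oto.

In the diffusive (Kramers) picture the residence times are

    t = 2π / (β·D*·ω*·ω_basin) · exp(β·ΔG‡)

with D* the diffusion coefficient at the barrier top and ω² the curvatures
of the free-energy surface, while the transition-path time follows Szabo:

    t_tp = ln(2·e^γ·β·ΔG‡) / (β·D*·ω*²),   γ Euler's constant.

The ratio t_residence/t_tp depends only on the curvature ratio ω*/ω_basin
and β·ΔG‡ — not on D* — which is what makes the barrier height extractable
from lifetime ratios alone.  The closed-side barrier ΔGc is modelled as
temperature-independent; the open-side barrier as ΔGo = T·ΔS_open (entropic),
making the open-side ratio temperature-flat.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .constants import EULER_GAMMA, EU_PER_KCAL_PER_MOL_K, KB_KCAL_PER_MOL_K, beta
from .errors import FitError, ValidationError


class RateRecord(NamedTuple):
    T: float  # K
    tau_cl: float  # ns
    tau_op: float  # ns
    ttp_oc: float  # ns, = tau_ctc
    ttp_co: float  # ns, = tau_oto
    k_minus: float  # 1/ns, opening
    k_plus: float  # 1/ns, closing
    ratio_cl: float  # t_cl / t_tp(c->o)
    ratio_op: float  # t_op / t_tp(o->c)


@dataclass(frozen=True)
class BarrierFit:
    """Result of the two-parameter ratio fit on one side of the barrier."""

    side: str  # 'closed' | 'open'
    barrier_kcal_per_mol: Optional[float]  # ΔGc for side='closed', else None
    entropy_open_eu: Optional[float]  # ΔS_open for side='open', else None
    omega_ratio: float  # ω*/ω_basin
    residuals: Tuple[float, ...]  # on ln(ratio)
    rms_log_residual: float
    identifiable: bool  # False when the model is flat in T (open side, free ΔS)


@dataclass(frozen=True)
class KineticsFit:
    records: Tuple[RateRecord, ...]
    dG_c: float  # kcal/mol, closed-side barrier
    omega_ratio_closed: float
    entropy_open_eu: Optional[float]
    omega_ratio_open: Optional[float]
    closed_fit: BarrierFit
    open_fit: Optional[BarrierFit]
    euler_gamma: float = EULER_GAMMA
    kB: float = KB_KCAL_PER_MOL_K


def rates_from_lifetimes(rows: Sequence[Dict[str, float]]) -> Tuple[RateRecord, ...]:
    """Per-temperature rates and ratios from mean-lifetime records.

    Each row needs keys T, tau_cl, tau_op, tau_ctc, tau_oto (ns).  A row
    missing a state's statistics is reported with NaN for the dependent
    quantities rather than dropped.
    """
    out = []
    for row in rows:
        T = float(row["T"])
        tau_cl = float(row.get("tau_cl", np.nan))
        tau_op = float(row.get("tau_op", np.nan))
        ttp_oc = float(row.get("tau_ctc", np.nan))
        ttp_co = float(row.get("tau_oto", np.nan))
        for name, v in (("tau_cl", tau_cl), ("tau_op", tau_op),
                        ("tau_ctc", ttp_oc), ("tau_oto", ttp_co)):
            if not np.isnan(v) and v <= 0:
                raise ValidationError(f"{name} must be positive at T={T}, got {v}")
        out.append(
            RateRecord(
                T=T,
                tau_cl=tau_cl,
                tau_op=tau_op,
                ttp_oc=ttp_oc,
                ttp_co=ttp_co,
                k_minus=1.0 / tau_cl,
                k_plus=1.0 / tau_op,
                ratio_cl=tau_cl / ttp_co,
                ratio_op=tau_op / ttp_oc,
            )
        )
    return tuple(out)


def kramers_residence_time(
    dG_barrier: float,
    T: float,
    D_star: float,
    omega_ratio: float,
    omega_basin_sq: float,
) -> float:
    """Kramers mean residence time in ns.

    ``omega_ratio`` is ω*/ω_basin and ``omega_basin_sq`` the basin curvature
    (kcal mol⁻¹ Å⁻²); then ω*·ω_basin = omega_ratio·ω_basin².  D* in Å²/ns.
    """
    if D_star <= 0 or omega_ratio <= 0 or omega_basin_sq <= 0:
        raise ValidationError("D*, curvature ratio and basin curvature must be positive")
    b = beta(T)
    return float(2.0 * np.pi / (b * D_star * omega_ratio * omega_basin_sq)
                 * np.exp(b * dG_barrier))


def szabo_transition_path_time(
    dG_barrier: float, T: float, D_star: float, omega_star_sq: float
) -> float:
    """Szabo mean transition-path time in ns.

    Valid in the high-barrier regime; when the log argument 2·e^γ·βΔG drops
    to 1 or below, a warning is issued (the asymptotic formula is outside
    its validity there).
    """
    if D_star <= 0 or omega_star_sq <= 0:
        raise ValidationError("D* and barrier curvature must be positive")
    b = beta(T)
    arg = 2.0 * np.exp(EULER_GAMMA) * b * dG_barrier
    if arg <= 0:
        raise ValidationError("szabo formula needs beta*dG > 0")
    if arg <= 1.0:
        warnings.warn(
            "2*e^gamma*beta*dG <= 1: outside the high-barrier validity regime",
            stacklevel=2,
        )
    return float(np.log(arg) / (b * D_star * omega_star_sq))


def _log_ratio_model(beta_dg: np.ndarray, log_omega_ratio: float) -> np.ndarray:
    """ln of ratio = 2π·(ω*/ω_basin)·exp(βΔG)/ln(2 e^γ βΔG)."""
    return (
        np.log(2.0 * np.pi)
        + log_omega_ratio
        + beta_dg
        - np.log(np.log(2.0 * np.exp(EULER_GAMMA) * beta_dg))
    )


def fit_barrier_from_ratios(
    points: Sequence[Tuple[float, float]],
    side: str = "closed",
    entropy_open_eu: Optional[float] = None,
    grid: Optional[np.ndarray] = None,
) -> BarrierFit:
    """Fit the Kramers/Szabo ratio expression to (T, t_residence/t_tp) points.

    side='closed': ΔGc is temperature-independent; the fit parameters are
    (ΔGc, ω*/ωc), initialised by a grid search over ΔGc ∈ [1, 15] kcal/mol
    and refined by nonlinear least squares on ln(ratio).

    side='open': ΔGo = T·ΔS_open, so β·ΔGo is constant and the model is
    exactly flat in temperature — ΔS_open and ω*/ωo are then not jointly
    identifiable from ratios alone.  Pass ``entropy_open_eu`` (e.g. from
    the thermodynamic fit) to pin ΔS_open and fit only the curvature
    ratio; otherwise the grid fit over ΔS_open ∈ [5, 30] eu is performed
    and the result is flagged ``identifiable=False``.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise FitError(f"need at least 2 temperatures, got {len(pts)}")
    T, ratio = pts[:, 0], pts[:, 1]
    if np.any(ratio <= 0):
        raise FitError("ratios must be positive")
    log_r = np.log(ratio)
    b = 1.0 / (KB_KCAL_PER_MOL_K * T)

    if side == "closed":
        def beta_dg_of(param: float) -> np.ndarray:
            return b * param  # param = ΔGc (kcal/mol)

        grid_vals = np.arange(1.0, 15.0 + 1e-9, 0.1) if grid is None else grid
        free = True
    elif side == "open":
        def beta_dg_of(param: float) -> np.ndarray:
            # param = ΔS_open (eu); ΔGo = T·ΔS_open so βΔGo = ΔS_open/kB
            s = param / EU_PER_KCAL_PER_MOL_K
            return np.full_like(T, s / KB_KCAL_PER_MOL_K)

        if entropy_open_eu is not None:
            beta_dg = beta_dg_of(entropy_open_eu)
            log_a = float(np.mean(log_r - _log_ratio_model(beta_dg, 0.0)))
            resid = log_r - _log_ratio_model(beta_dg, log_a)
            return BarrierFit(
                side="open",
                barrier_kcal_per_mol=None,
                entropy_open_eu=float(entropy_open_eu),
                omega_ratio=float(np.exp(log_a)),
                residuals=tuple(map(float, resid)),
                rms_log_residual=float(np.sqrt(np.mean(resid**2))),
                identifiable=True,
            )
        grid_vals = np.arange(5.0, 30.0 + 1e-9, 0.5) if grid is None else grid
        free = False
    else:
        raise ValueError(f"unknown side {side!r}")

    def sse(param: float) -> Tuple[float, float]:
        # the curvature-ratio factor enters linearly in log space, so it is
        # profiled out exactly for any candidate barrier parameter
        beta_dg = beta_dg_of(param)
        if np.any(2.0 * np.exp(EULER_GAMMA) * beta_dg <= 1.0):
            return np.inf, 0.0
        base = _log_ratio_model(beta_dg, 0.0)
        log_a = float(np.mean(log_r - base))
        return float(np.sum((log_r - base - log_a) ** 2)), log_a

    scores = [sse(g)[0] for g in grid_vals]
    best = grid_vals[int(np.argmin(scores))]
    res = optimize.minimize_scalar(
        lambda p: sse(p)[0],
        bracket=None,
        bounds=(max(best - 1.0, grid_vals[0] * 0.5), best + 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise FitError(f"barrier fit failed to converge: {res.message}")
    param = float(res.x)
    final_sse, log_a = sse(param)
    beta_dg = beta_dg_of(param)
    resid = log_r - _log_ratio_model(beta_dg, log_a)
    return BarrierFit(
        side=side,
        barrier_kcal_per_mol=param if side == "closed" else None,
        entropy_open_eu=param if side == "open" else None,
        omega_ratio=float(np.exp(log_a)),
        residuals=tuple(map(float, resid)),
        rms_log_residual=float(np.sqrt(np.mean(resid**2))),
        identifiable=free,
    )


class DwellCheck(NamedTuple):
    mean: float  # ns
    rate: float  # 1/ns, maximum-likelihood exponential rate
    ks_statistic: float  # distance to the fitted exponential
    n: int


def dwell_time_distribution_check(dwells: Sequence[float]) -> Optional[DwellCheck]:
    """Audit the memoryless-kinetics assumption on a sample of dwell times.

    Returns None (diagnostic absent) for fewer than 10 dwells.  The KS
    distance is computed against the exponential with the ML rate; because
    the rate is fitted from the same sample the distance is a diagnostic,
    not a calibrated test statistic.
    """
    dwells = np.asarray(list(dwells), dtype=float)
    if len(dwells) < 10:
        return None
    if np.any(dwells <= 0):
        raise ValidationError("dwell times must be positive")
    mean = float(np.mean(dwells))
    ks = stats.kstest(dwells, "expon", args=(0.0, mean))
    return DwellCheck(mean=mean, rate=1.0 / mean, ks_statistic=float(ks.statistic),
                      n=len(dwells))


def kinetics_fit_from_summaries(
    rows: Sequence[Dict[str, float]],
    entropy_open_eu: Optional[float] = None,
) -> KineticsFit:
    """Rates, ratios and barrier fits from per-temperature lifetime rows."""
    records = rates_from_lifetimes(rows)
    closed_pts = [(r.T, r.ratio_cl) for r in records if np.isfinite(r.ratio_cl)]
    closed_fit = fit_barrier_from_ratios(closed_pts, side="closed")
    open_pts = [(r.T, r.ratio_op) for r in records if np.isfinite(r.ratio_op)]
    open_fit = None
    if len(open_pts) >= 2:
        open_fit = fit_barrier_from_ratios(
            open_pts, side="open", entropy_open_eu=entropy_open_eu
        )
    return KineticsFit(
        records=records,
        dG_c=closed_fit.barrier_kcal_per_mol,
        omega_ratio_closed=closed_fit.omega_ratio,
        entropy_open_eu=open_fit.entropy_open_eu if open_fit else None,
        omega_ratio_open=open_fit.omega_ratio if open_fit else None,
        closed_fit=closed_fit,
        open_fit=open_fit,
    )
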