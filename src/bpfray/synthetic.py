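"""Synthetic trajectory generators.

Two independent stand-ins for long all-atom MD sampling of terminal
base-pair fraying:

* :func:`simulate_markov` — a hidden-state generator: alternating closed
  and open residences with exponentially distributed durations, nested
  Poisson-placed failed excursions (ctc within closed, oto within open),
  and per-state (RMSD, ζ) emissions matching the observed distributions.
  Used to validate the classifier and the thermodynamic extraction against
  known ground truth.

* :func:`simulate_langevin` — overdamped Brownian dynamics on a quartic
  double well U(x) = h·[(x/a)² − 1]², integrated with Euler–Maruyama.
  This is the physics oracle for the Kramers residence-time and Szabo
  transition-path-time expressions: the analytic curvatures are
  U''(±a) = 8h/a² and |U''(0)| = 4h/a².

Every generator is a pure function of its config (the seed lives in the
config); identical configs give bit-identical output.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.stats import truncnorm

from .constants import beta
from .errors import ConfigError
from .io_formats import TimeSeriesTable
from .reference_data import TOTAL_TIME_NS, reference_table
from .state_classifier import CLOSED, OPEN, TRANSITION, StateDefinition

from numba import njit


# ---------------------------------------------------------------------------
# Hidden-state Markov generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionModel:
    """Per-state (RMSD, ζ) distributions.

    Closed: RMSD ~ truncated normal around 0.7 Å, ζ ~ normal around −75°;
    open: RMSD uniform on [2, 13.5] Å, ζ ~ normal around 50°; transition:
    RMSD above 2 Å with ζ still in the closed torsion window.
    """

    closed_rmsd_mean: float = 0.7
    closed_rmsd_sd: float = 0.25
    closed_rmsd_bounds: Tuple[float, float] = (0.0, 2.0)
    closed_zeta_mean: float = -75.0
    closed_zeta_sd: float = 10.0
    open_rmsd_bounds: Tuple[float, float] = (2.0, 13.5)
    open_zeta_mean: float = 50.0
    open_zeta_sd: float = 15.0
    trans_rmsd_mean: float = 3.0
    trans_rmsd_sd: float = 1.0
    trans_rmsd_bounds: Tuple[float, float] = (2.0, 13.5)

    def validate_against(self, defs: StateDefinition) -> None:
        zc, zo = defs.zeta_closed_window, defs.zeta_open_window
        if not (zc[0] < self.closed_zeta_mean < zc[1]):
            raise ConfigError("closed ζ emission centre outside the closed window")
        if not (zo[0] < self.open_zeta_mean < zo[1]):
            raise ConfigError("open ζ emission centre outside the open window")
        if self.closed_rmsd_bounds[1] > defs.rmsd_closed_max:
            raise ConfigError("closed RMSD emission support exceeds rmsd_closed_max")
        if (self.open_rmsd_bounds[0] < defs.rmsd_open_range[0]
                or self.open_rmsd_bounds[1] > defs.rmsd_open_range[1]):
            raise ConfigError("open RMSD emission support outside rmsd_open_range")
        if self.trans_rmsd_bounds[0] < defs.rmsd_closed_max:
            raise ConfigError("transition RMSD emission support must exceed rmsd_closed_max")


@dataclass(frozen=True)
class MarkovTrajectoryConfig:
    """Two-basin trajectory with nested excursions at one temperature.

    Lifetime defaults correspond to the 370 K reference statistics; use
    :func:`reference_markov_config` for the other temperatures.  Rates are
    per ns of residence time; the frame step mirrors coordinates saved
    every 2 ps.
    """

    temperature_K: float = 370.0
    mean_closed_ns: float = 27.41
    mean_open_ns: float = 24.18
    excursion_rate_closed: float = 0.2035  # ctc starts per ns of closed residence
    mean_excursion_closed_ns: float = 0.23
    excursion_rate_open: float = 0.3561  # oto starts per ns of open residence
    mean_excursion_open_ns: float = 0.205
    step_ns: float = 0.002
    total_time_ns: float = TOTAL_TIME_NS
    emissions: EmissionModel = field(default_factory=EmissionModel)
    state_definition: StateDefinition = field(default_factory=StateDefinition)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_closed_ns <= 0 or self.mean_open_ns <= 0:
            raise ConfigError("mean residence times must be positive")
        if self.excursion_rate_closed < 0 or self.excursion_rate_open < 0:
            raise ConfigError("excursion rates must be non-negative")
        if self.mean_excursion_closed_ns <= 0 or self.mean_excursion_open_ns <= 0:
            raise ConfigError("mean excursion durations must be positive")
        if self.step_ns <= 0 or self.total_time_ns <= self.step_ns:
            raise ConfigError("need 0 < step < total_time")
        n = self.total_time_ns / self.step_ns
        if abs(n - round(n)) > 1e-6:
            raise ConfigError("step must divide total_time")
        self.emissions.validate_against(self.state_definition)


def reference_markov_config(T: float, seed: int = 0, **overrides) -> MarkovTrajectoryConfig:
    """Config matching the published per-temperature lifetime statistics."""
    tab = reference_table()
    if T not in tab.index:
        raise ConfigError(f"no reference statistics at T={T} K")
    row = tab.loc[T]
    return MarkovTrajectoryConfig(
        temperature_K=float(T),
        mean_closed_ns=float(row.tau_cl),
        mean_open_ns=float(row.tau_op),
        excursion_rate_closed=float(row.n_ctc / (row.tau_cl * row.n_cl)),
        mean_excursion_closed_ns=float(row.tau_ctc),
        excursion_rate_open=float(row.n_oto / (row.tau_op * row.n_op)),
        mean_excursion_open_ns=float(row.tau_oto),
        seed=seed,
        **overrides,
    )


def markov_config_from_thermo(
    T: float,
    dH_close: float,
    dS_close_eu: float,
    mean_open_ns: float = 23.0,
    seed: int = 0,
    **overrides,
) -> MarkovTrajectoryConfig:
    """Config whose stationary populations follow ΔG_close = ΔH − TΔS.

    The open-state lifetime is held at its observed, nearly
    temperature-flat value and the closed-state lifetime is set so that
    τ_cl/τ_op = p_cl/p_op = exp(−β ΔG_close).
    """
    dG_close = dH_close - T * dS_close_eu / 1000.0
    ratio = float(np.exp(-beta(T) * dG_close))
    return MarkovTrajectoryConfig(
        temperature_K=T,
        mean_closed_ns=mean_open_ns * ratio,
        mean_open_ns=mean_open_ns,
        seed=seed,
        **overrides,
    )


def _draw_excursions(rng, start, end, rate, mean_dur):
    """Non-overlapping excursion intervals Poisson-placed inside [start, end]."""
    span = end - start
    n = rng.poisson(rate * span)
    if n == 0:
        return []
    t0 = np.sort(rng.uniform(start, end, size=n))
    durs = rng.exponential(mean_dur, size=n)
    out = []
    cursor = start
    for s, d in zip(t0, durs):
        if s < cursor:
            continue  # overlaps the previous excursion; drop
        e = min(s + d, end)
        if e > s:
            out.append((s, e))
            cursor = e
    return out


def simulate_markov(config: MarkovTrajectoryConfig) -> Tuple[TimeSeriesTable, np.ndarray]:
    """Generate a (time, RMSD, ζ) table plus the true hidden-state labels.

    Residence durations are exponential (memoryless two-state kinetics);
    excursions within a residence carry the transition label but do not
    terminate the residence, mirroring the ctc/oto bookkeeping of the
    analysis.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.total_time_ns / config.step_ns))

    # 1. alternating residences
    bounds = [0.0]
    states = []
    state = CLOSED if rng.random() < 0.5 else OPEN
    t = 0.0
    while t < config.total_time_ns:
        mean = config.mean_closed_ns if state == CLOSED else config.mean_open_ns
        dur = rng.exponential(mean)
        t = min(t + dur, config.total_time_ns)
        bounds.append(t)
        states.append(state)
        state = OPEN if state == CLOSED else CLOSED

    # 2. nested excursions
    exc_intervals = []
    for (s, e), st in zip(zip(bounds[:-1], bounds[1:]), states):
        rate = config.excursion_rate_closed if st == CLOSED else config.excursion_rate_open
        mean_d = (config.mean_excursion_closed_ns if st == CLOSED
                  else config.mean_excursion_open_ns)
        if rate > 0:
            exc_intervals.extend(_draw_excursions(rng, s, e, rate, mean_d))

    # 3. per-frame labels
    times = config.step_ns * np.arange(n_frames)
    labels = np.asarray(states, dtype=np.int8)[
        np.clip(np.searchsorted(bounds, times, side="right") - 1, 0, len(states) - 1)
    ]
    for s, e in exc_intervals:
        i0, i1 = np.searchsorted(times, [s, e])
        labels[i0:i1] = TRANSITION

    # 4. emissions
    em = config.emissions
    rmsd = np.empty(n_frames)
    zeta = np.empty(n_frames)
    # draw order is fixed (closed, open, transition) for determinism
    m_cl = labels == CLOSED
    m_op = labels == OPEN
    m_ts = labels == TRANSITION

    def _tnorm(lo, hi, mean, sd, size):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)

    zc = config.state_definition.zeta_closed_window
    zo = config.state_definition.zeta_open_window
    rmsd[m_cl] = _tnorm(*em.closed_rmsd_bounds, em.closed_rmsd_mean, em.closed_rmsd_sd,
                        int(m_cl.sum()))
    zeta[m_cl] = _tnorm(zc[0], zc[1], em.closed_zeta_mean, em.closed_zeta_sd, int(m_cl.sum()))
    rmsd[m_op] = rng.uniform(*em.open_rmsd_bounds, size=int(m_op.sum()))
    zeta[m_op] = _tnorm(zo[0], zo[1], em.open_zeta_mean, em.open_zeta_sd, int(m_op.sum()))
    rmsd[m_ts] = _tnorm(*em.trans_rmsd_bounds, em.trans_rmsd_mean, em.trans_rmsd_sd,
                        int(m_ts.sum()))
    zeta[m_ts] = _tnorm(zc[0], zc[1], em.closed_zeta_mean, em.closed_zeta_sd, int(m_ts.sum()))

    return TimeSeriesTable.from_arrays(times, rmsd, zeta, wrap=False), labels


# ---------------------------------------------------------------------------
# Overdamped Langevin double well
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LangevinConfig:
    """Quartic double well U(x) = h·[(x/a)² − 1]² under overdamped dynamics.

    ``tp_boundary_fraction`` places the transition-path boundaries at
    ±fraction·a.  The default 1/√2 puts them where the inverted parabola
    at the barrier top has dropped by the full barrier height h — the
    regime the Szabo transition-path-time expression is derived for.
    """

    barrier_height_kcal: float = 3.0  # h
    half_separation_A: float = 1.0  # a
    diffusion_A2_per_ns: float = 1.0  # D
    temperature_K: float = 300.0
    time_step_ns: float = 5e-4
    n_steps: int = 1_000_000
    tp_boundary_fraction: float = 1.0 / np.sqrt(2.0)
    store_every: int = 0  # 0: do not store the trace
    seed: int = 0

    def __post_init__(self) -> None:
        if self.half_separation_A <= 0 or self.diffusion_A2_per_ns <= 0:
            raise ConfigError("a and D must be positive")
        if self.barrier_height_kcal < 0:
            raise ConfigError("barrier height must be non-negative")
        if not 0 < self.tp_boundary_fraction < 1:
            raise ConfigError("tp_boundary_fraction must lie in (0, 1)")
        if self.time_step_ns <= 0 or self.n_steps < 1:
            raise ConfigError("need positive time step and step count")
        # stability: the drift displacement per step must stay well below a
        h, a = self.barrier_height_kcal, self.half_separation_A
        b = beta(self.temperature_K)
        x = np.linspace(-1.5 * a, 1.5 * a, 1001)
        fmax = float(np.max(np.abs(4.0 * h / a**2 * x * ((x / a) ** 2 - 1.0))))
        if self.time_step_ns * b * self.diffusion_A2_per_ns * fmax > 0.1 * a:
            raise ConfigError(
                "time step too large for stable integration: "
                f"drift per step {self.time_step_ns * b * self.diffusion_A2_per_ns * fmax:.3g} Å "
                f"exceeds 0.1·a = {0.1 * a:.3g} Å"
            )


@dataclass(frozen=True)
class LangevinResult:
    residences_left: np.ndarray  # ns, completed dwells in the x<0 basin
    residences_right: np.ndarray
    tp_left_to_right: np.ndarray  # ns, direct barrier crossings
    tp_right_to_left: np.ndarray
    trace_times: Optional[np.ndarray]
    trace_positions: Optional[np.ndarray]
    config: LangevinConfig

    @property
    def n_crossings(self) -> int:
        return len(self.tp_left_to_right) + len(self.tp_right_to_left)


@njit(cache=False)
def _langevin_core(x0, n_steps, dt, drift_k, noise_scale, a, b_abs, seed,
                   store_every, max_events):  # pragma: no cover - jitted
    np.random.seed(seed)
    res_l = np.empty(max_events)
    res_r = np.empty(max_events)
    tp_lr = np.empty(max_events)
    tp_rl = np.empty(max_events)
    n_rl = 0
    n_rr = 0
    n_lr = 0
    n_tprl = 0
    n_store = n_steps // store_every + 1 if store_every > 0 else 0
    trace = np.empty(n_store)
    x = x0
    basin = -1 if x < 0 else 1
    entry_t = 0.0
    in_path = False
    path_start = 0.0
    for i in range(n_steps):
        inv = x / a
        force = drift_k * x * (inv * inv - 1.0)  # = beta*D*U'(x)
        x = x - force * dt + noise_scale * np.random.normal()
        t = (i + 1) * dt
        if store_every > 0 and (i + 1) % store_every == 0:
            trace[(i + 1) // store_every - 1] = x
        if not in_path:
            if basin == -1 and x >= -b_abs:
                in_path = True
                path_start = t
            elif basin == 1 and x <= b_abs:
                in_path = True
                path_start = t
        else:
            if basin == -1:
                if x >= b_abs:  # successful left -> right crossing
                    if n_lr < max_events:
                        tp_lr[n_lr] = t - path_start
                        n_lr += 1
                    if n_rl < max_events:
                        res_l[n_rl] = path_start - entry_t
                        n_rl += 1
                    basin = 1
                    entry_t = t
                    in_path = False
                elif x < -b_abs:  # failed excursion, back home
                    in_path = False
            else:
                if x <= -b_abs:
                    if n_tprl < max_events:
                        tp_rl[n_tprl] = t - path_start
                        n_tprl += 1
                    if n_rr < max_events:
                        res_r[n_rr] = path_start - entry_t
                        n_rr += 1
                    basin = -1
                    entry_t = t
                    in_path = False
                elif x > b_abs:
                    in_path = False
    return (res_l[:n_rl], res_r[:n_rr], tp_lr[:n_lr], tp_rl[:n_tprl],
            trace[: (n_steps // store_every if store_every > 0 else 0)], x)


def simulate_langevin(config: LangevinConfig) -> LangevinResult:
    """Euler–Maruyama integration with residence / transition-path logging.

    A transition path is the segment from the last exit out of one basin
    region (|x| > b) to the first arrival in the opposite one, without an
    intervening return.  Residences are the complementary waiting times.
    With h = 0 there is no barrier and no well-defined residences: the
    trace is still produced but the event log is empty (with a warning).
    """
    h, a, D = (config.barrier_height_kcal, config.half_separation_A,
               config.diffusion_A2_per_ns)
    b = beta(config.temperature_K)
    dt = config.time_step_ns
    noise_scale = float(np.sqrt(2.0 * D * dt))
    drift_k = b * D * 4.0 * h / a**2
    free_diffusion = h == 0.0
    if free_diffusion:
        warnings.warn("h = 0: free diffusion, event log will be empty", stacklevel=2)
    res_l, res_r, tp_lr, tp_rl, trace, _ = _langevin_core(
        -a,
        config.n_steps,
        dt,
        drift_k,
        noise_scale,
        a,
        config.tp_boundary_fraction * a,
        config.seed,
        config.store_every,
        min(config.n_steps, 1_000_000),
    )
    if free_diffusion:
        res_l = res_r = tp_lr = tp_rl = np.empty(0)
    times = (
        dt * config.store_every * np.arange(1, len(trace) + 1)
        if config.store_every > 0
        else None
    )
    return LangevinResult(
        residences_left=np.asarray(res_l),
        residences_right=np.asarray(res_r),
        tp_left_to_right=np.asarray(tp_lr),
        tp_right_to_left=np.asarray(tp_rl),
        trace_times=times,
        trace_positions=np.asarray(trace) if config.store_every > 0 else None,
        config=config,
    )


# ---------------------------------------------------------------------------
# Langevin trace -> classifier observables
# ---------------------------------------------------------------------------

def _ramp(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def default_observable_map(
    x: np.ndarray, a: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Monotone map from well coordinate to (RMSD, ζ).

    The RMSD ramp starts rising before the torsion flips, so frames leaving
    the closed basin first appear as transition-state frames (high RMSD,
    closed-like ζ) — the same signature the real observables show.
    """
    rmsd = 0.7 + 4.3 * _ramp(x, -0.9 * a, 0.0)
    zeta = -75.0 + 125.0 * _ramp(x, -0.1 * a, 0.6 * a)
    return rmsd, zeta


def langevin_to_observables(
    result: LangevinResult,
    mapping: Optional[Callable[[np.ndarray, float], Tuple[np.ndarray, np.ndarray]]] = None,
    defs: Optional[StateDefinition] = None,
) -> TimeSeriesTable:
    """Convert a stored Langevin trace into a classifier-ready table.

    The mapping must send the left basin bottom into the closed (RMSD, ζ)
    window and the right basin bottom into the open window; this is
    checked and a ConfigError raised otherwise.
    """
    if result.trace_positions is None:
        raise ConfigError("simulate_langevin must be run with store_every > 0")
    defs = defs or StateDefinition()
    mapping = mapping or default_observable_map
    a = result.config.half_separation_A
    for x_bottom, (z_win, r_ok) in (
        (-a, (defs.zeta_closed_window, lambda r: r <= defs.rmsd_closed_max)),
        (+a, (defs.zeta_open_window,
              lambda r: defs.rmsd_open_range[0] <= r <= defs.rmsd_open_range[1])),
    ):
        r0, z0 = mapping(np.asarray([x_bottom]), a)
        if not (z_win[0] <= z0[0] <= z_win[1]) or not r_ok(r0[0]):
            raise ConfigError(
                f"mapping sends basin bottom x={x_bottom:g} outside its state window"
            )
    rmsd, zeta = mapping(result.trace_positions, a)
    return TimeSeriesTable.from_arrays(result.trace_times, rmsd, zeta, wrap=False)
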