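"""Three-state segmentation of a (RMSD, ζ) time series.

A frame is *closed* when ζ sits in the closed torsion window and the RMSD
stays below the closed-state ceiling; *transition* when the torsion is
still closed-like but the bases have moved away (RMSD above the ceiling);
*open* when the torsion has flipped into the open window with RMSD in the
open range.  Residences in the two basins alternate and tile the whole
trajectory; failed excursions (ctc: closed→ts→closed, oto: open→ts→open)
are nested inside residences and tallied separately, so p_cl + p_op = 1
while the transition-state occupancy overlaps the residences.

Each frame is treated as owning one step-width interval centred on its
timestamp, so a trajectory of n frames at step Δ spans exactly n·Δ ns.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Tuple

import numpy as np

from .errors import ValidationError
from .io_formats import TimeSeriesTable

# Frame label codes (compact int8 storage for multi-million-frame arrays).
CLOSED, OPEN, TRANSITION, UNASSIGNED = 0, 1, 2, 3
LABEL_NAMES = {CLOSED: "closed", OPEN: "open", TRANSITION: "transition", UNASSIGNED: "unassigned"}


@dataclass(frozen=True)
class StateDefinition:
    """Threshold windows defining the closed, open and transition regions.

    Defaults: closed torsion window [−100°, −50°] with RMSD ≤ 2 Å; open
    torsion window [0°, 100°] with RMSD in [2, 13.5] Å.  The open window is
    symmetric about the observed ≈50° centre.  ``min_excursion_frames`` and
    ``min_residence_frames`` are dwell filters (1 = no suppression).
    """

    zeta_closed_window: Tuple[float, float] = (-100.0, -50.0)
    zeta_open_window: Tuple[float, float] = (0.0, 100.0)
    rmsd_closed_max: float = 2.0
    rmsd_open_range: Tuple[float, float] = (2.0, 13.5)
    min_excursion_frames: int = 1
    min_residence_frames: int = 1

    def __post_init__(self) -> None:
        zc, zo = self.zeta_closed_window, self.zeta_open_window
        if not (zc[0] < zc[1] and zo[0] < zo[1]):
            raise ValidationError("torsion windows must be (low, high) with low < high")
        if max(zc[0], zo[0]) < min(zc[1], zo[1]):
            raise ValidationError("closed and open torsion windows overlap")
        if self.rmsd_closed_max <= 0 or self.rmsd_closed_max > self.rmsd_open_range[0]:
            raise ValidationError("need 0 < rmsd_closed_max <= rmsd_open_range.low")
        if self.rmsd_open_range[0] >= self.rmsd_open_range[1]:
            raise ValidationError("rmsd_open_range must be (low, high) with low < high")
        if self.min_excursion_frames < 1 or self.min_residence_frames < 1:
            raise ValidationError("dwell filters must be >= 1 frame")


class Residence(NamedTuple):
    label: str  # 'closed' | 'open'
    start: float  # ns
    end: float  # ns

    @property
    def duration(self) -> float:
        return self.end - self.start


class Excursion(NamedTuple):
    subtype: str  # 'ctc' | 'oto' | 'cto' | 'otc'
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SegmentationResult:
    """Alternating residences tiling the trajectory plus nested excursions."""

    residences: List[Residence]
    excursions: List[Excursion]
    total_time: float  # ns, = n_frames * step
    step: float  # ns
    no_crossings: bool = False  # warning flag: single residence, no c<->o events

    def _totals(self, kind: str) -> Tuple[float, int]:
        if kind in ("closed", "open"):
            items = [r for r in self.residences if r.label == kind]
        else:
            items = [e for e in self.excursions if e.subtype == kind]
        return sum(i.duration for i in items), len(items)

    @property
    def tau_cl(self) -> float:
        return self._totals("closed")[0]

    @property
    def tau_op(self) -> float:
        return self._totals("open")[0]

    @property
    def tau_ts(self) -> float:
        return sum(e.duration for e in self.excursions)

    @property
    def n_cl(self) -> int:
        return self._totals("closed")[1]

    @property
    def n_op(self) -> int:
        return self._totals("open")[1]


class StateSummary(NamedTuple):
    tau_total: float  # ns in the state
    n: int  # occurrences
    tau_ave: Optional[float]  # ns; None when n == 0
    p: float  # occupancy tau_total / total_time


def label_frames(series: TimeSeriesTable, defs: StateDefinition) -> np.ndarray:
    """Raw per-frame labels; exactly one label per frame (labeling is total)."""
    z, r = series.zeta, series.rmsd
    zc, zo = defs.zeta_closed_window, defs.zeta_open_window
    in_zc = (z >= zc[0]) & (z <= zc[1])
    in_zo = (z >= zo[0]) & (z <= zo[1])
    labels = np.full(series.n_frames, UNASSIGNED, dtype=np.int8)
    labels[in_zc & (r <= defs.rmsd_closed_max)] = CLOSED
    labels[in_zc & (r > defs.rmsd_closed_max)] = TRANSITION
    labels[in_zo & (r >= defs.rmsd_open_range[0]) & (r <= defs.rmsd_open_range[1])] = OPEN
    return labels


def resolve_unassigned(labels: np.ndarray) -> np.ndarray:
    """Give every unassigned frame the label of the nearest assigned frame.

    Ties between the preceding and following assigned frame go to the
    preceding one.
    """
    labels = np.asarray(labels, dtype=np.int8)
    assigned = np.flatnonzero(labels != UNASSIGNED)
    if len(assigned) == 0:
        raise ValidationError("all frames are unassigned; check the state definition")
    if len(assigned) == len(labels):
        return labels.copy()
    idx = np.arange(len(labels))
    pos = np.searchsorted(assigned, idx)
    prev = assigned[np.clip(pos - 1, 0, len(assigned) - 1)]
    nxt = assigned[np.clip(pos, 0, len(assigned) - 1)]
    d_prev = np.where(prev <= idx, idx - prev, np.iinfo(np.int64).max)
    d_next = np.where(nxt >= idx, nxt - idx, np.iinfo(np.int64).max)
    nearest = np.where(d_prev <= d_next, prev, nxt)  # tie -> preceding
    return labels[nearest]


def _run_lengths(labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode: (values, starts, lengths)."""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [len(labels)])))
    return labels[starts], starts, lengths


def _absorb_short_runs(
    values: np.ndarray, lengths: np.ndarray, target: int, min_frames: int
) -> np.ndarray:
    """Relabel runs of ``target`` shorter than ``min_frames`` to a flank label.

    Absorption goes to the preceding run's label (the following run's for a
    leading run).  Applied iteratively until stable so that newly merged
    runs are re-measured.
    """
    values = values.copy()
    while True:
        changed = False
        vals, starts, lens = values, None, lengths
        # recompute runs over current values with original frame lengths merged
        merged_vals: list[int] = []
        merged_lens: list[int] = []
        for v, ln in zip(vals, lens):
            if merged_vals and merged_vals[-1] == v:
                merged_lens[-1] += ln
            else:
                merged_vals.append(int(v))
                merged_lens.append(int(ln))
        vals = np.asarray(merged_vals)
        lens = np.asarray(merged_lens)
        for i, (v, ln) in enumerate(zip(vals, lens)):
            if v == target and ln < min_frames:
                if i > 0:
                    vals[i] = vals[i - 1]
                elif i + 1 < len(vals):
                    vals[i] = vals[i + 1]
                changed = True
                break
        values, lengths = vals, lens
        if not changed:
            return np.repeat(values, lengths)


def segment(
    labels: np.ndarray,
    times: np.ndarray,
    defs: StateDefinition,
) -> SegmentationResult:
    """Turn resolved frame labels into residences and excursions.

    Transition runs shorter than ``min_excursion_frames`` are absorbed into
    a flanking basin.  Surviving transition runs are typed by their flanks
    (ctc, oto, cto, otc).  Successful crossings (cto/otc, or a direct basin
    change) split the trajectory at the midpoint of the crossing interval,
    so residences alternate and tile [t0 − Δ/2, t_end + Δ/2] exactly.
    """
    labels = np.asarray(labels, dtype=np.int8)
    times = np.asarray(times, dtype=float)
    if len(labels) != len(times):
        raise ValidationError("labels and times must have equal length")
    if np.any(labels == UNASSIGNED):
        raise ValidationError("labels must be resolved before segmentation")
    step = float(times[1] - times[0])
    if defs.min_excursion_frames > 1:
        vals, _, lens = _run_lengths(labels)
        labels = _absorb_short_runs(vals, lens, TRANSITION, defs.min_excursion_frames)
    if defs.min_residence_frames > 1:
        for basin in (CLOSED, OPEN):
            vals, _, lens = _run_lengths(labels)
            labels = _absorb_short_runs(vals, lens, basin, defs.min_residence_frames)

    values, starts, lengths = _run_lengths(labels)
    t_lo = times[0] - step / 2.0
    t_hi = times[-1] + step / 2.0
    total_time = t_hi - t_lo

    def run_interval(i: int) -> Tuple[float, float]:
        s, ln = starts[i], lengths[i]
        return times[s] - step / 2.0, times[s + ln - 1] + step / 2.0

    basin_runs = [i for i, v in enumerate(values) if v in (CLOSED, OPEN)]
    if not basin_runs:
        raise ValidationError("no basin frames after filtering; nothing to segment")

    excursions: List[Excursion] = []
    boundaries: List[float] = []  # residence split times, in order
    first_label = LABEL_NAMES[int(values[basin_runs[0]])]

    prev_basin_value: Optional[int] = None
    for i, v in enumerate(values):
        if v == TRANSITION:
            # flanking basins; edge transition runs attach to the adjacent
            # residence without counting as excursions
            left = prev_basin_value
            right = next((int(values[j]) for j in range(i + 1, len(values))
                          if values[j] in (CLOSED, OPEN)), None)
            if left is None or right is None:
                continue
            lo, hi = run_interval(i)
            if left == right:
                excursions.append(Excursion("ctc" if left == CLOSED else "oto", lo, hi))
            else:
                # successful crossing: residence boundary at the midpoint
                # of the transition interval
                excursions.append(Excursion("cto" if left == CLOSED else "otc", lo, hi))
                boundaries.append((lo + hi) / 2.0)
        else:
            if (
                prev_basin_value is not None
                and v != prev_basin_value
                and values[i - 1] != TRANSITION
            ):
                # direct basin change: the crossing interval is empty, and
                # its midpoint is the shared frame-interval edge
                boundaries.append(run_interval(i)[0])
            prev_basin_value = int(v)

    residences: List[Residence] = []
    label = first_label
    start = t_lo
    for b in boundaries:
        residences.append(Residence(label, start, b))
        label = "open" if label == "closed" else "closed"
        start = b
    residences.append(Residence(label, start, t_hi))

    return SegmentationResult(
        residences=residences,
        excursions=excursions,
        total_time=total_time,
        step=step,
        no_crossings=(len(boundaries) == 0),
    )


def classify(series: TimeSeriesTable, defs: StateDefinition = StateDefinition()) -> SegmentationResult:
    """Label, resolve and segment in one call."""
    return segment(resolve_unassigned(label_frames(series, defs)), series.time, defs)


def summarize(seg: SegmentationResult) -> Dict[str, StateSummary]:
    """Per-state totals, counts, mean lifetimes and occupancies.

    Occupancy is total state time over total trajectory time; closed and
    open occupancies sum to 1 while ctc/oto occupancies overlap them.
    A state never visited reports ``tau_ave`` as None, not zero.
    """
    if not seg.residences:
        raise ValidationError("empty segmentation")
    out: Dict[str, StateSummary] = {}
    for kind in ("closed", "open", "ctc", "oto", "cto", "otc"):
        tau, n = seg._totals(kind)
        if kind in ("cto", "otc") and n == 0:
            continue
        out[kind] = StateSummary(
            tau_total=tau,
            n=n,
            tau_ave=(tau / n) if n else None,
            p=tau / seg.total_time,
        )
    return out


def summary_row(T: float, summary: Dict[str, StateSummary]) -> Dict[str, float]:
    """Flatten a summary into the per-temperature record the fits consume."""
    row: Dict[str, float] = {"T": float(T)}
    for kind, short in (("closed", "cl"), ("open", "op"), ("ctc", "ctc"), ("oto", "oto")):
        s = summary.get(kind)
        if s is None or s.n == 0:
            continue
        row[f"tau_{short}"] = s.tau_ave
        row[f"n_{short}"] = s.n
        row[f"p_{short}"] = s.p
    return row
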