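"""Readers and writers for every file the pipeline touches.

Plain-text formats only: TSV/CSV time series of per-frame observables,
multi-model PDB or XYZ coordinate frames, segmentation tables, and a
key-value result report.  Time is in ns, distances in Å, angles in degrees
wrapped to (−180, 180].
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Union

import numpy as np
import pandas as pd

from .constants import KB_KCAL_PER_MOL_K
from .errors import FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .kinetics import KineticsFit
    from .state_classifier import SegmentationResult
    from .thermodynamics import ThermoFit

PathLike = Union[str, Path]

_TIME_COL, _RMSD_COL, _ZETA_COL = "time_ns", "rmsd_A", "zeta_deg"

#: Relative tolerance on the uniformity of the time step.
STEP_RTOL = 1e-9


def wrap_angle_deg(angle):
    """Wrap an angle (scalar or array) into (−180, 180] degrees.

    Idempotent (values already in range are returned bit-identically), and
    preserves sin/cos of the input up to rounding.
    """
    a = np.asarray(angle, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return np.where((a > -180.0) & (a <= 180.0), a, wrapped)


@dataclass(frozen=True)
class TimeSeriesTable:
    """Per-frame (time, RMSD, ζ) observables on a uniform time grid."""

    time: np.ndarray  #: ns, strictly increasing, uniform step
    rmsd: np.ndarray  #: Å, non-negative
    zeta: np.ndarray  #: degrees in (−180, 180]

    def __post_init__(self) -> None:
        t, r, z = (np.asarray(a, dtype=float) for a in (self.time, self.rmsd, self.zeta))
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "rmsd", r)
        object.__setattr__(self, "zeta", z)
        if not (t.ndim == r.ndim == z.ndim == 1):
            raise ValidationError("time, rmsd and zeta must be 1-D")
        if not (len(t) == len(r) == len(z)):
            raise ValidationError("time, rmsd and zeta must have equal length")
        if len(t) < 2:
            raise ValidationError(f"need at least 2 frames, got {len(t)}")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError("time must be strictly increasing")
        step = dt[0]
        if np.any(np.abs(dt - step) > STEP_RTOL * max(abs(step), abs(t[-1]))):
            raise ValidationError("time step is not uniform")
        if np.any(r < 0):
            raise ValidationError("rmsd must be non-negative")
        if np.any((z <= -180.0) | (z > 180.0)):
            raise ValidationError("zeta must lie in (-180, 180]")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def step(self) -> float:
        """Uniform frame spacing in ns."""
        return float(self.time[1] - self.time[0])

    @classmethod
    def from_arrays(cls, time, rmsd, zeta, wrap: bool = True) -> "TimeSeriesTable":
        zeta = wrap_angle_deg(zeta) if wrap else np.asarray(zeta, float)
        return cls(np.asarray(time, float), np.asarray(rmsd, float), zeta)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({_TIME_COL: self.time, _RMSD_COL: self.rmsd, _ZETA_COL: self.zeta})


def _sep_for(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")


def read_timeseries(path: PathLike, dialect: str = "tsv") -> TimeSeriesTable:
    """Read a per-frame observable table.

    The file must have a header naming columns ``time_ns``, ``rmsd_A`` and
    ``zeta_deg``; extra columns are ignored.  ζ values outside (−180, 180]
    are wrapped into that interval on input.
    """
    try:
        df = pd.read_csv(path, sep=_sep_for(dialect), float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: could not parse {dialect} table: {exc}") from exc
    for col in (_TIME_COL, _RMSD_COL, _ZETA_COL):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return TimeSeriesTable.from_arrays(
        df[_TIME_COL].to_numpy(float),
        df[_RMSD_COL].to_numpy(float),
        df[_ZETA_COL].to_numpy(float),
        wrap=True,
    )


def write_timeseries(table: TimeSeriesTable, path: PathLike, dialect: str = "tsv") -> None:
    """Write a TimeSeriesTable at full (round-trippable) precision."""
    table.to_dataframe().to_csv(path, sep=_sep_for(dialect), index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Coordinate frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoordinateFrameSet:
    """Multi-frame coordinates sharing one ordered atom roster."""

    atom_names: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray  #: (n_frames, n_atoms, 3) Å
    times: np.ndarray  #: ns, one per frame

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", c)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(c)):
            raise ValidationError("coordinates must be finite")
        n_atoms = c.shape[1]
        for name in ("atom_names", "res_ids", "res_names", "chain_ids"):
            if len(getattr(self, name)) != n_atoms:
                raise ValidationError(f"{name} length does not match atom count")
        if len(self.times) != c.shape[0]:
            raise ValidationError("times length does not match frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def _read_pdb_models(path: PathLike) -> tuple:
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises InvalidFileError / ValueError
        raise FormatError(f"{path}: could not parse multi-model PDB: {exc}") from exc
    coords = np.atleast_3d(stack.coord)
    if coords.ndim == 2:  # single model came back as AtomArray
        coords = coords[None, :, :]
    return (
        np.asarray(stack.atom_name),
        np.asarray(stack.res_id, dtype=int),
        np.asarray(stack.res_name),
        np.asarray(stack.chain_id),
        coords,
    )


def _read_xyz(path: PathLike) -> tuple:
    # Minimal XYZ dialect: count line, comment line, then "name x y z" rows,
    # repeated per frame; every frame must repeat the first frame's roster.
    names: list[str] = []
    frames: list[list[list[float]]] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}") from exc
        if i + 2 + count > len(lines):
            raise FormatError(
                f"{path}:{i + 1}: frame declares {count} atoms but only "
                f"{len(lines) - i - 2} rows follow"
            )
        frame_names, frame_xyz = [], []
        for j in range(count):
            ln = i + 2 + j
            parts = lines[ln].split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln + 1}: expected 'name x y z', got {lines[ln]!r}")
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{ln + 1}: unparsable coordinate field in {lines[ln]!r}"
                ) from exc
            frame_names.append(parts[0])
            frame_xyz.append(xyz)
        if not names:
            names = frame_names
        elif frame_names != names:
            raise FormatError(f"{path}: frame {len(frames) + 1} has a different atom roster")
        frames.append(frame_xyz)
        i += 2 + count
    if not frames:
        raise FormatError(f"{path}: no frames found")
    n = len(names)
    return (
        np.array(names),
        np.arange(1, n + 1),
        np.array(["UNK"] * n),
        np.array(["A"] * n),
        np.asarray(frames, dtype=float),
    )


def read_frames(
    path: PathLike,
    format: str = "pdb_models",
    start_time_ns: float = 0.0,
    step_ns: float = 1.0,
) -> CoordinateFrameSet:
    """Read multi-frame coordinates from a PDB (MODEL/ENDMDL) or XYZ file.

    PDB carries no time field, so frame times are synthesized as
    ``start_time_ns + index * step_ns``.
    """
    if format == "pdb_models":
        names, res_ids, res_names, chains, coords = _read_pdb_models(path)
    elif format == "xyz":
        names, res_ids, res_names, chains, coords = _read_xyz(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'pdb_models' or 'xyz')")
    times = start_time_ns + step_ns * np.arange(coords.shape[0], dtype=float)
    return CoordinateFrameSet(names, res_ids, res_names, chains, coords, times)


# ---------------------------------------------------------------------------
# Segmentation table
# ---------------------------------------------------------------------------

def write_segments(segments: "SegmentationResult", path: PathLike) -> None:
    """Write residences and excursions to a TSV with exact durations."""
    res = list(segments.residences)
    exc = list(segments.excursions)
    if not res and not exc:
        raise ValidationError("segmentation is empty, nothing to write")
    res_sorted = sorted(res, key=lambda r: r.start)
    for a, b in zip(res_sorted, res_sorted[1:]):
        if b.start < a.end - 1e-12 * max(1.0, abs(a.end)):
            raise ValidationError(f"overlapping residences at {b.start} ns")
    rows = [
        {"label": r.label, "kind": "residence", "start_ns": r.start, "end_ns": r.end}
        for r in res_sorted
    ] + [
        {"label": e.subtype, "kind": "excursion", "start_ns": e.start, "end_ns": e.end}
        for e in sorted(exc, key=lambda e: e.start)
    ]
    df = pd.DataFrame(rows)
    df["duration_ns"] = df["end_ns"] - df["start_ns"]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_segments(path: PathLike) -> pd.DataFrame:
    """Read a segmentation TSV back into a DataFrame."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("label", "kind", "start_ns", "end_ns", "duration_ns"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


# ---------------------------------------------------------------------------
# Key-value report
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    if isinstance(value, float):
        if math.isnan(value):
            return "nan"
        return repr(value)
    return str(value)


def write_keyvalues(items: Mapping[str, object], path: PathLike) -> None:
    with open(path, "w") as fh:
        for key, value in items.items():
            fh.write(f"{key} = {_fmt(value)}\n")


def read_keyvalues(path: PathLike) -> dict:
    """Parse a key-value report; numeric values come back as floats."""
    out: dict[str, object] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            raw = raw.strip()
            try:
                out[key.strip()] = float(raw)
            except ValueError:
                out[key.strip()] = raw
    return out


def report_items(thermo: "ThermoFit | None", kinetics: "KineticsFit | None") -> dict:
    """Flatten fit results into the key-value report schema."""
    items: dict[str, object] = {"boltzmann_kcal_per_mol_K": KB_KCAL_PER_MOL_K}
    if thermo is not None:
        items["convention"] = thermo.convention
        items["enthalpy_kcal_per_mol"] = float(thermo.dH)
        items["entropy_eu"] = float(thermo.dS_eu)
        items["melting_temperature_K"] = float(thermo.t_m)
        items["enthalpy_stderr_kcal_per_mol"] = float(thermo.dH_stderr)
        items["entropy_stderr_eu"] = float(thermo.dS_stderr_eu)
        for rec in thermo.records:
            pfx = f"T{rec.T:g}"
            items[f"{pfx}.p_closed"] = float(rec.p_cl)
            items[f"{pfx}.p_open"] = float(rec.p_op)
            items[f"{pfx}.delta_g_kcal_per_mol"] = float(rec.dG)
    if kinetics is not None:
        items["barrier_closed_kcal_per_mol"] = float(kinetics.dG_c)
        items["curvature_ratio_closed"] = float(kinetics.omega_ratio_closed)
        if kinetics.entropy_open_eu is not None:
            items["barrier_open_entropy_eu"] = float(kinetics.entropy_open_eu)
        if kinetics.omega_ratio_open is not None:
            items["curvature_ratio_open"] = float(kinetics.omega_ratio_open)
        for rec in kinetics.records:
            pfx = f"T{rec.T:g}"
            items[f"{pfx}.lifetime_closed_ns"] = float(rec.tau_cl)
            items[f"{pfx}.lifetime_open_ns"] = float(rec.tau_op)
            items[f"{pfx}.opening_rate_per_ns"] = float(rec.k_minus)
            items[f"{pfx}.closing_rate_per_ns"] = float(rec.k_plus)
            items[f"{pfx}.tp_time_open_to_closed_ns"] = float(rec.ttp_oc)
            items[f"{pfx}.tp_time_closed_to_open_ns"] = float(rec.ttp_co)
            items[f"{pfx}.ratio_closed"] = float(rec.ratio_cl)
            items[f"{pfx}.ratio_open"] = float(rec.ratio_op)
    return items


def write_report(
    thermo: "ThermoFit | None", kinetics: "KineticsFit | None", path: PathLike
) -> None:
    """Write the machine-parseable result report (see :func:`read_keyvalues`)."""
    write_keyvalues(report_items(thermo, kinetics), path)
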