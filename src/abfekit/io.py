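"""Data model and readers/writers for alchemical free-energy legs.

The core containers are :class:`LambdaSchedule` (the staged coupling-parameter
vectors defining one leg of the thermodynamic cycle), :class:`WindowSamples`
(the time series recorded in one lambda window: dH/dlambda components and the
potential-energy differences to every other window of the same stage) and
:class:`LegEnsemble` (one replica of one leg: schedule plus one WindowSamples
per window).

Readers cover the GROMACS dhdl ``.xvg`` dialect and a documented plain-CSV
interchange format, plus the experimental affinity and elaboration-decision
tables.  Energies are stored internally in kcal/mol; reduced potentials
``u = U / k_B T`` are computed lazily at the stated temperature.
"""

from __future__ import annotations

import csv
import io as _io
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np

from ._constants import DEFAULT_TEMPERATURE, KJ_PER_KCAL, kt_kcal

logger = logging.getLogger(__name__)

STAGE_NAMES = ("coul", "vdw", "restraint")

#: Canonical lambda schedules: 11 electrostatics windows at intervals of 0.1,
#: 21 van der Waals windows at intervals of 0.05, and a 12-window
#: non-uniform restraint switching schedule.
CANONICAL_STAGES = {
    "coul": tuple(round(0.1 * i, 10) for i in range(11)),
    "vdw": tuple(round(0.05 * i, 10) for i in range(21)),
    "restraint": (0.0, 0.01, 0.025, 0.05, 0.075, 0.1, 0.15, 0.2, 0.35, 0.5, 0.75, 1.0),
}


class XVGParseError(ValueError):
    """Raised when a dhdl ``.xvg`` stream violates the expected dialect."""


class TableError(ValueError):
    """Raised when an affinity or decision table row cannot be interpreted."""


# ---------------------------------------------------------------------------
# Lambda schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LambdaSchedule:
    """Staged lambda vectors defining one alchemical leg.

    Parameters
    ----------
    stages
        Ordered ``(stage_name, lambda_values)`` pairs; stage names are
        ``coul``, ``vdw`` or ``restraint``.
    leg_kind
        ``"complex"`` (protein-ligand, includes exactly one restraint stage)
        or ``"solvent"`` (ligand in water, no restraint stage).
    """

    stages: tuple[tuple[str, tuple[float, ...]], ...]
    leg_kind: str

    def __post_init__(self):
        object.__setattr__(
            self,
            "stages",
            tuple((name, tuple(float(x) for x in lams)) for name, lams in self.stages),
        )

    @property
    def stage_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.stages)

    def stage_lambdas(self, name: str) -> tuple[float, ...]:
        for stage_name, lams in self.stages:
            if stage_name == name:
                return lams
        raise KeyError(f"schedule has no stage {name!r}")

    @property
    def n_windows(self) -> int:
        return sum(len(lams) for _, lams in self.stages)

    def violations(self) -> list[str]:
        """Invariant violations, empty when the schedule is valid."""
        out: list[str] = []
        for name, lams in self.stages:
            if name not in STAGE_NAMES:
                out.append(f"unknown stage name {name!r}")
            if len(lams) < 2:
                out.append(f"stage {name!r} has {len(lams)} windows; need >= 2")
                continue
            if lams[0] != 0.0:
                out.append(f"stage {name!r} does not start at 0.0 (starts {lams[0]})")
            if lams[-1] != 1.0:
                out.append(f"stage {name!r} does not end at 1.0 (ends {lams[-1]})")
            if any(b <= a for a, b in zip(lams, lams[1:])):
                out.append(f"stage {name!r} lambda values are not strictly increasing")
            if any(x < 0.0 or x > 1.0 for x in lams):
                out.append(f"stage {name!r} has lambda values outside [0, 1]")
        n_restraint = sum(1 for name, _ in self.stages if name == "restraint")
        if self.leg_kind == "solvent" and n_restraint:
            out.append("solvent legs must not contain a restraint stage")
        elif self.leg_kind == "complex" and n_restraint != 1:
            out.append(
                f"complex legs must contain exactly one restraint stage (found {n_restraint})"
            )
        elif self.leg_kind not in ("solvent", "complex"):
            out.append(f"unknown leg_kind {self.leg_kind!r}")
        seen = set()
        for name, _ in self.stages:
            if name in seen:
                out.append(f"duplicate stage {name!r}")
            seen.add(name)
        return out

    @classmethod
    def solvent_default(cls) -> "LambdaSchedule":
        """Canonical solvent leg: 11 coul + 21 vdw windows."""
        return cls(
            stages=(("coul", CANONICAL_STAGES["coul"]), ("vdw", CANONICAL_STAGES["vdw"])),
            leg_kind="solvent",
        )

    @classmethod
    def complex_default(cls) -> "LambdaSchedule":
        """Canonical complex leg: 12 restraint + 11 coul + 21 vdw windows."""
        return cls(
            stages=(
                ("restraint", CANONICAL_STAGES["restraint"]),
                ("coul", CANONICAL_STAGES["coul"]),
                ("vdw", CANONICAL_STAGES["vdw"]),
            ),
            leg_kind="complex",
        )

    @classmethod
    def single_stage(cls, name: str, lambdas: Sequence[float], leg_kind: str = "solvent") -> "LambdaSchedule":
        return cls(stages=((name, tuple(lambdas)),), leg_kind=leg_kind)


@dataclass(frozen=True)
class ScheduleReport:
    """Validation report for a :class:`LambdaSchedule`."""

    valid: bool
    violations: tuple[str, ...]
    canonical_stages: tuple[str, ...]  # stages matching a canonical preset

    def __str__(self) -> str:
        if self.valid:
            extra = (
                f" (canonical stages: {', '.join(self.canonical_stages)})"
                if self.canonical_stages
                else ""
            )
            return f"schedule valid{extra}"
        return "schedule invalid:\n" + "\n".join(f"  - {v}" for v in self.violations)


def validate_schedule(schedule: LambdaSchedule) -> ScheduleReport:
    """Check schedule invariants and flag stages matching the canonical presets.

    Never raises; violations are listed in the report.
    """
    violations = tuple(schedule.violations())
    canonical = tuple(
        name
        for name, lams in schedule.stages
        if name in CANONICAL_STAGES
        and len(lams) == len(CANONICAL_STAGES[name])
        and all(abs(a - b) < 1e-9 for a, b in zip(lams, CANONICAL_STAGES[name]))
    )
    return ScheduleReport(valid=not violations, violations=violations, canonical_stages=canonical)


# ---------------------------------------------------------------------------
# Window samples
# ---------------------------------------------------------------------------


@dataclass
class WindowSamples:
    """Time series recorded in one lambda window.

    ``energies`` holds, per stored frame, the potential-energy difference
    (kcal/mol) between every window of the stage and this window; the column
    for the window itself is identically zero.  Reduced potentials are
    obtained with :meth:`u_foreign` at the stored temperature.  Rows with a
    common per-frame offset give identical free energies under MBAR, so
    storing differences to the sampling window loses nothing.
    """

    window_index: int
    own_lambda: tuple[float, ...]
    times: np.ndarray  # (n_frames,) ps
    energies: np.ndarray  # (n_frames, n_stage_windows) kcal/mol
    dhdl: np.ndarray | None = None  # (n_frames, n_components) kcal/mol
    temperature: float = DEFAULT_TEMPERATURE
    foreign_lambdas: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.dhdl is not None:
            self.dhdl = np.atleast_2d(np.asarray(self.dhdl, dtype=float))
        if isinstance(self.own_lambda, (int, float)):
            self.own_lambda = (float(self.own_lambda),)
        else:
            self.own_lambda = tuple(float(x) for x in self.own_lambda)
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.energies.shape[0] != self.times.shape[0]:
            raise ValueError("energies and times disagree on frame count")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame spacing must be uniform within a window")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_stage_windows(self) -> int:
        return self.energies.shape[1]

    @property
    def timestep(self) -> float:
        """Frame spacing in ps (nan for fewer than two frames)."""
        if len(self.times) < 2:
            return float("nan")
        return float(self.times[1] - self.times[0])

    def u_foreign(self, temperature: float | None = None) -> np.ndarray:
        """Reduced potentials u = U/k_BT, shape (n_frames, n_stage_windows)."""
        T = self.temperature if temperature is None else temperature
        return self.energies / kt_kcal(T)

    def sliced(self, index: np.ndarray | slice) -> "WindowSamples":
        """A copy restricted to the selected frames."""
        return replace(
            self,
            times=self.times[index],
            energies=self.energies[index],
            dhdl=None if self.dhdl is None else self.dhdl[index],
        )


@dataclass
class LegEnsemble:
    """One replica of one alchemical leg.

    ``windows`` is flat and ordered stage by stage following ``schedule``;
    :meth:`stage_windows` recovers the per-stage groups.
    """

    schedule: LambdaSchedule
    windows: list[WindowSamples]
    replica_id: str = "r1"
    system_id: str = ""
    ligand_id: str = ""

    def __post_init__(self):
        if len(self.windows) != self.schedule.n_windows:
            raise ValueError(
                f"expected {self.schedule.n_windows} windows for schedule, got {len(self.windows)}"
            )
        temps = {w.temperature for w in self.windows}
        if len(temps) > 1:
            raise ValueError(f"windows disagree on temperature: {sorted(temps)}")
        offset = 0
        for name, lams in self.schedule.stages:
            for w in self.windows[offset : offset + len(lams)]:
                if w.n_stage_windows != len(lams):
                    raise ValueError(
                        f"window in stage {name!r} has {w.n_stage_windows} foreign "
                        f"columns; stage has {len(lams)} windows"
                    )
            offset += len(lams)

    @property
    def temperature(self) -> float:
        return self.windows[0].temperature

    def stage_windows(self, name: str) -> list[WindowSamples]:
        offset = 0
        for stage_name, lams in self.schedule.stages:
            if stage_name == name:
                return self.windows[offset : offset + len(lams)]
            offset += len(lams)
        raise KeyError(f"leg has no stage {name!r}")

    def n_k(self, stage: str) -> np.ndarray:
        """Retained sample count per window of a stage."""
        return np.array([w.n_frames for w in self.stage_windows(stage)], dtype=int)


def truncate_equilibration(leg: LegEnsemble, discard_ps: float = 1000.0) -> LegEnsemble:
    """Drop the initial *discard_ps* of every production window.

    Frames with ``time >= discard_ps`` are retained (default 1 ns, discarded
    as extra equilibration time).  Raises ``ValueError`` if any window would
    be left empty.
    """
    if discard_ps < 0:
        raise ValueError(f"discard_ps must be non-negative, got {discard_ps}")
    if discard_ps == 0:
        return leg
    new_windows = []
    for w in leg.windows:
        keep = w.times >= discard_ps
        if not keep.any():
            raise ValueError(
                f"discarding {discard_ps} ps leaves no frames in window "
                f"{w.window_index} (last frame at {w.times[-1] if w.n_frames else 'n/a'} ps)"
            )
        new_windows.append(w.sliced(keep))
    return replace(leg, windows=new_windows)


# ---------------------------------------------------------------------------
# GROMACS dhdl .xvg reader
# ---------------------------------------------------------------------------

_RE_TEMPERATURE = re.compile(r"T\s*=\s*([0-9.eE+-]+)")
_RE_STATE = re.compile(r"state\s+(\d+)")
_RE_LAMBDA_TUPLE = re.compile(r"(?:=|\bto)\s*\(([^)]*)\)\s*\"?\s*$")
_RE_LAMBDA_SCALAR = re.compile(r"(?:=|\bto)\s*([0-9.eE+-]+)\s*\"?\s*$")
_RE_LEGEND = re.compile(r"^@\s*s(\d+)\s+legend\s+\"(.*)\"")


def _parse_lambda_value(text: str) -> tuple[float, ...] | None:
    m = _RE_LAMBDA_TUPLE.search(text)
    if m:
        return tuple(float(x) for x in m.group(1).split(","))
    m = _RE_LAMBDA_SCALAR.search(text)
    if m:
        return (float(m.group(1)),)
    return None


def parse_dhdl_xvg(source: str | Path | TextIO) -> WindowSamples:
    """Parse a GROMACS dhdl ``.xvg`` stream into a :class:`WindowSamples`.

    The dialect: ``#`` comment lines; ``@`` metadata lines carrying the
    subtitle (temperature, own lambda state), axis labels (energy unit) and
    per-column legends (dH/dlambda components, Delta-H to each foreign
    state, optional pV term); whitespace-separated numeric rows starting
    with the time in ps.  Energies are converted to kcal/mol on read.

    Raises :class:`XVGParseError` on malformed rows (naming the line
    number), missing lambda metadata, or non-monotone times.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source) as fh:
            return parse_dhdl_xvg(fh)
    if isinstance(source, str):
        source = _io.StringIO(source)

    temperature: float | None = None
    own_lambda: tuple[float, ...] | None = None
    window_index: int | None = None
    unit_factor = 1.0 / KJ_PER_KCAL  # GROMACS default is kJ/mol
    legends: dict[int, str] = {}
    rows: list[list[float]] = []
    row_lines: list[int] = []
    n_cols: int | None = None

    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@"):
            m = _RE_LEGEND.match(line)
            if m:
                legends[int(m.group(1))] = m.group(2)
                continue
            if "subtitle" in line:
                tm = _RE_TEMPERATURE.search(line)
                if tm:
                    temperature = float(tm.group(1))
                sm = _RE_STATE.search(line)
                if sm:
                    window_index = int(sm.group(1))
                lam = _parse_lambda_value(line)
                if lam is not None:
                    own_lambda = lam
            elif "yaxis" in line and "label" in line:
                if "kcal" in line:
                    unit_factor = 1.0
                elif "kJ" in line:
                    unit_factor = 1.0 / KJ_PER_KCAL
            continue
        # numeric row
        fields = line.split()
        try:
            values = [float(x) for x in fields]
        except ValueError as exc:
            raise XVGParseError(f"line {lineno}: non-numeric field in data row") from exc
        if n_cols is None:
            n_cols = len(values)
        elif len(values) != n_cols:
            raise XVGParseError(
                f"line {lineno}: expected {n_cols} columns, found {len(values)}"
            )
        rows.append(values)
        row_lines.append(lineno)

    if own_lambda is None:
        raise XVGParseError("missing lambda-state metadata in subtitle")
    if not rows:
        raise XVGParseError("no data rows found")
    if temperature is None:
        logger.warning("no temperature in subtitle; assuming %.2f K", DEFAULT_TEMPERATURE)
        temperature = DEFAULT_TEMPERATURE

    data = np.array(rows, dtype=float)
    times = data[:, 0]
    if np.any(np.diff(times) <= 0):
        raise XVGParseError("time column is not strictly increasing")

    # classify data columns (column i+1 corresponds to legend s<i>)
    dhdl_cols: list[int] = []
    foreign_cols: list[int] = []
    foreign_lams: list[tuple[float, ...]] = []
    for s_index in sorted(legends):
        legend = legends[s_index]
        col = s_index + 1
        if col >= data.shape[1]:
            raise XVGParseError(f"legend s{s_index} refers to a missing data column")
        if "dH/d" in legend:
            dhdl_cols.append(col)
        elif "pV" in legend:
            continue
        elif "H" in legend and "to" in legend:
            lam = _parse_lambda_value(legend)
            if lam is None:
                raise XVGParseError(f"cannot parse foreign lambda from legend: {legend!r}")
            foreign_cols.append(col)
            foreign_lams.append(lam)
    if not foreign_cols:
        raise XVGParseError("no Delta-H foreign-state columns found in legends")

    energies = data[:, foreign_cols] * unit_factor
    dhdl = data[:, dhdl_cols] * unit_factor if dhdl_cols else None

    if window_index is None:
        # fall back to locating own lambda among the foreign states
        matches = [
            i
            for i, lam in enumerate(foreign_lams)
            if len(lam) == len(own_lambda)
            and all(abs(a - b) < 1e-9 for a, b in zip(lam, own_lambda))
        ]
        window_index = matches[0] if matches else 0

    return WindowSamples(
        window_index=window_index,
        own_lambda=own_lambda,
        times=times,
        energies=energies,
        dhdl=dhdl,
        temperature=temperature,
        foreign_lambdas=tuple(foreign_lams),
    )


# ---------------------------------------------------------------------------
# CSV interchange format for WindowSamples
# ---------------------------------------------------------------------------

_INTERCHANGE_MAGIC = "# abfekit-window-samples v1"


def write_window_csv(window: WindowSamples, dest: str | Path | TextIO) -> None:
    """Write a :class:`WindowSamples` in the plain-CSV interchange format.

    Header comment lines carry the metadata; the column block is
    ``time_ps, dhdl_<j>..., dE_<k>...`` with energies in kcal/mol at full
    precision (round-trips bit-exactly through :func:`read_window_csv`).
    """
    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="") as fh:
            write_window_csv(window, fh)
        return
    fh = dest
    fh.write(_INTERCHANGE_MAGIC + "\n")
    fh.write(f"# window_index={window.window_index}\n")
    fh.write("# own_lambda=" + ",".join(repr(float(x)) for x in window.own_lambda) + "\n")
    fh.write(f"# temperature={float(window.temperature)!r}\n")
    if window.foreign_lambdas is not None:
        for lam in window.foreign_lambdas:
            fh.write("# foreign_lambda=" + ",".join(repr(float(x)) for x in lam) + "\n")
    n_dhdl = 0 if window.dhdl is None else window.dhdl.shape[1]
    header = (
        ["time_ps"]
        + [f"dhdl_{j}" for j in range(n_dhdl)]
        + [f"dE_{k}" for k in range(window.n_stage_windows)]
    )
    writer = csv.writer(fh)
    writer.writerow(header)
    for i in range(window.n_frames):
        row = [repr(float(window.times[i]))]
        if window.dhdl is not None:
            row += [repr(float(x)) for x in window.dhdl[i]]
        row += [repr(float(x)) for x in window.energies[i]]
        writer.writerow(row)


def read_window_csv(source: str | Path | TextIO) -> WindowSamples:
    """Read the interchange CSV written by :func:`write_window_csv`."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_window_csv(fh)
    meta: dict[str, str] = {}
    foreign: list[tuple[float, ...]] = []
    lines = []
    for raw in source:
        line = raw.rstrip("\n")
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                if key.strip() == "foreign_lambda":
                    foreign.append(tuple(float(x) for x in value.split(",")))
                else:
                    meta[key.strip()] = value.strip()
            continue
        if line:
            lines.append(line)
    if not lines:
        raise TableError("interchange CSV contains no data")
    reader = csv.reader(lines)
    header = next(reader)
    dhdl_cols = [i for i, h in enumerate(header) if h.startswith("dhdl_")]
    e_cols = [i for i, h in enumerate(header) if h.startswith("dE_")]
    rows = [[float(x) for x in row] for row in reader if row]
    data = np.array(rows, dtype=float)
    return WindowSamples(
        window_index=int(meta.get("window_index", 0)),
        own_lambda=tuple(float(x) for x in meta["own_lambda"].split(",")),
        times=data[:, 0],
        energies=data[:, e_cols],
        dhdl=data[:, dhdl_cols] if dhdl_cols else None,
        temperature=float(meta.get("temperature", DEFAULT_TEMPERATURE)),
        foreign_lambdas=tuple(foreign) if foreign else None,
    )


# ---------------------------------------------------------------------------
# Affinity and decision tables
# ---------------------------------------------------------------------------

_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
    "fM": 1e-15,
}

MEASURES = ("Kd", "Ki", "IC50")


@dataclass(frozen=True)
class AffinityRecord:
    """One experimental affinity measurement.

    ``value`` is in molar.  Censored records were reported only as a bound:
    ``bound_direction="upper"`` means the dissociation/inhibition constant
    exceeds ``value`` (an upper bound on affinity, e.g. Ki > 1000 uM).
    """

    ligand_id: str
    measure: str
    value: float
    censored: bool = False
    bound_direction: str = "none"
    system_id: str = ""

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise TableError(f"unknown measure {self.measure!r}; expected one of {MEASURES}")
        if not (self.value > 0):
            raise TableError(f"affinity value must be positive, got {self.value}")
        if self.censored and self.bound_direction not in ("upper", "lower"):
            raise TableError("censored records need bound_direction 'upper' or 'lower'")
        if not self.censored and self.bound_direction != "none":
            raise TableError("uncensored records must have bound_direction 'none'")


_CENSOR_FALSE = {"", "no", "false", "0", "none", "="}


def _parse_censor_flag(text: str) -> tuple[bool, str]:
    text = text.strip()
    if text.lower() in _CENSOR_FALSE:
        return False, "none"
    if text in (">", "gt") or text.lower() in ("upper", "yes>"):
        return True, "upper"
    if text in ("<", "lt") or text.lower() == "lower":
        return True, "lower"
    raise TableError(f"cannot interpret censored flag {text!r} (use 'no', '>' or '<')")


def read_affinity_table(source: str | Path | TextIO) -> list[AffinityRecord]:
    """Read an experimental affinity CSV.

    Expected header: ``ligand_id, measure, value, unit, censored`` with an
    optional ``system_id`` column.  Units nM/uM/mM/M (and pM/fM) are
    normalised to molar; the censored column takes ``no``, ``>`` (bound on a
    weakly binding ligand, Ki above the stated value) or ``<``.

    Raises :class:`TableError` naming the offending row on unknown units or
    non-positive values.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="") as fh:
            return read_affinity_table(fh)
    reader = csv.DictReader(source, skipinitialspace=True)
    records = []
    for i, row in enumerate(reader, start=2):  # header is line 1
        try:
            unit = row["unit"].strip()
            if unit not in _UNIT_TO_MOLAR:
                raise TableError(f"unknown unit {unit!r}")
            value = float(row["value"]) * _UNIT_TO_MOLAR[unit]
            if not value > 0:
                raise TableError(f"non-positive value {row['value']!r}")
            censored, direction = _parse_censor_flag(row.get("censored", ""))
            records.append(
                AffinityRecord(
                    ligand_id=row["ligand_id"].strip(),
                    measure=row["measure"].strip(),
                    value=value,
                    censored=censored,
                    bound_direction=direction,
                    system_id=(row.get("system_id") or "").strip(),
                )
            )
        except (KeyError, ValueError, TableError) as exc:
            raise TableError(f"affinity table row {i}: {exc}") from exc
    return records


def read_decision_table(source: str | Path | TextIO) -> list[tuple[str, str, str]]:
    """Read an elaboration-decision CSV: ``decision_id, parent, child`` rows.

    A decision groups one or more (parent, child) ligand pairs that together
    test a chemical modification; multiple rows may share a decision id.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="") as fh:
            return read_decision_table(fh)
    reader = csv.DictReader(source, skipinitialspace=True)
    out = []
    for i, row in enumerate(reader, start=2):
        try:
            out.append(
                (row["decision_id"].strip(), row["parent"].strip(), row["child"].strip())
            )
        except KeyError as exc:
            raise TableError(f"decision table row {i}: missing column {exc}") from exc
    return out
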