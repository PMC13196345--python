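"""Plate-based screen data model, I/O, WT-referenced normalization, replicate aggregation.

A screen is a collection of 96-well plates read out with the JC-10
ratiometric mitochondrial membrane potential dye.  Each well carries the
red (F590, aggregate form) and green (F520, monomer form) fluorescence of
the whole well; the F590/F520 ratio rises with membrane-potential
polarization.  Every plate carries untreated wild-type (WT) wells used as
the normalization reference, untreated mutant (MT) wells, and — on drug
plates — FCCP-depolarized wells that anchor the zero-potential end of the
assay range.  Treatments are run on duplicate plates and averaged.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WellRole",
    "WellMeasurement",
    "Plate",
    "PlateLayout",
    "ScreenDataset",
    "NormalizedValue",
    "InvalidMeasurementError",
    "MissingReferenceError",
    "ScreenFormatError",
    "LayoutError",
    "well_ratio",
    "well_name",
    "parse_well",
    "normalize_plate",
    "normalize_screen",
    "aggregate_replicates",
    "read_screen_csv",
    "write_screen_csv",
    "write_normalized_csv",
]

_ROWS = "ABCDEFGH"
_WELL_RE = re.compile(r"^([A-Ha-h])(\d{1,2})$")


class InvalidMeasurementError(ValueError):
    """A well measurement violates a physical constraint (e.g. F520 <= 0)."""


class MissingReferenceError(ValueError):
    """A plate has no WT reference wells to normalize against."""


class ScreenFormatError(ValueError):
    """A screen CSV is malformed (bad rows, duplicate wells, missing columns)."""


class LayoutError(ValueError):
    """A plate violates the expected control/treatment layout."""


class WellRole(str, enum.Enum):
    WT_CONTROL = "wt_control"
    MT_CONTROL = "mt_control"
    FCCP_CONTROL = "fccp_control"
    TREATMENT = "treatment"


def well_ratio(f590: float, f520: float) -> float:
    """F590/F520 ratio of one well.

    Parameters
    ----------
    f590 : red-channel intensity (arbitrary units, >= 0)
    f520 : green-channel intensity (arbitrary units, > 0)
    """
    if not f520 > 0:
        raise InvalidMeasurementError(f"f520 must be > 0, got {f520!r}")
    if f590 < 0:
        raise InvalidMeasurementError(f"f590 must be >= 0, got {f590!r}")
    return f590 / f520


def well_name(row: str, col: int) -> str:
    """Canonical well address, e.g. ('b', 7) -> 'B7'."""
    return f"{row.upper()}{int(col)}"


def parse_well(name: str) -> tuple[str, int]:
    m = _WELL_RE.match(name.strip())
    if not m:
        raise ScreenFormatError(f"unparseable well address {name!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if row not in _ROWS or not 1 <= col <= 12:
        raise ScreenFormatError(f"well {name!r} outside 96-well range A1-H12")
    return row, col


@dataclass(frozen=True)
class WellMeasurement:
    """One well's two-channel readout with its role and treatment identity."""

    plate_id: str
    row: str
    col: int
    role: WellRole
    f590: float
    f520: float
    treatment_id: str | None = None

    def __post_init__(self) -> None:
        if self.row not in _ROWS or not 1 <= self.col <= 12:
            raise ScreenFormatError(
                f"well {self.row}{self.col} outside 96-well range A1-H12"
            )
        if not self.f520 > 0:
            raise InvalidMeasurementError(
                f"{self.plate_id}:{self.well}: f520 must be > 0, got {self.f520}"
            )
        if self.f590 < 0:
            raise InvalidMeasurementError(
                f"{self.plate_id}:{self.well}: f590 must be >= 0, got {self.f590}"
            )
        has_tid = self.treatment_id is not None
        if (self.role is WellRole.TREATMENT) != has_tid:
            raise LayoutError(
                f"{self.plate_id}:{self.well}: treatment_id must be present "
                f"iff role=treatment (role={self.role.value}, id={self.treatment_id!r})"
            )

    @property
    def well(self) -> str:
        return well_name(self.row, self.col)

    @property
    def ratio(self) -> float:
        return self.f590 / self.f520


@dataclass
class Plate:
    plate_id: str
    wells: list[WellMeasurement]

    def by_role(self, role: WellRole) -> list[WellMeasurement]:
        return [w for w in self.wells if w.role is role]


#: expected control counts per screen type: (n_wt, n_mt, n_fccp)
_CONTROL_COUNTS = {"drug": (3, 3, 2), "sirna": (4, 4, 0)}


@dataclass
class PlateLayout:
    """Role map of one plate plus the control/treatment census."""

    screen_type: str
    well_roles: dict[str, WellRole]
    n_wt: int
    n_mt: int
    n_fccp: int
    n_treatment: int

    @classmethod
    def from_plate(cls, plate: Plate, screen_type: str) -> "PlateLayout":
        roles: dict[str, WellRole] = {}
        for w in plate.wells:
            if w.well in roles:
                raise LayoutError(f"{plate.plate_id}: duplicate well {w.well}")
            roles[w.well] = w.role
        counts = {r: sum(1 for v in roles.values() if v is r) for r in WellRole}
        return cls(
            screen_type=screen_type,
            well_roles=roles,
            n_wt=counts[WellRole.WT_CONTROL],
            n_mt=counts[WellRole.MT_CONTROL],
            n_fccp=counts[WellRole.FCCP_CONTROL],
            n_treatment=counts[WellRole.TREATMENT],
        )

    def validate(self) -> list[str]:
        """Return human-readable layout violations (empty list = valid)."""
        problems: list[str] = []
        if len(self.well_roles) > 96:
            problems.append(f"{len(self.well_roles)} wells exceeds 96")
        exp = _CONTROL_COUNTS.get(self.screen_type)
        if exp is None:
            problems.append(f"unknown screen_type {self.screen_type!r}")
            return problems
        n_wt, n_mt, n_fccp = exp
        if self.n_wt != n_wt:
            problems.append(f"expected {n_wt} WT wells, found {self.n_wt}")
        if self.n_mt != n_mt:
            problems.append(f"expected {n_mt} MT wells, found {self.n_mt}")
        if self.n_fccp != n_fccp:
            problems.append(f"expected {n_fccp} FCCP wells, found {self.n_fccp}")
        if self.screen_type == "sirna" and self.n_treatment > 80:
            problems.append(f"siRNA plate carries {self.n_treatment} > 80 treatments")
        return problems


@dataclass
class ScreenDataset:
    """An ordered collection of plates plus the treatment -> wells replicate map."""

    screen_type: str
    plates: list[Plate]
    replicate_map: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.replicate_map:
            self.replicate_map = self._build_replicate_map()

    def _build_replicate_map(self) -> dict[str, list[tuple[str, str]]]:
        rep: dict[str, list[tuple[str, str]]] = {}
        for plate in self.plates:
            for w in plate.by_role(WellRole.TREATMENT):
                rep.setdefault(w.treatment_id, []).append((plate.plate_id, w.well))
        return rep

    @property
    def n_treatments(self) -> int:
        return len(self.replicate_map)

    def validate_layouts(self) -> dict[str, list[str]]:
        out = {}
        for plate in self.plates:
            problems = PlateLayout.from_plate(plate, self.screen_type).validate()
            if problems:
                out[plate.plate_id] = problems
        return out


def normalize_plate(wells: Sequence[WellMeasurement]) -> dict[str, float]:
    """Normalize every well's ratio to the same-plate WT-control mean.

    Returns a map well address -> normalized ratio.  The per-plate mean of
    the normalized WT wells is exactly 1, and the result is invariant to a
    common positive rescaling of all raw intensities on the plate.
    """
    wt = [w.ratio for w in wells if w.role is WellRole.WT_CONTROL]
    if not wt:
        plate = wells[0].plate_id if wells else "<empty>"
        raise MissingReferenceError(f"plate {plate}: no wt_control wells")
    ref = float(np.mean(wt))
    return {w.well: w.ratio / ref for w in wells}


def normalize_screen(screen: ScreenDataset) -> dict[str, dict[str, float]]:
    """Per-plate normalization maps for a whole screen, keyed by plate_id."""
    return {p.plate_id: normalize_plate(p.wells) for p in screen.plates}


@dataclass
class NormalizedValue:
    """Replicate-aggregated normalized readout of one treatment.

    ``cv_percent`` is 100 x sample SD (ddof=1) / mean across replicate
    wells; a single-replicate treatment gets cv_percent = 0 and is flagged.
    """

    treatment_id: str
    replicates: tuple[float, ...]
    aggregate: float
    cv_percent: float
    flagged_single: bool = False


def aggregate_replicates(
    screen: ScreenDataset, normalized: Mapping[str, Mapping[str, float]]
) -> list[NormalizedValue]:
    """Average each treatment's normalized values across its replicate wells."""
    out: list[NormalizedValue] = []
    for tid, wells in screen.replicate_map.items():
        reps = []
        for plate_id, well in wells:
            plate_map = normalized.get(plate_id)
            if plate_map is not None and well in plate_map:
                reps.append(plate_map[well])
        if not reps:
            logger.warning("treatment %s has no normalized replicates; dropped", tid)
            continue
        reps_t = tuple(reps)
        agg = float(np.mean(reps_t))
        if len(reps_t) == 1:
            out.append(NormalizedValue(tid, reps_t, agg, 0.0, flagged_single=True))
        else:
            sd = float(np.std(reps_t, ddof=1))
            out.append(NormalizedValue(tid, reps_t, agg, 100.0 * sd / agg))
    return out


_CSV_COLUMNS = ["plate_id", "well", "role", "treatment_id", "f590", "f520"]


def read_screen_csv(path, screen_type: str, strict_layout: bool = True) -> ScreenDataset:
    """Read a plate CSV (plate_id, well, role, treatment_id, f590, f520[, ratio]).

    A provided ratio column is cross-checked against f590/f520 at 1e-6
    relative tolerance.  Layout violations raise unless strict_layout=False,
    in which case they are logged.
    """
    try:
        df = pd.read_csv(
            path,
            dtype={"plate_id": str, "well": str, "treatment_id": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError as e:
        raise ScreenFormatError(f"{path}: empty or unreadable CSV") from e
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"{path}: missing columns {missing}")

    dups = df.duplicated(subset=["plate_id", "well"])
    if dups.any():
        rows = df.loc[dups, ["plate_id", "well"]].itertuples(index=False)
        raise ScreenFormatError(
            "duplicate (plate, well) entries: "
            + ", ".join(f"{p}:{w}" for p, w in rows)
        )

    plates: dict[str, list[WellMeasurement]] = {}
    for i, rec in enumerate(df.to_dict("records"), start=2):  # line 1 = header
        try:
            row, col = parse_well(str(rec["well"]))
            tid = rec["treatment_id"]
            if tid is None or (isinstance(tid, float) and math.isnan(tid)) or tid == "":
                tid = None
            wm = WellMeasurement(
                plate_id=str(rec["plate_id"]),
                row=row,
                col=col,
                role=WellRole(str(rec["role"])),
                f590=float(rec["f590"]),
                f520=float(rec["f520"]),
                treatment_id=tid,
            )
        except (ValueError, KeyError) as e:
            raise ScreenFormatError(f"{path} line {i}: {e}") from e
        if "ratio" in df.columns and not pd.isna(rec.get("ratio")):
            given = float(rec["ratio"])
            if not math.isclose(given, wm.ratio, rel_tol=1e-6):
                raise ScreenFormatError(
                    f"{path} line {i}: ratio column {given} inconsistent with "
                    f"f590/f520 = {wm.ratio}"
                )
        plates.setdefault(wm.plate_id, []).append(wm)

    ds = ScreenDataset(screen_type, [Plate(pid, ws) for pid, ws in plates.items()])
    problems = ds.validate_layouts()
    if problems:
        msg = "; ".join(f"{pid}: {'; '.join(ps)}" for pid, ps in problems.items())
        if strict_layout:
            raise LayoutError(msg)
        logger.warning("layout violations: %s", msg)
    return ds


def write_screen_csv(screen: ScreenDataset, path) -> None:
    rows = []
    for plate in screen.plates:
        for w in plate.wells:
            rows.append(
                {
                    "plate_id": w.plate_id,
                    "well": w.well,
                    "role": w.role.value,
                    "treatment_id": w.treatment_id or "",
                    "f590": repr(float(w.f590)),
                    "f520": repr(float(w.f520)),
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_normalized_csv(path) -> list[NormalizedValue]:
    df = pd.read_csv(path)
    rep_cols = sorted(c for c in df.columns if c.startswith("replicate_"))
    out = []
    for rec in df.to_dict("records"):
        reps = tuple(
            float(rec[c]) for c in rep_cols if not pd.isna(rec.get(c))
        )
        out.append(
            NormalizedValue(
                treatment_id=str(rec["treatment_id"]),
                replicates=reps or (float(rec["aggregate"]),),
                aggregate=float(rec["aggregate"]),
                cv_percent=float(rec["cv_percent"]),
                flagged_single=bool(rec.get("flagged_single", False)),
            )
        )
    return out


def write_normalized_csv(values: Iterable[NormalizedValue], path) -> None:
    rows = []
    for v in values:
        row = {
            "treatment_id": v.treatment_id,
            "aggregate": v.aggregate,
            "cv_percent": v.cv_percent,
            "n_replicates": len(v.replicates),
            "flagged_single": v.flagged_single,
        }
        for j, r in enumerate(v.replicates, 1):
            row[f"replicate_{j}"] = r
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
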