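"""Domain types and canonical CSV I/O for microplate time-course experiments.

A plate experiment is a set of wells read repeatedly over time. Each well
yields three channels per read: optical density (absorbance at 595 nm) and
fluorescence at two emission wavelengths (525 nm and 585 nm, both excited at
485 nm). A layout table assigns each well a role — ``media`` (blank),
``wildtype`` (untagged cells, used to estimate the autofluorescence emission
ratio), or ``tagged`` (the GFP-fusion strain of interest).

Canonical file format is long/tidy CSV:

* data CSV columns: ``well, time_h, od, f525, f585`` (one row per well x time);
* layout CSV columns: ``well, role, strain, condition, replicate_group``.

Vendor exports (e.g. Tecan XLSX matrices) must be reshaped to this layout
before use; every downstream module consumes only :class:`PlateDataset` and
never re-parses files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, LayoutError, SchemaError

ROLES = ("media", "wildtype", "tagged")

DATA_COLUMNS = ("well", "time_h", "od", "f525", "f585")
LAYOUT_COLUMNS = ("well", "role", "strain", "condition", "replicate_group")

#: Wells must share time stamps to within this fraction of the median
#: sampling interval; times are then snapped to the per-point median.
TIME_JITTER_FRACTION = 0.01


@dataclass(frozen=True)
class WellAnnotation:
    """Role and grouping of a single well within the plate layout."""

    well_id: str
    role: str
    strain: str = ""
    condition: str = ""
    replicate_group: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise LayoutError(
                f"well {self.well_id!r}: role {self.role!r} not in {ROLES}"
            )
        if self.role == "media" and self.strain:
            raise LayoutError(
                f"well {self.well_id!r}: media wells must have an empty strain, "
                f"got {self.strain!r}"
            )


@dataclass
class WellTimeSeries:
    """Measured OD and dual-emission fluorescence for one well over time."""

    well_id: str
    times: np.ndarray
    od: np.ndarray
    f525: np.ndarray
    f585: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        self.f525 = np.asarray(self.f525, dtype=float)
        self.f585 = np.asarray(self.f585, dtype=float)
        n = len(self.times)
        if n < 2:
            raise DataError(f"well {self.well_id!r}: need >= 2 time points, got {n}")
        for name in ("od", "f525", "f585"):
            if len(getattr(self, name)) != n:
                raise DataError(
                    f"well {self.well_id!r}: {name} length "
                    f"{len(getattr(self, name))} != times length {n}"
                )
        if not np.all(np.diff(self.times) > 0):
            raise DataError(f"well {self.well_id!r}: times not strictly increasing")
        for name in ("times", "od", "f525", "f585"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise DataError(f"well {self.well_id!r}: non-finite values in {name}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PlateDataset:
    """All well time series plus layout annotations for one experiment."""

    wells: dict[str, WellTimeSeries]
    layout: dict[str, WellAnnotation]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for wid in self.wells:
            if wid not in self.layout:
                raise LayoutError(f"well {wid!r} present in data but not in layout")

    @property
    def times(self) -> np.ndarray:
        """The shared time grid (validated at read time)."""
        first = next(iter(self.wells.values()))
        return first.times

    def wells_by_role(self, role: str) -> list[WellTimeSeries]:
        if role not in ROLES:
            raise LayoutError(f"unknown role {role!r}")
        return [
            self.wells[wid]
            for wid in sorted(self.wells)
            if self.layout[wid].role == role
        ]

    def replicate_groups(self, role: str = "tagged") -> dict[str, list[str]]:
        """Map replicate-group label -> sorted well ids, for wells of ``role``."""
        groups: dict[str, list[str]] = {}
        for wid in sorted(self.wells):
            ann = self.layout[wid]
            if ann.role == role:
                groups.setdefault(ann.replicate_group or wid, []).append(wid)
        return groups

    def drop_role(self, role: str) -> "PlateDataset":
        keep = {w: s for w, s in self.wells.items() if self.layout[w].role != role}
        layout = {w: a for w, a in self.layout.items() if w in keep}
        return PlateDataset(wells=keep, layout=layout, meta=dict(self.meta))


@dataclass(frozen=True)
class UnmixingConstants:
    """Spectral constants of the reporter fluorophore.

    ``rg`` is the ratio of reporter emission at 585 nm to 525 nm (excitation
    485 nm). For enhanced GFP the normalized emissions are 0.065 and 0.570,
    giving rg ~ 0.114; override for other fluorophores.
    """

    rg: float = 0.114

    def __post_init__(self):
        if not 0 <= self.rg < 1:
            raise DataError(f"rg must be in [0, 1), got {self.rg}")


def emission_ratio(em_high: float, em_low: float) -> float:
    """Ratio of a fluorophore's emission at the high wavelength to the low one.

    Parameters are normalized emission intensities (e.g. from published
    spectra); the returned value is stored at full precision and conventionally
    reported to 3 significant figures.
    """
    if em_low <= 0:
        raise ValueError(f"em_low must be > 0, got {em_low}")
    if em_high < 0:
        raise ValueError(f"em_high must be >= 0, got {em_high}")
    return em_high / em_low


def _require_columns(df: pd.DataFrame, cols: tuple, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _snap_time_grid(by_well: dict[str, pd.DataFrame]) -> dict[str, np.ndarray]:
    """Validate that wells share a time grid and snap to per-point medians."""
    lengths = {w: len(df) for w, df in by_well.items()}
    if len(set(lengths.values())) != 1:
        raise DataError(
            f"wells have differing numbers of time points: {sorted(set(lengths.values()))}; "
            "missing readings are not imputed"
        )
    tmat = np.vstack([df["time_h"].to_numpy() for df in by_well.values()])
    grid = np.median(tmat, axis=0)
    dt = np.median(np.diff(grid)) if len(grid) > 1 else 1.0
    tol = TIME_JITTER_FRACTION * dt
    worst = np.max(np.abs(tmat - grid))
    if worst > tol:
        raise DataError(
            f"well time stamps deviate from the shared grid by {worst:.4g} h "
            f"(> {tol:.4g} h, 1% of the median sampling interval)"
        )
    return {w: grid for w in by_well}


def read_plate_csv(path, layout_path) -> PlateDataset:
    """Read the canonical tidy data CSV plus layout CSV into a PlateDataset.

    Rows are sorted by well then time; all wells must share a common time grid
    (within 1% jitter of the sampling interval, then snapped to the per-point
    median); every well in the data must appear in the layout.
    """
    data = pd.read_csv(path, float_precision="round_trip")
    _require_columns(data, DATA_COLUMNS, path)
    layout_df = pd.read_csv(layout_path, dtype=str).fillna("")
    _require_columns(layout_df, LAYOUT_COLUMNS, layout_path)

    layout = {}
    for row in layout_df.itertuples(index=False):
        if row.well in layout:
            raise LayoutError(f"{layout_path}: duplicate well {row.well!r}")
        layout[row.well] = WellAnnotation(
            well_id=row.well,
            role=row.role,
            strain=row.strain,
            condition=row.condition,
            replicate_group=row.replicate_group,
        )

    by_well = {
        str(w): g.sort_values("time_h").reset_index(drop=True)
        for w, g in data.groupby("well", sort=True)
    }
    for wid in by_well:
        if wid not in layout:
            raise LayoutError(f"well {wid!r} present in data but not in layout")
    grids = _snap_time_grid(by_well)

    wells = {
        wid: WellTimeSeries(
            well_id=wid,
            times=grids[wid],
            od=g["od"].to_numpy(dtype=float),
            f525=g["f525"].to_numpy(dtype=float),
            f585=g["f585"].to_numpy(dtype=float),
        )
        for wid, g in by_well.items()
    }
    used_layout = {w: layout[w] for w in wells}
    return PlateDataset(wells=wells, layout=used_layout)


def write_plate_csv(dataset: PlateDataset, path, layout_path=None) -> None:
    """Write a PlateDataset to the canonical tidy CSV (full float precision).

    ``read_plate_csv(write_plate_csv(d))`` reproduces ``d`` exactly. When
    ``layout_path`` is given the layout table is written alongside.
    """
    if not dataset.wells:
        raise DataError("dataset has no wells; nothing to write")
    frames = []
    for wid in sorted(dataset.wells):
        s = dataset.wells[wid]
        frames.append(
            pd.DataFrame(
                {
                    "well": wid,
                    "time_h": s.times,
                    "od": s.od,
                    "f525": s.f525,
                    "f585": s.f585,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )
    if layout_path is not None:
        write_layout_csv(dataset.layout, layout_path)


def write_layout_csv(layout: Mapping[str, WellAnnotation], path) -> None:
    rows = [
        {
            "well": a.well_id,
            "role": a.role,
            "strain": a.strain,
            "condition": a.condition,
            "replicate_group": a.replicate_group,
        }
        for _, a in sorted(layout.items())
    ]
    pd.DataFrame(rows, columns=list(LAYOUT_COLUMNS)).to_csv(path, index=False)
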