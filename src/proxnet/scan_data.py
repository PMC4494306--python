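"""Scan-sample data model, validation and I/O.

Scan sampling records, at a fixed time interval, the state of every
identified individual in a group: either an x-y position in metres on the
enclosure plane (field maps, video tracking, location sensors) or a directly
observed nearest neighbour plus nearest facility (video scans of pens).
A dataset is a flat table with one row per (day, scan, individual).

Two dataset modes are distinguished:

``"coordinate"``
    at least one record carries x-y coordinates; nearest neighbours are
    derived geometrically (see :mod:`proxnet.neighbors`).
``"neighbor"``
    the nearest neighbour (and optionally the nearest facility) was recorded
    directly and no coordinates exist.

Files are plain comma-separated text with a header row; a *schema* mapping
lets arbitrary column names play the required roles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "IntegrityError",
    "ScanParseError",
    "ScanDataset",
    "read_scans",
    "write_scans",
    "filter_daylight",
    "uniform_scan_hours",
    "visible_counts",
    "joint_visible_counts",
]

#: canonical column order of the records table
COLUMNS = ["day", "scan", "individual", "x", "y", "neighbor", "facility", "behavior", "visible"]

REQUIRED_ROLES = ("day", "scan", "individual")
OPTIONAL_ROLES = ("x", "y", "neighbor", "facility", "behavior", "visible")

#: tokens in a neighbour column meaning the focal animal was not seen
NOT_SEEN_TOKENS = ("NS",)


class SchemaError(ValueError):
    """A required column/role is missing or the file layout is unusable."""


class IntegrityError(ValueError):
    """The data violate a dataset invariant (duplicates, unknown ids...)."""


class ScanParseError(ValueError):
    """A cell could not be parsed; the message names the offending row."""


@dataclass
class ScanDataset:
    """Validated collection of scan records for one observed group.

    Parameters
    ----------
    records
        DataFrame with the canonical :data:`COLUMNS`. ``day`` and ``scan``
        are 1-based integers, ``individual`` a string identifier, ``x``/``y``
        floats in metres (NaN when absent), ``neighbor``/``facility``/
        ``behavior`` strings or None, ``visible`` bool.
    individuals
        Identifiers in order of first appearance in the records.
    facilities
        Facility names in order of first appearance (may be empty).
    mode
        ``"coordinate"`` or ``"neighbor"``.
    meta
        Free-form provenance mapping.
    """

    records: pd.DataFrame
    individuals: list
    facilities: list
    mode: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate(self.records, self.individuals, self.facilities, self.mode)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def days(self) -> list:
        return sorted(self.records["day"].unique().tolist())

    def equals(self, other: "ScanDataset") -> bool:
        """Field-for-field equality (NaN == NaN for coordinates)."""
        if (
            self.individuals != other.individuals
            or self.facilities != other.facilities
            or self.mode != other.mode
        ):
            return False
        a = self.records.reset_index(drop=True)
        b = other.records.reset_index(drop=True)
        return a.equals(b)


def _canonical_records(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    out["day"] = df["day"].astype(int)
    out["scan"] = df["scan"].astype(int)
    out["individual"] = df["individual"].astype(str)
    for col in ("x", "y"):
        out[col] = pd.to_numeric(df[col], errors="raise").astype(float) if col in df else np.nan
    for col in ("neighbor", "facility", "behavior"):
        if col in df:
            vals = df[col]
            out[col] = vals.where(vals.notna(), None)
        else:
            out[col] = None
    out["visible"] = df["visible"].astype(bool) if "visible" in df else True
    return out[COLUMNS]


def _validate(records: pd.DataFrame, individuals: list, facilities: list, mode: str) -> None:
    if mode not in ("coordinate", "neighbor"):
        raise SchemaError(f"unknown dataset mode {mode!r}")
    if list(records.columns) != COLUMNS:
        raise SchemaError(f"records must have canonical columns {COLUMNS}")
    if records.duplicated(subset=["day", "scan", "individual"]).any():
        dup = records[records.duplicated(subset=["day", "scan", "individual"], keep=False)]
        raise IntegrityError(
            "duplicate (day, scan, individual) rows: "
            + ", ".join(map(str, dup[["day", "scan", "individual"]].iloc[0].tolist()))
        )
    known = set(individuals)
    if not set(records["individual"]).issubset(known):
        missing = sorted(set(records["individual"]) - known)
        raise IntegrityError(f"records name individuals not in the dataset list: {missing}")
    named = {f for f in records["facility"] if f is not None}
    if not named.issubset(set(facilities)):
        raise IntegrityError(f"records name facilities not in the dataset list: {sorted(named - set(facilities))}")
    # (x, y) both present or both absent, row by row
    bad = records["x"].isna() != records["y"].isna()
    if bad.any():
        raise ScanParseError(f"row {int(records.index[bad][0])}: x and y must both be present or both absent")
    self_nb = records["neighbor"].notna() & (records["neighbor"] == records["individual"])
    if self_nb.any():
        raise IntegrityError(f"row {int(records.index[self_nb][0])}: individual recorded as its own neighbor")
    invis = ~records["visible"]
    leaking = invis & (records["x"].notna() | records["neighbor"].notna())
    if leaking.any():
        raise IntegrityError(
            f"row {int(records.index[leaking][0])}: not-visible record carries coordinates or a neighbor"
        )
    if mode == "coordinate" and len(records) and not records["x"].notna().any():
        raise SchemaError("coordinate mode requires at least one record with coordinates")


def read_scans(path, schema: dict | None = None, not_seen=NOT_SEEN_TOKENS, meta: dict | None = None) -> ScanDataset:
    """Read a delimited scan-sample file into a validated :class:`ScanDataset`.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Mapping of roles to column names, e.g. ``{"day": "Day", "x": "X_m"}``.
        Roles not mentioned default to their own name. Required roles:
        ``day``, ``scan``, ``individual``; optional: ``x``, ``y``,
        ``neighbor``, ``facility``, ``behavior``, ``visible``.
    not_seen
        Tokens in the neighbour column that mean the neighbour was not
        recorded (the record is kept, the neighbour left absent).

    Raises
    ------
    SchemaError, IntegrityError, ScanParseError
    """
    schema = dict(schema or {})
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {}
    for role in REQUIRED_ROLES + OPTIONAL_ROLES:
        name = schema.get(role, role)
        if name in raw.columns:
            colmap[role] = name
        elif role in REQUIRED_ROLES:
            raise SchemaError(f"required column {name!r} (role {role!r}) missing from {path}")
    df = pd.DataFrame({role: raw[name] for role, name in colmap.items()})
    df = df.replace("", None)

    for role in ("day", "scan"):
        try:
            df[role] = df[role].astype(int)
        except (TypeError, ValueError) as err:
            raise ScanParseError(f"non-integer value in column for role {role!r}: {err}") from None
    for role in ("x", "y"):
        if role in df:
            try:
                df[role] = df[role].astype(float)
            except (TypeError, ValueError):
                bad = df[role][pd.to_numeric(df[role], errors="coerce").isna() & df[role].notna()]
                raise ScanParseError(
                    f"row {int(bad.index[0])}: non-numeric coordinate {bad.iloc[0]!r} in role {role!r}"
                ) from None
    if "neighbor" in df:
        df["neighbor"] = df["neighbor"].where(~df["neighbor"].isin(not_seen), None)
    if "visible" in df:
        truthy = {"1": True, "true": True, "True": True, "0": False, "false": False, "False": False}
        try:
            df["visible"] = df["visible"].map(truthy.__getitem__)
        except KeyError as err:
            raise ScanParseError(f"unparseable visibility flag {err}") from None

    records = _canonical_records(df)
    individuals = list(dict.fromkeys(records["individual"]))
    facilities = list(dict.fromkeys(f for f in records["facility"] if f is not None))
    if len(records) == 0 or records["x"].notna().any():
        mode = "coordinate" if "x" in colmap else "neighbor"
    elif "neighbor" in colmap or "facility" in colmap:
        mode = "neighbor"
    else:
        raise SchemaError("file carries neither coordinates nor recorded neighbors/facilities")
    return ScanDataset(records, individuals, facilities, mode, dict(meta or {}))


def write_scans(ds: ScanDataset, path) -> None:
    """Write a dataset as canonical CSV; ``read_scans`` round-trips it."""
    out = ds.records.copy()
    out["visible"] = out["visible"].astype(int)
    out.to_csv(path, index=False, na_rep="")


def uniform_scan_hours(n_scans: int, session_start_hour: float = 6.0, scan_interval_minutes: float = 10.0) -> dict:
    """Clock hour of each 1-based scan index under uniform spacing."""
    return {s: session_start_hour + (s - 1) * scan_interval_minutes / 60.0 for s in range(1, n_scans + 1)}


def filter_daylight(ds: ScanDataset, start_hour: float, end_hour: float, scan_times: dict) -> ScanDataset:
    """Keep only scans whose clock hour falls in ``[start_hour, end_hour)``.

    ``scan_times`` maps every scan index appearing in the data to a clock
    hour (see :func:`uniform_scan_hours`). The individuals list is kept
    unchanged so day-to-day matrices stay label-compatible. Idempotent.
    """
    scans = ds.records["scan"].unique()
    missing = [s for s in scans if s not in scan_times]
    if missing:
        raise SchemaError(f"scan_times mapping missing scan indices {sorted(missing)}")
    keep = ds.records["scan"].map(lambda s: start_hour <= scan_times[s] < end_hour)
    records = ds.records[keep].reset_index(drop=True)
    if len(records) == 0:
        warnings.warn("daylight filter removed every scan", stacklevel=2)
    return ScanDataset(records, list(ds.individuals), list(ds.facilities), ds.mode, dict(ds.meta))


def visible_counts(ds: ScanDataset) -> pd.Series:
    """Number of scans in which each individual was visible.

    Indexed by the dataset's individual order; individuals never seen get 0.
    """
    vis = ds.records[ds.records["visible"]]
    return vis.groupby("individual").size().reindex(ds.individuals, fill_value=0)


def joint_visible_counts(ds: ScanDataset) -> pd.DataFrame:
    """Symmetric matrix of scans in which both members of a dyad were visible.

    This is the natural denominator basis of the simple ratio index when
    animals are occasionally out of sight.
    """
    ids = list(ds.individuals)
    idx = {a: k for k, a in enumerate(ids)}
    joint = np.zeros((len(ids), len(ids)), dtype=int)
    vis = ds.records[ds.records["visible"]]
    for _, grp in vis.groupby(["day", "scan"]):
        present = [idx[a] for a in grp["individual"]]
        for i in present:
            joint[i, present] += 1
    np.fill_diagonal(joint, 0)
    return pd.DataFrame(joint, index=ids, columns=ids)
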