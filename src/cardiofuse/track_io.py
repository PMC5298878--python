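"""Reading, validating and writing cell-track and domain-edge tables.

The native on-disk format is a plain long-format CSV: one row per tracked
object per timepoint, with table-level metadata (midline x-coordinate,
sampling interval, processing flags) stored as ``# key=value`` comment
lines before the header.  An Imaris-style export dialect is also accepted;
it maps generic position/time/track-ID headers onto the native schema and
requires a companion mapping table carrying the biological annotations
(embryo, side, cell class) that an export of raw spots does not contain.

Axis conventions are fixed at the I/O boundary: x is the medial-lateral
axis, y the anterior-posterior axis (+y = anterior), z the imaging depth;
units are micrometres and minutes throughout.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import pandas as pd

__all__ = [
    "TrackTable",
    "SchemaError",
    "IntegrityError",
    "TRACK_COLUMNS",
    "EDGE_COLUMNS",
    "read_tracks",
    "write_tracks",
    "filter_complete_tracks",
    "read_edges",
    "write_edges",
]

#: Column order of the native track CSV dialect.
TRACK_COLUMNS = [
    "embryo_id",
    "group",
    "track_id",
    "cell_class",
    "side",
    "t_index",
    "t",
    "x",
    "y",
    "z",
]

#: Column order of the native domain-edge CSV dialect.
EDGE_COLUMNS = ["embryo_id", "stage_label", "side", "y", "x"]

CELL_CLASSES = {"cardiomyocyte", "reference"}
SIDES = {"left", "right", "none"}

#: Header synonyms accepted by the ``imaris_export`` dialect (lower-cased,
#: stripped of spaces/units).  Generic across Imaris/TrackMate-style spot
#: exports; the exact vendor schema varies by version.
_IMARIS_SYNONYMS = {
    "x": {"positionx", "posx", "x"},
    "y": {"positiony", "posy", "y"},
    "z": {"positionz", "posz", "z"},
    "t_frame": {"time", "timepoint", "frame", "t"},
    "track_id": {"trackid", "track", "id", "parent"},
}


class SchemaError(ValueError):
    """A required column is missing or has an unusable form."""


class IntegrityError(ValueError):
    """Table content violates a structural invariant."""


@dataclass
class TrackTable:
    """Long-format positions over time for all tracked objects in a cohort.

    Parameters
    ----------
    data
        One row per (embryo, track, timepoint); columns ``TRACK_COLUMNS``
        plus any derived columns added downstream (``xm``, ``ap_band``).
    midline_x
        x-coordinate of the embryonic midline, in μm.  Required before
        left/right alignment; may be ``None`` for raw imports.
    dt
        Sampling interval in minutes (``t = t_index * dt``).
    drift_corrected, aligned
        Processing flags set by the preprocessing steps.
    """

    data: pd.DataFrame
    midline_x: float | None = None
    dt: float = 4.0
    drift_corrected: bool = False
    aligned: bool = False

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)

    # -- convenience ---------------------------------------------------

    def copy(self) -> "TrackTable":
        return replace(self, data=self.data.copy())

    @property
    def cells(self) -> pd.DataFrame:
        """Rows belonging to cardiomyocyte tracks."""
        return self.data[self.data["cell_class"] == "cardiomyocyte"]

    @property
    def n_tracks(self) -> int:
        """Number of distinct cardiomyocyte tracks."""
        c = self.cells
        return c.groupby(["embryo_id", "track_id"], sort=False).ngroups

    def validate(self) -> "TrackTable":
        """Check structural invariants; return self for chaining.

        Raises
        ------
        SchemaError
            If a required column is missing.
        IntegrityError
            If keys are duplicated, t does not equal t_index*dt, the
            side/cell-class vocabulary is violated, or side='none' is
            used for a non-reference track.
        """
        df = self.data
        for col in TRACK_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column: {col!r}")
        dup = df.duplicated(subset=["embryo_id", "track_id", "t_index"])
        if dup.any():
            bad = df.loc[dup, ["embryo_id", "track_id", "t_index"]].iloc[0]
            raise IntegrityError(
                "duplicate (embryo_id, track_id, t_index): "
                f"{tuple(bad)}"
            )
        if (df["t_index"] < 0).any():
            raise IntegrityError("negative t_index")
        expected_t = df["t_index"] * self.dt
        if not ((df["t"] - expected_t).abs() < 1e-6).all():
            raise IntegrityError("t column inconsistent with t_index * dt")
        bad_class = set(df["cell_class"]) - CELL_CLASSES
        if bad_class:
            raise IntegrityError(f"unknown cell_class values: {bad_class}")
        bad_side = set(df["side"]) - SIDES
        if bad_side:
            raise IntegrityError(f"unknown side values: {bad_side}")
        none_cells = df[(df["side"] == "none") & (df["cell_class"] == "cardiomyocyte")]
        if len(none_cells):
            raise IntegrityError(
                "side='none' is reserved for reference tracks; offending "
                f"track_ids: {sorted(none_cells['track_id'].unique())}"
            )
        for emb, sub in df.groupby("embryo_id", sort=False):
            n_ref = sub.loc[sub["cell_class"] == "reference", "track_id"].nunique()
            if n_ref > 1:
                raise IntegrityError(f"embryo {emb!r} has {n_ref} reference tracks")
            if n_ref == 0 and not self.drift_corrected:
                warnings.warn(
                    f"embryo {emb!r} has no reference track; "
                    "drift correction will refuse it",
                    stacklevel=2,
                )
        return self


# ---------------------------------------------------------------------
# native dialect
# ---------------------------------------------------------------------

def _read_metadata(path: Union[str, Path, io.IOBase]) -> tuple[dict, str]:
    """Split leading '# key=value' comment lines from the CSV body."""
    if isinstance(path, io.IOBase):
        text = path.read()
    else:
        text = Path(path).read_text()
    meta: dict[str, str] = {}
    lines = text.splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            break
    return meta, "".join(lines[body_start:])


def write_tracks(tracks: TrackTable, dest: Union[str, Path]) -> Path:
    """Serialize a TrackTable losslessly to the native CSV dialect."""
    dest = Path(dest)
    extra = [c for c in tracks.data.columns if c not in TRACK_COLUMNS]
    cols = TRACK_COLUMNS + extra
    header = [
        f"# midline_x={tracks.midline_x if tracks.midline_x is not None else 'none'}",
        f"# dt={tracks.dt}",
        f"# drift_corrected={tracks.drift_corrected}",
        f"# aligned={tracks.aligned}",
    ]
    with open(dest, "w", newline="") as fh:
        fh.write("\n".join(header) + "\n")
        tracks.data.to_csv(fh, index=False, columns=cols)
    return dest


def read_tracks(
    source: Union[str, Path],
    dialect: str = "native_csv",
    mapping: Union[str, Path, pd.DataFrame, None] = None,
    dt: float | None = None,
    midline_x: float | None = None,
) -> TrackTable:
    """Read a track table and validate it.

    Parameters
    ----------
    source
        CSV file to read.
    dialect
        ``"native_csv"`` (the format written by :func:`write_tracks`) or
        ``"imaris_export"`` (generic position/time/track-ID export).
    mapping
        For ``imaris_export`` only: a CSV or DataFrame with columns
        ``track_id, embryo_id, group, side, cell_class`` annotating every
        exported track.
    dt, midline_x
        For ``imaris_export``: sampling interval (minutes) and midline
        position (μm); for ``native_csv`` these are read from the file
        header and the arguments are ignored.
    """
    if dialect == "native_csv":
        meta, body = _read_metadata(source)
        df = pd.read_csv(io.StringIO(body))
        mx = meta.get("midline_x", "none")
        tt = TrackTable(
            data=df,
            midline_x=None if mx == "none" else float(mx),
            dt=float(meta.get("dt", 4.0)),
            drift_corrected=meta.get("drift_corrected", "False") == "True",
            aligned=meta.get("aligned", "False") == "True",
        )
        return tt.validate()
    if dialect == "imaris_export":
        return _read_imaris(source, mapping=mapping, dt=dt, midline_x=midline_x)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _normalize_header(name: str) -> str:
    out = name.lower()
    for junk in (" ", "_", "-", "[um]", "[µm]", "(um)", "reference", "frame"):
        out = out.replace(junk, "")
    return out


def _read_imaris(
    source: Union[str, Path],
    mapping: Union[str, Path, pd.DataFrame, None],
    dt: float | None,
    midline_x: float | None,
) -> TrackTable:
    if mapping is None:
        raise SchemaError(
            "imaris_export dialect requires a companion mapping table with "
            "columns track_id, embryo_id, group, side, cell_class"
        )
    if not isinstance(mapping, pd.DataFrame):
        mapping = pd.read_csv(mapping)
    for col in ["track_id", "embryo_id", "group", "side", "cell_class"]:
        if col not in mapping.columns:
            raise SchemaError(f"mapping table missing column: {col!r}")
    if dt is None:
        raise SchemaError("imaris_export dialect requires dt (minutes)")

    raw = pd.read_csv(source)
    colmap: dict[str, str] = {}
    for raw_col in raw.columns:
        norm = _normalize_header(str(raw_col))
        for canon, synonyms in _IMARIS_SYNONYMS.items():
            if norm in synonyms and canon not in colmap:
                colmap[canon] = raw_col
    missing = [c for c in ("x", "y", "z", "t_frame", "track_id") if c not in colmap]
    if missing:
        raise SchemaError(f"imaris export missing column(s): {missing}")

    df = pd.DataFrame(
        {
            "track_id": raw[colmap["track_id"]].astype(str),
            "t_frame": raw[colmap["t_frame"]].astype(int),
            "x": raw[colmap["x"]].astype(float),
            "y": raw[colmap["y"]].astype(float),
            "z": raw[colmap["z"]].astype(float),
        }
    )
    # Imaris time indices are conventionally 1-based
    df["t_index"] = df["t_frame"] - df["t_frame"].min()
    mapping = mapping.copy()
    mapping["track_id"] = mapping["track_id"].astype(str)
    merged = df.merge(mapping, on="track_id", how="left")
    unmapped = merged["embryo_id"].isna()
    if unmapped.any():
        bad = sorted(merged.loc[unmapped, "track_id"].unique())
        raise SchemaError(f"tracks absent from mapping table: {bad}")
    merged["t"] = merged["t_index"] * dt
    tt = TrackTable(
        data=merged[TRACK_COLUMNS].copy(), midline_x=midline_x, dt=dt
    )
    return tt.validate()


# ---------------------------------------------------------------------
# complete-track filter
# ---------------------------------------------------------------------

def filter_complete_tracks(tracks: TrackTable) -> tuple[TrackTable, pd.DataFrame]:
    """Keep only tracks with a position at every timepoint of their embryo.

    A track is complete when it is observed at every integer t_index in
    ``[0, max t_index of its embryo]``.  Incomplete tracks are dropped
    entirely; only complete tracks enter the kinematic analysis.

    Returns
    -------
    (filtered, report)
        ``report`` has one row per embryo with columns
        ``embryo_id, retained, dropped``.
    """
    df = tracks.data
    keep_masks = []
    rows = []
    for emb, sub in df.groupby("embryo_id", sort=False):
        t_max = int(sub["t_index"].max())
        expected = t_max + 1
        counts = sub.groupby("track_id")["t_index"].agg(["size", "nunique", "min", "max"])
        complete = counts[
            (counts["nunique"] == expected)
            & (counts["min"] == 0)
            & (counts["max"] == t_max)
        ].index
        keep_masks.append((df["embryo_id"] == emb) & df["track_id"].isin(complete))
        rows.append(
            {
                "embryo_id": emb,
                "retained": len(complete),
                "dropped": len(counts) - len(complete),
            }
        )
    if keep_masks:
        mask = pd.concat(keep_masks, axis=1).any(axis=1)
    else:
        mask = pd.Series(False, index=df.index)
    out = replace(tracks, data=df[mask].reset_index(drop=True))
    report = pd.DataFrame(rows, columns=["embryo_id", "retained", "dropped"])
    if len(out.data) == 0:
        warnings.warn("no complete tracks remain after filtering", stacklevel=2)
    return out, report


# ---------------------------------------------------------------------
# domain edges
# ---------------------------------------------------------------------

def read_edges(source: Union[str, Path]) -> pd.DataFrame:
    """Read a bilateral domain-edge table (medial edge sample points).

    Columns: ``embryo_id, stage_label, side, y, x`` with side in
    {left, right}; each (embryo, stage, side) curve is a sampled
    x(y) profile of the domain's medial edge.
    """
    df = pd.read_csv(source)
    for col in EDGE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"edge table missing column: {col!r}")
    bad = set(df["side"]) - {"left", "right"}
    if bad:
        raise IntegrityError(f"edge side must be left/right, got {bad}")
    return df[EDGE_COLUMNS].copy()


def write_edges(edges: pd.DataFrame, dest: Union[str, Path]) -> Path:
    dest = Path(dest)
    edges.to_csv(dest, index=False, columns=EDGE_COLUMNS)
    return dest
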