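"""Drift correction against a reference landmark and left/right alignment.

Timelapse stacks drift relative to the embryo (stage movement, agarose
relaxation, growth).  The analysis corrects for this by tracking a single
anatomical landmark — the notochord tip — in every embryo and subtracting
its cumulative displacement from every tracked cell, so that all motion is
expressed in the landmark's frame.  The landmark itself retracts slightly
posteriorly over the timelapse; it nevertheless defines the reference
frame, and that biological motion is deliberately not modelled out.

After correction, left and right cell populations are mapped into a common
medial coordinate ``xm`` that increases toward the midline for cells on
either side, so that medial movement is a positive quantity regardless of
side.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .track_io import TrackTable

__all__ = ["CorrectionError", "drift_correct", "align_sides", "split_ap_bands"]


class CorrectionError(ValueError):
    """Reference track missing or unusable for an embryo."""


def drift_correct(tracks: TrackTable) -> TrackTable:
    """Subtract the reference landmark's cumulative displacement per embryo.

    For every embryo, the reference track's displacement from t_index 0 to
    t_index k is subtracted from each cell position at t_index k (x, y and
    z).  Positions at t_index 0 are unchanged.  Reference rows are dropped
    from the output and the ``drift_corrected`` flag is set.

    Raises
    ------
    CorrectionError
        If an embryo lacks a reference track, or its reference track does
        not cover every timepoint the embryo's cells span.
    """
    df = tracks.data
    pieces = []
    for emb, sub in df.groupby("embryo_id", sort=False):
        ref = sub[sub["cell_class"] == "reference"]
        cells = sub[sub["cell_class"] != "reference"].copy()
        if ref.empty:
            raise CorrectionError(f"embryo {emb!r}: no reference track")
        ref = ref.sort_values("t_index")
        t_max = int(sub["t_index"].max())
        ref_idx = ref["t_index"].to_numpy()
        if len(ref) != t_max + 1 or ref_idx[0] != 0 or ref_idx[-1] != t_max:
            raise CorrectionError(
                f"embryo {emb!r}: reference track incomplete "
                f"({len(ref)} of {t_max + 1} timepoints)"
            )
        # cumulative displacement of the reference from t0, indexed by t_index
        for axis in ("x", "y", "z"):
            disp = ref[axis].to_numpy() - ref[axis].to_numpy()[0]
            cells[axis] = cells[axis].to_numpy() - disp[cells["t_index"].to_numpy()]
        pieces.append(cells)
    out = pd.concat(pieces, ignore_index=True) if pieces else df.iloc[0:0].copy()
    return replace(tracks, data=out, drift_corrected=True)


def align_sides(tracks: TrackTable) -> TrackTable:
    """Map both sides into a shared medial coordinate ``xm``.

    ``xm = x - midline_x`` for left-side cells and ``midline_x - x`` for
    right-side cells, so that movement toward the midline strictly
    increases ``xm`` on both sides.  Sets the ``aligned`` flag.

    Raises
    ------
    ValueError
        If drift correction has not been applied, midline metadata is
        absent, or any cardiomyocyte lacks a left/right label.
    """
    if not tracks.drift_corrected:
        raise ValueError("align_sides requires a drift-corrected table")
    if tracks.midline_x is None:
        raise ValueError("align_sides requires midline_x metadata")
    df = tracks.data.copy()
    cells = df["cell_class"] == "cardiomyocyte"
    unlabeled = df[cells & ~df["side"].isin(["left", "right"])]
    if len(unlabeled):
        raise ValueError(
            "cardiomyocyte tracks without left/right side label: "
            f"{sorted(unlabeled['track_id'].unique())}"
        )
    mx = float(tracks.midline_x)
    x = df["x"].to_numpy(float)
    xm = np.where(df["side"].to_numpy() == "left", x - mx, mx - x)
    df["xm"] = xm
    return replace(tracks, data=df, aligned=True)


def split_ap_bands(tracks: TrackTable) -> TrackTable:
    """Label cells top/middle/bottom by tertiles of initial AP position.

    Within each embryo and side, tracks are ranked by their position at
    t_index 0, most anterior (largest y) first, ties broken by track_id,
    and split into three contiguous bands of balanced size.  When the
    count is not divisible by three the spare cells go to the outer bands
    (top first), so two cells split into top and bottom with an empty
    middle.  Band labels are fixed at the start of the timelapse; cells do
    not change band mid-track.
    """
    if not tracks.aligned:
        raise ValueError("split_ap_bands requires an aligned table")
    df = tracks.data.copy()
    df["ap_band"] = pd.NA
    cells = df[df["cell_class"] == "cardiomyocyte"]
    for (emb, side), sub in cells.groupby(["embryo_id", "side"], sort=False):
        first = sub[sub["t_index"] == 0]
        order = first.sort_values(
            ["y", "track_id"], ascending=[False, True]
        )["track_id"].tolist()
        n = len(order)
        q, r = divmod(n, 3)
        n_top = q + (1 if r >= 1 else 0)
        n_bottom = q + (1 if r == 2 else 0)
        bands: dict = {}
        for i, tid in enumerate(order):
            if i < n_top:
                bands[tid] = "top"
            elif i < n - n_bottom:
                bands[tid] = "middle"
            else:
                bands[tid] = "bottom"
        mask = (df["embryo_id"] == emb) & (df["side"] == side) & (
            df["cell_class"] == "cardiomyocyte"
        )
        df.loc[mask, "ap_band"] = df.loc[mask, "track_id"].map(bands)
    return replace(tracks, data=df)
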