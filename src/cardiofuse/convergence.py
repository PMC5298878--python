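"""Bilateral-domain gap statistic and its per-stage group comparison.

The convergence of the bilateral heart-forming fields is summarised per
embryo and stage by sampling the distance between the medial edges of the
left and right domains at three anterior-posterior positions spaced
200 μm apart and keeping the largest of the three distances as the
representative gap.  Taking the maximum makes the statistic sensitive to
a failure of convergence anywhere along the AP extent of the field, not
only at its narrowest point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .group_stats import compare_groups

__all__ = [
    "GapMeasurement",
    "CoverageError",
    "measure_gap",
    "measure_gap_table",
    "gap_timecourse",
    "make_edges",
    "simulate_edge_cohort",
    "gap_plot",
]


class CoverageError(ValueError):
    """Sample points fall outside an edge curve's sampled span."""


@dataclass
class GapMeasurement:
    """Gap between bilateral medial edges for one embryo at one stage."""

    embryo_id: str
    stage_label: str
    sample_points: np.ndarray  # 3 AP positions, μm
    distances: np.ndarray      # right_x - left_x at each point, μm
    representative_gap: float  # max of the distances


def _interp_curve(curve: pd.DataFrame, ys: np.ndarray, embryo_id, side: str) -> np.ndarray:
    y = curve["y"].to_numpy(float)
    x = curve["x"].to_numpy(float)
    order = np.argsort(y)
    y, x = y[order], x[order]
    if len(y) < 2:
        raise CoverageError(f"embryo {embryo_id!r}: {side} edge has <2 samples")
    if ys.min() < y[0] or ys.max() > y[-1]:
        raise CoverageError(
            f"embryo {embryo_id!r}: sample points [{ys.min():g}, {ys.max():g}] "
            f"exceed {side} edge span [{y[0]:g}, {y[-1]:g}]"
        )
    return np.interp(ys, y, x)


def measure_gap(
    edges: pd.DataFrame,
    embryo_id=None,
    stage_label=None,
    anchor: str = "centered",
    spacing: float = 200.0,
    n_points: int = 3,
) -> GapMeasurement:
    """Distance between bilateral medial edges at equidistant AP points.

    Parameters
    ----------
    edges
        Edge table (columns ``embryo_id, stage_label, side, y, x``) for
        one embryo/stage, or a larger table with ``embryo_id`` and
        ``stage_label`` given to select one.
    anchor
        ``"centered"`` places the sample points symmetrically about the
        midpoint of the two curves' common AP span; ``"anterior"``
        anchors the first point at the anterior end of the common span
        and steps posteriorly.
    spacing
        Distance between consecutive sample points, μm.

    Returns
    -------
    GapMeasurement
        With ``distances[i] = right_edge_x(y_i) - left_edge_x(y_i)``
        (linear interpolation between edge samples) and
        ``representative_gap = max(distances)``.
    """
    sub = edges
    if embryo_id is not None:
        sub = sub[sub["embryo_id"] == embryo_id]
    if stage_label is not None:
        sub = sub[sub["stage_label"] == stage_label]
    if embryo_id is None:
        ids = sub["embryo_id"].unique()
        if len(ids) != 1:
            raise ValueError("edge table spans multiple embryos; pass embryo_id")
        embryo_id = ids[0]
    if stage_label is None:
        labels = sub["stage_label"].unique()
        if len(labels) != 1:
            raise ValueError("edge table spans multiple stages; pass stage_label")
        stage_label = labels[0]
    left = sub[sub["side"] == "left"]
    right = sub[sub["side"] == "right"]
    if left.empty or right.empty:
        raise CoverageError(f"embryo {embryo_id!r}: missing an edge curve")

    lo = max(left["y"].min(), right["y"].min())
    hi = min(left["y"].max(), right["y"].max())
    extent = (n_points - 1) * spacing
    if hi - lo < extent:
        raise CoverageError(
            f"embryo {embryo_id!r}: common AP span {hi - lo:g} μm shorter than "
            f"required {extent:g} μm"
        )
    if anchor == "centered":
        mid = (lo + hi) / 2
        ys = mid + (np.arange(n_points) - (n_points - 1) / 2) * spacing
    elif anchor == "anterior":
        ys = hi - np.arange(n_points) * spacing
    else:
        raise ValueError(f"unknown anchor: {anchor!r}")

    xl = _interp_curve(left, ys, embryo_id, "left")
    xr = _interp_curve(right, ys, embryo_id, "right")
    distances = xr - xl
    return GapMeasurement(
        embryo_id=embryo_id,
        stage_label=stage_label,
        sample_points=ys,
        distances=distances,
        representative_gap=float(distances.max()),
    )


def measure_gap_table(
    edges: pd.DataFrame, group_of: dict | None = None, **kwargs
) -> pd.DataFrame:
    """Apply :func:`measure_gap` to every (embryo, stage) in an edge table."""
    rows = []
    for (emb, stage), _ in edges.groupby(["embryo_id", "stage_label"], sort=False):
        m = measure_gap(edges, embryo_id=emb, stage_label=stage, **kwargs)
        rows.append(
            {
                "embryo_id": emb,
                "stage_label": stage,
                "group": (group_of or {}).get(emb, "unknown"),
                "gap": m.representative_gap,
            }
        )
    return pd.DataFrame(rows)


def gap_timecourse(
    measurements: pd.DataFrame,
    group_a: str = "wt",
    group_b: str = "mutant",
    variant: str = "student",
) -> pd.DataFrame:
    """Per-stage group comparison of representative gaps.

    ``measurements`` needs columns ``embryo_id, stage_label, group, gap``.
    Stages with fewer than two embryos in either group are skipped with a
    warning.  Returns one row per compared stage with group means,
    standard errors and the two-tailed t-test p-value.
    """
    rows = []
    for stage, sub in measurements.groupby("stage_label", sort=False):
        a = sub.loc[sub["group"] == group_a, "gap"].to_numpy(float)
        b = sub.loc[sub["group"] == group_b, "gap"].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"stage {stage!r}: <2 embryos per group "
                f"({group_a}: {len(a)}, {group_b}: {len(b)}); skipped",
                stacklevel=2,
            )
            continue
        cmp = compare_groups(a, b, metric="gap", level="per_embryo", variant=variant)
        rows.append(
            {
                "stage_label": stage,
                f"mean_{group_a}": cmp.mean_a,
                f"mean_{group_b}": cmp.mean_b,
                f"se_{group_a}": cmp.sd_a / np.sqrt(cmp.n_a),
                f"se_{group_b}": cmp.sd_b / np.sqrt(cmp.n_b),
                f"n_{group_a}": cmp.n_a,
                f"n_{group_b}": cmp.n_b,
                "t_statistic": cmp.t_statistic,
                "p_value": cmp.p_value,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# synthetic edge curves, for testing the gap machinery end to end
# ---------------------------------------------------------------------

def make_edges(
    embryo_id: str,
    stage_label: str,
    gap: float,
    y_span: tuple[float, float] = (0.0, 500.0),
    n_samples: int = 26,
    midline_x: float = 0.0,
    taper: float = 0.0,
) -> pd.DataFrame:
    """Build a synthetic bilateral edge pair with a prescribed gap.

    ``taper`` adds a linear AP trend: the gap is ``gap + taper`` at the
    anterior end and ``gap - taper`` at the posterior end (floored at 0),
    emulating fields that are closer together posteriorly.
    """
    ys = np.linspace(y_span[0], y_span[1], n_samples)
    frac = (ys - y_span[0]) / (y_span[1] - y_span[0])  # 0 posterior, 1 anterior
    local_gap = np.maximum(gap + taper * (2 * frac - 1), 0.0)
    rows = []
    for side, sign in (("left", -1), ("right", +1)):
        for y, g in zip(ys, local_gap):
            rows.append(
                {
                    "embryo_id": embryo_id,
                    "stage_label": stage_label,
                    "side": side,
                    "y": y,
                    "x": midline_x + sign * g / 2,
                }
            )
    return pd.DataFrame(rows)


def simulate_edge_cohort(
    gap_by_stage: dict[str, dict[str, float]],
    n_embryos: dict[str, int],
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate edge tables for two groups with known per-stage gaps.

    Parameters
    ----------
    gap_by_stage
        ``{group: {stage_label: true mean gap μm}}``.
    n_embryos
        ``{group: embryo count}``.
    noise_sd
        Between-embryo SD of the realised gap, μm.

    Returns
    -------
    (edges, group_of)
        Concatenated edge table and an embryo→group mapping usable with
        :func:`measure_gap_table`.
    """
    rng = np.random.default_rng(seed)
    pieces = []
    group_of: dict[str, str] = {}
    for group, stages in gap_by_stage.items():
        for i in range(n_embryos[group]):
            emb = f"{group}_{i + 1}"
            group_of[emb] = group
            for stage, mean_gap in stages.items():
                g = max(mean_gap + rng.normal(0, noise_sd), 0.0)
                pieces.append(make_edges(emb, stage, g))
    return pd.concat(pieces, ignore_index=True), group_of


def gap_plot(timecourse: pd.DataFrame, group_a="wt", group_b="mutant", ax=None):
    """Mean-gap-per-stage plot with standard-error bars for both groups."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(len(timecourse))
    for g, color in ((group_a, "tab:blue"), (group_b, "tab:red")):
        ax.errorbar(
            x, timecourse[f"mean_{g}"], yerr=timecourse[f"se_{g}"],
            label=g, color=color, marker="o", capsize=3,
        )
    ax.set_xticks(x)
    ax.set_xticklabels(timecourse["stage_label"])
    ax.set_ylabel("distance between medial edges (μm)")
    ax.legend()
    return ax
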