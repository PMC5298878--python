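"""Embryo- and cohort-level aggregation, direction histograms, group tests.

Two aggregation levels are exposed because both are biologically
informative: per-cell statistics across a whole cohort (treating cells as
replicates) and per-embryo means of cell metrics (treating embryos as
replicates).  Cohort velocity figures quoted by the pipeline are per-cell
means; per-embryo summaries reveal inter-embryo variability such as a
mild/severe phenotype split.

Group comparisons use the classic pooled-variance two-sample Student's
t-test, two-tailed; a Welch variant is available via ``variant="welch"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import KINEMATIC_METRICS

__all__ = [
    "DirectionHistogram",
    "GroupComparison",
    "summarize_embryos",
    "cohort_means",
    "direction_histogram",
    "compare_groups",
    "fraction_non_medial",
    "rose_plot",
    "dot_plot",
]

logger = logging.getLogger(__name__)


@dataclass
class DirectionHistogram:
    """Counts of cells per angular bin of net movement direction.

    ``bin_edges`` spans [0°, 180°]; bins are right-open except the last,
    which is closed at 180° so that both a purely medial (0°) and a
    purely lateral (180°) cell are counted.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    group: str | None = None

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def n_cells(self) -> int:
        return int(self.counts.sum())


@dataclass
class GroupComparison:
    """Two-sample comparison of one metric between groups."""

    metric: str
    level: str  # per_cell | per_embryo
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    df: float
    variant: str = "student"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_embryos(kin: pd.DataFrame) -> pd.DataFrame:
    """Per-embryo arithmetic means of each kinematic metric.

    Undefined (missing) values are excluded metric by metric; an embryo
    with no defined value for a metric gets a missing summary value.
    Adds ``n_cells`` and ``fraction_non_medial`` (share of cells with
    medial-lateral velocity ≤ 0).
    """
    if kin.empty:
        raise ValueError("empty kinematics table")
    metrics = [m for m in KINEMATIC_METRICS if m in kin.columns]
    grouped = kin.groupby("embryo_id", sort=False)
    out = grouped[metrics].mean()
    out.insert(0, "group", grouped["group"].first())
    out.insert(1, "n_cells", grouped.size())
    out["fraction_non_medial"] = grouped["velocity_ml"].apply(fraction_non_medial)
    for emb, row in out.iterrows():
        missing = [m for m in metrics if pd.isna(row[m])]
        if missing:
            logger.warning("embryo %r: no defined values for %s", emb, missing)
    return out.reset_index()


def cohort_means(kin: pd.DataFrame) -> pd.DataFrame:
    """Per-cell means of each metric across all embryos, by group."""
    metrics = [m for m in KINEMATIC_METRICS if m in kin.columns]
    grouped = kin.groupby("group", sort=False)
    out = grouped[metrics].mean()
    out.insert(0, "n_cells", grouped.size())
    out["fraction_non_medial"] = grouped["velocity_ml"].apply(fraction_non_medial)
    return out.reset_index()


def direction_histogram(
    kin: pd.DataFrame | np.ndarray, n_bins: int = 10, group: str | None = None
) -> DirectionHistogram:
    """Bin net-movement directions into ``n_bins`` angular bins over [0°, 180°].

    Accepts a kinematics table (uses its ``direction`` column; optionally
    filtered to one group) or a bare array of angles.  Cells with
    undefined direction are excluded; counts therefore sum to the number
    of cells with a defined direction.
    """
    if isinstance(kin, pd.DataFrame):
        sub = kin if group is None else kin[kin["group"] == group]
        angles = sub["direction"].to_numpy(float)
    else:
        angles = np.asarray(kin, float)
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        raise ValueError("no defined directions to bin")
    if np.any((angles < 0) | (angles > 180)):
        raise ValueError("directions outside [0, 180]")
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)  # last bin closed at 180
    return DirectionHistogram(bin_edges=edges, counts=counts, group=group)


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    metric: str = "",
    level: str = "per_cell",
    variant: str = "student",
) -> GroupComparison:
    """Two-tailed unpaired two-sample t-test between value vectors a and b.

    ``variant="student"`` (default) pools the variance with
    n_a + n_b - 2 degrees of freedom; ``variant="welch"`` uses the
    unequal-variance form.

    Raises
    ------
    ValueError
        If either group has n < 2, contains non-finite values, or both
        groups are constant and equal (zero pooled variance, t undefined).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 defined values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if variant == "student":
        res = stats.ttest_ind(a, b, equal_var=True)
        dof = len(a) + len(b) - 2
    elif variant == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        dof = float(res.df)
    else:
        raise ValueError(f"unknown t-test variant: {variant!r}")
    if not np.isfinite(res.statistic):
        raise ValueError("degenerate input: zero variance with equal means")
    return GroupComparison(
        metric=metric,
        level=level,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=len(a),
        n_b=len(b),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(dof),
        variant=variant,
    )


def fraction_non_medial(values) -> float:
    """Share of cells showing no medial movement (velocity_ml ≤ 0).

    Accepts a velocity vector, a kinematics table, or an embryo-summary
    table (cell-weighted).  Missing values are excluded.
    """
    if isinstance(values, pd.DataFrame):
        if "n_cells" in values.columns and "fraction_non_medial" in values.columns:
            w = values["n_cells"].to_numpy(float)
            return float(
                (values["fraction_non_medial"].to_numpy(float) * w).sum() / w.sum()
            )
        values = values["velocity_ml"]
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no defined medial-lateral velocities")
    return float((v <= 0).mean())


# ---------------------------------------------------------------------
# figures (side outputs; all quantitative results go through CSVs)
# ---------------------------------------------------------------------

def rose_plot(hist: DirectionHistogram, ax=None, color="tab:blue"):
    """Radial bar chart of a direction histogram (0° medial, 180° lateral)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = np.radians((hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2)
    width = np.radians(np.diff(hist.bin_edges))
    ax.bar(centers, hist.counts, width=width, bottom=0.0, color=color,
           edgecolor="black", alpha=0.8)
    ax.set_thetamin(0)
    ax.set_thetamax(180)
    ax.set_title(hist.group or "")
    return ax


def dot_plot(values_by_group: dict, ylabel: str, ax=None):
    """Dot plot of per-cell or per-embryo values, one column per group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rng = np.random.default_rng(0)  # cosmetic jitter only
    for i, (name, vals) in enumerate(values_by_group.items()):
        vals = np.asarray(vals, float)
        vals = vals[~np.isnan(vals)]
        x = i + rng.uniform(-0.12, 0.12, len(vals))
        ax.plot(x, vals, "o", ms=4, alpha=0.7, label=name)
        ax.hlines(vals.mean(), i - 0.25, i + 0.25, color="black")
    ax.set_xticks(range(len(values_by_group)))
    ax.set_xticklabels(list(values_by_group))
    ax.set_ylabel(ylabel)
    return ax
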