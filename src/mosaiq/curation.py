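"""Curation and statistical comparison of annotated measurements.

Cells on the periphery of a clone sit next to dissimilar neighbors and are
exposed to non-autonomous signaling, so expression comparisons exclude them.
Analyses may further be restricted to a polygonal region of interest and an
x-axis window (cells at similar positions along the anteroposterior axis are
of similar developmental age).  Dosage groups are compared by two-sided
Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .data import MeasurementTable
from .errors import GeometryError, InsufficientDataError, PrecondError
from .geometry import delaunay_edges


def flag_borders(
    positions: np.ndarray,
    dosages: np.ndarray,
    edge_quantile: float = 0.95,
) -> np.ndarray:
    """True for every cell with a Delaunay neighbor of different dosage.

    Uses the same edge-length quantile filter as the annotation cell graph,
    so "neighbor" means the same thing in both places.  Symmetric by
    construction: if i is flagged because of j then j is flagged too.
    """
    dosages = np.asarray(dosages, dtype=float)
    if np.any(~np.isfinite(dosages)):
        raise PrecondError("all cells must be labeled before border flagging")
    edges, _ = delaunay_edges(np.asarray(positions, float), edge_quantile)
    border = np.zeros(len(dosages), dtype=bool)
    differ = dosages[edges[:, 0]] != dosages[edges[:, 1]]
    border[edges[differ, 0]] = True
    border[edges[differ, 1]] = True
    return border


def flag_borders_table(
    table: MeasurementTable, edge_quantile: float = 0.95
) -> MeasurementTable:
    """Return a copy of the table with the ``border`` column filled in."""
    border = flag_borders(table.positions, table.dosages, edge_quantile)
    out = table.data.copy()
    out["border"] = border
    return MeasurementTable(out)


def apply_roi(
    table: MeasurementTable,
    roi,
    x_window: tuple[float, float] | None = None,
) -> MeasurementTable:
    """Keep rows whose centroid falls inside the polygon (boundary included).

    ``roi`` is a sequence of (x, y) vertices of a simple polygon; an
    optional ``x_window = (xmin, xmax)`` further restricts along x.

    Raises
    ------
    GeometryError
        If the polygon is self-intersecting.
    """
    from shapely.geometry import Point, Polygon

    poly = Polygon([(float(x), float(y)) for x, y in roi])
    if not poly.is_valid:
        raise GeometryError("ROI polygon is self-intersecting")
    pos = table.positions
    keep = np.array([poly.covers(Point(x, y)) for x, y in pos])
    if x_window is not None:
        lo, hi = x_window
        keep &= (pos[:, 0] >= lo) & (pos[:, 0] <= hi)
    return MeasurementTable(table.data.loc[keep].reset_index(drop=True))


@dataclass
class ComparisonResult:
    """Two-sided Mann-Whitney comparison of one channel between two dosages."""

    group_a: int
    group_b: int
    n_a: int
    n_b: int
    U: float          # min-orientation statistic, 0 <= U <= n_a * n_b
    p: float

    def __str__(self):
        return (
            f"dosage {self.group_a} (n={self.n_a}) vs dosage {self.group_b} "
            f"(n={self.n_b}): U={self.U:.1f}, p={self.p:.3g}"
        )


def compare_clones(
    table: MeasurementTable,
    channel: int,
    group_a: int,
    group_b: int,
    exclude_borders: bool = True,
) -> ComparisonResult:
    """Mann-Whitney U test on (corrected, if available) levels of a channel.

    Exact null distribution when both groups have <= 20 cells and there are
    no ties; normal approximation with tie correction otherwise.  The
    reported U is the smaller of the two orientations; p is two-sided and
    invariant to exchanging the groups.
    """
    df = table.data
    mask = df["dosage"].notna()
    if exclude_borders and df["border"].notna().any():
        mask &= df["border"].fillna(False).astype(bool) == False  # noqa: E712
    levels = table.level(channel)
    a = levels[np.asarray(mask & (df["dosage"] == group_a))]
    b = levels[np.asarray(mask & (df["dosage"] == group_b))]
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError(
            f"empty dosage group after filtering (n_a={len(a)}, n_b={len(b)})"
        )
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, len(a) * len(b) - u1)
    return ComparisonResult(
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        U=u,
        p=float(min(res.pvalue, 1.0)),
    )
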