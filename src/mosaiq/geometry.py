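"""Delaunay neighbor extraction shared by the annotation and curation stages.

"Neighbor" means the same thing everywhere: an edge of the Delaunay
triangulation of the cell centroids whose length does not exceed a stated
quantile of all edge lengths (long edges along the tissue hull are spurious
adjacencies, not physical contacts).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .errors import TriangulationError


def delaunay_edges(
    positions: np.ndarray, max_edge_quantile: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Unique Delaunay edges filtered by length quantile.

    Returns
    -------
    edges : (M, 2) int array of vertex index pairs, i < j
    lengths : (M,) Euclidean edge lengths

    Raises
    ------
    TriangulationError
        For < 3 points or degenerate (collinear/coincident) geometry.
    """
    pts = np.asarray(positions, dtype=float)
    if len(pts) < 3:
        raise TriangulationError("need at least 3 cells to triangulate")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise TriangulationError(f"degenerate cell geometry: {exc}") from exc
    simplices = tri.simplices
    pairs = np.vstack(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]]
    )
    pairs.sort(axis=1)
    edges = np.unique(pairs, axis=0)
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    if max_edge_quantile is not None and max_edge_quantile < 1.0:
        cutoff = np.quantile(lengths, max_edge_quantile)
        keep = lengths <= cutoff
        edges, lengths = edges[keep], lengths[keep]
    return edges, lengths
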