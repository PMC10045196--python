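"""Scoring layer: group detected foci and tally counts per cell.

Foci within a pair distance (3 px) of one another — transitively — form
a group that is assigned jointly to the nearest nucleus, where nearness
is the distance from the group centroid to the nearest pixel of the
nucleus mask (0 when the centroid falls inside). Using the mask rather
than the nucleus centroid keeps peripheral centrioles of large nuclei
attached to the right cell. Nuclei with no nearby foci keep an explicit
zero count.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

from .data import FociList
from .nuclei import NucleiLabels

import logging

logger = logging.getLogger(__name__)


@dataclass
class CellScore:
    field: str
    channel: int
    nucleus: int
    foci_indices: list[int] = dc_field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.foci_indices)


def group_foci(foci: FociList, pair_distance: float = 3.0) -> list[list[int]]:
    """Connected components of the <= pair_distance proximity graph.

    Grouping is transitive: a chain A-B-C with consecutive gaps within
    the pair distance is one group even if A and C are farther apart.
    Groups are ordered by their smallest member index.
    """
    n = len(foci)
    if n == 0:
        return []
    tree = cKDTree(foci.points)
    pairs = np.array(sorted(tree.query_pairs(pair_distance)))
    if len(pairs):
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        _, comp = connected_components(adj, directed=False)
    else:
        comp = np.arange(n)
    groups: dict[int, list[int]] = {}
    for i, c in enumerate(comp):
        groups.setdefault(int(c), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def assign(groups: list[list[int]], foci: FociList, labels: NucleiLabels,
           max_distance: float = np.inf):
    """Assign each focus group to its nearest nucleus.

    Returns ``(scores, unassigned)`` where ``scores`` has one CellScore
    per nucleus (zero counts included) and ``unassigned`` lists groups
    farther than ``max_distance`` from every nucleus (or all groups when
    there is no nucleus). Ties are broken towards the lowest label.
    """
    scores = {rec.label: CellScore(foci.field, foci.channel, rec.label)
              for rec in labels.records}
    unassigned: list[list[int]] = []
    if not labels.records:
        if groups:
            logger.warning("no nuclei: %d focus group(s) left unassigned", len(groups))
        return list(scores.values()), list(groups)

    grid = labels.labels
    h, w = grid.shape
    boundary = find_boundaries(grid, mode="inner")
    coords_by_label = {
        rec.label: np.argwhere(boundary & (grid == rec.label))
        for rec in labels.records
    }
    for lab, coords in coords_by_label.items():
        if len(coords) == 0:  # tiny nucleus: every pixel is "boundary"
            coords_by_label[lab] = np.argwhere(grid == lab)

    for group in groups:
        centroid = foci.points[group].mean(axis=0)
        ri, ci = int(round(centroid[0])), int(round(centroid[1]))
        best_lab, best_d = None, np.inf
        if 0 <= ri < h and 0 <= ci < w and grid[ri, ci] > 0:
            best_lab, best_d = int(grid[ri, ci]), 0.0
        else:
            for rec in labels.records:  # ascending label: ties keep the lowest
                coords = coords_by_label[rec.label]
                d = float(np.min(np.hypot(coords[:, 0] - centroid[0],
                                          coords[:, 1] - centroid[1])))
                if d < best_d:
                    best_lab, best_d = rec.label, d
        if best_lab is None or best_d > max_distance:
            unassigned.append(group)
        else:
            scores[best_lab].foci_indices.extend(group)
    return list(scores.values()), unassigned


def score_field(plane: np.ndarray, model, labels: NucleiLabels, field: str = "",
                channel: int = 1, pair_distance: float = 3.0,
                max_distance: float = np.inf):
    """Detect foci on a marker plane and tally per-nucleus counts.

    Composition of the pipeline stages: probability-map prediction,
    peak extraction, pair grouping and nucleus assignment. Returns
    ``(scores, foci, unassigned)``.
    """
    from .spot_model import detect
    foci = detect(model, plane, field=field, channel=channel)
    groups = group_foci(foci, pair_distance=pair_distance)
    scores, unassigned = assign(groups, foci, labels, max_distance=max_distance)
    return scores, foci, unassigned


def scores_to_rows(scores: list[CellScore]) -> list[dict]:
    """Long-format rows 'field,channel,nucleus,count' for CSV export."""
    return [{"field": s.field, "channel": s.channel, "nucleus": s.nucleus,
             "count": s.count} for s in scores]
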