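"""Brute-force geometry oracles, independent of shapely."""

import numpy as np


def brute_force_hull_area(points: np.ndarray) -> float:
    """O(n³) hull oracle: an edge (i, j) is on the hull iff all other points
    lie on one side; the shoelace sum over directed hull edges gives the area.
    Independent of shapely."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        return 0.0
    area2 = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts - pts[i]
            cross = (pts[j, 0] - pts[i, 0]) * d[:, 1] - (pts[j, 1] - pts[i, 1]) * d[:, 0]
            # directed edge i->j on the hull: everything strictly left or on it
            others = np.delete(cross, [i, j])
            if (others >= -1e-12).all():
                on_edge = np.isclose(cross, 0.0, atol=1e-12)
                # break collinear ties: keep only the farthest endpoint
                dist_ij = np.hypot(*(pts[j] - pts[i]))
                dists = np.hypot(d[:, 0], d[:, 1])
                if (on_edge & (dists > dist_ij + 1e-12)).any():
                    continue
                area2 += pts[i, 0] * pts[j, 1] - pts[j, 0] * pts[i, 1]
    return abs(area2) / 2.0


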