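"""Partition a pass's sensor points into footfalls and build footprint geometry.

Footfalls are re-derived from the point cloud rather than trusted from the
device: the footfall count and initial centroids come from a gap scan of the
longitudinal (walking-axis) projection, K-means refines the memberships, and
each footprint is enclosed in its minimum-area rotated rectangle, which is
sliced into heel/mid/fore thirds along the foot's long axis.  Sides are
assigned by strict alternation in contact order, with the global left/right
choice fixed by each footfall's signed lateral offset from the fitted
central line of the pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from sklearn.cluster import KMeans

from .exceptions import DegenerateFootprintError, ParameterError
from .walkway_io import GRID_PITCH_CM

logger = logging.getLogger(__name__)

#: longitudinal point-gap (cm) separating two footfalls; successive prints at
#: walking speed are >= ~10 cm apart while intra-print row gaps stay near one
#: grid pitch, so four pitches splits robustly
DEFAULT_GAP_CM = 4 * GRID_PITCH_CM


@dataclass
class Footfall:
    """One segmented footprint with its enclosing geometry.

    ``quad`` is the minimum-area rotated bounding rectangle (4x2 corners);
    the three region polygons are its equal-length slices along the long
    axis, ordered heel -> mid -> fore with "fore" the end farther along the
    direction of progression.  Sub-centroids are means of the sensor points
    falling in each slice; ``midline`` runs heel centroid -> fore centroid.
    """

    points: pd.DataFrame
    order_index: int
    first_contact: float
    last_contact: float
    quad: np.ndarray
    heel_region: np.ndarray
    mid_region: np.ndarray
    fore_region: np.ndarray
    heel_centroid: np.ndarray
    mid_centroid: np.ndarray
    fore_centroid: np.ndarray
    overall_centroid: np.ndarray
    quad_length: float
    quad_width: float
    side: str | None = None
    low_confidence_side: bool = False

    @property
    def midline(self) -> np.ndarray:
        return np.vstack([self.heel_centroid, self.fore_centroid])


def _gap_groups(y: np.ndarray, gap_cm: float) -> np.ndarray:
    """Group labels from a 1-D gap scan of sorted longitudinal coordinates."""
    order = np.argsort(y, kind="stable")
    labels = np.empty(len(y), dtype=int)
    g = 0
    prev = None
    for idx in order:
        if prev is not None and y[idx] - prev > gap_cm:
            g += 1
        labels[idx] = g
        prev = y[idx]
    return labels


def estimate_footfall_count(points: pd.DataFrame, gap_cm: float = DEFAULT_GAP_CM) -> int:
    """Number of footfalls in a pass, from the longitudinal gap scan."""
    if len(points) == 0:
        raise ParameterError("cannot estimate footfall count of an empty pass")
    return int(_gap_groups(points["y_cm"].to_numpy(float), gap_cm).max()) + 1


def cluster_footfalls(points: pd.DataFrame, k: int, seed: int = 0,
                      init_centers: np.ndarray | None = None) -> np.ndarray:
    """K-means membership labels for ``k`` footfalls over (x, y) coordinates.

    When ``init_centers`` is given (one per footfall, e.g. gap-scan group
    means) K-means is seeded deterministically with them; otherwise it falls
    back to seeded k-means++.
    """
    xy = points[["x_cm", "y_cm"]].to_numpy(float)
    if k > len(xy):
        raise ParameterError(f"k={k} exceeds the number of points ({len(xy)})")
    if k == 1:
        return np.zeros(len(xy), dtype=int)
    if init_centers is not None:
        km = KMeans(n_clusters=k, init=np.asarray(init_centers, float), n_init=1,
                    random_state=seed)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(xy)


def assign_sides(footfalls: list[Footfall], direction: np.ndarray) -> list[Footfall]:
    """Label footfalls left/right: strict alternation, oriented by lateral offset.

    The central line of the pass is fitted through the footfall centroids
    along ``direction``; the alternating parity group with the smaller mean
    signed lateral offset (rightward positive) is labelled left.  With a
    single footfall the label comes from the offset sign alone and is
    flagged low-confidence.
    """
    d = np.asarray(direction, float)
    d = d / np.hypot(*d)
    centers = np.array([f.overall_centroid for f in footfalls])
    base = centers.mean(axis=0)
    # rightward lateral coordinate relative to the direction of progression
    offsets = d[1] * (centers[:, 0] - base[0]) - d[0] * (centers[:, 1] - base[1])

    if len(footfalls) == 1:
        footfalls[0].side = "left" if offsets[0] <= 0 else "right"
        footfalls[0].low_confidence_side = True
        logger.warning("single footfall: side assigned from lateral offset only")
        return footfalls

    even = offsets[0::2].mean()
    odd = offsets[1::2].mean()
    if even == odd:
        logger.warning("indistinguishable lateral offsets; alternation imposed "
                       "by contact order")
        first_side = "left"
    else:
        first_side = "left" if even < odd else "right"
    other = "right" if first_side == "left" else "left"
    for i, f in enumerate(footfalls):
        f.side = first_side if i % 2 == 0 else other
    return footfalls


def segment_footprint(points: pd.DataFrame, direction=(0.0, 1.0),
                      order_index: int = 0) -> Footfall:
    """Build a footfall's enclosing rectangle, heel/mid/fore slices and centroids.

    The enclosing quadrilateral is the minimum-area rotated bounding
    rectangle of the points; it is cut into three equal-length slices along
    its long axis, with the fore slice at the end farther along
    ``direction``.  Each sub-centroid is the mean of the points in its
    slice.  Raises :class:`DegenerateFootprintError` for < 3 points,
    collinear points, or an empty slice.
    """
    xy = points[["x_cm", "y_cm"]].to_numpy(float)
    if len(xy) < 3:
        raise DegenerateFootprintError("footprint has fewer than 3 points")
    rect = shapely.MultiPoint(xy).minimum_rotated_rectangle
    if rect.area <= 0.0:
        raise DegenerateFootprintError("collinear footprint points")
    corners = np.asarray(rect.exterior.coords)[:4]

    e1 = corners[1] - corners[0]
    e2 = corners[3] - corners[0]
    if np.hypot(*e1) >= np.hypot(*e2):
        long_vec, short_vec, origin = e1, e2, corners[0]
    else:
        long_vec, short_vec, origin = e2, e1, corners[0]
    length = float(np.hypot(*long_vec))
    width = float(np.hypot(*short_vec))
    axis = long_vec / length
    d = np.asarray(direction, float)
    if float(axis @ d) < 0:  # fore end points along the progression
        origin = origin + long_vec
        long_vec = -long_vec
        axis = -axis

    # longitudinal position of each point within [0, length]
    s = (xy - origin) @ axis
    slice_idx = np.clip(np.floor(s / length * 3.0).astype(int), 0, 2)
    centroids = []
    for j in range(3):
        mask = slice_idx == j
        if not mask.any():
            raise DegenerateFootprintError(f"empty {'heel mid fore'.split()[j]} slice")
        centroids.append(xy[mask].mean(axis=0))

    def slab(a, b):
        p0 = origin + long_vec * a
        p1 = origin + long_vec * b
        return np.array([p0, p0 + short_vec, p1 + short_vec, p1])

    t = points["t_peak"].to_numpy(float)
    quad = np.array([origin, origin + short_vec,
                     origin + short_vec + long_vec, origin + long_vec])
    return Footfall(
        points=points.reset_index(drop=True),
        order_index=order_index,
        first_contact=float(t.min()),
        last_contact=float(t.max()),
        quad=quad,
        heel_region=slab(0, 1 / 3), mid_region=slab(1 / 3, 2 / 3),
        fore_region=slab(2 / 3, 1.0),
        heel_centroid=centroids[0], mid_centroid=centroids[1],
        fore_centroid=centroids[2],
        overall_centroid=xy.mean(axis=0),
        quad_length=length, quad_width=width,
    )


def segment_pass(points: pd.DataFrame, gap_cm: float = DEFAULT_GAP_CM,
                 seed: int = 0, exclude_edges: bool = True,
                 dialect=None) -> list[Footfall]:
    """Full segmentation of one pass: count, cluster, orient, slice, label.

    Returns footfalls sorted by first contact with sides assigned.
    Degenerate footprints and prints touching the mat edge are dropped with
    a logged warning.
    """
    from .walkway_io import WalkwayDialect
    dialect = dialect or WalkwayDialect()
    if len(points) == 0:
        return []
    y = points["y_cm"].to_numpy(float)
    groups = _gap_groups(y, gap_cm)
    k = int(groups.max()) + 1
    xy = points[["x_cm", "y_cm"]].to_numpy(float)
    centers = np.array([xy[groups == g].mean(axis=0) for g in range(k)])
    labels = cluster_footfalls(points, k, seed=seed, init_centers=centers)

    clusters = []
    for g in range(k):
        sub = points[labels == g]
        if len(sub) == 0:
            continue
        clusters.append(sub.reset_index(drop=True))
    clusters.sort(key=lambda sub: float(sub["t_peak"].min()))

    if len(clusters) >= 2:
        c_first = clusters[0][["x_cm", "y_cm"]].to_numpy(float).mean(axis=0)
        c_last = clusters[-1][["x_cm", "y_cm"]].to_numpy(float).mean(axis=0)
        direction = c_last - c_first
        if np.hypot(*direction) == 0.0:
            direction = np.array([0.0, 1.0])
    else:
        direction = np.array([0.0, 1.0])

    x_max = (dialect.n_cols - 1) * dialect.pitch_cm
    y_max = (dialect.n_rows - 1) * dialect.pitch_cm
    footfalls = []
    for i, sub in enumerate(clusters):
        if exclude_edges:
            sx = sub["x_cm"].to_numpy(float)
            sy = sub["y_cm"].to_numpy(float)
            if sx.min() <= 0 or sy.min() <= 0 or sx.max() >= x_max or sy.max() >= y_max:
                logger.warning("footfall %d touches the mat edge; excluded", i)
                continue
        try:
            footfalls.append(segment_footprint(sub, direction, order_index=len(footfalls)))
        except DegenerateFootprintError as exc:
            logger.warning("footfall %d dropped: %s", i, exc)
    if not footfalls:
        return []
    return assign_sides(footfalls, direction)


def plot_pass(footfalls: list[Footfall], path=None, ax=None):
    """Debug plot of a segmented pass: points, rectangles, centroids, midlines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 12))
    colors = {"heel": "tab:red", "mid": "tab:blue", "fore": "tab:green"}
    for f in footfalls:
        ax.scatter(f.points["x_cm"], f.points["y_cm"], s=4, c="0.6")
        for name, region in (("heel", f.heel_region), ("mid", f.mid_region),
                             ("fore", f.fore_region)):
            poly = np.vstack([region, region[:1]])
            ax.plot(poly[:, 0], poly[:, 1], color=colors[name], lw=0.8)
        ax.plot(f.midline[:, 0], f.midline[:, 1], color="gold", lw=1.5)
        ax.annotate(f.side or "?", f.overall_centroid, fontsize=8)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
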