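"""Spatiotemporal and geometric gait features computed from segmented footfalls.

Conventions
-----------
* The walkway's long (walking) axis is *y*; *x* is the lateral axis.
* A footfall's *heel center* is the sub-centroid of the heel third of its
  enclosing rectangle; its *midline midpoint* is the midpoint of the
  heel-centroid -> fore-centroid segment.
* The line of progression (LOP) of a footfall is the segment joining its
  heel center to the heel center of the next same-side footfall.
* Toe angle is the signed angle between a footfall's midline and its LOP;
  positive means toe-out (midline rotated laterally away from the body
  midline).  The sign convention can be flipped via ``toe_out_positive``.
* Footfalls in a pass strictly alternate sides, so index neighbours
  ``i-1``/``i+1`` are the opposite foot and ``i-2``/``i+2`` the same foot.

Lengths are cm, times seconds, velocities cm/s, areas cm^2, angles degrees.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely

from .exceptions import DegenerateFootprintError
from .walkway_io import GRID_PITCH_CM, PassRecording

logger = logging.getLogger(__name__)

#: anchor columns consumed by :func:`pairwise_features`
ANCHOR_COLUMNS = (
    "side", "heel_x", "heel_y", "fore_x", "fore_y",
    "mid_x", "mid_y", "cx", "cy", "first_contact", "last_contact",
)

#: all feature columns produced by :func:`assemble_feature_rows`
FEATURE_COLUMNS = (
    "foot_type",
    "foot_length", "foot_width", "foot_area", "hull_area", "bos_area",
    "toe_angle_signed", "toe_angle_unsigned", "toe_direction",
    "lop_deviation_angle",
    "step_length", "step_width", "stride_length", "stride_width", "base_width",
    "step_time", "stride_time", "single_support_time", "double_support_time",
    "stance_time", "step_velocity", "stride_velocity",
)


# ---------------------------------------------------------------------------
# scalar geometric primitives
# ---------------------------------------------------------------------------

def hull_area(points: np.ndarray) -> float:
    """Area of the convex hull of a footprint's sensor points (cm^2).

    Raises :class:`DegenerateFootprintError` for fewer than three points or
    a collinear point set.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise DegenerateFootprintError("convex hull needs at least 3 points")
    hull = shapely.MultiPoint(pts).convex_hull
    if hull.area <= 0.0:
        raise DegenerateFootprintError("collinear points have no hull area")
    return float(hull.area)


def bos_area(points: np.ndarray, preceding_points: np.ndarray) -> float:
    """Base-of-support area: convex-hull area of two pooled footprints (cm^2).

    The base of support between a footfall and its preceding (opposite-foot)
    print is approximated by the convex polygon enclosing both point clouds.
    Always >= the hull area of either footprint alone.
    """
    pooled = np.vstack([np.asarray(points, float), np.asarray(preceding_points, float)])
    return hull_area(pooled)


def point_line_distance(p, a, b) -> float:
    """Perpendicular distance from point ``p`` to the line through ``a``, ``b``."""
    p, a, b = (np.asarray(v, float) for v in (p, a, b))
    d = b - a
    n = np.hypot(*d)
    if n == 0.0:
        raise DegenerateFootprintError("line through coincident points is undefined")
    return float(abs(d[0] * (p[1] - a[1]) - d[1] * (p[0] - a[0])) / n)


def signed_toe_angle(heel, fore, heel_next_same, side, toe_out_positive=True) -> float:
    """Signed toe angle (degrees) of a footfall relative to its LOP.

    ``heel``/``fore`` are the footfall's heel and fore centroids,
    ``heel_next_same`` the heel centroid of the next same-side footfall.
    Result in (-90, 90]; positive = toe-out under the default convention.
    """
    heel = np.asarray(heel, float)
    lop = np.asarray(heel_next_same, float) - heel
    mid = np.asarray(fore, float) - heel
    if np.hypot(*mid) == 0.0 or np.hypot(*lop) == 0.0:
        raise DegenerateFootprintError("zero-length midline or LOP")
    cross = lop[0] * mid[1] - lop[1] * mid[0]
    dot = lop[0] * mid[0] + lop[1] * mid[1]
    psi = np.degrees(np.arctan2(cross, dot))
    # walking along +y, a left foot's outward (toe-out) rotation is counter-
    # clockwise (+psi); a right foot's is clockwise
    angle = psi if side == "left" else -psi
    if not toe_out_positive:
        angle = -angle
    # map to (-90, 90] (midline orientation is axial)
    if angle > 90.0:
        angle -= 180.0
    elif angle <= -90.0:
        angle += 180.0
    return float(angle)


def lop_deviation_angle(center, center_next_same) -> float:
    """Unsigned angle (degrees, [0, 90]) between the actual LOP and the mat axis.

    The actual LOP joins the overall centroids of two consecutive same-side
    footfalls; the normal LOP runs parallel to the walkway's long axis.
    """
    d = np.asarray(center_next_same, float) - np.asarray(center, float)
    n = np.hypot(*d)
    if n == 0.0:
        raise DegenerateFootprintError("coincident footfall centers")
    return float(np.degrees(np.arctan2(abs(d[0]), abs(d[1]))))


def toe_direction_split(toe_angle_signed: float) -> tuple[float, int]:
    """Split a signed toe angle into (magnitude, direction).

    Direction is the binary category 1 for angles >= 0 and 0 for negative
    angles.
    """
    if not np.isfinite(toe_angle_signed):
        raise ValueError("toe angle must be finite")
    return abs(float(toe_angle_signed)), int(toe_angle_signed >= 0)


def foot_dimensions(footfall) -> tuple[float, float, float]:
    """(foot_length, foot_width, foot_area) of a segmented footfall.

    * foot_length: heel-to-fore centroid distance scaled by 1.5.  For a
      uniformly covered footprint the two sub-centroids sit at 1/6 and 5/6
      of the foot, 2/3 of the foot apart, so the factor recovers the full
      length.
    * foot_width: the short side of the enclosing rectangle, i.e. the
      distance across the fore slice measured through its midpoint
      perpendicular to the long axis.
    * foot_area: number of distinct activated cells times the cell area.
    """
    d = np.hypot(*(np.asarray(footfall.fore_centroid) - np.asarray(footfall.heel_centroid)))
    if d == 0.0:
        raise DegenerateFootprintError("coincident heel and fore centroids")
    length = 1.5 * d
    width = float(footfall.quad_width)
    xy = footfall.points[["x_cm", "y_cm"]].to_numpy()
    n_cells = len(np.unique(np.round(xy / GRID_PITCH_CM).astype(int), axis=0))
    area = n_cells * GRID_PITCH_CM ** 2
    return float(length), width, float(area)


# ---------------------------------------------------------------------------
# pairwise (neighbour-dependent) features
# ---------------------------------------------------------------------------

def pairwise_features(anchors: pd.DataFrame, toe_out_positive: bool = True) -> pd.DataFrame:
    """Compute all neighbour-dependent features for one pass.

    ``anchors`` has one row per footfall, sorted by first contact, with the
    :data:`ANCHOR_COLUMNS`.  Rows at pass boundaries that lack the required
    neighbour get NaN for the affected features.  Negative double support
    (flight) is clamped to 0 with a warning.
    """
    n = len(anchors)
    heel = anchors[["heel_x", "heel_y"]].to_numpy(float)
    fore = anchors[["fore_x", "fore_y"]].to_numpy(float)
    mid = anchors[["mid_x", "mid_y"]].to_numpy(float)
    cen = anchors[["cx", "cy"]].to_numpy(float)
    first = anchors["first_contact"].to_numpy(float)
    last = anchors["last_contact"].to_numpy(float)
    side = anchors["side"].to_numpy()

    out = pd.DataFrame(index=range(n), columns=[
        "step_length", "step_width", "stride_length", "stride_width", "base_width",
        "toe_angle_signed", "lop_deviation_angle",
        "step_time", "stride_time", "single_support_time", "double_support_time",
        "stance_time", "step_velocity", "stride_velocity",
    ], dtype=float)

    out["stance_time"] = last - first
    for i in range(n):
        if i >= 1:  # previous opposite foot
            out.at[i, "step_length"] = abs(heel[i, 1] - heel[i - 1, 1])
            out.at[i, "step_width"] = abs(mid[i, 0] - mid[i - 1, 0])
            out.at[i, "step_time"] = first[i] - first[i - 1]
        if i >= 2:  # previous same-side foot
            out.at[i, "stride_length"] = float(np.hypot(*(heel[i] - heel[i - 2])))
            out.at[i, "stride_time"] = first[i] - first[i - 2]
        if 1 <= i <= n - 2:  # bracketing opposite-foot pair
            try:
                out.at[i, "stride_width"] = point_line_distance(mid[i], mid[i - 1], mid[i + 1])
                out.at[i, "base_width"] = point_line_distance(heel[i], heel[i - 1], heel[i + 1])
            except DegenerateFootprintError:
                pass
        if i <= n - 3:  # next same-side foot
            try:
                out.at[i, "toe_angle_signed"] = signed_toe_angle(
                    heel[i], fore[i], heel[i + 2], side[i], toe_out_positive)
                out.at[i, "lop_deviation_angle"] = lop_deviation_angle(cen[i], cen[i + 2])
            except DegenerateFootprintError:
                pass
            out.at[i, "single_support_time"] = first[i + 2] - last[i]
        if i <= n - 2:  # next (opposite) foot: shared-contact window
            ds = last[i] - first[i + 1]
            if ds < 0:
                logger.warning("negative double support at footfall %d clamped to 0", i)
                ds = 0.0
            out.at[i, "double_support_time"] = ds

    with np.errstate(invalid="ignore", divide="ignore"):
        sv = out["step_length"] / out["step_time"]
        out["step_velocity"] = sv.where(out["step_time"] > 0)
        rv = out["stride_length"] / out["stride_time"]
        out["stride_velocity"] = rv.where(out["stride_time"] > 0)
    return out


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def assemble_feature_rows(recordings: list[PassRecording],
                          toe_out_positive: bool = True,
                          lop_from_centroids: bool = True) -> pd.DataFrame:
    """Segment every pass and build the per-footfall feature table.

    One row per retained footfall, carrying subject/visit/class metadata
    (``visit_id`` is the grouping key for cross-validation) and every feature
    column.  Boundary footfalls keep NaN for neighbour-dependent features;
    degenerate footfalls are excluded with a logged count.

    ``lop_from_centroids`` switches the LOP-deviation construction between
    overall footprint centroids (default) and heel centers.
    """
    from .segmentation import segment_pass  # deferred to avoid import cycle

    rows = []
    n_excluded = 0
    for rec in recordings:
        footfalls = segment_pass(rec.points)
        if not footfalls:
            continue
        anchors = pd.DataFrame([{
            "side": f.side,
            "heel_x": f.heel_centroid[0], "heel_y": f.heel_centroid[1],
            "fore_x": f.fore_centroid[0], "fore_y": f.fore_centroid[1],
            "mid_x": (f.heel_centroid[0] + f.fore_centroid[0]) / 2,
            "mid_y": (f.heel_centroid[1] + f.fore_centroid[1]) / 2,
            "cx": f.overall_centroid[0] if lop_from_centroids else f.heel_centroid[0],
            "cy": f.overall_centroid[1] if lop_from_centroids else f.heel_centroid[1],
            "first_contact": f.first_contact, "last_contact": f.last_contact,
        } for f in footfalls])
        pair = pairwise_features(anchors, toe_out_positive=toe_out_positive)

        for i, f in enumerate(footfalls):
            try:
                length, width, area = foot_dimensions(f)
                h_area = hull_area(f.points[["x_cm", "y_cm"]].to_numpy())
            except DegenerateFootprintError:
                n_excluded += 1
                continue
            if i >= 1:
                b_area = bos_area(f.points[["x_cm", "y_cm"]].to_numpy(),
                                  footfalls[i - 1].points[["x_cm", "y_cm"]].to_numpy())
            else:
                b_area = np.nan
            toe = pair.at[i, "toe_angle_signed"]
            if np.isfinite(toe):
                toe_mag, toe_dir = toe_direction_split(toe)
            else:
                toe_mag, toe_dir = np.nan, np.nan
            row = {
                "subject_id": rec.subject_id,
                "visit_id": rec.visit_id,
                "class_label": rec.class_label,
                "height_cm": rec.height_cm,
                "pass_index": rec.pass_index,
                "footfall_index": i,
                "foot_type": f.side,
                "foot_length": length, "foot_width": width, "foot_area": area,
                "hull_area": h_area, "bos_area": b_area,
                "toe_angle_signed": toe, "toe_angle_unsigned": toe_mag,
                "toe_direction": toe_dir,
            }
            row.update({c: pair.at[i, c] for c in pair.columns if c != "toe_angle_signed"})
            rows.append(row)
    if n_excluded:
        logger.info("excluded %d degenerate footfalls from the feature table", n_excluded)
    meta_cols = ["subject_id", "visit_id", "class_label", "height_cm",
                 "pass_index", "footfall_index"]
    return pd.DataFrame(rows, columns=meta_cols + list(FEATURE_COLUMNS))
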