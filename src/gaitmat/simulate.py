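"""Synthetic instrumented-walkway cohorts with per-footfall ground truth.

The generator plans a sequence of alternating left/right footfalls from a
parametric gait profile (step geometry, cadence, contact durations, foot
shape), rasterizes each footprint onto the 1.27 cm sensor grid, and emits
per-cell pressure time series shaped like a heel-to-toe rollover: every cell
rises to a peak and decays, heel cells peaking before fore cells, with the
rearmost cell peaking at first contact and the foremost at last contact.
Reducing each cell to its peak-pressure timestamp therefore recovers the
planned contact window exactly.

Ground truth is recorded per footfall: the true value of every feature the
extraction pipeline computes (evaluated analytically on the planned
continuous geometry, or on the emitted cell set for the area features) plus
the cell membership of every emitted sensor cell.

Class-conditional defaults emulate a mobility-impaired gait (shorter, more
variable steps, wider base, larger toe-angle variance, longer double
support) versus an unimpaired one.  They are test fixtures for recovery and
classification experiments, not clinical claims.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import shapely

from .exceptions import GenerationError, ProfileValidationError
from .features import ANCHOR_COLUMNS, pairwise_features
from .walkway_io import WalkwayDialect

__all__ = [
    "GaitProfile", "FootTemplate", "PlannedStep", "CohortData",
    "CONTROL_PROFILE", "MS_LIKE_PROFILE",
    "sample_gait_sequence", "rasterize_footprint", "generate_cohort",
]

MAT_WIDTH_CM = 90.0
MAT_LENGTH_CM = 420.0


@dataclass(frozen=True)
class GaitProfile:
    """Class-conditional gait parameter distributions, each (mean, sd).

    Units: lengths/widths cm, times s, angles degrees.  ``toe_angle`` is the
    signed toe-out angle (positive = toes pointing laterally outward);
    ``lop_drift`` is the per-pass deviation of the walking direction from
    the mat axis.  ``n_steps_per_pass`` is an inclusive integer range.
    """

    class_label: str
    step_length: tuple = (65.0, 5.0)
    step_width: tuple = (9.0, 2.0)
    toe_angle: tuple = (5.0, 3.0)
    step_time: tuple = (0.53, 0.04)
    stance_time: tuple = (0.62, 0.05)
    foot_length: tuple = (25.4, 1.2)
    foot_width: tuple = (9.5, 0.7)
    lop_drift: tuple = (0.0, 1.0)
    n_steps_per_pass: tuple = (5, 6)

    def validate(self) -> None:
        for name in ("step_length", "step_width", "toe_angle", "step_time",
                     "stance_time", "foot_length", "foot_width", "lop_drift"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ProfileValidationError(f"{name} has negative sd {sd}")
        if self.step_width[0] > MAT_WIDTH_CM:
            raise ProfileValidationError("mean step width exceeds the mat width")
        if self.step_width[0] + self.foot_width[0] > MAT_WIDTH_CM:
            raise ProfileValidationError("footprints cannot fit the mat width")
        if self.stance_time[0] >= 2 * self.step_time[0]:
            raise ProfileValidationError("stance time must be < 2 x step time")
        lo, hi = self.n_steps_per_pass
        if not (1 <= lo <= hi):
            raise ProfileValidationError("invalid n_steps_per_pass range")

    def with_zero_sd(self) -> "GaitProfile":
        """Degenerate copy with every sd set to 0 (deterministic geometry)."""
        kwargs = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple) and len(v) == 2 and f.name != "n_steps_per_pass":
                kwargs[f.name] = (v[0], 0.0)
        return replace(self, **kwargs)


#: unimpaired reference gait
CONTROL_PROFILE = GaitProfile(class_label="control")

#: mobility-impaired gait: shorter and more variable steps, wider base,
#: larger toe-angle variance, slower cadence, longer double support
MS_LIKE_PROFILE = GaitProfile(
    class_label="patient",
    step_length=(50.0, 8.0),
    step_width=(13.0, 3.0),
    toe_angle=(8.0, 6.0),
    step_time=(0.62, 0.08),
    stance_time=(0.78, 0.09),
    foot_length=(25.4, 1.2),
    foot_width=(9.5, 0.7),
    lop_drift=(0.0, 3.0),
    n_steps_per_pass=(5, 7),
)


@dataclass(frozen=True)
class FootTemplate:
    """Rectangular foot outline in foot-local cm coordinates.

    Heel edge at the origin, long axis along +y: x in [-w/2, w/2],
    y in [0, L].  Pressure rollover: a cell at normalized longitudinal
    position p peaks at stance phase p with magnitude 100 - 30 p, so heel
    cells peak earlier and harder than fore cells.
    """

    length_cm: float
    width_cm: float

    def outline(self) -> np.ndarray:
        w, L = self.width_cm / 2.0, self.length_cm
        return np.array([[-w, 0.0], [w, 0.0], [w, L], [-w, L]])


@dataclass
class PlannedStep:
    """One planned footfall: pose, side, contact window, and foot shape."""

    index: int
    side: str  # "left" | "right"
    heel: np.ndarray  # global heel position, cm
    phi_deg: float  # foot long-axis rotation, CCW from +y
    first_contact: float
    last_contact: float
    template: FootTemplate


def _rot(deg: float) -> np.ndarray:
    r = np.radians(deg)
    return np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])


def sample_gait_sequence(profile: GaitProfile, seed, start_y: float = 15.0,
                         center_x: float = MAT_WIDTH_CM / 2.0) -> list[PlannedStep]:
    """Plan one pass: alternating footfalls advancing along the walkway.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  Draws are
    truncated to feasible geometry (in particular, consecutive prints stay
    longitudinally disjoint so footprints never merge on the mat).  Steps
    that would run off the end of the mat are dropped.
    """
    profile.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_steps = int(rng.integers(profile.n_steps_per_pass[0],
                               profile.n_steps_per_pass[1] + 1))
    drift = float(rng.normal(*profile.lop_drift))
    templates = {
        side: FootTemplate(
            length_cm=float(np.clip(rng.normal(*profile.foot_length), 15.0, 35.0)),
            width_cm=float(np.clip(rng.normal(*profile.foot_width), 5.0, 16.0)))
        for side in ("left", "right")
    }
    R = _rot(drift)

    steps: list[PlannedStep] = []
    y_walk = 0.0
    t_first = 0.0
    for i in range(n_steps):
        side = "left" if i % 2 == 0 else "right"
        tpl = templates[side]
        if i > 0:
            # keep prints longitudinally disjoint: floor at foot length + 10
            step_len = max(float(rng.normal(*profile.step_length)), tpl.length_cm + 10.0)
            y_walk += step_len
            t_first += max(float(rng.normal(*profile.step_time)), 0.15)
        width = float(np.clip(rng.normal(*profile.step_width), 1.0, 40.0))
        lateral = -width / 2.0 if side == "left" else width / 2.0
        heel = np.array([center_x, start_y]) + R @ np.array([lateral, y_walk])
        toe = float(np.clip(rng.normal(*profile.toe_angle), -45.0, 45.0))
        phi = drift + toe if side == "left" else drift - toe
        stance = max(float(rng.normal(*profile.stance_time)), 0.10)
        # keep the rotated footprint on the mat laterally (subjects drift
        # back toward the centre rather than stepping off the edge)
        corners = heel + tpl.outline() @ _rot(phi).T
        margin = 1.27
        if corners[:, 0].min() < margin:
            heel = heel + np.array([margin - corners[:, 0].min(), 0.0])
        elif corners[:, 0].max() > MAT_WIDTH_CM - margin:
            heel = heel - np.array([corners[:, 0].max() - (MAT_WIDTH_CM - margin), 0.0])
        corners = heel + tpl.outline() @ _rot(phi).T
        if corners[:, 1].max() + 2.0 > MAT_LENGTH_CM:
            break  # ran off the end of the mat
        steps.append(PlannedStep(index=i, side=side, heel=heel, phi_deg=phi,
                                 first_contact=t_first,
                                 last_contact=t_first + stance,
                                 template=tpl))
    if len(steps) < 2:
        raise GenerationError("pass does not fit on the mat; shorten the steps")
    return steps


def footprint_polygon(step: PlannedStep) -> np.ndarray:
    """Global corner coordinates of a planned footprint's outline."""
    return step.heel + step.template.outline() @ _rot(step.phi_deg).T


def rasterize_footprint(step: PlannedStep,
                        dialect: WalkwayDialect | None = None,
                        pass_index: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Emit raw sensor events for one footprint on the sensor grid.

    The emitted cells are exactly those whose centres fall inside the
    rotated/translated outline.  Each cell emits 2-3 samples spanning the
    contact window, with its maximum pressure at the rollover phase given by
    its longitudinal position along the foot.

    Returns ``(events, cells)`` where ``cells`` is the (n, 2) array of
    (x_index, y_index) memberships.  Raises :class:`GenerationError` if the
    outline leaves the mat or is degenerate.
    """
    dialect = dialect or WalkwayDialect()
    pitch = dialect.pitch_cm
    corners = footprint_polygon(step)
    poly = shapely.Polygon(corners)
    if poly.area <= 0.0:
        raise GenerationError(f"step {step.index}: degenerate zero-area outline")
    if (corners[:, 0].min() < 0 or corners[:, 1].min() < 0
            or corners[:, 0].max() > (dialect.n_cols - 1) * pitch
            or corners[:, 1].max() > (dialect.n_rows - 1) * pitch):
        raise GenerationError(f"step {step.index}: footprint outside the mat")

    ix_lo = int(np.floor(corners[:, 0].min() / pitch))
    ix_hi = int(np.ceil(corners[:, 0].max() / pitch))
    iy_lo = int(np.floor(corners[:, 1].min() / pitch))
    iy_hi = int(np.ceil(corners[:, 1].max() / pitch))
    ix, iy = np.meshgrid(np.arange(ix_lo, ix_hi + 1), np.arange(iy_lo, iy_hi + 1),
                         indexing="ij")
    ix, iy = ix.ravel(), iy.ravel()
    inside = shapely.contains_xy(poly, ix * pitch, iy * pitch)
    ix, iy = ix[inside], iy[inside]
    if len(ix) == 0:
        raise GenerationError(f"step {step.index}: outline covers no cell centre")

    # rollover phase from the longitudinal foot-local coordinate of each cell
    local = (np.column_stack([ix * pitch, iy * pitch]) - step.heel) @ _rot(step.phi_deg)
    y_local = local[:, 1]
    span = y_local.max() - y_local.min()
    phase = (y_local - y_local.min()) / span if span > 0 else np.full(len(ix), 0.5)

    t0, t1 = step.first_contact, step.last_contact
    t_peak = t0 + phase * (t1 - t0)
    peak = 100.0 - 30.0 * phase

    times = np.concatenate([np.full(len(ix), t0), t_peak, np.full(len(ix), t1)])
    pressures = np.concatenate([0.3 * peak, peak, 0.2 * peak])
    cells_x = np.tile(ix, 3)
    cells_y = np.tile(iy, 3)
    events = pd.DataFrame({
        "time": times, "x_index": cells_x, "y_index": cells_y,
        "pressure": pressures,
        "foot_type": "Left" if step.side == "left" else "Right",
        "foot_count": step.index + 1, "footfall": step.index,
        "pass_index": pass_index,
    })
    # a cell sampled twice at the same instant keeps the higher pressure
    events = (events.sort_values("pressure", ascending=False, kind="stable")
              .drop_duplicates(["x_index", "y_index", "time"])
              .sort_values(["y_index", "x_index", "time"], kind="stable")
              .reset_index(drop=True))
    return events, np.column_stack([ix, iy])


def _analytic_anchors(steps: list[PlannedStep]) -> pd.DataFrame:
    """Continuous-geometry anchors (heel/fore/midline/centroid, contacts)."""
    rows = []
    for s in steps:
        R = _rot(s.phi_deg)
        L = s.template.length_cm
        heel_c = s.heel + R @ np.array([0.0, L / 6.0])
        fore_c = s.heel + R @ np.array([0.0, 5.0 * L / 6.0])
        mid = s.heel + R @ np.array([0.0, L / 2.0])
        rows.append({
            "side": s.side,
            "heel_x": heel_c[0], "heel_y": heel_c[1],
            "fore_x": fore_c[0], "fore_y": fore_c[1],
            "mid_x": mid[0], "mid_y": mid[1],
            "cx": mid[0], "cy": mid[1],
            "first_contact": s.first_contact, "last_contact": s.last_contact,
        })
    return pd.DataFrame(rows, columns=list(ANCHOR_COLUMNS))


def _pass_truth(steps, cell_sets, pitch) -> pd.DataFrame:
    """Ground-truth feature rows for one pass."""
    anchors = _analytic_anchors(steps)
    pair = pairwise_features(anchors)
    rows = []
    for i, s in enumerate(steps):
        centers = cell_sets[i] * pitch
        h_area = shapely.MultiPoint(centers).convex_hull.area
        if i >= 1:
            pooled = np.vstack([centers, cell_sets[i - 1] * pitch])
            b_area = shapely.MultiPoint(pooled).convex_hull.area
        else:
            b_area = np.nan
        toe = pair.at[i, "toe_angle_signed"]
        row = {
            "footfall_index": i, "foot_type": s.side,
            "foot_length": s.template.length_cm,
            "foot_width": s.template.width_cm,
            "foot_area": len(cell_sets[i]) * pitch ** 2,
            "hull_area": float(h_area), "bos_area": float(b_area),
            "toe_angle_signed": toe,
            "toe_angle_unsigned": abs(toe) if np.isfinite(toe) else np.nan,
            "toe_direction": int(toe >= 0) if np.isfinite(toe) else np.nan,
            "n_cells": len(cell_sets[i]),
        }
        row.update({c: pair.at[i, c] for c in pair.columns if c != "toe_angle_signed"})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortData:
    """A generated cohort: raw events, pass metadata, and ground truth."""

    events: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame
    memberships: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path
        from .walkway_io import write_raw_export
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_raw_export(self.events, outdir / "raw_export.csv")
        self.metadata.to_csv(outdir / "metadata.csv", index=False)
        self.truth.to_csv(outdir / "ground_truth.csv", index=False)
        self.memberships.to_csv(outdir / "memberships.csv", index=False)


def _subject_profile(profile: GaitProfile, rng, between_frac, within_frac) -> GaitProfile:
    """Draw a subject-level profile: means shifted once, sds left for steps."""
    kwargs = {}
    for f in dataclasses.fields(profile):
        v = getattr(profile, f.name)
        if f.name == "n_steps_per_pass" or not isinstance(v, tuple):
            continue
        mean, sd = v
        kwargs[f.name] = (float(rng.normal(mean, sd * between_frac)), sd * within_frac)
    sub = replace(profile, **kwargs)
    # re-impose feasibility on the drawn means
    sub = replace(sub,
                  step_length=(max(sub.step_length[0], 25.0), sub.step_length[1]),
                  step_width=(float(np.clip(sub.step_width[0], 2.0, 40.0)), sub.step_width[1]),
                  step_time=(max(sub.step_time[0], 0.2), sub.step_time[1]),
                  stance_time=(min(max(sub.stance_time[0], 0.15),
                                   1.9 * max(sub.step_time[0], 0.2)), sub.stance_time[1]),
                  foot_length=(float(np.clip(sub.foot_length[0], 15.0, 35.0)), sub.foot_length[1]),
                  foot_width=(float(np.clip(sub.foot_width[0], 5.0, 16.0)), sub.foot_width[1]))
    return sub


def generate_cohort(n_patients: int,
                    n_controls: int | None = None,
                    passes_per_subject: int = 2,
                    patient_profile: GaitProfile = MS_LIKE_PROFILE,
                    control_profile: GaitProfile = CONTROL_PROFILE,
                    seed: int = 0,
                    ratio: float = 6.0,
                    between_frac: float = 0.8,
                    within_frac: float = 0.5,
                    height: tuple = (170.0, 8.0),
                    dialect: WalkwayDialect | None = None) -> CohortData:
    """Generate a full cohort of raw walkway recordings with ground truth.

    Each subject's gait parameters are drawn once from the class profile
    (between-subject spread ``between_frac`` x sd) and then perturbed per
    step (within-subject spread ``within_frac`` x sd).  When ``n_controls``
    is None it is derived from the patient:control ``ratio`` (at least 1).
    Every pass gets a globally unique ``pass_index``; each subject has one
    visit, whose id is the cross-validation group key.
    """
    if n_patients < 1:
        raise GenerationError("need at least one patient")
    if n_controls is None:
        n_controls = max(1, round(n_patients / ratio))
    dialect = dialect or WalkwayDialect()
    rng = np.random.default_rng(seed)

    events_parts, meta_rows, truth_parts, member_rows = [], [], [], []
    pass_counter = 0
    specs = ([("patient", patient_profile)] * n_patients
             + [("control", control_profile)] * n_controls)
    for subj_no, (label, profile) in enumerate(specs):
        subject_id = f"S{subj_no:03d}"
        visit_id = f"{subject_id}_v1"
        height_cm = float(np.clip(rng.normal(*height), 145.0, 205.0))
        sub_profile = _subject_profile(profile, rng, between_frac, within_frac)
        for _ in range(passes_per_subject):
            steps = sample_gait_sequence(sub_profile, rng)
            cell_sets = []
            for s in steps:
                ev, cells = rasterize_footprint(s, dialect, pass_index=pass_counter)
                events_parts.append(ev)
                cell_sets.append(cells)
                member_rows.append(pd.DataFrame({
                    "pass_index": pass_counter, "footfall_index": s.index,
                    "x_index": cells[:, 0], "y_index": cells[:, 1],
                }))
            truth = _pass_truth(steps, cell_sets, dialect.pitch_cm)
            truth.insert(0, "pass_index", pass_counter)
            truth.insert(0, "class_label", label)
            truth.insert(0, "visit_id", visit_id)
            truth.insert(0, "subject_id", subject_id)
            truth_parts.append(truth)
            meta_rows.append({"pass_index": pass_counter, "subject_id": subject_id,
                              "visit_id": visit_id, "class_label": label,
                              "height_cm": height_cm})
            pass_counter += 1

    events = pd.concat(events_parts, ignore_index=True)
    events = events.sort_values(["pass_index", "time", "y_index", "x_index"],
                                kind="stable").reset_index(drop=True)
    return CohortData(
        events=events,
        metadata=pd.DataFrame(meta_rows),
        truth=pd.concat(truth_parts, ignore_index=True),
        memberships=pd.concat(member_rows, ignore_index=True),
    )
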