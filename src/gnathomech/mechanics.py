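"""Mechanical advantage of the mandibular lever system.

The mandible acts as a lever: the adductor muscle pulls on an inlever arm
(joint -> muscle attachment) and transmits force at a bite point on the
gnathal edge, at the end of an outlever arm (joint -> bite point).  The
mechanical advantage (MA) at a bite point is the inlever / outlever ratio:
the fraction of muscle force transmitted to the food item.  Low MA means a
fast, weak bite (typical of predators); high MA a slow, forceful bite
(typical of herbivores).

MA is computed along the entire gnathal edge, from the proximal molar region
(s = 0, largest MA) to the distal incisivus apex (s = 1), after resampling
the edge polyline uniformly in arc length.  For flattened (2D) fossils the
joint is a single pivot point; for 3D data it is the dicondylar axis through
the two condyles, and moment arms are perpendicular distances to that axis.
Because MA is a ratio of moment arms it is invariant to translation,
rotation, reflection and uniform scaling of the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landmarks import LandmarkConfiguration


@dataclass
class MandibleGeometry:
    """Lever elements of one mandible.

    ``joint`` is a ``(d,)`` pivot point (2D) or a ``(2, d)`` array holding
    the two condyle points of the dicondylar axis (3D).  ``edge`` is the
    ordered gnathal-edge polyline, proximal (molar) first.
    """

    specimen_id: str
    joint: np.ndarray
    inlever_point: np.ndarray
    edge: np.ndarray

    def __post_init__(self):
        self.joint = np.asarray(self.joint, dtype=float)
        self.inlever_point = np.asarray(self.inlever_point, dtype=float)
        self.edge = np.asarray(self.edge, dtype=float)
        if self.edge.ndim != 2 or self.edge.shape[0] < 4:
            raise ValueError(f"{self.specimen_id}: edge polyline needs >= 4 points")
        d = self.edge.shape[1]
        if self.joint.shape not in ((d,), (2, d)):
            raise ValueError(f"{self.specimen_id}: joint must be a point or a "
                             f"2-point axis of dimension {d}")
        if self.is_axis and np.allclose(self.joint[0], self.joint[1]):
            raise ValueError(f"{self.specimen_id}: coincident condyles")
        seg = np.linalg.norm(np.diff(self.edge, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError(f"{self.specimen_id}: repeated consecutive edge points")
        if seg.sum() <= 0.0:
            raise ValueError(f"{self.specimen_id}: edge has zero arc length")
        if inlever_length(self) <= 0.0:
            raise ValueError(
                f"{self.specimen_id}: adductor attachment coincides with the joint")

    @property
    def is_axis(self) -> bool:
        return self.joint.ndim == 2

    @property
    def ndim(self) -> int:
        return self.edge.shape[1]


@dataclass
class MACurve:
    """Mechanical advantage sampled along the gnathal edge.

    ``s`` holds normalized arc-length positions in [0, 1] (0 proximal, 1
    distal), strictly increasing; ``ma`` the positive MA values.
    """

    specimen_id: str
    s: np.ndarray
    ma: np.ndarray

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.ma = np.asarray(self.ma, dtype=float)
        if self.s.shape != self.ma.shape or self.s.ndim != 1:
            raise ValueError(f"{self.specimen_id}: s and ma must be equal-length vectors")
        if not (np.all(np.diff(self.s) > 0) and self.s[0] == 0.0 and self.s[-1] == 1.0):
            raise ValueError(f"{self.specimen_id}: s must increase strictly from 0 to 1")
        if not np.all(np.isfinite(self.ma)) or np.any(self.ma <= 0):
            raise ValueError(f"{self.specimen_id}: MA values must be finite and positive")

    @property
    def n_points(self) -> int:
        return self.s.size


def _axis_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Perpendicular distance of `points` to the line through a and b."""
    u = (b - a) / np.linalg.norm(b - a)
    rel = np.atleast_2d(points) - a
    perp = rel - np.outer(rel @ u, u)
    return np.linalg.norm(perp, axis=1)


def _joint_distance(geom: MandibleGeometry, points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(points)
    if geom.is_axis:
        return _axis_distance(pts, geom.joint[0], geom.joint[1])
    return np.linalg.norm(pts - geom.joint, axis=1)


def inlever_length(geom: MandibleGeometry) -> float:
    """Moment arm of the adductor: distance from the joint to its attachment.

    Euclidean distance to the pivot in 2D; perpendicular distance to the
    dicondylar axis in 3D (the axial component exerts no moment).
    """
    return float(_joint_distance(geom, geom.inlever_point)[0])


def lever_geometry_from_landmarks(config: LandmarkConfiguration) -> MandibleGeometry:
    """Assemble lever geometry from a role-labelled configuration.

    Edge points are taken in stored order (proximal -> distal).  In 2D the
    joint pivot is the single condyle landmark (the midpoint if both condyles
    were digitized on a flattened specimen); in 3D both condyles are required
    and define the dicondylar axis.
    """
    cond_a = config.points_with_role("condyle_anterior")
    cond_p = config.points_with_role("condyle_posterior")
    adductor = config.points_with_role("adductor_attachment")
    edge = config.points_with_role("edge_point")
    if adductor.shape[0] != 1:
        raise ValueError(f"{config.specimen_id}: exactly one adductor_attachment "
                         f"landmark required, found {adductor.shape[0]}")
    if edge.shape[0] < 4:
        raise ValueError(f"{config.specimen_id}: need >= 4 edge_point landmarks, "
                         f"found {edge.shape[0]}")
    condyles = np.vstack([c for c in (cond_a, cond_p) if c.size])
    if condyles.shape[0] == 0:
        raise ValueError(f"{config.specimen_id}: missing condyle landmark "
                         f"(condyle_anterior or condyle_posterior)")
    if config.ndim == 2:
        joint = condyles.mean(axis=0)
    else:
        if condyles.shape[0] != 2:
            raise ValueError(f"{config.specimen_id}: 3D geometry requires both "
                             f"condyle_anterior and condyle_posterior")
        joint = condyles
    return MandibleGeometry(config.specimen_id, joint, adductor[0], edge)


def resample_polyline(points: np.ndarray, n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at `n_points` positions equally spaced in arc length.

    Returns ``(s, resampled)`` where ``s`` is normalized cumulative arc
    length in [0, 1].
    """
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.linspace(0.0, total, n_points)
    resampled = np.column_stack(
        [np.interp(targets, cum, points[:, j]) for j in range(points.shape[1])])
    return targets / total, resampled


def ma_curve(geom: MandibleGeometry, n_points: int = 100) -> MACurve:
    """Mechanical-advantage curve along the gnathal edge.

    The edge polyline is resampled at `n_points` positions equally spaced in
    arc length; at each position MA = inlever / outlever, with the outlever
    the straight-line (2D) or perpendicular-to-axis (3D) distance to the
    joint.
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    s, pts = resample_polyline(geom.edge, n_points)
    outlever = _joint_distance(geom, pts)
    zero = outlever <= 1e-300
    if np.any(zero):
        raise ValueError(
            f"{geom.specimen_id}: zero outlever (edge point on the joint) at "
            f"s = {s[zero][0]:.4f}")
    return MACurve(geom.specimen_id, s, inlever_length(geom) / outlever)


def curves_from_configs(configs: list[LandmarkConfiguration],
                        n_points: int = 100) -> list[MACurve]:
    """MA curves for a batch of role-labelled landmark configurations."""
    return [ma_curve(lever_geometry_from_landmarks(c), n_points=n_points)
            for c in configs]


def ma_from_curve_table(path) -> list[MACurve]:
    """Read MA curves from a CSV table with columns specimen_id, s, ma.

    Rows are sorted by ``s`` per specimen; ``s`` is rescaled to [0, 1] when
    given on another range.  Duplicated positions within a specimen are an
    error.
    """
    df = pd.read_csv(path)
    missing = {"specimen_id", "s", "ma"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for spec_id, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("s", kind="stable")
        s = grp["s"].to_numpy(dtype=float)
        if np.any(np.diff(s) == 0):
            dup = s[:-1][np.diff(s) == 0][0]
            raise ValueError(f"{spec_id}: duplicated s position {dup}")
        if s[0] != 0.0 or s[-1] != 1.0:
            s = (s - s[0]) / (s[-1] - s[0])
        curves.append(MACurve(str(spec_id), s, grp["ma"].to_numpy(dtype=float)))
    return curves


def curves_to_table(curves: list[MACurve], path=None) -> pd.DataFrame:
    """Serialize MA curves to a long-format table (specimen_id, s, ma)."""
    df = pd.concat(
        [pd.DataFrame({"specimen_id": c.specimen_id, "s": c.s, "ma": c.ma})
         for c in curves], ignore_index=True)
    if path is not None:
        df.to_csv(path, index=False)
    return df
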