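"""Landmark configurations, Procrustes superimposition and composite shapes.

A mandible specimen is represented as an ordered, labelled set of 2D or 3D
landmarks (:class:`LandmarkConfiguration`).  Several configurations sharing
one label set can be superimposed by generalized Procrustes analysis (GPA):
each shape is translated to its centroid, rescaled to unit centroid size and
rotated onto the running mean shape until the summed squared Procrustes
distance stabilises.  The mean of several aligned fossil fragments is the
composite fossil mandible representation used downstream as a single
terminal unit.

Scaling is always to unit centroid size: the downstream statistic
(mechanical advantage) is a dimensionless lever ratio, so only shape is
retained.  Reflections are never applied silently inside the alignment —
mirroring a mandible flips the chirality of its lever geometry — and must be
requested explicitly through :func:`reflect_to_reference`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

logger = logging.getLogger("gnathomech")

#: Semantic roles a landmark may carry.
VALID_ROLES = frozenset(
    {"condyle_anterior", "condyle_posterior", "adductor_attachment", "edge_point"}
)
VALID_SIDES = frozenset({"left", "right"})


class TPSParseError(ValueError):
    """Raised when a TPS file cannot be parsed; carries the offending line."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class LandmarkConfiguration:
    """Ordered labelled landmarks of one mandible specimen.

    Parameters
    ----------
    specimen_id
        Unique specimen identifier.
    labels
        One label per landmark, unique within the configuration.
    coords
        Array of shape ``(k, d)`` with ``k >= 3`` finite points, ``d`` 2 or 3.
        Units are arbitrary (pixels or mm); alignment removes scale.
    side
        ``"left"``, ``"right"`` or ``None`` when unknown.
    role_labels
        Partial map label -> semantic role (condyle_anterior,
        condyle_posterior, adductor_attachment, edge_point).
    """

    specimen_id: str
    labels: list[str]
    coords: np.ndarray
    side: str | None = None
    role_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError(
                f"{self.specimen_id}: coords must be (k, d) with d in {{2, 3}}, "
                f"got shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 3:
            raise ValueError(f"{self.specimen_id}: need at least 3 landmarks")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError(f"{self.specimen_id}: {len(self.labels)} labels for "
                             f"{self.coords.shape[0]} points")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"{self.specimen_id}: duplicate landmark labels")
        if self.side is not None and self.side not in VALID_SIDES:
            raise ValueError(f"{self.specimen_id}: unknown side {self.side!r}")
        bad_roles = set(self.role_labels.values()) - VALID_ROLES
        if bad_roles:
            raise ValueError(f"{self.specimen_id}: unknown roles {sorted(bad_roles)}")
        unknown = set(self.role_labels) - set(self.labels)
        if unknown:
            raise ValueError(
                f"{self.specimen_id}: roles assigned to unknown labels {sorted(unknown)}"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def ndim(self) -> int:
        return self.coords.shape[1]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def centroid_size(self) -> float:
        """Square root of summed squared deviations from the centroid."""
        return float(np.linalg.norm(self.coords - self.centroid))

    def points_with_role(self, role: str) -> np.ndarray:
        """Coordinates of landmarks carrying `role`, in stored order."""
        idx = [i for i, lab in enumerate(self.labels) if self.role_labels.get(lab) == role]
        return self.coords[idx]

    def with_coords(self, coords: np.ndarray, **changes) -> "LandmarkConfiguration":
        return replace(self, coords=np.asarray(coords, dtype=float), **changes)


@dataclass
class AlignedShapeSet:
    """Result of a generalized Procrustes alignment."""

    configurations: list[LandmarkConfiguration]
    mean_shape: LandmarkConfiguration
    centroid_sizes: dict[str, float]
    procrustes_distances: dict[str, float]
    n_iterations: int
    ss_history: list[float]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_tps(path) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file.

    Supports ``LM=`` (2D) and ``LM3=`` (3D) records, with optional ``ID=``,
    ``IMAGE=`` and ``SCALE=`` keys; ``SCALE`` multiplies the coordinates.
    Unknown keys are ignored with a logged warning.  Labels are generated as
    ``p000, p001, ...`` so that records of equal length share a label set.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    configs: list[LandmarkConfiguration] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        upper = line.upper()
        if upper.startswith("LM3="):
            dim, count_str = 3, line[4:]
        elif upper.startswith("LM="):
            dim, count_str = 2, line[3:]
        else:
            raise TPSParseError(f"expected LM=/LM3= record, got {line!r}", i + 1)
        try:
            k = int(count_str)
        except ValueError:
            raise TPSParseError(f"malformed landmark count {line!r}", i + 1) from None
        i += 1
        pts = []
        while i < n_lines and len(pts) < k:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if "=" in row and not _looks_numeric(row):
                break  # next key or record: record is short
            vals = row.split()
            if len(vals) != dim:
                raise TPSParseError(
                    f"expected {dim} coordinates, got {len(vals)}", i + 1)
            try:
                pts.append([float(v) for v in vals])
            except ValueError:
                raise TPSParseError(f"non-numeric coordinate row {row!r}", i + 1) from None
            i += 1
        if len(pts) != k:
            raise TPSParseError(
                f"record declares {k} landmarks but contains {len(pts)}", i)
        # trailing key=value lines
        spec_id, scale = None, None
        while i < n_lines:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if row.upper().startswith(("LM=", "LM3=")):
                break
            if "=" not in row:
                raise TPSParseError(f"unexpected line {row!r}", i + 1)
            key, _, value = row.partition("=")
            key = key.strip().upper()
            if key == "ID":
                spec_id = value.strip()
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError:
                    raise TPSParseError(f"malformed SCALE {value!r}", i + 1) from None
            elif key == "IMAGE":
                pass
            else:
                logger.warning("read_tps: ignoring unknown TPS key %r", key)
            i += 1
        coords = np.asarray(pts, dtype=float)
        if scale is not None:
            coords = coords * scale
        if spec_id is None:
            spec_id = f"tps_{len(configs)}"
        labels = [f"p{j:03d}" for j in range(k)]
        configs.append(LandmarkConfiguration(spec_id, labels, coords))
    return configs


def _looks_numeric(row: str) -> bool:
    try:
        [float(v) for v in row.split()]
        return True
    except ValueError:
        return False


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    """Write configurations as a TPS file (LM= for 2D, LM3= for 3D)."""
    with open(path, "w") as fh:
        for cfg in configs:
            key = "LM3" if cfg.ndim == 3 else "LM"
            fh.write(f"{key}={cfg.k}\n")
            for row in cfg.coords:
                fh.write(" ".join(format(v, ".12g") for v in row) + "\n")
            fh.write(f"ID={cfg.specimen_id}\n")


def read_landmarks_csv(path) -> list[LandmarkConfiguration]:
    """Read a long-format landmark table.

    Columns: ``specimen_id, label, x, y[, z][, role][, side]``.  Row order
    within a specimen defines landmark order.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"specimen_id", "label", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_z = "z" in df.columns and df["z"].notna().all()
    coord_cols = ["x", "y", "z"] if has_z else ["x", "y"]
    configs = []
    for spec_id, grp in df.groupby("specimen_id", sort=False):
        labels = [str(v) for v in grp["label"]]
        coords = grp[coord_cols].to_numpy(dtype=float)
        roles = {}
        if "role" in grp.columns:
            for lab, role in zip(labels, grp["role"]):
                if isinstance(role, str) and role:
                    roles[lab] = role
        side = None
        if "side" in grp.columns:
            sides = {s for s in grp["side"] if isinstance(s, str) and s}
            if len(sides) > 1:
                raise ValueError(f"{spec_id}: inconsistent side labels {sorted(sides)}")
            side = sides.pop() if sides else None
        configs.append(LandmarkConfiguration(str(spec_id), labels, coords,
                                             side=side, role_labels=roles))
    return configs


def write_landmarks_csv(configs: list[LandmarkConfiguration], path) -> None:
    """Write configurations as a long-format landmark table (inverse of read)."""
    import pandas as pd

    rows = []
    for cfg in configs:
        for lab, pt in zip(cfg.labels, cfg.coords):
            row = {"specimen_id": cfg.specimen_id, "label": lab,
                   "x": pt[0], "y": pt[1]}
            if cfg.ndim == 3:
                row["z"] = pt[2]
            row["role"] = cfg.role_labels.get(lab, "")
            row["side"] = cfg.side or ""
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reflection
# ---------------------------------------------------------------------------

def reflect_to_reference(config: LandmarkConfiguration,
                         reference_side: str) -> LandmarkConfiguration:
    """Mirror `config` onto `reference_side` by negating the first axis.

    Identity when the configuration is already on the reference side.
    Applying the operation twice returns the original configuration.
    """
    if reference_side not in VALID_SIDES:
        raise ValueError(f"unknown reference side {reference_side!r}")
    if config.side is None:
        raise ValueError(f"{config.specimen_id}: side unknown, cannot reflect")
    if config.side == reference_side:
        return config
    coords = config.coords.copy()
    coords[:, 0] = -coords[:, 0]
    return config.with_coords(coords, side=reference_side)


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

def _normalize(coords: np.ndarray, specimen_id: str) -> tuple[np.ndarray, float]:
    """Center to the origin and rescale to unit centroid size."""
    centered = coords - coords.mean(axis=0)
    size = float(np.linalg.norm(centered))
    if size <= 0.0:
        raise ValueError(
            f"{specimen_id}: degenerate configuration (zero centroid size)")
    return centered / size, size


def _optimal_rotation(x: np.ndarray, target: np.ndarray,
                      allow_reflection: bool) -> np.ndarray:
    """Orthogonal matrix R minimising ||x R - target||_F.

    With ``allow_reflection=False`` the solution is constrained to a proper
    rotation (det +1) by flipping the smallest singular direction.
    """
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


class GeneralizedProcrustes(BaseEstimator):
    """Generalized Procrustes alignment of labelled landmark configurations.

    Iteratively translates every configuration to its centroid, rescales to
    unit centroid size, rotates each onto the current mean shape, and updates
    the mean (itself renormalized to unit centroid size) until the summed
    squared Procrustes distance changes by less than `tol`.

    Parameters
    ----------
    allow_reflection : bool, default False
        Permit improper rotations in the fit.  Off by default: mirroring
        flips the chirality of mandibular lever geometry and must be an
        explicit, recorded decision (see :func:`reflect_to_reference`).
    tol : float, default 1e-10
        Convergence tolerance on the summed squared Procrustes distance.
    max_iter : int, default 100

    Attributes
    ----------
    mean_shape_ : LandmarkConfiguration
        Consensus shape, unit centroid size, specimen_id ``"mean"``.
    aligned_ : list of LandmarkConfiguration
        Input configurations after superimposition, in input order.
    centroid_sizes_ : dict
        Original centroid size per specimen.
    procrustes_distances_ : dict
        Distance of each aligned configuration to the mean.
    n_iter_ : int
    ss_history_ : list of float
        Summed squared distance to the mean after each iteration
        (non-increasing).
    """

    def __init__(self, allow_reflection: bool = False, tol: float = 1e-10,
                 max_iter: int = 100):
        self.allow_reflection = allow_reflection
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: list[LandmarkConfiguration], y=None):
        configs = list(X)
        if len(configs) < 2:
            raise ValueError("GPA needs at least 2 configurations")
        ref_labels = configs[0].labels
        for cfg in configs[1:]:
            if cfg.labels != ref_labels:
                raise ValueError(
                    f"{cfg.specimen_id}: label set differs from "
                    f"{configs[0].specimen_id}; joint alignment requires an "
                    f"identical ordered label set")
            if cfg.ndim != configs[0].ndim:
                raise ValueError("configurations mix 2D and 3D coordinates")

        sizes, arrays = {}, []
        for cfg in configs:
            arr, size = _normalize(cfg.coords, cfg.specimen_id)
            sizes[cfg.specimen_id] = size
            arrays.append(arr)

        reference = arrays[0].copy()
        mean = arrays[0].copy()
        ss_prev = np.inf
        history: list[float] = []
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            arrays = [a @ _optimal_rotation(a, mean, self.allow_reflection)
                      for a in arrays]
            new_mean = np.mean(arrays, axis=0)
            new_mean, _ = _normalize(new_mean, "mean")
            mean = new_mean
            ss = float(sum(np.sum((a - mean) ** 2) for a in arrays))
            history.append(ss)
            if abs(ss_prev - ss) < self.tol:
                break
            ss_prev = ss

        # Gauge fix: the superimposition is defined only up to a global
        # rotation; orient the solution so the mean best aligns with the
        # first input configuration.  This keeps the mean of identical
        # inputs equal to the (normalized) input and makes re-alignment of
        # an already-aligned set an exact identity.
        canon = _optimal_rotation(mean, reference, self.allow_reflection)
        mean = mean @ canon
        arrays = [a @ canon for a in arrays]

        self.n_iter_ = n_iter
        self.ss_history_ = history
        self.mean_shape_ = configs[0].with_coords(
            mean, specimen_id="mean", side=None)
        self.aligned_ = [cfg.with_coords(arr)
                         for cfg, arr in zip(configs, arrays)]
        self.centroid_sizes_ = sizes
        self.procrustes_distances_ = {
            cfg.specimen_id: float(np.linalg.norm(arr - mean))
            for cfg, arr in zip(configs, arrays)}
        return self

    def transform(self, X: list[LandmarkConfiguration]) -> list[LandmarkConfiguration]:
        """Align new configurations to the fitted mean shape."""
        if not hasattr(self, "mean_shape_"):
            raise ValueError("GeneralizedProcrustes is not fitted")
        out = []
        mean = self.mean_shape_.coords
        for cfg in X:
            arr, _ = _normalize(cfg.coords, cfg.specimen_id)
            arr = arr @ _optimal_rotation(arr, mean, self.allow_reflection)
            out.append(cfg.with_coords(arr))
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).aligned_


def generalized_procrustes(configs: list[LandmarkConfiguration],
                           allow_reflection: bool = False,
                           tol: float = 1e-10,
                           max_iter: int = 100) -> AlignedShapeSet:
    """Functional wrapper around :class:`GeneralizedProcrustes`."""
    est = GeneralizedProcrustes(allow_reflection=allow_reflection, tol=tol,
                                max_iter=max_iter).fit(configs)
    return AlignedShapeSet(
        configurations=est.aligned_,
        mean_shape=est.mean_shape_,
        centroid_sizes=est.centroid_sizes_,
        procrustes_distances=est.procrustes_distances_,
        n_iterations=est.n_iter_,
        ss_history=est.ss_history_,
    )


def procrustes_distance(a: LandmarkConfiguration, b: LandmarkConfiguration,
                        allow_reflection: bool = False) -> float:
    """Two-shape Procrustes distance after optimal superimposition.

    Both shapes are centred and scaled to unit centroid size; `a` is rotated
    onto `b` by the orthogonal Procrustes solution.
    """
    x, _ = _normalize(a.coords, a.specimen_id)
    y, _ = _normalize(b.coords, b.specimen_id)
    r = _optimal_rotation(x, y, allow_reflection)
    return float(np.linalg.norm(x @ r - y))


def composite_representation(configs: list[LandmarkConfiguration],
                             specimen_id: str = "CFMR",
                             allow_reflection: bool = False,
                             ) -> LandmarkConfiguration:
    """Mean shape of several aligned fossil fragments (the composite mandible).

    All fragments must share an identical ordered label set, including role
    labels, which the composite retains so that lever geometry can be derived
    from it.  Fragments of opposite sides must be reflected onto a common
    reference side beforehand.
    """
    if len(configs) < 2:
        raise ValueError("composite representation needs at least 2 configurations")
    ref = configs[0]
    for cfg in configs[1:]:
        if set(cfg.labels) != set(ref.labels):
            diff = sorted(set(cfg.labels) ^ set(ref.labels))
            raise ValueError(
                f"label sets differ between {ref.specimen_id} and "
                f"{cfg.specimen_id}; symmetric difference: {diff}")
        if cfg.labels != ref.labels:
            raise ValueError(
                f"{cfg.specimen_id}: labels ordered differently from {ref.specimen_id}")
    aligned = generalized_procrustes(configs, allow_reflection=allow_reflection)
    mean = aligned.mean_shape
    return mean.with_coords(mean.coords, specimen_id=specimen_id,
                            role_labels=dict(ref.role_labels))
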