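"""3D osteocyte-lacuna morphometrics and 2D mineralization robustness.

Lacuna candidates come in as binary or probability volumes (the output of
any upstream pixel classifier); objects are extracted by 26-connected
component labeling, filtered by volume and by the requirement that their
centroid lies inside the bone mask, and each surviving object gets a full
morphometric record: voxel volume, moment-fitted ellipsoid semi-axes and
major axis, sphericity, orientation relative to the centrum center,
nearest-neighbour distance and distance to the bone surface.

The ellipsoid fit uses second moments: for a solid ellipsoid the
covariance eigenvalues are a²/5, b²/5, c²/5, so semi-axis i = √(5 λᵢ)
exactly; this is robust for small voxelized objects.  Sphericity is
π^(1/3)·(6V)^(2/3)/A with V = (4/3)πabc and A the Knud Thomsen surface
area approximation (p = 1.6075), which is exact (=1) for a sphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import Volume

logger = logging.getLogger("spinemetrics")

_THOMSEN_P = 1.6075


@dataclass
class SegmentedObjects:
    """Connected lacuna candidates after size and inside-bone filtering."""

    label_volume: np.ndarray  # int labels 1..M, 0 background
    bone_mask: np.ndarray  # bool
    voxel_size_um: tuple[float, float, float]
    n_objects: int
    threshold: float
    size_bounds_um3: tuple[float, float]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))


@dataclass
class LacunaRecord:
    """Morphometrics of one lacuna."""

    id: int
    centroid_um: np.ndarray  # (z, y, x)
    volume_um3: float
    semi_axes_um: tuple[float, float, float]  # a >= b >= c
    major_axis: np.ndarray  # unit vector, sign-normalized
    sphericity: float
    orientation_deg: Optional[float] = None
    nn_distance_um: Optional[float] = None
    surface_distance_um: Optional[float] = None
    degenerate: bool = False


@dataclass
class LacunarProfile:
    records: list[LacunaRecord]
    cells_per_um3: float
    bone_volume_um3: float
    smallest_quartile_mean_um3: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "id": r.id,
                    "z_um": r.centroid_um[0],
                    "y_um": r.centroid_um[1],
                    "x_um": r.centroid_um[2],
                    "volume_um3": r.volume_um3,
                    "a_um": r.semi_axes_um[0],
                    "b_um": r.semi_axes_um[1],
                    "c_um": r.semi_axes_um[2],
                    "axis_z": r.major_axis[0],
                    "axis_y": r.major_axis[1],
                    "axis_x": r.major_axis[2],
                    "sphericity": r.sphericity,
                    "orientation_deg": r.orientation_deg,
                    "nn_distance_um": r.nn_distance_um,
                    "surface_distance_um": r.surface_distance_um,
                    "degenerate": r.degenerate,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class MineralizationSlice:
    percent_per_roi: np.ndarray  # four corner ROIs
    mean_percent: float
    threshold: float
    roi_side_px: int


# ---------------------------------------------------------------------------


def segment_lacunae(
    cells: Volume,
    bone_mask: Volume,
    threshold: float = 0.5,
    size_bounds_um3: tuple[float, float] = (5.0, 5000.0),
    connectivity: int = 26,
) -> SegmentedObjects:
    """Binarize, label 26-connected components, apply the volume filter and
    discard objects whose centroid falls outside the bone mask."""
    if cells.data.shape != bone_mask.data.shape:
        raise ValueError(
            f"shape mismatch: cells {cells.data.shape} vs bone {bone_mask.data.shape}"
        )
    binary = cells.data >= threshold
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labeled, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return SegmentedObjects(labeled, bone_mask.data.astype(bool),
                                cells.voxel_size_um, 0, threshold, size_bounds_um3)

    voxvol = float(np.prod(cells.voxel_size_um))
    counts = np.bincount(labeled.ravel())[1:]  # per label 1..n
    volumes = counts * voxvol
    lo, hi = size_bounds_um3
    keep = (volumes >= lo) & (volumes <= hi)

    bone = bone_mask.data.astype(bool)
    centroids = np.asarray(ndimage.center_of_mass(binary, labeled, np.arange(1, n + 1)))
    cz = np.clip(np.round(centroids).astype(int), 0, np.array(binary.shape) - 1)
    inside = bone[cz[:, 0], cz[:, 1], cz[:, 2]]
    keep &= inside

    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1:][keep] = np.arange(1, keep.sum() + 1)
    out = remap[labeled]
    logger.info(
        "segment_lacunae: %d components, %d after size filter, %d after bone filter",
        n, ((volumes >= lo) & (volumes <= hi)).sum(), keep.sum(),
    )
    return SegmentedObjects(out, bone, cells.voxel_size_um, int(keep.sum()),
                            threshold, size_bounds_um3)


def fit_ellipsoid(
    coords_um: np.ndarray,
) -> tuple[tuple[float, float, float], np.ndarray, bool]:
    """Second-moment ellipsoid fit of an object's voxel-center coordinates.

    Returns (semi-axes a>=b>=c in µm, sign-normalized major-axis unit
    vector, degenerate flag).  Degenerate (coplanar / too small) objects
    get a zero smallest axis and the flag set.
    """
    coords = np.asarray(coords_um, dtype=float)
    if coords.shape[0] < 4:
        return (0.0, 0.0, 0.0), np.array([1.0, 0.0, 0.0]), True
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    w, v = np.linalg.eigh(cov)  # ascending
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    degenerate = bool(w[-1] <= 1e-12)
    semi = tuple(float(np.sqrt(5.0 * max(x, 0.0))) for x in w)
    major = _sign_normalize(v[:, 0])
    return semi, major, degenerate


def _sign_normalize(vec: np.ndarray) -> np.ndarray:
    for comp in vec:
        if comp != 0:
            return vec if comp > 0 else -vec
    return vec


def ellipsoid_surface_area(a: float, b: float, c: float, p: float = _THOMSEN_P) -> float:
    """Knud Thomsen approximation of the ellipsoid surface area (max error
    about 1.2% at p = 1.6075); exact for a sphere."""
    return 4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


def sphericity(semi_axes: tuple[float, float, float],
               volume_um3: Optional[float] = None) -> float:
    """π^(1/3)·(6V)^(2/3) / A on the fitted ellipsoid; 1 iff a = b = c.

    By default V is the fitted ellipsoid's own volume (4/3)πabc, so the
    statistic is purely a shape measure; pass a measured volume to fold in
    voxel-counting volume instead."""
    a, b, c = semi_axes
    if min(a, b, c) <= 0:
        raise ValueError("sphericity undefined for degenerate axes")
    v = volume_um3 if volume_um3 is not None else 4.0 / 3.0 * np.pi * a * b * c
    area = ellipsoid_surface_area(a, b, c)
    return float(np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / area)


def orientation_angle(
    major_axis: np.ndarray, centroid_um: np.ndarray, centrum_center_um: np.ndarray
) -> float:
    """Angle in degrees between the lacuna's major axis and the radial
    direction from the centrum center, folded to [0°, 90°]."""
    radial = np.asarray(centroid_um, dtype=float) - np.asarray(centrum_center_um, dtype=float)
    norm = np.linalg.norm(radial)
    if norm == 0:
        raise ValueError("centroid coincides with centrum center; radial undefined")
    axis = np.asarray(major_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cosang = abs(float(np.dot(axis, radial / norm)))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def nn_distances(centroids_um: np.ndarray) -> np.ndarray:
    """Euclidean nearest-neighbour (centroid-to-centroid) distance per
    lacuna, excluding self; requires at least two lacunae."""
    pts = np.atleast_2d(np.asarray(centroids_um, dtype=float))
    if len(pts) < 2:
        raise ValueError("nearest-neighbour distances need >= 2 lacunae")
    dist, _ = cKDTree(pts).query(pts, k=2)
    return dist[:, 1]


def surface_distances(
    centroids_um: np.ndarray, bone_mask: Volume
) -> np.ndarray:
    """Shortest distance (µm) from each centroid to the bone surface.

    The surface is the layer of bone voxels 6-adjacent to background; the
    distance is the exact Euclidean distance transform of that layer's
    complement, evaluated at each centroid's voxel.
    """
    bone = bone_mask.data.astype(bool)
    if not bone.any() or bone.all():
        raise ValueError("bone mask needs both bone and background")
    interior = ndimage.binary_erosion(bone, ndimage.generate_binary_structure(3, 1),
                                      border_value=0)
    boundary = bone & ~interior
    dt = ndimage.distance_transform_edt(~boundary, sampling=bone_mask.voxel_size_um)
    vs = np.asarray(bone_mask.voxel_size_um)
    idx = np.clip(
        np.floor(np.atleast_2d(centroids_um) / vs).astype(int),
        0,
        np.array(bone.shape) - 1,
    )
    out = dt[idx[:, 0], idx[:, 1], idx[:, 2]]
    outside = ~bone[idx[:, 0], idx[:, 1], idx[:, 2]]
    if outside.any():
        logger.warning("surface_distances: %d centroids outside bone", outside.sum())
    return out


def lacunar_profile(
    objects: SegmentedObjects,
    centrum_center_um: Optional[np.ndarray] = None,
) -> LacunarProfile:
    """Assemble the per-lacuna records and the cohort summary statistics:
    lacunae per µm³ of bone and the mean volume of the smallest quartile
    (the ⌈M/4⌉ smallest lacunae)."""
    voxvol = objects.voxel_volume_um3
    bone_volume = float(objects.bone_mask.sum()) * voxvol
    m = objects.n_objects
    if m == 0:
        return LacunarProfile([], 0.0, bone_volume, None)

    vs = np.asarray(objects.voxel_size_um)
    records: list[LacunaRecord] = []
    slices = ndimage.find_objects(objects.label_volume)
    for lab in range(1, m + 1):
        sl = slices[lab - 1]
        sub = objects.label_volume[sl] == lab
        idx = np.argwhere(sub) + [s.start for s in sl]
        coords = (idx + 0.5) * vs
        semi, major, degenerate = fit_ellipsoid(coords)
        volume = len(idx) * voxvol
        sph = float("nan") if degenerate else sphericity(semi)
        centroid = coords.mean(axis=0)
        orient = None
        if centrum_center_um is not None and not degenerate:
            orient = orientation_angle(major, centroid, centrum_center_um)
        records.append(
            LacunaRecord(
                id=lab, centroid_um=centroid, volume_um3=volume,
                semi_axes_um=semi, major_axis=major, sphericity=sph,
                orientation_deg=orient, degenerate=degenerate,
            )
        )

    centroids = np.array([r.centroid_um for r in records])
    if m >= 2:
        for r, d in zip(records, nn_distances(centroids)):
            r.nn_distance_um = float(d)
    else:
        logger.warning("lacunar_profile: single lacuna; nn distance undefined")
    bone_vol_obj = Volume(objects.bone_mask.astype(np.uint8), objects.voxel_size_um)
    for r, d in zip(records, surface_distances(centroids, bone_vol_obj)):
        r.surface_distance_um = float(d)

    volumes = np.sort([r.volume_um3 for r in records])
    q = int(np.ceil(m / 4.0))
    return LacunarProfile(
        records=records,
        cells_per_um3=m / bone_volume,
        bone_volume_um3=bone_volume,
        smallest_quartile_mean_um3=float(volumes[:q].mean()),
    )


def mineralization_robustness(
    slice_2d: np.ndarray,
    threshold: float,
    roi_side_px: int,
    polarity: str = "bright",
) -> MineralizationSlice:
    """Percent mineralized area in four square ROIs anchored at the four
    corners of the centrum's bounding box on a binarized orthoslice.

    ``polarity`` selects which side of the threshold counts as mineralized
    (the published measurement counted its binarization's foreground
    pixels)."""
    img = np.asarray(slice_2d)
    if img.ndim != 2:
        raise ValueError("slice must be 2D")
    fg = img >= threshold if polarity == "bright" else img < threshold
    if not fg.any():
        return MineralizationSlice(np.zeros(4), 0.0, threshold, roi_side_px)
    rows = np.any(fg, axis=1)
    cols = np.any(fg, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    side = roi_side_px
    anchors = [(r0, c0), (r0, c1 - side + 1), (r1 - side + 1, c0), (r1 - side + 1, c1 - side + 1)]
    percents = []
    for ar, ac in anchors:
        ar0, ac0 = max(0, ar), max(0, ac)
        ar1, ac1 = min(img.shape[0], ar + side), min(img.shape[1], ac + side)
        if (ar1 - ar0, ac1 - ac0) != (side, side):
            logger.warning("mineralization ROI clipped to image bounds")
        roi = fg[ar0:ar1, ac0:ac1]
        percents.append(100.0 * roi.sum() / roi.size)
    percents = np.asarray(percents)
    return MineralizationSlice(percents, float(percents.mean()), threshold, roi_side_px)


def coefficient_of_variation(values: np.ndarray) -> float:
    """CV in percent across repeated slice measurements."""
    values = np.asarray(values, dtype=float)
    return float(100.0 * values.std(ddof=1) / values.mean())
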