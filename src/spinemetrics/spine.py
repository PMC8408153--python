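"""Automated vertebral-centra segmentation and relative-density statistics.

The chain mirrors the published protocol: downsample the reconstruction by
0.5, keep the brightest 0.7% of voxels as a sparse quadruplet cloud
(coordinates + intensity), strip the head by its higher point density, fit
a smoothing B-spline through the transverse intensity-weighted centroids,
project every point onto the curve to build a 1D axial density profile,
find the intervertebral spacings as profile minima, seed labels in the
core of each inter-boundary segment, and propagate them with a
deterministic k-nearest-neighbour label-spreading pass (k = 12).  A
two-point hydroxyapatite phantom calibration (0.25 / 0.75 g·cm⁻³ CaHA)
maps mean grayscales to tissue mineral density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, signal
from scipy.spatial import cKDTree

from .io import Volume

logger = logging.getLogger("spinemetrics")


class DegenerateInputError(ValueError):
    """Raised when an input has no usable structure (e.g. constant volume)."""


class FitError(RuntimeError):
    """Raised when the spine axis cannot be fitted."""


class CalibrationError(ValueError):
    """Raised for unusable phantom calibration values."""


# ---------------------------------------------------------------------------
# Containers


@dataclass
class SparseVoxelCloud:
    """Thresholded bone voxels as (z, y, x, intensity) quadruplets in µm."""

    coords_um: np.ndarray  # (N, 3) voxel centers, (z, y, x)
    intensity: np.ndarray  # (N,)
    voxel_size_um: tuple[float, float, float]
    indices: Optional[np.ndarray] = None  # (N, 3) source voxel indices

    def __len__(self) -> int:
        return len(self.intensity)

    def subset(self, keep: np.ndarray) -> "SparseVoxelCloud":
        return SparseVoxelCloud(
            self.coords_um[keep],
            self.intensity[keep],
            self.voxel_size_um,
            None if self.indices is None else self.indices[keep],
        )


@dataclass
class SpineAxis:
    """Smooth spine centerline with an arc-length parameterization."""

    tck: tuple
    polyline: np.ndarray  # (P, 3) fine discretization, (z, y, x) µm
    arc_um: np.ndarray  # (P,) cumulative arc length from the anterior end
    smoothing: float

    @property
    def arc_length_um(self) -> float:
        return float(self.arc_um[-1])

    def project(self, coords_um: np.ndarray) -> np.ndarray:
        """Arc-length position of the nearest curve point, per input point."""
        _, idx = cKDTree(self.polyline).query(np.atleast_2d(coords_um))
        return self.arc_um[idx]


@dataclass
class AxialDensityProfile:
    """Summed cloud intensity per arc-length bin along the spine axis."""

    s_um: np.ndarray  # bin centers
    density: np.ndarray  # summed intensity per bin
    bin_width_um: float


@dataclass
class CentrumLabeling:
    labels: np.ndarray  # per-point, 1..N
    boundaries: np.ndarray  # arc-length positions of intervertebral spacings
    n_centra: int


@dataclass
class CentrumStats:
    per_centrum: pd.DataFrame  # label, mean_gray, relative_density, n_points
    within_sample_sd: float
    reference_mean: float


@dataclass
class DensityCalibration:
    """Two-point affine map from grayscale to mineral density (g·cm⁻³ CaHA)."""

    gray_lo: float
    gray_hi: float
    density_lo: float = 0.25
    density_hi: float = 0.75

    def __post_init__(self) -> None:
        if not self.gray_hi > self.gray_lo:
            raise CalibrationError("gray_hi must exceed gray_lo")

    @property
    def slope(self) -> float:
        return (self.density_hi - self.density_lo) / (self.gray_hi - self.gray_lo)

    @property
    def intercept(self) -> float:
        return self.density_lo - self.slope * self.gray_lo

    def map(self, gray: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(gray, dtype=float) + self.intercept


# ---------------------------------------------------------------------------
# Operations


def downsample(vol: Volume, factor: float) -> Volume:
    """Local-mean downsampling; output dims are dim * factor, voxel size
    scaled by 1/factor.  ``factor=1`` is the identity."""
    if not 0 < factor <= 1:
        raise ValueError(f"downsample factor must be in (0, 1], got {factor}")
    if factor == 1:
        return Volume(vol.data.copy(), vol.voxel_size_um)
    inv = 1.0 / factor
    new_voxel = tuple(v / factor for v in vol.voxel_size_um)
    if abs(inv - round(inv)) < 1e-9:
        b = int(round(inv))
        trimmed = vol.data[
            : vol.data.shape[0] // b * b,
            : vol.data.shape[1] // b * b,
            : vol.data.shape[2] // b * b,
        ]
        nz, ny, nx = (s // b for s in trimmed.shape)
        out = trimmed.reshape(nz, b, ny, b, nx, b).mean(axis=(1, 3, 5))
    else:
        from scipy import ndimage

        new_shape = tuple(max(1, round(s * factor)) for s in vol.data.shape)
        zoom = [ns / s for ns, s in zip(new_shape, vol.data.shape)]
        out = ndimage.zoom(vol.data.astype(float), zoom, order=1, mode="nearest",
                           grid_mode=True)
    return Volume(out, new_voxel)


def threshold_to_cloud(vol: Volume, retained_fraction: float) -> SparseVoxelCloud:
    """Keep exactly ``ceil(retained_fraction * n_voxels)`` brightest voxels
    (ties broken by raster order) as a sparse cloud in physical µm."""
    if not 0 < retained_fraction < 1:
        raise ValueError(f"retained_fraction must be in (0, 1), got {retained_fraction}")
    flat = vol.data.ravel()
    if flat.max() == flat.min():
        raise DegenerateInputError("constant volume has no orderable brightest set")
    k = math.ceil(retained_fraction * flat.size)
    order = np.argsort(-flat, kind="stable")  # stable => ties in raster order
    keep = np.sort(order[:k])  # raster-ordered output, deterministic
    idx = np.column_stack(np.unravel_index(keep, vol.data.shape))
    coords = (idx + 0.5) * np.asarray(vol.voxel_size_um)
    logger.info("threshold_to_cloud: retained %d/%d voxels", k, flat.size)
    return SparseVoxelCloud(coords, flat[keep].astype(float), vol.voxel_size_um, idx)


def remove_head(
    cloud: SparseVoxelCloud,
    ratio: float = 2.0,
    bin_um: Optional[float] = None,
    terminal_window: Optional[int] = None,
) -> SparseVoxelCloud:
    """Strip a terminal high-point-density run (the head) from the cloud.

    Points are binned along the first principal axis; contiguous runs of
    bins whose count exceeds ``ratio`` times the median occupied-bin count
    and that start within ``terminal_window`` bins of either end are
    removed, together with everything between them and that end.  The cut
    then advances through the blob's sparse taper (bins below half the
    median count, at most 3 bins) so no detached remnant survives.  If no
    dense terminal run exists the cloud is returned unchanged.
    """
    coords = cloud.coords_um
    proj, _ = _principal_projection(coords)
    if bin_um is None:
        bin_um = 2.0 * float(np.mean(cloud.voxel_size_um))
    span = proj.max() - proj.min()
    n = int(np.ceil(span / bin_um))
    if n < 3:
        return cloud
    edges = np.linspace(proj.min(), proj.max(), n + 1)  # equal-width bins
    counts, _ = np.histogram(proj, bins=edges)
    occupied = counts[counts > 0]
    med = np.median(occupied)
    dense = counts > ratio * med
    n_bins = len(counts)
    if terminal_window is None:
        # a terminal blob's sparse taper may occupy several bins before its
        # dense core starts; "terminal" therefore means the outer 15%
        terminal_window = max(3, int(np.ceil(0.15 * n_bins)))

    drop_upto = -1  # inclusive bin index from the low end
    drop_from = n_bins  # inclusive bin index to the high end
    runs = _contiguous_runs(dense)
    for start, stop in runs:  # stop is inclusive
        if stop - start + 1 < 2:
            continue  # a blob spans several bins; lone fat bins are aliasing
        if start <= terminal_window:
            drop_upto = max(drop_upto, stop)
        if stop >= n_bins - 1 - terminal_window:
            drop_from = min(drop_from, start)
    if drop_upto < 0 and drop_from >= n_bins:
        logger.info("remove_head: no dense terminal run found; cloud unchanged")
        return cloud

    # The blob tapers from its dense core down to zero at the head-spine
    # clearance; advance the cut to the first empty bin so no remnant of
    # the taper survives (bounded look-ahead, else fall back to the run).
    cap = int(np.ceil(150.0 / bin_um))
    if drop_upto >= 0:
        for j in range(drop_upto + 1, min(drop_upto + 1 + cap, n_bins)):
            if counts[j] == 0:
                drop_upto = j
                break
    if drop_from < n_bins:
        for j in range(drop_from - 1, max(drop_from - 1 - cap, -1), -1):
            if counts[j] == 0:
                drop_from = j
                break

    bin_idx = np.clip(np.digitize(proj, edges) - 1, 0, n_bins - 1)
    keep = (bin_idx > drop_upto) & (bin_idx < drop_from)
    logger.info("remove_head: removed %d of %d points", (~keep).sum(), len(cloud))
    return cloud.subset(keep)


def _principal_projection(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    if axis[0] < 0:  # orient along increasing z (anteroposterior)
        axis = -axis
    return centered @ axis, axis


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def fit_spine_axis(
    cloud: SparseVoxelCloud,
    smoothing: Optional[float] = None,
    bin_um: Optional[float] = None,
) -> SpineAxis:
    """Fit a smoothing cubic B-spline through the per-bin intensity-weighted
    transverse centroids of the cloud (the operational reading of the
    vertebrae's transverse symmetry).

    ``smoothing`` is the spline's residual budget per centroid in µm²; the
    default of one voxel squared keeps a straight phantom straight while
    still following a gentle lateral bow.
    """
    coords = cloud.coords_um
    proj, _ = _principal_projection(coords)
    if bin_um is None:
        bin_um = 4.0 * float(np.mean(cloud.voxel_size_um))
    n_ax = max(2, int(np.ceil((proj.max() - proj.min()) / bin_um)))
    edges = np.linspace(proj.min(), proj.max(), n_ax + 1)
    bin_idx = np.clip(np.digitize(proj, edges) - 1, 0, len(edges) - 2)
    w = cloud.intensity
    centroids = []
    positions = []
    for b in range(len(edges) - 1):
        sel = bin_idx == b
        if not sel.any():
            continue
        wsum = w[sel].sum()
        centroids.append((coords[sel] * w[sel, None]).sum(axis=0) / wsum)
        positions.append((proj[sel] * w[sel]).sum() / wsum)
    if len(centroids) < 10:
        raise FitError(f"need >= 10 occupied axial bins, got {len(centroids)}")
    centroids = np.asarray(centroids)
    positions = np.asarray(positions)
    order = np.argsort(positions)
    centroids = centroids[order]
    positions = positions[order]

    voxel = float(np.mean(cloud.voxel_size_um))
    if smoothing is None:
        smoothing = voxel**2
    s_total = smoothing * len(centroids)
    u = (positions - positions[0]) / (positions[-1] - positions[0])
    u = np.maximum.accumulate(u + np.arange(len(u)) * 1e-12)  # strictly increasing
    tck, _ = interpolate.splprep(list(centroids.T), u=u, s=s_total, k=3)

    # Extend slightly beyond the first/last centroid so the axis covers the
    # cloud's full axial span (points past the ends would otherwise clamp
    # onto the terminal arc position and pile into one profile bin).
    span = positions[-1] - positions[0]
    pad = 1.5 * bin_um / span
    n_fine = max(64, int(4 * span / voxel))
    uf = np.linspace(-pad, 1 + pad, n_fine)
    polyline = np.column_stack(interpolate.splev(uf, tck))
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return SpineAxis(tck=tck, polyline=polyline, arc_um=arc, smoothing=smoothing)


def project_profile(
    cloud: SparseVoxelCloud, axis: SpineAxis, bin_width_um: float
) -> AxialDensityProfile:
    """Curvilinear 1D density profile: every point contributes its intensity
    to the arc-length bin of its nearest curve point.  Total profile density
    equals total cloud intensity exactly."""
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    s = axis.project(cloud.coords_um)
    n_bins = max(1, int(np.floor(s.max() / bin_width_um)) + 1)
    bin_idx = np.minimum((s / bin_width_um).astype(int), n_bins - 1)
    density = np.bincount(bin_idx, weights=cloud.intensity, minlength=n_bins)
    centers = (np.arange(n_bins) + 0.5) * bin_width_um
    return AxialDensityProfile(centers, density, bin_width_um)


def find_spacings(
    profile: AxialDensityProfile,
    prominence: float = 0.1,
    min_separation_um: float = 0.0,
    depth_ratio: float = 0.35,
) -> np.ndarray:
    """Intervertebral spacings as local minima of the density profile.

    Candidate minima need a prominence of at least ``prominence`` times the
    profile's dynamic range and a mutual separation of
    ``min_separation_um``.  A candidate is accepted only if its density is
    below ``depth_ratio`` times its lower flanking maximum: a true spacing
    contains essentially background, while the waist of an hourglass
    centrum only dips to roughly half of its endplate peaks, whatever that
    centrum's absolute density.  Returns strictly increasing arc-length
    positions (possibly empty).
    """
    if len(profile.density) < 3:
        raise ValueError("profile must have >= 3 bins")
    d = profile.density
    rng_ = d.max() - d.min()
    if rng_ == 0:
        return np.array([])
    inverted = d.max() - d
    distance = max(1, int(round(min_separation_um / profile.bin_width_um)))
    peaks, props = signal.find_peaks(
        inverted, prominence=prominence * rng_, distance=distance
    )
    flank = np.minimum(d[props["left_bases"]], d[props["right_bases"]])
    keep = d[peaks] <= depth_ratio * flank
    return profile.s_um[peaks[keep]]


def label_centra(
    cloud: SparseVoxelCloud,
    axis: SpineAxis,
    boundaries: Sequence[float],
    core_fraction: float = 0.5,
    k: int = 12,
) -> CentrumLabeling:
    """Seed the core of each inter-boundary segment and propagate labels to
    every remaining point by deterministic k-nearest-neighbour voting.

    Each pass labels all unlabeled points that have at least one labeled
    point among their k nearest neighbours, by majority vote; ties go to
    the label with the smaller mean neighbour distance, then to the lower
    label.  Every point ends up labeled.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 < core_fraction <= 1:
        raise ValueError("core_fraction must be in (0, 1]")
    n_pts = len(cloud)
    boundaries = np.asarray(sorted(boundaries), dtype=float)
    if len(boundaries) == 0:
        return CentrumLabeling(np.ones(n_pts, dtype=int), boundaries, 1)

    s = axis.project(cloud.coords_um)
    seg = np.searchsorted(boundaries, s)  # 0..N-1
    n_centra = len(boundaries) + 1
    edges = np.concatenate([[s.min()], boundaries, [s.max() + 1e-9]])
    labels = np.zeros(n_pts, dtype=int)
    for j in range(n_centra):
        lo, hi = edges[j], edges[j + 1]
        center = 0.5 * (lo + hi)
        half = 0.5 * core_fraction * (hi - lo)
        seed = (seg == j) & (np.abs(s - center) <= half)
        labels[seed] = j + 1
    if not labels.any():  # pathological: seed at least the segment medians
        for j in range(n_centra):
            sel = np.flatnonzero(seg == j)
            if len(sel):
                labels[sel[np.argsort(s[sel])[len(sel) // 2]]] = j + 1

    if (labels == 0).any():
        kq = min(k, n_pts - 1)
        dist, nbr = cKDTree(cloud.coords_um).query(cloud.coords_um, k=kq + 1)
        dist, nbr = dist[:, 1:], nbr[:, 1:]  # drop self
        while (labels == 0).any():
            unl = np.flatnonzero(labels == 0)
            nbr_lab = labels[nbr[unl]]  # (U, k)
            has = (nbr_lab > 0).any(axis=1)
            if not has.any():
                # disconnected remainder: nearest labeled point wins
                lab_idx = np.flatnonzero(labels > 0)
                _, nearest = cKDTree(cloud.coords_um[lab_idx]).query(
                    cloud.coords_um[unl]
                )
                labels[unl] = labels[lab_idx[nearest]]
                break
            front = unl[has]
            fl = labels[nbr[front]]
            fd = dist[front]
            labeled_mask = fl > 0
            counts = np.zeros((len(front), n_centra + 1))
            dsum = np.zeros((len(front), n_centra + 1))
            rows = np.repeat(np.arange(len(front)), labeled_mask.sum(axis=1))
            cols = fl[labeled_mask]
            np.add.at(counts, (rows, cols), 1)
            np.add.at(dsum, (rows, cols), fd[labeled_mask])
            counts[:, 0] = -1  # label 0 never wins
            best = counts.max(axis=1, keepdims=True)
            tied = counts == best
            mean_d = np.where(tied, dsum / np.maximum(counts, 1), np.inf)
            # among tied labels: smallest mean neighbour distance, then lowest label
            order_key = mean_d + np.arange(n_centra + 1) * 1e-12
            labels[front] = np.argmin(order_key, axis=1)
    return CentrumLabeling(labels, boundaries, n_centra)


def centrum_stats(
    labeling: CentrumLabeling,
    cloud: SparseVoxelCloud,
    reference_group_mean: Optional[float] = None,
) -> CentrumStats:
    """Per-centrum mean intensity and relative density, plus the
    within-sample SD of centrum means (the mineral-heterogeneity readout).

    Without an explicit reference, densities are scaled by the sample's own
    average so the mean relative density is 1 (the published plots scale by
    the 3-year group's average)."""
    rows = []
    for lab in range(1, labeling.n_centra + 1):
        sel = labeling.labels == lab
        if not sel.any():
            logger.warning("centrum_stats: centrum %d is empty; excluded", lab)
            continue
        rows.append(
            {"label": lab, "mean_gray": float(cloud.intensity[sel].mean()),
             "n_points": int(sel.sum())}
        )
    df = pd.DataFrame(rows)
    ref = reference_group_mean if reference_group_mean is not None else df["mean_gray"].mean()
    df["relative_density"] = df["mean_gray"] / ref
    sd = float(df["mean_gray"].std(ddof=1)) if len(df) > 1 else 0.0
    return CentrumStats(per_centrum=df, within_sample_sd=sd, reference_mean=float(ref))


def calibrate_tmd(
    gray_values: np.ndarray | float, calib: DensityCalibration
) -> np.ndarray | float:
    """Map grayscales to tissue mineral density through the two-point
    phantom calibration; extrapolation beyond the anchors is allowed but
    logged."""
    gray = np.asarray(gray_values, dtype=float)
    if np.any(gray < calib.gray_lo) or np.any(gray > calib.gray_hi):
        logger.info("calibrate_tmd: extrapolating outside phantom anchors")
    out = calib.map(gray)
    return float(out) if np.isscalar(gray_values) else out
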