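"""Seeded phantom generators with known ground truth.

Three generators stand in for the imaging data the analysis pipeline was
designed for:

* :func:`make_spine_phantom` — a curved spine of hourglass-profiled
  vertebral centra with per-centrum densities, an optional dense head blob,
  and additive Gaussian noise; truth carries per-voxel labels, per-centrum
  mean densities and the arc-length positions of the intervertebral gaps.
* :func:`make_lacunae_phantom` — a bone slab containing non-overlapping
  voxelized ellipsoidal lacunae with known semi-axes, orientations and
  analytic volumes.
* :func:`make_radiograph_cohort` — 1D vertebral intensity profiles of a
  7-vertebra segment for a cohort of fish, with a tunable monotone coupling
  between bone density and morphological deformation, per-fish exposure
  gain, calibration-phantom patches, and a noise-free undeformed standard.

Every generator is a pure function of its spec: identical specs give
bit-identical output (randomness flows through one ``numpy`` generator
seeded from the spec).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import LabelVolume, Volume
from .radiograph import RadiographProfile


class SpecError(ValueError):
    """Raised when a phantom spec violates its invariants (names the field)."""


class PlacementError(RuntimeError):
    """Raised when lacunae cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# Spine phantom


@dataclass
class SpinePhantomSpec:
    """Geometry and intensity parameters of the spine phantom.

    Defaults describe a desk-scale adult-zebrafish spine: 20 centra of
    54 µm at 6 µm voxels with 36 µm intervertebral gaps, a gentle lateral
    bow, and a dense head blob at the anterior end.  ``axis_curvature`` is
    the lateral bow amplitude in units of the centrum radius.
    """

    n_vertebrae: int = 20
    centrum_length_um: float = 54.0
    gap_um: float = 36.0
    centrum_radius_um: float = 60.0
    hourglass_depth: float = 0.35
    axis_curvature: float = 0.5
    centrum_densities: Optional[Sequence[float]] = None
    head: bool = True
    head_length_um: float = 144.0
    noise_sd: float = 0.0
    voxel_size_um: float = 6.0
    transverse_extent_um: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 2:
            raise SpecError("n_vertebrae must be >= 2")
        if self.centrum_densities is None:
            self.centrum_densities = [1000.0] * self.n_vertebrae
        self.centrum_densities = [float(d) for d in self.centrum_densities]
        if len(self.centrum_densities) != self.n_vertebrae:
            raise SpecError("centrum_densities must have length n_vertebrae")
        if any(d <= 0 for d in self.centrum_densities):
            raise SpecError("centrum_densities must all be > 0")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        for name in ("centrum_length_um", "gap_um", "centrum_radius_um", "voxel_size_um"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be > 0")
        if not 0 <= self.hourglass_depth < 1:
            raise SpecError("hourglass_depth must be in [0, 1)")


@dataclass
class SpinePhantom:
    """A spine phantom volume with its full ground truth."""

    volume: Volume
    truth_labels: LabelVolume
    truth_densities: list[float]
    truth_boundaries: np.ndarray  # arc-length (µm) of gap centers, origin at first centrum
    truth_axis: np.ndarray  # (K, 3) generating curve, (z,y,x) µm

    @property
    def bone_fraction(self) -> float:
        """Fraction of voxels occupied by bone or head — the natural
        ``retained_fraction`` when thresholding this phantom."""
        return float((self.truth_labels.data != 0).mean())


def make_spine_phantom(spec: SpinePhantomSpec) -> SpinePhantom:
    """Voxelize the spine phantom described by ``spec``.

    Each centrum is a solid of revolution around a smooth laterally-bowed
    axis whose radius narrows mid-centrum and flares at the endplates
    (hourglass); centra are separated by background-intensity gaps so the
    1D axial density profile has true minima at the intervertebral
    spacings.  The head blob is a solid ellipsoid brighter than any
    centrum, giving it a higher thresholded point density than the spine.
    """
    vs = spec.voxel_size_um
    L, G, R = spec.centrum_length_um, spec.gap_um, spec.centrum_radius_um
    n = spec.n_vertebrae
    margin = 3 * vs
    head_span = (spec.head_length_um + 2 * G) if spec.head else 0.0
    z0 = margin + head_span  # start of first centrum (µm)
    spine_len = n * L + (n - 1) * G
    z_extent = z0 + spine_len + margin

    amplitude = spec.axis_curvature * R
    tight = 2 * (R + amplitude + margin)
    extent_t = max(tight, spec.transverse_extent_um or 0.0)

    nz = int(np.ceil(z_extent / vs))
    ny = nx = int(np.ceil(extent_t / vs))
    cy = ny * vs / 2.0
    cx = nx * vs / 2.0

    zc = (np.arange(nz) + 0.5) * vs
    yc = (np.arange(ny) + 0.5) * vs
    xc = (np.arange(nx) + 0.5) * vs
    axis_x = cx + amplitude * np.sin(np.pi * zc / z_extent)

    vol = np.zeros((nz, ny, nx), dtype=np.float64)
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    yy = yc[:, None] - cy
    pitch = L + G

    for iz in range(nz):
        u = zc[iz] - z0
        if u < 0 or u >= spine_len:
            continue
        j = int(u // pitch)
        w = u - j * pitch
        if w >= L or j >= n:
            continue  # intervertebral gap
        t = w / L
        r = R * (1.0 - spec.hourglass_depth * np.sin(np.pi * t))
        mask = (yy**2 + (xc[None, :] - axis_x[iz]) ** 2) <= r**2
        vol[iz][mask] = spec.centrum_densities[j]
        labels[iz][mask] = j + 1

    if spec.head:
        hz = margin + spec.head_length_um / 2.0
        az = spec.head_length_um / 2.0
        at = 1.5 * R
        head_intensity = 2.2 * max(spec.centrum_densities)
        iz0 = max(0, int((hz - az) / vs) - 1)
        iz1 = min(nz, int((hz + az) / vs) + 2)
        zz = zc[iz0:iz1]
        hx = cx + amplitude * np.sin(np.pi * zz / z_extent)
        q = (
            ((zz[:, None, None] - hz) / az) ** 2
            + ((yc[None, :, None] - cy) / at) ** 2
            + ((xc[None, None, :] - hx[:, None, None]) / at) ** 2
        )
        inside = q <= 1.0
        vol[iz0:iz1][inside] = head_intensity
        labels[iz0:iz1][inside] = -1

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape)

    # Arc length along the generating curve, origin at the first centrum start.
    z_fine = np.linspace(0.0, z_extent, 4 * nz)
    x_fine = cx + amplitude * np.sin(np.pi * z_fine / z_extent)
    ds = np.hypot(np.diff(z_fine), np.diff(x_fine))
    s_fine = np.concatenate([[0.0], np.cumsum(ds)])
    s_of = lambda z: np.interp(z, z_fine, s_fine)
    gap_centers_z = z0 + np.arange(1, n) * pitch - G / 2.0
    boundaries = s_of(gap_centers_z) - s_of(z0)
    truth_axis = np.column_stack([z_fine, np.full_like(z_fine, cy), x_fine])

    return SpinePhantom(
        volume=Volume(vol, (vs, vs, vs)),
        truth_labels=LabelVolume(labels),
        truth_densities=list(spec.centrum_densities),
        truth_boundaries=np.asarray(boundaries),
        truth_axis=truth_axis,
    )


# ---------------------------------------------------------------------------
# Lacunae phantom


@dataclass
class LacunaePhantomSpec:
    """Bone slab with ellipsoidal lacunae of known axes and orientation.

    ``semi_axis_ranges_um`` gives per-axis (a, b, c) uniform sampling
    ranges with a >= b >= c; ``min_separation_um`` must exceed twice the
    largest possible semi-axis so placed lacunae cannot overlap.
    ``centrum_center`` is the (z,y,x) µm reference point used downstream
    for the orientation angle.
    """

    n_lacunae: int = 8
    semi_axis_ranges_um: tuple[tuple[float, float], ...] = ((13.0, 16.0), (10.0, 12.0), (8.0, 10.0))
    orientation_mode: str = "random"
    slab_dims_um: tuple[float, float, float] = (140.0, 130.0, 130.0)
    centrum_center: tuple[float, float, float] = (70.0, 65.0, -400.0)
    min_separation_um: float = 36.0
    voxel_size_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lacunae < 1:
            raise SpecError("n_lacunae must be >= 1")
        if self.orientation_mode not in ("aligned", "random"):
            raise SpecError("orientation_mode must be 'aligned' or 'random'")
        ranges = self.semi_axis_ranges_um
        if len(ranges) != 3 or any(lo <= 0 or hi < lo for lo, hi in ranges):
            raise SpecError("semi_axis_ranges_um must be three positive (lo, hi) pairs")
        a_max = max(hi for _, hi in ranges)
        if self.min_separation_um <= 2 * a_max:
            raise SpecError("min_separation_um must exceed twice the largest semi-axis")
        if self.voxel_size_um <= 0:
            raise SpecError("voxel_size_um must be > 0")


@dataclass
class LacunaePhantom:
    bone_mask: Volume
    lacuna_mask: Volume
    truth_table: pd.DataFrame  # id, centroid, semi-axes, major axis, analytic volume


_BONE_MARGIN_VOX = 4  # background border so the slab has a real surface


def make_lacunae_phantom(spec: LacunaePhantomSpec) -> LacunaePhantom:
    """Place and voxelize non-overlapping ellipsoidal lacunae in a bone slab."""
    rng = np.random.default_rng(spec.seed)
    vs = spec.voxel_size_um
    dims = np.array([int(np.ceil(d / vs)) for d in spec.slab_dims_um])
    bone = np.zeros(tuple(dims), dtype=bool)
    m = _BONE_MARGIN_VOX
    bone[m:-m, m:-m, m:-m] = True

    ranges = spec.semi_axis_ranges_um
    a_hi = max(hi for _, hi in ranges)
    buffer_um = a_hi + (m + 2) * vs
    lo_um = np.full(3, buffer_um)
    hi_um = dims * vs - buffer_um
    if np.any(hi_um <= lo_um):
        raise SpecError("slab_dims_um too small for the requested lacuna sizes")

    centers: list[np.ndarray] = []
    max_tries = 200 * spec.n_lacunae
    tries = 0
    while len(centers) < spec.n_lacunae:
        if tries >= max_tries:
            raise PlacementError(
                f"placed {len(centers)}/{spec.n_lacunae} lacunae in {max_tries} tries"
            )
        tries += 1
        cand = rng.uniform(lo_um, hi_um)
        if all(np.linalg.norm(cand - c) >= spec.min_separation_um for c in centers):
            centers.append(cand)

    rows = []
    lacunae = np.zeros_like(bone)
    idx_um = [(np.arange(d) + 0.5) * vs for d in dims]
    for i, center in enumerate(centers):
        axes = np.sort([rng.uniform(lo, hi) for lo, hi in ranges])[::-1]
        if spec.orientation_mode == "aligned":
            frame = np.eye(3)  # major axis along z (anteroposterior)
        else:
            frame = _random_rotation(rng)
        _voxelize_ellipsoid(lacunae, idx_um, center, axes, frame)
        major = _sign_normalize(frame[:, 0])
        rows.append(
            {
                "id": i + 1,
                "z_um": center[0],
                "y_um": center[1],
                "x_um": center[2],
                "a_um": axes[0],
                "b_um": axes[1],
                "c_um": axes[2],
                "axis_z": major[0],
                "axis_y": major[1],
                "axis_x": major[2],
                "volume_um3": 4.0 / 3.0 * np.pi * axes[0] * axes[1] * axes[2],
            }
        )

    if not (lacunae <= bone).all():  # pragma: no cover - construction guarantees this
        raise PlacementError("lacuna mask escaped the bone slab")
    return LacunaePhantom(
        bone_mask=Volume(bone.astype(np.uint8), (vs, vs, vs)),
        lacuna_mask=Volume(lacunae.astype(np.uint8), (vs, vs, vs)),
        truth_table=pd.DataFrame(rows),
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (columns = body axes in lab frame)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q


def _sign_normalize(v: np.ndarray) -> np.ndarray:
    for comp in v:
        if comp != 0:
            return v if comp > 0 else -v
    return v


def _voxelize_ellipsoid(
    out: np.ndarray,
    idx_um: list[np.ndarray],
    center: np.ndarray,
    axes: np.ndarray,
    frame: np.ndarray,
) -> None:
    vs = idx_um[0][1] - idx_um[0][0] if len(idx_um[0]) > 1 else 1.0
    lo = [max(0, int((center[d] - axes[0] - vs) / vs)) for d in range(3)]
    hi = [min(out.shape[d], int((center[d] + axes[0] + vs) / vs) + 1) for d in range(3)]
    sub = np.meshgrid(
        idx_um[0][lo[0] : hi[0]], idx_um[1][lo[1] : hi[1]], idx_um[2][lo[2] : hi[2]],
        indexing="ij",
    )
    rel = np.stack([g - c for g, c in zip(sub, center)], axis=-1)
    body = rel @ frame  # lab -> body coordinates
    q = (body / axes) ** 2
    inside = q.sum(axis=-1) <= 1.0
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= inside


# ---------------------------------------------------------------------------
# Radiograph cohort


@dataclass
class RadiographCohortSpec:
    """Cohort of 7-vertebra radiograph intensity profiles.

    Each fish carries a density scalar ``b_i`` (relative to
    ``baseline_density``); the monotone coupling maps the density excess
    ``|b_i - baseline|`` to a deformation amplitude
    ``d_i = coupling_strength * |b_i - baseline| / baseline``.  The
    deformation emulates endplate sclerosis: a fraction
    ``shoulder_frac * d_i`` of each vertebral peak's mass is redistributed
    symmetrically onto two sub-peaks 1.5 peak-widths toward the two
    endplates (mineral concentrating at the endplates, thinning
    mid-centrum), and every peak is additionally shifted along a fixed
    per-vertebra pattern scaled by ``jitter_frac * d_i``.  The symmetric
    split cannot be undone by any global lag, so the lag-maximized
    cross-correlation decays linearly in ``d_i``, while the
    inter-vertebral valleys rise only uniformly (absorbed by the linear
    background fit) and profile BMD keeps tracking ``b_i``.
    Profiles carry a per-fish exposure gain and offset that the
    calibration-phantom patches (true densities 0.25 / 0.75 g·cm⁻³ CaHA)
    allow downstream rescaling to undo.
    """

    n_fish: int = 40
    n_vertebrae_in_profile: int = 7
    samples_per_vertebra: int = 40
    baseline_density: float = 1.0
    density_values: Optional[Sequence[float]] = None
    density_range: tuple[float, float] = (1.0, 1.28)
    coupling_strength: float = 6.0
    peak_sigma_frac: float = 0.12
    shoulder_frac: float = 0.5
    jitter_frac: float = 0.05
    peak_amplitude: float = 1.0
    noise_sd: float = 0.02
    background_slope: float = 2e-4
    background_offset: float = 0.02
    gain_range: tuple[float, float] = (0.8, 1.2)
    phantom_true_densities: tuple[float, float] = (0.25, 0.75)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 3:
            raise SpecError("n_fish must be >= 3")
        if self.n_vertebrae_in_profile < 2:
            raise SpecError("n_vertebrae_in_profile must be >= 2")
        if self.baseline_density <= 0:
            raise SpecError("baseline_density must be > 0")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.coupling_strength < 0:
            raise SpecError("coupling_strength must be >= 0")
        if self.density_values is not None and len(self.density_values) != self.n_fish:
            raise SpecError("density_values must have length n_fish")
        lo, hi = self.phantom_true_densities
        if not lo < hi:
            raise SpecError("phantom_true_densities must be increasing")


# Fixed per-vertebra shift pattern (zero mean so a global lag cannot undo it).
_SHIFT_PATTERN = np.array([0.8, -0.2, 0.5, -0.7, 0.3, -0.9, 0.1, -0.4, 0.6, -0.3])


def _vertebra_template(
    s: np.ndarray, period: float, n_vertebrae: int, sigma0: float,
    widen: float = 0.0, shifts: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Sum of per-vertebra Gaussian peaks; ``widen`` scales each width by
    (1 + widen) with peak area preserved, ``shifts`` displaces centers."""
    sigma = sigma0 * (1.0 + widen)
    amp = sigma0 / sigma  # area-preserving
    out = np.zeros_like(s, dtype=float)
    for j in range(n_vertebrae):
        c = (j + 0.5) * period
        if shifts is not None:
            c = c + shifts[j]
        out += amp * np.exp(-((s - c) ** 2) / (2.0 * sigma**2))
    return out


def make_radiograph_cohort(
    spec: RadiographCohortSpec,
) -> tuple[list[RadiographProfile], RadiographProfile, pd.DataFrame]:
    """Generate the cohort, the noise-free undeformed standard profile, and
    the truth table of per-fish (b_i, d_i, gain)."""
    rng = np.random.default_rng(spec.seed)
    nv = spec.n_vertebrae_in_profile
    period = float(spec.samples_per_vertebra)
    npts = int(nv * period)
    s = np.arange(npts, dtype=float)
    sigma0 = spec.peak_sigma_frac * period
    p_lo, p_hi = spec.phantom_true_densities
    amp_scale = spec.peak_amplitude  # template peak amplitude on the reference scale

    if spec.density_values is not None:
        b = np.asarray([float(v) for v in spec.density_values])
    else:
        b = rng.uniform(*spec.density_range, size=spec.n_fish)
    gains = rng.uniform(*spec.gain_range, size=spec.n_fish)
    offsets = rng.uniform(0.0, 0.1, size=spec.n_fish)

    base = _vertebra_template(s, period, nv, sigma0)
    background = spec.background_offset + spec.background_slope * s
    standard = RadiographProfile(
        fish_id="standard",
        s_px=s.copy(),
        intensity=spec.baseline_density * amp_scale * base + background,
        width_px=40,
        n_vertebrae=nv,
        phantom_means=(p_lo, p_hi),
    )

    pattern = np.resize(_SHIFT_PATTERN, nv)
    profiles: list[RadiographProfile] = []
    rows = []
    for i in range(spec.n_fish):
        d = spec.coupling_strength * abs(b[i] - spec.baseline_density) / spec.baseline_density
        shifts = spec.jitter_frac * period * d * pattern
        mix = min(0.85, spec.shoulder_frac * d)
        core = _vertebra_template(s, period, nv, sigma0, shifts=shifts)
        left = _vertebra_template(s, period, nv, sigma0, shifts=shifts - 1.5 * sigma0)
        right = _vertebra_template(s, period, nv, sigma0, shifts=shifts + 1.5 * sigma0)
        warped = (1.0 - mix) * core + 0.5 * mix * (left + right)
        clean = b[i] * amp_scale * warped + background
        raw = gains[i] * clean + offsets[i]
        if spec.noise_sd > 0:
            raw = raw + rng.normal(0.0, spec.noise_sd, npts)
        measured = (gains[i] * p_lo + offsets[i], gains[i] * p_hi + offsets[i])
        profiles.append(
            RadiographProfile(
                fish_id=f"fish_{i:03d}",
                s_px=s.copy(),
                intensity=raw,
                width_px=40,
                n_vertebrae=nv,
                phantom_means=measured,
            )
        )
        rows.append({"fish_id": f"fish_{i:03d}", "b": b[i], "d": d, "gain": gains[i]})

    return profiles, standard, pd.DataFrame(rows)


def make_radiograph_image(profile: np.ndarray, height: int = 64) -> np.ndarray:
    """A 2D image whose every row equals ``profile`` — the round-trip
    fixture for :func:`spinemetrics.radiograph.extract_profile`."""
    return np.tile(np.asarray(profile, dtype=float), (height, 1))
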