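"""Synthetic needle-core biopsy phantoms and oblique light-sheet acquisition.

A phantom is a ground-truthed 3D nuclear-fluorescence volume emulating a
~1-mm-wide needle core containing prostatic glands of three architectures:
benign (two concentric layers of nuclei around an empty lumen), pattern-3
cancer (a single small ring) and pattern-4 cancer (fused glands sharing a
merged lumen).  The acquisition simulator renders the phantom into the raw
oblique 2D frame stack a 45-degree stage-scanning light-sheet microscope
would record, including depth attenuation and shot/read noise.

Coordinate conventions (applies package-wide):

* phantom / volume grids are indexed ``(z, y, x)``; ``x`` is the stage-scan
  axis, ``y`` lateral, ``z`` depth from the tissue surface, increasing into
  the tissue; 0-based, half-open;
* all physical quantities are micrometres unless a name says otherwise;
* every stochastic operation takes an explicit integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage

__all__ = [
    "GLAND_KINDS",
    "CANCER_KINDS",
    "GlandSpec",
    "BiopsyPhantom",
    "AcquisitionGeometry",
    "NoiseParams",
    "RawStack",
    "generate_phantom",
    "simulate_acquisition",
    "save_phantom",
    "load_phantom",
    "save_stack",
    "load_stack",
]

GLAND_KINDS = ("benign", "gleason3", "gleason4")
CANCER_KINDS = ("gleason3", "gleason4")

#: label-volume codes
LABEL_BACKGROUND = 0
LABEL_BENIGN = 1
LABEL_CANCER = 2


@dataclass(frozen=True)
class GlandSpec:
    """Geometry and class of a single gland within a phantom.

    ``center`` is ``(x, y, z)`` in micrometres.  ``depth_range`` is the
    closed z-interval the gland occupies.
    """

    center: tuple[float, float, float]
    kind: str
    lumen_radius: float
    n_layers: int
    nucleus_radius: float
    fused_partners: tuple[int, ...] = ()
    depth_range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in GLAND_KINDS:
            raise ValueError(f"unknown gland kind {self.kind!r}")
        if not (self.lumen_radius > self.nucleus_radius > 0):
            raise ValueError(
                "require lumen_radius > nucleus_radius > 0, got "
                f"{self.lumen_radius} and {self.nucleus_radius}"
            )
        if self.kind == "benign" and self.n_layers != 2:
            raise ValueError("benign glands have exactly 2 nuclear layers")
        if self.kind in CANCER_KINDS and self.n_layers != 1:
            raise ValueError("cancer glands have exactly 1 nuclear layer")
        if self.kind == "gleason4" and not self.fused_partners:
            raise ValueError("gleason4 glands must name at least one fused partner")
        if self.kind != "gleason4" and self.fused_partners:
            raise ValueError("only gleason4 glands may be fused")

    @property
    def is_cancer(self) -> bool:
        return self.kind in CANCER_KINDS

    @property
    def outer_radius(self) -> float:
        """Radius enclosing the outermost nuclear layer."""
        return self.lumen_radius + 2.0 * self.n_layers * self.nucleus_radius


@dataclass
class BiopsyPhantom:
    """Ground-truth nuclear-intensity volume plus per-gland truth labels.

    ``volume`` and ``labels`` are ``(z, y, x)`` grids on an isotropic
    ``voxel_pitch``; ``extent`` is ``(length_x, width_y, thickness_z)``.
    """

    volume: np.ndarray
    labels: np.ndarray
    glands: list[GlandSpec]
    truth_label: str
    voxel_pitch: float
    extent: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        if self.volume.ndim != 3 or self.volume.size == 0:
            raise ValueError("phantom volume must be a non-empty 3D grid")
        if self.volume.shape != self.labels.shape:
            raise ValueError("volume and labels must share a shape")
        if self.voxel_pitch <= 0:
            raise ValueError("voxel pitch must be positive")
        if np.any(self.volume < 0):
            raise ValueError("phantom intensity must be non-negative")
        expected = "cancer" if any(g.is_cancer for g in self.glands) else "benign"
        if self.truth_label != expected:
            raise ValueError(
                f"truth_label {self.truth_label!r} inconsistent with gland kinds"
            )

    @property
    def length_um(self) -> float:
        return self.extent[0]

    @property
    def width_um(self) -> float:
        return self.extent[1]

    @property
    def thickness_um(self) -> float:
        return self.extent[2]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Optical sampling constants of the oblique stage-scanning microscope.

    Defaults reproduce the published configuration: 0.44 um/pixel native
    sampling, 2x camera binning, a 45-degree sheet, a 2048x256 ROI and an
    ~80-um vertical field of view.  ``frame_interval`` of ``None`` means
    "matched": the stage step equals the binned pitch projected onto the
    scan axis (``binned_pitch * cos(sheet_angle)``).
    """

    native_pixel_pitch: float = 0.44
    binning: int = 2
    sheet_angle: float = 45.0
    frame_interval: float | None = None
    roi_rows: int = 256
    roi_cols: int = 2048
    vertical_fov: float = 80.0

    def __post_init__(self) -> None:
        if self.native_pixel_pitch <= 0:
            raise ValueError("native pixel pitch must be positive")
        if self.binning < 1 or int(self.binning) != self.binning:
            raise ValueError("binning must be a positive integer")
        if not (0.0 < self.sheet_angle < 90.0):
            raise ValueError("sheet angle must lie strictly between 0 and 90 degrees")
        if self.frame_interval is not None and self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")
        if self.roi_rows > self.roi_cols:
            raise ValueError("ROI rows must not exceed ROI columns")

    @property
    def binned_pitch(self) -> float:
        """In-plane sampling pitch after binning (um/pixel)."""
        return self.native_pixel_pitch * self.binning

    @property
    def sheet_angle_rad(self) -> float:
        return math.radians(self.sheet_angle)

    @property
    def frame_interval_um(self) -> float:
        """Effective stage step; matched to the lateral pitch unless set."""
        if self.frame_interval is not None:
            return self.frame_interval
        return self.binned_pitch * math.cos(self.sheet_angle_rad)

    @property
    def frame_shape(self) -> tuple[int, int]:
        """Binned frame shape (rows, cols)."""
        return (self.roi_rows // self.binning, self.roi_cols // self.binning)

    @property
    def strip_width_mm(self) -> float:
        """Lateral width of one image strip in millimetres."""
        return self.frame_shape[1] * self.binned_pitch / 1000.0


@dataclass(frozen=True)
class NoiseParams:
    """Detection-noise model for the simulated camera.

    ``photon_scale`` of ``None`` disables shot noise (noiseless mode);
    otherwise the recorded value is ``Poisson(photon_scale * signal) /
    photon_scale``.  Gaussian read noise of standard deviation
    ``read_noise_sd`` is then added, and the result clipped at zero.
    ``attenuation_length_um`` is the 1/e depth of the single-exponential
    signal attenuation (``math.inf`` disables attenuation).
    """

    photon_scale: float | None = 50.0
    read_noise_sd: float = 2.0
    attenuation_length_um: float = 100.0

    def __post_init__(self) -> None:
        if self.photon_scale is not None and self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive or None")
        if self.read_noise_sd < 0:
            raise ValueError("read noise SD must be non-negative")
        if self.attenuation_length_um <= 0:
            raise ValueError("attenuation length must be positive")


NOISELESS = NoiseParams(photon_scale=None, read_noise_sd=0.0,
                        attenuation_length_um=math.inf)


@dataclass
class RawStack:
    """Ordered oblique 2D frames with their acquisition geometry.

    ``frames[k]`` was recorded with the stage at ``k * frame_interval``;
    within a frame, row ``r`` runs along the 45-degree oblique axis and
    column ``c`` is lateral.
    """

    frames: np.ndarray
    geometry: AcquisitionGeometry
    noise_params: NoiseParams
    seed: int

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("stack needs at least one 2D frame")
        if self.frames.shape[1:] != self.geometry.frame_shape:
            raise ValueError(
                f"frame shape {self.frames.shape[1:]} does not match geometry "
                f"{self.geometry.frame_shape}"
            )
        if np.any(self.frames < 0):
            raise ValueError("frame pixel values must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# phantom generation


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly equidistant unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    zc = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - zc * zc))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), zc], axis=1)


def _paint_ellipsoid(grid: np.ndarray, labels: np.ndarray, center_um, semi_axes_um,
                     pitch: float, value: float, label: int) -> None:
    """Set voxels inside an axis-aligned ellipsoid to max(current, value)."""
    cx, cy, cz = center_um
    ax, ay, az = semi_axes_um
    nz, ny, nx = grid.shape
    x0 = max(0, int(math.floor((cx - ax) / pitch)))
    x1 = min(nx, int(math.ceil((cx + ax) / pitch)) + 1)
    y0 = max(0, int(math.floor((cy - ay) / pitch)))
    y1 = min(ny, int(math.ceil((cy + ay) / pitch)) + 1)
    z0 = max(0, int(math.floor((cz - az) / pitch)))
    z1 = min(nz, int(math.ceil((cz + az) / pitch)) + 1)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1) * pitch,
        np.arange(y0, y1) * pitch,
        np.arange(x0, x1) * pitch,
        indexing="ij",
    )
    inside = (((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
              + ((zz - cz) / az) ** 2) <= 1.0
    sub = grid[z0:z1, y0:y1, x0:x1]
    sub[inside] = np.maximum(sub[inside], value)
    lsub = labels[z0:z1, y0:y1, x0:x1]
    lsub[inside] = np.maximum(lsub[inside], label)


def _carve_sphere(grid: np.ndarray, center_um, radius: float, pitch: float,
                  value: float) -> None:
    """Set voxels inside a sphere to ``value`` (lumen carving)."""
    cx, cy, cz = center_um
    nz, ny, nx = grid.shape
    x0 = max(0, int(math.floor((cx - radius) / pitch)))
    x1 = min(nx, int(math.ceil((cx + radius) / pitch)) + 1)
    y0 = max(0, int(math.floor((cy - radius) / pitch)))
    y1 = min(ny, int(math.ceil((cy + radius) / pitch)) + 1)
    z0 = max(0, int(math.floor((cz - radius) / pitch)))
    z1 = min(nz, int(math.ceil((cz + radius) / pitch)) + 1)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1) * pitch,
        np.arange(y0, y1) * pitch,
        np.arange(x0, x1) * pitch,
        indexing="ij",
    )
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= radius ** 2
    grid[z0:z1, y0:y1, x0:x1][inside] = value


def _render_gland(grid, labels, gland: GlandSpec, pitch: float, peak: float,
                  rng: np.random.Generator) -> None:
    label = LABEL_CANCER if gland.is_cancer else LABEL_BENIGN
    rn = gland.nucleus_radius
    for layer in range(gland.n_layers):
        ring_r = gland.lumen_radius + (2 * layer + 1) * rn
        n_nuclei = max(6, int(4.0 * math.pi * ring_r ** 2 / (2.2 * rn) ** 2))
        dirs = _fibonacci_sphere(n_nuclei)
        jitter = rng.normal(scale=0.15 * rn, size=dirs.shape)
        for d, j in zip(dirs, jitter):
            pos = (
                gland.center[0] + ring_r * d[0] + j[0],
                gland.center[1] + ring_r * d[1] + j[1],
                gland.center[2] + ring_r * d[2] + j[2],
            )
            # slightly oblate nuclei: flattened along z
            _paint_ellipsoid(grid, labels, pos, (rn, rn, 0.8 * rn), pitch,
                             peak, label)


def generate_phantom(
    length_um: float,
    width_um: float,
    thickness_um: float,
    gland_mix: dict[str, int],
    voxel_pitch_um: float,
    seed: int,
    *,
    lumen_radius_um: float = 12.0,
    cancer_lumen_radius_um: float | None = None,
    nucleus_radius_um: float = 3.0,
    background_fraction: float = 0.05,
    nuclear_peak: float = 1000.0,
    cancer_depth_range_um: tuple[float, float] | None = None,
) -> BiopsyPhantom:
    """Generate a seeded synthetic biopsy phantom.

    Parameters
    ----------
    length_um, width_um, thickness_um
        Physical extent along x (scan), y (lateral) and z (depth).
    gland_mix
        Counts per gland kind, e.g. ``{"benign": 4, "gleason3": 1}``.
        Keys absent default to zero.  A single ``gleason4`` gland is
        rejected (fusion needs at least a pair).
    voxel_pitch_um
        Isotropic voxel pitch; must not exceed the nucleus radius so that
        nuclei remain resolvable.
    cancer_depth_range_um
        When given, every cancer gland is confined to this depth interval
        (used for the depth-restricted-lesion scenario).

    Returns
    -------
    BiopsyPhantom
        Deterministic for fixed arguments and seed.
    """
    if min(length_um, width_um, thickness_um) <= 0:
        raise ValueError("phantom dimensions must be positive")
    if voxel_pitch_um <= 0:
        raise ValueError("voxel pitch must be positive")
    if voxel_pitch_um > nucleus_radius_um:
        raise ValueError(
            "voxel pitch must not exceed the nucleus radius "
            f"({voxel_pitch_um} > {nucleus_radius_um})"
        )
    unknown = set(gland_mix) - set(GLAND_KINDS)
    if unknown:
        raise ValueError(f"unknown gland kinds in mix: {sorted(unknown)}")
    counts = {k: int(gland_mix.get(k, 0)) for k in GLAND_KINDS}
    if any(v < 0 for v in counts.values()):
        raise ValueError("gland counts must be non-negative")
    if counts["gleason4"] == 1:
        raise ValueError("gleason4 glands fuse in groups; need at least 2")

    shape = tuple(
        int(round(d / voxel_pitch_um))
        for d in (thickness_um, width_um, length_um)
    )
    if min(shape) < 1:
        raise ValueError("zero-size volume: extent smaller than one voxel")

    rng = np.random.default_rng(seed)
    background = background_fraction * nuclear_peak
    grid = np.full(shape, background, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.uint8)

    if cancer_lumen_radius_um is None:
        cancer_lumen_radius_um = 0.6 * lumen_radius_um

    # Build gland specs: benign, then gleason3, then gleason4 fused pairs.
    specs: list[GlandSpec] = []
    n_total = counts["benign"] + counts["gleason3"] + counts["gleason4"]
    phantom = BiopsyPhantom(
        volume=grid, labels=labels, glands=specs,
        truth_label="benign", voxel_pitch=voxel_pitch_um,
        extent=(length_um, width_um, thickness_um), seed=seed,
    )
    if n_total == 0:
        return phantom

    def depth_center(outer: float, is_cancer: bool) -> float:
        if is_cancer and cancer_depth_range_um is not None:
            lo, hi = cancer_depth_range_um
            if hi - lo < 2 * outer:
                raise ValueError(
                    f"cancer gland of radius {outer} um cannot fit in depth "
                    f"range [{lo}, {hi}] um"
                )
            return 0.5 * (lo + hi)
        return min(max(outer, thickness_um / 2.0), thickness_um - outer)

    # lay glands out along the scan axis at even spacing
    slots = np.linspace(0.0, length_um, n_total + 2)[1:-1]
    slot_iter = iter(range(n_total))

    def place(kind: str, lumen: float, n_layers: int, fused: tuple[int, ...],
              idx: int) -> GlandSpec:
        outer = lumen + 2 * n_layers * nucleus_radius_um
        cx = float(slots[idx])
        cy = width_um / 2.0 + float(rng.uniform(-0.05, 0.05)) * width_um
        cz = depth_center(outer, kind in CANCER_KINDS)
        spec = GlandSpec(
            center=(cx, cy, cz), kind=kind, lumen_radius=lumen,
            n_layers=n_layers, nucleus_radius=nucleus_radius_um,
            fused_partners=fused, depth_range=(cz - outer, cz + outer),
        )
        for name, lo, hi, c in (
            ("x", cx - outer, cx + outer, length_um),
            ("y", cy - outer, cy + outer, width_um),
            ("z", cz - outer, cz + outer, thickness_um),
        ):
            if lo < -1e-9 or hi > c + 1e-9:
                raise ValueError(
                    f"gland {idx} ({kind}) does not fit inside the phantom "
                    f"extent along {name}: needs [{lo:.1f}, {hi:.1f}] um "
                    f"within [0, {c:.1f}] um"
                )
        return spec

    for _ in range(counts["benign"]):
        specs.append(place("benign", lumen_radius_um, 2, (), next(slot_iter)))
    for _ in range(counts["gleason3"]):
        specs.append(place("gleason3", cancer_lumen_radius_um, 1, (),
                           next(slot_iter)))
    # gleason4: consecutive fused pairs; an odd trailing gland joins the
    # last pair as a three-way fusion
    g4_start = len(specs)
    n4 = counts["gleason4"]
    for j in range(n4):
        # placeholder partner for validation; rewired symmetrically below
        partner = g4_start + (j + 1 if j % 2 == 0 and j + 1 < n4 else j - 1)
        specs.append(place("gleason4", cancer_lumen_radius_um, 1, (partner,),
                           next(slot_iter)))
    # fuse in consecutive pairs; an odd trailing gland joins the last pair
    if n4:
        groups = [[g4_start + i, g4_start + i + 1]
                  for i in range(0, n4 - n4 % 2, 2)]
        if n4 % 2:
            groups[-1].append(g4_start + n4 - 1)
        for grp in groups:
            for gi in grp:
                partners = tuple(p for p in grp if p != gi)
                specs[gi] = replace(specs[gi], fused_partners=partners)
        # pull fused glands together so their lumens merge
        for grp in groups:
            anchor = specs[grp[0]]
            sep = 1.5 * anchor.lumen_radius
            for off, gi in enumerate(grp[1:], start=1):
                g = specs[gi]
                cx = anchor.center[0] + off * sep
                new_center = (cx, anchor.center[1], anchor.center[2])
                outer = g.outer_radius
                if cx + outer > length_um + 1e-9:
                    raise ValueError(
                        f"gland {gi} (gleason4) does not fit inside the "
                        "phantom extent along x after fusion"
                    )
                specs[gi] = replace(
                    g, center=new_center,
                    depth_range=(new_center[2] - outer, new_center[2] + outer),
                )

    # render: nuclei first (max-composited), lumens carved afterwards so
    # fused lumens merge into one dark cavity
    for gland in specs:
        _render_gland(grid, labels, gland, voxel_pitch_um, nuclear_peak, rng)
    for gland in specs:
        _carve_sphere(grid, gland.center, gland.lumen_radius, voxel_pitch_um,
                      0.0)

    truth = "cancer" if any(g.is_cancer for g in specs) else "benign"
    return BiopsyPhantom(
        volume=grid, labels=labels, glands=specs, truth_label=truth,
        voxel_pitch=voxel_pitch_um,
        extent=(length_um, width_um, thickness_um), seed=seed,
    )


# ---------------------------------------------------------------------------
# acquisition simulation


def simulate_acquisition(
    phantom: BiopsyPhantom,
    geometry: AcquisitionGeometry,
    noise_params: NoiseParams = NoiseParams(),
    seed: int = 0,
) -> RawStack:
    """Render a phantom into the raw oblique frame stack.

    Frame ``k``, row ``r``, column ``c`` samples the phantom by trilinear
    interpolation at::

        x = k * s + r * p * cos(theta)
        y = c * p
        z = r * p * sin(theta)

    with ``s`` the frame interval, ``p`` the binned pixel pitch and
    ``theta`` the sheet angle.  The sampled intensity is attenuated by
    ``exp(-z / attenuation_length)``, shot noise and read noise are applied
    per :class:`NoiseParams`, and values are clipped at zero.  The frame
    count covers the phantom length plus the oblique overhang of the
    deepest row.
    """
    p = geometry.binned_pitch
    theta = geometry.sheet_angle_rad
    s = geometry.frame_interval_um
    rows, cols = geometry.frame_shape

    if phantom.width_um > geometry.strip_width_mm * 1000.0 + 1e-9:
        raise ValueError(
            f"phantom width {phantom.width_um} um exceeds the "
            f"{geometry.strip_width_mm:.3f}-mm image strip"
        )
    v = phantom.voxel_pitch

    overhang = (rows - 1) * p * math.cos(theta)
    n_frames = int(math.ceil((phantom.length_um + overhang) / s)) + 1

    r = np.arange(rows, dtype=np.float64)
    c = np.arange(cols, dtype=np.float64)
    # voxel-index coordinates of each (r, c) sample, before the stage
    # offset; voxel i sits at physical position i * pitch (node-centred)
    z_idx = (r * p * math.sin(theta)) / v
    y_idx = (c * p) / v
    x_off = (r * p * math.cos(theta)) / v

    zz = np.broadcast_to(z_idx[:, None], (rows, cols))
    yy = np.broadcast_to(y_idx[None, :], (rows, cols))

    frames = np.empty((n_frames, rows, cols), dtype=np.float64)
    vol = phantom.volume
    for k in range(n_frames):
        xx = np.broadcast_to((x_off + k * s / v)[:, None], (rows, cols))
        frames[k] = ndimage.map_coordinates(
            vol, [zz, yy, xx], order=1, mode="constant", cval=0.0,
            prefilter=False,
        )

    att = noise_params.attenuation_length_um
    if math.isfinite(att):
        depth = r * p * math.sin(theta)
        frames *= np.exp(-depth / att)[None, :, None]

    rng = np.random.default_rng(seed)
    if noise_params.photon_scale is not None:
        frames = rng.poisson(noise_params.photon_scale * frames).astype(
            np.float64) / noise_params.photon_scale
    if noise_params.read_noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_params.read_noise_sd,
                                     size=frames.shape)
    np.clip(frames, 0.0, None, out=frames)

    return RawStack(frames=frames, geometry=geometry,
                    noise_params=noise_params, seed=seed)


# ---------------------------------------------------------------------------
# serialization: multi-page TIFF + YAML sidecar


def _geometry_to_dict(g: AcquisitionGeometry) -> dict:
    return {
        "native_pixel_pitch": g.native_pixel_pitch,
        "binning": g.binning,
        "sheet_angle": g.sheet_angle,
        "frame_interval": g.frame_interval,
        "roi_rows": g.roi_rows,
        "roi_cols": g.roi_cols,
        "vertical_fov": g.vertical_fov,
    }


def _noise_to_dict(n: NoiseParams) -> dict:
    att = n.attenuation_length_um
    return {
        "photon_scale": n.photon_scale,
        "read_noise_sd": n.read_noise_sd,
        "attenuation_length_um": "inf" if math.isinf(att) else att,
    }


def _noise_from_dict(d: dict) -> NoiseParams:
    att = d["attenuation_length_um"]
    return NoiseParams(
        photon_scale=d["photon_scale"],
        read_noise_sd=d["read_noise_sd"],
        attenuation_length_um=math.inf if att == "inf" else float(att),
    )


def save_stack(stack: RawStack, tiff_path: str | Path) -> Path:
    """Write frames as a multi-page TIFF plus a ``.yaml`` sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    sidecar = tiff_path.with_suffix(".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {
                "geometry": _geometry_to_dict(stack.geometry),
                "noise_params": _noise_to_dict(stack.noise_params),
                "seed": stack.seed,
            },
            fh,
        )
    return tiff_path


def load_stack(tiff_path: str | Path) -> RawStack:
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path).astype(np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    with open(tiff_path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    return RawStack(
        frames=frames,
        geometry=AcquisitionGeometry(**meta["geometry"]),
        noise_params=_noise_from_dict(meta["noise_params"]),
        seed=meta["seed"],
    )


def save_phantom(phantom: BiopsyPhantom, tiff_path: str | Path) -> Path:
    """Write intensity + label TIFFs and a YAML gland list."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, phantom.volume.astype(np.float32),
                     photometric="minisblack")
    label_path = tiff_path.with_name(tiff_path.stem + "_labels.tif")
    tifffile.imwrite(label_path, phantom.labels,
                     photometric="minisblack")
    meta = {
        "truth_label": phantom.truth_label,
        "voxel_pitch": phantom.voxel_pitch,
        "extent": list(phantom.extent),
        "seed": phantom.seed,
        "glands": [
            {
                "center": list(g.center),
                "kind": g.kind,
                "lumen_radius": g.lumen_radius,
                "n_layers": g.n_layers,
                "nucleus_radius": g.nucleus_radius,
                "fused_partners": list(g.fused_partners),
                "depth_range": list(g.depth_range),
            }
            for g in phantom.glands
        ],
    }
    with open(tiff_path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)
    return tiff_path


def load_phantom(tiff_path: str | Path) -> BiopsyPhantom:
    tiff_path = Path(tiff_path)
    volume = tifffile.imread(tiff_path).astype(np.float64)
    labels = tifffile.imread(tiff_path.with_name(tiff_path.stem + "_labels.tif"))
    with open(tiff_path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    glands = [
        GlandSpec(
            center=tuple(g["center"]), kind=g["kind"],
            lumen_radius=g["lumen_radius"], n_layers=g["n_layers"],
            nucleus_radius=g["nucleus_radius"],
            fused_partners=tuple(g["fused_partners"]),
            depth_range=tuple(g["depth_range"]),
        )
        for g in meta["glands"]
    ]
    return BiopsyPhantom(
        volume=volume, labels=labels, glands=glands,
        truth_label=meta["truth_label"], voxel_pitch=meta["voxel_pitch"],
        extent=tuple(meta["extent"]), seed=meta["seed"],
    )
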