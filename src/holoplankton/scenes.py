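"""Ground-truth particle scenes with taxon-specific silhouettes.

Every downstream stage (hologram simulation, extraction, classification,
profiling) is exercised against scenes generated here, so each particle
carries its true taxon, size ``H``, morphological parameter ``M``,
antennas flag and 3D position.

Silhouette conventions
----------------------
* Ellipse bodies for Copepoda, Copelata, Cladocera, Other, Rotifera and
  Suspension; a thin flexed strip for Chaetognatha and Phytoplankton
  chain; an irregular multi-lobe blob for Marine snow.
* Antennas are two thin anterior protrusions (length 0.3 H by default)
  attached to the body; their geometry is a declared convention of this
  package, constrained so the antenna is thinner than the body core and
  the full mask still fits the target circumscribed rectangle.
* After drawing, the mask is rescaled iteratively until its measured
  minimum-area rectangle matches the requested H (within one pixel) and
  M (within a few hundredths).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw
from skimage import morphology, transform

from .classify import TAXA
from .geometry import min_area_rect
from .optics import OpticalConfig

H_MIN_UM = 100.0   # lower bound of the measurable size range (0.1 mm)
H_MAX_UM = 28000.0  # upper bound (28 mm)


@dataclass
class TrueParticle:
    """Ground truth for one simulated particle."""

    taxon: str
    H_um: float
    M: float
    antennas: bool
    x_um: float
    y_um: float
    z_mm: float
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not H_MIN_UM <= self.H_um <= H_MAX_UM:
            raise ValueError(f"H={self.H_um} um outside [{H_MIN_UM}, {H_MAX_UM}]")
        if not 0 <= self.M <= 1:
            raise ValueError(f"M={self.M} outside [0, 1]")
        if self.taxon not in TAXA:
            raise ValueError(f"unknown taxon {self.taxon!r}")


@dataclass
class Scene:
    particles: list[TrueParticle]
    config: OpticalConfig
    depth_of_cast_m: float | None = None


@dataclass(frozen=True)
class CastSpec:
    """A vertical cast: concentration profiles sampled at constant speed.

    ``concentration_spp_m3`` maps taxon name to either a constant or a
    callable of depth (m) returning individuals per cubic metre.
    """

    concentration_spp_m3: dict
    submersion_speed_m_s: float = 0.3
    frame_rate_hz: float = 1.0
    max_depth_m: float = 10.0
    rng_seed: int = 0
    frame_cap: int = 5000

    def __post_init__(self) -> None:
        if not 0.1 <= self.submersion_speed_m_s <= 1.0:
            raise ValueError("submersion speed must lie in [0.1, 1.0] m/s")
        if not 0 < self.frame_rate_hz <= 24:
            raise ValueError("frame rate must lie in (0, 24] Hz")
        if self.max_depth_m <= 0:
            raise ValueError("max depth must be positive")


# Per-taxon generation cells: antennas flag and the (H, M) sub-ranges the
# sampler draws from.  The M range is the taxon's decision-tree cell,
# floored where needed so the silhouette stays rasterisable; the H range
# is restricted to sizes that fit the simulated sensor footprint.
TAXON_CELLS: dict[str, dict] = {
    "Chaetognatha":        dict(antennas=True,  h=(800.0, 1800.0),  m=(0.06, 0.2)),
    "Copepoda":            dict(antennas=True,  h=(250.0, 700.0),   m=(0.2, 0.5)),
    "Copelata":            dict(antennas=True,  h=(250.0, 700.0),   m=(0.5, 0.66)),
    "Cladocera":           dict(antennas=True,  h=(250.0, 600.0),   m=(0.66, 0.9)),
    "Other":               dict(antennas=True,  h=(250.0, 600.0),   m=(0.9, 1.0)),
    "Rotifera":            dict(antennas=True,  h=(120.0, 200.0),   m=(0.25, 0.9)),
    "Phytoplankton chain": dict(antennas=False, h=(300.0, 1800.0),  m=(0.06, 0.25)),
    "Marine snow":         dict(antennas=False, h=(250.0, 900.0),   m=(0.25, 0.9)),
    "Suspension":          dict(antennas=False, h=(100.0, 200.0),   m=(0.9, 1.0)),
}

_STRIP_TAXA = {"Chaetognatha", "Phytoplankton chain"}
_BLOB_TAXA = {"Marine snow"}


def _draw_body(taxon: str, h_px: float, w_px: float, rng: np.random.Generator) -> np.ndarray:
    """Binary body silhouette drawn along the column (x) axis."""
    pad = int(math.ceil(h_px * 0.45)) + 4
    rows = int(math.ceil(w_px)) + 2 * pad
    cols = int(math.ceil(h_px)) + 2 * pad
    canvas = np.zeros((rows, cols), dtype=bool)
    r0, c0 = rows / 2, cols / 2
    if taxon in _STRIP_TAXA:
        t = max(5.0, h_px / 30.0)
        t = min(t, max(w_px - 1.0, 2.0))
        amp = max((w_px - t) / 2.0, 0.0)
        s = np.linspace(0.0, 1.0, max(int(h_px * 2), 32))
        cc = c0 - h_px / 2 + s * h_px
        rr = r0 + amp * np.sin(np.pi * s + rng.uniform(-0.2, 0.2))
        for r, c in zip(rr, cc):
            rd, cd = skdraw.disk((r, c), t / 2.0, shape=canvas.shape)
            canvas[rd, cd] = True
    elif taxon in _BLOB_TAXA:
        # connected chain of overlapping lobes spanning the target box
        n_lobes = int(rng.integers(5, 9))
        xs = np.linspace(-0.42, 0.42, n_lobes) * h_px
        ys = rng.uniform(-0.18, 0.18, n_lobes) * w_px
        radii = rng.uniform(0.55, 0.85, n_lobes) * (w_px / 2.0)
        prev = None
        for x, y, rad in zip(xs, ys, radii):
            center = np.array([r0 + y, c0 + x])
            if prev is not None:  # enforce overlap with the previous lobe
                gap = np.linalg.norm(center - prev[0])
                max_gap = 0.8 * (rad + prev[1])
                if gap > max_gap:
                    center = prev[0] + (center - prev[0]) * max_gap / gap
            rd, cd = skdraw.disk(tuple(center), max(rad, 2.0), shape=canvas.shape)
            canvas[rd, cd] = True
            prev = (center, rad)
        canvas = ndimage.binary_closing(canvas, structure=morphology.disk(3))
    else:
        rr, cc = skdraw.ellipse(r0, c0, max(w_px / 2.0, 1.0), h_px / 2.0, shape=canvas.shape)
        canvas[rr, cc] = True
    return canvas


def _attach_antennas(
    canvas: np.ndarray, h_px: float, w_px: float, taxon: str, rng: np.random.Generator
) -> np.ndarray:
    """Two thin protrusions from the anterior (right) end of the body."""
    cols_on = np.where(canvas.any(axis=0))[0]
    tip_c = cols_on.max()
    rows_at_tip = np.where(canvas[:, max(tip_c - 1, 0)])[0]
    tip_r = rows_at_tip.mean() if rows_at_tip.size else canvas.shape[0] / 2

    # small bodies get relatively longer antennas so the protrusions stay
    # resolvable at the pixel scale
    length = 0.45 * h_px if h_px < 80 else 0.32 * h_px
    if taxon in _STRIP_TAXA:
        t_body = max(5.0, h_px / 30.0)
        width = max(3.0, 0.4 * t_body)
    else:
        width = max(3.0, min(h_px / 40.0, 0.2 * w_px))
    # keep the lateral excursion inside the target half-width
    max_sin = max(0.1, min(0.85, 0.8 * (w_px / 2.0) / length))
    for sign in (+1, -1):
        ang = math.asin(max_sin * rng.uniform(0.6, 1.0))
        r1 = tip_r + sign * length * math.sin(ang)
        c1 = tip_c + length * math.cos(ang)
        rr, cc = skdraw.line(
            int(round(tip_r)), int(round(tip_c)), int(round(r1)), int(round(c1))
        )
        keep = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
        line = np.zeros_like(canvas)
        line[rr[keep], cc[keep]] = True
        line = ndimage.binary_dilation(line, morphology.disk(max(1, int(round(width / 2)))))
        canvas = canvas | line
    return canvas


def make_silhouette(
    taxon: str,
    H_um: float,
    M: float,
    antennas: bool,
    pixel_pitch_um: float,
    rng_seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Binary silhouette whose circumscribed rectangle measures H x M*H.

    The composite (body plus antennas, if any) is rescaled until the
    measured minimum-area rectangle length agrees with ``H`` to about a
    pixel and the aspect ratio with ``M`` to a few hundredths.
    """
    if H_um <= 0 or H_um < 2 * pixel_pitch_um:
        raise ValueError(f"H={H_um} um is below 2 pixels at pitch {pixel_pitch_um} um")
    if not 0 <= M <= 1:
        raise ValueError("M must lie in [0, 1]")
    if M * H_um < pixel_pitch_um:
        raise ValueError("M*H below one pixel: silhouette not rasterisable")
    if rng is None:
        rng = np.random.default_rng(rng_seed)

    h_px = H_um / pixel_pitch_um
    w_px = max(M * h_px, 1.0)
    canvas = _draw_body(taxon, h_px, w_px, rng)
    if antennas:
        canvas = _attach_antennas(canvas, h_px, w_px, taxon, rng)
    canvas = ndimage.binary_fill_holes(canvas)

    for _ in range(4):
        rect = min_area_rect(canvas)
        err_len = rect.length - h_px
        err_m = rect.aspect - M
        if abs(err_len) <= 1.0 and abs(err_m) <= 0.02:
            break
        sx = h_px / max(rect.length, 1.0)
        sy = (M * h_px) / max(rect.width, 1.0)
        sy = float(np.clip(sy, 0.3, 2.5))
        sx = float(np.clip(sx, 0.3, 2.5))
        zoomed = ndimage.zoom(canvas.astype(float), (sy, sx), order=1) > 0.5
        if not zoomed.any():
            break
        canvas = zoomed
    return _crop_to_content(canvas, margin=2)


def _crop_to_content(mask: np.ndarray, margin: int = 2) -> np.ndarray:
    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    out = mask[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    return np.pad(out, margin)


def sample_particle(
    taxon: str,
    config: OpticalConfig,
    rng: np.random.Generator,
    z_range_mm: tuple[float, float] | None = None,
    margin_px: int = 6,
    rotate: bool = True,
) -> TrueParticle:
    """Draw one particle of a taxon uniformly within its generation cell."""
    cell = TAXON_CELLS[taxon]
    h = float(rng.uniform(*cell["h"]))
    m = float(rng.uniform(*cell["m"]))
    antennas = bool(cell["antennas"])
    mask = make_silhouette(taxon, h, m, antennas, config.pixel_pitch_um, rng=rng)
    if rotate:
        ang = float(rng.uniform(0.0, 180.0))
        mask = transform.rotate(
            mask.astype(float), ang, resize=True, order=0, preserve_range=True
        ) > 0.5
        mask = _crop_to_content(mask, margin=2)
    if z_range_mm is None:
        L = config.working_length_mm
        z_range_mm = (0.02 * L, 0.98 * L)
    z = float(rng.uniform(*z_range_mm))
    rows, cols = config.sensor_shape
    p = config.pixel_pitch_um
    mr, mc = mask.shape
    half_y = (rows - mr) / 2 - margin_px
    half_x = (cols - mc) / 2 - margin_px
    if half_x <= 0 or half_y <= 0:
        raise ValueError(f"{taxon} silhouette (H={h:.0f} um) does not fit the sensor")
    x = float(rng.uniform(-half_x, half_x)) * p
    y = float(rng.uniform(-half_y, half_y)) * p
    return TrueParticle(taxon, h, m, antennas, x, y, z, mask)


def sample_scene(
    spec: dict[str, int],
    config: OpticalConfig,
    rng_seed: int = 0,
    z_range_mm: tuple[float, float] | None = None,
    rotate: bool = True,
    area_fraction_cap: float = 0.05,
    depth_of_cast_m: float | None = None,
    rng: np.random.Generator | None = None,
) -> Scene:
    """Generate a scene with exactly the requested per-taxon counts.

    Positions are uniform in the working volume (particles kept fully
    inside the sensor footprint); H and M are uniform within each
    taxon's generation cell.  Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    for taxon in spec:
        if taxon not in TAXON_CELLS:
            raise ValueError(f"unknown taxon {taxon!r}")
    particles: list[TrueParticle] = []
    for taxon in sorted(spec):
        for _ in range(int(spec[taxon])):
            particles.append(
                sample_particle(taxon, config, rng, z_range_mm=z_range_mm, rotate=rotate)
            )
    total_px = sum(int(q.mask.sum()) for q in particles)
    sensor_px = config.sensor_shape[0] * config.sensor_shape[1]
    if total_px > area_fraction_cap * sensor_px:
        raise ValueError(
            f"requested particles shade {total_px / sensor_px:.1%} of the pupil "
            f"(cap {area_fraction_cap:.0%})"
        )
    return Scene(particles, config, depth_of_cast_m=depth_of_cast_m)


def ground_truth_table(scenes: list[tuple[Scene, float]], frame_offset: int = 0) -> pd.DataFrame:
    """One row per true particle across a sequence of (scene, depth) frames."""
    rows = []
    for i, (scene, depth) in enumerate(scenes):
        for q in scene.particles:
            rows.append(
                dict(
                    frame=frame_offset + i,
                    depth_m=depth,
                    taxon=q.taxon,
                    H_um=q.H_um,
                    M=q.M,
                    antennas=q.antennas,
                    x_um=q.x_um,
                    y_um=q.y_um,
                    z_mm=q.z_mm,
                )
            )
    cols = ["frame", "depth_m", "taxon", "H_um", "M", "antennas", "x_um", "y_um", "z_mm"]
    return pd.DataFrame(rows, columns=cols)


def generate_cast(
    cast: CastSpec,
    config: OpticalConfig,
    z_range_mm: tuple[float, float] | None = None,
) -> tuple[list[tuple[Scene, float]], pd.DataFrame]:
    """Simulate a vertical cast: one scene per exposure plus ground truth.

    Frame depths follow the kinematics ``depth = speed * i / rate``; the
    expected particle count per frame is ``concentration(depth) x
    exposure volume`` realised as a Poisson draw.
    """
    if cast.submersion_speed_m_s <= 0:
        raise ValueError("speed must be positive")
    n_frames = int(math.floor(cast.max_depth_m * cast.frame_rate_hz / cast.submersion_speed_m_s)) + 1
    if n_frames > cast.frame_cap:
        raise ValueError(f"cast would produce {n_frames} frames (cap {cast.frame_cap})")
    rng = np.random.default_rng(cast.rng_seed)
    scenes: list[tuple[Scene, float]] = []
    for i in range(n_frames):
        depth = cast.submersion_speed_m_s * i / cast.frame_rate_hz
        particles: list[TrueParticle] = []
        for taxon in sorted(cast.concentration_spp_m3):
            conc = cast.concentration_spp_m3[taxon]
            lam = float(conc(depth) if callable(conc) else conc) * config.exposure_volume_m3
            if lam < 0:
                raise ValueError("concentration must be non-negative")
            for _ in range(int(rng.poisson(lam))):
                particles.append(
                    sample_particle(taxon, config, rng, z_range_mm=z_range_mm)
                )
        scene = Scene(particles, config, depth_of_cast_m=depth)
        scenes.append((scene, depth))
    return scenes, ground_truth_table(scenes)
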