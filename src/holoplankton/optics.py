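"""Scalar-wave optics for an in-line (Gabor) holographic camera.

The sensor records the intensity of a collimated beam after it has
traversed a water volume containing opaque particles.  Because the
hologram is digital, the volume is refocused numerically plane by
plane; each particle appears as a dark silhouette at its own depth.

Conventions
-----------
* ``z`` is measured from the sensor plane, increasing toward the light
  source; all internal lengths are in micrometres, ``z`` arguments in
  millimetres where noted.
* Propagation uses the angular-spectrum method with the evanescent band
  removed and, for long throws, a band limit that suppresses the
  wrap-around aliasing of the sampled transfer function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

MM = 1000.0  # micrometres per millimetre


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry of the holographic camera and its sampled water column.

    Parameters
    ----------
    wavelength_um:
        Laser-diode wavelength in the medium, micrometres.
    pixel_pitch_um:
        Sensor pixel pitch, micrometres.
    sensor_shape:
        (rows, cols) of the sensor.
    working_length_mm:
        Length of the sampled water column along the optical axis.
    exposure_volume_l:
        Water volume analysed per exposure, litres.
    pupil_area_mm2:
        Cross-sectional (entrance-pupil) area of the sampled column.
        Derived as ``exposure_volume / working_length`` when omitted;
        0.5 L over 338.4 mm gives 1477.5 mm**2.
    medium_refractive_index:
        Refractive index entering the dispersion relation.
    """

    wavelength_um: float = 0.66
    pixel_pitch_um: float = 3.45
    sensor_shape: tuple[int, int] = (1024, 1024)
    working_length_mm: float = 338.4
    exposure_volume_l: float = 0.5
    pupil_area_mm2: float | None = None
    medium_refractive_index: float = 1.0

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.working_length_mm <= 0:
            raise ValueError("working length must be positive")
        derived = self.derived_pupil_area_mm2()
        if self.pupil_area_mm2 is None:
            object.__setattr__(self, "pupil_area_mm2", derived)
        elif abs(self.pupil_area_mm2 - derived) > 1e-3 * derived:
            raise ValueError(
                f"pupil_area_mm2={self.pupil_area_mm2} inconsistent with "
                f"exposure_volume/working_length={derived:.2f} mm^2"
            )

    def derived_pupil_area_mm2(self) -> float:
        return self.exposure_volume_l * 1e6 / self.working_length_mm

    @property
    def exposure_volume_m3(self) -> float:
        return self.exposure_volume_l * 1e-3

    @property
    def sensor_extent_um(self) -> tuple[float, float]:
        r, c = self.sensor_shape
        return r * self.pixel_pitch_um, c * self.pixel_pitch_um


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor noise: additive Gaussian (relative sigma) plus optional shot noise."""

    gaussian_sigma: float = 0.01
    shot_noise: bool = False
    shot_scale: float = 1e4  # photons per unit intensity


@dataclass
class Hologram:
    """A recorded (or simulated) sensor-plane intensity image."""

    intensity: np.ndarray
    config: OpticalConfig
    depth_of_cast_m: float | None = None
    timestamp_index: int = 0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != tuple(self.config.sensor_shape):
            raise ValueError(
                f"intensity shape {self.intensity.shape} != sensor shape "
                f"{self.config.sensor_shape}"
            )
        if not np.all(np.isfinite(self.intensity)) or (self.intensity < 0).any():
            raise ValueError("intensity must be finite and non-negative")


@dataclass
class Slice:
    """Amplitude of the reconstructed field at depth ``z_mm`` from the sensor."""

    amplitude: np.ndarray
    z_mm: float


def angular_spectrum_propagate(
    field: np.ndarray,
    distance_um: float,
    config: OpticalConfig,
    band_limit: bool = False,
) -> np.ndarray:
    """Propagate a complex field between parallel planes.

    The transfer function is ``exp(2j*pi*d*sqrt((n/lambda)^2 - fx^2 - fy^2))``;
    evanescent components are suppressed.  Propagating components have a
    unit-modulus kernel, so power is conserved and ``+d`` followed by
    ``-d`` is the identity exactly.  The optional ``band_limit`` applies
    the Matsushima frequency cap that suppresses wrap-around replicas at
    distances beyond ``N*p^2/lambda``; it is off by default because the
    simulate/reconstruct pair is then an exact inverse, wrap-around and
    all, which is the property the closed-loop pipeline relies on.
    """
    field = np.asarray(field, dtype=complex)
    if field.shape != tuple(config.sensor_shape):
        raise ValueError("field shape must equal sensor shape")
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    if abs(distance_um) > 10 * config.working_length_mm * MM:
        raise ValueError("propagation distance exceeds 10x the working length")
    if distance_um == 0:
        return field.copy()

    p = config.pixel_pitch_um
    inv_lam = config.medium_refractive_index / config.wavelength_um
    fr = np.fft.fftfreq(field.shape[0], d=p)
    fc = np.fft.fftfreq(field.shape[1], d=p)
    fr2 = fr[:, None] ** 2
    fc2 = fc[None, :] ** 2
    kz2 = inv_lam**2 - fr2 - fc2
    propagating = kz2 > 0
    kz = np.sqrt(np.where(propagating, kz2, 0.0))
    kernel = np.where(propagating, np.exp(2j * np.pi * distance_um * kz), 0.0)

    if band_limit:
        # Matsushima-style separable limit on the local kernel frequency.
        d = abs(distance_um)
        dfr = fr[1] - fr[0] if len(fr) > 1 else 1.0 / p
        dfc = fc[1] - fc[0] if len(fc) > 1 else 1.0 / p
        fr_lim = inv_lam / np.sqrt((2 * d * abs(dfr)) ** 2 + 1)
        fc_lim = inv_lam / np.sqrt((2 * d * abs(dfc)) ** 2 + 1)
        kernel = np.where(
            (np.abs(fr)[:, None] <= fr_lim) & (np.abs(fc)[None, :] <= fc_lim),
            kernel,
            0.0,
        )

    return np.fft.ifft2(np.fft.fft2(field) * kernel)


def simulate_hologram(
    scene,
    config: OpticalConfig | None = None,
    noise: NoiseSpec | None = NoiseSpec(),
    rng_seed: int = 0,
) -> Hologram:
    """Simulate the in-line hologram of a particle scene.

    A unit plane wave travels from the source toward the sensor; each
    opaque particle blocks the field with its binary silhouette at its
    own plane, and the partially shadowed field diffracts onward.  The
    recorded image is the squared modulus plus sensor noise
    (deterministic for a fixed ``rng_seed``).
    """
    if config is None:
        config = scene.config
    shape = tuple(config.sensor_shape)
    parts = sorted(scene.particles, key=lambda q: -q.z_mm)
    seen: set[tuple[float, float, float]] = set()
    for q in parts:
        if not (0 < q.z_mm < config.working_length_mm):
            raise ValueError(
                f"particle z={q.z_mm} mm outside working volume "
                f"(0, {config.working_length_mm})"
            )
        key = (q.x_um, q.y_um, q.z_mm)
        if key in seen:
            warnings.warn("overlapping particles at identical position", stacklevel=2)
        seen.add(key)

    field = np.ones(shape, dtype=complex)
    z_cur = parts[0].z_mm if parts else 0.0
    for q in parts:
        field = angular_spectrum_propagate(field, -(z_cur - q.z_mm) * MM, config)
        field *= 1.0 - _place_mask(q.mask, q.x_um, q.y_um, shape, config.pixel_pitch_um)
        z_cur = q.z_mm
    field = angular_spectrum_propagate(field, -z_cur * MM, config)
    intensity = np.abs(field) ** 2

    if noise is not None:
        rng = np.random.default_rng(rng_seed)
        if noise.shot_noise:
            intensity = rng.poisson(intensity * noise.shot_scale) / noise.shot_scale
        if noise.gaussian_sigma > 0:
            intensity = intensity + rng.normal(
                0.0, noise.gaussian_sigma * max(intensity.mean(), 1e-12), shape
            )
        intensity = np.clip(intensity, 0.0, None)
    return Hologram(intensity, config, depth_of_cast_m=getattr(scene, "depth_of_cast_m", None))


def _place_mask(
    mask: np.ndarray,
    x_um: float,
    y_um: float,
    shape: tuple[int, int],
    pitch_um: float,
) -> np.ndarray:
    """Paint a particle mask onto a full-frame canvas.

    (x, y) locate the mask centre in micrometres from the sensor centre,
    x along columns and y along rows.
    """
    canvas = np.zeros(shape, dtype=float)
    mr, mc = mask.shape
    r0 = int(round(shape[0] / 2 + y_um / pitch_um - mr / 2))
    c0 = int(round(shape[1] / 2 + x_um / pitch_um - mc / 2))
    if r0 < 0 or c0 < 0 or r0 + mr > shape[0] or c0 + mc > shape[1]:
        raise ValueError("particle silhouette does not fit the sensor footprint")
    canvas[r0 : r0 + mr, c0 : c0 + mc] = mask
    return canvas


def remove_background(
    hologram: Hologram,
    method: str = "divide_lowpass",
    sigma_frac: float = 1.0 / 20.0,
    sequence: list[Hologram] | None = None,
) -> Hologram:
    """Remove slowly varying illumination from a hologram.

    ``divide_lowpass`` divides by a Gaussian-blurred copy (sigma =
    ``sigma_frac`` of the sensor width), leaving a mean near 1.
    ``subtract_sequence_mean`` subtracts the mean frame of a recorded
    sequence, which cancels any static background.
    """
    I = hologram.intensity
    if np.ptp(I) == 0:
        if method == "divide_lowpass":
            return replace(hologram, intensity=np.ones_like(I))
        raise ValueError("degenerate hologram: all pixels equal")
    if method == "divide_lowpass":
        sigma = sigma_frac * hologram.config.sensor_shape[1]
        bg = ndimage.gaussian_filter(I, sigma)
        bg = np.clip(bg, 1e-12 * I.max(), None)
        return replace(hologram, intensity=I / bg)
    if method == "subtract_sequence_mean":
        if sequence is None or len(sequence) < 2:
            raise ValueError("subtract_sequence_mean needs a sequence of >= 2 frames")
        mean_frame = np.mean([h.intensity for h in sequence], axis=0)
        out = np.clip(I - mean_frame + mean_frame.mean(), 0.0, None)
        return replace(hologram, intensity=out)
    raise ValueError(f"unknown background-removal method: {method}")


def reconstruct_slice(hologram: Hologram, z_mm: float) -> Slice:
    """Numerically refocus the hologram at depth ``z_mm`` from the sensor.

    The square root of the recorded intensity is back-propagated by
    ``z``; opaque particles in focus appear as local amplitude minima.
    """
    if not (0 < z_mm < hologram.config.working_length_mm):
        raise ValueError(
            f"z={z_mm} mm outside (0, {hologram.config.working_length_mm}) mm"
        )
    field = np.sqrt(np.clip(hologram.intensity, 0.0, None)).astype(complex)
    out = angular_spectrum_propagate(field, z_mm * MM, hologram.config)
    return Slice(np.abs(out), z_mm)


def reconstruct_volume(
    hologram: Hologram,
    z_range_mm: tuple[float, float],
    z_step_mm: float,
) -> list[Slice]:
    """Layer-by-layer reconstruction over ``[z_min, z_max]`` with step ``z_step``."""
    z_min, z_max = z_range_mm
    if z_min >= z_max:
        raise ValueError("z range must satisfy z_min < z_max")
    if z_step_mm <= 0:
        raise ValueError("z_step must be positive")
    n = int(np.floor((z_max - z_min) / z_step_mm)) + 1
    return [reconstruct_slice(hologram, z_min + i * z_step_mm) for i in range(n)]
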