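"""Geometric-optics point-spread functions from wavefront data.

The pipeline here is: sample a circular pupil on a Cartesian grid, build an
optical-path-difference (OPD) map over it (from Zernike coefficients or from
a radial lens power profile), differentiate the map to obtain transverse ray
angles, and histogram the ray landing positions at the image plane.

Unit conventions (fixed for the whole package):

* pupil coordinates in millimetres,
* OPD in micrometres,
* ray slopes (angles) in radians,
* PSF axes in arcminutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

RAD_TO_ARCMIN = 180.0 / math.pi * 60.0
#: OPD is stored in um while pupil coordinates are in mm; a slope in um/mm
#: is 1e-3 radians.
_UM_PER_MM = 1e-3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PupilGrid:
    """Square Cartesian sampling of a circular pupil.

    Parameters
    ----------
    diameter : float
        Pupil diameter in mm. Must be positive.
    resolution : int
        Number of samples across the diameter (>= 16).
    """

    diameter: float
    resolution: int = 256

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError(f"pupil diameter must be > 0, got {self.diameter}")
        if self.resolution < 16:
            raise ValueError(f"resolution must be >= 16, got {self.resolution}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def axis(self) -> np.ndarray:
        """1D coordinate axis (mm), endpoints at +/- radius."""
        return np.linspace(-self.radius, self.radius, self.resolution)

    @property
    def step(self) -> float:
        """Sample spacing in mm."""
        return self.diameter / (self.resolution - 1)

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """2D meshgrid of (x, y) sample positions in mm."""
        ax = self.axis
        return np.meshgrid(ax, ax, indexing="xy")

    def mask(self) -> np.ndarray:
        """Boolean array marking samples inside the circular aperture."""
        x, y = self.coordinates()
        return x * x + y * y <= self.radius**2 + 1e-12


@dataclass(frozen=True)
class WavefrontMap:
    """OPD map (um) over a pupil grid; defined on the full square, masked
    to the circular aperture downstream."""

    grid: PupilGrid
    opd: np.ndarray
    wavelength_nm: float = 570.0

    def __post_init__(self) -> None:
        opd = np.asarray(self.opd, dtype=float)
        if opd.shape != (self.grid.resolution, self.grid.resolution):
            raise ValueError(
                f"opd shape {opd.shape} does not match grid resolution "
                f"{self.grid.resolution}"
            )
        if not np.all(np.isfinite(opd[self.grid.mask()])):
            raise ValueError("OPD contains non-finite values inside the pupil")
        object.__setattr__(self, "opd", opd)


@dataclass(frozen=True)
class LensProfile:
    """Radial lens power profile P(r) in diopters over [0, profile_radius] mm.

    ``design`` is one of ``single_vision``, ``centre_distance``,
    ``centre_near_aspheric``, ``dual_focus_zonal``, ``edof``.
    """

    design: str
    power: Callable[[np.ndarray], np.ndarray]
    base_power: float
    add_power: float
    profile_radius: float
    zone_radii: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.zone_radii)
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("zone radii must be strictly increasing")
        object.__setattr__(self, "zone_radii", radii)

    def __call__(self, r: np.ndarray) -> np.ndarray:
        return np.asarray(self.power(np.asarray(r, dtype=float)), dtype=float)


@dataclass(frozen=True)
class SlopeField:
    """Transverse ray angles (radians) per pupil sample."""

    grid: PupilGrid
    slope_x: np.ndarray
    slope_y: np.ndarray


@dataclass(frozen=True)
class GeometricPSF:
    """2D histogram of ray intersections with the image plane.

    ``counts`` is bins x bins (first axis = y, second = x, as produced by
    histogramming); the field spans ``[-half_width, half_width]`` arcmin on
    both axes.
    """

    counts: np.ndarray
    bin_width: float
    half_width: float
    rays_total: int
    out_of_field: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square 2D array")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if int(counts.sum()) + self.out_of_field != self.rays_total:
            raise ValueError("in-field + out-of-field counts must equal rays_total")

    @property
    def bins(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class ImageRaster:
    """Grayscale raster with values in [0, 1] and an angular pixel scale.

    Pixels are quantized to 16-bit gray levels (the interchange precision of
    the PGM writer); this makes inversion an exact involution.
    """

    pixels: np.ndarray
    polarity: str  # "dark_on_light" | "light_on_dark"
    arcmin_per_pixel: float

    _LEVELS = 65535

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.min() < -1e-12 or px.max() > 1 + 1e-12:
            raise ValueError("pixel values must lie in [0, 1]")
        px = np.round(np.clip(px, 0.0, 1.0) * self._LEVELS) / self._LEVELS
        object.__setattr__(self, "pixels", px)

    def inverted(self) -> "ImageRaster":
        pol = "light_on_dark" if self.polarity == "dark_on_light" else "dark_on_light"
        return ImageRaster(1.0 - self.pixels, pol, self.arcmin_per_pixel)


# ---------------------------------------------------------------------------
# Zernike expansion (OSA/ANSI single index, normalized polynomials)
# ---------------------------------------------------------------------------


def osa_index_to_nm(j: int) -> tuple[int, int]:
    """Convert an OSA/ANSI single index to (radial order n, frequency m)."""
    if j < 0:
        raise ValueError(f"Zernike index must be >= 0, got {j}")
    n = int(math.ceil((-3.0 + math.sqrt(9.0 + 8.0 * j)) / 2.0))
    m = 2 * j - n * (n + 2)
    return n, m


def zernike_polynomial(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Normalized Zernike polynomial Z_j on the unit disc (OSA indexing)."""
    n, m = osa_index_to_nm(j)
    am = abs(m)
    radial = np.zeros_like(rho, dtype=float)
    for k in range((n - am) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + am) // 2 - k)
                * math.factorial((n - am) // 2 - k)
            )
        )
        radial += c * rho ** (n - 2 * k)
    norm = math.sqrt(2.0 * (n + 1) / (1.0 + (1.0 if m == 0 else 0.0)))
    if m > 0:
        angular = np.cos(am * theta)
    elif m < 0:
        angular = np.sin(am * theta)
    else:
        angular = np.ones_like(theta)
    return norm * radial * angular


def zernike_wavefront(
    coeffs: Sequence[float], pupil: PupilGrid, wavelength_nm: float = 570.0
) -> WavefrontMap:
    """Build a wavefront from OSA-indexed Zernike coefficients (um).

    ``coeffs[j]`` multiplies the normalized Zernike polynomial with OSA
    single index ``j``, evaluated on pupil coordinates normalized by the
    pupil radius.
    """
    coeffs = list(coeffs)
    if not coeffs:
        raise ValueError("coefficient list must be non-empty")
    for j, c in enumerate(coeffs):
        if not math.isfinite(c):
            raise ValueError(f"non-finite Zernike coefficient at OSA index {j}")
    x, y = pupil.coordinates()
    rho = np.hypot(x, y) / pupil.radius
    theta = np.arctan2(y, x)
    opd = np.zeros_like(rho)
    for j, c in enumerate(coeffs):
        if c != 0.0:
            opd += c * zernike_polynomial(j, rho, theta)
    return WavefrontMap(pupil, opd, wavelength_nm)


# ---------------------------------------------------------------------------
# Power-profile wavefronts
# ---------------------------------------------------------------------------


def profile_wavefront(
    profile: LensProfile, pupil: PupilGrid, wavelength_nm: float = 570.0
) -> WavefrontMap:
    """Integrate a radial power profile into a rotationally symmetric OPD map.

    Under the local-vergence definition of power, W(r) = integral_0^r
    P(rho) * rho d rho with P in diopters and r in metres, giving W in
    metres (stored in um).

    The quadrature places nodes at every sampled radius and at every zone
    boundary, so the trapezoid rule is exact for piecewise-constant power
    profiles and for constant power yields W(r) = P r^2 / 2 to machine
    precision.
    """
    if profile.profile_radius + 1e-9 < pupil.radius:
        raise ValueError(
            f"lens profile (radius {profile.profile_radius} mm) does not cover "
            f"the pupil (radius {pupil.radius} mm)"
        )
    x, y = pupil.coordinates()
    r_mm = np.hypot(x, y)
    sample_r = np.unique(r_mm[pupil.mask()])
    dense = np.linspace(0.0, float(sample_r.max()), 2049)
    nodes = np.unique(
        np.concatenate(
            [sample_r, dense, [z for z in profile.zone_radii if z <= sample_r.max()]]
        )
    )
    # per-interval midpoint power times the exact integral of rho: exact for
    # piecewise-constant P (zone boundaries are nodes), O(h^2) for smooth P
    rho_m = nodes * 1e-3
    p_mid = profile((nodes[1:] + nodes[:-1]) / 2.0)
    cumulative = np.concatenate(
        [[0.0], np.cumsum(p_mid * (rho_m[1:] ** 2 - rho_m[:-1] ** 2) / 2.0)]
    )
    w_um = cumulative * 1e6  # metres -> um
    opd = np.interp(r_mm, nodes, w_um)  # clamps at nodes[-1] outside the pupil
    return WavefrontMap(pupil, opd, wavelength_nm)


# ---------------------------------------------------------------------------
# Slopes and the ray-intersection histogram
# ---------------------------------------------------------------------------


def wavefront_slopes(w: WavefrontMap) -> SlopeField:
    """Differentiate the OPD map into transverse ray angles (radians).

    Central differences in the interior, one-sided at the boundary
    (``numpy.gradient`` semantics).
    """
    if w.grid.resolution < 3:
        raise ValueError("grid too coarse to differentiate")
    step = w.grid.step
    # axis 0 is y, axis 1 is x in the meshgrid(indexing="xy") layout
    d_dy, d_dx = np.gradient(w.opd, step)
    return SlopeField(w.grid, d_dx * _UM_PER_MM, d_dy * _UM_PER_MM)


def geometric_psf(
    slopes: SlopeField, bins: int = 255, half_width: float = 30.0
) -> GeometricPSF:
    """Histogram ray landing angles into a square field of view.

    Each in-pupil sample contributes one ray at angular position
    ``(slope_x, slope_y)`` (converted to arcmin). Rays outside
    ``[-half_width, half_width]`` on either axis are tallied in
    ``out_of_field``, never dropped silently.
    """
    if bins < 3 or bins % 2 == 0:
        raise ValueError(f"bins must be an odd integer >= 3, got {bins}")
    if not half_width > 0:
        raise ValueError(f"half_width must be > 0, got {half_width}")
    mask = slopes.grid.mask()
    ax = np.asarray(slopes.slope_x)[mask] * RAD_TO_ARCMIN
    ay = np.asarray(slopes.slope_y)[mask] * RAD_TO_ARCMIN
    rays_total = int(mask.sum())
    edges = np.linspace(-half_width, half_width, bins + 1)
    counts, _, _ = np.histogram2d(ay, ax, bins=[edges, edges])
    counts = counts.astype(np.int64)
    out_of_field = rays_total - int(counts.sum())
    return GeometricPSF(
        counts=counts,
        bin_width=2.0 * half_width / bins,
        half_width=half_width,
        rays_total=rays_total,
        out_of_field=out_of_field,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def rescale_raster(raster: ImageRaster, factor: float) -> ImageRaster:
    """Resample a raster to cover ``factor`` times the angular extent.

    Pixel angular scale is preserved; the pixel count changes. Linear
    interpolation with aligned corners, so an integer upsample followed by
    the inverse downsample is an exact round trip.
    """
    if not factor > 0:
        raise ValueError("scale factor must be > 0")
    if factor == 1.0:
        return raster
    n = raster.pixels.shape[0]
    m = int(round((n - 1) * factor)) + 1
    src = np.linspace(0.0, n - 1.0, m)
    grid_y, grid_x = np.meshgrid(src, src, indexing="ij")
    out = ndimage.map_coordinates(
        raster.pixels, [grid_y, grid_x], order=1, mode="nearest"
    )
    return ImageRaster(out, raster.polarity, raster.arcmin_per_pixel)


def render_psf(
    psf: GeometricPSF, invert: bool = False, target_half_width: float | None = None
) -> ImageRaster:
    """Turn a ray-count histogram into a grayscale raster.

    Counts are max-normalized to [0, 1]; ``invert`` flips to dark-on-light
    (matching hand-drawn ink on paper); if ``target_half_width`` differs
    from the histogram's half-width the raster is resampled so it spans the
    target angular extent.
    """
    total = int(psf.counts.sum())
    if total == 0:
        raise ValueError("cannot render a PSF with zero in-field counts")
    intensity = psf.counts.astype(float) / psf.counts.max()
    raster = ImageRaster(intensity, "light_on_dark", psf.bin_width)
    if invert:
        raster = raster.inverted()
    if target_half_width is not None and target_half_width != psf.half_width:
        raster = rescale_raster(raster, target_half_width / psf.half_width)
    return raster
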