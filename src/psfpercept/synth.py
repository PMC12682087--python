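"""Seeded generators for every input the pipeline consumes.

No raw study data ship with this package; instead this module plants known
structure — lens designs, pupils, wavefronts, surrogate "hand-drawn" PSFs,
ordinal rater responses over latent binary features, and similarity ratings
drawn from a low-dimensional configuration — so every downstream stage can
be exercised and its recovery properties measured against the truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform, pdist
from scipy.stats import truncnorm

from .agreement import N_DESCRIPTORS, LikertResponseSet
from .mds import SimilarityStudy
from .optics import (
    GeometricPSF,
    ImageRaster,
    LensProfile,
    PupilGrid,
    WavefrontMap,
    geometric_psf,
    profile_wavefront,
    render_psf,
    wavefront_slopes,
    zernike_wavefront,
)

DESIGNS = (
    "single_vision",
    "centre_distance",
    "centre_near_aspheric",
    "dual_focus_zonal",
    "edof",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic study; defaults mirror the emulated design
    (15 image pairs, 13 analysts, pupils 5.82 +/- 1.05 mm)."""

    seed: int = 0
    n_images: int = 15
    n_raters: int = 13
    design_mix: tuple[str, ...] = DESIGNS
    pupil_mean_mm: float = 5.82
    pupil_sd_mm: float = 1.05
    rater_reliability: float = 0.85
    likert_fidelity: float = 0.95
    similarity_noise_sd: float = 0.75
    similarity_gamma: float = 2.0
    self_pair_boost: float = 2.0
    d2g_noise_inflation: float = 1.2
    d2g_compression: float = 0.4
    d2g_midpoint: float = 5.5
    planted_ndim: int = 3
    sketch_noise: float = 0.5
    grid_resolution: int = 128
    psf_bins: int = 121
    psf_half_width: float = 30.0

    def __post_init__(self) -> None:
        if not 0.5 < self.rater_reliability <= 1.0:
            raise ValueError("rater_reliability must be in (0.5, 1]")
        for name in ("similarity_noise_sd", "sketch_noise", "pupil_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.design_mix) - set(DESIGNS)
        if unknown:
            raise ValueError(f"unknown lens designs: {sorted(unknown)}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Lenses and pupils
# ---------------------------------------------------------------------------


def make_lens_profile(
    design: str,
    base_power: float = 0.0,
    add_power: float = 2.0,
    zone_radii: tuple[float, ...] | None = None,
    profile_radius: float = 4.5,
) -> LensProfile:
    """Radial power profile for one of the five design archetypes.

    * ``single_vision``: constant base power.
    * ``centre_distance``: base at centre, quadratic progression to
      base + add at the profile edge.
    * ``centre_near_aspheric``: base + add at centre, smooth quadratic
      falloff to base at the edge.
    * ``dual_focus_zonal``: concentric zones alternating base (centre) and
      base + add at the given radii.
    * ``edof``: linear power sweep from base to base + add.
    """
    if add_power < 0:
        raise ValueError(f"add_power must be >= 0, got {add_power}")
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    radii: tuple[float, ...] = ()
    if design == "dual_focus_zonal":
        radii = tuple(zone_radii) if zone_radii else (1.5, 2.5, 3.5)

    if design == "single_vision":
        fn = lambda r: np.full_like(r, base_power, dtype=float)
    elif design == "centre_distance":
        fn = lambda r: base_power + add_power * np.minimum(r / profile_radius, 1.0) ** 2
    elif design == "centre_near_aspheric":
        fn = lambda r: base_power + add_power * (
            1.0 - np.minimum(r / profile_radius, 1.0) ** 2
        )
    elif design == "edof":
        fn = lambda r: base_power + add_power * np.minimum(r / profile_radius, 1.0)
    else:  # dual_focus_zonal: even-numbered zones carry base power
        def fn(r, _radii=radii):
            zone = np.searchsorted(np.asarray(_radii), r, side="right")
            return np.where(zone % 2 == 1, base_power + add_power, base_power)

    return LensProfile(
        design=design,
        power=fn,
        base_power=base_power,
        add_power=add_power,
        profile_radius=profile_radius,
        zone_radii=radii,
    )


def sample_pupils(
    n: int,
    mean_mm: float = 5.82,
    sd_mm: float = 1.05,
    seed: int | None = None,
    bounds: tuple[float, float] = (2.0, 9.0),
) -> np.ndarray:
    """Seeded truncated-normal pupil diameters (mm)."""
    rng = np.random.default_rng(seed)
    if sd_mm == 0:
        return np.full(n, mean_mm)
    lo, hi = bounds
    a, b = (lo - mean_mm) / sd_mm, (hi - mean_mm) / sd_mm
    return truncnorm.rvs(a, b, loc=mean_mm, scale=sd_mm, size=n, random_state=rng)


# ---------------------------------------------------------------------------
# Surrogate hand-drawn PSFs
# ---------------------------------------------------------------------------


def binarize_psf(psf: GeometricPSF, threshold_quantile: float = 0.75) -> np.ndarray:
    """Boolean support: bins whose intensity reaches the given quantile of
    the positive intensities."""
    if psf.counts.max() == 0:
        raise ValueError("PSF has no in-field rays")
    intensity = psf.counts.astype(float) / psf.counts.max()
    positive = intensity[intensity > 0]
    thresh = np.quantile(positive, threshold_quantile)
    return intensity >= thresh


def surrogate_drawn_psf(
    psf: GeometricPSF,
    sketch_noise: float = 0.5,
    seed: int | None = None,
    threshold_quantile: float = 0.75,
) -> ImageRaster:
    """Raster stand-in for a participant's drawing of a PSF.

    The PSF is thresholded at an intensity quantile; each connected feature
    (core, rings, rays) is independently jittered by a seeded integer shift
    of SD ``sketch_noise`` pixels and occasionally thickened or thinned,
    emulating a sketch that keeps salient features but loses fine detail.
    Rendered dark-on-light. With ``sketch_noise=0`` the binarized support
    equals the thresholded PSF support exactly.
    """
    support = binarize_psf(psf, threshold_quantile)
    if sketch_noise == 0:
        return ImageRaster(1.0 - support.astype(float), "dark_on_light", psf.bin_width)
    rng = np.random.default_rng(seed)
    labels, n_comp = ndimage.label(support, structure=np.ones((3, 3)))
    out = np.zeros_like(support)
    for comp in range(1, n_comp + 1):
        piece = labels == comp
        dy, dx = np.round(rng.normal(0.0, sketch_noise, size=2)).astype(int)
        piece = np.roll(np.roll(piece, dy, axis=0), dx, axis=1)
        u = rng.uniform()
        if u < min(0.3, sketch_noise / 4):
            piece = ndimage.binary_dilation(piece)
        elif u > 1 - min(0.3, sketch_noise / 4):
            eroded = ndimage.binary_erosion(piece)
            if eroded.any():
                piece = eroded
        out |= piece
    if not out.any():  # jitter must never erase the drawing entirely
        out = support
    return ImageRaster(1.0 - out.astype(float), "dark_on_light", psf.bin_width)


def match_by_correlation(
    drawn: list[ImageRaster], geometric: list[ImageRaster]
) -> tuple[np.ndarray, int]:
    """Assign each drawn raster to a geometric raster by maximizing total
    normalized cross-correlation (optimal one-to-one assignment).

    Returns (assignment array, number of fixed points), where
    ``assignment[i]`` is the geometric index matched to drawn i.
    """
    if len(drawn) != len(geometric):
        raise ValueError("need equally many drawn and geometric rasters")

    def ink(raster: ImageRaster) -> np.ndarray:
        px = raster.pixels
        if raster.polarity == "dark_on_light":
            px = 1.0 - px
        v = px - px.mean()
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v

    d = [ink(r) for r in drawn]
    g = [ink(r) for r in geometric]
    score = np.array([[float(np.sum(di * gj)) for gj in g] for di in d])
    rows, cols = linear_sum_assignment(-score)
    assignment = np.empty(len(drawn), dtype=int)
    assignment[rows] = cols
    return assignment, int(np.sum(assignment == np.arange(len(drawn))))


# ---------------------------------------------------------------------------
# Likert responses over latent binary features
# ---------------------------------------------------------------------------


def simulate_likert(
    truth: np.ndarray, config: SimulationConfig, seed: int | None = None
) -> tuple[LikertResponseSet, LikertResponseSet]:
    """Ordinal responses from ``n_raters`` raters on drawn and geometric
    versions of each image.

    ``truth`` is an (n_images, 13) binary array of features truly present in
    the geometric image. The drawn version shares each truth bit except for
    independent flips at rate 1 - ``likert_fidelity`` (drawing infidelity).
    A rater facing a present feature answers Agree/Strongly Agree with
    probability ``rater_reliability`` and otherwise lands in the
    Neutral/Disagree tiers; absent features are mirrored.
    """
    truth = np.asarray(truth)
    if truth.shape[1] != N_DESCRIPTORS:
        raise ValueError(f"truth must have {N_DESCRIPTORS} columns")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    flips = rng.random(truth.shape) < (1.0 - config.likert_fidelity)
    drawn_truth = np.where(flips, 1 - truth, truth)

    def responses(bits: np.ndarray) -> pd.DataFrame:
        n_img = bits.shape[0]
        rows = []
        for rater in range(config.n_raters):
            reliable = rng.random((n_img, N_DESCRIPTORS)) < config.rater_reliability
            hi = rng.integers(4, 6, size=(n_img, N_DESCRIPTORS))  # {4, 5}
            lo = rng.integers(1, 3, size=(n_img, N_DESCRIPTORS))  # {1, 2}
            mid_hi = rng.integers(1, 4, size=(n_img, N_DESCRIPTORS))  # {1, 2, 3}
            mid_lo = rng.integers(3, 6, size=(n_img, N_DESCRIPTORS))  # {3, 4, 5}
            resp = np.where(
                bits == 1,
                np.where(reliable, hi, mid_hi),
                np.where(reliable, lo, mid_lo),
            )
            for img in range(n_img):
                for desc in range(N_DESCRIPTORS):
                    rows.append(
                        {
                            "rater_id": f"r{rater:02d}",
                            "image_id": img,
                            "descriptor_index": desc,
                            "response": int(resp[img, desc]),
                        }
                    )
        return pd.DataFrame(rows)

    drawn = LikertResponseSet(responses(drawn_truth), image_type="drawn")
    geometric = LikertResponseSet(responses(truth), image_type="geometric")
    return drawn, geometric


# ---------------------------------------------------------------------------
# Similarity ratings from a planted configuration
# ---------------------------------------------------------------------------


def simulate_similarity(
    planted: np.ndarray, config: SimulationConfig, seed: int | None = None
) -> SimilarityStudy:
    """Rater similarity ratings in D2D / G2G / D2G blocks.

    Ratings are a monotone (affine) map of planted inter-point distance onto
    the 1-10 scale plus Gaussian rater noise, rounded and clipped. Within a
    type, self-pairs are boosted toward 10. The cross-type (D2G) block is
    compressed toward mid-scale and its noise inflated, mimicking the harder
    drawn-vs-computed comparison; it is generated as a full ordered grid.
    """
    planted = np.asarray(planted, dtype=float)
    n = planted.shape[0]
    dist = squareform(pdist(planted))
    dmax = dist.max()
    if dmax == 0:
        raise ValueError("planted configuration has no spread")
    # convex monotone map: most distinct pairs land low on the scale (the
    # emulated rating behaviour), self-pairs (zero distance) at 10
    s_base = 1.0 + 9.0 * (1.0 - dist / dmax) ** config.similarity_gamma
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    rows = []
    for rater in range(config.n_raters):
        rid = f"r{rater:02d}"
        for block in ("D2D", "G2G"):
            for i in range(n):
                for j in range(i, n):
                    target = s_base[i, j] + (config.self_pair_boost if i == j else 0.0)
                    noise = rng.normal(0.0, config.similarity_noise_sd)
                    rating = int(np.clip(round(target + noise), 1, 10))
                    rows.append(
                        {
                            "rater_id": rid,
                            "image_a": i,
                            "image_b": j,
                            "block": block,
                            "rating": rating,
                        }
                    )
        sd = config.similarity_noise_sd * config.d2g_noise_inflation
        for i in range(n):
            for j in range(n):
                target = config.d2g_midpoint + (
                    s_base[i, j] - config.d2g_midpoint
                ) * config.d2g_compression
                rating = int(np.clip(round(target + rng.normal(0.0, sd)), 1, 10))
                rows.append(
                    {
                        "rater_id": rid,
                        "image_a": i,
                        "image_b": j,
                        "block": "D2G",
                        "rating": rating,
                    }
                )
    return SimilarityStudy(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    config: SimulationConfig
    planted_coords: np.ndarray
    truth_bits: np.ndarray
    likert_drawn: LikertResponseSet
    likert_geometric: LikertResponseSet
    similarity: SimilarityStudy
    profiles: list[LensProfile] = field(default_factory=list)
    pupils_mm: np.ndarray | None = None
    wavefronts: list[WavefrontMap] = field(default_factory=list)
    psfs: list[GeometricPSF] = field(default_factory=list)
    geometric_rasters: list[ImageRaster] = field(default_factory=list)
    drawn_rasters: list[ImageRaster] = field(default_factory=list)


def generate_study(
    config: SimulationConfig | None = None, include_optics: bool = True
) -> StudyBundle:
    """Generate a complete synthetic study from one seed.

    Optics (profiles, wavefronts, PSFs, rendered and surrogate-drawn
    rasters) can be skipped when only the psychometric stages are needed.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    planted = rng.normal(size=(config.n_images, config.planted_ndim))
    truth = rng.integers(0, 2, size=(config.n_images, N_DESCRIPTORS))
    # keep every image's feature vector mixed so 2x2 association tables
    # stay informative
    for row in truth:
        while row.min() == row.max():
            row[:] = rng.integers(0, 2, size=N_DESCRIPTORS)
    drawn_lrs, geo_lrs = simulate_likert(
        truth, config, seed=int(rng.integers(2**31))
    )
    similarity = simulate_similarity(planted, config, seed=int(rng.integers(2**31)))
    bundle = StudyBundle(
        config=config,
        planted_coords=planted,
        truth_bits=truth,
        likert_drawn=drawn_lrs,
        likert_geometric=geo_lrs,
        similarity=similarity,
    )
    if not include_optics:
        return bundle
    pupils = sample_pupils(
        config.n_images,
        config.pupil_mean_mm,
        config.pupil_sd_mm,
        seed=int(rng.integers(2**31)),
    )
    for i in range(config.n_images):
        design = config.design_mix[i % len(config.design_mix)]
        profile = make_lens_profile(design, base_power=0.0, add_power=2.0)
        pupil = PupilGrid(diameter=float(pupils[i]), resolution=config.grid_resolution)
        base = profile_wavefront(profile, pupil)
        # idiosyncratic higher-order aberrations so images differ in shape
        coeffs = np.zeros(15)
        coeffs[3:] = rng.normal(0.0, 0.15, size=12)
        hoa = zernike_wavefront(coeffs, pupil)
        wavefront = WavefrontMap(pupil, base.opd + hoa.opd)
        psf = geometric_psf(
            wavefront_slopes(wavefront),
            bins=config.psf_bins,
            half_width=config.psf_half_width,
        )
        bundle.profiles.append(profile)
        bundle.wavefronts.append(wavefront)
        bundle.psfs.append(psf)
        bundle.geometric_rasters.append(render_psf(psf, invert=True))
        bundle.drawn_rasters.append(
            surrogate_drawn_psf(
                psf, config.sketch_noise, seed=int(rng.integers(2**31))
            )
        )
    bundle.pupils_mm = pupils
    return bundle
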