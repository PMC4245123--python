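"""Seeded synthetic vesicle populations, rendered micrograph tracks, and ground truth.

Emulates what a bright-field video microscope sees when recording electroformed
giant unilamellar vesicles (GUVs) settling in a perfusion chamber:

* vesicle diameters follow a broad, mono-modal, truncated lognormal law
  (all vesicles between 1 and 50 um);
* contours are near-circular closed curves with a tunable mean isoperimetric
  quotient (IPQ), built from a low-order radial harmonic perturbation;
* sucrose-filled vesicles sediment into the focal plane with a Stokes-law
  settling speed proportional to diameter squared, so large vesicles appear
  first and the visible count grows with incubation time;
* each vesicle is imaged as a dark membrane ring with a nearly
  background-level interior on a noisy background, plus occasional
  "crystallized lipid" distractor blobs;
* the camera travels predominantly along one axis with per-frame jitter,
  producing an overlapping frame sequence (a track) ready for stitching.

Everything is deterministic given the seed carried by the parameter objects.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .errors import ParameterError

__all__ = [
    "PopulationParams",
    "SedimentationParams",
    "RenderParams",
    "MotionModel",
    "VesicleGroundTruth",
    "Distractor",
    "Track",
    "RenderedFrame",
    "sample_population",
    "sample_distractors",
    "simulate_sedimentation",
    "visible_at",
    "render_frame",
    "generate_track",
    "write_track",
    "write_ground_truth",
]

#: harmonic orders of the radial contour perturbation (ellipticity .. hexalobes)
_HARMONICS = np.arange(2, 7)
#: number of polygon vertices per ground-truth contour
_N_VERTICES = 256
#: largest total relative radial perturbation still guaranteeing a simple,
#: star-shaped contour with r(theta) > 0
_MAX_TOTAL_AMPLITUDE = 0.42


@dataclass(frozen=True)
class PopulationParams:
    """Statistical description of one synthetic vesicle population.

    Diameters are drawn from a lognormal law truncated to
    ``[diam_min, diam_max]``; contour roughness is calibrated so the
    population mean IPQ matches ``target_mean_ipq`` within +/-0.01.
    ``distractor_rate`` is the expected number of crystallized-lipid blobs
    per one camera frame area.  ``chamber_um`` is the (rows, cols) extent in
    micrometres of the chamber region the population occupies; the default
    is sized for a single ~3000-frame track.
    """

    n_vesicles: int = 250
    diam_lognormal_mu: float = math.log(6.5)
    diam_lognormal_sigma: float = 0.6
    diam_min: float = 1.0
    diam_max: float = 50.0
    target_mean_ipq: float = 0.93
    distractor_rate: float = 0.5
    chamber_um: tuple[float, float] = (1650.0, 190.5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_vesicles < 0:
            raise ParameterError("n_vesicles must be >= 0")
        if not 0 < self.diam_min < self.diam_max:
            raise ParameterError("diam_min/diam_max must satisfy 0 < diam_min < diam_max")
        if not 0 < self.target_mean_ipq <= 1:
            raise ParameterError("target_mean_ipq must lie in (0, 1]")
        if self.diam_lognormal_sigma <= 0:
            raise ParameterError("diam_lognormal_sigma must be > 0")
        if self.distractor_rate < 0:
            raise ParameterError("distractor_rate must be >= 0")
        if min(self.chamber_um) <= 0:
            raise ParameterError("chamber_um extents must be > 0")


@dataclass(frozen=True)
class SedimentationParams:
    """Stokes-style settling model: speed v(d) = coeff * d^2, chamber depth H.

    The visibility probability of a vesicle of diameter ``d`` (um) after
    ``t`` minutes is ``p = 1 - exp(-t * v(d) / H)``.  The default coefficient
    makes roughly three quarters of a default population visible after
    30 minutes, which reproduces the observed settling dynamics (visible
    counts growing ~3x between 3 and 30 min and ~1.2-1.3x between 30 and
    60 min).
    """

    settling_coeff_mm_per_min_um2: float = 7.4e-4
    chamber_depth_mm: float = 0.5

    def rate_per_min(self, diameter_um):
        d = np.asarray(diameter_um, dtype=float)
        return self.settling_coeff_mm_per_min_um2 * d * d / self.chamber_depth_mm


@dataclass(frozen=True)
class RenderParams:
    """Bright-field rendering model for one camera frame.

    Intensities are on the 8-bit scale; each vesicle is a dark ring with a
    Gaussian radial profile of scale ``ring_width_px`` whose *outer* edge
    coincides with the vesicle boundary, over a slightly offset interior.
    """

    frame_shape: tuple[int, int] = (570, 762)
    pixel_size_um: float = 0.25
    background_level: float = 200.0
    ring_contrast: float = 90.0
    ring_width_px: float = 1.5
    interior_offset: float = -8.0
    noise_sigma: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.frame_shape) != 2 or min(self.frame_shape) < 8:
            raise ParameterError("frame_shape must be a (rows, cols) pair of at least 8 px")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        if not 0 <= self.background_level <= 255:
            raise ParameterError("background_level must be representable in 8 bits")
        if not 0 <= self.background_level - self.ring_contrast <= 255:
            raise ParameterError("ring_contrast drives intensities outside the 8-bit range")
        if not 0 <= self.background_level + self.interior_offset <= 255:
            raise ParameterError("interior_offset drives intensities outside the 8-bit range")
        if self.ring_width_px < 1:
            raise ParameterError("ring_width_px must be >= 1")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class MotionModel:
    """Manually guided 1-D slide motion: steady drift along one axis + jitter."""

    step_mean_px: float = 2.0
    step_jitter_px: float = 0.5
    transverse_jitter_px: float = 0.3
    axis: int = 0


@dataclass
class VesicleGroundTruth:
    """One synthetic vesicle: placement, size, shape, and settling time.

    ``contour_um`` is a closed simple polygon (first vertex repeated last) in
    chamber (row, col) micrometre coordinates whose area is consistent with
    ``diameter_um``; ``true_ipq`` is computed from that same polygon.
    ``settled_at_min`` is the time at which the vesicle reaches the focal
    plane and becomes visible.
    """

    id: int
    center_rc_um: tuple[float, float]
    diameter_um: float
    contour_um: np.ndarray
    true_ipq: float
    settled_at_min: float
    amplitudes: np.ndarray
    phases: np.ndarray

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    @property
    def max_radius_um(self) -> float:
        return self.radius_um * (1.0 + float(np.sum(np.abs(self.amplitudes))))


@dataclass
class Distractor:
    """A crystallized-lipid blob: filled, irregular, and not a vesicle."""

    id: int
    center_rc_um: tuple[float, float]
    radius_um: float
    amplitudes: np.ndarray
    phases: np.ndarray

    @property
    def max_radius_um(self) -> float:
        return self.radius_um * (1.0 + float(np.sum(np.abs(self.amplitudes))))


@dataclass
class Track:
    """An ordered sequence of equally shaped grayscale frames."""

    frames: list[np.ndarray]
    pixel_size_um: float

    def __post_init__(self):
        if not self.frames:
            raise ParameterError("a Track needs at least one frame")
        shape = self.frames[0].shape
        dtype = self.frames[0].dtype
        for f in self.frames:
            if f.shape != shape or f.dtype != dtype:
                raise ParameterError("all frames must share one shape and dtype")


@dataclass
class RenderedFrame:
    """A rendered frame with its ground-truth label mask.

    ``mask`` labels only vesicles lying fully inside the view (distractors
    are background); ``vesicle_ids[k]`` is the ground-truth id of label k+1.
    """

    image: np.ndarray
    mask: np.ndarray
    vesicle_ids: list[int]


# ----------------------------------------------------------------- geometry

def _harmonic_radii(theta, amplitudes, phases):
    """r(theta)/R = 1 + sum_k a_k cos(k theta + phi_k) for k = 2..6."""
    r = np.ones_like(theta)
    for k, a, p in zip(_HARMONICS, amplitudes, phases):
        r += a * np.cos(k * theta + p)
    return r


def _polygon_area_perimeter(rows, cols):
    """Shoelace area and segment-sum perimeter of closed-by-wraparound rings."""
    r2, c2 = np.roll(rows, -1, axis=-1), np.roll(cols, -1, axis=-1)
    area = 0.5 * np.abs(np.sum(cols * r2 - c2 * rows, axis=-1))
    perim = np.sum(np.hypot(r2 - rows, c2 - cols), axis=-1)
    return area, perim


def _batch_ipq(amp_matrix, phase_matrix, theta):
    """IPQ of every unit-radius harmonic contour in a batch (rows = vesicles)."""
    r = np.ones((amp_matrix.shape[0], theta.size))
    for i, k in enumerate(_HARMONICS):
        r += amp_matrix[:, i, None] * np.cos(k * theta[None, :] + phase_matrix[:, i, None])
    rows = r * np.sin(theta)[None, :]
    cols = r * np.cos(theta)[None, :]
    area, perim = _polygon_area_perimeter(rows, cols)
    return 4.0 * math.pi * area / perim**2


def _clip_amplitudes(amps, scale):
    """Scale raw amplitudes, clipping each vesicle's total perturbation."""
    scaled = amps * scale
    total = np.sum(np.abs(scaled), axis=1, keepdims=True)
    factor = np.minimum(1.0, _MAX_TOTAL_AMPLITUDE / np.maximum(total, 1e-12))
    return scaled * factor


# ------------------------------------------------------------- population

def sample_population(params: PopulationParams) -> list[VesicleGroundTruth]:
    """Draw a seeded synthetic population of vesicles.

    Diameters come from the truncated lognormal size law; contour roughness
    amplitudes are drawn per vesicle and rescaled globally (by a bracketed
    root find on the numerically evaluated mean) so the population mean of
    ``true_ipq`` matches ``params.target_mean_ipq`` within +/-0.01; settling
    times follow the Stokes sedimentation model.  Centers are placed by
    rejection sampling with a small clearance so vesicles rarely touch,
    mirroring the dilution used to keep micrographs segmentable.
    """
    params.validate()
    if params.n_vesicles == 0:
        return []
    rng = np.random.default_rng(params.seed)
    n = params.n_vesicles

    mu, sig = params.diam_lognormal_mu, params.diam_lognormal_sigma
    lo = (math.log(params.diam_min) - mu) / sig
    hi = (math.log(params.diam_max) - mu) / sig
    diameters = np.exp(truncnorm.rvs(lo, hi, loc=mu, scale=sig, size=n, random_state=rng))

    # raw roughness: heavier weight on low harmonics, random phases
    raw_amps = np.abs(rng.normal(0.0, 1.0, size=(n, _HARMONICS.size))) / _HARMONICS[None, :]
    phases = rng.uniform(0.0, 2.0 * math.pi, size=(n, _HARMONICS.size))
    theta = np.linspace(0.0, 2.0 * math.pi, _N_VERTICES, endpoint=False)

    def mean_ipq(scale: float) -> float:
        return float(np.mean(_batch_ipq(_clip_amplitudes(raw_amps, scale), phases, theta)))

    target = params.target_mean_ipq
    if target >= mean_ipq(0.0) - 1e-12:  # circles (target == 1)
        scale = 0.0
    else:
        s_hi = 2.0
        if mean_ipq(s_hi) > target:
            raise ParameterError(
                "target_mean_ipq too low to reach with simple star-shaped contours"
            )
        scale = brentq(lambda s: mean_ipq(s) - target, 0.0, s_hi, xtol=1e-6)
    amps = _clip_amplitudes(raw_amps, scale)

    # per-vesicle contours at unit nominal radius, then area-normalized so the
    # polygon area is exactly consistent with the drawn diameter
    r_unit = np.ones((n, theta.size))
    for i, k in enumerate(_HARMONICS):
        r_unit += amps[:, i, None] * np.cos(k * theta[None, :] + phases[:, i, None])
    rows_u = r_unit * np.sin(theta)[None, :]
    cols_u = r_unit * np.cos(theta)[None, :]
    area_u, perim_u = _polygon_area_perimeter(rows_u, cols_u)
    ipq = 4.0 * math.pi * area_u / perim_u**2
    # radius factor giving polygon area == pi * (d/2)^2
    radius_factor = (math.pi * (diameters / 2.0) ** 2 / area_u) ** 0.5

    sed = SedimentationParams()
    settled = rng.exponential(1.0 / sed.rate_per_min(diameters))

    centers = _place_centers(rng, diameters, amps, params)

    vesicles: list[VesicleGroundTruth] = []
    order = np.arange(n)
    for i in order:
        rr = centers[i, 0] + radius_factor[i] * rows_u[i]
        cc = centers[i, 1] + radius_factor[i] * cols_u[i]
        contour = np.column_stack([np.append(rr, rr[0]), np.append(cc, cc[0])])
        vesicles.append(
            VesicleGroundTruth(
                id=int(i),
                center_rc_um=(float(centers[i, 0]), float(centers[i, 1])),
                diameter_um=float(diameters[i]),
                contour_um=contour,
                true_ipq=float(ipq[i]),
                settled_at_min=float(settled[i]),
                amplitudes=amps[i] * 1.0,
                phases=phases[i] * 1.0,
            )
        )
    return vesicles


def _place_centers(rng, diameters, amps, params):
    """Placement with clearance by grid-hashed rejection sampling, largest first.

    When the requested population is too dense for clearance placement
    (projected fill fraction above 30%), centers fall back to plain uniform
    placement -- such populations model suspensions before dilution, where
    overlap is physical anyway.
    """
    n = diameters.size
    h, w = params.chamber_um
    max_r = diameters / 2.0 * (1.0 + np.sum(np.abs(amps), axis=1))
    fill = float(np.sum(np.pi * max_r**2) / (h * w))
    lo_r = np.minimum(max_r, h / 2)
    hi_r = np.maximum(h - max_r, h / 2)
    lo_c = np.minimum(max_r, w / 2)
    hi_c = np.maximum(w - max_r, w / 2)
    if fill > 0.3:
        rows = rng.uniform(lo_r, hi_r)
        cols = rng.uniform(lo_c, hi_c)
        return np.column_stack([rows, cols])

    gap = 1.0  # um clearance between membranes
    cell = max(2.0 * float(max_r.max()) + gap, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    centers = np.zeros((n, 2))

    def neighbors(cand):
        ci, cj = int(cand[0] // cell), int(cand[1] // cell)
        out = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                out.extend(grid.get((ci + di, cj + dj), ()))
        return out

    for i in np.argsort(-diameters, kind="stable"):
        r = max_r[i]
        best = None
        best_clear = -np.inf
        for _ in range(100):
            cand = np.array([rng.uniform(lo_r[i], hi_r[i]), rng.uniform(lo_c[i], hi_c[i])])
            near = neighbors(cand)
            if near:
                d = np.hypot(*(centers[near] - cand).T)
                clear = float(np.min(d - max_r[near] - r))
            else:
                clear = np.inf
            if clear >= gap:
                best = cand
                break
            if clear > best_clear:
                best_clear, best = clear, cand
        centers[i] = best
        grid.setdefault((int(best[0] // cell), int(best[1] // cell)), []).append(int(i))
    return centers


def sample_distractors(params: PopulationParams, render: RenderParams | None = None,
                       seed_offset: int = 1) -> list[Distractor]:
    """Draw crystallized-lipid distractor blobs at ``distractor_rate`` per frame area.

    Blobs carry strong high-order radial harmonics, giving the deeply
    non-convex outlines (low solidity) that let the segmentation layer flag
    them for expert review.
    """
    params.validate()
    render = render or RenderParams()
    rng = np.random.default_rng(params.seed + seed_offset)
    h, w = params.chamber_um
    frame_area = (render.frame_shape[0] * render.pixel_size_um) * (
        render.frame_shape[1] * render.pixel_size_um
    )
    expected = params.distractor_rate * (h * w) / frame_area
    count = int(rng.poisson(expected))
    out = []
    ks = np.arange(3, 9)
    for i in range(count):
        radius = float(rng.uniform(2.0, 8.0))
        amps_k = rng.uniform(0.05, 0.12, size=ks.size) * (ks / 3.0)
        phases_k = rng.uniform(0, 2 * math.pi, size=ks.size)
        center = (float(rng.uniform(0, h)), float(rng.uniform(0, w)))
        out.append(Distractor(i, center, radius, amps_k, phases_k))
    return out


# ----------------------------------------------------------- sedimentation

def simulate_sedimentation(diameter_um, time_min, sed_params: SedimentationParams | None = None):
    """Probability that a vesicle of given diameter is visible after ``time_min``.

    Implements ``p = 1 - exp(-t * v(d) / H)`` with Stokes settling speed
    ``v(d) = c d^2``; monotonically non-decreasing in both diameter and time.
    Accepts scalars or arrays.
    """
    sed = sed_params or SedimentationParams()
    d = np.asarray(diameter_um, dtype=float)
    t = np.asarray(time_min, dtype=float)
    if np.any(d <= 0):
        raise ParameterError("diameter_um must be > 0")
    if np.any(t < 0):
        raise ParameterError("time_min must be >= 0")
    p = 1.0 - np.exp(-t * sed.rate_per_min(d))
    if p.ndim == 0:
        return float(p)
    return p


def visible_at(vesicles: list[VesicleGroundTruth], time_min: float) -> list[VesicleGroundTruth]:
    """Vesicles that have settled into the focal plane by ``time_min``."""
    if time_min < 0:
        raise ParameterError("time_min must be >= 0")
    return [v for v in vesicles if v.settled_at_min <= time_min]


# -------------------------------------------------------------- rendering

def _radial_field(shape, center_px, origin_px):
    rows = np.arange(shape[0])[:, None] - (center_px[0] - origin_px[0])
    cols = np.arange(shape[1])[None, :] - (center_px[1] - origin_px[1])
    return np.hypot(rows, cols), np.arctan2(rows, cols)


def render_frame(
    vesicles: list[VesicleGroundTruth],
    view_origin_um: tuple[float, float],
    render_params: RenderParams,
    distractors: list[Distractor] = (),
    rng: np.random.Generator | None = None,
) -> RenderedFrame:
    """Render one bright-field frame plus its ground-truth label mask.

    The view window starts at ``view_origin_um`` (row, col in chamber
    micrometres).  Vesicles are dark rings whose outer edge sits on the true
    contour; the mask labels exactly the vesicles lying fully inside the
    view, in list order.  Distractors are filled irregular blobs and stay
    background (0) in the mask.
    """
    render_params.validate()
    p = render_params
    shape = tuple(p.frame_shape)
    pix = p.pixel_size_um
    canvas = np.full(shape, p.background_level, dtype=float)
    mask = np.zeros(shape, dtype=np.uint16)
    origin_px = (view_origin_um[0] / pix, view_origin_um[1] / pix)
    vesicle_ids: list[int] = []

    def local_window(center_px, reach_px):
        r0 = int(np.floor(center_px[0] - origin_px[0] - reach_px)) - 2
        r1 = int(np.ceil(center_px[0] - origin_px[0] + reach_px)) + 3
        c0 = int(np.floor(center_px[1] - origin_px[1] - reach_px)) - 2
        c1 = int(np.ceil(center_px[1] - origin_px[1] + reach_px)) + 3
        return max(r0, 0), min(r1, shape[0]), max(c0, 0), min(c1, shape[1])

    label = 0
    for v in vesicles:
        center_px = (v.center_rc_um[0] / pix, v.center_rc_um[1] / pix)
        reach = v.max_radius_um / pix + 3 * p.ring_width_px
        r0, r1, c0, c1 = local_window(center_px, reach)
        if r0 >= r1 or c0 >= c1:
            continue
        sub = (slice(r0, r1), slice(c0, c1))
        rows = np.arange(r0, r1)[:, None] - (center_px[0] - origin_px[0])
        cols = np.arange(c0, c1)[None, :] - (center_px[1] - origin_px[1])
        rho = np.hypot(rows, cols)
        theta = np.arctan2(rows, cols)
        r_contour = (v.radius_um / pix) * _harmonic_radii(theta, v.amplitudes, v.phases)
        ring_center = r_contour - p.ring_width_px
        canvas[sub] -= p.ring_contrast * np.exp(
            -0.5 * ((rho - ring_center) / p.ring_width_px) ** 2
        )
        canvas[sub] += p.interior_offset * (rho < ring_center - 1.5 * p.ring_width_px)

        fully_inside = (
            center_px[0] - origin_px[0] - reach >= 0
            and center_px[1] - origin_px[1] - reach >= 0
            and center_px[0] - origin_px[0] + reach <= shape[0]
            and center_px[1] - origin_px[1] + reach <= shape[1]
        )
        if fully_inside:
            label += 1
            mask[sub][rho <= r_contour] = label
            vesicle_ids.append(v.id)

    for d in distractors:
        center_px = (d.center_rc_um[0] / pix, d.center_rc_um[1] / pix)
        reach = d.max_radius_um / pix
        r0, r1, c0, c1 = local_window(center_px, reach)
        if r0 >= r1 or c0 >= c1:
            continue
        sub = (slice(r0, r1), slice(c0, c1))
        rows = np.arange(r0, r1)[:, None] - (center_px[0] - origin_px[0])
        cols = np.arange(c0, c1)[None, :] - (center_px[1] - origin_px[1])
        rho = np.hypot(rows, cols)
        theta = np.arctan2(rows, cols)
        r_blob = np.full_like(theta, d.radius_um / pix)
        for k, a, ph in zip(np.arange(3, 9), d.amplitudes, d.phases):
            r_blob *= 1.0 + a * np.cos(k * theta + ph) / (1.0 + a)
        canvas[sub] -= 0.6 * p.ring_contrast * (rho <= r_blob)

    if p.noise_sigma > 0:
        rng = rng if rng is not None else np.random.default_rng(p.seed)
        canvas = canvas + rng.normal(0.0, p.noise_sigma, size=shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return RenderedFrame(image=image, mask=mask, vesicle_ids=vesicle_ids)


# ----------------------------------------------------------------- tracks

def generate_track(
    population: list[VesicleGroundTruth],
    motion_model: MotionModel,
    n_frames: int,
    render_params: RenderParams,
    distractors: list[Distractor] = (),
    start_um: tuple[float, float] = (0.0, 0.0),
) -> tuple[Track, np.ndarray]:
    """Render a camera track over the population and return true frame offsets.

    The camera starts at ``start_um`` and advances along ``motion_model.axis``
    by a normal step (mean ``step_mean_px``, sd ``step_jitter_px``) per frame
    with small transverse jitter; cumulative offsets are rounded to integer
    pixels and returned (shape ``(n_frames, 2)``, first row zero) for
    validating the stitcher.
    """
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    render_params.validate()
    extent = render_params.frame_shape[motion_model.axis]
    if abs(motion_model.step_mean_px) > 0.75 * extent:
        raise ParameterError(
            "step_mean_px motion leaves less than 25% frame overlap"
        )
    rng = np.random.default_rng(render_params.seed)
    steps_along = motion_model.step_mean_px + rng.normal(
        0.0, motion_model.step_jitter_px, size=n_frames - 1
    )
    steps_cross = rng.normal(0.0, motion_model.transverse_jitter_px, size=n_frames - 1)
    cum = np.zeros((n_frames, 2))
    cum[1:, motion_model.axis] = np.cumsum(steps_along)
    cum[1:, 1 - motion_model.axis] = np.cumsum(steps_cross)
    offsets = np.rint(cum).astype(int)

    pix = render_params.pixel_size_um
    frames = []
    for i in range(n_frames):
        origin = (
            start_um[0] + offsets[i, 0] * pix,
            start_um[1] + offsets[i, 1] * pix,
        )
        rf = render_frame(population, origin, render_params, distractors, rng=rng)
        frames.append(rf.image)
    return Track(frames=frames, pixel_size_um=pix), offsets


# -------------------------------------------------------------------- I/O

def write_track(directory, track: Track, fmt: str = "png") -> list[Path]:
    """Write frames as zero-padded numbered images; returns the paths."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(len(track.frames))))
    paths = []
    for i, frame in enumerate(track.frames):
        path = directory / f"frame_{i:0{width}d}.{fmt}"
        iio.imwrite(path, frame)
        paths.append(path)
    return paths


def write_ground_truth(directory, vesicles, mask=None, params=None) -> None:
    """Write ground truth: CSV of vesicles, 16-bit label TIFF, JSON manifest."""
    import pandas as pd
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "id": v.id,
            "center_row_um": v.center_rc_um[0],
            "center_col_um": v.center_rc_um[1],
            "diameter_um": v.diameter_um,
            "true_ipq": v.true_ipq,
            "settled_at_min": v.settled_at_min,
        }
        for v in vesicles
    ]
    pd.DataFrame(rows).to_csv(directory / "ground_truth.csv", index=False)
    if mask is not None:
        tifffile.imwrite(directory / "ground_truth_mask.tif", mask.astype(np.uint16))
    manifest = {"n_vesicles": len(vesicles)}
    if params is not None:
        manifest["params"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(params).items()
        }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
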