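"""Synthetic-data generators with ground truth for every pipeline stage.

No public imaging data accompanies the study this pipeline supports, so
every downstream stage is validated against generated inputs whose ground
truth is known exactly: two-channel elliptical cluster fields along a
membrane line (sharing the placement code path, so the attraction between
channels is known), localization-style rendered images of those fields,
fiducial pairs under a known affine map, analytic height maps, and
particle stacks with recorded poses.

All generators are deterministic under their integer seed; each call uses
a single ``numpy.random.default_rng(seed)`` stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .clusters import ReconstructedImage
from .geometry import Ellipse, ellipse_edge_distance
from .placement import (
    DEFAULT_REJECTION_CAP,
    PlacementFailure,
    _propose,
    place_query,
    place_reference,
)
from .registration import AffineTransform2D, transform_points
from .topology import HeightMap

__all__ = [
    "GroundTruthField",
    "ParticleStackTruth",
    "default_size_sampler",
    "gen_ellipse_field",
    "render_localization_image",
    "gen_fiducial_pairs",
    "gen_height_map",
    "gen_particle_stack",
    "default_particle_template",
]


@dataclass
class GroundTruthField:
    """A simulated two-channel cluster field in a membrane box.

    The box is ``box_length`` x 2*halfwidth nm with the membrane line
    running horizontally through its middle.
    """

    reference_ellipses: list[Ellipse]
    query_ellipses: list[Ellipse]
    membrane_line: np.ndarray  # (n, 2) nm
    box_length: float
    box_halfwidth_nm: float
    attraction_f: float
    seed: int


@dataclass
class ParticleStackTruth:
    """Synthetic particle stack with per-particle ground-truth poses.

    ``particles`` has shape (n, 2, box, box); ``poses`` rows are
    (shift_x_px, shift_y_px, rotation_deg) applied to the template to make
    each particle (rotation about the box center, then shift).
    """

    particles: np.ndarray
    template: np.ndarray  # (2, box, box)
    poses: np.ndarray  # (n, 3)
    noise_level: float


def default_size_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """Log-normal cluster sizes at plausible SMLM cluster scales.

    Semi-major axis ~ LogNormal(median 90 nm, sigma 0.3); semi-minor is
    the major times Uniform(0.5, 0.9).  The experimental size list is not
    published, so any empirical sampler can be plugged in instead.
    """
    major = np.exp(rng.normal(np.log(90.0), 0.3, size=n))
    minor = major * rng.uniform(0.5, 0.9, size=n)
    return np.column_stack([major, minor])


def gen_ellipse_field(
    box_length: float,
    n_ref: int,
    n_query: int,
    size_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    attraction_f: float = 1.0,
    seed: int = 0,
    *,
    box_halfwidth_nm: float = 500.0,
    min_clearance_nm: float = 0.0,
    edge_margin_nm: float = 0.0,
    rejection_cap: int = DEFAULT_REJECTION_CAP,
) -> GroundTruthField:
    """Generate a two-channel ellipse field by the placement algorithm itself.

    Reference ellipses are placed uniformly without mutual overlap; query
    ellipses follow the attraction rejection scheme with factor
    ``attraction_f`` (1 = uniform), through the same code path as the
    placement Monte Carlo, so the generating attraction is known exactly.

    ``min_clearance_nm > 0`` switches to a well-separated layout (every
    pair of ellipses at least that far apart edge-to-edge, query placement
    uniform, centers kept ``edge_margin_nm`` away from the field borders)
    for validating detection round-trips; it is not a model of attraction
    and requires ``attraction_f == 1``.
    """
    if box_length <= 0:
        raise ValueError("box_length must be positive")
    if n_ref < 0 or n_query < 0:
        raise ValueError("counts must be >= 0")
    if attraction_f < 1:
        raise ValueError("attraction_f must be >= 1")
    rng = np.random.default_rng(seed)
    sampler = size_sampler or default_size_sampler
    height = 2.0 * box_halfwidth_nm
    ref_sizes = sampler(rng, n_ref)
    qry_sizes = sampler(rng, n_query)
    if min_clearance_nm > 0:
        if attraction_f != 1.0:
            raise ValueError("min_clearance_nm requires attraction_f == 1")
        placed: list[Ellipse] = []
        sizes = list(ref_sizes) + list(qry_sizes)
        m = edge_margin_nm
        for i, size in enumerate(sizes):
            for _ in range(rejection_cap):
                cand = _propose(box_length, height, size, rng)
                if not (m <= cand.cx <= box_length - m and m <= cand.cy <= height - m):
                    continue
                if all(
                    ellipse_edge_distance(cand, e) >= min_clearance_nm for e in placed
                ):
                    placed.append(cand)
                    break
            else:
                raise PlacementFailure(f"ellipse {i} could not be placed with clearance")
        ref, qry = placed[:n_ref], placed[n_ref:]
    else:
        ref = place_reference(box_length, height, ref_sizes, rng, rejection_cap)
        qry = place_query(box_length, height, ref, qry_sizes, attraction_f, rng, rejection_cap)
    line = np.array([[0.0, box_halfwidth_nm], [box_length, box_halfwidth_nm]])
    return GroundTruthField(ref, qry, line, box_length, box_halfwidth_nm, attraction_f, seed)


def _sample_in_ellipse(e: Ellipse, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside an ellipse (unit-disc mapping)."""
    r = np.sqrt(rng.uniform(0.0, 1.0, n))
    phi = rng.uniform(0.0, 2 * np.pi, n)
    u = np.column_stack([e.a * r * np.cos(phi), e.b * r * np.sin(phi)])
    th = np.deg2rad(e.angle_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return u @ R.T + np.array([e.cx, e.cy])


def render_localization_image(
    field: GroundTruthField,
    pixel_nm: float = 20.0,
    density: float = 0.01,
    precision_nm: float = 10.0,
    seed: int = 0,
) -> ReconstructedImage:
    """Render a field as a two-channel localization-count image.

    Per ellipse, ``Poisson(density * area)`` localizations are drawn
    uniformly inside it, jittered by isotropic Gaussian noise of scale
    ``precision_nm`` (the localization precision), and binned into pixels
    of ``pixel_nm``.  Localizations jittered outside the field of view are
    discarded.  Channel 0 is 'reference', channel 1 'query'.
    """
    if pixel_nm <= 0 or density <= 0:
        raise ValueError("pixel_nm and density must be positive")
    rng = np.random.default_rng(seed)
    width = int(np.ceil(field.box_length / pixel_nm))
    height = int(np.ceil(2.0 * field.box_halfwidth_nm / pixel_nm))
    data = np.zeros((2, height, width))
    for ci, ellipses in enumerate((field.reference_ellipses, field.query_ellipses)):
        for e in ellipses:
            n = rng.poisson(density * e.area)
            if n == 0:
                continue
            pts = _sample_in_ellipse(e, n, rng)
            if precision_nm > 0:
                pts = pts + rng.normal(0.0, precision_nm, size=pts.shape)
            cols = np.floor(pts[:, 0] / pixel_nm).astype(int)
            rows = np.floor(pts[:, 1] / pixel_nm).astype(int)
            ok = (cols >= 0) & (cols < width) & (rows >= 0) & (rows < height)
            np.add.at(data[ci], (rows[ok], cols[ok]), 1.0)
    return ReconstructedImage(data, pixel_nm=pixel_nm, channel_names=("reference", "query"))


def gen_fiducial_pairs(
    transform: AffineTransform2D,
    n: int,
    noise_nm: float = 0.0,
    seed: int = 0,
    fov_nm: float = 10_000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched fiducial pairs under a known affine map plus Gaussian noise.

    Source points are uniform in a ``fov_nm`` x ``fov_nm`` field of view;
    targets are ``transform(source) + N(0, noise_nm)`` per coordinate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    src = rng.uniform(0.0, fov_nm, size=(n, 2))
    dst = transform_points(src, transform)
    if noise_nm > 0:
        dst = dst + rng.normal(0.0, noise_nm, size=dst.shape)
    return src, dst


def gen_height_map(
    kind: str,
    amplitude: float = 100.0,
    period: float = 500.0,
    extent: float = 4000.0,
    spacing: float = 20.0,
) -> HeightMap:
    """Analytic height maps: flat, sinusoid, or a square lattice of bumps.

    flat: z = 0.  sinusoid: z = A sin(2 pi x / period).  bump_lattice:
    Gaussian bumps (sigma = period / 6) of height A centered on a square
    lattice of pitch ``period``.  The period must exceed twice the grid
    spacing (Nyquist).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if kind not in ("flat", "sinusoid", "bump_lattice"):
        raise ValueError(f"unknown height-map kind {kind!r}")
    if kind != "flat" and period <= 2 * spacing:
        raise ValueError(f"period {period} nm aliases at spacing {spacing} nm")
    n = int(np.round(extent / spacing)) + 1
    x = np.arange(n) * spacing
    if kind == "flat":
        z = np.zeros((n, n))
    elif kind == "sinusoid":
        z = np.tile(amplitude * np.sin(2 * np.pi * x / period), (n, 1))
    else:
        xx, yy = np.meshgrid(x, x)
        z = np.zeros((n, n))
        sigma = period / 6.0
        centers = np.arange(period / 2.0, extent, period)
        for cx in centers:
            for cy in centers:
                z += amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    return HeightMap(z, spacing)


def default_particle_template(box_px: int = 100) -> np.ndarray:
    """Asymmetric two-channel binary template for alignment tests.

    Channel 0 ('reference', the first-alignment channel) holds a disc plus
    a small satellite blob breaking rotational symmetry; channel 1
    ('secondary') holds an offset ellipse, the two overlapping near the
    box center as co-localized cluster pairs do.
    """
    c = box_px / 2.0
    yy, xx = np.mgrid[0:box_px, 0:box_px] + 0.5
    ref = ((xx - (c - 8)) ** 2 + (yy - c) ** 2 <= 12**2) | (
        (xx - (c + 14)) ** 2 + (yy - (c + 10)) ** 2 <= 5**2
    )
    qry = ((xx - (c + 6)) ** 2 / 16**2 + (yy - (c - 4)) ** 2 / 8**2) <= 1.0
    return np.stack([ref.astype(float), qry.astype(float)])


def gen_particle_stack(
    template: np.ndarray | None = None,
    n: int = 50,
    max_shift_px: float = 10.0,
    max_rot_deg: float = 30.0,
    noise_level: float = 0.1,
    seed: int = 0,
    box_px: int = 100,
) -> ParticleStackTruth:
    """Particle stack: the template under recorded poses plus Gaussian noise.

    Each particle is the template rotated about the box center by a
    uniform angle in [-max_rot, max_rot] and shifted by a uniform integer
    offset in [-max_shift, max_shift] per axis (both channels with the
    same pose), plus additive Gaussian noise of ``noise_level`` times the
    template intensity range.  Poses are stored as ground truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if template is None:
        template = default_particle_template(box_px)
    template = np.asarray(template, dtype=float)
    if template.ndim != 3 or template.shape[0] != 2:
        raise ValueError("template must have shape (2, box, box)")
    box = template.shape[1]
    if max_shift_px > box / 2:
        raise ValueError("max_shift_px exceeds half the box size")
    rng = np.random.default_rng(seed)
    shifts = rng.integers(-int(max_shift_px), int(max_shift_px) + 1, size=(n, 2))
    rots = rng.uniform(-max_rot_deg, max_rot_deg, size=n)
    rng_scale = float(np.ptp(template)) or 1.0
    particles = np.empty((n, 2, box, box))
    for i in range(n):
        for ch in range(2):
            img = ndimage.rotate(template[ch], rots[i], reshape=False, order=1)
            img = np.roll(img, (shifts[i, 1], shifts[i, 0]), axis=(0, 1))
            if noise_level > 0:
                img = img + rng.normal(0.0, noise_level * rng_scale, size=img.shape)
            particles[i, ch] = img
    poses = np.column_stack([shifts[:, 0], shifts[:, 1], rots])
    return ParticleStackTruth(particles, template, poses, noise_level)
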