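"""Membrane-surface topology from height maps.

The plicate region of the intercalated disc folds into regularly spaced
peaks and valleys that greatly amplify the true membrane area over its
planform projection.  Given a height map z(x, y) on a regular grid (nm),
this module computes the surface-area amplification factor, detects peaks,
measures nearest-neighbour peak spacing in 3D and in 2D projection, and
extracts the dominant spatial period from the Fourier spectrum of the
projected peak positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import label, regionprops
from skimage.morphology import h_maxima

__all__ = [
    "HeightMap",
    "PeakSet",
    "amplification_factor",
    "detect_peaks",
    "peak_spacing_stats",
    "periodicity_spectrum",
]


@dataclass
class HeightMap:
    """Heights z (nm) on a regular grid with lateral spacing (nm).

    ``z[i, j]`` sits at (x, y) = (j * spacing, i * spacing); an optional
    boolean mask marks valid samples.
    """

    z: np.ndarray
    spacing_nm: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.spacing_nm <= 0:
            raise ValueError("spacing_nm must be positive")
        if self.mask is None:
            self.mask = np.ones_like(self.z, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.z.shape:
                raise ValueError("mask shape must match z shape")
        if not np.all(np.isfinite(self.z[self.mask])):
            raise ValueError("non-finite heights on valid samples")


@dataclass
class PeakSet:
    """Detected peaks as (x, y, z) nm rows plus a snapshot of the detector settings."""

    coords_nm: np.ndarray  # (n, 3)
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.coords_nm)


def amplification_factor(surface: HeightMap) -> float:
    """Triangulated 3D surface area over projected (planform) area; >= 1.

    Each grid cell whose four corners are valid contributes two triangles
    split along the same diagonal (top-left to bottom-right by default).
    """
    z, h, m = surface.z, surface.spacing_nm, surface.mask
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("need at least a 2x2 grid")
    valid = m[:-1, :-1] & m[1:, :-1] & m[:-1, 1:] & m[1:, 1:]
    if not valid.any():
        raise ValueError("no fully valid grid cell")
    z00, z10 = z[:-1, :-1], z[1:, :-1]
    z01, z11 = z[:-1, 1:], z[1:, 1:]
    # triangle (00, 01, 11) and (00, 11, 10); cross-product areas
    area = _tri_area(z00, z01, z11, h, (0, 1), (1, 1)) + _tri_area(
        z00, z11, z10, h, (1, 1), (1, 0)
    )
    total = float(area[valid].sum())
    projected = float(valid.sum()) * h * h
    return total / projected


def _tri_area(za, zb, zc, h, db, dc):
    """Area of triangles over one grid cell; db/dc are (row, col) steps of b, c from a."""
    u = np.array([dc[1] * h, dc[0] * h], dtype=float)
    v = np.array([db[1] * h, db[0] * h], dtype=float)
    # vectors a->c = (u, zc-za), a->b = (v, zb-za); |cross| / 2
    dz_c = zc - za
    dz_b = zb - za
    cx = u[1] * dz_b - v[1] * dz_c
    cy = v[0] * dz_c - u[0] * dz_b
    cz = u[0] * v[1] - u[1] * v[0]
    return 0.5 * np.sqrt(cx**2 + cy**2 + cz**2)


def detect_peaks(
    surface: HeightMap,
    min_distance_nm: float,
    min_prominence_nm: float,
) -> PeakSet:
    """Local maxima filtered by prominence and minimum separation.

    Prominence filtering uses the h-maxima transform (a maximum survives if
    it stands at least ``min_prominence_nm`` above the level at which its
    basin merges with a higher one).  Minimum separation is enforced
    greedily, higher peak winning.
    """
    if min_distance_nm <= 0 or min_prominence_nm <= 0:
        raise ValueError("detection parameters must be positive")
    z = surface.z.copy()
    zmin = z[surface.mask].min() if surface.mask.any() else 0.0
    z[~surface.mask] = zmin
    if np.ptp(z) == 0:
        return PeakSet(np.empty((0, 3)), _peak_params(min_distance_nm, min_prominence_nm))
    hmax = h_maxima(z, min_prominence_nm)
    peaks = []
    for region in regionprops(label(hmax, connectivity=2)):
        i, j = region.centroid
        ii, jj = int(round(i)), int(round(j))
        if not surface.mask[ii, jj]:
            continue
        peaks.append((j * surface.spacing_nm, i * surface.spacing_nm, z[ii, jj]))
    if not peaks:
        return PeakSet(np.empty((0, 3)), _peak_params(min_distance_nm, min_prominence_nm))
    coords = np.array(peaks)
    order = np.argsort(-coords[:, 2], kind="stable")  # highest first
    kept: list[np.ndarray] = []
    for idx in order:
        p = coords[idx]
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_distance_nm for q in kept):
            kept.append(p)
    return PeakSet(np.array(kept), _peak_params(min_distance_nm, min_prominence_nm))


def _peak_params(d, p):
    return {"min_distance_nm": d, "min_prominence_nm": p}


def peak_spacing_stats(
    peaks: PeakSet, mode: str = "3d", bin_nm: float = 100.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-peak nearest-neighbour distances and their histogram.

    ``mode='3d'`` uses full (x, y, z); ``mode='projected_2d'`` drops z.
    Returns (distances_nm, hist_counts, bin_edges_nm).
    """
    if mode not in ("3d", "projected_2d"):
        raise ValueError("mode must be '3d' or 'projected_2d'")
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks for spacing statistics")
    pts = peaks.coords_nm if mode == "3d" else peaks.coords_nm[:, :2]
    d, _ = cKDTree(pts).query(pts, k=2)
    nn = d[:, 1]
    edges = np.arange(0.0, nn.max() + bin_nm, bin_nm)
    if len(edges) < 2:
        edges = np.array([0.0, bin_nm])
    hist, edges = np.histogram(nn, bins=edges)
    return nn, hist, edges


def periodicity_spectrum(
    peaks: PeakSet,
    render_sigma_nm: float = 50.0,
    pixel_nm: float = 20.0,
    extent_nm: float | None = None,
) -> dict:
    """Dominant spatial period of the projected peak arrangement via 2D FFT.

    The projected peak positions are rendered as Gaussian spots on a black
    background, the power spectrum computed, and the strongest non-DC
    radial frequency converted to a period (nm).  Returns a dict with the
    power spectrum, the radial profile, ``dominant_period_nm`` (nan when no
    non-DC structure exists) and a ``flagged`` bool mirroring that case or
    a field shorter than two periods.
    """
    if len(peaks) < 1:
        raise ValueError("need at least one peak")
    xy = peaks.coords_nm[:, :2]
    if extent_nm is None:
        extent_nm = float(max(xy.max() - xy.min() if len(xy) > 1 else 0.0, 1.0) + 6 * render_sigma_nm)
    n = max(int(np.ceil(extent_nm / pixel_nm)), 8)
    img = np.zeros((n, n))
    origin = xy.min(axis=0) - 3 * render_sigma_nm if len(xy) > 1 else xy[0] - extent_nm / 2
    idx = np.round((xy - origin) / pixel_nm).astype(int)
    ok = (idx >= 0).all(axis=1) & (idx < n).all(axis=1)
    img[idx[ok, 1], idx[ok, 0]] = 1.0
    img = ndimage.gaussian_filter(img, render_sigma_nm / pixel_nm)

    power = np.abs(np.fft.fftshift(np.fft.fft2(img))) ** 2
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=pixel_nm))
    fy, fx = np.meshgrid(freqs, freqs, indexing="ij")
    fr = np.hypot(fx, fy)

    # radial profile of power vs frequency
    nbins = n // 2
    fmax = freqs.max() if freqs.max() > 0 else 1.0
    rbin = np.minimum((fr / fmax * (nbins - 1)).astype(int), nbins - 1)
    radial = np.bincount(rbin.ravel(), weights=power.ravel(), minlength=nbins)
    counts = np.bincount(rbin.ravel(), minlength=nbins)
    radial = radial / np.maximum(counts, 1)
    radial_freq = (np.arange(nbins) + 0.5) / (nbins) * fmax

    nondc = fr > (1.5 / extent_nm)  # exclude DC and its immediate neighbourhood
    flagged = False
    if len(peaks) < 2 or not nondc.any() or power[nondc].max() <= 0:
        dominant = float("nan")
        flagged = True
    else:
        k = np.unravel_index(np.argmax(np.where(nondc, power, 0.0)), power.shape)
        fdom = fr[k]
        dominant = float(1.0 / fdom)
        if extent_nm < 2 * dominant:
            flagged = True
    return {
        "power": power,
        "freq_nm_inv": freqs,
        "radial_profile": np.column_stack([radial_freq, radial]),
        "dominant_period_nm": dominant,
        "frequency_bin_nm_inv": 1.0 / extent_nm,
        "flagged": flagged,
    }
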