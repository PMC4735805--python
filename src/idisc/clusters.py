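"""Cluster detection and inter-cluster distance statistics for SMLM images.

The workflow mirrors standard super-resolution cluster analysis: a
reconstructed image (20 nm/px by default) is smoothed, rescaled and
thresholded into a binary mask; connected components above a minimum size
become clusters with centroid, area (or volume in 3D), circularity and a
boundary representation; analysis is restricted to a band around the
intercalated-disc membrane line (500 nm on either side by default); and
nearest-neighbour distances between a query species (e.g. Nav1.5) and a
reference species (e.g. N-cadherin) are summarised as a contact fraction
plus a 100-nm-binned histogram.  Contact means edge-to-edge distance <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .geometry import Ellipse, ellipse_edge_distance

__all__ = [
    "ReconstructedImage",
    "Cluster",
    "MembraneMask",
    "DistanceRecord",
    "binarize",
    "detect_clusters",
    "filter_by_membrane",
    "nn_distances",
    "distance_summary",
    "clusters_from_ellipses",
]

DEFAULT_PIXEL_NM = 20.0
DEFAULT_HALFWIDTH_NM = 500.0


@dataclass
class ReconstructedImage:
    """Multi-channel raster with physical pixel size.

    ``data`` has shape (channels, y, x) for 2D or (channels, z, y, x) for a
    z-stack; ``channel_names`` labels axis 0.
    """

    data: np.ndarray
    pixel_nm: float = DEFAULT_PIXEL_NM
    channel_names: Sequence[str] = ("ch0",)
    z_step_nm: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (C, Y, X) or (C, Z, Y, X)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names must match data channels")
        if self.data.ndim == 4 and not self.z_step_nm:
            raise ValueError("z_step_nm required for z-stacks")

    @property
    def is_3d(self) -> bool:
        return self.data.ndim == 4

    def channel(self, name: str) -> np.ndarray:
        try:
            i = list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {list(self.channel_names)}")
        return self.data[i]


@dataclass
class Cluster:
    """A detected (raster) or parametric (ellipse) cluster.

    Raster clusters carry their pixel/voxel index set and boundary subset
    plus the physical scale per axis; parametric clusters carry an Ellipse.
    Centroids are in nm, ordered (x, y[, z]).
    """

    id: int
    channel: str
    centroid_nm: np.ndarray
    area_nm2: float | None = None
    volume_nm3: float | None = None
    circularity: float | None = None
    pixels: np.ndarray | None = None  # (n, dim) integer indices, (row, col[, plane-first])
    boundary_pixels: np.ndarray | None = None
    scale_nm: np.ndarray | None = None  # physical size per index axis
    ellipse: Ellipse | None = None

    @property
    def is_parametric(self) -> bool:
        return self.ellipse is not None


@dataclass
class MembraneMask:
    """Band of ``halfwidth_nm`` on either side of the ID membrane polyline."""

    polyline_nm: np.ndarray  # (n, 2)
    halfwidth_nm: float = DEFAULT_HALFWIDTH_NM

    def __post_init__(self) -> None:
        self.polyline_nm = np.asarray(self.polyline_nm, dtype=float).reshape(-1, 2)
        if len(self.polyline_nm) < 2:
            raise ValueError("membrane polyline needs at least 2 vertices")
        if self.halfwidth_nm <= 0:
            raise ValueError("halfwidth_nm must be positive")


@dataclass
class DistanceRecord:
    query_id: int
    reference_id: int
    centroid_to_centroid_nm: float
    edge_to_edge_nm: float

    @property
    def contact(self) -> bool:
        return self.edge_to_edge_nm <= 0.0


def binarize(
    image: ReconstructedImage,
    channel: str,
    smooth_radius_px: int = 1,
    threshold: float | str = "otsu",
) -> np.ndarray:
    """Smooth, rescale to [0, 1] and threshold one channel into a binary mask.

    Smoothing is a mean filter of the given radius (0 disables it); the
    rescale is a deterministic linear map of the intensity range onto
    [0, 1] (the manual brightness/contrast step of interactive analysis);
    ``threshold`` is a fixed level in [0, 1] or the string ``"otsu"``.
    """
    img = image.channel(channel).astype(float)
    if smooth_radius_px > 0:
        img = ndimage.uniform_filter(img, size=2 * smooth_radius_px + 1)
    ptp = np.ptp(img)
    img = (img - img.min()) / ptp if ptp > 0 else np.zeros_like(img)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if np.ptp(img) == 0:
            return np.zeros_like(img, dtype=bool)
        level = threshold_otsu(img)
        return img > level
    return img >= float(threshold)


def detect_clusters(
    mask: np.ndarray,
    *,
    pixel_nm: float = DEFAULT_PIXEL_NM,
    z_step_nm: float | None = None,
    min_size: int = 1,
    connectivity: int | None = None,
    channel: str = "ch0",
) -> list[Cluster]:
    """Connected components of a binary mask as Cluster objects.

    2D masks default to 8-connectivity, 3D to 26-connectivity (matching the
    conventions of the common particle/object counters).  Components below
    ``min_size`` pixels/voxels are discarded.  Centroid is the pixel-center
    mean scaled to nm; 2D circularity is 4*pi*area/perimeter^2 clamped to
    [0, 1].
    """
    mask = np.asarray(mask).astype(bool)
    dim = mask.ndim
    if dim not in (2, 3):
        raise ValueError("mask must be 2D or 3D")
    if connectivity is None:
        connectivity = dim  # full connectivity: 8 in 2D, 26 in 3D
    if dim == 3 and not z_step_nm:
        raise ValueError("z_step_nm required for 3D masks")
    labels = label(mask, connectivity=connectivity)
    scale = (
        np.array([pixel_nm, pixel_nm])
        if dim == 2
        else np.array([z_step_nm, pixel_nm, pixel_nm])
    )
    out: list[Cluster] = []
    eroded_all = ndimage.binary_erosion(
        labels > 0, structure=ndimage.generate_binary_structure(dim, dim)
    )
    for region in regionprops(labels):
        if region.area < min_size:
            continue
        pix = np.array(region.coords)
        on_boundary = ~eroded_all[tuple(pix.T)]
        # centroid at pixel centers, converted to (x, y[, z]) nm
        c_idx = pix.mean(axis=0) + 0.5
        c_nm = c_idx * scale
        if dim == 2:
            centroid = np.array([c_nm[1], c_nm[0]])
            perim = max(region.perimeter, 1e-12)
            area_px = float(region.area)
            circ = float(np.clip(4 * np.pi * area_px / perim**2, 0.0, 1.0))
            out.append(
                Cluster(
                    id=len(out),
                    channel=channel,
                    centroid_nm=centroid,
                    area_nm2=area_px * pixel_nm**2,
                    circularity=circ,
                    pixels=pix,
                    boundary_pixels=pix[on_boundary],
                    scale_nm=scale,
                )
            )
        else:
            centroid = np.array([c_nm[2], c_nm[1], c_nm[0]])
            out.append(
                Cluster(
                    id=len(out),
                    channel=channel,
                    centroid_nm=centroid,
                    volume_nm3=float(region.area) * pixel_nm**2 * z_step_nm,
                    pixels=pix,
                    boundary_pixels=pix[on_boundary],
                    scale_nm=scale,
                )
            )
    return out


def clusters_from_ellipses(
    ellipses: Sequence[Ellipse], channel: str, id_offset: int = 0
) -> list[Cluster]:
    """Wrap parametric ellipses as Cluster objects (exact geometry path)."""
    return [
        Cluster(
            id=id_offset + i,
            channel=channel,
            centroid_nm=np.array([e.cx, e.cy]),
            area_nm2=e.area,
            ellipse=e,
        )
        for i, e in enumerate(ellipses)
    ]


def filter_by_membrane(clusters: Sequence[Cluster], mask: MembraneMask) -> list[Cluster]:
    """Keep clusters whose (x, y) centroid lies within halfwidth of the polyline."""
    line = LineString(mask.polyline_nm)
    return [
        c for c in clusters if line.distance(Point(c.centroid_nm[:2])) <= mask.halfwidth_nm
    ]


def _raster_edge_distance(q: Cluster, r: Cluster) -> float:
    """Edge-to-edge distance between two raster clusters (nm).

    Disjoint: minimal boundary pixel-center distance minus one pixel
    diagonal (subpixel correction for boundary thickness).  Overlapping or
    shared pixels: minus the maximal mutual penetration measured with the
    Euclidean distance transform.
    """
    scale = q.scale_nm
    qs = {tuple(p) for p in q.pixels}
    shared = qs.intersection(tuple(p) for p in r.pixels)
    if shared:
        depth = 0.0
        for a, b in ((q, r), (r, q)):
            bset = {tuple(p) for p in b.pixels}
            inside = np.array([p for p in a.pixels if tuple(p) in bset])
            if len(inside):
                shape = tuple(inside.max(axis=0) + 2)
                m = np.zeros(shape, dtype=bool)
                bpix = np.array([p for p in b.pixels if np.all(p < shape)])
                m[tuple(bpix.T)] = True
                edt = ndimage.distance_transform_edt(m, sampling=scale)
                depth = max(depth, float(edt[tuple(inside.T)].max()))
        return -depth
    qb = q.boundary_pixels * scale
    rb = r.boundary_pixels * scale
    d2 = np.sum((qb[:, None, :] - rb[None, :, :]) ** 2, axis=-1)
    diag = float(np.linalg.norm(scale))
    return float(np.sqrt(d2.min()) - diag)


def edge_distance(q: Cluster, r: Cluster) -> float:
    """Edge-to-edge distance (nm) between two clusters; negative = overlap."""
    if q.is_parametric and r.is_parametric:
        return ellipse_edge_distance(q.ellipse, r.ellipse)
    if q.is_parametric or r.is_parametric:
        raise ValueError("cannot mix parametric and raster clusters in distances")
    return _raster_edge_distance(q, r)


def nn_distances(
    query: Sequence[Cluster], reference: Sequence[Cluster]
) -> list[DistanceRecord]:
    """Nearest reference cluster for each query, by edge-to-edge distance.

    Reports both centroid and edge metrics; a query present in the
    reference list (same-species analysis) is never matched to itself.
    Ties break toward the lowest reference id.
    """
    if len(reference) == 0:
        raise ValueError("reference cluster set is empty")
    records = []
    for q in query:
        best: tuple[float, int, float] | None = None
        for r in sorted(reference, key=lambda c: c.id):
            if r is q:
                continue
            e = edge_distance(q, r)
            if best is None or e < best[0]:
                cc = float(np.linalg.norm(q.centroid_nm - r.centroid_nm))
                best = (e, r.id, cc)
        if best is None:
            raise ValueError("reference set contains only the query cluster itself")
        records.append(DistanceRecord(q.id, best[1], best[2], best[0]))
    return records


def distance_summary(records: Sequence[DistanceRecord], bin_nm: float = 100.0) -> dict:
    """Contact fraction plus per-bin fractions of nearest-neighbour distances.

    Contact is edge-to-edge <= 0; positive distances fall into bins
    (0, bin], (bin, 2*bin], ...  Fractions sum to 1 over contact + bins.
    """
    if bin_nm <= 0:
        raise ValueError("bin_nm must be positive")
    if len(records) == 0:
        raise ValueError("no distance records to summarise")
    edges_vals = np.array([r.edge_to_edge_nm for r in records])
    n = len(edges_vals)
    contact = int(np.sum(edges_vals <= 0))
    pos = edges_vals[edges_vals > 0]
    nbins = max(int(np.ceil(pos.max() / bin_nm)), 1) if len(pos) else 1
    # bins are left-open, right-closed: (0, b], (b, 2b], ...; the floor
    # guards against positive values so small that pos / bin underflows
    idx = np.maximum(np.ceil(pos / bin_nm).astype(int) - 1, 0)
    counts = np.bincount(idx, minlength=nbins)
    bin_edges = np.arange(nbins + 1) * bin_nm
    fractions = counts / n
    return {
        "n": n,
        "contact_fraction": contact / n,
        "bin_nm": bin_nm,
        "bin_edges_nm": bin_edges,
        "bin_fractions": fractions,
    }
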