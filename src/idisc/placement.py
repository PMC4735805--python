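"""Monte Carlo simulation of cluster placement: random vs. attraction models.

Observed two-channel cluster fields are modelled as ellipses placed in
rectangular boxes that approximate the membrane band around the
intercalated-disc line (line length x 2 x 500 nm).  Reference ellipses
(the adhesion species, N-cadherin) are drawn first with uniform position
and rotation, redrawn on reference-reference overlap until all fit.  Query
ellipses (Nav1.5) are placed by a rejection scheme governed by an
attraction factor f >= 1: a uniform proposal overlapping a reference
ellipse is always accepted, a non-overlapping proposal is accepted with
probability 1/f.  f = 1 is exactly uniform placement (the random model).

For a single reference configuration covering an area fraction p of the
proposal space, the scheme yields a closed-form contact probability
p*f / (p*f + 1 - p), used as an analytic oracle.

Conventions: ellipse centers are uniform over the box interior; ellipses
may extend past box edges.  Query ellipses may overlap one another — only
reference-reference overlap is forbidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .clusters import DistanceRecord, clusters_from_ellipses, nn_distances
from .geometry import Ellipse, ellipses_overlap

__all__ = [
    "PlacementConfig",
    "PlacementResult",
    "PlacementFailure",
    "place_reference",
    "place_query",
    "run_placement_experiment",
    "compare_distributions",
    "expected_contact_probability",
    "overlap_probability_grid",
]

DEFAULT_REJECTION_CAP = 100_000
DEFAULT_HIST_BINS = 20  # 100-nm bins; distances beyond go to an overflow bin


class PlacementFailure(RuntimeError):
    """Raised when an ellipse cannot be placed within the rejection cap."""


@dataclass
class PlacementConfig:
    """One box per correlative image: (length_nm, n_ref, n_query).

    ``size_source`` maps species ('reference'/'query') to either a list of
    (major, minor) semi-axis pairs sampled with replacement, or a callable
    ``sampler(rng, n) -> (n, 2)`` array of semi-axes in nm.
    """

    boxes: Sequence[tuple[float, int, int]]
    size_source: dict
    attraction_f: float = 1.0
    n_reps: int = 1000
    box_halfwidth_nm: float = 500.0
    bin_nm: float = 100.0
    hist_bins: int = DEFAULT_HIST_BINS
    rejection_cap: int = DEFAULT_REJECTION_CAP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attraction_f < 1:
            raise ValueError("attraction_f must be >= 1 (1 = random model)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class PlacementResult:
    """Pooled nearest-neighbour statistics over replicates.

    ``mean_histogram`` is the per-rep fraction vector
    [contact, (0,100], ..., overflow] averaged over reps (sums to 1).
    """

    per_rep_records: list[list[DistanceRecord]]
    mean_histogram: np.ndarray
    bin_nm: float
    contact_fraction_mean: float
    contact_fraction_sd: float
    attraction_f: float
    n_reps: int


def _sample_sizes(source, rng: np.random.Generator, n: int) -> np.ndarray:
    if callable(source):
        out = np.asarray(source(rng, n), dtype=float).reshape(n, 2)
    else:
        pool = np.asarray(source, dtype=float).reshape(-1, 2)
        out = pool[rng.integers(0, len(pool), size=n)]
    if n and out.min() <= 0:
        raise ValueError("sampled semi-axes must be positive")
    return out


def _propose(box_length: float, box_height: float, size, rng) -> Ellipse:
    return Ellipse(
        cx=rng.uniform(0.0, box_length),
        cy=rng.uniform(0.0, box_height),
        a=size[0],
        b=size[1],
        angle_deg=rng.uniform(0.0, 180.0),
    )


def place_reference(
    box_length: float,
    box_height: float,
    sizes: np.ndarray,
    rng: np.random.Generator,
    rejection_cap: int = DEFAULT_REJECTION_CAP,
) -> list[Ellipse]:
    """Place reference ellipses uniformly, rejecting reference-reference overlap."""
    placed: list[Ellipse] = []
    for i, size in enumerate(np.atleast_2d(sizes) if len(sizes) else []):
        for _ in range(rejection_cap):
            cand = _propose(box_length, box_height, size, rng)
            if not any(ellipses_overlap(cand, e) for e in placed):
                placed.append(cand)
                break
        else:
            raise PlacementFailure(
                f"reference ellipse {i} could not be placed in "
                f"{rejection_cap} draws (box {box_length:.0f} x {box_height:.0f} nm)"
            )
    return placed


def place_query(
    box_length: float,
    box_height: float,
    reference: Sequence[Ellipse],
    sizes: np.ndarray,
    attraction_f: float,
    rng: np.random.Generator,
    rejection_cap: int = DEFAULT_REJECTION_CAP,
) -> list[Ellipse]:
    """Place query ellipses under the attraction rejection scheme.

    Overlapping proposals are accepted unconditionally; non-overlapping
    ones with probability 1/f.  With f = 1 every proposal is accepted, so
    the path is bit-identical to uniform placement apart from unused draws.
    """
    if attraction_f < 1:
        raise ValueError("attraction_f must be >= 1")
    placed: list[Ellipse] = []
    for i, size in enumerate(np.atleast_2d(sizes) if len(sizes) else []):
        for _ in range(rejection_cap):
            cand = _propose(box_length, box_height, size, rng)
            overlaps = any(ellipses_overlap(cand, e) for e in reference)
            if overlaps or attraction_f == 1.0 or rng.uniform() <= 1.0 / attraction_f:
                placed.append(cand)
                break
        else:
            raise PlacementFailure(
                f"query ellipse {i} could not be placed in {rejection_cap} draws"
            )
    return placed


def _rep_histogram(records: Sequence[DistanceRecord], bin_nm: float, nbins: int) -> np.ndarray:
    """[contact, nbins bins, overflow] fraction vector for one replicate."""
    vec = np.zeros(nbins + 2)
    for r in records:
        d = r.edge_to_edge_nm
        if d <= 0:
            vec[0] += 1
        else:
            k = max(int(np.ceil(d / bin_nm)), 1)  # guard against underflow
            vec[min(k, nbins + 1)] += 1
    return vec / max(len(records), 1)


def run_placement_experiment(config: PlacementConfig) -> PlacementResult:
    """Run the full placement simulation over all boxes and replicates.

    Per replicate, every box is populated (reference first, then query
    under the attraction scheme), nearest-neighbour query-to-reference
    distances are measured on the exact ellipse geometry, and the pooled
    distance histogram recorded; histograms are averaged over replicates.
    """
    rng = np.random.default_rng(config.seed)
    per_rep: list[list[DistanceRecord]] = []
    hists = []
    for rep in range(config.n_reps):
        records: list[DistanceRecord] = []
        for bi, (length, n_ref, n_query) in enumerate(config.boxes):
            height = 2.0 * config.box_halfwidth_nm
            try:
                ref = place_reference(
                    length,
                    height,
                    _sample_sizes(config.size_source["reference"], rng, n_ref),
                    rng,
                    config.rejection_cap,
                )
                qry = place_query(
                    length,
                    height,
                    ref,
                    _sample_sizes(config.size_source["query"], rng, n_query),
                    config.attraction_f,
                    rng,
                    config.rejection_cap,
                )
            except PlacementFailure as exc:
                raise PlacementFailure(f"box {bi}, rep {rep}: {exc}") from exc
            if n_ref and n_query:
                records.extend(
                    nn_distances(
                        clusters_from_ellipses(qry, "query"),
                        clusters_from_ellipses(ref, "reference"),
                    )
                )
        per_rep.append(records)
        if records:
            hists.append(_rep_histogram(records, config.bin_nm, config.hist_bins))
    if not hists:
        raise ValueError("no distance records produced (empty boxes?)")
    H = np.array(hists)
    contact = H[:, 0]
    return PlacementResult(
        per_rep_records=per_rep,
        mean_histogram=H.mean(axis=0),
        bin_nm=config.bin_nm,
        contact_fraction_mean=float(contact.mean()),
        contact_fraction_sd=float(contact.std(ddof=1)) if len(contact) > 1 else 0.0,
        attraction_f=config.attraction_f,
        n_reps=config.n_reps,
    )


def compare_distributions(
    sim_histogram: np.ndarray,
    observed_histogram: np.ndarray,
    bin_nm_sim: float = 100.0,
    bin_nm_obs: float = 100.0,
) -> dict:
    """Total-variation distance and chi-square statistic between histograms.

    Both inputs are fraction vectors on identical binning ([contact,
    bins..., overflow]); no p-value is attached — model choice is by
    divergence, mirroring a visual comparison.
    """
    p = np.asarray(sim_histogram, dtype=float)
    q = np.asarray(observed_histogram, dtype=float)
    if p.shape != q.shape or bin_nm_sim != bin_nm_obs:
        raise ValueError("histogram binning mismatch")
    tv = 0.5 * float(np.abs(p - q).sum())
    denom = np.where(p > 0, p, 1.0)
    chi2 = float(np.sum(np.where(p > 0, (q - p) ** 2 / denom, 0.0)))
    per_bin = np.column_stack([p, q, np.abs(p - q)])
    return {"total_variation": tv, "chi_square": chi2, "per_bin": per_bin}


def expected_contact_probability(p_overlap: float, attraction_f: float) -> float:
    """Closed-form contact probability of the rejection scheme.

    With uniform-proposal overlap probability p, an accepted placement
    overlaps with probability p*f / (p*f + 1 - p).
    """
    p = p_overlap
    return p * attraction_f / (p * attraction_f + 1.0 - p)


def overlap_probability_grid(
    box_length: float,
    box_height: float,
    reference: Sequence[Ellipse],
    query_size: tuple[float, float],
    n_grid: int = 100,
    n_angles: int = 12,
) -> float:
    """Uniform-proposal overlap probability p by dense enumeration.

    Evaluates overlap over an n_grid x n_grid lattice of candidate centers
    and n_angles rotations — an independent oracle for the analytic
    acceptance formula.
    """
    xs = (np.arange(n_grid) + 0.5) / n_grid * box_length
    ys = (np.arange(n_grid) + 0.5) / n_grid * box_height
    angles = np.arange(n_angles) / n_angles * 180.0
    hits = 0
    for x in xs:
        for y in ys:
            for ang in angles:
                cand = Ellipse(x, y, query_size[0], query_size[1], ang)
                if any(ellipses_overlap(cand, e) for e in reference):
                    hits += 1
    return hits / (n_grid * n_grid * n_angles)
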