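"""Ensemble sodium-current prediction from cluster geometry.

Bridges the structural measurements to electrophysiology: channels per
cluster from cluster area and pore-to-pore spacing, expected clusters under
a patch pipette from inter-cluster spacing and membrane-surface
amplification, and the aggregate peak current those channels carry.

Unit bookkeeping: 1 pS x 1 mV = 1e-3 pA, so 10 pS at a 60 mV driving force
is 0.6 pA per open channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CurrentModelParams",
    "channels_from_cluster_area",
    "clusters_under_patch",
    "predicted_patch_current",
]

_PACKINGS = ("square", "hexagonal")


@dataclass(frozen=True)
class CurrentModelParams:
    """Defaults reflect the measured ID geometry: 44 channels per cluster at a
    33 nm pore-to-pore pitch, ~1 um between clusters, 6.5x surface
    amplification in the plicate region, a 2 um patch pipette, 10 pS unitary
    conductance and 60 mV driving force."""

    unitary_conductance_pS: float = 10.0
    driving_force_mV: float = 60.0
    channels_per_cluster: int = 44
    pore_spacing_nm: float = 33.0
    patch_diameter_um: float = 2.0
    amplification: float = 6.5
    cluster_spacing_um: float = 1.0
    packing: str = "square"

    def __post_init__(self) -> None:
        for name in (
            "unitary_conductance_pS",
            "driving_force_mV",
            "channels_per_cluster",
            "pore_spacing_nm",
            "patch_diameter_um",
            "amplification",
            "cluster_spacing_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.packing not in _PACKINGS:
            raise ValueError(f"packing must be one of {_PACKINGS}")


def _site_area(spacing: float, packing: str) -> float:
    if packing == "square":
        return spacing**2
    if packing == "hexagonal":
        return math.sqrt(3.0) / 2.0 * spacing**2
    raise ValueError(f"packing must be one of {_PACKINGS}")


def channels_from_cluster_area(
    area_nm2: float, pore_spacing_nm: float = 33.0, packing: str = "square"
) -> int:
    """Channel count in a cluster of the given area at the given pore pitch.

    Each channel occupies one lattice site of area ``spacing**2`` (square
    packing) or ``sqrt(3)/2 * spacing**2`` (hexagonal).
    """
    if area_nm2 <= 0 or pore_spacing_nm <= 0:
        raise ValueError("area and spacing must be positive")
    return int(round(area_nm2 / _site_area(pore_spacing_nm, packing)))


def clusters_under_patch(params: CurrentModelParams = CurrentModelParams()) -> tuple[float, int]:
    """Expected number of channel clusters sampled by a patch pipette.

    The pipette seals over a disc of the given diameter; membrane folding
    amplifies the true membrane area under it, and clusters tile that area
    at one per ``cluster_spacing**2`` (square) tile.  Returns the unrounded
    expectation and its rounded value.
    """
    r_um = params.patch_diameter_um / 2.0
    patch_area = math.pi * r_um**2 * params.amplification  # um^2 of true membrane
    tile = _site_area(params.cluster_spacing_um, params.packing)
    n = patch_area / tile
    return n, int(round(n))


def predicted_patch_current(
    n_clusters: float,
    channels_per_cluster: float = 44,
    unitary_conductance_pS: float = 10.0,
    driving_force_mV: float = 60.0,
) -> float:
    """Aggregate peak current (pA) = clusters x channels x g x V.

    Linear in every argument; (19, 44, 10 pS, 60 mV) -> 501.6 pA.
    """
    if min(n_clusters, channels_per_cluster, unitary_conductance_pS, driving_force_mV) < 0:
        raise ValueError("all arguments must be non-negative")
    per_channel_pA = unitary_conductance_pS * driving_force_mV * 1e-3
    return n_clusters * channels_per_cluster * per_channel_pA
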