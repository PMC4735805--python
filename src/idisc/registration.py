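"""Fiducial-based affine registration of fluorescence and EM coordinate frames.

Correlative light-electron microscopy (CLEM) overlays a super-resolved
fluorescence image on a transmission EM image of the same section.  Gold
fiducials visible in both modalities provide matched point pairs from which
a 2D affine map (linear part + translation) is estimated by least squares;
an affine rather than rigid model absorbs distortion introduced during EM
processing.  All coordinates are in nm, y pointing down.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AffineTransform2D",
    "estimate_affine",
    "transform_points",
    "registration_error",
    "DEFAULT_QC_THRESHOLD_NM",
]

#: Default registration QC threshold: the mapping error of the super-resolved
#: overlay is about 20 nm, so residuals above this indicate a bad fiducial set.
DEFAULT_QC_THRESHOLD_NM = 20.0


@dataclass(frozen=True)
class AffineTransform2D:
    """y = L @ x + t with a non-singular 2x2 linear part L and translation t (nm)."""

    linear: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        L = np.asarray(self.linear, dtype=float).reshape(2, 2)
        t = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(L)) < 1e-12:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "linear", L)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    def inverse(self) -> "AffineTransform2D":
        Linv = np.linalg.inv(self.linear)
        return AffineTransform2D(Linv, -Linv @ self.translation)

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return AffineTransform2D(
            self.linear @ other.linear,
            self.linear @ other.translation + self.translation,
        )

    def coefficients(self) -> list[float]:
        """Six coefficients row-major: [a, b, tx, c, d, ty]."""
        L, t = self.linear, self.translation
        return [L[0, 0], L[0, 1], t[0], L[1, 0], L[1, 1], t[1]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"coefficients": self.coefficients()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform2D":
        a, b, tx, c, d, ty = json.loads(Path(path).read_text())["coefficients"]
        return cls(np.array([[a, b], [c, d]]), np.array([tx, ty]))


def estimate_affine(source_points, target_points) -> AffineTransform2D:
    """Least-squares affine map from matched fiducial pairs.

    Requires at least 3 non-collinear pairs; exact for noiseless consistent
    pairs.  Solved on homogeneous coordinates by ``numpy.linalg.lstsq``.
    """
    src = np.asarray(source_points, dtype=float).reshape(-1, 2)
    dst = np.asarray(target_points, dtype=float).reshape(-1, 2)
    if src.shape != dst.shape:
        raise ValueError("source and target point lists differ in length")
    if len(src) < 3:
        raise ValueError(f"need >= 3 fiducial pairs, got {len(src)}")
    H = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(H) < 3:
        raise ValueError("degenerate fiducial configuration (collinear points)")
    # columns of the solution are (a, b, tx) and (c, d, ty)
    sol, *_ = np.linalg.lstsq(H, dst, rcond=None)
    L = sol[:2].T
    t = sol[2]
    return AffineTransform2D(L, t)


def transform_points(points, transform: AffineTransform2D) -> np.ndarray:
    """Apply y = L x + t to an (n, 2) array of nm coordinates."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return pts @ transform.linear.T + transform.translation


def registration_error(
    source_points,
    target_points,
    transform: AffineTransform2D,
    *,
    qc_threshold_nm: float = DEFAULT_QC_THRESHOLD_NM,
) -> tuple[float, bool]:
    """RMSE (nm) of transformed source vs. target, with a QC flag.

    Returns ``(rmse_nm, ok)`` where ``ok`` is False when the RMSE exceeds
    the threshold (default 20 nm, the mapping error of the overlay).
    """
    src = np.asarray(source_points, dtype=float).reshape(-1, 2)
    dst = np.asarray(target_points, dtype=float).reshape(-1, 2)
    if len(src) == 0:
        raise ValueError("registration_error requires at least one pair")
    resid = transform_points(src, transform) - dst
    rmse = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return rmse, rmse <= qc_threshold_nm


def read_fiducial_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 4-column fiducial CSV (src_x, src_y, dst_x, dst_y in nm)."""
    df = pd.read_csv(path)
    return df[["src_x", "src_y"]].to_numpy(), df[["dst_x", "dst_y"]].to_numpy()


def write_fiducial_csv(path: str | Path, source, target) -> None:
    src = np.asarray(source, float).reshape(-1, 2)
    dst = np.asarray(target, float).reshape(-1, 2)
    pd.DataFrame(
        {"src_x": src[:, 0], "src_y": src[:, 1], "dst_x": dst[:, 0], "dst_y": dst[:, 1]}
    ).to_csv(path, index=False)
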