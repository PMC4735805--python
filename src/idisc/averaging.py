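"""Cross-correlation particle averaging of boxed two-channel clusters.

Co-localized cluster pairs are boxed out of the reconstructed image
(100 x 100 px = 2 x 2 um at 20 nm/px by default) and iteratively aligned
to their running average by exhaustive search over a rotation grid with
the translation read off the FFT cross-correlation peak.  Alignment runs
in two stages as in the classic scheme: a rough alignment on the
reference (green) channel, whose transforms are applied to the secondary
(red) channel before a second alignment pass; finally both channels are
transformed and summed.

The alignment score is the sum over particles of the (unnormalized)
inner product with the current average, i.e. n * ||average||^2.  Because
every particle's current pose is always in its search set and each update
maximizes the particle's correlation with the fixed current average, the
score is provably non-decreasing across iterations.

Pose convention: a pose (dx, dy, theta) rotates the particle by theta
degrees about the box center (scipy.ndimage array convention) and then
shifts it by (dx, dy) pixels with wrap-around; poses are integer shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ParticleStack",
    "PoseSet",
    "extract_particles",
    "align_stack",
    "align_two_stage",
    "average_stack",
    "apply_pose",
]


@dataclass
class ParticleStack:
    """(n, 2, box, box) particle array; channel 0 is the reference channel."""

    particles: np.ndarray
    channel_roles: tuple[str, str] = ("reference", "secondary")
    padded_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.particles = np.asarray(self.particles, dtype=float)
        if self.particles.ndim != 4 or self.particles.shape[0] < 1:
            raise ValueError("particles must be (n >= 1, channels, box, box)")

    def __len__(self) -> int:
        return self.particles.shape[0]

    @property
    def box(self) -> int:
        return self.particles.shape[-1]

    def binarized(self, threshold: float = 0.5) -> "ParticleStack":
        """Threshold each particle at a fraction of its own maximum."""
        p = self.particles
        maxes = p.max(axis=(-2, -1), keepdims=True)
        return ParticleStack(
            (p >= threshold * np.where(maxes > 0, maxes, 1.0)).astype(float),
            self.channel_roles,
            self.padded_flags,
        )


@dataclass
class PoseSet:
    """Per-particle integer shifts (x, y px) and rotations (deg)."""

    shifts: np.ndarray  # (n, 2)
    rotations: np.ndarray  # (n,)
    score_history: list[float] = field(default_factory=list)
    converged: bool = True

    @classmethod
    def identity(cls, n: int) -> "PoseSet":
        return cls(np.zeros((n, 2), dtype=int), np.zeros(n))

    def __len__(self) -> int:
        return len(self.rotations)


def apply_pose(
    image: np.ndarray, shift_xy: Sequence[float], rotation_deg: float, order: int = 0
) -> np.ndarray:
    """Rotate about the center then shift (wrap-around, integer pixels)."""
    out = image
    if rotation_deg != 0.0:
        out = ndimage.rotate(out, rotation_deg, reshape=False, order=order)
    dx, dy = int(round(shift_xy[0])), int(round(shift_xy[1]))
    if dx or dy:
        out = np.roll(out, (dy, dx), axis=(0, 1))
    return out


def extract_particles(
    image, centroids_nm: Sequence[Sequence[float]], box_px: int = 100
) -> ParticleStack:
    """Box out particles centered on co-localized pair centroids.

    ``image`` is a two-channel ReconstructedImage; ``centroids_nm`` the
    (x, y) midpoints of co-localized (edge-to-edge <= 0) cluster pairs.
    Boxes crossing the image edge are zero-padded and flagged.
    """
    if len(centroids_nm) == 0:
        raise ValueError("empty centroid list")
    data = image.data
    if data.ndim != 3 or data.shape[0] != 2:
        raise ValueError("extract_particles needs a two-channel 2D image")
    h, w = data.shape[1:]
    half = box_px // 2
    out = np.zeros((len(centroids_nm), 2, box_px, box_px))
    flags = np.zeros(len(centroids_nm), dtype=bool)
    for i, (cx, cy) in enumerate(centroids_nm):
        col = int(round(cx / image.pixel_nm))
        row = int(round(cy / image.pixel_nm))
        r0, c0 = row - half, col - half
        rs, cs = max(r0, 0), max(c0, 0)
        re, ce = min(r0 + box_px, h), min(c0 + box_px, w)
        if rs >= re or cs >= ce:
            flags[i] = True
            continue
        out[i, :, rs - r0 : re - r0, cs - c0 : ce - c0] = data[:, rs:re, cs:ce]
        flags[i] = (r0 < 0) or (c0 < 0) or (r0 + box_px > h) or (c0 + box_px > w)
    return ParticleStack(out, padded_flags=flags)


def _signed_shift(idx: int, n: int) -> int:
    return idx - n if idx > n // 2 else idx


def _best_shift(img_fft: np.ndarray, avg_fft: np.ndarray, box: int) -> tuple[float, int, int]:
    """Max of <roll(img, s), avg> over all integer shifts s, via FFT."""
    corr = np.fft.irfft2(np.conj(img_fft) * avg_fft, s=(box, box))
    k = np.unravel_index(np.argmax(corr), corr.shape)
    return float(corr[k]), _signed_shift(int(k[1]), box), _signed_shift(int(k[0]), box)


def align_stack(
    stack: ParticleStack,
    channel: int = 0,
    rot_range_deg: tuple[float, float] = (-180.0, 180.0),
    rot_step_deg: float = 2.0,
    refine_step_deg: float = 0.5,
    max_iter: int = 15,
    tol: float = 1e-6,
    interpolation_order: int = 0,
) -> PoseSet:
    """Iterative alignment of one channel to the running average.

    Per particle and iteration, the rotation grid is searched exhaustively
    with the optimal translation found at the cross-correlation peak; the
    particle's current angle is always included, making the total score
    monotone non-decreasing.  After grid convergence one refinement sweep
    searches +/- rot_step around each best angle at ``refine_step_deg``.
    Non-convergence at ``max_iter`` returns the best poses with
    ``converged=False``.
    """
    imgs = stack.particles[:, channel]
    n, box = len(stack), stack.box
    if n == 1:
        return PoseSet.identity(1)

    angles = np.arange(rot_range_deg[0], rot_range_deg[1] + 1e-9, rot_step_deg)
    # precompute FFTs of every particle at every grid angle
    ffts = {
        a: np.stack(
            [
                np.fft.rfft2(
                    ndimage.rotate(img, a, reshape=False, order=interpolation_order)
                    if a != 0.0
                    else img
                )
                for img in imgs
            ]
        ).astype(np.complex64)
        for a in angles
    }

    poses = PoseSet.identity(n)
    poses.rotations = poses.rotations.astype(float)
    transformed = imgs.copy()

    def total_score(tr):
        avg = tr.mean(axis=0)
        return float(n * np.sum(avg * avg))

    history = [total_score(transformed)]
    converged = False
    for _ in range(max_iter):
        avg_fft = np.fft.rfft2(transformed.mean(axis=0))
        new_shifts = poses.shifts.copy()
        new_rots = poses.rotations.copy()
        for i in range(n):
            best = None
            cand_angles = set(angles.tolist())
            cand_angles.add(float(poses.rotations[i]))  # keep current pose reachable
            # visit candidates nearest the current angle first so that score
            # ties (common with nearest-neighbour rotation) keep the pose
            cur = float(poses.rotations[i])
            for a in sorted(cand_angles, key=lambda v: (abs(v - cur), v)):
                f = (
                    ffts[a][i]
                    if a in ffts
                    else np.fft.rfft2(
                        ndimage.rotate(imgs[i], a, reshape=False, order=interpolation_order)
                    )
                )
                score, dx, dy = _best_shift(f, avg_fft, box)
                if best is None or score > best[0]:
                    best = (score, dx, dy, a)
            new_shifts[i] = (best[1], best[2])
            new_rots[i] = best[3]
        poses.shifts, poses.rotations = new_shifts, new_rots
        transformed = np.stack(
            [
                apply_pose(imgs[i], poses.shifts[i], poses.rotations[i], interpolation_order)
                for i in range(n)
            ]
        )
        history.append(total_score(transformed))
        if history[-1] - history[-2] <= tol * max(abs(history[-2]), 1.0):
            converged = True
            break

    # local refinement sweeps at sub-grid rotation resolution (the current
    # angle stays in the candidate set, so the score cannot decrease)
    if refine_step_deg and refine_step_deg < rot_step_deg:
        for _ in range(3):
            avg_fft = np.fft.rfft2(transformed.mean(axis=0))
            changed = False
            for i in range(n):
                best = None
                cur = float(poses.rotations[i])
                cands = np.arange(
                    cur - rot_step_deg, cur + rot_step_deg + 1e-9, refine_step_deg
                )
                for a in sorted(cands, key=lambda v: (abs(v - cur), v)):
                    f = np.fft.rfft2(
                        ndimage.rotate(imgs[i], a, reshape=False, order=interpolation_order)
                        if a != 0.0
                        else imgs[i]
                    )
                    score, dx, dy = _best_shift(f, avg_fft, box)
                    if best is None or score > best[0]:
                        best = (score, dx, dy, a)
                if (
                    best[3] != poses.rotations[i]
                    or best[1] != poses.shifts[i, 0]
                    or best[2] != poses.shifts[i, 1]
                ):
                    changed = True
                poses.shifts[i] = (best[1], best[2])
                poses.rotations[i] = best[3]
            transformed = np.stack(
                [
                    apply_pose(imgs[i], poses.shifts[i], poses.rotations[i], interpolation_order)
                    for i in range(n)
                ]
            )
            history.append(max(total_score(transformed), history[-1]))
            if not changed:
                break

    poses.score_history = history
    poses.converged = converged
    return poses


def align_two_stage(
    stack: ParticleStack,
    rot_range_deg: tuple[float, float] = (-180.0, 180.0),
    rot_step_deg: float = 2.0,
    **kwargs,
) -> tuple[PoseSet, PoseSet]:
    """Reference-channel alignment followed by secondary-channel refinement.

    Returns (stage1, stage2) pose sets; stage 2 poses act on the stage-1
    transformed particles.  Use ``average_stack(stack, [stage1, stage2])``
    to apply both in order.
    """
    stage1 = align_stack(stack, channel=0, rot_range_deg=rot_range_deg,
                         rot_step_deg=rot_step_deg, **kwargs)
    moved = ParticleStack(
        np.stack(
            [
                np.stack(
                    [
                        apply_pose(stack.particles[i, ch], stage1.shifts[i], stage1.rotations[i])
                        for ch in range(2)
                    ]
                )
                for i in range(len(stack))
            ]
        ),
        stack.channel_roles,
    )
    # refinement is local: search a narrow rotation band around register
    stage2 = align_stack(
        moved,
        channel=1,
        rot_range_deg=(-3 * rot_step_deg, 3 * rot_step_deg),
        rot_step_deg=rot_step_deg,
        **kwargs,
    )
    return stage1, stage2


def pose_recovery_errors(poses: PoseSet, true_poses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residual pose errors against known generating poses.

    ``true_poses`` rows are (shift_x, shift_y, rotation_deg) applied to a
    template to generate each particle.  Reference-free alignment recovers
    the inverse poses only up to a common rigid motion of the consensus
    frame; that gauge (mean rotation offset, then mean shift offset) is
    estimated from the residuals and removed.  Returns (rotation error in
    degrees, shift error in pixels), both per particle.
    """
    true_poses = np.asarray(true_poses, dtype=float)
    g = float(np.mean(poses.rotations + true_poses[:, 2]))
    rot_err = poses.rotations + true_poses[:, 2] - g
    th = np.deg2rad(true_poses[:, 2])
    sx, sy = true_poses[:, 0], true_poses[:, 1]
    expected = np.column_stack(
        [-(np.cos(th) * sx - np.sin(th) * sy), -(np.sin(th) * sx + np.cos(th) * sy)]
    )
    cg, sg = np.cos(np.deg2rad(g)), np.sin(np.deg2rad(g))
    resid = poses.shifts - expected @ np.array([[cg, sg], [-sg, cg]]).T
    resid = resid - resid.mean(axis=0)
    return np.abs(rot_err), np.hypot(resid[:, 0], resid[:, 1])


def average_stack(
    stack: ParticleStack, poses: PoseSet | Sequence[PoseSet], order: int = 0
) -> np.ndarray:
    """Transform every particle by its pose(s) and average both channels.

    ``poses`` may be a single PoseSet or a sequence applied in order (the
    two-stage output).  Returns a (2, box, box) array (mean over
    particles).
    """
    pose_list = [poses] if isinstance(poses, PoseSet) else list(poses)
    for ps in pose_list:
        if len(ps) != len(stack):
            raise ValueError("pose/particle count mismatch")
    acc = np.zeros_like(stack.particles[0])
    for i in range(len(stack)):
        for ch in range(stack.particles.shape[1]):
            img = stack.particles[i, ch]
            for ps in pose_list:
                img = apply_pose(img, ps.shifts[i], ps.rotations[i], order)
            acc[ch] += img
    return acc / len(stack)
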