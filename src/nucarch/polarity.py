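"""Reproducible epipolarity scoring of a histone-mark channel.

The visual call — "polarized when a clear asymmetric distribution is
visible across the middle of the nucleus" — is replaced by a half-space
mass score: over a deterministic lattice of unit directions, find the plane
through the mask's geometric centroid that maximises the fraction of total
within-mask mark intensity on one side.  The score lies in [0.5, 1]: a
perfectly symmetric mark scores 0.5, a mark entirely in one half-space
scores 1.  A cell is called polar when the score reaches a threshold τ
(default 0.7, a value that separates the isotropic null — which scores
≈ 0.55–0.65 at realistic voxel counts — from concentrated marks).

The direction lattice is a Fibonacci spiral symmetrised over the 24
rotations of the octahedral group, so the score is seed-free and exactly
invariant under 90° axis rotations of the scene (on grids whose lateral
spacing is symmetric in the rotated plane).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np

from .core import NuclearMask

__all__ = [
    "PolarityResult",
    "direction_lattice",
    "epipolarity_score",
    "classify_polar",
    "percent_polar",
]


@dataclass
class PolarityResult:
    score: float
    direction: np.ndarray  # unit (z, y, x)
    polar: bool
    tau: float


def _octahedral_rotations() -> np.ndarray:
    """The 24 proper rotations permuting and sign-flipping the axes."""
    mats = []
    for perm in permutations(range(3)):
        p = np.zeros((3, 3))
        p[np.arange(3), perm] = 1.0
        for signs in product((1.0, -1.0), repeat=3):
            m = p * np.asarray(signs)
            if np.isclose(np.linalg.det(m), 1.0):
                mats.append(m)
    return np.stack(mats)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)],
        axis=1,
    )


def direction_lattice(n_directions: int = 200) -> np.ndarray:
    """Deterministic, octahedrally symmetric set of ≥ ``n_directions`` unit
    vectors (z, y, x).  Antipodes are handled implicitly by the scorer."""
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    base = _fibonacci_sphere(max(1, -(-n_directions // 24)))
    rots = _octahedral_rotations()
    dirs = np.einsum("rij,nj->rni", rots, base).reshape(-1, 3)
    # The coordinate axes are their own octahedral orbit; including them
    # makes axis-aligned asymmetries score exactly 1.
    axes = np.eye(3)
    dirs = np.concatenate([axes, -axes, dirs])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def epipolarity_score(
    mark: np.ndarray,
    mask: NuclearMask,
    n_directions: int = 200,
    tau: float = 0.7,
) -> PolarityResult:
    """Maximum half-space intensity fraction about the mask centroid.

    For each lattice direction the plane through the geometric mask
    centroid splits the nucleus; the score is the largest fraction of total
    mark intensity on either side (voxels exactly on the plane contribute
    half to each side).  Raises ``ValueError`` when the mark carries no
    signal inside the mask.
    """
    mark = np.asarray(mark, dtype=float)
    if mark.shape != mask.grid.shape:
        raise ValueError("mark and mask are on different grids")
    if (mark < 0).any():
        raise ValueError("mark intensities must be nonnegative")
    w = mark[mask.mask]
    total = w.sum()
    if total <= 0:
        raise ValueError("no signal: mark has zero intensity inside the mask")

    spacing = np.asarray(mask.grid.spacing)
    idx = np.argwhere(mask.mask)
    pos = (idx + 0.5) * spacing - mask.centroid()

    dirs = direction_lattice(n_directions)
    best_score = -1.0
    best_dir = dirs[0]
    # Chunk the direction axis to bound the projection matrix size.
    chunk = max(1, int(2e7 // max(len(pos), 1)))
    for start in range(0, len(dirs), chunk):
        d = dirs[start : start + chunk]
        proj = pos @ d.T  # (voxels, directions)
        pos_mass = w @ (proj > 0) + 0.5 * (w @ (proj == 0))
        frac = pos_mass / total
        flip = frac < 0.5
        scores = np.where(flip, 1.0 - frac, frac)
        j = int(np.argmax(scores))
        if scores[j] > best_score:
            best_score = float(scores[j])
            best_dir = -d[j] if flip[j] else d[j]
    return PolarityResult(
        score=best_score,
        direction=best_dir,
        polar=classify_polar(best_score, tau),
        tau=tau,
    )


def classify_polar(score: float, tau: float = 0.7) -> bool:
    """Polar ⇔ score ≥ τ, with τ required to lie in (0.5, 1]."""
    if not 0.5 < tau <= 1.0:
        raise ValueError(f"tau must lie in (0.5, 1], got {tau}")
    if not 0.5 - 1e-9 <= score <= 1.0 + 1e-9:
        raise ValueError(f"score must lie in [0.5, 1], got {score}")
    return bool(score >= tau)


def percent_polar(flags_by_repeat: dict[str, list[bool]]) -> tuple[float, float]:
    """Percent-polar summarised across biological repeats.

    Each repeat contributes the percentage of its cells called polar; the
    return value is (mean, SEM) of those per-repeat percentages, matching
    mean + 1 SE reporting with the biological repeat as the unit of
    replication.  With a single repeat the SEM is undefined and reported as
    0.0 with a warning.
    """
    if not flags_by_repeat:
        raise ValueError("no repeats given")
    percents = []
    for rep, flags in flags_by_repeat.items():
        flags = list(flags)
        if not flags:
            raise ValueError(f"repeat {rep!r} has no cells")
        percents.append(100.0 * sum(bool(f) for f in flags) / len(flags))
    mean = float(np.mean(percents))
    if len(percents) == 1:
        warnings.warn(
            "SEM undefined with a single repeat; reporting 0.0", stacklevel=2
        )
        return mean, 0.0
    sem = float(np.std(percents, ddof=1) / np.sqrt(len(percents)))
    return mean, sem
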