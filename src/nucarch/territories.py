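"""Homolog distances, proximity classification and mark–territory
co-localization.

Distances are centroid-to-centroid in physical micrometres, the centroid
being the unweighted mean of the voxel centres making up the object.  A
cell is classified *proximal* when its two chromosome-paint homologs are
detected as one merged object (they sit closer than the optical merging
scale) or as two objects within ``d_prox`` of each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .core import GridSpec, NuclearMask
from .segmentation import Territory

__all__ = [
    "HomologPairResult",
    "ColocalizationResult",
    "centroid",
    "homolog_distance",
    "classify_proximity",
    "analyze_homolog_pair",
    "colocalization_volume",
]


@dataclass
class HomologPairResult:
    """Outcome of homolog-pair analysis for one paint channel of one cell."""

    n_objects: int
    distance_um: float | None
    proximal: bool | None  # None when no object was detected
    territory_volumes_um3: list[float]


@dataclass
class ColocalizationResult:
    overlap_um3: float
    mark_um3: float
    territory_um3: float
    overlap_fraction_of_territory: float


def centroid(t: Territory) -> np.ndarray:
    """Physical (z, y, x) centroid of a territory in µm."""
    return t.centroid


def homolog_distance(t1: Territory, t2: Territory) -> float:
    """Euclidean centroid-to-centroid distance in µm."""
    return float(np.linalg.norm(t1.centroid - t2.centroid))


def classify_proximity(
    territories: list[Territory], d_prox_um: float = 2.0
) -> bool | None:
    """Proximity call for a homolog pair.

    One merged object ⇒ proximal; two objects ⇒ proximal iff their distance
    is ≤ ``d_prox_um`` (boundary inclusive); zero objects ⇒ ``None``
    (excluded from percentages).  More than two objects violates the
    upstream ``max_objects`` contract.
    """
    if len(territories) > 2:
        raise ValueError(
            f"{len(territories)} territories passed; homolog analysis "
            "expects at most 2 (upstream max_objects violated)"
        )
    if len(territories) == 0:
        return None
    if len(territories) == 1:
        return True
    return homolog_distance(territories[0], territories[1]) <= d_prox_um


def analyze_homolog_pair(
    territories: list[Territory], d_prox_um: float = 2.0
) -> HomologPairResult:
    """Bundle object count, distance (two objects only) and proximity."""
    dist = (
        homolog_distance(territories[0], territories[1])
        if len(territories) == 2
        else None
    )
    return HomologPairResult(
        n_objects=len(territories),
        distance_um=dist,
        proximal=classify_proximity(territories, d_prox_um),
        territory_volumes_um3=[t.volume for t in territories],
    )


def colocalization_volume(
    mark: np.ndarray,
    territory: Territory,
    nucleus: NuclearMask | None = None,
    threshold: str = "otsu",
) -> ColocalizationResult:
    """Overlap volume between the thresholded mark signal and a territory.

    The mark is Otsu-thresholded within the nucleus when one is given
    (otherwise over the whole stack).  A zero mark yields an all-zero
    result, never an error.
    """
    mark = np.asarray(mark, dtype=float)
    grid: GridSpec = territory.grid
    if mark.shape != grid.shape:
        raise ValueError("mark and territory are on different grids")
    if threshold != "otsu":
        raise ValueError(f"unknown threshold method {threshold!r}")

    region = nucleus.mask if nucleus is not None else np.ones(grid.shape, bool)
    inside = mark[region]
    t_mask = territory.as_mask()
    t_vol = territory.volume
    if inside.size == 0 or inside.max() == inside.min():
        return ColocalizationResult(0.0, 0.0, t_vol, 0.0)
    thr = threshold_otsu(inside)
    mark_mask = (mark > thr) & region
    vv = grid.voxel_volume
    overlap = int((mark_mask & t_mask).sum()) * vv
    return ColocalizationResult(
        overlap_um3=overlap,
        mark_um3=int(mark_mask.sum()) * vv,
        territory_um3=t_vol,
        overlap_fraction_of_territory=overlap / t_vol,
    )
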