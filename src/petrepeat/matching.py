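"""Cross-timepoint lesion matching by centroid proximity.

A transparent stand-in for registration-based lesion tracking: lesions are
reduced to their ROI centroids in physical millimetres and paired greedily by
global nearest distance, one-to-one, up to a configurable maximum distance.
An optional affine (pre-computed rigid registration) can be applied to the
retest centroids first; the default is the identity, appropriate when both
scans share a frame (as synthetic phantom pairs do).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .features import LabeledImage

__all__ = ["MatchResult", "compute_centroids", "match_lesions"]

DEFAULT_MAX_DISTANCE_MM = 10.0


@dataclass
class MatchResult:
    """One-to-one lesion correspondences between two scans."""

    matched: list[tuple[int, int, float]]  # (test_label, retest_label, distance_mm)
    unmatched_test: list[int] = field(default_factory=list)
    unmatched_retest: list[int] = field(default_factory=list)

    @property
    def pairs(self) -> dict[int, int]:
        return {t: r for t, r, _ in self.matched}


def compute_centroids(image: LabeledImage) -> dict[int, np.ndarray]:
    """Unweighted ROI centroids in physical mm, one per nonzero label.

    Voxel-center convention: the center of voxel index (i, j, k) is at
    ((i + 1/2) dx, (j + 1/2) dy, (k + 1/2) dz).
    """
    from scipy import ndimage

    ids = np.unique(image.labels)
    ids = ids[ids > 0]
    voxel = np.asarray(image.voxel_size_mm)
    coms = ndimage.center_of_mass(np.ones(image.labels.shape), image.labels, ids)
    return {
        int(lid): (np.asarray(com) + 0.5) * voxel for lid, com in zip(ids, np.atleast_2d(coms))
    }


def match_lesions(
    test_centroids: dict[int, np.ndarray],
    retest_centroids: dict[int, np.ndarray],
    max_distance_mm: float = DEFAULT_MAX_DISTANCE_MM,
    affine: np.ndarray | None = None,
) -> MatchResult:
    """Greedy mutual-nearest-neighbour matching of centroid sets.

    Repeatedly takes the globally closest unmatched cross-timepoint pair with
    distance <= ``max_distance_mm``, records it and removes both lesions; ties
    are broken by smaller test label, then smaller retest label.  Remaining
    labels on either side are reported unmatched.  ``affine`` (4x4) is applied
    to the retest centroids before distances are computed.
    """
    if max_distance_mm <= 0:
        raise ParameterError("max_distance_mm must be positive")
    retest = dict(retest_centroids)
    if affine is not None:
        A = np.asarray(affine, dtype=float)
        if A.shape != (4, 4):
            raise ParameterError("affine must be a 4x4 matrix")
        retest = {k: A[:3, :3] @ np.asarray(v) + A[:3, 3] for k, v in retest.items()}

    candidates = sorted(
        (float(np.linalg.norm(np.asarray(tc) - rc)), tl, rl)
        for tl, tc in test_centroids.items()
        for rl, rc in retest.items()
    )
    matched: list[tuple[int, int, float]] = []
    used_t: set[int] = set()
    used_r: set[int] = set()
    for d, tl, rl in candidates:
        if d > max_distance_mm:
            break
        if tl in used_t or rl in used_r:
            continue
        matched.append((tl, rl, d))
        used_t.add(tl)
        used_r.add(rl)
    return MatchResult(
        matched=matched,
        unmatched_test=sorted(set(test_centroids) - used_t),
        unmatched_retest=sorted(set(retest_centroids) - used_r),
    )
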