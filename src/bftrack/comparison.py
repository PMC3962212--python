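"""Assessment toolkit: compare centroids and tracks across programs or
imaging modes.

Covers co-identification of cells between two point sets
(mutual-nearest-neighbor matching), translational alignment (removing a
constant instrument offset such as a fluorescence-filter light-path shift),
pairwise RMSD as the mismatch measure, decomposition of the squared RMSD
into per-program positional-noise variances, an isotropy test on mismatch
directions, and the focus-stack (z-stack) centroid stability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .tracking import Track

__all__ = [
    "MatchedPairs",
    "NoiseDecomposition",
    "match_point_sets",
    "translational_align",
    "pairwise_rmsd",
    "noise_decomposition",
    "mismatch_angle_uniformity",
    "zstack_displacement_analysis",
    "match_track_sets",
    "common_track_subset",
]


@dataclass
class MatchedPairs:
    """One-to-one matched points of two sets, with per-pair displacements.

    displacements[i] = B[pairs[i][1]] - A[pairs[i][0]] after any alignment.
    """

    pairs: list[tuple[int, int]]
    positions_a: np.ndarray
    positions_b: np.ndarray
    unmatched_a: list[int]
    unmatched_b: list[int]

    @property
    def displacements(self) -> np.ndarray:
        ia = [i for i, _ in self.pairs]
        ib = [j for _, j in self.pairs]
        return self.positions_b[ib] - self.positions_a[ia]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class NoiseDecomposition:
    """Decomposition of a squared pairwise RMSD into noise variances.

    residual_sq = rmsd_pair² − 2σᵢ² − 2σⱼ² — the part of the mean squared
    mismatch not explained by the two programs' white positional noise
    (systematic, algorithm-specific differences and cross terms).
    """

    rmsd_pair: float
    sigma_i: float
    sigma_j: float

    @property
    def residual_sq(self) -> float:
        return self.rmsd_pair**2 - 2.0 * self.sigma_i**2 - 2.0 * self.sigma_j**2


def match_point_sets(
    a: np.ndarray, b: np.ndarray, max_dist: float
) -> MatchedPairs:
    """Mutual-nearest-neighbor matching within `max_dist`.

    A pair (i, j) is matched iff j is i's nearest neighbor in B, i is j's
    nearest neighbor in A, and their distance is <= max_dist. Unpaired
    points are reported separately.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    pairs: list[tuple[int, int]] = []
    if len(a) and len(b):
        ta, tb = cKDTree(a), cKDTree(b)
        d_ab, j_ab = tb.query(a)  # nearest B for each A
        d_ba, i_ba = ta.query(b)  # nearest A for each B
        for i, (d, j) in enumerate(zip(d_ab, j_ab)):
            if d <= max_dist and i_ba[j] == i:
                pairs.append((i, int(j)))
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    return MatchedPairs(
        pairs=pairs,
        positions_a=a,
        positions_b=b,
        unmatched_a=[i for i in range(len(a)) if i not in matched_a],
        unmatched_b=[j for j in range(len(b)) if j not in matched_b],
    )


def translational_align(pairs: MatchedPairs) -> MatchedPairs:
    """Remove the mean displacement: shift all B positions by a constant so
    the mean of matched centroids coincides in both sets.

    This is the least-squares-optimal translation, so the pairwise RMSD can
    only decrease.
    """
    if len(pairs) == 0:
        raise ValueError("cannot align an empty pair set")
    shift = pairs.displacements.mean(axis=0)
    return MatchedPairs(
        pairs=list(pairs.pairs),
        positions_a=pairs.positions_a.copy(),
        positions_b=pairs.positions_b - shift,
        unmatched_a=list(pairs.unmatched_a),
        unmatched_b=list(pairs.unmatched_b),
    )


def pairwise_rmsd(pairs: MatchedPairs) -> float:
    """sqrt(mean squared pair displacement) — denominator N, not N−1."""
    if len(pairs) == 0:
        raise ValueError("pairwise RMSD of an empty pair set is undefined")
    d = pairs.displacements
    return float(np.sqrt((d**2).sum() / len(pairs)))


def noise_decomposition(
    rmsd_pair: float, sigma_i: float, sigma_j: float
) -> NoiseDecomposition:
    """Residual of the squared pairwise RMSD after removing white noise.

    With measured positions r = r_true + ξ (white noise variance 2σ² per
    point), E[RMSD²] = 2σᵢ² + 2σⱼ² + systematic terms; the residual
    rmsd² − 2σᵢ² − 2σⱼ² isolates the systematic part.
    """
    if rmsd_pair < 0 or sigma_i < 0 or sigma_j < 0:
        raise ValueError("inputs must be non-negative")
    return NoiseDecomposition(rmsd_pair=rmsd_pair, sigma_i=sigma_i, sigma_j=sigma_j)


def mismatch_angle_uniformity(pairs: MatchedPairs, n_bins: int = 8):
    """Chi-squared test of the polar angles of pair displacements against
    a uniform distribution.

    Returns (bin_counts, chi2, p_value). Zero-length displacements are
    excluded; if all displacements are zero the test is undefined and a
    ValueError is raised. An isotropic (white) mismatch gives a high p.
    """
    d = pairs.displacements
    nonzero = np.hypot(d[:, 0], d[:, 1]) > 0
    if not nonzero.any():
        raise ValueError("all displacements are zero: angle distribution undefined")
    angles = np.arctan2(d[nonzero, 1], d[nonzero, 0])  # (-pi, pi]
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    chi2, p = stats.chisquare(counts)
    return counts, float(chi2), float(p)


def zstack_displacement_analysis(
    centroids_per_plane: list[np.ndarray], z_values: np.ndarray
):
    """Centroid stability across a focus (z) stack, after drift removal.

    `centroids_per_plane[k]` holds the (n_cells, 2) centroids of the SAME
    cells, in the same order, in plane k. Each plane's mean centroid is
    subtracted (removes stage drift); each cell's displacement is measured
    from its stack-mean position. Returns (per_plane_rms, overall_rms):
    RMS of the 2-D displacement magnitude over cells, per plane and overall.
    """
    arr = np.asarray(centroids_per_plane, dtype=float)  # (planes, cells, 2)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError("need (n_planes, n_cells, 2) centroid array")
    if len(z_values) != arr.shape[0]:
        raise ValueError("z_values length must match number of planes")
    if not np.all(np.isfinite(arr)):
        # drop cells missing from any plane
        ok = np.all(np.isfinite(arr), axis=(0, 2))
        import warnings

        warnings.warn(
            f"excluding {np.count_nonzero(~ok)} cells missing from some plane",
            stacklevel=2,
        )
        arr = arr[:, ok, :]
    drift_removed = arr - arr.mean(axis=1, keepdims=True)  # per-plane mean out
    dev = drift_removed - drift_removed.mean(axis=0, keepdims=True)  # vs stack mean
    sq = (dev**2).sum(axis=2)  # (planes, cells) squared magnitudes
    per_plane_rms = np.sqrt(sq.mean(axis=1))
    overall_rms = float(np.sqrt(sq.mean()))
    return per_plane_rms, overall_rms


# ---------------------------------------------------------------------------
# track-level matching across programs


def _shared_samples(ta: Track, tb: Track) -> tuple[np.ndarray, np.ndarray]:
    common, ia, ib = np.intersect1d(ta.frames, tb.frames, return_indices=True)
    return ta.positions[ia], tb.positions[ib]


def match_track_sets(
    set_a: list[Track], set_b: list[Track], max_mean_dist: float = 10.0
) -> list[tuple[int, int]]:
    """Pair tracks of the same physical cell across two programs' outputs.

    Two tracks match when they overlap in time and their mean distance over
    shared frames is <= `max_mean_dist` (same units as positions); each
    track joins at most one pair (greedy by ascending mean distance).
    """
    cands = []
    for i, ta in enumerate(set_a):
        for j, tb in enumerate(set_b):
            pa, pb = _shared_samples(ta, tb)
            if len(pa) == 0:
                continue
            md = float(np.hypot(*(pb - pa).T).mean())
            if md <= max_mean_dist:
                cands.append((md, i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for _, i, j in cands:
        if i not in used_a and j not in used_b:
            out.append((i, j))
            used_a.add(i)
            used_b.add(j)
    return out


def common_track_subset(
    track_sets: list[list[Track]], max_mean_dist: float = 10.0
) -> list[tuple[int, ...]]:
    """Tuples of track indices present in ALL sets (pairwise matched).

    A tuple (i₀, i₁, ..., i_{k-1}) is common when every pair of its members
    matches under `match_track_sets`' criterion. Built by intersecting the
    pairwise matchings against the first set.
    """
    if len(track_sets) < 2:
        raise ValueError("need at least two track sets")
    base = track_sets[0]
    maps = []
    for other in track_sets[1:]:
        maps.append(dict(match_track_sets(base, other, max_mean_dist)))
    out = []
    for i in range(len(base)):
        if all(i in m for m in maps):
            out.append((i, *[m[i] for m in maps]))
    # verify remaining pairwise consistency between non-base sets
    verified = []
    for tup in out:
        ok = True
        for a in range(1, len(track_sets)):
            for b in range(a + 1, len(track_sets)):
                ta = track_sets[a][tup[a]]
                tb = track_sets[b][tup[b]]
                pa, pb = _shared_samples(ta, tb)
                if len(pa) == 0 or np.hypot(*(pb - pa).T).mean() > max_mean_dist:
                    ok = False
        if ok:
            verified.append(tup)
    return verified


def align_track_pair(ta: Track, tb: Track) -> MatchedPairs:
    """MatchedPairs over shared (track, frame) samples, for RMSD analyses."""
    pa, pb = _shared_samples(ta, tb)
    if len(pa) == 0:
        raise ValueError("tracks share no frames")
    pairs = [(k, k) for k in range(len(pa))]
    return MatchedPairs(
        pairs=pairs, positions_a=pa, positions_b=pb, unmatched_a=[], unmatched_b=[]
    )
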