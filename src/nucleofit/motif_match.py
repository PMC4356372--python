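"""Rigid placement of motif phosphate patterns into detected phosphate sets.

The matcher finds rigid-body transforms that superpose the ordered P-atom
pattern of a motif (M) onto a subset of the detected phosphate positions
(P).  All non-degenerate triplets of motif P atoms are compared against
geometrically similar triplets of target points (every pairwise distance
within a tolerance); each triplet correspondence proposes a least-squares
rigid transform (Kabsch), which is scored by the RMSD of the closest
one-to-one P pairs after applying it to the whole pattern.

Matching runs over an ascending RMSD-threshold schedule (0.5 to 1.0 Å by
default).  Every time a plausible solution is accepted its target points
are consumed and become unavailable to later matches, which keeps the
combinatorics in check; very large point sets are first partitioned into
overlapping boxes of fewer than 1000 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "RigidTransform",
    "MatchResult",
    "superpose_triplet",
    "kabsch",
    "find_similar_triplets",
    "match_motif",
    "partition_targets",
    "DEFAULT_SCHEDULE",
]

DEFAULT_SCHEDULE = (0.5, 0.75, 1.0)  # Å
EDGE_RANGE = (4.0, 25.0)             # Å; motif triplet edge-length window
PAIR_CUTOFF = 2.0                    # Å; max distance for a scored P pair
MIN_PAIR_FRACTION = 0.6              # fraction of motif P that must pair


@dataclass
class RigidTransform:
    """Proper rotation + translation, acting as x -> R x + t."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, float).reshape(3, 3)
        self.t = np.asarray(self.t, float).reshape(3)
        if abs(np.linalg.det(self.R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: first apply `other`, then `self`."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class MatchResult:
    transform: RigidTransform
    pairs: list[tuple[int, int]]       # (motif P index, target P index)
    rmsd: float
    consumed: frozenset = field(default_factory=frozenset)
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if not self.consumed:
            self.consumed = frozenset(j for _i, j in self.pairs)


def kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping `src` onto `dst`."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cd - R @ cs)


def _triplet_degenerate(pts: np.ndarray, min_edge: float = 0.1) -> bool:
    d01 = np.linalg.norm(pts[0] - pts[1])
    d02 = np.linalg.norm(pts[0] - pts[2])
    d12 = np.linalg.norm(pts[1] - pts[2])
    if min(d01, d02, d12) <= min_edge:
        return True
    area = 0.5 * np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
    return area < 0.01


def superpose_triplet(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Optimal proper rigid superposition of one point triplet onto another."""
    src = np.asarray(src, float).reshape(3, 3)
    dst = np.asarray(dst, float).reshape(3, 3)
    if _triplet_degenerate(src) or _triplet_degenerate(dst):
        raise ValueError("degenerate triplet (collinear or coincident points)")
    return kabsch(src, dst)


def _target_positions(targets) -> np.ndarray:
    pos = getattr(targets, "positions", targets)
    return np.asarray(pos, float).reshape(-1, 3)


def find_similar_triplets(
    motif_triplet: np.ndarray,
    targets,
    edge_tolerance: float,
) -> list[tuple[int, int, int]]:
    """Ordered target index triplets congruent to the motif triplet.

    A returned triplet (i, j, k) satisfies |d(i,j) - d01| <= tol,
    |d(i,k) - d02| <= tol and |d(j,k) - d12| <= tol, i.e. vertex q of the
    result corresponds to vertex q of the motif triplet.
    """
    pts = _target_positions(targets)
    if len(pts) < 3:
        return []
    m = np.asarray(motif_triplet, float).reshape(3, 3)
    d01 = np.linalg.norm(m[0] - m[1])
    d02 = np.linalg.norm(m[0] - m[2])
    d12 = np.linalg.norm(m[1] - m[2])
    tree = cKDTree(pts)
    out = []
    # candidate (i, j) pairs for the 0-1 edge
    pairs = tree.query_pairs(d01 + edge_tolerance, output_type="ndarray")
    if len(pairs) == 0:
        return []
    dist = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    pairs = pairs[np.abs(dist - d01) <= edge_tolerance]
    for i, j in np.vstack([pairs, pairs[:, ::-1]]):
        ks = tree.query_ball_point(pts[i], d02 + edge_tolerance)
        for k in ks:
            if k == i or k == j:
                continue
            if abs(np.linalg.norm(pts[i] - pts[k]) - d02) > edge_tolerance:
                continue
            if abs(np.linalg.norm(pts[j] - pts[k]) - d12) > edge_tolerance:
                continue
            out.append((int(i), int(j), int(k)))
    return out


def _closest_pairs(
    moved: np.ndarray, pts: np.ndarray, available: np.ndarray,
    cutoff: float = PAIR_CUTOFF,
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one pairing of transformed motif points with available
    targets, by ascending distance, within `cutoff`."""
    av_idx = np.where(available)[0]
    if len(av_idx) == 0:
        return []
    tree = cKDTree(pts[av_idx])
    cand = []
    for mi, p in enumerate(moved):
        dists, locs = tree.query(p, k=min(3, len(av_idx)),
                                 distance_upper_bound=cutoff)
        dists = np.atleast_1d(dists)
        locs = np.atleast_1d(locs)
        for d, loc in zip(dists, locs):
            if np.isfinite(d):
                cand.append((float(d), mi, int(av_idx[loc])))
    cand.sort()
    used_m: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for d, mi, tj in cand:
        if mi in used_m or tj in used_t:
            continue
        used_m.add(mi)
        used_t.add(tj)
        pairs.append((mi, tj, d))
    return pairs


def _evaluate_transform(
    tr: RigidTransform, motif_pts: np.ndarray, pts: np.ndarray,
    available: np.ndarray, threshold: float,
    min_pair_fraction: float = MIN_PAIR_FRACTION,
) -> MatchResult | None:
    """Score a candidate transform; one Kabsch re-fit on the matched pairs."""
    min_pairs = max(3, int(np.ceil(min_pair_fraction * len(motif_pts))))
    for _ in range(2):  # initial pairing, then one refined pairing
        moved = tr.apply(motif_pts)
        pairs = _closest_pairs(moved, pts, available)
        if len(pairs) < min_pairs:
            return None
        src = motif_pts[[mi for mi, _t, _d in pairs]]
        dst = pts[[tj for _m, tj, _d in pairs]]
        tr = kabsch(src, dst)
    moved = tr.apply(motif_pts)
    pairs = _closest_pairs(moved, pts, available)
    if len(pairs) < min_pairs:
        return None
    sq = [(np.linalg.norm(moved[mi] - pts[tj]) ** 2) for mi, tj, _d in pairs]
    rmsd = float(np.sqrt(np.mean(sq)))
    if rmsd > threshold:
        return None
    return MatchResult(tr, [(mi, tj) for mi, tj, _d in pairs], rmsd,
                       threshold=threshold)


def _motif_triplets(motif_pts: np.ndarray,
                    edge_range: tuple[float, float] = EDGE_RANGE) -> list:
    out = []
    n = len(motif_pts)
    for i, j, k in combinations(range(n), 3):
        trip = motif_pts[[i, j, k]]
        edges = [np.linalg.norm(trip[0] - trip[1]),
                 np.linalg.norm(trip[0] - trip[2]),
                 np.linalg.norm(trip[1] - trip[2])]
        if min(edges) < edge_range[0] or max(edges) > edge_range[1]:
            continue
        if _triplet_degenerate(trip):
            continue
        out.append((i, j, k))
    return out


def _best_match(
    motif_pts: np.ndarray, pts: np.ndarray, available: np.ndarray,
    threshold: float, triplets: list,
    context_pts: np.ndarray | None = None,
    min_pair_fraction: float = MIN_PAIR_FRACTION,
) -> MatchResult | None:
    edge_tol = threshold * np.sqrt(3.0)  # no triplet realizable at the
    # RMSD threshold can have an edge deviating by more than sqrt(3) * rmsd
    best: MatchResult | None = None
    best_key = None
    avail_set = _target_positions(pts)[available]
    avail_map = np.where(available)[0]
    all_tree = cKDTree(pts if context_pts is None else context_pts)
    seen: set[tuple] = set()
    for (i, j, k) in triplets:
        m_trip = motif_pts[[i, j, k]]
        for ti, tj, tk in find_similar_triplets(m_trip, avail_set, edge_tol):
            trip_pts = avail_set[[ti, tj, tk]]
            try:
                tr = superpose_triplet(m_trip, trip_pts)
            except ValueError:
                continue
            res = _evaluate_transform(tr, motif_pts, pts, available,
                                      threshold, min_pair_fraction)
            if res is None:
                continue
            sig = tuple(np.round(np.concatenate([res.transform.R.ravel(),
                                                 res.transform.t]), 2))
            if sig in seen:
                continue
            seen.add(sig)
            # tie-break: unmatched motif P atoms should still lie on the
            # full phosphate pattern (consumed points included) -- this
            # favours in-register placements over overhanging ones
            matched = {mi for mi, _tj in res.pairs}
            rest = [m for m in range(len(motif_pts)) if m not in matched]
            if rest:
                moved = res.transform.apply(motif_pts[rest])
                penalty = float(all_tree.query(moved)[0].sum())
            else:
                penalty = 0.0
            key2 = (round(res.rmsd, 6), round(penalty, 6),
                    min(res.consumed), sorted(res.consumed))
            if best_key is None or key2 < best_key:
                best, best_key = res, key2
    return best


def match_motif(
    motif,
    targets,
    schedule: tuple = DEFAULT_SCHEDULE,
    edge_range: tuple[float, float] = EDGE_RANGE,
    context_targets=None,
    min_pair_fraction: float = MIN_PAIR_FRACTION,
) -> list[MatchResult]:
    """Sequential motif matching with target consumption.

    For each RMSD threshold of the ascending `schedule`, the best remaining
    placement (lowest RMSD; ties broken by the lowest consumed target
    index) is accepted and its matched target points are removed, until no
    plausible placement remains; then the threshold is raised.

    `context_targets` (default: the targets themselves) is the phosphate
    pattern against which unmatched motif P atoms are judged when breaking
    ties between equal-RMSD placements; passing the full pre-consumption
    pattern keeps placements in register with previously matched motifs.
    """
    motif_pts = np.asarray(getattr(motif, "p_pattern", motif), float)
    if len(motif_pts) < 3:
        raise ValueError("motif must contain at least 3 P atoms")
    if list(schedule) != sorted(schedule):
        raise ValueError("threshold schedule must be ascending")
    pts = _target_positions(targets)
    available = np.ones(len(pts), bool)
    triplets = _motif_triplets(motif_pts, edge_range)
    if not triplets:
        raise ValueError("motif has no usable (non-degenerate) P triplet")
    context = None if context_targets is None \
        else _target_positions(context_targets)
    results: list[MatchResult] = []
    for thr in schedule:
        while available.sum() >= 3:
            res = _best_match(motif_pts, pts, available, thr, triplets,
                              context_pts=context,
                              min_pair_fraction=min_pair_fraction)
            if res is None:
                break
            results.append(res)
            for j in res.consumed:
                available[j] = False
    return results


def partition_targets(
    targets, max_points: int = 1000, overlap: float = 25.0
):
    """Split a large phosphate set into overlapping boxes of < `max_points`.

    Boxes overlap by at least `overlap` Å (the motif diameter bound) so a
    match straddling a boundary is fully contained in at least one box.
    Returns a list of index arrays into the original point list.
    """
    pts = _target_positions(targets)
    boxes: list[np.ndarray] = []

    def split(idx: np.ndarray) -> None:
        if len(idx) < max_points:
            boxes.append(idx)
            return
        sub = pts[idx]
        spans = sub.max(axis=0) - sub.min(axis=0)
        ax = int(np.argmax(spans))
        if spans[ax] <= 2.0 * overlap:  # cannot shrink further: accept as-is
            boxes.append(idx)
            return
        cut = np.median(sub[:, ax])
        left = idx[sub[:, ax] <= cut + overlap]
        right = idx[sub[:, ax] > cut - overlap]
        if len(left) == len(idx) or len(right) == len(idx):
            boxes.append(idx)
            return
        split(left)
        split(right)

    split(np.arange(len(pts)))
    return boxes


def matches_to_frame(matches: list[MatchResult]):
    """Match list as a DataFrame (rotation, translation, RMSD, pair count)."""
    import pandas as pd

    rows = []
    for m in matches:
        row = {f"r{i}{j}": m.transform.R[i, j] for i in range(3)
               for j in range(3)}
        row.update(tx=m.transform.t[0], ty=m.transform.t[1],
                   tz=m.transform.t[2], rmsd=m.rmsd,
                   n_pairs=len(m.pairs), threshold=m.threshold)
        rows.append(row)
    return pd.DataFrame(rows)
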