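"""Segmentation quality criteria for (reference, segmentation) label pairs.

Implements the pair-counting Rand Index and (unbounded) Jaccard Index,
the per-object Hausdorff metric, the Normalized Sum of Distances, and
the object-level added / missing / split / merged error counts used to
benchmark nucleus segmentation algorithms.

Pair-counting metrics are computed from the label contingency table over
all voxels (background counts as one block), never by pair enumeration.
Object-level metrics use maximal-overlap matching: each segmented object
is assigned to the reference object it overlaps most, or to background
(counted as added) when it overlaps no reference object.  Distances are
physical, i.e. anisotropy-aware via the voxel spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .volume_io import LabelImage

__all__ = [
    "EvaluationReport",
    "match_objects",
    "ObjectMatching",
    "rand_index",
    "jaccard_index",
    "hausdorff_metric",
    "nsd",
    "count_errors",
    "evaluate",
]


@dataclass(frozen=True)
class EvaluationReport:
    rand_index: float  # percentage in [0, 100]
    jaccard_index: float  # ratio, not upper-bounded; inf when identical
    hausdorff: float  # physical distance, mean over matched object pairs
    nsd: float  # ratio in [0, 1], mean over matched pairs
    n_split: int
    n_merged: int
    n_added: int
    n_missing: int
    n_reference: int
    n_segmented: int

    @property
    def nsd_x10(self) -> float:
        return self.nsd * 10.0

    def as_dict(self) -> dict:
        return {
            "rand_index": self.rand_index,
            "jaccard_index": self.jaccard_index,
            "hausdorff": self.hausdorff,
            "nsd": self.nsd,
            "nsd_x10": self.nsd_x10,
            "n_split": self.n_split,
            "n_merged": self.n_merged,
            "n_added": self.n_added,
            "n_missing": self.n_missing,
            "n_reference": self.n_reference,
            "n_segmented": self.n_segmented,
        }


@dataclass(frozen=True)
class ObjectMatching:
    """Overlap bookkeeping between reference and segmented objects.

    ``overlap[(r, s)]`` is the voxel count of reference label r (0 =
    background) under segmented label s.  ``seg_to_ref`` maps each
    segmented label to its maximal-overlap reference object (ties to the
    smaller reference label); a segment overlapping no reference object
    at all is assigned to background (0) and counts as added.
    ``ref_to_seg`` is the dual assignment.
    """

    overlap: dict[tuple[int, int], int]
    seg_to_ref: dict[int, int]
    ref_to_seg: dict[int, int]
    ref_labels: tuple[int, ...]
    seg_labels: tuple[int, ...]


def _check_pair(reference: LabelImage, segmentation: LabelImage) -> None:
    if reference.shape != segmentation.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs "
            f"segmentation {segmentation.shape}"
        )


def _contingency(ref: np.ndarray, seg: np.ndarray) -> dict[tuple[int, int], int]:
    pairs = np.stack([ref.ravel(), seg.ravel()], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    return {(int(r), int(s)): int(c) for (r, s), c in zip(uniq, counts)}


def match_objects(
    reference: LabelImage, segmentation: LabelImage
) -> ObjectMatching:
    """Maximal-overlap correspondence between the two label images."""
    _check_pair(reference, segmentation)
    overlap = _contingency(reference.labels, segmentation.labels)
    ref_labels = tuple(int(v) for v in reference.label_values())
    seg_labels = tuple(int(v) for v in segmentation.label_values())

    def _argmax_partner(label: int, axis: int) -> int:
        # axis 0: fixed segmented label, search reference partners; axis 1: dual
        best_count, best_partner = 0, 0
        for (r, s), c in overlap.items():
            partner, own = (r, s) if axis == 0 else (s, r)
            if own != label or partner == 0:
                continue
            if c > best_count or (c == best_count and partner < best_partner):
                best_count, best_partner = c, partner
        return best_partner

    seg_to_ref = {s: _argmax_partner(s, axis=0) for s in seg_labels}
    ref_to_seg = {r: _argmax_partner(r, axis=1) for r in ref_labels}
    return ObjectMatching(
        overlap=overlap,
        seg_to_ref=seg_to_ref,
        ref_to_seg=ref_to_seg,
        ref_labels=ref_labels,
        seg_labels=seg_labels,
    )


def _pair_counts(reference: LabelImage, segmentation: LabelImage) -> tuple[int, int]:
    """(agreeing, disagreeing) unordered voxel-pair counts via the
    contingency table."""
    _check_pair(reference, segmentation)
    n = reference.labels.size
    if n < 2:
        raise ValueError("need at least 2 voxels for pair-counting metrics")
    overlap = _contingency(reference.labels, segmentation.labels)
    nij = np.array(list(overlap.values()), dtype=np.int64)
    ref_vals, ref_counts = np.unique(reference.labels, return_counts=True)
    seg_vals, seg_counts = np.unique(segmentation.labels, return_counts=True)

    def comb2(x):
        return (x * (x - 1)) // 2

    total_pairs = comb2(n)
    same_both = int(comb2(nij).sum())  # pairs together in both partitions
    same_ref = int(comb2(ref_counts.astype(np.int64)).sum())
    same_seg = int(comb2(seg_counts.astype(np.int64)).sum())
    # together in ref only / seg only; apart in both by complement
    ref_only = same_ref - same_both
    seg_only = same_seg - same_both
    apart_both = total_pairs - same_ref - same_seg + same_both
    agreeing = same_both + apart_both
    disagreeing = ref_only + seg_only
    return agreeing, disagreeing


def rand_index(reference: LabelImage, segmentation: LabelImage) -> float:
    """Fraction of voxel pairs labelled consistently in both images, as a
    percentage (100 = perfect agreement)."""
    agreeing, disagreeing = _pair_counts(reference, segmentation)
    return 100.0 * agreeing / (agreeing + disagreeing)


def jaccard_index(reference: LabelImage, segmentation: LabelImage) -> float:
    """Agreeing voxel pairs divided by disagreeing pairs (not
    upper-bounded; inf for perfect agreement)."""
    agreeing, disagreeing = _pair_counts(reference, segmentation)
    if disagreeing == 0:
        return math.inf
    return agreeing / disagreeing


def _object_coords(labels: np.ndarray, label: int, spacing: np.ndarray) -> np.ndarray:
    idx = np.nonzero(labels == label)
    return np.stack([idx[a] * spacing[a] for a in range(labels.ndim)], axis=1)


def _matched_pairs(matching: ObjectMatching) -> list[tuple[int, int]]:
    return [(r, s) for s, r in matching.seg_to_ref.items() if r != 0]


def hausdorff_metric(
    reference: LabelImage,
    segmentation: LabelImage,
    matching: ObjectMatching | None = None,
) -> float:
    """Mean symmetric Hausdorff distance over matched object pairs.

    The Hausdorff distance of two voxel sets is the maximum over the set
    of minimal distances between the shapes, in physical coordinates.
    Returns NaN when no objects match.
    """
    _check_pair(reference, segmentation)
    if matching is None:
        matching = match_objects(reference, segmentation)
    pairs = _matched_pairs(matching)
    if not pairs:
        return math.nan
    spacing = np.asarray(reference.spacing)
    dists = []
    for r, s in pairs:
        ref_pts = _object_coords(reference.labels, r, spacing)
        seg_pts = _object_coords(segmentation.labels, s, spacing)
        d = max(
            directed_hausdorff(ref_pts, seg_pts)[0],
            directed_hausdorff(seg_pts, ref_pts)[0],
        )
        dists.append(d)
    return float(np.mean(dists))


def nsd(
    reference: LabelImage,
    segmentation: LabelImage,
    matching: ObjectMatching | None = None,
) -> float:
    """Normalized Sum of Distances, mean over matched object pairs.

    For each pair, every voxel is weighted by its physical distance to
    the border of the reference object; the score is the weighted mass
    of disagreeing voxels (symmetric difference) over the weighted mass
    of the union.  0 = perfect agreement, 1 = no overlap at all.
    """
    _check_pair(reference, segmentation)
    if matching is None:
        matching = match_objects(reference, segmentation)
    pairs = _matched_pairs(matching)
    if not pairs:
        return math.nan
    spacing = np.asarray(reference.spacing)
    scores = []
    for r, s in pairs:
        ref_mask = reference.labels == r
        seg_mask = segmentation.labels == s
        # restrict to the union bounding box: the reference border (the
        # distance source) lies inside it, so the transform is unchanged
        union = ref_mask | seg_mask
        bbox = ndimage.find_objects(union.astype(np.int8))[0]
        ref_mask, seg_mask, union = ref_mask[bbox], seg_mask[bbox], union[bbox]
        border = ref_mask & ~ndimage.binary_erosion(ref_mask)
        dist = ndimage.distance_transform_edt(~border, sampling=spacing)
        disagree = ref_mask ^ seg_mask
        denom = dist[union].sum()
        if denom == 0:
            scores.append(0.0)
            continue
        scores.append(float(dist[disagree].sum() / denom))
    return float(np.mean(scores))


def count_errors(matching: ObjectMatching) -> tuple[int, int, int, int]:
    """Object-level error counts ``(n_split, n_merged, n_added, n_missing)``.

    * missing: reference objects no segmented object was assigned to;
    * added: segmented objects assigned to background;
    * split: for each reference object with k >= 2 assigned segments,
      k - 1 splits;
    * merged: by the dual assignment, each segmented object claimed as
      maximal-overlap target by k >= 2 reference objects contributes
      k - 1 merges.
    """
    assigned_to: dict[int, int] = {}
    for s, r in matching.seg_to_ref.items():
        if r != 0:
            assigned_to[r] = assigned_to.get(r, 0) + 1
    n_missing = sum(1 for r in matching.ref_labels if r not in assigned_to)
    n_added = sum(1 for s, r in matching.seg_to_ref.items() if r == 0)
    n_split = sum(max(0, k - 1) for k in assigned_to.values())
    claims: dict[int, int] = {}
    for r, s in matching.ref_to_seg.items():
        if s != 0:
            claims[s] = claims.get(s, 0) + 1
    n_merged = sum(max(0, k - 1) for k in claims.values())
    return n_split, n_merged, n_added, n_missing


def evaluate(reference: LabelImage, segmentation: LabelImage) -> EvaluationReport:
    """Compute the full report for one (reference, segmentation) pair."""
    matching = match_objects(reference, segmentation)
    n_split, n_merged, n_added, n_missing = count_errors(matching)
    return EvaluationReport(
        rand_index=rand_index(reference, segmentation),
        jaccard_index=jaccard_index(reference, segmentation),
        hausdorff=hausdorff_metric(reference, segmentation, matching),
        nsd=nsd(reference, segmentation, matching),
        n_split=n_split,
        n_merged=n_merged,
        n_added=n_added,
        n_missing=n_missing,
        n_reference=len(matching.ref_labels),
        n_segmented=len(matching.seg_labels),
    )
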