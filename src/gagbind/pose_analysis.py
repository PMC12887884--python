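"""Bound-pose geometry: orientation filter, distance-RMSD features,
Ward clustering with medoid selection.

A bound pose is kept for refinement only if the glycan long axis lies
within 45 degrees of the fibril axis (inclusive).  Kept poses are described
by the vector of each glycan sulfur's distance to the nearest atom of the
binding residue(s); pairwise distance-RMSDs between these vectors feed
Ward agglomerative clustering, and each cluster is represented by its
medoid (the member minimizing summed distance to co-members).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .geometry import Pose

ANGLE_THRESHOLD = 45.0   # degrees, inclusive


@dataclass
class PoseRecord:
    pose: Pose
    bound_site: int
    angle_to_axis: float           # degrees in [0, 90]
    feature_vector: np.ndarray     # per-sulfur nearest-atom distances, Å


@dataclass
class ClusterResult:
    labels: np.ndarray             # cluster id per pose, 0-based
    k: int
    medoid_indices: np.ndarray     # one pose index per cluster
    linkage_record: np.ndarray     # scipy linkage matrix


def fibril_axis(fibril) -> np.ndarray:
    """Unit fibril axis: third-layer centroid to third-to-last-layer centroid.

    When those two layers coincide (fewer than 6 layers) the documented
    fallback uses the first and last layers instead.
    """
    cents = fibril.layer_centroids()
    n = len(cents)
    i, j = 2, n - 3
    if i >= j:
        i, j = 0, n - 1
    v = cents[j] - cents[i]
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError("degenerate fibril axis: coincident layer centroids")
    return v / norm


def glycan_axis(glycan, pose: Pose | None = None) -> np.ndarray:
    """Unit glycan axis: first to last ring centroid (world frame if posed)."""
    cents = glycan.ring_centroids
    if len(cents) < 2:
        raise ValueError("glycan axis needs at least two units")
    if pose is not None:
        cents = pose.apply(cents)
    v = cents[-1] - cents[0]
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError("degenerate glycan axis: coincident ring centroids")
    return v / norm


def orientation_angle(fibril, glycan, pose: Pose) -> float:
    """Angle in degrees between the glycan and fibril axes, folded to [0, 90]."""
    dot = abs(float(np.dot(fibril_axis(fibril), glycan_axis(glycan, pose))))
    return float(np.degrees(np.arccos(np.clip(dot, 0.0, 1.0))))


def bound_aligned(fibril, glycan, pose: Pose,
                  threshold: float = ANGLE_THRESHOLD) -> bool:
    """Orientation filter: axis angle <= threshold (45 degrees, inclusive).

    A 1e-9 degree grace keeps poses constructed at exactly the threshold on
    the aligned side despite arccos rounding.
    """
    return orientation_angle(fibril, glycan, pose) <= threshold + 1e-9


def pose_features(pose: Pose, fibril, glycan, site_residues) -> np.ndarray:
    """Per-sulfur distance to the nearest binding-residue atom (all layers)."""
    if not len(list(site_residues)):
        raise ValueError("site_residues must be nonempty")
    site_atoms = fibril.positions[fibril.residue_atom_mask(site_residues)]
    sulfurs = pose.apply(glycan.sulfur_positions)
    d = np.linalg.norm(sulfurs[:, None, :] - site_atoms[None, :, :], axis=2)
    return d.min(axis=1)


def distance_rmsd(f1: np.ndarray, f2: np.ndarray) -> float:
    """RMS difference between two equal-length feature vectors."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if f1.shape != f2.shape:
        raise ValueError("feature vectors must have equal length")
    return float(np.sqrt(np.mean((f1 - f2) ** 2)))


def ward_cluster(features, k: int) -> ClusterResult:
    """Ward agglomerative clustering on pairwise distance-RMSDs.

    The linkage operates on the precomputed distance-RMSD matrix via the
    Lance-Williams update (Ward on non-Euclidean precomputed distances is
    an accepted extension of the minimum-variance method).  Clusters are cut
    at ``k`` and relabelled in order of first appearance; the medoid of each
    cluster is found by exhaustive scan of summed within-cluster distances.
    """
    feats = np.asarray(features, dtype=float)
    n = len(feats)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    d = feats.shape[1] if feats.ndim == 2 else 1
    condensed = pdist(feats.reshape(n, -1)) / np.sqrt(d)
    if n == 1:
        return ClusterResult(np.zeros(1, dtype=int), 1, np.zeros(1, dtype=int),
                             np.empty((0, 4)))
    z = linkage(condensed, method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")
    # deterministic relabel: cluster ids in order of first appearance
    labels = np.empty(n, dtype=int)
    mapping = {}
    for idx, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        labels[idx] = mapping[lab]
    k_eff = len(mapping)
    dmat = squareform(condensed)
    medoids = np.empty(k_eff, dtype=int)
    for c in range(k_eff):
        members = np.flatnonzero(labels == c)
        sums = dmat[np.ix_(members, members)].sum(axis=1)
        medoids[c] = members[np.argmin(sums)]
    return ClusterResult(labels, k_eff, medoids, z)


def filter_and_cluster(outcomes, fibril, glycan, site_residues, k: int = 10,
                       angle_threshold: float = ANGLE_THRESHOLD):
    """Select aligned reacted poses at the given site(s) and cluster them.

    Returns ``(records, cluster_result_or_None)``; clustering is skipped
    (None) when fewer than 2 poses survive the filter.
    """
    site_set = set(site_residues)
    records = []
    for out in outcomes:
        if out.status != "reacted" or out.site not in site_set:
            continue
        angle = orientation_angle(fibril, glycan, out.final_pose)
        if angle > angle_threshold:
            continue
        fv = pose_features(out.final_pose, fibril, glycan, site_residues)
        records.append(PoseRecord(out.final_pose, out.site, angle, fv))
    if len(records) < 2:
        return records, None
    feats = np.array([r.feature_vector for r in records])
    return records, ward_cluster(feats, min(k, len(records)))
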