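"""Contact-pattern analysis: density clustering of contact-map points and
the coverage statistics built on it.

Native contacts between packed secondary-structure elements appear as
dense clusters of points on the contact map.  Clustering the medium/long
native contacts with HDBSCAN (hierarchical density-based clustering,
minimum cluster size 3) separates these patterns from isolated, scattered
contacts, and lets two predictors be compared by how many clusters they
hit and how many in-cluster contacts they recover:

* cluster coverage  — clusters containing at least one correctly predicted
  contact, divided by all native clusters;
* contact coverage  — correctly predicted contacts inside clusters,
  divided by all native in-cluster contacts;
* ΔCoverage         — coverage of one predictor minus the other on the
  same native cluster set;
* false-positive proximity — fraction of false positives within a small
  index shift (Chebyshev distance, default 2) of any native cluster member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN

DEFAULT_MIN_CLUSTER_SIZE = 3
DEFAULT_SHIFT = 2


@dataclass
class ClusterSet:
    """Partition of contact-map points into density clusters plus noise."""

    clusters: list[frozenset]
    noise: frozenset
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE

    def __post_init__(self) -> None:
        seen: set = set()
        for c in self.clusters:
            if len(c) < self.min_cluster_size:
                raise ValueError(
                    f"cluster of size {len(c)} below minimum "
                    f"{self.min_cluster_size}"
                )
            if seen & c:
                raise ValueError("clusters overlap")
            seen |= c
        if seen & self.noise:
            raise ValueError("noise points overlap a cluster")

    @property
    def points(self) -> frozenset:
        out = set(self.noise)
        for c in self.clusters:
            out |= c
        return frozenset(out)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def clustered_points(self) -> frozenset:
        out: set = set()
        for c in self.clusters:
            out |= c
        return frozenset(out)

    def basis_key(self) -> frozenset:
        """Hashable identity of the native basis, for ΔCoverage checks."""
        return frozenset(self.clusters) | {("noise", self.noise)}


@dataclass
class CoverageStats:
    """Coverage of a native cluster set by a set of predicted contacts."""

    cluster_coverage: float
    contact_coverage: float
    n_clusters_hit: int
    n_clusters: int
    basis: frozenset = field(repr=False, default=frozenset())

    def __post_init__(self) -> None:
        if not 0.0 <= self.cluster_coverage <= 1.0:
            raise ValueError("cluster coverage must lie in [0, 1]")
        if not 0.0 <= self.contact_coverage <= 1.0:
            raise ValueError("contact coverage must lie in [0, 1]")


def _as_points(points) -> list[tuple[int, int]]:
    pts = sorted({(int(i), int(j)) for (i, j) in points})
    for (i, j) in pts:
        if i >= j:
            raise ValueError(f"contact points must be upper-triangle; got {(i, j)}")
    return pts


def _chebyshev_components(members: set) -> list[set]:
    """Connected components under Chebyshev-distance <= 2 adjacency."""
    remaining = set(members)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            (i, j) = frontier.pop()
            near = {p for p in remaining
                    if max(abs(p[0] - i), abs(p[1] - j)) <= 2}
            remaining -= near
            comp |= near
            frontier.extend(near)
        comps.append(comp)
    return comps


def cluster_contacts(points, min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
                     min_samples: int | None = None) -> ClusterSet:
    """HDBSCAN clustering of contact-map points in (i, j) index space.

    Euclidean metric on the raw indices; ``min_samples`` defaults to
    ``min_cluster_size``.  Points assigned to no cluster are noise; with
    fewer than ``min_cluster_size`` points everything is noise.  Two
    refinements adapt the generic hierarchy to contact maps: (a) when the
    hierarchy never splits (the map is a single dense pattern) the root
    itself is accepted as one cluster, and (b) each density cluster is
    required to be Chebyshev-connected within a two-residue shift — a
    geometric contact pattern is a set of near-adjacent map points, so
    stragglers that joined a cluster only through a weak density bridge are
    reassigned to noise (fragments below the minimum size dissolve
    likewise).  Deterministic for a fixed point set.
    """
    pts = _as_points(points)
    if len(pts) < min_cluster_size:
        return ClusterSet(clusters=[], noise=frozenset(pts),
                          min_cluster_size=min_cluster_size)
    X = np.asarray(pts, dtype=float)
    kwargs = dict(
        min_cluster_size=min_cluster_size,
        min_samples=min_samples if min_samples is not None else min_cluster_size,
        metric="euclidean",
        copy=True,
    )
    labels = HDBSCAN(**kwargs).fit_predict(X)
    if (labels == -1).all():
        labels = HDBSCAN(allow_single_cluster=True, **kwargs).fit_predict(X)
    raw: dict[int, set] = {}
    noise: set = set()
    for pt, lab in zip(pts, labels):
        if lab == -1:
            noise.add(pt)
        else:
            raw.setdefault(int(lab), set()).add(pt)
    clusters: list[frozenset] = []
    for _, members in sorted(raw.items()):
        for comp in sorted(_chebyshev_components(members), key=sorted):
            if len(comp) >= min_cluster_size:
                clusters.append(frozenset(comp))
            else:
                noise |= comp
    return ClusterSet(
        clusters=clusters,
        noise=frozenset(noise),
        min_cluster_size=min_cluster_size,
    )


def true_positives(native_points, predicted) -> set:
    """Predicted pairs that are native contacts."""
    native = set(native_points)
    return {tuple(p) for p in predicted if tuple(p) in native}


def cluster_hits(native: ClusterSet, predicted) -> list[int]:
    """Indices of native clusters hit by >= 1 correctly predicted contact."""
    pred = {tuple(p) for p in predicted}
    return [k for k, c in enumerate(native.clusters) if c & pred]


def coverage_stats(native: ClusterSet, predicted) -> CoverageStats | None:
    """Cluster and contact coverage of the native clusters by predictions.

    Returns None (undefined) when the native map has no clusters.  Only
    true positives count: a predicted pair contributes iff it coincides
    with a native in-cluster contact.
    """
    if native.n_clusters == 0:
        return None
    hits = cluster_hits(native, predicted)
    in_cluster = native.clustered_points
    tp_in_cluster = true_positives(in_cluster, predicted)
    return CoverageStats(
        cluster_coverage=len(hits) / native.n_clusters,
        contact_coverage=len(tp_in_cluster) / len(in_cluster),
        n_clusters_hit=len(hits),
        n_clusters=native.n_clusters,
        basis=native.basis_key(),
    )


def delta_coverage(a: CoverageStats, b: CoverageStats) -> dict:
    """Signed coverage difference a - b on the same native basis."""
    if a.basis != b.basis:
        raise ValueError("coverage stats computed on different native cluster sets")
    return {
        "cluster_coverage": a.cluster_coverage - b.cluster_coverage,
        "contact_coverage": a.contact_coverage - b.contact_coverage,
    }


def fp_proximity_fraction(false_positives, native: ClusterSet,
                          shift: int = DEFAULT_SHIFT) -> float | None:
    """Fraction of false positives within ``shift`` of a native cluster.

    Distance is Chebyshev in (i, j) index space, so shift 2 means at most a
    two-residue displacement in either index.  Undefined (None) when there
    are no false positives.
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    fps = [tuple(p) for p in false_positives]
    if not fps:
        return None
    members = native.clustered_points
    if not members:
        return 0.0
    mem = np.asarray(sorted(members), dtype=int)
    near = 0
    for (i, j) in fps:
        cheb = np.maximum(np.abs(mem[:, 0] - i), np.abs(mem[:, 1] - j)).min()
        if cheb <= shift:
            near += 1
    return near / len(fps)


def truncate_to_count(pred: np.ndarray, n: int, native=None,
                      regimes=("medium", "long")) -> set:
    """Top-n ranked pairs of a map — the equal-footing comparison protocol.

    When comparing a second predictor against a reference that made n
    positive predictions, the second map is truncated to its n top-ranked
    pairs so both methods are judged on the same number of predictions.
    """
    from .evaluation import ranked_pairs

    return set(ranked_pairs(pred, native, regimes)[:n])


def compare_predictors(native_points, pred_a: np.ndarray, pred_b: np.ndarray,
                       cutoff: float = 0.5,
                       min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
                       shift: int = DEFAULT_SHIFT,
                       regimes=("medium", "long")) -> dict:
    """Fig.-3-style comparison of two predictors on one native cluster set.

    Predictor A contributes its positive predictions (P > cutoff);
    predictor B is truncated to the same number of top-ranked pairs.
    Returns both CoverageStats, their ΔCoverage, and the false-positive
    proximity fraction of each.
    """
    from .core import classify_range, positive_predictions

    native_cs = cluster_contacts(native_points,
                                 min_cluster_size=min_cluster_size)
    regime_names = {str(r).lower() for r in regimes}
    pos_a = {p for p in positive_predictions(pred_a, cutoff)
             if classify_range(*p).name.lower() in regime_names}
    pos_b = truncate_to_count(pred_b, len(pos_a), regimes=regimes)
    native_set = set(native_cs.points)
    stats_a = coverage_stats(native_cs, pos_a)
    stats_b = coverage_stats(native_cs, pos_b)
    out = {
        "native_clusters": native_cs.n_clusters,
        "native_noise": len(native_cs.noise),
        "a": stats_a,
        "b": stats_b,
        "fp_near_a": fp_proximity_fraction(
            [p for p in pos_a if p not in native_set], native_cs, shift),
        "fp_near_b": fp_proximity_fraction(
            [p for p in pos_b if p not in native_set], native_cs, shift),
    }
    if stats_a is not None and stats_b is not None:
        out["delta_coverage"] = delta_coverage(stats_a, stats_b)
    return out


def write_clusters_tsv(path, cs: ClusterSet) -> None:
    """Cluster assignments as TSV: i, j, cluster_id, is_noise (1-based)."""
    rows = []
    for k, c in enumerate(cs.clusters):
        rows.extend((i + 1, j + 1, k, 0) for (i, j) in sorted(c))
    rows.extend((i + 1, j + 1, -1, 1) for (i, j) in sorted(cs.noise))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("i\tj\tcluster_id\tis_noise\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")
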