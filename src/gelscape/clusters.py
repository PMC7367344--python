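"""Cluster-level order parameters of the gelation transition.

A frame of particle positions is turned into a contact graph (bonded
pairs), the graph into clusters (connected components), and the
clusters into the observables that track the approach to percolation:

* mean coordination number z = 2·bonds/N (the order parameter),
* fraction of particles in the largest cluster f_z and in the
  second-largest,
* per-cluster radius of gyration R_g (with periodic unwrapping),
* correlation length ξ² = 2 ∑ R_gi² N_i² / ∑ N_i²,
* percolation flag (a cluster bonded to its own periodic image),
* cluster-mass histograms and the mass–size fractal dimension d_f.

Bond criteria: in simulation mode two particles are bonded when their
minimum-image distance is below the inflection point of the pair
potential (scaled per species pair); in experiment mode a plain
distance threshold d0 is used (with open boundaries), and clusters may
be grouped at a looser second threshold d_c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .brownian import ParticleFrame, neighbor_pairs

__all__ = [
    "SimulationCriterion",
    "ExperimentCriterion",
    "ContactGraph",
    "ClusterSet",
    "FrameMetrics",
    "contact_pairs",
    "cluster_labels",
    "mean_coordination",
    "gyration_radius",
    "annotate_geometry",
    "correlation_length",
    "PowerLawFit",
    "mass_histogram",
    "largest_clusters",
    "fractal_dimension",
    "experiment_grouping",
    "frame_metrics",
]


@dataclass(frozen=True)
class SimulationCriterion:
    """Bond when r_ij < inflection radius of the pair potential.

    ``cutoff`` is the a–a inflection distance; per-pair cutoffs scale
    with the pair contact distance via the (2, 2) ``sigma`` matrix.
    Distances use the minimum image in the periodic box.
    """

    cutoff: float
    sigma: np.ndarray | None = None    # per-species-pair scale factors / sigma_aa

    def pair_cutoffs(self, species_i, species_j):
        if self.sigma is None:
            return np.full(len(species_i), self.cutoff)
        return self.cutoff * self.sigma[species_i, species_j]


@dataclass(frozen=True)
class ExperimentCriterion:
    """Bond when r_ij < d0 (open boundaries, point-cloud data)."""

    d0: float


@dataclass
class ContactGraph:
    n: int
    pairs: np.ndarray          # (M, 2) int
    criterion: object = None

    @property
    def n_bonds(self) -> int:
        return len(self.pairs)


@dataclass
class ClusterSet:
    labels: np.ndarray         # (N,) cluster id per particle
    sizes: np.ndarray          # (n_clusters,)
    gyration_radii: np.ndarray | None = None
    spanning: np.ndarray | None = None   # (n_clusters,) bool

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


@dataclass
class FrameMetrics:
    time: float
    z: float
    f_z: float
    f_second: float
    xi: float
    percolating: bool
    n_clusters: int
    largest: int


def contact_pairs(frame: ParticleFrame, criterion) -> ContactGraph:
    """All and only the pairs satisfying the bond criterion."""
    if isinstance(criterion, SimulationCriterion):
        rc_max = criterion.cutoff * (criterion.sigma.max() if criterion.sigma is not None else 1.0)
        pairs, dist = neighbor_pairs(frame, rc_max)
        if criterion.sigma is not None and len(pairs):
            cut = criterion.pair_cutoffs(frame.species[pairs[:, 0]],
                                         frame.species[pairs[:, 1]])
            keep = dist < cut
            pairs = pairs[keep]
        return ContactGraph(n=frame.n, pairs=pairs, criterion=criterion)
    if isinstance(criterion, ExperimentCriterion):
        tree = cKDTree(frame.positions)
        pairs = tree.query_pairs(criterion.d0, output_type="ndarray")
        return ContactGraph(n=frame.n, pairs=pairs, criterion=criterion)
    raise TypeError(f"unknown bond criterion {type(criterion).__name__}")


def cluster_labels(graph: ContactGraph) -> ClusterSet:
    """Connected components, labelled by the smallest member index."""
    if graph.n_bonds:
        m = coo_matrix((np.ones(graph.n_bonds), (graph.pairs[:, 0], graph.pairs[:, 1])),
                       shape=(graph.n, graph.n))
        _, raw = connected_components(m, directed=False)
    else:
        raw = np.arange(graph.n)
    # relabel deterministically: cluster id = rank of its smallest particle
    first = np.full(raw.max() + 1, graph.n, dtype=np.int64)
    np.minimum.at(first, raw, np.arange(graph.n))
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    labels = rank[raw]
    sizes = np.bincount(labels)
    return ClusterSet(labels=labels, sizes=sizes)


def mean_coordination(graph: ContactGraph) -> float:
    """z = 2 · bonds / N."""
    return 2.0 * graph.n_bonds / graph.n


def _unwrap_cluster(members, pairs_in, positions, box):
    """Unwrapped member coordinates via BFS over the bond graph.

    Walks bonds applying minimum-image displacements from an arbitrary
    root.  Returns (coords, spanning): ``spanning`` is True when some
    bond closes a loop around the periodic box, i.e. a particle is
    reached with two different image offsets — the self-image
    percolation signature.
    """
    idx = {p: i for i, p in enumerate(members)}
    adj = [[] for _ in members]
    for a, b in pairs_in:
        adj[idx[a]].append(idx[b])
        adj[idx[b]].append(idx[a])
    coords = np.full((len(members), 3), np.nan)
    pos = positions[members]
    coords[0] = pos[0]
    stack = [0]
    visited = np.zeros(len(members), bool)
    visited[0] = True
    spanning = False
    while stack:
        i = stack.pop()
        for j in adj[i]:
            d = pos[j] - pos[i]
            d -= box * np.round(d / box)
            target = coords[i] + d
            if not visited[j]:
                coords[j] = target
                visited[j] = True
                stack.append(j)
            elif not np.allclose(coords[j], target, atol=1e-6 * box):
                spanning = True
    if not visited.all():
        raise ValueError("cluster is not connected under the supplied bonds")
    return coords, spanning


def gyration_radius(members, graph: ContactGraph, positions, box) -> tuple[float, bool]:
    """R_g of one cluster with periodic unwrapping.

    R_g² = ⟨|r − r_cm|²⟩ over the unwrapped member coordinates.  Also
    returns the spanning flag detected during unwrapping.  For a
    spanning cluster R_g is still reported (on the unwrapped BFS tree)
    but is not unique.
    """
    members = np.asarray(members)
    if len(members) == 1:
        return 0.0, False
    mset = set(members.tolist())
    pairs_in = [(a, b) for a, b in graph.pairs if a in mset and b in mset]
    coords, spanning = _unwrap_cluster(members.tolist(), pairs_in, positions, box)
    com = coords.mean(axis=0)
    rg2 = ((coords - com) ** 2).sum(axis=1).mean()
    return float(np.sqrt(rg2)), spanning


def annotate_geometry(clusters: ClusterSet, graph: ContactGraph,
                      frame: ParticleFrame) -> ClusterSet:
    """Fill gyration radii and spanning flags for every cluster."""
    nc = clusters.n_clusters
    rg = np.zeros(nc)
    span = np.zeros(nc, bool)
    order = np.argsort(clusters.labels, kind="stable")
    bounds = np.searchsorted(clusters.labels[order], np.arange(nc + 1))
    # bucket bonds by cluster label for one pass
    pair_label = clusters.labels[graph.pairs[:, 0]] if graph.n_bonds else np.empty(0, int)
    porder = np.argsort(pair_label, kind="stable")
    pbounds = np.searchsorted(pair_label[porder], np.arange(nc + 1))
    for c in range(nc):
        members = order[bounds[c]:bounds[c + 1]]
        if len(members) == 1:
            continue
        pin = graph.pairs[porder[pbounds[c]:pbounds[c + 1]]]
        coords, s = _unwrap_cluster(members.tolist(), pin.tolist(),
                                    frame.positions, frame.box_edge)
        com = coords.mean(axis=0)
        rg[c] = np.sqrt(((coords - com) ** 2).sum(axis=1).mean())
        span[c] = s
    clusters.gyration_radii = rg
    clusters.spanning = span
    return clusters


def correlation_length(clusters: ClusterSet, include_largest: bool = True) -> float:
    """ξ² = 2 ∑_i R_gi² N_i² / ∑_i N_i² over the selected clusters."""
    if clusters.gyration_radii is None:
        raise ValueError("clusters carry no gyration radii; annotate first")
    sizes = clusters.sizes.astype(float)
    rg = clusters.gyration_radii
    sel = np.ones(len(sizes), bool)
    if not include_largest and len(sizes) > 1:
        sel[np.argmax(sizes)] = False
    num = 2.0 * (rg[sel] ** 2 * sizes[sel] ** 2).sum()
    den = (sizes[sel] ** 2).sum()
    return float(np.sqrt(num / den)) if den > 0 else 0.0


def mass_histogram(clusters: ClusterSet, exclude_largest: bool = False,
                   log_bins: int | None = None, volume: float | None = None):
    """Cluster counts per size k.

    Returns (k values, counts) for linear binning, or (bin centers,
    density per unit k) with ``log_bins`` logarithmic bins.  With
    ``exclude_largest`` exactly one cluster — the largest — is removed
    (the post-percolation convention).  ``volume`` normalizes counts to
    concentrations.
    """
    sizes = clusters.sizes.copy()
    if exclude_largest and len(sizes) > 0:
        sizes = np.delete(sizes, np.argmax(sizes))
    if len(sizes) == 0:
        return np.empty(0, int), np.empty(0)
    norm = volume if volume else 1.0
    if log_bins is None:
        counts = np.bincount(sizes)[1:]
        k = np.arange(1, len(counts) + 1)
        nz = counts > 0
        return k[nz], counts[nz] / norm
    edges = np.unique(np.round(np.logspace(0, np.log10(sizes.max() + 1), log_bins + 1)))
    hist, _ = np.histogram(sizes, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    nz = hist > 0
    return centers[nz], hist[nz] / widths[nz] / norm


def largest_clusters(clusters: ClusterSet):
    """(f_z, second fraction, percolation flag)."""
    n = clusters.labels.size
    sizes = np.sort(clusters.sizes)[::-1]
    f_z = sizes[0] / n
    f_2 = sizes[1] / n if len(sizes) > 1 else 0.0
    perc = bool(clusters.spanning.any()) if clusters.spanning is not None else False
    return float(f_z), float(f_2), perc


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float
    intercept: float
    stderr: float
    window: tuple[float, float]
    n_points: int


def fractal_dimension(clusters: ClusterSet, size_window: tuple[int, int] | None = None,
                      n_boot: int = 200, seed: int | None = None) -> PowerLawFit:
    """d_f from the mass–size relation N_i ∝ R_gi^{d_f} of the clusters.

    The regression is log R_g on log N (sizes are exact counts while
    R_g carries the shape scatter), and d_f is the inverted slope —
    regressing the noisy variable on the exact one avoids the
    attenuation bias of the opposite orientation.  Window defaults to
    3 ≤ N_i ≤ 0.1·N (avoids singletons and the spanning cluster);
    requires at least 10 clusters inside it.
    """
    if clusters.gyration_radii is None:
        raise ValueError("clusters carry no gyration radii; annotate first")
    sizes = clusters.sizes.astype(float)
    rg = clusters.gyration_radii
    if size_window is None:
        size_window = (3, max(3, int(0.1 * sizes.sum())))
    sel = (sizes >= size_window[0]) & (sizes <= size_window[1]) & (rg > 0)
    if clusters.spanning is not None:
        sel &= ~clusters.spanning
    if sel.sum() < 10:
        raise ValueError(f"only {int(sel.sum())} clusters in the fit window; need >= 10")
    x, y = np.log(sizes[sel]), np.log(rg[sel])
    slope, intercept = np.polyfit(x, y, 1)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), len(x))
        if np.ptp(x[idx]) > 0:
            s = np.polyfit(x[idx], y[idx], 1)[0]
            if s > 0:
                boots.append(1.0 / s)
    return PowerLawFit(exponent=float(1.0 / slope), intercept=float(-intercept / slope),
                       stderr=float(np.std(boots)) if boots else np.nan,
                       window=(float(size_window[0]), float(size_window[1])),
                       n_points=int(sel.sum()))


def experiment_grouping(points: np.ndarray, d0: float, dc: float):
    """Experimental double-threshold analysis of a point cloud.

    Bonds (coordination) use the tight threshold d0; cluster grouping
    uses the looser threshold dc.  Returns (bond graph at d0, ClusterSet
    from dc grouping).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    tree = cKDTree(points)
    bonds = tree.query_pairs(d0, output_type="ndarray")
    groups = tree.query_pairs(dc, output_type="ndarray")
    bond_graph = ContactGraph(n=n, pairs=bonds, criterion=ExperimentCriterion(d0))
    clusters = cluster_labels(ContactGraph(n=n, pairs=groups))
    return bond_graph, clusters


def frame_metrics(frame: ParticleFrame, criterion,
                  include_largest_in_xi: bool | None = None) -> FrameMetrics:
    """One frame → (z, f_z, second fraction, ξ, percolation flag).

    By default the spanning cluster is excluded from ξ once the system
    percolates and included before (set ``include_largest_in_xi`` to
    force either choice).
    """
    graph = contact_pairs(frame, criterion)
    clusters = annotate_geometry(cluster_labels(graph), graph, frame)
    f_z, f_2, perc = largest_clusters(clusters)
    if include_largest_in_xi is None:
        include_largest_in_xi = not perc
    xi = correlation_length(clusters, include_largest=include_largest_in_xi)
    return FrameMetrics(time=frame.time, z=mean_coordination(graph), f_z=f_z,
                        f_second=f_2, xi=xi, percolating=perc,
                        n_clusters=clusters.n_clusters,
                        largest=int(clusters.sizes.max()))
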