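"""Synthetic configurations and trajectories with known ground truth.

Every analysis stage in this package can be exercised without running
the simulator: these generators build

* cluster sizes drawn from the stationary law k^(−τ) e^(−k/k_c),
* single clusters grown with a prescribed fractal dimension d_f
  (mass ∝ R_g^{d_f}),
* whole frames of well-separated clusters with machine-readable
  ground-truth partitions, and
* scripted trajectories whose merge/split events follow an explicit
  schedule, for testing event tracking and rate estimation.

Fixtures are statistical stand-ins, not physical configurations: they
carry the target cluster statistics but no dynamics or excluded-volume
structure.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .brownian import ParticleFrame, Trajectory

__all__ = [
    "FixtureSpec",
    "sample_sizes",
    "build_cluster",
    "assemble_frame",
    "MergeEvent",
    "SplitEvent",
    "scripted_trajectory",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Target statistics for a synthetic frame."""

    tau: float = 1.5
    k_c: float = 100.0
    d_f: float = 2.0
    n_clusters: int = 100
    box_edge: float = 200.0
    bond_length: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 1:
            raise ValueError("size-law exponent tau must exceed 1")
        if not (1.0 <= self.d_f <= 3.0):
            raise ValueError("fractal dimension must lie in [1, 3]")
        if self.bond_length >= self.box_edge / 10:
            raise ValueError("bond length must be < box/10")


def sample_sizes(spec: FixtureSpec, n_clusters: int | None = None,
                 k_max: int | None = None, rng=None) -> np.ndarray:
    """i.i.d. cluster sizes from the discrete law k^(−τ) e^(−k/k_c).

    Inverse-CDF sampling on a precomputed table truncated at
    ``k_max`` (default: where the tail weight drops below 10⁻¹²).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_clusters if n_clusters is None else n_clusters
    if k_max is None:
        k_max = max(100, int(30 * spec.k_c))
    k = np.arange(1, k_max + 1)
    w = k ** (-spec.tau) * np.exp(-k / spec.k_c)
    cdf = np.cumsum(w / w.sum())
    u = rng.random(n)
    return np.searchsorted(cdf, u) + 1


def build_cluster(size: int, d_f: float, bond_length: float = 1.0,
                  seed: int | None = None, rng=None) -> np.ndarray:
    """Grow one connected cluster with mass ∝ radius^{d_f}.

    Sequential chain attachment: particle i+1 is bonded to particle i
    at exactly ``bond_length``, with the bond direction chosen so the
    new particle lands as close as possible to the target radial
    envelope ρ_i = c·b·(i + i₀)^(1/d_f) (random azimuth on the feasible
    cone).  The chain winds at constant local density inside a ball
    whose radius grows as N^(1/d_f), so R_g(N) ∝ N^(1/d_f); d_f = 1
    gives a straight chain and d_f = 3 a compact blob.  The radial
    offset i₀ is a calibration (zero for d_f ≤ 2, growing to 12 at
    d_f = 3) that compensates the small-N discreteness of the envelope,
    fixed once against the measured R_g(N) exponent of large clusters.
    """
    if not (1.0 <= d_f <= 3.0):
        raise ValueError("fractal dimension must lie in [1, 3]")
    if size < 1:
        raise ValueError("size must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    b = bond_length
    pos = np.zeros((size, 3))
    if size == 1:
        return pos
    c_env = 0.7    # envelope prefactor: keeps winding density of order one
    i0 = max(0.0, 12.0 * (d_f - 2.0))
    for i in range(1, size):
        p = pos[i - 1]
        rho_t = c_env * b * (i + i0) ** (1.0 / d_f)
        rp = np.linalg.norm(p)
        if rp < 1e-12:
            u = _random_unit(rng)
            pos[i] = b * u
            continue
        # cos(angle between bond and radial direction) that lands the
        # new particle at radius rho_t: |p + b u|^2 = rho_t^2
        cos_t = (rho_t**2 - rp**2 - b**2) / (2.0 * rp * b)
        cos_t = np.clip(cos_t, -1.0, 1.0)
        sin_t = np.sqrt(1.0 - cos_t**2)
        e_r = p / rp
        e_1, e_2 = _orthonormal(e_r)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        u = cos_t * e_r + sin_t * (np.cos(phi) * e_1 + np.sin(phi) * e_2)
        pos[i] = p + b * u
    return pos


def _random_unit(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _orthonormal(e):
    a = np.array([1.0, 0.0, 0.0]) if abs(e[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(e, a)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(e, e1)


def assemble_frame(spec: FixtureSpec, sizes: np.ndarray | None = None):
    """Place sampled clusters at non-overlapping random box locations.

    Returns (ParticleFrame, ground truth dict) with the true partition
    labels, per-cluster sizes, and the intra-cluster bond count at the
    bond criterion 1.1 × bond_length.  Inter-cluster gaps exceed twice
    the bond length by construction (bounding-sphere rejection
    sampling), so a bond-distance clustering of the frame must
    reproduce the partition exactly.
    """
    rng = np.random.default_rng(spec.seed)
    if sizes is None:
        sizes = sample_sizes(spec, rng=rng)
    L = spec.box_edge
    blobs = [build_cluster(int(s), spec.d_f, spec.bond_length, rng=rng) for s in sizes]
    radii = [np.linalg.norm(b - b.mean(axis=0), axis=1).max() if len(b) > 1 else 0.0
             for b in blobs]
    centers = []
    margin = 2.0 * spec.bond_length
    for ib, blob in enumerate(blobs):
        ok = False
        for _ in range(20000):
            c = rng.uniform(0, L, 3)
            ok = True
            for jc, jb in zip(centers, range(len(centers))):
                d = c - jc
                d -= L * np.round(d / L)
                if np.linalg.norm(d) < radii[ib] + radii[jb] + margin + 1e-9:
                    ok = False
                    break
            if ok:
                centers.append(c)
                break
        if not ok:
            raise RuntimeError("could not place clusters without contact; "
                               "increase the box edge")
    positions, labels = [], []
    bond_count = 0
    for lab, (blob, c) in enumerate(zip(blobs, centers)):
        com = blob.mean(axis=0)
        positions.append(np.mod(blob - com + c, L))
        labels.extend([lab] * len(blob))
        if len(blob) > 1:
            d = np.linalg.norm(blob[:, None] - blob[None, :], axis=-1)
            bond_count += int((np.triu(d < 1.1 * spec.bond_length, 1)).sum())
    positions = np.concatenate(positions) if positions else np.empty((0, 3))
    n = len(positions)
    frame = ParticleFrame(time=0.0, box_edge=L, positions=positions,
                          velocities=np.zeros((n, 3)),
                          species=np.zeros(n, dtype=np.int64),
                          radii=np.full(n, 0.5), masses=np.ones(n))
    truth = {"labels": np.array(labels, dtype=np.int64),
             "sizes": np.asarray(sizes, dtype=np.int64),
             "n_bonds": bond_count}
    return frame, truth


@dataclass(frozen=True)
class MergeEvent:
    time: float
    first: int      # cluster id
    second: int

    kind: str = "merge"


@dataclass(frozen=True)
class SplitEvent:
    time: float
    parent: int          # cluster id
    shed: int            # number of particles split off (forms a new cluster)

    kind: str = "split"


def scripted_trajectory(n_particles: int, events, t_end: float,
                        frame_interval: float = 1.0,
                        box_edge: float | None = None,
                        seed: int = 0) -> tuple[Trajectory, list]:
    """Trajectory whose cluster memberships change exactly per schedule.

    Starts from ``n_particles`` singletons (cluster id = particle id).
    A :class:`MergeEvent` joins two existing clusters (ids refer to the
    current partition; the merged cluster keeps ``first``'s id); a
    :class:`SplitEvent` moves ``shed`` particles of ``parent`` into a
    fresh cluster.  Coordinates are teleported so that members of one
    cluster sit within one bond length (unit distance) of a chain and
    distinct clusters are > 3 units apart on a grid.  Returns the
    trajectory and the realized event list (time, kind, sizes).
    """
    events = sorted(events, key=lambda e: e.time)
    for e in events:
        if e.time <= 0 or e.time >= t_end:
            raise ValueError("event times must lie strictly inside (0, t_end)")
    # partition state: list of member-lists keyed by cluster id
    clusters: dict[int, list[int]] = {i: [i] for i in range(n_particles)}
    next_id = n_particles
    rng = np.random.default_rng(seed)

    n_slots = max(4, int(np.ceil(n_particles ** (1 / 3)))) + 1
    spacing = max(6.0, n_particles ** 0.34 * 2)
    L = box_edge if box_edge else n_slots * spacing

    def render(time):
        pos = np.zeros((n_particles, 3))
        for slot, (cid, members) in enumerate(sorted(clusters.items())):
            base = np.array([slot % n_slots, (slot // n_slots) % n_slots,
                             slot // n_slots**2], dtype=float) * spacing + 1.0
            for j, p in enumerate(members):
                # compact chain: members one unit apart
                pos[p] = base + np.array([j % 3, (j // 3) % 3, j // 9], dtype=float)
        return ParticleFrame(time=time, box_edge=L, positions=pos,
                             velocities=np.zeros((n_particles, 3)),
                             species=np.zeros(n_particles, dtype=np.int64),
                             radii=np.full(n_particles, 0.5),
                             masses=np.ones(n_particles))

    times = np.arange(0.0, t_end + 1e-9, frame_interval)
    frames, realized = [], []
    ei = 0
    for t in times:
        while ei < len(events) and events[ei].time <= t:
            e = events[ei]
            if isinstance(e, MergeEvent):
                if e.first not in clusters or e.second not in clusters:
                    raise ValueError(f"merge references missing cluster at t={e.time}")
                i_sz, j_sz = len(clusters[e.first]), len(clusters[e.second])
                clusters[e.first].extend(clusters.pop(e.second))
                realized.append({"time": e.time, "kind": "merge",
                                 "i": i_sz, "j": j_sz, "k": i_sz + j_sz})
            elif isinstance(e, SplitEvent):
                members = clusters.get(e.parent)
                if members is None or not (0 < e.shed < len(members)):
                    raise ValueError(f"invalid split at t={e.time}")
                k_sz = len(members)
                moved = [members.pop() for _ in range(e.shed)]
                clusters[next_id] = moved
                next_id += 1
                realized.append({"time": e.time, "kind": "split",
                                 "i": k_sz - e.shed, "j": e.shed, "k": k_sz})
            ei += 1
        frames.append(render(t))
    return Trajectory(frames=frames, config=None, seed=seed), realized
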