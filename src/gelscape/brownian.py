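"""Langevin (Brownian) dynamics of a binary short-range-attractive mixture.

Integrates the inertial Langevin equation

    m dv/dt = F_pair − (m/ζ) v + f_B(t),
    ⟨f_B(t) f_B(t')⟩ = 2 m k_B T δ(t − t') / ζ,

for N particles in a periodic cubic box with the BAOAB splitting.  The
unit system is anchored to the small-particle radius r_a (length), the
attraction prefactor ε (energy) and t_s = sqrt(m r_a²/ε) (time); the
damping time ζ defaults to t_s.  The mixture is an equal-count binary
with size ratio r_b/r_a = 1.1 and equal material density, so
m_b = m_a (r_b/r_a)³.

The gelation protocol is: equilibrate in the liquid at ε/k_BT = 1, then
quench by switching the attraction to the target ε/k_BT and follow the
cluster formation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .potentials import MiePotential

__all__ = [
    "SimConfig",
    "ParticleFrame",
    "Trajectory",
    "pair_table",
    "init_equilibrate",
    "langevin_step",
    "neighbor_pairs",
    "run_quench",
    "pair_forces",
    "kinetic_temperature",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (units r_a, ε, t_s)."""

    n_particles: int = 512
    phi: float = 0.12
    size_ratio: float = 1.1
    eps_over_kT: float = 4.0
    dt: float = 0.0025
    zeta: float = 1.0
    seed: int = 0
    equil_eps_over_kT: float = 1.0
    equil_time: float = 100.0
    quench_time: float = 200.0
    frame_interval: float = 1.0
    fine_interval: float = 0.05    # frame spacing for rate measurements
    mie_n: float = 30.0
    mie_m: float = 20.0
    cutoff: float = 1.5

    def __post_init__(self):
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if not (0 < self.phi < 0.64):
            raise ValueError("volume fraction must be in (0, 0.64)")
        if self.dt <= 0 or self.zeta <= 0:
            raise ValueError("dt and zeta must be positive")

    @property
    def box_edge(self) -> float:
        """L from φ = (4π/3)(n_a r_a³ + n_b r_b³)/L³ with r_i = σ_ii/2."""
        n_a = self.n_particles - self.n_particles // 2
        n_b = self.n_particles // 2
        vol = 4.0 * np.pi / 3.0 * (n_a * 0.5**3 + n_b * (0.5 * self.size_ratio) ** 3)
        return float((vol / self.phi) ** (1.0 / 3.0))


@dataclass
class ParticleFrame:
    """Positions/velocities/identities of all particles plus the box."""

    time: float
    box_edge: float
    positions: np.ndarray      # (N, 3), wrapped into [0, L)
    velocities: np.ndarray     # (N, 3)
    species: np.ndarray        # (N,) int, 0 = a, 1 = b
    radii: np.ndarray          # (N,)
    masses: np.ndarray         # (N,)

    @property
    def n(self) -> int:
        return len(self.positions)

    def copy(self) -> "ParticleFrame":
        return ParticleFrame(self.time, self.box_edge,
                             self.positions.copy(), self.velocities.copy(),
                             self.species.copy(), self.radii.copy(),
                             self.masses.copy())


@dataclass
class Trajectory:
    """Ordered frames plus provenance."""

    frames: list
    config: SimConfig | None = None
    seed: int | None = None

    def __len__(self):
        return len(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)


@dataclass(frozen=True)
class PairTable:
    """Species-pair Mie parameters flattened for the force kernel."""

    sigma: np.ndarray      # (2, 2) contact distances
    epsilon: float
    n: float
    m: float
    prefactor: float
    cutoff: np.ndarray     # (2, 2) actual cutoffs (shared scalar here)
    shift: np.ndarray      # (2, 2) energy shifts


def pair_table(config: SimConfig, eps_over_kT: float | None = None) -> PairTable:
    """Mie parameters for the three species pairs.

    Additive mixing: σ_ab = (σ_aa + σ_bb)/2 with σ_aa = 1 and
    σ_bb = size_ratio; a single ε for all pairs.  Energies are measured
    in units of k_BT, so ε = eps_over_kT.
    """
    eps = config.eps_over_kT if eps_over_kT is None else eps_over_kT
    s_aa, s_bb = 1.0, config.size_ratio
    sig = np.array([[s_aa, 0.5 * (s_aa + s_bb)], [0.5 * (s_aa + s_bb), s_bb]])
    pot = MiePotential(n=config.mie_n, m=config.mie_m, epsilon=1.0)
    pref = pot.prefactor
    cut = np.full((2, 2), config.cutoff)
    sr = sig / cut
    shift = -pref * eps * (sr**config.mie_n - sr**config.mie_m)
    return PairTable(sigma=sig, epsilon=eps, n=config.mie_n, m=config.mie_m,
                     prefactor=pref, cutoff=cut, shift=shift)


def neighbor_pairs(frame: ParticleFrame, cutoff: float):
    """All unordered pairs with minimum-image distance < cutoff.

    Uses a periodic k-d tree; requires cutoff < L/2.  Returns
    (pairs (M, 2) int array, separations (M,)).
    """
    L = frame.box_edge
    if cutoff >= L / 2:
        raise ValueError(f"cutoff {cutoff} must be < half the box edge {L / 2}")
    pos = np.mod(frame.positions, L)
    tree = cKDTree(pos, boxsize=L)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2), np.empty(0)
    d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
    d -= L * np.round(d / L)
    return pairs, np.sqrt((d * d).sum(axis=1))


def pair_forces(frame: ParticleFrame, table: PairTable):
    """Total force on each particle and the pair potential energy.

    Neighbor search via the periodic k-d tree at the largest pair
    cutoff; the Mie force is evaluated analytically per pair.  Raises
    if any pair sits deep enough in the core to produce a non-finite
    force.
    """
    L = frame.box_edge
    N = frame.n
    forces = np.zeros((N, 3))
    rc_max = float(table.cutoff.max())
    pairs, _ = neighbor_pairs(frame, rc_max)
    if len(pairs) == 0:
        return forces, 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    d = frame.positions[i] - frame.positions[j]
    d -= L * np.round(d / L)
    r = np.sqrt((d * d).sum(axis=1))
    si, sj = frame.species[i], frame.species[j]
    sig = table.sigma[si, sj]
    rc = table.cutoff[si, sj]
    inside = r < rc
    sr = np.where(inside, sig / r, 1.0)
    srn, srm = sr**table.n, sr**table.m
    pref = table.prefactor * table.epsilon
    u = np.where(inside, pref * (srn - srm) + table.shift[si, sj], 0.0)
    fmag = np.where(inside, pref / r * (table.n * srn - table.m * srm), 0.0)
    if not np.all(np.isfinite(fmag)):
        bad = int(np.nonzero(~np.isfinite(fmag))[0][0])
        raise FloatingPointError(
            f"non-finite force on pair ({i[bad]}, {j[bad]}) at r={r[bad]:.3g}")
    fvec = (fmag / r)[:, None] * d
    np.add.at(forces, i, fvec)
    np.add.at(forces, j, -fvec)
    return forces, float(u.sum())


def _maxwell_velocities(rng, masses, kT=1.0):
    v = rng.standard_normal((len(masses), 3)) * np.sqrt(kT / masses)[:, None]
    v -= v.mean(axis=0)          # remove center-of-mass drift
    return v


def init_equilibrate(config: SimConfig, equil_time: float | None = None) -> ParticleFrame:
    """Initial liquid-state frame: jittered lattice, melted at ε/k_BT = 1.

    Particles are placed on a dilute cubic lattice with random jitter
    (guaranteeing no core overlaps at φ < 0.64), species alternating so
    counts are equal, with Maxwell–Boltzmann velocities at k_BT = 1.
    The system is then evolved at the equilibration attraction
    (default ε/k_BT = 1) for ``equil_time`` before being returned as
    the quench starting point.
    """
    rng = np.random.default_rng(config.seed)
    N = config.n_particles
    L = config.box_edge
    n_side = int(np.ceil(N ** (1.0 / 3.0)))
    a = L / n_side
    idx = np.arange(n_side**3)
    coords = np.stack([idx // n_side**2, (idx // n_side) % n_side, idx % n_side], axis=1)
    # keep a deterministic subset of N sites, spread by shuffling
    keep = rng.permutation(n_side**3)[:N]
    pos = (coords[keep] + 0.5) * a
    jitter = min(0.25 * a, 0.1)
    pos = np.mod(pos + rng.uniform(-jitter, jitter, (N, 3)), L)

    species = np.zeros(N, dtype=np.int64)
    species[rng.permutation(N)[: N // 2]] = 1
    radii = np.where(species == 0, 0.5, 0.5 * config.size_ratio)
    masses = np.where(species == 0, 1.0, config.size_ratio**3)
    vel = _maxwell_velocities(rng, masses)
    frame = ParticleFrame(time=0.0, box_edge=L, positions=pos, velocities=vel,
                          species=species, radii=radii, masses=masses)
    t_eq = config.equil_time if equil_time is None else equil_time
    if t_eq > 0:
        table = pair_table(config, eps_over_kT=config.equil_eps_over_kT)
        n_steps = int(round(t_eq / config.dt))
        frame, _ = _integrate(frame, config, table, n_steps, rng)
    frame.time = 0.0
    return frame


def langevin_step(frame: ParticleFrame, config: SimConfig, table: PairTable,
                  rng, forces: np.ndarray | None = None,
                  noise: bool = True, friction: bool = True):
    """One BAOAB step of the inertial Langevin equation.

    Returns (new frame, forces at the new positions) so the force
    evaluation can be reused across steps.  With ``noise`` and
    ``friction`` disabled this reduces to velocity Verlet.
    """
    dt = config.dt
    m = frame.masses[:, None]
    if forces is None:
        forces, _ = pair_forces(frame, table)
    v = frame.velocities + 0.5 * dt * forces / m          # B
    x = frame.positions + 0.5 * dt * v                    # A
    if friction:
        c1 = np.exp(-dt / config.zeta)
        if noise:
            c2 = np.sqrt(1.0 - c1 * c1)
            v = c1 * v + c2 * np.sqrt(1.0 / m) * rng.standard_normal(v.shape)
        else:
            v = c1 * v                                    # O
    elif noise:
        raise ValueError("noise without friction violates fluctuation-dissipation")
    x = np.mod(x + 0.5 * dt * v, frame.box_edge)          # A, rewrap
    new = ParticleFrame(time=frame.time + dt, box_edge=frame.box_edge,
                        positions=x, velocities=v, species=frame.species,
                        radii=frame.radii, masses=frame.masses)
    new_forces, _ = pair_forces(new, table)
    new.velocities = v + 0.5 * dt * new_forces / new.masses[:, None]   # B
    return new, new_forces


def _integrate(frame, config, table, n_steps, rng, noise=True, friction=True,
               callback=None, callback_every=0):
    forces, _ = pair_forces(frame, table)
    for step in range(n_steps):
        frame, forces = langevin_step(frame, config, table, rng, forces,
                                      noise=noise, friction=friction)
        if callback is not None and callback_every and (step + 1) % callback_every == 0:
            callback(frame)
    return frame, forces


def run_quench(start: ParticleFrame, config: SimConfig,
               quench_time: float | None = None,
               frame_interval: float | None = None,
               rng=None) -> Trajectory:
    """Switch the attraction to config.eps_over_kT and follow the growth.

    Emits a frame every ``frame_interval`` (plus the starting frame).
    The RNG is seeded from config.seed + 1 unless one is supplied, so
    the quench noise is decoupled from the equilibration noise.
    """
    t_q = config.quench_time if quench_time is None else quench_time
    dt_f = config.frame_interval if frame_interval is None else frame_interval
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    table = pair_table(config)
    frames = [start.copy()]
    if t_q > 0:
        steps_per_frame = max(1, int(round(dt_f / config.dt)))
        n_frames = int(round(t_q / (steps_per_frame * config.dt)))
        frame = start
        for _ in range(n_frames):
            frame, _ = _integrate(frame, config, table, steps_per_frame, rng)
            frames.append(frame.copy())
    return Trajectory(frames=frames, config=config, seed=config.seed)


def kinetic_temperature(frame: ParticleFrame) -> float:
    """Instantaneous kinetic temperature, ⟨m v²⟩ / 3 per particle."""
    ke = 0.5 * (frame.masses[:, None] * frame.velocities**2).sum()
    return float(2.0 * ke / (3.0 * frame.n))
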