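"""Plain-text trajectory and table I/O.

Trajectories are stored as extended XYZ: one block per frame, a comment
line carrying the time, the cubic lattice and the column schema, then
one line per particle (species label, position, radius, velocity).
The format round-trips bit-exactly through ``repr``-precision floats.

Point clouds (experiment-style data) are read from CSV with columns
x, y, z and optionally radius.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .brownian import ParticleFrame, Trajectory

__all__ = ["write_extxyz", "read_extxyz", "read_point_cloud"]

_SPECIES = np.array(["A", "B"])


def write_extxyz(traj, path) -> None:
    """Write a Trajectory (or list of frames) as extended XYZ."""
    frames = traj.frames if isinstance(traj, Trajectory) else list(traj)
    with open(path, "w") as fh:
        for fr in frames:
            L = float(fr.box_edge)
            fh.write(f"{fr.n}\n")
            fh.write(
                f'Lattice="{L!r} 0 0 0 {L!r} 0 0 0 {L!r}" '
                f'Properties=species:S:1:pos:R:3:radius:R:1:vel:R:3 '
                f"Time={float(fr.time)!r}\n")
            for s, p, r, v in zip(fr.species, fr.positions, fr.radii, fr.velocities):
                vals = " ".join(repr(float(x)) for x in (*p, r, *v))
                fh.write(f"{_SPECIES[s]} {vals}\n")


def read_extxyz(path) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_extxyz`."""
    frames = []
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            comment = fh.readline()
            fields = dict(_parse_comment(comment))
            lat = np.fromstring(fields["Lattice"], sep=" ").reshape(3, 3)
            time = float(fields.get("Time", 0.0))
            species = np.empty(n, dtype=np.int64)
            pos = np.empty((n, 3))
            rad = np.empty(n)
            vel = np.zeros((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                species[i] = 0 if parts[0] == "A" else 1
                pos[i] = [float(x) for x in parts[1:4]]
                if len(parts) > 4:
                    rad[i] = float(parts[4])
                else:
                    rad[i] = 0.5
                if len(parts) > 7:
                    vel[i] = [float(x) for x in parts[5:8]]
            masses = np.where(species == 0, 1.0, (rad / rad[species == 0].mean() if
                              (species == 0).any() else rad) ** 0)
            # equal-density masses from radii relative to species-a radius
            r_a = rad[species == 0].mean() if (species == 0).any() else rad.mean()
            masses = (rad / r_a) ** 3
            frames.append(ParticleFrame(time=time, box_edge=float(lat[0, 0]),
                                        positions=pos, velocities=vel,
                                        species=species, radii=rad, masses=masses))
    return Trajectory(frames=frames)


def _parse_comment(comment):
    """key=value pairs, values possibly quoted."""
    out = []
    i, s = 0, comment.strip()
    while i < len(s):
        eq = s.find("=", i)
        if eq < 0:
            break
        key = s[i:eq].strip().split()[-1]
        if eq + 1 < len(s) and s[eq + 1] == '"':
            end = s.find('"', eq + 2)
            val = s[eq + 2:end]
            i = end + 1
        else:
            end = s.find(" ", eq + 1)
            end = len(s) if end < 0 else end
            val = s[eq + 1:end]
            i = end + 1
        out.append((key, val))
    return out


def read_point_cloud(path) -> tuple[np.ndarray, np.ndarray | None]:
    """CSV point cloud -> (positions (N,3), radii or None)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    pos = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
    rad = df[cols["radius"]].to_numpy(dtype=float) if "radius" in cols else None
    return pos, rad
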