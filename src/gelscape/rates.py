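"""Association/dissociation kinetics from finely sampled trajectories.

Clusters are matched across consecutive frames by particle identity: a
cluster whose members came from two previous clusters of sizes i and j
records a merge (i, j) → i+j; a previous cluster whose members are
split over two current clusters records a split k → i + j.  Compound
transitions (three or more parents/children within one frame interval)
are decomposed greedily by largest shared membership and flagged, so
the frame interval should be fine enough to keep them rare.

Rate constants follow the kinetic-master-equation definitions:

* dissociation  K⁻_ij = (# of (i+j) → i+j splits) / ∫ n_{i+j}(t) dt
  — a per-cluster event rate, units 1/t_s;
* association   K⁺_ij = (# of i+j merges) / (V ∫ c_i c_j dt)
  — a second-order rate constant, units r_a³/t_s; the per-volume event
  rate (# merges / (V T)) is also reported.

Broken detailed balance shows up as forward fluxes K⁺ c_i c_j
exceeding the reverse fluxes K⁻ c_{i+j} for multi-particle classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict

import numpy as np
import pandas as pd

from .brownian import Trajectory
from .clusters import contact_pairs, cluster_labels

__all__ = [
    "ClusterEventLog",
    "RateTable",
    "track_events",
    "rate_constants",
    "balance_ratio",
]


@dataclass
class ClusterEventLog:
    """Merge/split events plus the per-frame size census."""

    events: pd.DataFrame            # columns: time, kind, i, j, k, compound
    census: pd.DataFrame            # columns: time, size, count
    n_particles: int
    total_time: float
    volume: float
    ambiguous_fraction: float = 0.0


def _partition(frame, criterion):
    graph = contact_pairs(frame, criterion)
    return cluster_labels(graph).labels


def track_events(traj: Trajectory, criterion,
                 warn_threshold: float = 0.01,
                 debounce: bool = False) -> ClusterEventLog:
    """Cluster-resolved merge and split events between consecutive frames.

    With ``debounce`` an event is counted only if it persists into the
    following frame (the merged cluster is still joint, the split
    fragments still apart).  This suppresses the bond-distance flicker
    of pairs vibrating across the contact cutoff, which otherwise
    saturates the apparent rates at the frame rate.
    """
    if len(traj) < 2:
        raise ValueError("need at least two frames to track events")
    n = traj[0].n
    for frame in traj.frames[1:]:
        if frame.n != n:
            raise ValueError("particle count changed between frames")
    all_labels = [_partition(f, criterion) for f in traj.frames]
    rows, census = [], []
    n_transitions = n_compound = 0
    for lab, frame in zip(all_labels, traj.frames):
        _append_census(census, frame.time, lab)
    for fi in range(1, len(traj)):
        frame = traj.frames[fi]
        prev_labels, labels = all_labels[fi - 1], all_labels[fi]
        next_labels = all_labels[fi + 1] if fi + 1 < len(traj) else None
        # overlap matrix between old and new clusters via pair counting
        pair_ids = prev_labels.astype(np.int64) * (labels.max() + 1) + labels
        order = np.argsort(pair_ids, kind="stable")
        uniq, first, counts = np.unique(pair_ids[order], return_index=True,
                                        return_counts=True)
        reps = order[first]                  # one particle per overlap cell
        old_of = uniq // (labels.max() + 1)
        new_of = uniq % (labels.max() + 1)
        # children per old cluster, parents per new cluster
        children = defaultdict(list)
        parents = defaultdict(list)
        for o, nw, ct, rep in zip(old_of, new_of, counts, reps):
            children[o].append((nw, ct, rep))
            parents[nw].append((o, ct, rep))
        for nw, plist in parents.items():
            if len(plist) > 1:   # merge into cluster nw
                if debounce and next_labels is not None:
                    top = sorted(plist, key=lambda x: x[1], reverse=True)[:2]
                    if next_labels[top[0][2]] != next_labels[top[1][2]]:
                        continue             # transient contact, not a merge
                n_transitions += 1
                compound = len(plist) > 2
                if compound:
                    n_compound += 1
                # greedy: merge the two largest contributors first, then fold
                sizes = sorted((ct for _, ct, _ in plist), reverse=True)
                acc = sizes[0]
                for s in sizes[1:]:
                    rows.append({"time": frame.time, "kind": "merge",
                                 "i": acc, "j": s, "k": acc + s,
                                 "compound": compound})
                    acc += s
        for o, clist in children.items():
            if len(clist) > 1:   # split of old cluster o
                if debounce and next_labels is not None:
                    top = sorted(clist, key=lambda x: x[1], reverse=True)[:2]
                    if next_labels[top[0][2]] == next_labels[top[1][2]]:
                        continue             # fragments rejoined immediately
                n_transitions += 1
                compound = len(clist) > 2
                if compound:
                    n_compound += 1
                sizes = sorted((ct for _, ct, _ in clist), reverse=True)
                rem = sum(sizes)
                for s in sizes[1:]:
                    rows.append({"time": frame.time, "kind": "split",
                                 "i": rem - s, "j": s, "k": rem,
                                 "compound": compound})
                    rem -= s
    events = pd.DataFrame(rows, columns=["time", "kind", "i", "j", "k", "compound"])
    census_df = pd.DataFrame(census, columns=["time", "size", "count"])
    frac = n_compound / n_transitions if n_transitions else 0.0
    if frac > warn_threshold:
        import warnings
        warnings.warn(f"{frac:.1%} of transitions are compound; "
                      "frame interval may be too coarse", stacklevel=2)
    t0, t1 = traj[0].time, traj.frames[-1].time
    return ClusterEventLog(events=events, census=census_df, n_particles=n,
                           total_time=t1 - t0, volume=float(traj[0].box_edge**3),
                           ambiguous_fraction=frac)


def _append_census(census, time, labels):
    sizes = np.bincount(np.bincount(labels))
    for s in np.nonzero(sizes)[0]:
        if s > 0:
            census.append({"time": time, "size": int(s), "count": int(sizes[s])})


@dataclass
class RateTable:
    """Association and dissociation constants per (i, j) size class."""

    association: pd.DataFrame    # i, j, events, exposure, K_plus, event_rate
    dissociation: pd.DataFrame   # i, j, events, exposure, K_minus

    def k_minus_size_average(self, k: int) -> float:
        """Dissociation rate of size-k clusters, averaged over channels j."""
        d = self.dissociation
        sel = d[d["k"] == k]
        if sel.empty:
            raise KeyError(f"no dissociation events observed for size {k}")
        return float(sel["events"].sum() / sel["exposure"].iloc[0])


def _exposure_integrals(log: ClusterEventLog):
    """Time integrals ∫ n_size dt (trapezoid over the census frames)."""
    piv = log.census.pivot_table(index="time", columns="size", values="count",
                                 fill_value=0.0)
    times = piv.index.to_numpy(dtype=float)
    integ = {}
    for size in piv.columns:
        integ[int(size)] = float(np.trapezoid(piv[size].to_numpy(), times))
    return integ, piv, times


def rate_constants(log: ClusterEventLog) -> RateTable:
    """Estimate K⁺_ij and K⁻_ij from an event log.

    Classes with zero exposure are omitted (absent, not zero).
    """
    if log.events.empty and log.census.empty:
        raise ValueError("empty event log")
    integ, piv, times = _exposure_integrals(log)
    V = log.volume

    rows_m = []
    splits = log.events[log.events["kind"] == "split"]
    for (i, j), grp in splits.groupby([np.minimum(splits["i"], splits["j"]),
                                       np.maximum(splits["i"], splits["j"])]):
        k = int(i + j)
        expo = integ.get(k, 0.0)
        if expo <= 0:
            continue
        rows_m.append({"i": int(i), "j": int(j), "k": k,
                       "events": len(grp), "exposure": expo,
                       "K_minus": len(grp) / expo})

    rows_p = []
    merges = log.events[log.events["kind"] == "merge"]
    for (i, j), grp in merges.groupby([np.minimum(merges["i"], merges["j"]),
                                       np.maximum(merges["i"], merges["j"])]):
        i, j = int(i), int(j)
        ci = piv[i].to_numpy() / V if i in piv.columns else None
        cj = piv[j].to_numpy() / V if j in piv.columns else None
        if ci is None or cj is None:
            continue
        expo = float(np.trapezoid(ci * cj, times)) * V
        if expo <= 0:
            continue
        rows_p.append({"i": i, "j": j, "k": i + j,
                       "events": len(grp), "exposure": expo,
                       "K_plus": len(grp) / expo,
                       "event_rate": len(grp) / (V * log.total_time)})

    return RateTable(
        association=pd.DataFrame(rows_p, columns=["i", "j", "k", "events",
                                                  "exposure", "K_plus", "event_rate"]),
        dissociation=pd.DataFrame(rows_m, columns=["i", "j", "k", "events",
                                                   "exposure", "K_minus"]))


def balance_ratio(rates: RateTable, concentrations: dict) -> pd.DataFrame:
    """Forward/reverse flux ratio per (i, j) class.

    ratio = K⁺_ij c_i c_j / (K⁻_ij c_{i+j}); detailed balance holds
    iff the ratio is 1.  Classes with an unobserved reverse channel are
    reported with ratio = inf and the forward event count.
    """
    rows = []
    assoc = rates.association.set_index(["i", "j"])
    dissoc = rates.dissociation.set_index(["i", "j"])
    for (i, j), row in assoc.iterrows():
        ci, cj = concentrations.get(i, 0.0), concentrations.get(j, 0.0)
        ck = concentrations.get(i + j, 0.0)
        fwd = row["K_plus"] * ci * cj
        if (i, j) in dissoc.index and ck > 0:
            rev = dissoc.loc[(i, j), "K_minus"] * ck
            ratio = fwd / rev if rev > 0 else np.inf
            n_rev = int(dissoc.loc[(i, j), "events"])
        else:
            ratio, n_rev = np.inf, 0
        rows.append({"i": i, "j": j, "forward_flux": fwd,
                     "reverse_flux": fwd / ratio if np.isfinite(ratio) else 0.0,
                     "ratio": ratio, "n_forward": int(row["events"]),
                     "n_reverse": n_rev})
    return pd.DataFrame(rows)
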