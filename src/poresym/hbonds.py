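"""Hydrogen-bond detection, water-bridged residue interactions and
occupancy-filtered network graphs.

Bonds are detected geometrically: donor/acceptor heavy-atom distance at most
``d_max`` (default 3.5 Å) and, when the donor carries hydrogens (any H atom of
the same residue within 1.2 Å of the donor heavy atom), a D–H···A angle of at
least ``angle_min`` (default 150°).  Fixtures without hydrogens fall back to
distance-only detection, flagged on each bond.

Donor/acceptor chemistry: Gln NE2 donates and OE1 accepts; Ser OG does both;
backbone carbonyl O accepts; water oxygen does both.

Two residues interact in a frame when a path of hydrogen bonds connects them
through at most ``max_waters`` interior water molecules (0 = a direct bond).
Interactions are aggregated over an analysis window into an undirected graph
whose edges carry occupancy (fraction of window frames with the interaction)
and the mean bridging-water count over the frames where it exists; edges
below the occupancy cutoff and nodes outside the core residue range are
dropped, mirroring the published network filtering (>=10% occupancy,
residues 6–20).
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.spatial import cKDTree

from .errors import PoresymError
from .trajectory import (
    TrajectoryFrames,
    WATER_OXYGEN_NAMES,
    WATER_RESNAMES,
    frame_window,
)

#: (resname, atomname) pairs that can donate / accept, besides waters and
#: backbone carbonyls.
SIDECHAIN_DONORS = {("GLN", "NE2"), ("SER", "OG")}
SIDECHAIN_ACCEPTORS = {("GLN", "OE1"), ("SER", "OG")}

DEFAULT_CORE = (6, 20)


@dataclass(frozen=True)
class HBond:
    """A single detected hydrogen bond (donor -> acceptor) in one frame."""

    donor: tuple  # (chain, resid, resname, atomname)
    acceptor: tuple
    frame: int
    distance: float
    angle: float | None  # None when detected in distance-only mode


def _roles(df: pd.DataFrame, water_resnames: frozenset[str]):
    """Boolean donor/acceptor masks for one frame's atom table."""
    resname = df["resname"].to_numpy()
    atomname = df["atomname"].to_numpy()
    is_water = np.isin(resname, list(water_resnames))
    water_o = is_water & np.isin(atomname, list(WATER_OXYGEN_NAMES))
    pair = list(zip(resname, atomname))
    donor = np.array([p in SIDECHAIN_DONORS for p in pair]) | water_o
    acceptor = (
        np.array([p in SIDECHAIN_ACCEPTORS for p in pair])
        | water_o
        | (~is_water & (atomname == "O"))
    )
    return donor, acceptor


def detect_hbonds(
    frame_df: pd.DataFrame,
    d_max: float = 3.5,
    angle_min: float = 150.0,
    water_resnames: frozenset[str] = WATER_RESNAMES,
) -> list[HBond]:
    """Geometric hydrogen-bond detection within a single frame table."""
    df = frame_df.reset_index(drop=True)
    donor_mask, acceptor_mask = _roles(df, water_resnames)
    coords = df[["x", "y", "z"]].to_numpy()
    names = df["atomname"].to_numpy()
    h_mask = np.array([str(n).startswith("H") for n in names])
    frame = int(df["frame"].iloc[0]) if "frame" in df.columns and len(df) else 0

    donors = np.nonzero(donor_mask)[0]
    acceptors = np.nonzero(acceptor_mask)[0]
    if len(donors) == 0 or len(acceptors) == 0:
        return []
    tree = cKDTree(coords[acceptors])
    h_tree = cKDTree(coords[h_mask]) if h_mask.any() else None
    h_idx = np.nonzero(h_mask)[0]

    key = df[["chain", "resid", "resname", "atomname"]].apply(tuple, axis=1).to_numpy()
    res_key = df[["chain", "resid"]].apply(tuple, axis=1).to_numpy()

    bonds = []
    for d in donors:
        hits = tree.query_ball_point(coords[d], d_max)
        # hydrogens covalently attached to this donor (same residue, <=1.2 A)
        attached = []
        if h_tree is not None:
            for hi in h_tree.query_ball_point(coords[d], 1.2):
                gi = h_idx[hi]
                if res_key[gi] == res_key[d]:
                    attached.append(gi)
        for ai in hits:
            a = acceptors[ai]
            if a == d or res_key[a] == res_key[d]:
                continue
            dist = float(np.linalg.norm(coords[a] - coords[d]))
            angle: float | None = None
            if attached:
                best = -np.inf
                for h in attached:
                    v1 = coords[d] - coords[h]
                    v2 = coords[a] - coords[h]
                    c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    best = max(best, np.degrees(np.arccos(np.clip(c, -1, 1))))
                if best < angle_min:
                    continue
                angle = float(best)
            bonds.append(
                HBond(
                    donor=tuple(key[d]),
                    acceptor=tuple(key[a]),
                    frame=frame,
                    distance=dist,
                    angle=angle,
                )
            )
    return bonds


def _node_of(endpoint: tuple, water_resnames: frozenset[str]) -> tuple:
    """Collapse an atom endpoint to a residue-level node (chain, resid, resname)."""
    chain, resid, resname, _atom = endpoint
    return (chain, resid, resname)


def water_bridges(
    bonds: list[HBond],
    max_waters: int = 5,
    water_resnames: frozenset[str] = WATER_RESNAMES,
) -> dict[tuple, int]:
    """Residue pairs connected through at most ``max_waters`` interior waters.

    Breadth-first search over the frame's bond graph, moving only through
    water nodes; the value for each unordered residue pair is the minimum
    interior water count among qualifying paths (0 = direct bond).
    """
    adj: dict[tuple, set[tuple]] = {}
    for b in bonds:
        u = _node_of(b.donor, water_resnames)
        v = _node_of(b.acceptor, water_resnames)
        if u == v:
            continue
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    residues = [n for n in adj if n[2] not in water_resnames]
    best: dict[tuple, int] = {}

    def record(a, b, k):
        if a == b:
            return
        pair = tuple(sorted((a, b)))
        if pair not in best or k < best[pair]:
            best[pair] = k

    for r in residues:
        # depth = number of interior waters traversed so far
        seen = {r}
        queue = deque([(r, 0)])
        while queue:
            node, k = queue.popleft()
            for nb in adj.get(node, ()):
                if nb[2] in water_resnames:
                    if k + 1 <= max_waters and nb not in seen:
                        seen.add(nb)
                        queue.append((nb, k + 1))
                else:
                    record(r, nb, k)
    return best


def interactions_by_frame(
    traj: TrajectoryFrames,
    frames: np.ndarray | None = None,
    d_max: float = 3.5,
    angle_min: float = 150.0,
    max_waters: int = 5,
    water_resnames: frozenset[str] = WATER_RESNAMES,
) -> dict[int, dict[tuple, int]]:
    """Detect bonds and water bridges for each frame of the window."""
    if frames is None:
        frames = np.arange(traj.n_frames)
    out = {}
    for f in frames:
        bonds = detect_hbonds(
            traj.frame(int(f)), d_max=d_max, angle_min=angle_min,
            water_resnames=water_resnames,
        )
        out[int(f)] = water_bridges(bonds, max_waters=max_waters,
                                    water_resnames=water_resnames)
    return out


def build_network(
    frame_interactions: dict[int, dict[tuple, int]],
    occupancy_min: float = 0.10,
    core: tuple[int, int] = DEFAULT_CORE,
) -> nx.Graph:
    """Aggregate per-frame interactions into an occupancy-filtered graph.

    Edge attributes: ``occupancy`` (fraction of window frames in which the
    pair interacts) and ``mean_bridge_waters`` (mean interior water count over
    the frames where the edge exists; 0 = always direct).  Nodes outside
    ``core`` (inclusive residue range) are removed with their edges.
    """
    n_frames = len(frame_interactions)
    if n_frames == 0:
        raise PoresymError("empty frame window for network construction")
    counts: dict[tuple, list[int]] = {}
    for inter in frame_interactions.values():
        for pair, k in inter.items():
            counts.setdefault(pair, []).append(k)
    g = nx.Graph(n_frames=n_frames, occupancy_min=occupancy_min, core=core)
    lo, hi = core
    for (u, v), ks in counts.items():
        if not (lo <= u[1] <= hi and lo <= v[1] <= hi):
            continue
        occ = len(ks) / n_frames
        if occ < occupancy_min:
            continue
        for node in (u, v):
            g.add_node(node, chain=node[0], resid=node[1], resname=node[2])
        g.add_edge(u, v, occupancy=occ, mean_bridge_waters=float(np.mean(ks)))
    return g


def analyze_hbond_network(
    traj: TrajectoryFrames,
    start_ns: float | None = None,
    end_ns: float | None = None,
    occupancy_min: float = 0.10,
    core: tuple[int, int] = DEFAULT_CORE,
    max_waters: int = 5,
    d_max: float = 3.5,
    angle_min: float = 150.0,
) -> nx.Graph:
    """Full pipeline: window selection, detection, bridging, aggregation.

    The default window is the second half of the trajectory (the conventional
    100–200 ns of a 200-ns run).
    """
    frames = frame_window(traj, start_ns=start_ns, end_ns=end_ns)
    inter = interactions_by_frame(
        traj, frames=frames, d_max=d_max, angle_min=angle_min, max_waters=max_waters
    )
    return build_network(inter, occupancy_min=occupancy_min, core=core)


def _endpoint_type(
    endpoint: tuple,
    core: tuple[int, int],
    water_resnames: frozenset[str],
) -> str | None:
    chain, resid, resname, atom = endpoint
    if resname in water_resnames:
        return "water"
    lo, hi = core
    if not lo <= resid <= hi:
        return None
    if resname == "GLN" and atom in ("NE2", "OE1"):
        return "Gln"
    if resname == "SER" and atom == "OG":
        return "Ser"
    return None


def interaction_fractions(
    bonds_by_frame: list[list[HBond]],
    core: tuple[int, int] = DEFAULT_CORE,
    water_resnames: frozenset[str] = WATER_RESNAMES,
) -> pd.Series:
    """Fractions of pore hydrogen bonds by partner-type pair.

    A bond is counted when both endpoints are typed (pore-facing Gln/Ser
    sidechain atom within the core, or water) and at least one endpoint is a
    sidechain; classes are the unordered pairs Gln–Gln, Gln–Ser, Ser–Ser,
    Gln–water and Ser–water.  Fractions sum to 1 over counted bonds.
    """
    counts: dict[str, int] = {}
    total = 0
    for bonds in bonds_by_frame:
        for b in bonds:
            t1 = _endpoint_type(b.donor, core, water_resnames)
            t2 = _endpoint_type(b.acceptor, core, water_resnames)
            if t1 is None or t2 is None:
                continue
            if t1 == t2 == "water":
                continue
            label = "–".join(sorted((t1, t2), key=lambda t: (t == "water", t)))
            counts[label] = counts.get(label, 0) + 1
            total += 1
    if total == 0:
        raise PoresymError("no pore hydrogen bonds to classify")
    frac = pd.Series({k: v / total for k, v in counts.items()}).sort_values(
        ascending=False
    )
    frac.attrs["n_bonds"] = total
    return frac
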