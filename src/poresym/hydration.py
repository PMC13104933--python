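"""Pore geometry, water occupancy, residence times, density profiles,
hydrophobic lengths and wet/dry frame classification.

The pore volume is approximated, frame by frame, as the convex hull of the
Cα atoms of two anchor residues (default 5 and 22) on all five chains — a
pentagonal prism for an ideal bundle that degrades gracefully when the
helices tilt.  Waters are located by their oxygen atom; a water is "in the
pore" when its oxygen is inside or on that hull.

The time-averaged water density along z (waters per Å, per frame) is
Savitzky–Golay smoothed before numerical differentiation; zero crossings of
the second derivative mark changes in hydrophobicity, and the longest
low-density span between consecutive crossings is the effective hydrophobic
length.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.spatial import ConvexHull

from .errors import SelectionError
from .trajectory import TrajectoryFrames, WATER_RESNAMES

DEFAULT_ANCHORS = (5, 22)


@dataclass
class PoreRegion:
    """Per-frame convex hulls of the 10 anchor Cα positions."""

    anchor_points: np.ndarray  # (n_frames, 10, 3)
    anchor_residues: tuple[int, int] = DEFAULT_ANCHORS
    _equations: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.anchor_points.shape[1:] != (10, 3):
            raise ValueError("expected 10 anchor points (2 residues x 5 chains)")
        if not self._equations:
            for pts in self.anchor_points:
                hull = ConvexHull(pts)
                if hull.volume <= 0:
                    raise SelectionError("degenerate pore hull (zero volume)")
                self._equations.append(hull.equations)

    @property
    def n_frames(self) -> int:
        return self.anchor_points.shape[0]

    def contains(self, frame: int, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Closed-hull membership test for (n, 3) points in one frame."""
        pts = np.atleast_2d(points)
        eq = self._equations[frame]
        return np.all(pts @ eq[:, :3].T + eq[:, 3] <= tol, axis=1)

    def z_extent(self) -> tuple[float, float]:
        z = self.anchor_points[:, :, 2]
        return float(z.min()), float(z.max())


def define_pore_region(
    traj: TrajectoryFrames, anchors: tuple[int, int] = DEFAULT_ANCHORS
) -> PoreRegion:
    """Convex hull of anchor-residue Cα atoms (all five chains), per frame."""
    pts = np.empty((traj.n_frames, 10, 3))
    ca = traj.select(atomname="CA")
    ca = ca[ca["resid"].isin(anchors)]
    for i in range(traj.n_frames):
        sub = ca[ca["frame"] == i]
        if len(sub) != 10:
            missing = set(anchors) - set(sub["resid"].unique())
            raise SelectionError(
                f"frame {i}: anchor CA atoms incomplete "
                f"(found {len(sub)}/10; missing resid {sorted(missing) or '?'})"
            )
        pts[i] = sub.sort_values(["resid", "chain"])[["x", "y", "z"]].to_numpy()
    return PoreRegion(pts, anchor_residues=anchors)


@dataclass
class WaterOccupancy:
    """Per-frame pore-water counts and identities.

    ``inside[f]`` is the frozenset of water ids ((chain, resid) pairs) inside
    the pore at frame f; ``counts[f]`` its size.
    """

    counts: np.ndarray
    inside: list[frozenset]
    dt: float

    @property
    def n_frames(self) -> int:
        return len(self.counts)


def count_pore_waters(
    traj: TrajectoryFrames,
    region: PoreRegion,
    water_resnames: frozenset[str] = WATER_RESNAMES,
) -> WaterOccupancy:
    """Identify the waters inside the pore region in every frame."""
    wat = traj.waters(water_resnames)
    counts = np.zeros(traj.n_frames, dtype=int)
    inside: list[frozenset] = []
    for i in range(traj.n_frames):
        sub = wat[wat["frame"] == i]
        if len(sub) == 0:
            inside.append(frozenset())
            continue
        mask = region.contains(i, sub[["x", "y", "z"]].to_numpy())
        ids = frozenset(
            zip(sub["chain"].to_numpy()[mask], sub["resid"].to_numpy()[mask])
        )
        inside.append(ids)
        counts[i] = len(ids)
    return WaterOccupancy(counts=counts, inside=inside, dt=traj.dt)


def residence_times(occupancy: WaterOccupancy) -> pd.DataFrame:
    """Maximal runs of consecutive inside-frames per water.

    Returns one row per residence interval with entry/exit frames (inclusive),
    duration in ns (run length x dt), and censoring flags for intervals that
    touch the start or end of the trajectory.
    """
    n = occupancy.n_frames
    frames_by_water: dict[tuple, list[int]] = {}
    for f, ids in enumerate(occupancy.inside):
        for wid in ids:
            frames_by_water.setdefault(wid, []).append(f)
    rows = []
    for wid in sorted(frames_by_water):
        fr = frames_by_water[wid]
        start = prev = fr[0]
        runs = []
        for f in fr[1:]:
            if f == prev + 1:
                prev = f
            else:
                runs.append((start, prev))
                start = prev = f
        runs.append((start, prev))
        for entry, exit_ in runs:
            rows.append(
                {
                    "water_chain": wid[0],
                    "water_resid": wid[1],
                    "entry_frame": entry,
                    "exit_frame": exit_,
                    "n_frames": exit_ - entry + 1,
                    "duration_ns": (exit_ - entry + 1) * occupancy.dt / 1000.0,
                    "censored_start": entry == 0,
                    "censored_end": exit_ == n - 1,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "water_chain",
            "water_resid",
            "entry_frame",
            "exit_frame",
            "n_frames",
            "duration_ns",
            "censored_start",
            "censored_end",
        ],
    )


@dataclass
class DensityProfile:
    """Time-averaged pore-water linear density along z.

    ``density`` is waters per Å of pore axis per frame, so
    sum(density) * bin_width equals the mean per-frame pore water count.
    """

    z: np.ndarray
    density: np.ndarray
    bin_width: float
    mean_count: float = 0.0
    n_frames: int = 0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.z.shape != self.density.shape:
            raise ValueError("z and density must have the same shape")


def density_profile(
    traj: TrajectoryFrames,
    region: PoreRegion,
    bin_width: float = 0.5,
    z_range: tuple[float, float] | None = None,
    water_resnames: frozenset[str] = WATER_RESNAMES,
) -> DensityProfile:
    """Per-frame histogram of pore-water z positions, averaged over frames."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if z_range is None:
        lo, hi = region.z_extent()
        z_range = (lo - bin_width, hi + bin_width)
    edges = np.arange(z_range[0], z_range[1] + bin_width / 2, bin_width)
    wat = traj.waters(water_resnames)
    total = np.zeros(len(edges) - 1)
    n_total_inside = 0
    for i in range(traj.n_frames):
        sub = wat[wat["frame"] == i]
        if len(sub) == 0:
            continue
        pts = sub[["x", "y", "z"]].to_numpy()
        mask = region.contains(i, pts)
        zs = pts[mask, 2]
        n_total_inside += int(mask.sum())
        counts, _ = np.histogram(zs, bins=edges)
        total += counts
    density = total / traj.n_frames / bin_width
    return DensityProfile(
        z=(edges[:-1] + edges[1:]) / 2.0,
        density=density,
        bin_width=bin_width,
        mean_count=n_total_inside / traj.n_frames,
        n_frames=traj.n_frames,
    )


@dataclass
class HydrophobicSpans:
    """Inflection analysis of a density profile."""

    inflection_zs: np.ndarray
    spans: pd.DataFrame  # z_start, z_end, length, interior_mean_density, hydrophobic
    effective_length: float
    smoothed: np.ndarray
    second_derivative: np.ndarray


def hydrophobic_length(
    profile: DensityProfile,
    low_density_frac: float = 0.25,
    smooth_window: int = 11,
    smooth_order: int = 3,
) -> HydrophobicSpans:
    """Spans between second-derivative zero crossings of the smoothed profile.

    A span between consecutive inflection points qualifies as hydrophobic when
    the mean smoothed density over its interior falls below
    ``low_density_frac`` of the profile maximum; the effective hydrophobic
    length is the longest qualifying span (0 with fewer than two inflections).
    """
    z = profile.z
    y = profile.density
    window = min(smooth_window, len(y) if len(y) % 2 == 1 else len(y) - 1)
    if window <= smooth_order:
        smoothed = y.copy()
    else:
        smoothed = savgol_filter(y, window_length=window, polyorder=smooth_order)
    d1 = np.gradient(smoothed, z)
    d2 = np.gradient(d1, z)
    # suppress numerically-zero curvature so flat profiles yield no crossings:
    # relative floor for genuine profiles, absolute floor tied to the density
    # scale for (near-)constant ones
    scale = np.max(np.abs(d2))
    abs_floor = 1e-8 * np.max(np.abs(smoothed), initial=0.0) / profile.bin_width**2
    sig = d2.copy()
    sig[np.abs(sig) < max(1e-3 * scale, abs_floor)] = 0.0
    crossings = []
    last_sign = 0
    last_idx = None
    for i, v in enumerate(sig):
        s = int(np.sign(v))
        if s == 0:
            continue
        if last_sign != 0 and s != last_sign:
            i0, i1 = last_idx, i
            # linear interpolation between the bracketing nonzero samples
            z0, z1 = z[i0], z[i1]
            y0, y1 = sig[i0], sig[i1]
            crossings.append(z0 - y0 * (z1 - z0) / (y1 - y0))
        last_sign = s
        last_idx = i
    crossings = np.asarray(crossings)
    rows = []
    max_density = float(np.max(smoothed)) if len(smoothed) else 0.0
    for a, b in zip(crossings[:-1], crossings[1:]):
        interior = (z > a) & (z < b)
        mean_d = float(np.mean(smoothed[interior])) if interior.any() else np.inf
        rows.append(
            {
                "z_start": a,
                "z_end": b,
                "length": b - a,
                "interior_mean_density": mean_d,
                "hydrophobic": max_density > 0 and mean_d < low_density_frac * max_density,
            }
        )
    spans = pd.DataFrame(
        rows,
        columns=["z_start", "z_end", "length", "interior_mean_density", "hydrophobic"],
    )
    hydrophobic = spans[spans["hydrophobic"]] if len(spans) else spans
    eff = float(hydrophobic["length"].max()) if len(hydrophobic) else 0.0
    return HydrophobicSpans(
        inflection_zs=crossings,
        spans=spans,
        effective_length=eff,
        smoothed=smoothed,
        second_derivative=d2,
    )


@dataclass
class WetDryLabels:
    labels: np.ndarray  # 'dry' | 'wet' | 'transition' per frame
    dry_max: int = 1
    wet_min: int = 10


def classify_wet_dry(
    occupancy: WaterOccupancy, dry_max: int = 1, wet_min: int = 10
) -> WetDryLabels:
    """Hysteresis classification of frames by pore-water count.

    A frame becomes wet at the first count >= wet_min and stays wet until a
    count <= dry_max, at which it becomes dry; intermediate counts inherit the
    current state.  Intermediate counts before any threshold crossing are
    labelled transition.
    """
    labels = np.empty(occupancy.n_frames, dtype=object)
    state: str | None = None
    for i, n in enumerate(occupancy.counts):
        if n >= wet_min:
            state = "wet"
        elif n <= dry_max:
            state = "dry"
        labels[i] = state if state is not None else "transition"
    return WetDryLabels(labels=labels, dry_max=dry_max, wet_min=wet_min)
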