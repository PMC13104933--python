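"""Gln sidechain orientation, state classification, symmetry statistics and
rotamer clustering.

The orientation of each pore-lining Gln is summarised by the vector from its
Cα to its sidechain amide nitrogen Nε2 (PDB atom NE2).  The signed height of
NE2 above the plane of the five Gln Cα atoms (taken as the mean Cα z of the
oriented frame) is the z-offset used to classify each sidechain as
down / neutral / up, and the fraction of frames in which two chains share a
state is the pairwise state-agreement symmetry statistic.

χ1 (N–Cα–Cβ–Cγ) and χ2 (Cα–Cβ–Cγ–Cδ) torsions are computed with the standard
signed atan2 form (IUPAC convention, cis = 0°, trans = 180°, range
(−180, 180]) and clustered with DBSCAN on the (sin, cos) torus embedding so
the ±180° seam introduces no artificial splits.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cluster import DBSCAN

from .errors import DegenerateInputError, SelectionError
from .trajectory import TrajectoryFrames

CHAINS = ("A", "B", "C", "D", "E")

#: Default down/neutral/up boundaries (Å): down z < 0, neutral 0 <= z < 2.5,
#: up z >= 2.5.  2.4 Å is the documented alternative upper boundary.
DEFAULT_THRESHOLDS = (0.0, 2.5)

GLN_CHI1_ATOMS = ("N", "CA", "CB", "CG")
GLN_CHI2_ATOMS = ("CA", "CB", "CG", "CD")


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle(s) in degrees, range (−180, 180].

    IUPAC convention: looking from atom 2 toward atom 3, the angle from the
    plane (1,2,3) to the plane (2,3,4); cis = 0, trans = 180.  Accepts single
    points or (n, 3) arrays.
    """
    p0, p1, p2, p3 = (np.atleast_2d(np.asarray(p, dtype=float)) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=1)
    norm2 = np.linalg.norm(n2, axis=1)
    if np.any(norm1 < 1e-12) or np.any(norm2 < 1e-12):
        bad = np.nonzero((norm1 < 1e-12) | (norm2 < 1e-12))[0]
        raise DegenerateInputError(
            f"collinear bonded triplet in dihedral geometry at index {bad[0]}"
        )
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    out = np.asarray(ang)
    return out if out.size > 1 else float(out[0])


def _pivot_atom(traj: TrajectoryFrames, resid: int, atomname: str) -> pd.DataFrame:
    """(frame, chain) -> x,y,z table for one atom of one residue position."""
    df = traj.select(atomname=atomname, resid=resid)
    chains = sorted(df["chain"].unique())
    if len(chains) != 5:
        raise SelectionError(
            f"residue {resid} atom {atomname}: found on {len(chains)} chains, need 5"
        )
    expected = traj.n_frames * 5
    if len(df) != expected:
        by_frame = df.groupby("frame").size()
        bad = by_frame[by_frame != 5]
        frame = bad.index[0] if len(bad) else "?"
        raise SelectionError(
            f"residue {resid} atom {atomname} missing in frame {frame}"
        )
    return df.set_index(["frame", "chain"])[["x", "y", "z"]].sort_index()


def compute_gln_vectors(traj: TrajectoryFrames, gln_resid: int = 10) -> pd.DataFrame:
    """Per-(frame, chain) Cα→Nε2 vectors and z-offsets.

    The z-offset of a chain's NE2 is measured from the mean z of the five Gln
    Cα atoms of the same frame (the Cα-plane reference).

    Returns a DataFrame with columns ``frame, chain, vx, vy, vz, z_offset``.
    """
    ca = _pivot_atom(traj, gln_resid, "CA")
    ne2 = _pivot_atom(traj, gln_resid, "NE2")
    v = ne2.to_numpy() - ca.to_numpy()
    if np.any(np.linalg.norm(v, axis=1) < 1e-9):
        raise DegenerateInputError("zero-length Ca->NE2 vector")
    plane_z = ca.groupby(level="frame")["z"].mean()
    frames = ca.index.get_level_values("frame")
    z_offset = ne2["z"].to_numpy() - plane_z.loc[frames].to_numpy()
    out = pd.DataFrame(
        {
            "frame": frames,
            "chain": ca.index.get_level_values("chain"),
            "vx": v[:, 0],
            "vy": v[:, 1],
            "vz": v[:, 2],
            "z_offset": z_offset,
        }
    )
    return out.reset_index(drop=True)


def classify_states(
    vectors: pd.DataFrame,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Classify each (frame, chain) into down / neutral / up.

    Half-open convention: z < t_low -> down; t_low <= z < t_high -> neutral;
    z >= t_high -> up.
    """
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ValueError(f"thresholds must satisfy t_low < t_high, got {thresholds}")
    z = vectors["z_offset"].to_numpy()
    state = np.where(z < t_low, "down", np.where(z < t_high, "neutral", "up"))
    out = vectors[["frame", "chain"]].copy()
    out["z_offset"] = z
    out["state"] = state
    out.attrs["thresholds"] = (t_low, t_high)
    return out


@dataclass
class AgreementMatrix:
    """5x5 time-averaged pairwise same-state fractions over chains A–E."""

    matrix: pd.DataFrame
    n_frames_used: int

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        if not np.allclose(m, m.T):
            raise ValueError("agreement matrix must be symmetric")


def pairwise_agreement(states: pd.DataFrame | list[pd.DataFrame]) -> AgreementMatrix:
    """Fraction of frames in which each chain pair occupies the same state.

    Accepts one state table or a list of them (replicates); replicate frames
    are pooled (concatenated) before averaging.  Diagonal is exactly 1.
    """
    tables = states if isinstance(states, list) else [states]
    mats = []
    for t in tables:
        piv = t.pivot(index="frame", columns="chain", values="state")
        if piv.isna().any().any():
            raise ValueError("state table has missing (frame, chain) entries")
        mats.append(piv.to_numpy())
    chains = sorted(tables[0]["chain"].unique())
    stacked = np.vstack(mats)
    if stacked.shape[0] == 0:
        raise ValueError("no frames supplied")
    n = len(chains)
    agree = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            agree[i, j] = agree[j, i] = float(
                np.mean(stacked[:, i] == stacked[:, j])
            )
    mat = pd.DataFrame(agree, index=chains, columns=chains)
    return AgreementMatrix(mat, n_frames_used=stacked.shape[0])


def compute_dihedrals(traj: TrajectoryFrames, gln_resid: int = 10) -> pd.DataFrame:
    """χ1/χ2 torsions (degrees) per (frame, chain) for one Gln position."""
    pos = {
        a: _pivot_atom(traj, gln_resid, a).to_numpy()
        for a in ("N", "CA", "CB", "CG", "CD")
    }
    chi1 = dihedral(*(pos[a] for a in GLN_CHI1_ATOMS))
    chi2 = dihedral(*(pos[a] for a in GLN_CHI2_ATOMS))
    idx = _pivot_atom(traj, gln_resid, "CA").index
    return pd.DataFrame(
        {
            "frame": idx.get_level_values("frame"),
            "chain": idx.get_level_values("chain"),
            "chi1": np.atleast_1d(chi1),
            "chi2": np.atleast_1d(chi2),
        }
    )


def _torus_embedding(chi1_deg: np.ndarray, chi2_deg: np.ndarray) -> np.ndarray:
    a = np.radians(chi1_deg)
    b = np.radians(chi2_deg)
    return np.column_stack([np.sin(a), np.cos(a), np.sin(b), np.cos(b)])


def cluster_rotamers(
    dihedrals: pd.DataFrame,
    eps: float = 20.0,
    min_samples: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DBSCAN clustering of (χ1, χ2) points on the torus.

    ``eps`` is an arc in degrees; it is converted to the chord length
    2·sin(eps/2) that the same displacement produces in the (sin, cos)
    embedding, so the ±180° seam is respected.  ``min_samples`` defaults to
    max(10, 0.5% of points).

    Returns ``(labelled, fractions)``: the input with a ``cluster`` column
    (noise = −1), and a table with per-cluster counts and fractions computed
    both over all points and excluding noise, sorted by descending size with
    the noise row last.
    """
    n = len(dihedrals)
    if min_samples is None:
        min_samples = max(10, int(round(0.005 * n)))
    if n < min_samples:
        raise ValueError(f"need at least min_samples={min_samples} points, got {n}")
    X = _torus_embedding(dihedrals["chi1"].to_numpy(), dihedrals["chi2"].to_numpy())
    chord = 2.0 * np.sin(np.radians(eps) / 2.0)
    labels = DBSCAN(eps=chord, min_samples=min_samples).fit_predict(X)
    # relabel clusters by descending size
    sizes = pd.Series(labels[labels >= 0]).value_counts()
    remap = {old: rank for rank, old in enumerate(sizes.index)}
    labels = np.array([remap.get(l, -1) for l in labels])
    out = dihedrals.copy()
    out["cluster"] = labels
    n_noise = int(np.sum(labels == -1))
    rows = []
    for lab in sorted(set(labels) - {-1}):
        cnt = int(np.sum(labels == lab))
        rows.append(
            {
                "cluster": lab,
                "count": cnt,
                "fraction": cnt / n,
                "fraction_excl_noise": cnt / (n - n_noise) if n > n_noise else np.nan,
            }
        )
    rows.append(
        {
            "cluster": -1,
            "count": n_noise,
            "fraction": n_noise / n,
            "fraction_excl_noise": np.nan,
        }
    )
    return out, pd.DataFrame(rows)


@dataclass
class KDEBackground:
    """Periodic 2-D KDE over reference (χ1, χ2) with mass-percentile contours.

    ``thresholds[p]`` is the density level whose super-level set encloses
    p% of the reference probability mass; the 90% region therefore contains
    the 70% region (d70 >= d90).
    """

    kde: gaussian_kde
    thresholds: dict[int, float]
    n_reference: int

    def density(self, chi1, chi2) -> np.ndarray:
        pts = np.vstack([np.atleast_1d(chi1), np.atleast_1d(chi2)])
        return self.kde(pts)

    def inside(self, chi1, chi2, percentile: int) -> np.ndarray:
        return self.density(chi1, chi2) >= self.thresholds[percentile]


def kde_background(
    reference: pd.DataFrame,
    percentiles: tuple[int, ...] = (70, 90),
    bw_method: str | float = "scott",
    margin: float = 90.0,
) -> KDEBackground:
    """Fit the background χ1/χ2 density from a reference dihedral table.

    Periodicity is handled by replicating reference points shifted by ±360°
    when they fall within ``margin`` degrees of the domain edge.  The returned
    thresholds are density quantiles at the reference points, so the
    super-level set at ``thresholds[p]`` encloses approximately p% of mass.
    """
    if not {"chi1", "chi2"}.issubset(reference.columns):
        raise ValueError("reference table needs columns chi1, chi2")
    pts = reference[["chi1", "chi2"]].to_numpy(dtype=float)
    if len(pts) < 25:
        raise DegenerateInputError(
            f"need >= 25 reference points for the KDE, got {len(pts)}"
        )
    tiles = [pts]
    for sx in (-360.0, 0.0, 360.0):
        for sy in (-360.0, 0.0, 360.0):
            if sx == 0.0 and sy == 0.0:
                continue
            shifted = pts + np.array([sx, sy])
            keep = (
                (shifted[:, 0] >= -180.0 - margin)
                & (shifted[:, 0] <= 180.0 + margin)
                & (shifted[:, 1] >= -180.0 - margin)
                & (shifted[:, 1] <= 180.0 + margin)
            )
            if keep.any():
                tiles.append(shifted[keep])
    data = np.vstack(tiles).T
    try:
        kde = gaussian_kde(data, bw_method=bw_method)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(
            "reference dihedrals are degenerate (singular covariance)"
        ) from exc
    dens = kde(pts.T)
    if np.ptp(dens) < 1e-300:
        raise DegenerateInputError("degenerate reference density")
    thresholds = {
        p: float(np.quantile(dens, 1.0 - p / 100.0)) for p in percentiles
    }
    return KDEBackground(kde=kde, thresholds=thresholds, n_reference=len(pts))


def z_histogram(
    vectors: pd.DataFrame | list[pd.DataFrame],
    bin_width: float = 0.25,
) -> pd.DataFrame:
    """Histogram of Gln z-offsets pooled over chains and replicates.

    Total count equals 5 x n_frames x n_replicates; stored in
    ``result.attrs['total']``.
    """
    tables = vectors if isinstance(vectors, list) else [vectors]
    z = np.concatenate([t["z_offset"].to_numpy() for t in tables])
    lo = np.floor(z.min() / bin_width) * bin_width
    hi = np.ceil(z.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(z, bins=edges)
    out = pd.DataFrame(
        {"z": (edges[:-1] + edges[1:]) / 2.0, "count": counts}
    )
    out.attrs["total"] = int(counts.sum())
    out.attrs["bin_width"] = bin_width
    return out
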