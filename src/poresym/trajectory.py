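"""Frame-based coordinate container plus readers, writers and pore-axis
alignment.

The pipeline's in-memory model is a :class:`TrajectoryFrames`: a tidy
:class:`pandas.DataFrame` of labelled atom coordinates (one row per atom per
frame, Å) together with the saving interval ``dt`` (ps).  Every frame must
carry the identical atom roster — the same set of ``(chain, resid, atomname)``
keys — which is what lets all downstream analyses index atoms positionally.

Two plain-text formats are supported: multi-model PDB (fixed-column,
MODEL/ENDMDL delimited) and a delimited "frame table" with columns
``frame, chain, resid, resname, atomname, x, y, z``.  Coordinates are Å
throughout; readers accept ``units="nm"`` to convert on input.

Saved frames are timestamped at the *end* of their saving interval:
frame ``i`` sits at ``t = (i + 1) * dt``.  A 200-ns run saved every 200 ps
therefore has 1,000 frames, and its 100–200 ns window is exactly the last 500.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .errors import RosterMismatchError, SelectionError, TrajectoryError

FRAME_COLUMNS = ["frame", "chain", "resid", "resname", "atomname", "x", "y", "z"]

#: Residue names recognised as water.
WATER_RESNAMES = frozenset({"HOH", "SOL", "TIP3", "WAT"})

#: Atom names used as the positional proxy for a water molecule (its oxygen).
WATER_OXYGEN_NAMES = frozenset({"O", "OW", "OH2"})


@dataclass
class TrajectoryFrames:
    """Ordered multi-frame atom table.

    Parameters
    ----------
    atoms:
        DataFrame with columns ``frame, chain, resid, resname, atomname,
        x, y, z``; frame indices contiguous from 0.
    dt:
        Time between saved frames, ps (default 200 as in the source data).
    replicate_id:
        Free-form label for the production run.
    """

    atoms: pd.DataFrame
    dt: float = 200.0
    replicate_id: str = "run"

    def __post_init__(self) -> None:
        missing = [c for c in FRAME_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise TrajectoryError(f"atom table missing column(s): {missing}")
        self.atoms = self.atoms[FRAME_COLUMNS].reset_index(drop=True)
        self.atoms["frame"] = self.atoms["frame"].astype(int)
        self.atoms["resid"] = self.atoms["resid"].astype(int)
        for c in "xyz":
            self.atoms[c] = self.atoms[c].astype(float)
        if (self.atoms["resid"] < 1).any():
            raise TrajectoryError("residue numbers must be >= 1")
        if (self.atoms["atomname"].astype(str).str.len() == 0).any():
            raise TrajectoryError("empty atom names are not allowed")
        frames = np.sort(self.atoms["frame"].unique())
        if len(frames) == 0:
            raise TrajectoryError("trajectory has no frames")
        if frames[0] != 0 or not np.array_equal(frames, np.arange(len(frames))):
            raise TrajectoryError(
                f"frame indices must be contiguous from 0; got {frames[:10]}..."
            )
        self._validate_roster()

    def _validate_roster(self) -> None:
        key = self.atoms[["chain", "resid", "atomname"]].apply(tuple, axis=1)
        ref = None
        for f, grp in key.groupby(self.atoms["frame"]):
            roster = frozenset(grp)
            if len(roster) != len(grp):
                raise RosterMismatchError(f"duplicate atom key in frame {f}")
            if ref is None:
                ref = roster
            elif roster != ref:
                raise RosterMismatchError(
                    f"frame {f} atom roster differs from frame 0 "
                    f"({len(roster)} vs {len(ref)} atoms)"
                )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(self.atoms["frame"].max()) + 1

    @property
    def span_ps(self) -> float:
        """Trajectory span in ps (n_frames * dt)."""
        return self.n_frames * self.dt

    def times_ns(self) -> np.ndarray:
        """Timestamp of each frame in ns; frame i at (i + 1) * dt."""
        return (np.arange(self.n_frames) + 1) * self.dt / 1000.0

    def frame(self, i: int) -> pd.DataFrame:
        return self.atoms[self.atoms["frame"] == i]

    def select(
        self,
        atomname: str | None = None,
        resid: int | None = None,
        resnames: set[str] | None = None,
    ) -> pd.DataFrame:
        df = self.atoms
        if atomname is not None:
            df = df[df["atomname"] == atomname]
        if resid is not None:
            df = df[df["resid"] == resid]
        if resnames is not None:
            df = df[df["resname"].isin(resnames)]
        return df

    def waters(self, water_resnames: frozenset[str] = WATER_RESNAMES) -> pd.DataFrame:
        """Water oxygen rows (the positional proxy for each water molecule)."""
        df = self.atoms
        return df[
            df["resname"].isin(water_resnames)
            & df["atomname"].isin(WATER_OXYGEN_NAMES)
        ]


def frame_window(
    traj: TrajectoryFrames,
    start_ns: float | None = None,
    end_ns: float | None = None,
) -> np.ndarray:
    """Frame indices with start_ns < t <= end_ns (t = (i+1)*dt).

    Defaults select the second half of the trajectory, the conventional
    analysis window for the hydrogen-bond network.
    """
    t = traj.times_ns()
    if start_ns is None:
        start_ns = traj.span_ps / 2000.0
    if end_ns is None:
        end_ns = traj.span_ps / 1000.0
    idx = np.nonzero((t > start_ns) & (t <= end_ns))[0]
    if idx.size == 0:
        raise TrajectoryError(
            f"window ({start_ns}, {end_ns}] ns selects no frames"
        )
    return idx


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _unit_scale(units: str) -> float:
    if units == "angstrom":
        return 1.0
    if units == "nm":
        return 10.0
    raise ValueError(f"unknown units {units!r}; expected 'angstrom' or 'nm'")


def _prescan_pdb(path: Path) -> None:
    """Cheap line-level validation so parse errors carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except (ValueError, IndexError):
                    raise TrajectoryError(
                        f"{path}: unparseable coordinate field on line {lineno}"
                    ) from None


def read_multimodel_pdb(
    path: str | Path,
    dt: float = 200.0,
    replicate_id: str | None = None,
    units: str = "angstrom",
) -> TrajectoryFrames:
    """Read a single- or multi-model PDB into a :class:`TrajectoryFrames`.

    One MODEL per frame; the atom roster must be identical across models.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    scale = _unit_scale(units)
    pdbfile = pdb.PDBFile.read(str(path))
    n_models = pdbfile.get_model_count()
    rows = []
    ref_roster = None
    for m in range(1, n_models + 1):
        arr = pdbfile.get_structure(model=m)
        roster = list(
            zip(arr.chain_id.tolist(), arr.res_id.tolist(), arr.atom_name.tolist())
        )
        if ref_roster is None:
            ref_roster = roster
        elif roster != ref_roster:
            raise RosterMismatchError(
                f"{path}: model {m} atom roster differs from model 1"
            )
        rows.append(
            pd.DataFrame(
                {
                    "frame": m - 1,
                    "chain": arr.chain_id,
                    "resid": arr.res_id,
                    "resname": arr.res_name,
                    "atomname": arr.atom_name,
                    "x": arr.coord[:, 0] * scale,
                    "y": arr.coord[:, 1] * scale,
                    "z": arr.coord[:, 2] * scale,
                }
            )
        )
    atoms = pd.concat(rows, ignore_index=True)
    return TrajectoryFrames(
        atoms, dt=dt, replicate_id=replicate_id or path.stem
    )


def _element_of(atom_name: str) -> str:
    stripped = "".join(ch for ch in atom_name if ch.isalpha())
    return stripped[:1].upper() if stripped else "C"


def write_multimodel_pdb(traj: TrajectoryFrames, path: str | Path) -> None:
    """Write one MODEL per frame (fixed-column PDB via biotite)."""
    frames = []
    water = traj.atoms["resname"].isin(WATER_RESNAMES)
    for i in range(traj.n_frames):
        df = traj.frame(i)
        arr = struc.AtomArray(len(df))
        arr.chain_id = df["chain"].to_numpy(dtype="U4")
        arr.res_id = df["resid"].to_numpy()
        arr.res_name = df["resname"].to_numpy(dtype="U5")
        arr.atom_name = df["atomname"].to_numpy(dtype="U6")
        arr.element = np.array([_element_of(a) for a in df["atomname"]], dtype="U2")
        arr.hetero = water[df.index].to_numpy()
        arr.coord = df[["x", "y", "z"]].to_numpy()
        frames.append(arr)
    stack = struc.stack(frames)
    out = pdb.PDBFile()
    out.set_structure(stack)
    out.write(str(path))


def read_frame_table(
    path: str | Path | io.IOBase,
    dt: float = 200.0,
    replicate_id: str = "run",
    units: str = "angstrom",
) -> TrajectoryFrames:
    """Read a delimited frame table (CSV or TSV, header required)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"frame table missing column(s): {missing}")
    scale = _unit_scale(units)
    if scale != 1.0:
        df = df.copy()
        df[["x", "y", "z"]] = df[["x", "y", "z"]] * scale
    frames = np.sort(df["frame"].unique())
    if frames[0] != 0 or not np.array_equal(frames, np.arange(len(frames))):
        raise TrajectoryError(
            f"non-contiguous frame indices in table: {frames[:10]}..."
        )
    return TrajectoryFrames(df, dt=dt, replicate_id=replicate_id)


def write_frame_table(traj: TrajectoryFrames, path: str | Path) -> None:
    traj.atoms.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Pore-axis alignment
# ---------------------------------------------------------------------------

def _minimal_rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector `axis` onto +z by the smallest arc."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(axis @ z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about x
        return np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def orient_pore_axis(
    traj: TrajectoryFrames,
    atomname: str = "CA",
    resids: list[int] | None = None,
    sign_resids: tuple[int, int] = (22, 5),
) -> TrajectoryFrames:
    """Rigidly rotate every frame so the selection's principal axis lies
    along +z, with the selection centroid at the origin.

    The principal axis is the largest-variance eigenvector of the selected
    atoms' covariance.  Its sign is fixed so +z points from the Cα centroid of
    ``sign_resids[0]`` toward that of ``sign_resids[1]`` (N-terminal side up
    with the default ``(22, 5)``); when either reference residue is absent the
    axis is oriented to keep its largest-magnitude component positive.

    Idempotent to numerical precision, and a rigid transform (pairwise
    distances preserved).
    """
    new_frames = []
    for i in range(traj.n_frames):
        df = traj.frame(i)
        sel = df[df["atomname"] == atomname]
        if resids is not None:
            sel = sel[sel["resid"].isin(resids)]
        pts = sel[["x", "y", "z"]].to_numpy()
        if pts.shape[0] < 3:
            raise SelectionError(
                f"frame {i}: selection matched {pts.shape[0]} atoms (need >= 3)"
            )
        centroid = pts.mean(axis=0)
        cov = np.cov((pts - centroid).T)
        evals, evecs = np.linalg.eigh(cov)
        if evals[-1] < 1e-12:
            raise SelectionError(f"frame {i}: selection has zero spatial extent")
        axis = evecs[:, -1]
        # sign convention
        ref_lo = sel[sel["resid"] == sign_resids[0]][["x", "y", "z"]].to_numpy()
        ref_hi = sel[sel["resid"] == sign_resids[1]][["x", "y", "z"]].to_numpy()
        if len(ref_lo) and len(ref_hi):
            direction = ref_hi.mean(axis=0) - ref_lo.mean(axis=0)
            if axis @ direction < 0:
                axis = -axis
        else:
            k = int(np.argmax(np.abs(axis)))
            if axis[k] < 0:
                axis = -axis
        rot = _minimal_rotation_to_z(axis)
        coords = df[["x", "y", "z"]].to_numpy()
        new = (coords - centroid) @ rot.T
        out = df.copy()
        out[["x", "y", "z"]] = new
        new_frames.append(out)
    atoms = pd.concat(new_frames, ignore_index=True)
    return TrajectoryFrames(atoms, dt=traj.dt, replicate_id=traj.replicate_id)
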