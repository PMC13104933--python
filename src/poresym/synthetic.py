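"""Ground-truth-labelled synthetic inputs for every pipeline stage.

MD trajectories and plate-reader data for the studied channels are not
distributable, so this module forward-generates stand-ins with known answers:

* :func:`generate_trajectory` — an ideal C5-symmetric pentamer scaffold
  (5 chains x 25 residues on a circle, 1.5 Å helical rise) whose pore-lining
  Gln sidechains follow a scripted or Markov down/neutral/up state sequence
  realised as exact NE2 z-offsets, plus waters that enter and leave the
  anchor-residue hull on a scripted schedule and optional scripted
  water-bridge geometries between chains.  Every scripted quantity is returned
  as :class:`GroundTruth` so the analysis stages can be checked exactly at
  zero noise.
* :func:`generate_flux_traces` — plate-reader F460/F417 channel pairs forward
  generated from a parametric pH(t) decay through the published calibration,
  with seeded multiplicative ratio noise and the analytic window rate as
  ground truth.
* :func:`generate_density_fixture` — analytic sum-of-logistics density
  profiles whose second-derivative zero crossings (hence hydrophobic spans)
  are known in closed form.

Everything is deterministic for a fixed spec and seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PoresymError
from .flux import BufferModel, CalibrationCurve, pH_to_ratio, total_proton
from .hydration import DensityProfile
from .rotamers import DEFAULT_THRESHOLDS, dihedral
from .trajectory import TrajectoryFrames

CHAINS = ("A", "B", "C", "D", "E")
STATES = ("down", "neutral", "up")

#: Default state -> target NE2 z-offset (Å above the Gln Cα plane); values
#: chosen near the reported per-variant cluster means (up ~3.1–3.3, neutral
#: ~1.2, down ~ -0.4 to -1).
DEFAULT_STATE_Z = {"down": -1.0, "neutral": 1.2, "up": 3.3}

_HELIX_RISE = 1.5  # Å per residue
_CENTER_RESID = 13
_SIDECHAIN_REACH = 4.8  # Å, Cα -> Nε2


@dataclass
class TrajectorySpec:
    """Parameters of a synthetic pentamer trajectory.

    ``state_script`` maps chain -> per-frame state sequence; when absent,
    states evolve as a per-chain Markov chain with ``markov_stay``
    self-transition probability.  ``water_schedule`` maps a water id to a list
    of inclusive (entry_frame, exit_frame) intervals during which the water is
    inside the pore; outside those intervals it is parked far from the bundle
    (the roster is constant across frames).  ``bridge_script`` maps a frame
    index to a list of (chain_i, chain_j, n_waters) water bridges placed
    between chain_i's Gln NE2 and chain_j's Gln OE1.
    """

    n_frames: int = 1000
    dt: float = 200.0
    bundle_radius: float = 8.0
    n_residues: int = 25
    gln_resid: int = 10
    ser_resids: tuple[int, ...] = (6, 13)
    state_script: dict[str, list[str]] | None = None
    markov_stay: float = 0.98
    initial_state_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    state_z_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STATE_Z))
    water_schedule: dict[str, list[tuple[int, int]]] | None = None
    bridge_script: dict[int, list[tuple[str, str, int]]] | None = None
    noise_sd: float = 0.0
    seed: int = 0
    replicate_id: str = "synthetic"
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS

    @classmethod
    def from_duration(cls, duration_ns: float, dt: float = 200.0, **kw) -> "TrajectorySpec":
        """Spec for a run of ``duration_ns`` saved every ``dt`` ps."""
        n = int(round(duration_ns * 1000.0 / dt))
        return cls(n_frames=n, dt=dt, **kw)

    def validate(self) -> None:
        t_low, t_high = self.thresholds
        for s, z in self.state_z_map.items():
            if min(abs(z - t_low), abs(z - t_high)) < 0.5:
                raise PoresymError(
                    f"state {s!r} target z={z} is within 0.5 Å of a threshold; "
                    "ground truth would be ambiguous"
                )
            if abs(z) / _SIDECHAIN_REACH >= 0.95:
                raise PoresymError(
                    f"state {s!r} target z={z} exceeds the sidechain reach"
                )
        if self.water_schedule:
            for wid, intervals in self.water_schedule.items():
                prev_end = -1
                for a, b in sorted(intervals):
                    if a <= prev_end or b < a or b >= self.n_frames or a < 0:
                        raise PoresymError(
                            f"water {wid!r}: invalid/overlapping interval ({a}, {b})"
                        )
                    prev_end = b


@dataclass
class GroundTruth:
    """Scripted quantities emitted alongside a synthetic trajectory."""

    states: pd.DataFrame  # frame, chain, state, z_target
    chi: pd.DataFrame  # frame, chain, chi1, chi2 (exact, pre-noise)
    water_counts: np.ndarray
    residence: pd.DataFrame  # water id, entry_frame, exit_frame, n_frames, duration_ns
    bridge_occupancy: dict[tuple, float]  # (chain_i, chain_j) -> scripted frequency


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _gln_sidechain(ca: np.ndarray, u_in: np.ndarray, z_target: float) -> dict[str, np.ndarray]:
    """Place CB..NE2/OE1 so NE2 sits exactly z_target above the Cα z."""
    z_hat = np.array([0.0, 0.0, 1.0])
    dz = z_target / _SIDECHAIN_REACH
    d = np.sqrt(1 - dz**2) * u_in + dz * z_hat
    p = _unit(np.cross(d, z_hat))
    L = _SIDECHAIN_REACH
    atoms = {
        "CB": ca + 0.32 * L * d + 0.55 * p,
        "CG": ca + 0.55 * L * d - 0.55 * p,
        "CD": ca + 0.78 * L * d + 0.55 * p,
        "NE2": ca + L * d,
    }
    atoms["OE1"] = atoms["CD"] + 1.23 * _unit(np.cross(d, p))
    return atoms


def _sample_states(spec: TrajectorySpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    if spec.state_script is not None:
        out = {}
        for c in CHAINS:
            seq = np.asarray(spec.state_script[c], dtype=object)
            if len(seq) != spec.n_frames:
                raise PoresymError(
                    f"state script for chain {c} has {len(seq)} frames, "
                    f"expected {spec.n_frames}"
                )
            out[c] = seq
        return out
    p_stay = spec.markov_stay
    out = {}
    for c in CHAINS:
        seq = np.empty(spec.n_frames, dtype=object)
        seq[0] = STATES[rng.choice(3, p=spec.initial_state_probs)]
        for f in range(1, spec.n_frames):
            if rng.random() < p_stay:
                seq[f] = seq[f - 1]
            else:
                others = [s for s in STATES if s != seq[f - 1]]
                seq[f] = others[rng.integers(2)]
        out[c] = seq
    return out


def generate_trajectory(spec: TrajectorySpec) -> tuple[TrajectoryFrames, GroundTruth]:
    """Build the synthetic trajectory and its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    states = _sample_states(spec, rng)

    thetas = {c: 2 * np.pi * k / 5 for k, c in enumerate(CHAINS)}
    z_hat = np.array([0.0, 0.0, 1.0])

    # static scaffold rows (everything except the Gln sidechain and waters)
    static_rows = []
    ca_pos: dict[tuple[str, int], np.ndarray] = {}
    for c in CHAINS:
        th = thetas[c]
        radial = np.array([np.cos(th), np.sin(th), 0.0])
        u_in = -radial
        t_hat = np.array([-np.sin(th), np.cos(th), 0.0])
        for r in range(1, spec.n_residues + 1):
            # N-terminal side up: +z points from residue 22 toward residue 5
            ca = spec.bundle_radius * radial + (_CENTER_RESID - r) * _HELIX_RISE * z_hat
            ca_pos[(c, r)] = ca
            if r == spec.gln_resid:
                resname = "GLN"
            elif r in spec.ser_resids:
                resname = "SER"
            else:
                resname = "LEU"
            static_rows.append((c, r, resname, "CA", *ca))
            if r == spec.gln_resid:
                n_atom = ca + 1.45 * (-0.80 * z_hat + 0.60 * t_hat)
                static_rows.append((c, r, "GLN", "N", *n_atom))
            if r in spec.ser_resids and r != spec.gln_resid:
                cb = ca + 1.53 * (np.cos(np.radians(20)) * u_in + np.sin(np.radians(20)) * z_hat)
                og = ca + 2.4 * (np.cos(np.radians(40)) * u_in + np.sin(np.radians(40)) * z_hat)
                static_rows.append((c, r, "SER", "CB", *cb))
                static_rows.append((c, r, "SER", "OG", *og))

    # per-(chain, state) Gln sidechain geometries (precomputed)
    sidechains: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    chi_of_state: dict[tuple[str, str], tuple[float, float]] = {}
    for c in CHAINS:
        th = thetas[c]
        u_in = -np.array([np.cos(th), np.sin(th), 0.0])
        ca = ca_pos[(c, spec.gln_resid)]
        n_atom = ca + 1.45 * (-0.80 * z_hat + 0.60 * np.array([-np.sin(th), np.cos(th), 0.0]))
        for s, z_target in spec.state_z_map.items():
            atoms = _gln_sidechain(ca, u_in, z_target)
            sidechains[(c, s)] = atoms
            chi1 = dihedral(n_atom, ca, atoms["CB"], atoms["CG"])
            chi2 = dihedral(ca, atoms["CB"], atoms["CG"], atoms["CD"])
            chi_of_state[(c, s)] = (chi1, chi2)

    # water bookkeeping: scheduled pore waters + parked bridge waters
    schedule = spec.water_schedule or {}
    inside_at: dict[str, np.ndarray] = {}
    for wid, intervals in schedule.items():
        mask = np.zeros(spec.n_frames, dtype=bool)
        for a, b in intervals:
            mask[a : b + 1] = True
        inside_at[wid] = mask
    water_ids = sorted(schedule)
    anchor_zs = sorted(
        (_CENTER_RESID - r) * _HELIX_RISE for r in (5, min(22, spec.n_residues))
    )
    z_lo, z_hi = anchor_zs

    bridge_script = spec.bridge_script or {}
    n_bridge_waters = max(
        (sum(n for _, _, n in evs) for evs in bridge_script.values()), default=0
    )

    frames_out = []
    chi_rows = []
    state_rows = []
    for f in range(spec.n_frames):
        rows = list(static_rows)
        for c in CHAINS:
            s = states[c][f]
            if s not in spec.state_z_map:
                raise PoresymError(f"unknown scripted state {s!r}")
            for name, pos in sidechains[(c, s)].items():
                rows.append((c, spec.gln_resid, "GLN", name, *pos))
            chi1, chi2 = chi_of_state[(c, s)]
            chi_rows.append((f, c, chi1, chi2))
            state_rows.append((f, c, s, spec.state_z_map[s]))
        # scheduled pore waters (resid index within chain "W")
        for k, wid in enumerate(water_ids):
            if inside_at[wid][f]:
                xy = rng.uniform(-1.0, 1.0, size=2)
                z = rng.uniform(z_lo + 1.0, z_hi - 1.0)
                pos = np.array([xy[0], xy[1], z])
            else:
                pos = np.array([40.0 + 3.0 * k, 0.0, 0.0])
            rows.append(("W", k + 1, "HOH", "O", *pos))
        # bridge waters
        used = 0
        for ci, cj, nw in bridge_script.get(f, []):
            e0 = sidechains[(ci, states[ci][f])]["NE2"]
            e1 = sidechains[(cj, states[cj][f])]["OE1"]
            gap = np.linalg.norm(e1 - e0) / (nw + 1)
            if gap > 3.4:
                raise PoresymError(
                    f"frame {f}: bridge {ci}-{cj} with {nw} waters needs "
                    f"{gap:.2f} Å O–O spacing (> 3.4 Å hydrogen-bond reach)"
                )
            for m in range(1, nw + 1):
                pos = e0 + (e1 - e0) * m / (nw + 1)
                rows.append(("X", used + m, "HOH", "O", *pos))
            used += nw
        for m in range(used + 1, n_bridge_waters + 1):
            rows.append(("X", m, "HOH", "O", -60.0 - 3.0 * m, 0.0, 0.0))
        df = pd.DataFrame(
            rows, columns=["chain", "resid", "resname", "atomname", "x", "y", "z"]
        )
        df.insert(0, "frame", f)
        frames_out.append(df)

    atoms = pd.concat(frames_out, ignore_index=True)
    if spec.noise_sd > 0:
        atoms[["x", "y", "z"]] += rng.normal(0.0, spec.noise_sd, size=(len(atoms), 3))
    traj = TrajectoryFrames(atoms, dt=spec.dt, replicate_id=spec.replicate_id)

    counts = np.zeros(spec.n_frames, dtype=int)
    res_rows = []
    for k, wid in enumerate(water_ids):
        counts += inside_at[wid].astype(int)
        for a, b in sorted(schedule[wid]):
            res_rows.append(
                {
                    "water_chain": "W",
                    "water_resid": k + 1,
                    "water_label": wid,
                    "entry_frame": a,
                    "exit_frame": b,
                    "n_frames": b - a + 1,
                    "duration_ns": (b - a + 1) * spec.dt / 1000.0,
                }
            )
    bridge_occ: dict[tuple, float] = {}
    for f, evs in bridge_script.items():
        for ci, cj, _ in evs:
            key = tuple(sorted((ci, cj)))
            bridge_occ[key] = bridge_occ.get(key, 0.0) + 1.0
    bridge_occ = {k: v / spec.n_frames for k, v in bridge_occ.items()}

    truth = GroundTruth(
        states=pd.DataFrame(state_rows, columns=["frame", "chain", "state", "z_target"]),
        chi=pd.DataFrame(chi_rows, columns=["frame", "chain", "chi1", "chi2"]),
        water_counts=counts,
        residence=pd.DataFrame(
            res_rows,
            columns=[
                "water_chain", "water_resid", "water_label",
                "entry_frame", "exit_frame", "n_frames", "duration_ns",
            ],
        ),
        bridge_occupancy=bridge_occ,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Flux traces
# ---------------------------------------------------------------------------

@dataclass
class FluxSpec:
    """Parametric ground-truth pH(t) and plate layout for one variant.

    pH(t) = pH0 for t <= t_val, then pH0 - amplitude * (1 - exp(-(t-t_val)/tau)).
    Sampling every ``interval`` s out to ``t_total`` s, mirroring a
    10-s-interval plate read with valinomycin at 2 min.
    """

    label: str = "variant"
    pH0: float = 7.5
    amplitude: float = 0.4
    tau: float = 180.0
    t_val: float = 120.0
    t_total: float = 720.0
    interval: float = 10.0
    # Multiplicative noise on the 460-nm channel.  The published calibration
    # compresses pH 3-9 into a relative ratio interval of ~6e-5, so the
    # default is set to produce ~0.005 pH units of read noise; much larger
    # values drive the ratio below the calibration floor.
    noise_sd: float = 2e-11
    n_biological: int = 8
    n_technical: int = 3
    f417: float = 10000.0
    calibration: CalibrationCurve = field(default_factory=CalibrationCurve)
    buffer: BufferModel = field(default_factory=BufferModel)
    rate_window: float = 60.0
    seed: int = 0

    def pH_curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        dtv = np.clip(t - self.t_val, 0.0, None)
        return self.pH0 - self.amplitude * (1.0 - np.exp(-dtv / self.tau))

    def validate(self) -> None:
        t = np.arange(0.0, self.t_total + self.interval / 2, self.interval)
        pH = self.pH_curve(t)
        if pH.min() < 3.0 or pH.max() > 9.0:
            raise PoresymError(
                f"pH excursion [{pH.min():.2f}, {pH.max():.2f}] leaves the "
                "calibration range [3, 9]"
            )


def generate_flux_traces(
    spec: FluxSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Forward-generate plate and layout tables plus ground truth.

    Returns ``(plate, layout, truth)`` where ``plate`` has columns
    ``time_s, well, F460, F417``, ``layout`` maps wells to
    (variant, biological_replicate, technical_replicate), and ``truth``
    holds the noiseless window rate (the OLS slope of the exact total-proton
    curve over the sampled points in (t_val, t_val + rate_window]).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.t_total + spec.interval / 2, spec.interval)
    pH = spec.pH_curve(t)
    ratio_true = pH_to_ratio(pH, spec.calibration)
    plate_rows = []
    layout_rows = []
    for b in range(1, spec.n_biological + 1):
        for tech in range(1, spec.n_technical + 1):
            well = f"{spec.label}_b{b}_t{tech}"
            noise = 1.0 + rng.normal(0.0, spec.noise_sd, size=len(t))
            f460 = ratio_true * spec.f417 * noise
            plate_rows.append(
                pd.DataFrame(
                    {"time_s": t, "well": well, "F460": f460, "F417": spec.f417}
                )
            )
            layout_rows.append(
                {
                    "well": well,
                    "variant": spec.label,
                    "biological_replicate": b,
                    "technical_replicate": tech,
                }
            )
    plate = pd.concat(plate_rows, ignore_index=True)
    layout = pd.DataFrame(layout_rows)

    h_true = total_proton(pH, spec.buffer)
    mask = (t > spec.t_val) & (t <= spec.t_val + spec.rate_window)
    slope = np.polyfit(t[mask], h_true[mask], 1)[0]
    truth = {
        "rate": float(slope),
        "t_val": spec.t_val,
        "window": spec.rate_window,
        "pH0": spec.pH0,
        "amplitude": spec.amplitude,
        "tau": spec.tau,
    }
    return plate, layout, truth


# ---------------------------------------------------------------------------
# Analytic density fixtures
# ---------------------------------------------------------------------------

def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class DensityFixture:
    profile: DensityProfile
    inflection_zs: np.ndarray
    expected_length: float

    def sample_waters(
        self, n_frames: int, waters_per_frame: int, seed: int = 0
    ) -> pd.DataFrame:
        """Water z placements realizing the analytic density (inverse CDF)."""
        rng = np.random.default_rng(seed)
        z = self.profile.z
        pdf = np.clip(self.profile.density, 0.0, None)
        if pdf.sum() == 0:
            raise PoresymError("cannot sample from an all-zero density")
        cdf = np.cumsum(pdf)
        cdf = cdf / cdf[-1]
        rows = []
        for f in range(n_frames):
            u = rng.random(waters_per_frame)
            zs = np.interp(u, cdf, z)
            for k, zz in enumerate(zs):
                rows.append({"frame": f, "water": k, "z": zz})
        return pd.DataFrame(rows)


def generate_density_fixture(
    inflection_zs: list[float],
    scale: float = 0.5,
    bin_width: float = 0.25,
    z_pad: float = 8.0,
    amplitude: float = 1.0,
) -> DensityFixture:
    """Analytic density whose second derivative changes sign at known z.

    The curve starts at ``amplitude`` on the left and steps down/up through an
    alternating sum of logistics centred at the requested inflection points
    (each logistic's curvature changes sign exactly at its centre); an empty
    list yields a flat profile with zero hydrophobic length.
    """
    zs = np.asarray(sorted(inflection_zs), dtype=float)
    if len(zs) > 1 and np.min(np.diff(zs)) <= 4.0 * scale:
        raise PoresymError(
            "inflection points must be separated by more than 4*scale"
        )
    lo = (zs.min() - z_pad) if len(zs) else -z_pad
    hi = (zs.max() + z_pad) if len(zs) else z_pad
    z = np.arange(lo, hi + bin_width / 2, bin_width)
    d = np.full_like(z, amplitude)
    sign = -1.0
    for zk in zs:
        d = d + sign * amplitude * _logistic((z - zk) / scale)
        sign = -sign
    d = np.clip(d, 0.0, None)
    profile = DensityProfile(
        z=z, density=d, bin_width=bin_width,
        mean_count=float(d.sum() * bin_width), n_frames=1,
    )
    expected = 0.0
    for a, b in zip(zs[:-1], zs[1:]):
        mid = (a + b) / 2
        level = np.interp(mid, z, d)
        if level < 0.25 * d.max():
            expected = max(expected, b - a)
    return DensityFixture(
        profile=profile, inflection_zs=zs, expected_length=float(expected)
    )
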