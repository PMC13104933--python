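"""Gln orientation vectors, state classification, agreement matrices,
dihedrals, rotamer clustering and the KDE background."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from MDAnalysis.lib.distances import calc_dihedrals

from poresym import DegenerateInputError, TrajectoryFrames, rotamers
from conftest import make_state_table, random_states


def _frame_with_gln(ca_z, ne2, resid=10):
    """One frame: five Gln CA atoms at given z (on a circle) plus one NE2
    on chain A; remaining chains get NE2 colocated with a dummy offset."""
    rows = []
    for k, (c, z) in enumerate(zip("ABCDE", ca_z)):
        th = 2 * np.pi * k / 5
        x, y = 8 * np.cos(th), 8 * np.sin(th)
        rows.append({"frame": 0, "chain": c, "resid": resid, "resname": "GLN",
                     "atomname": "CA", "x": x, "y": y, "z": z})
        pos = ne2 if c == "A" else (x - 1, y, z + 1.0)
        rows.append({"frame": 0, "chain": c, "resid": resid, "resname": "GLN",
                     "atomname": "NE2", "x": pos[0], "y": pos[1], "z": pos[2]})
    return TrajectoryFrames(pd.DataFrame(rows))


class TestGlnVectors:
    def test_vector_and_offset_by_construction(self):
        traj = _frame_with_gln(ca_z=[0, 0, 0, 0, 0], ne2=(9, 0, 3))
        vec = rotamers.compute_gln_vectors(traj)
        a = vec[vec.chain == "A"].iloc[0]
        np.testing.assert_allclose([a.vx, a.vy, a.vz], [1.0, 0.0, 3.0])
        assert a.z_offset == pytest.approx(3.0)

    def test_ne2_on_plane_gives_zero_offset(self):
        traj = _frame_with_gln(ca_z=[0, 0, 0, 0, 0], ne2=(9, 0, 0.0))
        vec = rotamers.compute_gln_vectors(traj)
        assert vec[vec.chain == "A"].iloc[0].z_offset == pytest.approx(0.0)

    def test_plane_is_mean_of_five_ca(self):
        traj = _frame_with_gln(ca_z=[-0.2, -0.1, 0.0, 0.1, 0.2], ne2=(9, 0, 1.0))
        vec = rotamers.compute_gln_vectors(traj)
        # mean CA z = 0, NE2 z = 1.0
        assert vec[vec.chain == "A"].iloc[0].z_offset == pytest.approx(1.0)

    def test_missing_atom_errors(self):
        traj = _frame_with_gln(ca_z=[0] * 5, ne2=(9, 0, 3))
        atoms = traj.atoms[~((traj.atoms.chain == "B") & (traj.atoms.atomname == "NE2"))]
        from poresym.errors import SelectionError
        with pytest.raises(SelectionError):
            rotamers.compute_gln_vectors(
                TrajectoryFrames(atoms.reset_index(drop=True))
            )


class TestClassifyStates:
    @pytest.mark.parametrize(
        "z,expected",
        [(-1.0, "down"), (1.2, "neutral"), (0.0, "neutral"), (2.5, "up"),
         (-1e-9, "down"), (2.4999, "neutral")],
    )
    def test_boundaries(self, z, expected):
        df = pd.DataFrame({"frame": [0], "chain": ["A"], "z_offset": [z]})
        out = rotamers.classify_states(df)
        assert out["state"].iloc[0] == expected

    def test_alternate_methods_threshold(self):
        df = pd.DataFrame({"frame": [0], "chain": ["A"], "z_offset": [2.45]})
        assert rotamers.classify_states(df)["state"].iloc[0] == "neutral"
        assert (
            rotamers.classify_states(df, thresholds=(0.0, 2.4))["state"].iloc[0]
            == "up"
        )


class TestPairwiseAgreement:
    def test_all_same_state(self):
        t = make_state_table({c: ["up"] * 4 for c in "ABCDE"})
        m = rotamers.pairwise_agreement(t).matrix.to_numpy()
        np.testing.assert_allclose(m, 1.0)

    def test_always_disagreeing_pair(self):
        t = make_state_table(
            {"A": ["up"] * 3, "B": ["down"] * 3, "C": ["up"] * 3,
             "D": ["up"] * 3, "E": ["up"] * 3}
        )
        m = rotamers.pairwise_agreement(t).matrix
        assert m.loc["A", "B"] == 0.0

    def test_two_of_three_frames(self):
        t = make_state_table(
            {"A": ["up", "up", "down"], "B": ["up", "up", "up"],
             "C": ["up"] * 3, "D": ["up"] * 3, "E": ["up"] * 3}
        )
        m = rotamers.pairwise_agreement(t).matrix
        assert m.loc["A", "B"] == pytest.approx(2 / 3)

    def test_replicates_are_pooled(self):
        t1 = make_state_table({c: ["up"] * 2 for c in "ABCDE"})
        t2 = make_state_table(
            {"A": ["down"] * 2, "B": ["up"] * 2, "C": ["up"] * 2,
             "D": ["up"] * 2, "E": ["up"] * 2}
        )
        res = rotamers.pairwise_agreement([t1, t2])
        assert res.n_frames_used == 4
        assert res.matrix.loc["A", "B"] == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 40))
    def test_symmetry_diagonal_range(self, seed, n_frames):
        t = random_states(np.random.default_rng(seed), n_frames)
        m = rotamers.pairwise_agreement(t).matrix.to_numpy()
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert np.all((m >= 0) & (m <= 1))

    def test_iid_limit_sum_p_squared(self):
        # independent chains, p = (0.5, 0.3, 0.2): agreement -> sum p^2 = 0.38
        rng = np.random.default_rng(7)
        t = random_states(rng, 30000, probs=(0.5, 0.3, 0.2))
        m = rotamers.pairwise_agreement(t).matrix.to_numpy()
        off = m[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 0.38, atol=0.02)


class TestDihedrals:
    def test_cis_is_zero(self):
        ang = rotamers.dihedral([1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0])
        assert ang == pytest.approx(0.0, abs=1e-12)

    def test_trans_is_180(self):
        ang = rotamers.dihedral([-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0])
        assert abs(ang) == pytest.approx(180.0, abs=1e-12)
        assert ang == 180.0  # range (-180, 180]

    @staticmethod
    def _projection_oracle(p0, p1, p2, p3):
        """Independent float64 torsion: project bond vectors off the central
        axis and take atan2 in that plane."""
        out = np.empty(len(p0))
        for i in range(len(p0)):
            b0 = p0[i] - p1[i]
            b1 = p2[i] - p1[i]
            b2 = p3[i] - p2[i]
            b1 = b1 / np.linalg.norm(b1)
            v = b0 - (b0 @ b1) * b1
            w = b2 - (b2 @ b1) * b1
            x = v @ w
            y = np.cross(b1, v) @ w
            out[i] = np.degrees(np.arctan2(y, x))
        return out

    def test_matches_independent_oracles(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(1000, 4, 3)) * 3.0
        ours = rotamers.dihedral(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        proj = self._projection_oracle(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        diff = np.abs(((ours - proj) + 180.0) % 360.0 - 180.0)
        assert diff.max() < 1e-9
        # MDAnalysis runs in float32; cross-check at its precision
        mda = np.degrees(
            calc_dihedrals(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        )
        diff = np.abs(((ours - mda) + 180.0) % 360.0 - 180.0)
        assert diff.max() < 1e-3

    def test_collinear_triplet_errors(self):
        with pytest.raises(DegenerateInputError):
            rotamers.dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestClusterRotamers:
    @staticmethod
    def _blob(rng, center, n, sd=4.0):
        return pd.DataFrame(
            {
                "frame": np.arange(n), "chain": "A",
                "chi1": rng.normal(center[0], sd, n),
                "chi2": rng.normal(center[1], sd, n),
            }
        )

    def test_two_separated_blobs(self):
        rng = np.random.default_rng(1)
        d = pd.concat(
            [self._blob(rng, (-60, -60), 100), self._blob(rng, (180, 60), 100)],
            ignore_index=True,
        )
        labelled, frac = rotamers.cluster_rotamers(d, eps=20.0)
        clusters = frac[frac.cluster >= 0]
        assert len(clusters) == 2
        np.testing.assert_allclose(clusters["fraction"].to_numpy(), [0.5, 0.5])

    def test_all_identical_points(self):
        d = pd.DataFrame(
            {"frame": np.arange(50), "chain": "A",
             "chi1": np.full(50, -60.0), "chi2": np.full(50, 170.0)}
        )
        _, frac = rotamers.cluster_rotamers(d)
        clusters = frac[frac.cluster >= 0]
        assert len(clusters) == 1
        assert clusters["fraction"].iloc[0] == 1.0

    def test_wraparound_blob_is_one_cluster(self):
        rng = np.random.default_rng(2)
        chi2 = rng.normal(180.0, 6.0, 200)
        chi2 = ((chi2 + 180.0) % 360.0) - 180.0  # wrap to (-180, 180]
        d = pd.DataFrame(
            {"frame": np.arange(200), "chain": "A",
             "chi1": rng.normal(-60, 5, 200), "chi2": chi2}
        )
        labelled, frac = rotamers.cluster_rotamers(d, eps=20.0)
        clusters = frac[frac.cluster >= 0]
        assert len(clusters) == 1
        assert clusters["fraction"].iloc[0] == 1.0


class TestKDEBackground:
    def test_gaussian_enclosed_mass(self):
        rng = np.random.default_rng(3)
        ref = pd.DataFrame(
            {"chi1": rng.normal(-60, 15, 3000), "chi2": rng.normal(60, 15, 3000)}
        )
        bg = rotamers.kde_background(ref)
        fresh_c1 = rng.normal(-60, 15, 10000)
        fresh_c2 = rng.normal(60, 15, 10000)
        for p, target in ((70, 0.70), (90, 0.90)):
            frac = bg.inside(fresh_c1, fresh_c2, p).mean()
            assert frac == pytest.approx(target, abs=0.03)
        assert bg.thresholds[70] >= bg.thresholds[90]

    def test_uniform_enclosed_mass(self):
        rng = np.random.default_rng(4)
        ref = pd.DataFrame(
            {"chi1": rng.uniform(-180, 180, 4000),
             "chi2": rng.uniform(-180, 180, 4000)}
        )
        bg = rotamers.kde_background(ref)
        c1, c2 = rng.uniform(-180, 180, 10000), rng.uniform(-180, 180, 10000)
        for p, target in ((70, 0.70), (90, 0.90)):
            frac = bg.inside(c1, c2, p).mean()
            assert frac == pytest.approx(target, abs=0.04)

    def test_degenerate_reference_raises(self):
        ref = pd.DataFrame({"chi1": np.full(100, -60.0), "chi2": np.full(100, 60.0)})
        with pytest.raises(DegenerateInputError):
            rotamers.kde_background(ref)

    def test_too_few_points(self):
        ref = pd.DataFrame({"chi1": np.zeros(10), "chi2": np.ones(10)})
        with pytest.raises(DegenerateInputError):
            rotamers.kde_background(ref)


class TestZHistogram:
    def test_total_counts_replicates(self):
        rng = np.random.default_rng(6)
        reps = []
        for _ in range(3):
            rows = []
            for c in "ABCDE":
                for f in range(20):
                    rows.append({"frame": f, "chain": c,
                                 "z_offset": rng.normal(1.0, 1.0)})
            reps.append(pd.DataFrame(rows))
        hist = rotamers.z_histogram(reps)
        assert hist.attrs["total"] == 5 * 20 * 3

    def test_single_replicate_arithmetic(self):
        rows = [{"frame": f, "chain": c, "z_offset": 0.7}
                for c in "ABCDE" for f in range(10)]
        hist = rotamers.z_histogram(pd.DataFrame(rows))
        assert hist.attrs["total"] == 50
        assert (hist["count"] > 0).sum() == 1  # all z identical: one bin
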