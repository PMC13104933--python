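import numpy as np
import pandas as pd
import pytest

from poresym import synthetic


@pytest.fixture(scope="session")
def small_traj():
    """30-frame synthetic pentamer with a scripted water schedule."""
    spec = synthetic.TrajectorySpec(
        n_frames=30,
        seed=11,
        water_schedule={"w1": [(3, 7)], "w2": [(0, 4), (8, 9)]},
    )
    traj, truth = synthetic.generate_trajectory(spec)
    return traj, truth


def make_state_table(states_by_chain: dict[str, list[str]]) -> pd.DataFrame:
    """Hand-built state table for agreement-matrix tests."""
    rows = []
    n = len(next(iter(states_by_chain.values())))
    for c, seq in states_by_chain.items():
        assert len(seq) == n
        for f, s in enumerate(seq):
            rows.append({"frame": f, "chain": c, "z_offset": 0.0, "state": s})
    return pd.DataFrame(rows)


def random_states(rng: np.random.Generator, n_frames: int, chains="ABCDE",
                  probs=(1 / 3, 1 / 3, 1 / 3)) -> pd.DataFrame:
    labels = np.array(["down", "neutral", "up"])
    rows = []
    for c in chains:
        seq = labels[rng.choice(3, size=n_frames, p=probs)]
        rows.extend(
            {"frame": f, "chain": c, "z_offset": 0.0, "state": s}
            for f, s in enumerate(seq)
        )
    return pd.DataFrame(rows)
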