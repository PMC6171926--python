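import numpy as np
import pandas as pd
import pytest

from agonet import HerdConfig, generate_herd


def star_adjacency(n: int) -> np.ndarray:
    adj = np.zeros((n, n), dtype=int)
    adj[0, 1:] = 1
    adj[1:, 0] = 1
    return adj


def ring_adjacency(n: int) -> np.ndarray:
    adj = np.zeros((n, n), dtype=int)
    for i in range(n):
        adj[i, (i + 1) % n] = 1
        adj[(i + 1) % n, i] = 1
    return adj


def path_adjacency(n: int) -> np.ndarray:
    adj = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        adj[i, i + 1] = 1
        adj[i + 1, i] = 1
    return adj


def random_adjacency(n: int, p: float, rng: np.random.Generator, directed=False) -> np.ndarray:
    adj = (rng.random((n, n)) < p).astype(int)
    np.fill_diagonal(adj, 0)
    if not directed:
        adj = np.triu(adj, 1)
        adj = adj + adj.T
    return adj


def toy_roster(pen_id="penA", n=15) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pig_id": [f"{pen_id}_p{i:02d}" for i in range(n)],
            "pen_id": pen_id,
            "litter_id": [f"{pen_id}_L{i // 3 + 1}" for i in range(n)],
            "sex": "female",
            "breed": "purebred",
            "weight": 27.6,
            "batch_id": "batch00",
        }
    )


def toy_events(rows, pen_id="penA") -> pd.DataFrame:
    """rows: (initiator, receiver, behaviour, duration[, bite_count])."""
    columns = [
        "pen_id", "initiator", "receiver", "behaviour", "start_time", "duration", "bite_count",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    recs = []
    for t, row in enumerate(rows):
        ini, rec, behaviour, duration = row[:4]
        bite = row[4] if len(row) > 4 else np.nan
        recs.append(
            {
                "pen_id": pen_id,
                "initiator": ini,
                "receiver": rec,
                "behaviour": behaviour,
                "start_time": 60 * t,
                "duration": float(duration),
                "bite_count": bite,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def small_herd():
    """A 12-pen synthetic herd with planted effects (kept small for speed)."""
    config = HerdConfig(n_pens=12, n_batches=4, seed=11)
    roster, events, lesions = generate_herd(config)
    return config, roster, events, lesions


@pytest.fixture(scope="session")
def default_herd():
    """One full-size herd at the default (planted-effect) configuration."""
    config = HerdConfig(seed=5)
    roster, events, lesions = generate_herd(config)
    return config, roster, events, lesions
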