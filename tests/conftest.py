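import numpy as np
import pandas as pd
import pytest

from twintaste import simulate as sim
from twintaste.qc import RatingMatrix


@pytest.fixture(scope="session")
def small_ratings():
    """Small noise-free-ish rating table with repeats, two domains."""
    cfg = sim.SimulationConfig.default(n_mz_pairs=12, n_dz_pairs=8, seed=42)
    object.__setattr__(cfg, "domains", (
        sim.DomainConfig("scenes", n_images=12, n_repeats=5),
        sim.DomainConfig("faces", n_images=10, n_repeats=4),
    ))
    traits = sim.simulate_twin_traits(cfg)
    return sim.simulate_ratings(cfg, traits)


@pytest.fixture
def toy_matrix():
    """Tiny hand-built rating matrix: 3 families x 2 twins, 5 images."""
    rng = np.random.default_rng(7)
    ids = [f"I{f}_{t}" for f in range(3) for t in (1, 2)]
    values = pd.DataFrame(rng.normal(4, 1, size=(6, 5)),
                          index=pd.Index(ids, name="individual_id"),
                          columns=[f"img{j}" for j in range(5)])
    meta = pd.DataFrame({
        "family_id": [f for f in range(3) for _ in (1, 2)],
        "twin_order": [t for _ in range(3) for t in (1, 2)],
        "zygosity": ["MZ", "MZ", "DZ", "DZ", "MZ", "MZ"],
        "sex": ["F"] * 6,
        "age": [30.0, 30.0, 45.0, 45.0, 52.0, 52.0],
    }, index=values.index)
    return RatingMatrix("toy", values, meta)
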