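import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import marrowmap as mm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_dataset():
    """One full 487-vessel dataset with measured calibers (shared, slow)."""
    sets, truth = mm.generate_dataset(mm.FixtureConfig(seed=7))
    rows = []
    for ms in sets:
        for vid in np.unique(ms.lumen_labels):
            if vid == 0:
                continue
            rows.append(
                {
                    "id": int(vid),
                    "ic_um": mm.measure_inner_caliber(
                        ms.lumen_labels == vid, ms.um_per_px
                    ),
                }
            )
    measured = truth.vessel_table.merge(pd.DataFrame(rows), on="id", how="left")
    measured["ic_um"] = measured["ic_um"].fillna(0.0)
    return sets, truth, measured


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_correlated_pair(rng, n=64, rho=0.5, levels=256):
    """Integer channel pair with common signal + independent noise."""
    common = rng.gamma(2.0, 20.0, (n, n))
    g = common + rng.normal(0, 25, (n, n))
    r = rho * common + rng.normal(0, 25, (n, n))
    g = np.clip(np.round(g), 0, levels - 1).astype(np.uint16)
    r = np.clip(np.round(r), 0, levels - 1).astype(np.uint16)
    return mm.ChannelPair(green=g, red=r)
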