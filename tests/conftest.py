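import numpy as np
import pandas as pd
import pytest

import stemniche as sn


@pytest.fixture(scope="session")
def lineage():
    """500-cell differentiation hierarchy with a planted 50-gene module."""
    return sn.simulate_lineage_cells(sn.LineageConfig(seed=1))


@pytest.fixture(scope="session")
def spatial_sample():
    """30x30 Visium-style sample with a tumor disc, planted CNV and signatures."""
    prof = sn.SpotProfiles(
        cnv=sn.CNVGroundTruth(
            segments=[("chr1", 0, 60, 2.0), ("chr2", 100, 150, 0.5), ("chr3", 220, 270, 1.5)],
            malignant_fraction=1.0,
        )
    )
    return sn.simulate_visium_sample(sn.SpatialConfig(seed=1), prof)


@pytest.fixture(scope="session")
def blob_adata():
    """Two well-separated 200-cell populations with inverted expression patterns."""
    import anndata as ad

    rng = np.random.default_rng(0)
    n, g = 200, 60
    up = np.r_[np.ones(30) * 3, np.ones(30) * 0.3]
    b1 = rng.poisson(rng.gamma(2, 2, size=(n, g)) * up)
    b2 = rng.poisson(rng.gamma(2, 2, size=(n, g)) * up[::-1])
    a = ad.AnnData(
        X=np.vstack([b1, b2]),
        obs=pd.DataFrame({"blob": np.r_[np.zeros(n), np.ones(n)]},
                         index=[f"c{i}" for i in range(2 * n)]),
        var=pd.DataFrame(index=[f"g{i}" for i in range(g)]),
    )
    return a
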