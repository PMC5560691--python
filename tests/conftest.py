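import numpy as np
import pandas as pd
import pytest

import censorq as cq


@pytest.fixture
def toy_long_csv(tmp_path):
    """3 samples x 2 targets, one undetermined well."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "sample_id,target_id,group,cq\n"
        "s1,tA,g1,24.1\n"
        "s1,tB,g1,30.2\n"
        "s2,tA,g1,25.0\n"
        "s2,tB,g1,Undetermined\n"
        "s3,tA,g2,23.7\n"
        "s3,tB,g2,31.9\n"
    )
    return path


@pytest.fixture
def small_complete():
    """Complete (censoring-free) dataset, 10 targets, 10+10 samples."""
    cfg = cq.SimConfig(n_targets=10, group_sizes=(10, 10), n_de=4,
                       sigma_range=(1.0, 1.0), seed=42)
    return cq.generate_synthetic(cfg)


@pytest.fixture
def small_censored():
    """Same scale with ~25% censoring."""
    cfg = cq.SimConfig(n_targets=10, group_sizes=(10, 10), n_de=4,
                       sigma_range=(1.0, 1.0), seed=43)
    ds, truth = cq.generate_synthetic(cfg)
    return cq.censor_at_fraction(ds, 0.25), truth


def grid_dataset(values, groups, lod=40.0, censored=None):
    """Build a dataset from a targets x samples array."""
    values = np.asarray(values, float)
    I, J = values.shape
    tids = [f"t{i}" for i in range(I)]
    sids = [f"s{j}" for j in range(J)]
    cens = np.zeros((I, J), bool) if censored is None else np.asarray(censored, bool)
    obs = pd.DataFrame({
        "sample_id": np.tile(sids, I),
        "target_id": np.repeat(tids, J),
        "group": np.tile(groups, I),
        "cq": values.ravel(),
        "censored": cens.ravel(),
    })
    return cq.make_dataset(obs, lod)
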