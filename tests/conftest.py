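import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bandprot import seqdb, simdata

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_dataset():
    """One deterministic synthetic dataset under the default configuration."""
    cfg = simdata.SimConfig(seed=123)
    transcripts, evd, truth = simdata.simulate_dataset(cfg)
    return cfg, transcripts, evd, truth


@pytest.fixture(scope="session")
def sim_db(sim_dataset):
    _, transcripts, _, _ = sim_dataset
    db = seqdb.build_database(transcripts)
    return {p.unigene_id: p.aa_seq for p in db}


@pytest.fixture(scope="session")
def sim_bins(sim_dataset):
    cfg, _, _, truth = sim_dataset
    names = {code: name for code, name, _ in cfg.classes}
    return pd.DataFrame(
        [
            (u, c, names.get(c, ""))
            for u, c in sorted(truth.protein_class.items())
        ],
        columns=["unigene_id", "bin_code", "bin_name"],
    )


def random_transcript(rng: np.random.Generator, min_len: int = 30, max_len: int = 300) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list("ACGT"), size=n))
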