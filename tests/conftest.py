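import numpy as np
import pytest

import mitoscreen as ms


@pytest.fixture(scope="session")
def drug_pipeline():
    """Default synthetic compound screen run through the full pipeline."""
    ds, truth = ms.gen_drug_screen(ms.DrugScreenConfig(seed=5))
    norm = ms.normalize_screen(ds)
    agg = ms.aggregate_replicates(ds, norm)
    return {"dataset": ds, "truth": truth, "normalized": norm, "aggregated": agg}


@pytest.fixture(scope="session")
def sirna_pipeline():
    ds, truth = ms.gen_sirna_screen(ms.SirnaScreenConfig(seed=5))
    norm = ms.normalize_screen(ds)
    agg = ms.aggregate_replicates(ds, norm)
    return {"dataset": ds, "truth": truth, "normalized": norm, "aggregated": agg}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
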