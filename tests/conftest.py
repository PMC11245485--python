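import warnings

import numpy as np
import pandas as pd
import pytest

import stresshub as sh

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions shared by the slower fixtures."""
    return sh.SimConfig(seed=7, n_genes=1000, n_regulators=20,
                        n_planted_hubs=3, n_targets_per_hub=20,
                        n_extra_de=200, n_accessions=60, n_variants=800)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return sh.simulate_bundle(small_config)


@pytest.fixture(scope="session")
def zscored_logtpm(small_bundle):
    expr = small_bundle[0]
    return pd.DataFrame(sh.zscore_rows(np.log2(expr.tpm + 1.0)),
                        index=expr.gene_ids, columns=expr.sample_ids)
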