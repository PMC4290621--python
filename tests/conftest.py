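import numpy as np
import pandas as pd
import pytest

import lncarray as la


@pytest.fixture(scope="session")
def genome_fixture():
    return la.gen_genome_fixture(seed=0)


@pytest.fixture(scope="session")
def planted_cohort():
    spec = la.CohortGenSpec(n_patients=60, n_probes=300, n_informative=30,
                            effect_per_stage=1.0, noise_sd=0.5, seed=11)
    return la.gen_cohort(spec)


@pytest.fixture(scope="session")
def knockdown_cohort():
    return la.gen_knockdown(n_probes=400, de_up=20, de_down=25,
                            effect_log2=2.0, reps=4, seed=5)


@pytest.fixture()
def tiny_matrix():
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["p1", "p2", "p3"], columns=["s1", "s2", "s3", "s4"])
    meta = pd.DataFrame({"stage": ["1", "2b", "3", "4"]},
                        index=["s1", "s2", "s3", "s4"])
    return la.CohortMatrix(values, meta)
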