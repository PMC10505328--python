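import numpy as np
import pandas as pd
import pytest

from hlmetsig import qc
from hlmetsig.synthetic import SimConfig, generate_cohort, generate_metabolome


@pytest.fixture(scope="session")
def small_study():
    """A small but information-rich study: strong loadings, no missingness."""
    cfg = SimConfig(n_participants=500, n_metabolites=50, n_true_signal=5,
                    loading_scale=0.45, missing_rate=0.0, seed=42)
    cohort, truth = generate_cohort(cfg)
    met = generate_metabolome(cohort, truth, cfg)
    return cfg, cohort, truth, met


@pytest.fixture(scope="session")
def prepared_xy(small_study):
    cfg, cohort, truth, met = small_study
    mm, _ = qc.qc_pipeline(met, seed=1)
    X = mm.participant_values()
    y = cohort["hl_true"].to_numpy()
    return X, y, truth


@pytest.fixture()
def toy_matrix():
    """4 participants x 3 metabolites with one missing value and a pooled
    reference interleaved."""
    values = pd.DataFrame(
        [[10.0, 5.0, 1.0],
         [20.0, np.nan, 2.0],
         [15.0, 6.0, 3.0],   # pooled reference row
         [30.0, 9.0, 4.0],
         [40.0, 12.0, 5.0]],
        columns=["m1", "m2", "m3"],
        index=["p1", "p2", "REF_001", "p3", "p4"],
    )
    meta = pd.DataFrame({"is_internal_standard": [False, False, False]},
                        index=["m1", "m2", "m3"])
    from hlmetsig import MetaboliteMatrix
    return MetaboliteMatrix(values=values, meta=meta,
                            run_order=np.arange(5),
                            is_reference=np.array([0, 0, 1, 0, 0], bool))
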