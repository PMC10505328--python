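"""Shared demo study conditions for the numbered analysis scripts.

A mid-sized synthetic study that runs in minutes on one CPU: 800
participants, 120 metabolites with 10 carrying signal, loadings strong
enough for a clearly detectable signature, 2% missing values, a protective
hazard of the true signature and a 30% subcohort.
"""

from hlmetsig.synthetic import SimConfig

SEED = 2026

DEMO = SimConfig(
    n_participants=800,
    n_metabolites=120,
    n_true_signal=10,
    loading_scale=0.35,
    missing_rate=0.02,
    n_internal_standards=2,
    n_high_missing=4,
    logHR_per_unit=-0.6,
    baseline_hazard=0.03,
    censor_time=6.0,
    subcohort_fraction=0.3,
    seed=SEED,
)
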