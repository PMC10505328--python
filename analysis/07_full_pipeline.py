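"""Run the whole pipeline through the orchestration layer and render the
run report (the same path exercised by `hlmetsig all`)."""

from pathlib import Path

from demo_config import DEMO, SEED
from hlmetsig import PipelineConfig, make_report, run_pipeline

out = Path(__file__).resolve().parents[1] / "results" / "pipeline_run"
cfg = PipelineConfig(seed=SEED, sim=DEMO, families=("linear",),
                     alpha_linear=0.6, R=10, K=10,
                     qc_n_trees=30, qc_max_iter=4)
run_pipeline(cfg, out)
print(make_report(out))
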