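"""Growth-chart report: trajectory directions and cross-type correlations.

Summarizes per-region net density change between the first and last age and
the Pearson correlation between the cortex-mean GABAergic and microglial
trajectories (the anti-correlated pair of archetypes).  Results land in
results/pipeline/report/.
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from growthchart.pipeline import PipelineConfig, run_pipeline

if __name__ == "__main__":
    cfg = PipelineConfig(outdir="results/pipeline", seed=1)
    cfg.stages = ("report",)
    manifest = run_pipeline(cfg)
    corr = json.load(open(manifest["stages"]["report"]["correlations"]))
    for c in corr["correlations"]:
        print(f"{c['cell_type_a']} vs {c['cell_type_b']}: "
              f"r = {c['pearson_r']:.4f}, p = {c['p_value']:.4f}")
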