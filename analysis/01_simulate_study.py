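"""Generate the default synthetic developmental study.

Builds the miniature atlas (64x64x32 voxels at 20 um: a 6x6-parcel cortical
slab over four subcortical blocks), draws GABAergic and microglial cell
clouds for 6 ages (P4-P14) x 4 samples/age from the archetype density
trajectories, simulates stochastic 2D detection, and writes the label
volume, ontology, cell tables, flatmap lookup and manifest under
results/pipeline/simulate/.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from growthchart.pipeline import PipelineConfig, run_pipeline

if __name__ == "__main__":
    cfg = PipelineConfig(outdir="results/pipeline", seed=1)
    cfg.stages = ("simulate",)
    manifest = run_pipeline(cfg)
    print("simulate artifacts:")
    for name, path in manifest["stages"]["simulate"].items():
        print(f"  {name}: {path}")
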