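"""Cortical flatmaps: project, average per age, volume-normalize.

Projects each sample's cortical detections onto the AP x azimuth bin grid,
averages samples within (cell type, age), applies the volume-ratio
normalization, and writes CSV matrices + JSON sidecars under
results/pipeline/flatmap/.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from growthchart.pipeline import PipelineConfig, run_pipeline

if __name__ == "__main__":
    cfg = PipelineConfig(outdir="results/pipeline", seed=1)
    cfg.stages = ("flatmap",)
    manifest = run_pipeline(cfg)
    n = len(manifest["stages"]["flatmap"])
    print(f"wrote {n} averaged flatmaps (one per cell type x age)")
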