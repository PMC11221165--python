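"""End-to-end: simulate -> correct -> specialize -> niche -> trends."""

import json
from pathlib import Path

from isobeak.pipeline import PipelineConfig, run_pipeline

outdir = Path("scratch/example_pipeline")
cfg = PipelineConfig(outdir=outdir, seed=1, n_draws=300, n_mc=500, n_perm=199)
manifest = run_pipeline(cfg)

print("artifacts:", ", ".join(manifest["artifacts"]))
print("rows:", json.dumps(manifest["row_counts"]))

trends = json.loads((outdir / "trends.json").read_text())
for key, fit in sorted(trends.items())[:4]:
    print(f"{key}: deviance explained {100 * fit['deviance_explained']:.0f}%"
          f", p_smooth={fit['p_smooth']:.3f}")

print("\nEvery stage ran on the default synthetic scenario (two species, "
      "ten time series, 1844-2018) with one seed; rerunning with the same "
      "seed reproduces every artifact byte for byte.")
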