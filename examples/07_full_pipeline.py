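"""Run every stage end to end and render the figures.

Equivalent to `degpool all` on the command line: the manifest records
the seed, every effective threshold and per-stage row counts, and the
run is byte-identical when repeated with the same seed.
"""

import json

from degpool import figures, pipeline

cfg = pipeline.PipelineConfig(seed=1, outdir="scratch/example_run")
manifest = pipeline.run_pipeline(cfg)
print(json.dumps(manifest["stages"], indent=2))

written = figures.render_figures(cfg.outdir)
print("figures:")
for path in written:
    print(f"  {path}")
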