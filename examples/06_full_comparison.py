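"""The full wild-type vs phosphorylation-mimic comparison pipeline.

One call runs: synthetic reference -> elastic networks -> ensembles ->
descriptors -> essential dynamics -> PRS -> LMI network -> dBC flags,
and returns a report whose every number traces to an on-disk artifact
when an output directory is set.
"""

import json

from allostery.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, n_frames=1000))
print(json.dumps(report.summaries, indent=2, default=str))
print(f"{len(report.flags)} betweenness-centrality flag(s) above 0.1")
print("-> 'rmsd'/'rg' follow the mean (sd) convention; the perturbed system")
print("   shows larger lyase RMSF and extra dBC flags, recovering the")
print("   planted contact edit (44-335 broken, 44-149 formed).")
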