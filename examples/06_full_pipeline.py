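"""Run the whole chain in one call and read the machine-readable report.

Equivalent to `cisclone run-all --out results_demo --n-tumors 150`.
"""

import json

from cisclone import RunConfig, run_pipeline

config = RunConfig(out_dir="results_demo", n_tumors=150, n_perm=200, seed=5)
report = run_pipeline(config)

print(json.dumps(report["stages"], indent=2, default=str))
print()
print("All intermediates (fragments.tsv, insertions.tsv, cis.tsv,")
print("incidence.tsv, network_edges.tsv, progression_edges.tsv, report.json)")
print("are plain text under", config.out_dir + "/")
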