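"""Run the whole pipeline from one configuration mapping.

simulate -> survey -> knee selection, producing the JSON-serializable
report the `uiknmf run` command writes.  The same mapping can live in a
TOML file.
"""

import json

import uiknmf as u

report = u.run_pipeline({
    "simulate": True,
    "sim_processes": 5,
    "sim_genomes": 50,
    "ranks": "2:10",
    "n_run": 5,
    "algorithm": "brunet",
    "seed": 11,
})

print(json.dumps({k: report[k] for k in
                  ("source", "shape", "algorithm", "ranks", "selected_rank",
                   "knee_start", "knee_end")}, indent=2))
print(f"\nselected_rank = {report['selected_rank']}: the knee of the RSS curve "
      "over the surveyed ranks, i.e. the number of latent processes the "
      "pipeline recommends for this catalog.")
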