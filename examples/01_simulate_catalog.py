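"""Simulate a mutational catalog with a known number of processes.

Builds the default benchmark: 10 mutational processes with distinct
96-channel signatures, 100 genomes each dominated by one process, Poisson
counting noise, ~1000 mutations per genome.  Writes the catalog as TSV and
prints what a fitted model should later recover.
"""

import uiknmf as u

spec = u.SimulationSpec(seed=1)
catalog = u.simulate_catalog(spec)
V = catalog.to_target_matrix()

u.write_matrix(V, "catalog.tsv")

print(f"catalog: {V.shape[0]} mutation types x {V.shape[1]} genomes -> catalog.tsv")
print(f"total mutations: {int(catalog.counts.sum())} "
      f"(~{catalog.counts.sum() / spec.n_genomes:.0f} per genome)")
print(f"planted (ground-truth) rank: {catalog.true_rank}")
print("A rank survey of this catalog should place the knee of the RSS curve "
      f"at r = {catalog.true_rank}.")
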