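"""Survey candidate ranks and pick the optimal one at the knee of the RSS curve.

A small catalog with 5 planted processes is surveyed over ranks 2-10 with
5 KL-NMF restarts per rank; the unit-invariant knee estimator then locates
the rank where the residual-sum-of-squares curve turns flat.  Takes a few
seconds.
"""

import uiknmf as u

catalog = u.simulate_catalog(u.SimulationSpec(n_processes=5, n_genomes=50, seed=11))
V = catalog.to_target_matrix()

survey = u.run_survey(V, list(range(2, 11)), n_run=5,
                      spec=u.AlgorithmSpec(name="brunet", seed=11))
knee = u.select_rank(survey)

print(f"{'rank':>4} {'RSS (best of 5)':>16} {'cophenetic':>11}")
for r, rss, coph in zip(survey.ranks, survey.rss_curve, survey.cophenetic_curve):
    marker = "  <- selected" if r == knee.selected else ""
    print(f"{r:>4} {rss:>16.0f} {coph:>11.3f}{marker}")

print(f"\ncurve: {knee.curve_type.convexity}, {knee.curve_type.trend}")
print(f"knee at r = {knee.selected} (true rank {catalog.true_rank}): the RSS drops "
      "steeply while real processes remain unmodeled, then flattens once only "
      "Poisson noise is left.  The cophenetic column barely discriminates here, "
      "which is exactly why the knee criterion is useful.")
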