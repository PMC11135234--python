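# uiknmf

Automatic rank selection for nonnegative matrix factorization (NMF) via the
unit-invariant knee of the RSS rank survey — for gene-expression
deconvolution and mutational-signature analysis.

## The problem

NMF approximates a nonnegative feature-by-sample matrix *V* (genes × tissues,
or 96 trinucleotide mutation types × tumor genomes) as a product of
nonnegative factors,

```
V ≈ W H,     W ∈ R≥0^(m×r),  H ∈ R≥0^(r×n),  r ≤ min(m, n),
```

minimizing either the Frobenius reconstruction error ‖V − WH‖²_F or the
generalized Kullback–Leibler divergence D(V‖WH) by multiplicative updates.
The columns of *W* are metagenes or mutational signatures; the columns of
*H* mix them per sample.  Everything hinges on the rank *r* — the number of
latent processes — which is not known in advance.

`uiknmf` selects *r* automatically from the **residual sum of squares (RSS)
rank survey**: fit NMF at each candidate rank (best of several random
restarts), plot RSS(r), and locate the *knee* — the point where the steeply
falling curve turns flat.  The knee is found with the extremum-distance
estimator: draw the chord between the curve's endpoints and take the first
point of maximal vertical distance to it.  Vertical distance is invariant
under independent positive rescaling of either axis, so the selected rank
does not depend on units (hence *unit-invariant knee*).  Two classical
comparators are included: the cophenetic correlation coefficient of the
restart-consensus matrix, and PRESS (predicted residual sum of squares)
cross-validation by entry holdout, where E(r) = Σ_ab (V_ab − [WH]_ab)² over
held-out entries is minimized at the optimal rank.

A synthetic mutational-catalog generator with a known planted rank (10
processes × 96 mutation types × 100 genomes, Poisson counting noise) makes
the whole pipeline testable end to end without any external data.

## Worked example

```python
import uiknmf as u

catalog = u.simulate_catalog(u.SimulationSpec(n_processes=5, n_genomes=50, seed=11))
V = catalog.to_target_matrix()
survey = u.run_survey(V, ranks=list(range(2, 11)), n_run=5,
                      spec=u.AlgorithmSpec(name="brunet", seed=11))
knee = u.select_rank(survey)
print(survey.rss_curve, knee.selected)
```

This surveys a 94 × 50 catalog with 5 planted processes and prints

```
rank  RSS (best of 5)  cophenetic
   2          1283992       0.899
   3           900030       0.972
   4           426090       0.988
   5            39655       1.000  <- selected
   6            38032       1.000
   ...
  10            32501       0.995
```

RSS collapses by an order of magnitude at r = 5 — each added factor below
the true rank absorbs a real process — then flattens, leaving only the
Poisson noise floor.  The knee estimator selects r = 5, the planted rank,
while the cophenetic column is near 1 almost everywhere and barely
discriminates.  The scripts in `examples/` run this and the other
capabilities (simulation, PRESS cross-validation, the full pipeline) in a
few seconds each.

The same pipeline is available from the shell:

```bash
uiknmf simulate --processes 10 --genomes 100 --seed 1 --out catalog.tsv
uiknmf survey --input catalog.tsv --ranks 2:15 --nrun 10 --algorithm brunet \
              --seed 1 --out survey.tsv --plot survey.png
uiknmf select --input survey.tsv
```

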