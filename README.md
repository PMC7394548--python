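# homeoscreen

Analysis machinery for quantal electrophysiology and genetic-screen
statistics at the *Drosophila* larval neuromuscular junction (NMJ), built
around **presynaptic homeostatic plasticity (PHP)**: when the glutamate
receptor antagonist philanthotoxin-433 (PhTx) reduces the postsynaptic
response to single vesicles, a healthy synapse compensates within minutes by
releasing more vesicles, keeping the evoked depolarization constant.

The package is for physiologists and screeners who need, from per-NMJ
recording summaries:

- **quantal metrics** — quantal content `QC = mean EPSP / mean mEPSP`,
  percent change of mEPSP and QC ±PhTx, and the standard three-way PHP
  classification (<15 % QC change: *blocked*; 15–30 %: *suppressed*;
  ≥30 %: *intact*);
- **a forward-screen hit caller** — flags genotypes whose mean +PhTx QC is
  more than one SD below the population mean of all genotype means, or whose
  mean (mEPSP, QC) point falls below a 95 %-coverage envelope fitted on the
  reference genotype's recordings; candidate hits are triaged into baseline
  versus PHP defects with −PhTx data;
- **a genotype × modifier interaction matrix** — per-cell ±PhTx summaries,
  within-cell Student's t-tests, Dunnett many-to-one comparisons against the
  wild-type cell (seeded Monte-Carlo critical values), heat-map tables;
- **a count-data sub-module** — CPM filtering, a simplified negative-binomial
  Wald test with batch covariate, Benjamini–Hochberg FDR, DEG calling at
  FDR < 0.05 and ±50 % expression change, exclusive (UpSet-style)
  intersections, double-mutant **synergy selection** (DE against all three
  controls with a consistent direction), and ΔΔCt qPCR fold changes;
- **simulators** for every input: seeded quantal recordings with a PhTx
  perturbation (quantal-size scale φ) and a compensation parameter *h*
  (percent QC change = `(1/φ − 1)·h·100`), voltage traces with planted
  miniature/evoked events plus a matched-filter mini detector, and
  negative-binomial count matrices with planted (including synergistic)
  fold changes.

## Worked example

```python
import numpy as np
from homeoscreen import GenotypeParams, ScreenModel, php_summary
from homeoscreen.simulate import simulate_genotype, simulate_screen

rng = np.random.default_rng(7)
reference = GenotypeParams(name="ref")          # full compensation, h = 1
defs = [(f"Df{i:02d}", int(rng.integers(5, 51)),
         GenotypeParams(name=f"Df{i:02d}", compensation=0.0 if i < 3 else 1.0))
        for i in range(10)]                     # 3 planted blocked hits
table, truth = simulate_screen(reference, defs, n_per_genotype=10, rng=rng)

print(php_summary(table[table.genotype == "ref"]).pct_qc_change)
# 99.94000409598925   -> ~ +100% QC change: intact PHP in the reference

res = ScreenModel(table, "ref").fit(coverage=0.95, rule="either")
print(res.frame()[["genotype", "crit_sd", "crit_envelope", "is_hit", "triage"]]
      .query("is_hit"))
#   genotype  crit_sd  crit_envelope  is_hit      triage
# 0     Df00     True           True    True  php_defect
# 1     Df01     True           True    True  php_defect
# 2     Df02     True           True    True  php_defect
```

The three planted zero-compensation deficiencies — and only those — satisfy
both screen criteria, and triage labels them selective PHP defects because
their −PhTx EPSPs match the reference. `res.plot()` draws the screen scatter
with the envelope; `res.summary()` prints the full hit table.

The same pattern applies to the other analyses: `InteractionModel(...).fit()`
returns the matrix with per-cell classes and Dunnett-adjusted p-values, and
`NBExpressionModel(counts, design).fit(("double", "wt"))` returns a DEG
table. A `homeoscreen` CLI exposes each stage (`simulate`, `detect`,
`metrics`, `screen`, `matrix`, `deg`, `run`).

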