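# chemscreen

Quantitative analytics for chemical-biology drug screens, built for the
kind of campaign that takes a compound from a cell-line panel through a
resistance screen, target-engagement metabolomics, and xenograft
efficacy. The package implements four analysis surfaces and a seeded
simulation layer so every stage is testable end to end without
instrument data:

- **Growth scoring** (`chemscreen.growth`) — luminescence plates to
  exponential growth rates `mu = ln((Tend−blank)/(T0−blank))/t`,
  normalized to the DMSO control mean (`mu/mu.max`; 1 = no effect,
  < 0 = cytotoxic), four-parameter log-logistic dose-response fits,
  AUC over the tested log-dose range, sensitivity categories
  (AUC < 2 sensitive, 2–9 moderate, > 9 insensitive), GI75 calls, and
  caspase fold-induction.
- **CRISPR screen scoring** (`chemscreen.screen`) — pooled suppressor
  screens: constant-prefix trimming, exact 22-nt barcode counting
  (perfect matches only), reads-per-million normalization, per-guide
  `log2((RPM_t+0.5)/(RPM_c+0.5))`, gene-level median log2FC and
  abundance, MA table.
- **Isotope tracing** (`chemscreen.isotopes`) — natural-abundance
  correction of mass isotopomer distributions by nonnegative
  least-squares deconvolution, labeled fractions (e.g. cholesterol m+2
  from ¹³C₂-acetate), labeling-inhibition IC50 fits, and IRMS δ →
  atom % D conversion.
- **PK / tumor** (`chemscreen.pk`) — terminal plasma half-life by
  log-linear regression (t½ = ln2/|k|), caliper tumor volume
  0.5·W²·L, and percent tumor-growth inhibition 100·(1 − ΔT/ΔC).
- **Simulation** (`chemscreen.simulate`) — seeded generators for
  plates, screens, isotopomer spectra, PK series and tumor series,
  each returning a truth record for recovery testing.

## Worked example

`examples/` contains one narrative script per surface. For instance,
isotope tracing:

```bash
$ python examples/isotope_tracing.py
corrected m+0: 0.5980 (true 0.6000)
corrected m+2: 0.4012 (true 0.4000)
total labeled: 0.4020
labeling IC50: 78.9 nM (true 76 nM)
delta    +0.0 per mil -> 0.015574 atom % D
delta  +500.0 per mil -> 0.023359 atom % D
delta +2000.0 per mil -> 0.046706 atom % D
```

A cholesterol labeling pattern (40% m+2) is convolved with natural
isotope abundance plus noise, recovered by the correction, and a
nine-point inhibitor titration of the m+2 readout is refit to within a
few percent of its generating 76 nM midpoint. And in vivo:

```bash
$ python examples/pk_tumor.py
terminal t1/2: 8.93 h (true 8.35 h, R^2 = 0.998)
caliper check: W=10, L=12 mm -> 600 mm^3
TGI at day 21: 83.9% (generated inhibition 85%), t-test p = 2.12e-08
```

The other scripts (`growth_scoring.py`, `crispr_screen.py`) score a
simulated viability plate into an AUC category and run a full
FASTQ-to-gene-ranking screen analysis that recovers 10/10 planted
suppressor genes.

A thin CLI mirrors the library (`chemscreen score-growth`,
`score-screen`, `correct-mid`, `labeling-ic50`, `pk-halflife`,
`tumor-tgi`, `simulate`); run `chemscreen --help`.

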