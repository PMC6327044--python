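# Methods

This note records the models behind each analysis surface, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions a maintainer would want to know.

## Growth-rate drug-sensitivity scoring (`chemscreen.growth`)

**Model.** Cell growth over a two-timepoint viability assay is treated
as exponential. With blank-subtracted, ATP-normalized luminescence
signals the growth rate is

    mu = ln((Tend - blank) / (T0 - blank)) / time   [1/h]

and drug effect is expressed as mu/mu.max, where mu.max is the mean mu
of the DMSO control replicates. mu/mu.max = 1 means no effect, 0 means
full growth arrest, and negative values mean net cell loss over the
assay (cytotoxicity) — a property an endpoint-only viability fraction
cannot distinguish from strong growth inhibition.

**ATP calibration.** Every readout passes through a linear ATP standard
curve (signal = slope·ATP + intercept, least squares). This removes
batch-to-batch luminescence scale differences, so T0 and Tend plates
read on different days remain comparable. Signals below the intercept
clamp to 0 ATP with a warning.

**Dose-response fit.** A four-parameter log-logistic in log10 dose:

    r(x) = bottom + (top - bottom) / (1 + 10^(hill (log_ec50 - x)))

fit by `scipy.optimize.curve_fit`. `top` is bounded to [0.5, 1.5]
(a well-behaved assay anchors near 1 at vanishing dose); `bottom` is
unconstrained down to -10 because cytotoxic responses push mu/mu.max
below zero and must be representable. At least 4 distinct nonzero
concentrations are required. On non-convergence the fit is flagged and
downstream AUC integration falls back to piecewise-linear interpolation
of the dose-averaged ratios — a deliberate, conservative fallback since
no behaviour is specified for failed fits.

**AUC and categories.** Sensitivity is the trapezoid integral of the
fitted curve over the tested log-dose range (1001-point grid), in
(mu/mu.max)·decades. The integration domain is each experiment's own
[log10 min dose, log10 max dose]; the category thresholds (sensitive
< 2, moderate 2–9, insensitive > 9) implicitly assume the panel's
ten-point range, so both thresholds and domain are configuration, not
hard-coded semantics. Boundary AUCs (exactly 2 or 9) land in the
moderate band: the strict inequalities of the published rule leave
boundaries undefined and the middle band is the conservative choice.

**GI75.** The dose at which endpoint viability falls to 25% of the DMSO
control, located by piecewise-linear interpolation of fraction against
log10 dose between tested doses only — no extrapolation. If the lowest
tested dose is already at or below 0.25 the GI75 is reported as that
dose (the true crossing lies below the tested range; reporting the
range edge keeps the sensitive call correct without extrapolating). If
0.25 is never reached the GI75 is undefined and the sensitive call
(GI75 < 2 µM by default) is false.

**Degenerate wells.** A Tend signal at or below blank would make the
log undefined; such wells are treated as complete kill, flooring mu at
ln(floor_ratio)/time with floor_ratio = 0.01 (one surviving cell per
hundred) and a warning. A T0 signal at or below blank is an input
error — the assay cannot have started empty.

## Pooled CRISPR suppressor screen (`chemscreen.screen`)

**Counting.** Reads carry a constant vector sequence followed by a
22-nt guide barcode. The constant prefix is located by exact substring
search (first occurrence); the following 22 bases are matched exactly
against the library. Any mismatch anywhere — in prefix or barcode —
drops the read. Exact matching of unique 22-mers is equivalent to
seed-22/zero-mismatch alignment for error-free barcode regions, and
multimapping is impossible because library barcodes are unique.

**Scoring.** Counts are normalized per condition to reads per million
mapped reads (RPM). Per guide,

    log2FC = log2((RPM_treated + 0.5) / (RPM_control + 0.5))

The 0.5-RPM symmetric pseudocount is needed because a suppressor screen
against a lethal dose guarantees dropouts (zero counts) in one
condition; 0.5 is the smallest half-unit that keeps a single-read guide
distinguishable from absence. A gene's score is the median of its
guides' log2FCs (standard median, mean of the central pair for even
counts) — robust to one or two outlier guides. Gene abundance, for the
MA table, is the treated-condition median guide RPM plus the
control-condition median. Guides absent in one condition count as zero
there; they are not dropped. No significance model is layered on top:
the output is the ranked median-log2FC table.

## Isotope tracing (`chemscreen.isotopes`)

**Natural-abundance correction.** For a species with n atoms of the
tracer element, the observed m+0…m+n intensity vector is modelled as
M x, where column j of M is the mass-shift distribution of a molecule
carrying exactly j tracer-labeled atoms: a binomial(n−j, p_tracer) over
the remaining tracer atoms, convolved with the aggregate natural-shift
distribution of every non-tracer atom in the formula (H, N, O, S, P by
default — the correction covers all elements unless configured
otherwise). Shifts heavier than m+n are folded into the m+n bin so
columns are exact probability vectors; the same construction is the
forward model in the generator, making noiseless round trips exact.
Natural abundances default to IUPAC values (13C 0.0107, 2H 0.000156,
15N 0.00364, 17O 0.00038, 18O 0.00205, 33S/34S/36S standard) and are
configurable; tracer isotopic purity is assumed 100% (configurable in
the generator).

**Deconvolution.** x is recovered by nonnegative least squares rather
than matrix inversion: with noisy intensities plain inversion produces
negative fractions. Results are clamped at zero and renormalized to
sum to 1.

**Labeling IC50.** Labeled fractions (e.g. cholesterol m+2 from
13C2-acetate) are expressed as percent of the vehicle-control fraction
and fit with the same 4PL machinery as growth scoring; the IC50 is the
fitted midpoint in the dose units supplied. A response spanning less
than 5% of vehicle is flagged flat and returns no IC50.

**IRMS conversion.** Delta-per-mil values convert to atom % D via
R = R_ref (δ/1000 + 1), atom% = 100 R/(1+R). R_ref defaults to VSMOW
(155.76 × 10⁻⁶) and is configurable, since instrument reference gases
are calibrated per laboratory.

## PK and tumor quantification (`chemscreen.pk`)

**Half-life.** Noncompartmental: ordinary least squares of
ln(concentration) against time over the last `terminal_points` samples
(default 3), t½ = ln 2/|slope|. A nonnegative slope raises (no
elimination phase). Compartmental modelling is out of scope — the
quantity of interest is the terminal half-life alone.

**Tumor volume.** Caliper volume 0.5·W²·L (mm³), with W and L swapped
on input when W > L so the squared axis is always the short one.

**TGI.** Percent tumor-growth inhibition uses the standard xenograft
definition 100·(1 − ΔT/ΔC), with Δ the group-mean volume change from
the randomization baseline to the endpoint day. Vehicle Δ ≤ 0 raises:
the ratio is meaningless when controls did not grow. A Welch t-test on
endpoint volumes is provided as a convenience comparison.

## Synthetic data (`chemscreen.simulate`)

All generators draw from `numpy.random.default_rng(seed)` and are pure
functions of their arguments: a seed fixes every output bit-for-bit.
Every generator returns a truth record with its generating parameters.
Noise is multiplicative lognormal throughout, the standard model for
positive-valued assay signals.

- **Plates**: exponential growth from 1000 ATP units over 96 h at
  mu(dose) = mu.max · 4PL(dose), default mu.max = ln 2/48 h⁻¹ (a 48-h
  doubling time, typical of the cell lines this assay targets), triplicate
  wells over a ten-point 3-fold dilution from 3 µM (the panel's dose
  design), plate CV 5%, a shared cell-free background, and a linear ATP
  standard series.
- **Screens**: default 500 genes × 8 guides (a scaled-down version of a
  ~52k-guide, ~6.5k-gene library) with lognormal control abundances
  (shape 0.5), planted suppressor guides enriched by +4 log2 units,
  other guides depleted by −2 (killed-control design), and multinomial
  read sampling at 10⁶ reads per condition. Reads are constant prefix +
  barcode + random filler at 50 bp.
- **Labeling**: m+2 fractions falling from a vehicle fraction of 0.30
  along a 4PL with hill −1; 5% CV.
- **PK**: mono-exponential decay c(t) = c0·2^(−t/t½), 10% CV, sampled
  at 1–48 h.
- **Tumors**: exponential vehicle growth from a ~200 mm³ randomization
  baseline (0.08/day); the treated arm's volume *gain* is scaled by
  (1 − inhibition), so at zero noise the realized TGI equals the
  nominal inhibition exactly and the TGI estimator can be checked
  against its closed form. Calipers are back-calculated with L = 1.2 W.

**What the generators do not emulate** — and hence what passing tests
do not demonstrate about real data: plate edge/position effects and
drift; sequencing errors inside the barcode region (all simulated reads
are error-free, so exact matching is lossless by construction); PCR
amplification bias beyond lognormal abundance spread; chromatographic
peak-integration error and detector saturation in MS; absorption/
distribution phases and enterohepatic recirculation in PK; and
heteroscedastic caliper error or regressing tumors. Real screens also
carry guide-efficacy variation that the flat planted effect does not
model.

## Test and verification scales

The suite exercises the screen at 200 genes × 5 guides and 1–2 × 10⁵
reads, the MID round trip over 200 random distributions up to C30, and
plates at the full ten-point triplicate design; these sizes make the
whole suite run in seconds while leaving every code path identical to
full-scale runs. Recovery checks on stochastic quantities (labeling
IC50 within 15% at 5% noise; terminal half-life within 10% at 10%
noise) hold for the large majority of seeds under the stated designs;
single-seed failures at roughly the few-percent rate are expected
behaviour of the estimators at those noise levels, not defects.

## Known limitations

- The AUC category thresholds assume the ten-point 3-fold-from-3-µM
  dose design; other designs need recalibrated thresholds.
- GI75 is endpoint-based and does not correct for growth rate, so fast-
  and slow-growing lines are not directly comparable on it.
- The correction matrix assumes the supplied elemental formula is the
  measured ion; adduct atoms must be included by the caller.
- `fit_half_life` assumes the chosen terminal points are in the mono-
  exponential phase; it does not auto-select the terminal window.
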