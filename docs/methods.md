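# Methods

This note documents the statistical model behind `lipidshift`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions at the edges.

## 1. The analysis model

### Normalization

Raw data are counts-per-second per (analyte × injection) from an MRM panel.
Each lipid is divided by the signal of its class' deuterated internal
standard in the same injection; where a class carries several standards
(carnitines: octanoyl- and palmitoyl-carnitine-d3), their mean is the
denominator. Technical replicates are then averaged per mouse. Because the
standards are spiked into the sample *before* extraction, any factor common
to an injection — extraction recovery, injected volume, spray efficiency,
day-to-day drift — cancels in the ratio. The pipeline is therefore
semi-quantitative by construction: only ratios, never absolute amounts, are
interpreted.

The optional *class-relative* mode further divides each species value by
the sum over its class in the same sample. Within each class the values
then sum to 1, and a uniform class-level effect cancels exactly; what
remains is redistribution among the species of a class (chain length /
saturation effects rather than head-group effects).

### Fold changes and tests

Per species and tissue: fold change = treated mean / control mean of the
per-mouse values; SEM = treated-group SEM divided by the control mean
(fold-change units); p-value from a two-tailed two-sample Student's
(pooled-variance) t-test on the per-mouse values. Choices and alternatives:

- **Student vs Welch** — pooled variance is the default (the classical
  "student's t-test" of this analysis style); `test="welch"` switches.
- **SEM basis** — the plotted quantity is the treated group relative to the
  control mean, so the default SEM ignores control-mean uncertainty;
  `sem_basis="delta"` adds it via the delta method and is always larger.
- **No log transform** by default (`log_transform=True` available): tests
  run on the ratio scale the values are reported on.
- **No multiple-testing correction** by default. The analysis philosophy is
  to read effect strength and significance jointly from the volcano
  classification rather than to Bonferroni-correct ~200 correlated
  species; `multiple_testing="bh"` applies Benjamini–Hochberg when a
  corrected view is wanted.
- Mice with missing replicates are averaged over the available replicates,
  with a logged warning.

### Eight-square classification

Each species is categorized on three binary axes: direction (fold change
above/below 1; an exact 1.0 counts as "down", a measure-zero event on
continuous data), significance (p < 0.05, strict), and effect strength
(|fold change − 1| > reference SEM, strict). The reference SEM is the
*mean* of the per-species SEMs, either over the whole record set
(`sem_scope="global"`, used for panel-wide overviews) or over the species'
class (`per_class`, used for per-class panels) — always an explicit
parameter, never inferred. Color mapping: grey (neither), green (beyond SEM
only), blue (significant only), red (both). "Greater than the average SEM"
is operationalized symmetrically in fold-change units — |FC − 1| — because
effects are described as increases/decreases around 1 and both directions
must be treated alike. Strict inequalities make the boundary cases
conservative (a species exactly at the threshold does not qualify).

### Shift statistics

- **Binomial shift test**: exact two-sided binomial test (minimum-likelihood
  convention) of the up/down split of beyond-SEM species against p₀ = 0.5.
  Counting only beyond-SEM species is the default (matching the headline
  tallies of this analysis style); `count_beyond_only=False` counts all.
  Two-sided is the conservative choice; the headline counts are significant
  either way.
- **Mean class effect**: mean and SEM of the species-level fold changes of
  a class, in percent of control, with a two-tailed one-sample t-test
  against 1.0. The SEM is across species (the aggregate is "mean effect on
  all species of the class"); an across-mice alternative would require the
  per-mouse class means and is not the reported quantity. For carnitines
  the aggregate covers acyl-carnitines with chain length > 3 only; free
  carnitine (C0) and acetyl-carnitine (C2) are biologically distinct pools
  and are reported individually via their per-species two-sample t-tests.
- **Cross-tissue comparison**: Fisher's exact test (two-sided) on the 2×2
  table of beyond-SEM up/down counts per tissue; a two-sample t-test on the
  per-species fold changes between tissues; and a Venn partition of
  beyond-SEM species (tissue-exclusive vs both, each annotated with its
  direction per tissue — species can and do disagree in direction).
  Venn membership is beyond-SEM species only, which keeps the partition's
  disjoint-union invariant exact; `include_within_sem=True` adds
  significant-but-within-SEM species tagged tier "within".
- A 2×2 table with a zero margin carries no information about association;
  Fisher's p is reported as 1.0 by convention (logged).

### QC and dose scaling

Spike recovery (100 × measured/expected per analyte, mean reported),
replicate CV (intra-day: sd/mean across same-day replicates; inter-day:
across day means; combined: their mean — both are reported because "the"
replicate CV of a panel can denote either), matrix effect (100 × |ratioA/
ratioB − 1| per ordered pair of distinct class standards; mean and max),
and the body-surface-area dose conversion mouse dose [mg/kg] =
(human dose / human weight) × Km_human/Km_mouse with the conventional
Km = 37 (adult human) and 3 (mouse), both configurable. 50 mg/day at 60 kg
gives 10.28, i.e. a 10 mg/kg daily mouse dose. A simple linear-fit helper
(`dilution_linearity`) covers dilution-series R² checks; no full linearity
module is provided.

## 2. The synthetic-data generator

### Generating model

All noise is multiplicative log-normal with mean 1 (σ of the underlying
normal = √ln(1+CV²)): MS signals are non-negative, noise is roughly
scale-proportional, and variability is quoted as CV. For species *s* in
injection *j* of mouse *m* (group *g*, day *d*):

    cps(s, j) = baseline_s · effect(tissue, s, g) · bio(m, s) · day(d)
                · tech(j) · recovery

Standards share the injection's recovery, day and technical factors and
get an extra matrix-effect factor per (injection × class). Treatment
effects are class-level multipliers with optional per-species multipliers
on top, applied to treated mice only; the exact generating ratio of every
species is always returned as ground truth.

Two structural consequences are worth stating explicitly:

- The technical factor is a **per-injection scalar common to all
  analytes**, so it cancels in every lipid/standard ratio — exactly the
  behaviour internal-standard normalization is designed to produce. Raw
  counts still show the full ~6.5% triplicate CV (what replicate QC
  measures), while normalized values do not.
- The biological factor is drawn **independently per (mouse × species)**.
  It is the only stochastic component that survives normalization, so
  per-species fold changes are independent across species under the null —
  the property that keeps the binomial shift test calibrated (a shared
  per-species technical term in the ratio would correlate signs within a
  class and inflate its type-I error).

### Defaults (the study conditions)

| parameter | default | origin |
|---|---|---|
| mice per group | 5 | study design (n = 10 per tissue) |
| technical replicates | 3 | study design |
| panel | 199 species: 39 TAG, 43 PCaa, 39 PCae, 22 lyso-PC, 15 SM, 41 carnitines; 7 standards | study panel composition |
| technical CV | 0.065 | reported intra/inter-day variance |
| recovery | 0.807 | reported extraction efficiency |
| matrix-effect CV | 0.0088 | closed-form calibration: mean abs. standard-ratio change 2σ√(2/π) ≈ 1.4% (reported mean; reported max 3.2%) |
| biological CV | 0.15 | **not reported**; chosen so that at n = 5 most species-level tests are non-significant while class means are — the qualitative signature of this analysis |
| day CV | 0.02 | **not reported**; a small drift term |
| baselines | log-uniform 10³–10⁶ cps, stable per label | **not reported**; exercises dynamic range without affecting ratio-based results |
| day layout | whole triplicate on one day, mice alternate days | a technical triplicate is acquired back-to-back; day drift enters between mice |

Presets: `brain_pcae` / `liver_pcae` put the plasmalogen class at the
study's printed class means (×1.1086 / ×1.0501); `brain_all` / `liver_all`
additionally set the other classes in the study's summary directions with
calibration-choice magnitudes (brain: TAG 0.85, PCaa 0.88, SM 0.90,
carnitines 0.85; liver: TAG 1.25, PCaa 1.15, SM 0.92, carnitines 1.15;
lyso-PC unchanged in both — only the plasmalogen magnitudes are reported
quantities); `null_brain` has no effects; `two_tissue_all` combines both
tissues. None of these values were adjusted after observing test results.

The matrix-effect and recovery QC figures come from *dedicated* simulated
experiments (`simulate_matrix_experiment`, `simulate_recovery_experiment`)
mirroring how such figures are actually measured — a standard mix in the
presence of extract from each group, and a spike-recovery run — because in
the main dataset, averaging standard ratios over all injections of a group
would shrink the matrix statistic far below its per-sample size.

### What the generator does not emulate

No chromatography, isotope patterns, spectral interference, detector
saturation, or missing values; noise is exactly log-normal with no heavy
tails or outlier injections; species are independent given the class
effect (no correlated lipid metabolism); both groups share one biological
CV. Passing tests on synthetic data therefore validate the *computational
chain and its calibration under the stated noise model* — they do not show
that real tissue data meet these assumptions. The small upward bias of the
ratio-of-means fold-change estimator under biological noise
(≈ +0.5% at CV 0.15, n = 5, visible in the simulation studies) is a
property of the estimator, faithfully reproduced, not an artifact.

## 3. Numerical conventions and degenerate inputs

- Zero-variance t-tests take the limit convention: p = 1 if the group means
  coincide, 0 otherwise (with a warning for the class-mean case).
- Zero/negative standard counts, zero class totals, zero control means,
  groups with fewer than 2 mice, species-set mismatches and malformed
  labels all raise typed errors naming the offending injection/class/
  species; file validation collects *all* violations into one message.
- Exact tests delegate to scipy (`binomtest`, `fisher_exact`); the test
  suite verifies them against independent enumeration oracles exhaustively
  for all tables with n ≤ 20.
- Determinism: every stochastic routine takes a single integer seed; equal
  seeds give bit-identical tables and byte-identical summary bundles
  (JSON with sorted keys, no timestamps).

## 4. Problem sizes used in the checks

The simulation-based checks run at the study's own size (199 species,
5 + 5 mice, triplicates): 200 datasets per tissue for the plasmalogen
class-effect recovery (mean estimate within ±1.5 percentage points of the
generating value), 1000 null datasets for the binomial type-I calibration,
100 paired datasets for the cross-tissue Fisher power check, and 300
repetitions of the matrix-effect experiment. These sizes give Monte-Carlo
standard errors comfortably below the tolerances being checked.
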