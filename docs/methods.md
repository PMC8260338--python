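# Methods

## Binding model

The core model is classical 1:1 receptor occupancy applied to serum:
sFlt-1 is the receptor pool [R]_total, free PlGF the unbound ligand [D],
and the sFlt-1–PlGF complex [DR] satisfies K_D·[DR] = [D]·([R]_total − [DR])
at equilibrium. Assumptions, made explicit:

- **1:1 stoichiometry, single ligand.** No VEGF competition, no sFlt-1
  dimerization, no isoform-specific affinities. A competitive multi-ligand
  model would need assays and affinities that routine practice does not
  have; with only sFlt-1 and free PlGF reported, the two-parameter model is
  the usable one.
- **The measured sFlt-1 is [R]_total** (free plus complexed receptor), with
  no correction for epitope masking by bound ligand.
- **Molecular weights** are fixed at 34 kDa (PlGF) and 100 kDa (sFlt-1) for
  the pg/mL ↔ pmol/L conversion (pmol/L = pg/mL × 1000 / MW). Whether the
  34 kDa refers to the assay-detected monomer or homodimer is not resolved;
  the constant is taken at face value. All internal arithmetic is molar;
  pg/mL exists only at I/O boundaries.
- **Heating is a perfect total readout**: thermal dissociation destroys
  sFlt-1 without degrading PlGF, so the post-heating free-PlGF measurement
  equals free + bound. Partial PlGF degradation at high concentration is
  not modelled.

Per-sample K_D uses [DR] = (total − free) in molar units, then
K_D = [D]([R]_total − [DR]) / [DR]. Samples are excluded when no total is
available, when total ≤ free (zero or negative implied complex — also the
numerically hopeless regime, since total − free cancels catastrophically),
or when the implied complex meets or exceeds [R]_total (physically
inconsistent). The cohort estimate is the arithmetic mean with
SEM = sd/√n; a geometric mean is available but not the default, matching
the convention of reporting mean ± SEM for this constant.

The default K_D is **50 pmol/L**, inside the 20–200 pmol/L range reported
for PlGF/VEGF binding to Flt-1. Every function takes it as a parameter.

### Numerical choices

Free-from-total inverts T = D + D·R/(K_D + D) as the positive root of
D² + D(K_D + R − T) − K_D·T = 0. When b = K_D + R − T ≥ 0 the root is
computed as 2·K_D·T / (b + √(b² + 4·K_D·T)) to avoid subtractive
cancellation in the regime K_D ≪ R that is typical here (K_D ~50 pmol/L vs
sFlt-1 up to ~10⁶ pmol·10⁻³/L); the test suite verifies round-trip accuracy
at K_D/R ratios down to 10⁻¹².

Closed forms are cross-checked against a brute-force bisection solver of
the mass-action balance (1000 random states, 10⁻⁶ relative agreement).

## Statistics

The analysis pipeline mirrors standard biomarker-study practice:

- **Two groups**: Shapiro–Wilk on each group at alpha 0.05 (the test's
  alpha is a package choice consistent with the global 0.05 significance
  rule); both normal → Student t, else Mann–Whitney U. The U test is exact
  (full enumeration over C(n1+n2, n1) assignments of tie-averaged ranks,
  two-sided by distance from the null mean) when both groups have n ≤ 8,
  otherwise the normal approximation with tie correction. The enumeration
  is authored here because library exact methods do not handle ties; it is
  cross-checked against scipy's exact method on tie-free inputs. A `test=`
  argument can force either branch, since the gate itself is a modelling
  choice (e.g. three equally spaced values pass Shapiro–Wilk trivially).
- **Multiple groups**: normality-gated one-way ANOVA vs Kruskal–Wallis,
  with pairwise follow-up (t or Mann–Whitney matching the omnibus branch)
  Bonferroni-corrected for the number of pairs. Dunn's z on pooled ranks is
  available as an alternative post hoc; which correction the original
  analysis used is ambiguous, so both are exposed and neither asserted.
- **Correlation**: Spearman rho on average ranks; exact permutation p (all
  n! pairings) for n ≤ 10, t-approximation above.
- **Line of identity**: OLS of predicted on measured with 95% CIs;
  "identity-compatible" means the slope CI contains 1 and the intercept CI
  contains 0. The CIs carry a float-precision pad (10⁻⁹ relative to scale)
  so that an exactly perfect fit — zero residual variance, zero-width CI —
  is classified compatible. Passing–Bablok regression is available as an
  option; the named test behind "not different from the line of identity"
  is not specified in the source analyses, so the simplest defensible
  reading (OLS CIs) is the default.
- **Quantiles**: linear interpolation between order statistics throughout
  (numpy's default), so simulator parameters and summaries use one
  convention.
- **Clinical rules**: preeclampsia per ISSHP 2001 (new-onset hypertension
  ≥140/90 at ≥20 weeks plus proteinuria: PCR ≥30 mg/mmol, ≥300 mg/24 h, or
  ≥2+ dipstick) and HELLP per ISSHP 2013 (platelets <100×10⁹/L; ALT or AST
  ≥2× ULN; LDH ≥2× ULN or >650 IU/L; all three → HELLP, exactly two →
  partial HELLP). These are the restated operational definitions, not the
  full guideline documents; Swansea scoring for AFLP is out of scope.
- **Ratio cutoffs**: sFlt-1/free-PlGF ≤38 → low, ≥85 → high, both
  boundaries inclusive, in between → intermediate.

## Synthetic cohorts

The generator emulates the marginal structure of the study population.
Marker marginals are **log-normal**, chosen because the printed summaries
are right-skewed positive medians with IQRs; the parameterization is
mu = ln(median), sigma = ln(q3/q1)/(2·z₀.₇₅). This reproduces the median
and the IQR *ratio* exactly; individual quartile endpoints are reproduced
exactly only when the inputs are log-symmetric (true of any log-normal's
own quartiles, approximately true of the printed IQRs — the worst case,
HELLP free PlGF, implies q1 = 37.4 vs printed 39).

The default registry hard-codes the published group statistics (pg/mL,
median [IQR]): sFlt-1 — no-PE 2518 [1744–3903], PE 8772 [6410–10 736],
HELLP 14 572 [5641–20 056], AFLP 77 762 [45 044–116 657]; free PlGF —
no-PE 349, PE 117, HELLP 59 [39–97], AFLP 208 [106–293]; total PlGF —
no-PE 354, PE 435, HELLP 344, AFLP 2054, AFLP postpartum 163; nonpregnant
references sFlt-1 76 [67–84] and PlGF 16 [14–18]; liver failure sFlt-1
446 [211–1414] and total PlGF 22 [12–51]. Where an IQR was not published,
sigma is borrowed from the same group's free-PlGF marginal when available,
otherwise its sFlt-1 marginal — a declared invention. The registry is
serializable to YAML/JSON and fully overridable.

Modes: **marginal** draws every marker independently (distribution-fidelity
checks); **mechanistic_from_free** draws sFlt-1 and free PlGF and derives
total through the binding model; **mechanistic_from_total** draws sFlt-1
and total and derives free by the quadratic inversion. The mechanistic
modes deliberately cannot match all three printed medians at once — medians
do not commute with the nonlinear occupancy map — and exist for round-trip
and parameter-recovery testing. Measurement noise is multiplicative
log-normal with unit mean, default CV 5% (typical automated-immunoassay
imprecision), applied independently per reported analyte; CV 0 yields exact
model states. Identical `SimConfig` (including seed) gives bit-identical
cohorts.

What the generator does **not** emulate: gestational-age dependence,
within-patient longitudinal trajectories, correlation between sFlt-1 and
PlGF production beyond the mechanistic link, assay floors/ceilings, and
cohort selection effects. Passing fidelity and recovery tests therefore
demonstrates internal consistency of the method under the stated
distributional conditions, not performance on real sera.

**Postpartum decay** is exponential toward a nonpregnant floor:
value(d) = floor + (ante − floor)·2^(−d/h), floors 76 pg/mL (sFlt-1) and
16 pg/mL (PlGF) — the nonpregnant reference medians — and half-lives
h(sFlt-1) = 0.85 d, h(PlGF) = 0.58 d. The half-lives are package inventions
constrained only by the published day-2 bounds (<20% of sFlt-1 and <10% of
total PlGF remaining); the generator is not a pharmacokinetic model.

**Spike experiment**: adding exogenous ligand raises the total pool; the
mixture re-equilibrates at the configured K_D. Before heating the assay
sees the new equilibrium free level (strictly less than endogenous free +
added whenever sFlt-1 is present); after heating it sees the full spiked
total, exactly at CV 0.

## Problem sizes

The test suite and acceptance script use 42-sample mechanistic cohorts
(11/13/12/6 across no-PE/PE/HELLP/AFLP — the composition with 42 usable
samples), 200 replicate seeds for noise studies, 100 000 draws for marginal
median fidelity, and 1000 random states for the bisection oracle; these
sizes give sampling error comfortably inside the tolerances checked while
keeping the whole suite interactive.

## Known limitations

- Single-ligand model: systematic K_D bias is expected if VEGF occupies a
  material fraction of sFlt-1 sites.
- The per-sample K_D is undefined (and numerically hopeless) when
  total ≈ free; low-sFlt-1 samples contribute no information about K_D.
- Log-normal marginals are an assumption; only medians and IQRs of the
  source population are honoured.
- The exact Mann–Whitney and Spearman p-values are enumerative and
  intentionally limited to small n (≤8 per group, ≤10 pairs); larger
  samples use standard approximations.
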