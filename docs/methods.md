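# Methods

## Scope and model

`soilmrm` implements the computational half of a multi-residue LC-ESI-MS/MS
(triple-quadrupole, MRM) method for trace pesticide analysis in soils: the
quantification and quality-control pipeline that turns vendor-exported peak
areas into censored concentrations in ng/g dry weight. Peak integration is
out of scope by design — peak areas, signal-to-noise ratios and observed
retention times are inputs, one row per sample × transition.

The quantification model is matrix-matched internal-standard calibration.
The response of analyte *a* in sample *s* is the peak area ratio

    PAR(a, s) = Σ_stereoisomers area_quantifier(a, s) / area_quantifier(ILIS(a), s)

against the analyte's assigned isotope-labelled internal standard (ILIS).
Calibration curves are linear least squares with weights 1/x over twelve
matrix-matched levels (0.05–50 ng/mL in a pesticide-free reference soil
extract, "S2"); the extract concentration is (PAR − a)/b and converts to
ng/g dry weight via extract volume over dry-weight soil mass (1 g : 1 mL in
the reference design, so the two scales coincide numerically).

A result is reportable only if it passes identification: retention time
within ±0.05 min of the batch's calibration standards, and
qualifier/quantifier ion ratio within the banded relative tolerance of EC
Directive 2002/657/EC around the batch-mean reference ratio (> 0.5: ±20%;
0.2–0.5: ±25%; 0.1–0.2: ±30%; ≤ 0.1: ±50%). Results are further censored
against the analyte's method limit of quantification and the curve's
linear range (above-range samples are flagged for re-dilution, never
extrapolated).

Electrospray matrix effects are evaluated from post-extraction spikes:

    ME [%] = (1 − (PA̅_spiked − PA̅_unspiked) / reference) · (−100)

with the solvent standard (case i) or the spiked-minus-unspiked S2 extract
(case ii) as reference; negative values are ion suppression. Because field
soils can suppress more than the S2 calibration matrix, S2-based MLOQs are
multiplied by a *global matrix correction factor*: the smallest suppression
magnitude *s* on a 5%-grid such that at most three analytes (worst case
over soils) suppress beyond −*s* is converted to 1/(1 − s/100) and rounded
*up* to a granularity of 0.5 — the conservative direction, since the factor
only ever raises reporting limits. At the study conditions this yields a
factor of 2 (maximal allowed suppression −50%).

## Surrogate-ILIS assignment

Structure-identical ILIS exist for 65% of analytes. For the rest, a
surrogate is selected systematically: candidates are all same-polarity
ILIS (within ±2 min retention time in positive mode; unrestricted in
negative mode, where only eight ILIS exist), scored by the relative
recoveries they produce in five spiked soils (2.5 ng/g,
spiked-minus-unspiked so native residues cannot bias selection). The
ranking is a strict total order: most soils with recovery inside 70–120%,
then smallest Σ|recovery − 100|, then smallest |ΔRT|, then ILIS id — so
assignment is deterministic and auditable. The exact operationalisation of
"ideally in band in all soils" was an open design choice; this hierarchy
is ours and is configurable.

## The synthetic batch generator

No raw instrument data are deposited with methods of this kind, so every
stage is exercised against a generator whose ground truth is known in
closed form. It emulates:

- **Matrix effects** as ME(species, soil) = β₀ + β₁·C_org + σ·Z(RT), with
  β₀ = +8%, β₁ = −8% per % organic carbon (reproducing median effects of
  ≈ +1% at C_org 0.9 and ≈ −24% at 3.9), σ = 8%, and Z a unit-variance
  Ornstein–Uhlenbeck field over retention time whose correlation decays as
  exp(−|ΔRT|/1 min). A structure-identical ILIS copies its analyte's field
  value (correlation 1); surrogates are merely correlated — the mechanism
  that makes ILIS compensation, and hence the assignment experiment,
  informative.
- **Extraction losses** as per-sample recovery shocks (mean 0.95, sd 0.05)
  drawn from the same kind of RT-correlated field, shared between an
  analyte and any ILIS spiked before extraction.
- **Replicate noise** as multiplicative lognormal factors on peak areas.
  `noise_cv` (default 0.03) parameterises the replicate CV of the *area
  ratio*, the measured response; each individual area receives
  cv/√2, because variability shared by co-injected species (injection
  volume, source drift) cancels in the ratio and must not be
  double-counted. Qualifier areas are the (noisy) quantifier times a
  per-analyte qualifier fraction (0.45 ± 0.15) times an own factor.
- **Sensitivity** via per-species response slopes (lognormal, median
  2·10⁴ counts per ng/mL, GSD 2) and additive-baseline noise floors
  (median 120 counts, GSD 2.5) that enter only S/N = area/floor. Solvent
  standards see a 4× cleaner baseline than matrix extracts, reflecting
  chemical background from co-extracted matrix; this reproduces the
  solvent-vs-matrix gap between instrumental and method LOQs (median
  ILOQ 0.025 ng/mL vs base MLOQ 0.1 ng/g).
- **Aging** of the reference soil S2.1 (spiked at 10 ng/g): per-analyte
  loss fractions, lognormal around a median of 0.07 with a heavy upper
  tail clipped at 0.98 — most analytes lose little, a few degradation-prone
  ones lose almost everything. The tail constant (log-sd 1.56) was set so
  that roughly a quarter of analytes deviate more than ±20% from the
  nominal spike, the qualitative pattern of partly aged reference soils.
  No quantitative aging kinetics were available; these are free parameters
  of the generator, not estimates of any real soil.
- **Day and operator structure**: a per-(analyte, day) lognormal factor
  (CV 0.05) that the ILIS does not share, so inter-day precision on day
  means exceeds intra-day precision, as in real intermediate-precision
  data. No operator effect is injected (the inter-person tier then
  measures only averaging noise).

Randomness comes from one seed fanned out into named substreams keyed by
species/sample/soil identifiers, so output is bit-reproducible and adding
species or samples does not perturb existing draws. Fields are realised on
a 0.05-min RT grid (an AR(1) path with step correlation e^(−0.05/scale)).

What the generator does *not* emulate: chromatographic peak shapes,
integration errors correlated with peak size, carryover, injection-order
drift, heteroscedasticity beyond constant CV, and real soil chemistry.
Passing tests therefore demonstrate that the pipeline's arithmetic,
gating, censoring and selection logic are correct and self-consistent
under realistic statistical structure — not that the real method performs
as simulated.

## Numerical and design choices

- Weighted R² is reported on the weighted residuals, consistent with the
  1/x fit; the unweighted value is also computed.
- The intercept is estimated, not forced through zero.
- Linearity review (±20%, boundary inclusive) evaluates level means and
  trims only contiguously at the range edges; interior failures are
  flagged for review, keeping one linear range per analyte.
- Ion-ratio band boundaries are closed on the lower band (a reference
  ratio of exactly 0.5 gets ±25%); the Directive's text is ambiguous and
  the table is configurable.
- RT gating compares against the batch-mean standard RT (the nearest
  in-sequence standard is not defined for a simulated batch).
- Censored values contribute 0 to site sums; MLOQ-fraction substitution is
  available behind a flag. Sample standard deviation (n−1) throughout.
- MLOQs snap to the calibration-level grid (the definition is "the lowest
  qualifying standard"), never interpolated; the correction factor never
  lowers an MLOQ. Analytes suppressing beyond the factor's design limit
  are listed in the derivation result rather than exempted.
- z-scores use median/MADe (1.4826 × median absolute deviation) as a
  robust simplification of full proficiency-testing statistics; panels
  with fewer than 8 peers are flagged as small (dedicated small-n
  procedures are out of scope).
- Degenerate inputs: zero ILIS area flags an undefined PAR (censored as
  `ilis_missing`, never an exception); a missing qualifier fails the ratio
  gate with a reason code; zero variance in both groups with equal means
  returns p = 1 in the F/t comparison.

## Problem sizes

The shipped analyses use one validation batch of the full method — 146
analytes + 95 ILIS (482 transitions), 103 samples, ≈ 50 000 measurement
rows — which processes end to end, including the surrogate assignment of
51 analytes against a median of 13 candidates each, in well under a
minute. The ILIS-selection experiment uses 200 independently seeded small
batches (1 analyte, 4 candidates, 5 soils). The selection experiment's
candidate geometry (nearest |ΔRT| = 0.07 min, the typical offset of a
well-chosen surrogate, against three candidates ≥ 1.5 min away) was chosen
so the RT-correlation contrast is large relative to the sampling
variability of a five-soil recovery profile; with near-equidistant
candidates the ranking is dominated by that sampling noise and the
experiment stops being informative about the mechanism.

## Known limitations

- The identification module handles exactly two transitions per species;
  identification-point scoring for richer acquisitions is out of scope.
- No left-censored statistics (Kaplan–Meier, regression on order
  statistics) for non-detects; sums treat censored values as 0.
- The generator's matrix-effect mean is linear in organic carbon; real
  suppression saturates and depends on pH, texture and co-elution.
- Replicate combination (duplicate injections, duplicate preparations) is
  by plain means.
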