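# soilmrm

Quantification and quality control for multi-residue pesticide analysis of
soils by LC-ESI-MS/MS in multiple-reaction-monitoring (MRM) mode.

Long-term soil monitoring needs one analytical method to report trace
(sub-ng/g) concentrations of ~150 pesticides consistently across soils
whose organic-carbon content — and hence electrospray ion suppression —
varies several-fold. `soilmrm` implements the data-processing half of such
a method for analysts and method developers: everything after peak
integration, from vendor-exported peak areas to censored concentrations in
ng/g dry weight, with the quality control that makes the numbers
defensible.

The core computations:

- **Matrix-matched internal-standard calibration.** The response is the
  peak area ratio PAR = area(analyte) / area(ILIS) (stereoisomer peaks
  summed); curves are linear least squares with weights 1/x over twelve
  levels (0.05–50 ng/mL) in a pesticide-free soil extract, reviewed for
  linearity at ±20% back-calculation deviation.
- **Identification gating.** Retention time within ±0.05 min of the
  batch's standards and qualifier/quantifier ion ratio within the banded
  tolerance of EC Directive 2002/657/EC (±20/25/30/50% depending on the
  reference ratio).
- **Matrix effects and reporting limits.** Post-extraction spikes give
  ME [%] = (1 − (PA̅_spiked − PA̅_unspiked)/reference)·(−100); the case-(ii)
  suppression distribution across soils sets a *global matrix correction
  factor* (1/(1 − s/100), rounded up to 0.5) that scales the S/N- and
  ion-ratio-based method LOQs.
- **Systematic surrogate-ILIS assignment** for analytes without a
  structure-identical internal standard: same-polarity candidates within
  ±2 min (positive mode), ranked by cross-soil relative-recovery
  conformity (70–120% band count, then dispersion, then |ΔRT|).
- **Figures of merit.** Absolute (extraction) and relative (ILIS-corrected)
  recoveries, four precision tiers (instrumental, intra-day, inter-day,
  inter-person), trueness against a partly aged reference soil, and robust
  median/MADe proficiency z-scores.

Since raw instrument data for such methods are not public, the package
ships a synthetic MRM batch generator (`soilmrm.simulate`) with known
ground truth: C_org-dependent ion suppression correlated between species
with similar retention times, per-sample extraction-recovery shocks shared
with pre-extraction-spiked internal standards, aging losses, and
replicate noise. Every pipeline stage is tested against the generator's
closed forms. See `docs/methods.md` for the model and its limits.

## Worked example

Process one full synthetic validation batch (146 analytes, 95 ILIS,
103 samples) and print the method's figures of merit:

```python
from soilmrm.pipeline import run_validation_batch, figures_of_merit

result = run_validation_batch(seed=1)
fom = figures_of_merit(result)
print(f"median relative recovery: {fom['median_relative_recovery_pct']:.1f}%")
print(f"median intra-day RSD:     {fom['median_intra_day_rsd_pct']:.1f}%")
print(f"median corrected MLOQ:    {fom['median_mloq_ng_g']:g} ng/g")
print(f"global correction factor: {fom['global_matrix_correction_factor']:g}")
```

prints

```
median relative recovery: 99.9%
median intra-day RSD:     3.1%
median corrected MLOQ:    0.2 ng/g
global correction factor: 2
```

i.e. the internal standards compensate extraction losses and matrix
effects almost completely (recovery ≈ 100% despite a simulated 95%
extraction efficiency), replicate precision matches the injected 3% noise,
and the method reports to 0.2 ng/g after doubling the soil-matrix LOQs for
worst-case ion suppression (−50% → factor 2).

The same pipeline is broken into narrative steps under `analysis/`
(simulate → assign ILIS → calibrate → identification QC → matrix
effects/MLOQ → quantify → figures of merit → ILIS-selection experiment);
each script prints what it found and writes its tables to `results/`
(large raw tables go to `scratch/`). Run them in order, e.g.
`python analysis/01_simulate_batch.py --seed 1`.

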