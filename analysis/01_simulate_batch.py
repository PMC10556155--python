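#!/usr/bin/env python
"""Generate one full synthetic validation batch and write its raw tables.

The batch emulates the reference soil multi-residue method: 146 analytes /
95 ILIS, duplicate 12-level matrix-matched calibration (0.05-50 ng/mL) in
the S2 extract, pre-extraction spikes (2.5 ng/g, n=4) and unspiked samples
in soils S1-S5, the post-extraction-spike matrix-effect experiment, a
solvent dilution series, and the partly aged reference soil S2.1 measured
in duplicate on eight days by two operators.

Raw long-format tables are large and go to scratch/sim/; the method
configuration and batch design stay alongside them.
"""

import argparse
from pathlib import Path

from soilmrm.io import write_design, write_measurements, write_method_config, write_soils
from soilmrm.presets import default_scenario, full_method_config, validation_design
from soilmrm.simulate import make_reference_aged, simulate_batch

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("scratch/sim"))
args = parser.parse_args()

out = args.out_dir
out.mkdir(parents=True, exist_ok=True)

scenario = default_scenario(args.seed)
config = full_method_config(scenario)
scenario, aged_truth = make_reference_aged(
    scenario, spike_ng_g=10.0, analyte_ids=[a.analyte_id for a in config.analytes]
)
design = validation_design(config)
measurements, truth = simulate_batch(scenario, design, config)

write_method_config(config, out / "method.yaml")
write_design(design, out / "design.csv")
write_soils(scenario.soils, out / "soils.csv")
write_measurements(measurements, out / "measurements.csv")
truth.true_conc.to_csv(out / "truth_native_conc.csv", index=False)
aged_truth.to_csv(out / "truth_aged_conc.csv", index=False)
truth.matrix_effects.to_csv(out / "truth_matrix_effects.csv", index=False)

print(f"batch: {len(design)} samples x {len(config.species_ids)} species "
      f"-> {len(measurements)} measurement rows")
print(f"aged reference: median true concentration "
      f"{aged_truth['true_conc_ng_g'].median():.2f} ng/g "
      f"(spiked 10 ng/g, partly aged)")
print(f"written to {out}/")
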