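"""Generate a synthetic leaf-spectra survey and write it to disk.

Draws 91 leaf samples on the 350-2500 nm grid with SPAD-driven green
peak / red edge morphology plus per-sample scatter corruption, then
writes the wide spectra CSV, the targets CSV and the ground-truth JSON.
"""

import json
from pathlib import Path

import numpy as np

import leafspec as L

out = Path("scratch/example_data")
out.mkdir(parents=True, exist_ok=True)

cfg = L.SimConfig(n_samples=91, seed=7)
spectra, targets, truth = L.generate_dataset(cfg)

L.write_spectra(spectra, out / "spectra.csv", source="leafspec simulator")
L.write_targets(targets, out / "targets.csv")
(out / "truth.json").write_text(json.dumps({
    "spad": truth.spad.tolist(),
    "sensitive_bands_nm": truth.sensitive_bands.tolist(),
}, indent=2))

print(f"samples: {spectra.n_samples}, bands: {spectra.n_bands} "
      f"({spectra.grid.wavelengths_nm[0]:.0f}-{spectra.grid.wavelengths_nm[-1]:.0f} nm)")
print(f"SPAD: mean {targets.spad.mean():.1f}, range "
      f"{targets.spad.min():.1f}-{targets.spad.max():.1f}")
print(f"chlorophyll-sensitive bands (|dR/dSPAD| >= {truth.sensitivity_threshold}): "
      f"{truth.sensitive_bands.min():.0f}-{truth.sensitive_bands.max():.0f} nm "
      f"({truth.sensitive_bands.size} bands)")
print(f"wrote {out}/spectra.csv, targets.csv, truth.json")
# The sensitive bands cluster at the green peak (551 nm), the red-valley
# shoulder and the red edge (~720 nm) - the regions a chlorophyll model
# should be using.
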