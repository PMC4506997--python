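#!/usr/bin/env python
"""Multi-resolution PET/CT comparison on one fixed phantom.

Renders the same ground truth through three modality pairs — clinical PET/CT,
μPET/μCT, autoradiography/histology — quantifies the PET+/CT−, PET+/CT+ and
PET−/CT+ partition for each, and profiles a transect across the largest
macrodeposit (rim maxima on PET, plateau on CT).

Writes results/tri_class.csv and results/transect.csv.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np

import nafsim as nf
from nafsim import io as nafio
from nafsim.imaging import MODALITY_PRESETS

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

cfg = nf.RunConfig(seed=12345)
phantom = nf.generate_phantom(cfg.phantom.to_phantom_config(), seed=12345)
activity = nf.simulate_uptake(phantom, nf.KineticParameters())
hu = nf.mineral_to_hu(phantom)

comp = nf.resolution_comparison(phantom, activity, hu, cfg)["tri_class"]
nafio.write_tri_class(comp, OUT / "tri_class.csv")

print("PET+/CT- | PET+/CT+ | PET-/CT+ (% of union of positives)")
for pair, res in comp.items():
    p = res.percentages
    print(f"  {pair:35s} {p['pet_only']:5.1f} | {p['both']:5.1f} | {p['ct_only']:5.1f}")

# transect across the largest macrodeposit, noiseless μPET/μCT
big = max(phantom.deposits, key=lambda d: d.radius)
pet = nf.apply_modality(activity, replace(MODALITY_PRESETS["micro_pet"], noise_model="none"))
ct = nf.apply_modality(hu, replace(MODALITY_PRESETS["micro_ct"], noise_model="none"))
c = np.asarray(big.center)
span = big.radius + 500.0
ext = np.minimum(np.asarray(pet.extent), np.asarray(ct.extent))
start = np.clip(c - [span, 0.0], 0.0, ext)
end = np.clip(c + [span, 0.0], 0.0, ext)
tp = nf.transect_profile(pet, ct, start, end, 256)
nafio.write_transect(tp, OUT / "transect.csv")

mid = tp.pet_values[(tp.positions_mm > span / 1000.0 * 0.8)
                    & (tp.positions_mm < span / 1000.0 * 1.2)].mean()
print(f"transect across R={big.radius:.0f} μm deposit: "
      f"rim max {tp.pet_values.max():.3f} vs core mean {mid:.3f}; "
      f"CT plateau max {tp.ct_values.max():.0f} HU")
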