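#!/usr/bin/env python
"""Surface-restricted uptake on the default plaque phantom.

Generates the default 8×8 mm section, simulates tracer uptake with and
without prior sectioning, and tabulates per-deposit signal-per-volume by size
class — the surface-to-volume mechanism behind the micro > macro signal
enrichment.

Writes results/signal_per_volume.csv and the phantom ground truth.
"""

from pathlib import Path

import pandas as pd

import nafsim as nf
from nafsim import io as nafio

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

phantom = nf.generate_phantom(nf.PhantomConfig(), seed=12345)
params = nf.KineticParameters()
whole = nf.simulate_uptake(phantom, params)  # intact tissue: shells only
cut = nf.simulate_uptake(phantom, params, sectioned_first=True)

# volumes are binary scratch output; tables below go to results/
nafio.write_phantom(
    phantom, Path(__file__).resolve().parent.parent / "scratch" / "phantom", "phantom"
)

rows = []
spv_whole = nf.signal_per_volume(whole, phantom)
spv_cut = nf.signal_per_volume(cut, phantom)
for i, dep in enumerate(phantom.deposits):
    rows.append(
        {
            "deposit": i,
            "class": nf.classify_deposit(dep),
            "radius_um": dep.radius,
            "spv_unsectioned": spv_whole[i],
            "spv_sectioned": spv_cut[i],
        }
    )
df = pd.DataFrame(rows)
df.to_csv(OUT / "signal_per_volume.csv", index=False)

by_class = df.groupby("class")["spv_unsectioned"].mean()
print(f"{len(df)} deposits ({(df['class'] == 'micro').sum()} micro, "
      f"{(df['class'] == 'macro').sum()} macro)")
print("mean signal per volume, intact tissue:")
print(f"  micro {by_class['micro']:.3f}  macro {by_class['macro']:.3f} "
      f"(ratio {by_class['micro'] / by_class['macro']:.1f}x)")
print("sectioning never decreases per-deposit signal:",
      bool((df.spv_sectioned >= df.spv_unsectioned - 1e-12).all()))
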