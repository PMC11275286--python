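"""Generate a small synthetic paired-view dataset and inspect its manifest.

Builds 20 synthetic patients (frontal + lateral pseudo-radiographs with the
study's ~4:1 pneumonia imbalance), including some uncertain labels and some
single-view patients, then shows how the label policy and pair filtering
treat them.
"""

from pathlib import Path

import pandas as pd

from vaefusion.manifest_io import build_pairs, parse_manifest
from vaefusion.synthetic_data import SyntheticConfig, generate

out = Path("scratch/example_dataset")
config = SyntheticConfig(n_patients=20, image_size=64, uncertain_fraction=0.1,
                         single_view_fraction=0.1, seed=42)
manifest = generate(config, out)
print(f"manifest: {manifest}")
print(pd.read_csv(manifest).head(6).to_string(index=False))

records = parse_manifest(manifest, "Pneumonia")
pairs = build_pairs(records)
print(f"\n{len(records)} image rows -> {len(pairs)} frontal/lateral pairs")
print(f"positive pairs: {sum(p.label for p in pairs)} "
      f"(uncertain labels count as positive; single-view patients dropped)")
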