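"""Generate a small synthetic cohort and inspect its structure.

Each phantom is a neuromelanin-like / T1-like volume pair with exact
ground-truth masks: a bright midbrain ellipsoid, two crescent-shaped SN
regions inside it and a small hyperintense core per crescent. PD phantoms
draw smaller SN crescents and smaller, dimmer cores than HC phantoms.
"""

import numpy as np

from nigraseg.phantom import PhantomParams, generate_cohort

params = PhantomParams()
records, manifest = generate_cohort(n_hc=3, n_pd=3, params=params, seed=42)

print(manifest[["id", "label", "true_core_volume_mm3"]].to_string(index=False))
for label in ("HC", "PD"):
    vols = [r.sn.physical_volume() for r in records if r.label == label]
    print(f"{label}: mean SN volume {np.mean(vols):7.1f} mm^3 over {len(vols)} subjects")

# The SN volumes echo the clinical picture: the PD group's substantia nigra
# (and its hyperintense core, third column above) is visibly smaller.
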