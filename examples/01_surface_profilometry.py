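"""Measure a surface by phase-shifting fringe projection.

Renders fringe stacks for a sloped block (heights 20-30 mm, the range of a
metacarpophalangeal joint), runs the full chain -- wrapped phase, temporal
unwrapping, rational height model -- and reports the recovery error.  With
noiseless images the chain is exact to well below a micrometre.
"""

import numpy as np

from specdot import phantoms
from specdot.profilometry import measure_height

ramp = np.linspace(20.0, 30.0, 96)[None, :].repeat(64, axis=0)
obj, ref, truth, calib = phantoms.synthesize_profilometry_scene(ramp)

height = measure_height(obj, ref, calib, smoothing=None)
err = np.abs(height.values - truth.values)

print(f"fringe images rendered : {obj.images.shape[0] * obj.images.shape[1]} "
      f"({len(obj.frequencies)} frequencies x {obj.n_shifts} shifts)")
print(f"recovered height range : {height.values.min():.3f} - "
      f"{height.values.max():.3f} mm (truth 20-30 mm)")
print(f"max abs error          : {err.max():.2e} mm")
print("The error is floating-point round-off: the N-step phase estimator and")
print("the temporal unwrapping ladder are exact for noiseless sinusoids.")
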