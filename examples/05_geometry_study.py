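"""Why the single-view system cannot separate the two rods in depth.

Reconstructs the block phantom under three source-detector geometries and
prints the depth profile of recovered concentration through the rod axis.
Only when sources AND detectors surround the object on three orthogonal
faces do the two rods (10 mm apart along z) appear as two maxima.
"""

import numpy as np

from specdot import phantoms, recon, spectra
from specdot.recon import ReconSettings

phantom = phantoms.build_block_phantom(resolution=2.5)
bg = phantom.region_params[0]
musp = {lam: spectra.musp_from_mie(bg.a, bg.b, lam)
        for lam in sorted(spectra.SYSTEM_WAVELENGTHS)}

for label, layout in [("single view", "single"),
                      ("detectors on 3 faces", "det3"),
                      ("sources+detectors on 3 faces", "full")]:
    if layout == "single":
        optodes = phantoms.single_view_optodes(phantom.mesh)
    else:
        optodes = phantoms.three_view_optodes(
            phantom.mesh, sources_three_views=(layout == "full"),
            n_sources=(3, 3), source_spacing=6.0,
            n_detectors=(4, 4), detector_spacing=4.0)
    data = phantoms.simulate_phantom_data(phantom, optodes)
    hom = phantoms.homogeneous_like(phantom)
    result = recon.reconstruct(
        data, hom.mesh, optodes, phantom.table, bg,
        ReconSettings(pixel_size=2.5, max_iterations=12),
        musp_by_wavelength=musp)
    z, prof = recon.axis_profile(result, "dye", axis=2, through=(0.0, 0.0))
    ratio = recon.separation_ratio(z, prof, 5.0, 15.0)
    sep = "separated" if ratio > 0.2 else "merged"
    print(f"{label:30s}: valley ratio {ratio:5.3f} -> rods {sep}")
    print(f"  depth profile c(z): {np.array2string(prof, precision=3)}")
print("Rods sit at z = 5 and 15 mm; the valley ratio measures the dip between")
print("the two expected maxima relative to the overall contrast.")
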