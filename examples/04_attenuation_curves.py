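"""Attenuation of recovered signal under planar vs depth-dependent correction.

Draws a surrogate ensemble of 100,000 subtomograms spread uniformly through
160 nm-thick tomograms at defoci between 1500 and 4500 nm, phase-flips each
one's CTF at the defocus the correction scheme would assume, and reports how
much signal survives at a few resolutions — plus the fold gain of 3D (15 nm
step) over 2D correction at 4.1 A.
"""

import numpy as np

from depthctf import (CtfParams, SubtomogramEnsemble, attenuation_curve,
                      fold_gain)

ens = SubtomogramEnsemble.uniform(100_000, thickness=160.0, seed=1)
base = CtfParams()  # 300 kV, Cs 2.7 mm, amplitude contrast 0.07
freqs = np.union1d(np.linspace(0.0, 0.26, 261), 1.0 / np.array([20.0, 10.0, 4.1]))

curves = {"2D": attenuation_curve(ens, base, "2d", freqs=freqs)}
for step in (30.0, 15.0):
    curves[f"3D step {step:.0f} nm"] = attenuation_curve(ens, base, "3d",
                                                         step=step, freqs=freqs)

print("fraction of signal recovered (1.0 = everything, <0 = net inversion):")
print(f"{'scheme':18s}" + "".join(f"{r:>10.1f} A" for r in (20.0, 10.0, 4.1)))
for name, c in curves.items():
    vals = [c.value_at(1.0 / r) for r in (20.0, 10.0, 4.1)]
    print(f"{name:18s}" + "".join(f"{v:12.3f}" for v in vals))

gain = fold_gain(curves["3D step 15 nm"], curves["2D"], 4.1)
print(f"\nfold gain of 3D (15 nm) over 2D at 4.1 A: {gain:.1f}x")
print("planar correction misassigns the defocus of off-center subtomograms "
      "by up to half the tomogram thickness, flipping the sign of entire "
      "CTF oscillations at high resolution; depth-dependent correction "
      "bounds the error by half the defocus step")
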