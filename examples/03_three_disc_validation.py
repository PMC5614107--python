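"""Synthetic three-disc validation: depth-dependent vs planar CTF correction.

Simulates a tilt series (41 projections, -60..+60 deg) of the three-disc
phantom with a depth-dependent CTF (4000 nm underfocus at the volume center),
reconstructs it with (a) no correction, (b) the single-defocus 2D baseline,
(c) depth-dependent correction at a 60 nm step, plus a CTF-free control, and
scores each disc by local correlation with the ground truth.  Runs at
grid-scale 4 (1024 x 1024, 10.4 A pixels) to stay fast.
"""

from depthctf import (CtfParams, default_geometry, local_correlation,
                      make_disc_phantom, plan_defocus_planes,
                      project_tilt_series, single_plane_plan, three_disc_spec,
                      wbp_3dctf)

spec = three_disc_spec(grid_scale=4)
vol = make_disc_phantom(spec)
geom = default_geometry(vol, defocus=4000.0)
ctf = CtfParams(defocus=4000.0, pixel_size=vol.pixel_size)

series_ctf = project_tilt_series(vol, geom, slab_thickness=20.0, ctf=ctf)
series_free = project_tilt_series(vol, geom, ctf=None)
print(f"simulated {series_ctf.n_tilts} projections of a "
      f"{vol.data.shape[-1]}^2 phantom ({vol.pixel_size:.1f} A pixels)")

radial = (1.0, 0.0)  # full ramp: noise-free synthetic data
recs = {
    "no correction": wbp_3dctf(series_ctf, geom, None, mode="none", radial=radial),
    "2D (single defocus)": wbp_3dctf(series_ctf, geom, single_plane_plan(geom),
                                     mode="phaseflip", ctf=ctf, radial=radial),
    "3D (60 nm step)": wbp_3dctf(series_ctf, geom, plan_defocus_planes(geom, 60.0),
                                 mode="phaseflip", ctf=ctf, radial=radial),
    "CTF-free control": wbp_3dctf(series_free, geom, None, mode="none",
                                  radial=radial),
}

n = vol.data.shape[-1]
px = vol.pixel_size
discs = {"disc #1 (center)": (0.0, 0.0), "disc #2 (z=250 nm)": (0.0, 250.0),
         "disc #3 (x=500 nm)": (500.0, 0.0)}
print(f"{'reconstruction':22s}" + "".join(f"{k:>20s}" for k in discs))
for name, rec in recs.items():
    row = []
    for x_nm, z_nm in discs.values():
        c = (int(round(z_nm * 10 / px)) + n // 2, 0,
             int(round(x_nm * 10 / px)) + n // 2)
        row.append(local_correlation(rec.data, vol.data, c, 4.0))
    print(f"{name:22s}" + "".join(f"{v:20.4f}" for v in row))
print("uncorrected reconstructions anticorrelate with the phantom (inverted "
      "contrast); phase-flipped ones recover it, with the depth-dependent "
      "path scoring at least as high as the planar baseline for the "
      "off-center discs")
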