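# depthctf

Depth-dependent (3D) CTF correction and weighted back projection for
cryo-electron tomography.

Tilt images of a thick, tilted specimen carry two defocus gradients: one
across the image and one through the specimen depth.  Conventional planar
("2D") CTF correction assigns every object the defocus of the tomogram
mid-plane, so objects above or below it are corrected at the wrong defocus —
at high resolution the correction then flips the wrong CTF oscillation
intervals and cancels signal during subtomogram averaging.  `depthctf`
implements the multi-defocus remedy: every tilt image is CTF-corrected at
several defoci spaced by a user-chosen *defocus step* Δ, and during weighted
back projection each voxel is reconstructed from the corrected variant whose
defocus matches the voxel's own depth at that tilt, looked up in a
precomputed (x, z, tilt) defocus index array.

The CTF is modelled as

    CTF(f) = -w1 sin(γ) - w2 cos(γ),   γ = π λ f² (Δz - 0.5 λ² f² Cs)

with w1 = √(1-A²), w2 = A, optional astigmatism
Δz(θ) = Δz + ΔΔz·cos 2(θ-θ_ast), and correction by phase-flipping,
CTF multiplication (with Σ CTF² reweighting of averages) or Wiener
filtering.  The package also ships the two quantitative companions of the
method: a Monte-Carlo simulation of the signal attenuation caused by
phase-flipping at an erroneous defocus (planar vs depth-dependent schemes),
and a synthetic three-disc phantom pipeline (forward projector with a
depth-dependent CTF, FSC and local-correlation metrics) for validation
without any experimental data.

## Worked example

`examples/` contains one short script per capability.
`examples/02_defocus_planes_worked_example.py` plans a 7-plane correction
(step 10 nm) for a two-tilt geometry and looks up three marker voxels in the
defocus index array:

```
planes per tilt: [7, 7]
correction defoci at 0 deg (nm): [3970.0, 3980.0, 3990.0, 4000.0, 4010.0, 4020.0, 4030.0]
blue (above center, off-axis): 0 deg -> image #3 (local defocus 3990.0 nm); 60 deg -> image #2 (local defocus 3980.3 nm)
green (above center, on-axis): 0 deg -> image #3 (local defocus 3990.0 nm); 60 deg -> image #3 (local defocus 3989.8 nm)
red (below center, off-axis): 0 deg -> image #5 (local defocus 4010.0 nm); 60 deg -> image #6 (local defocus 4019.7 nm)
```

A voxel one defocus step above the volume center is reconstructed from
variant #3 (d - Δ) at 0° but — if it sits √3 steps off the tilt axis — from
variant #2 (d - 2Δ) at 60°: the index array tracks each voxel's depth under
rotation.

`examples/04_attenuation_curves.py` quantifies why this matters for
averaging (100,000 subtomograms spread uniformly through 160 nm-thick
tomograms, defoci 1500-4500 nm, 300 kV, Cs 2.7 mm):

```
fraction of signal recovered (1.0 = everything, <0 = net inversion):
scheme                  20.0 A      10.0 A       4.1 A
2D                       0.996       0.961       0.061
3D step 30 nm            1.000       0.999       0.948
3D step 15 nm            1.000       1.000       0.988

fold gain of 3D (15 nm) over 2D at 4.1 A: 16.1x
```

Below 1/(10 Å) the two schemes are equivalent; beyond 1/(5 Å) planar
correction loses nearly everything for this ensemble while the
depth-dependent error stays bounded by Δ/2.
`examples/03_three_disc_validation.py` runs the synthetic three-disc
validation end to end, and `examples/01_ctf_and_correction.py` exercises the
CTF model itself.

## Command line

A thin CLI wraps the library for shell workflows:

```sh
depthctf simulate --out series.mrc --tlt angles.tlt --grid-scale 4 --defocus-table defocus.txt
depthctf reconstruct --tilt-series series.mrc --tlt angles.tlt --defocus defocus.txt \
    --mode phaseflip --defocus-step 15 --thickness 1024 --output tomo.mrc
depthctf attenuate --scheme 3d --step 15 --n 100000 --seed 1 --out curve.tsv
depthctf fsc half_a.mrc half_b.mrc --threshold 0.143 --out fsc.tsv
```

`--defocus-step 0` selects the planar single-defocus baseline;
`plan`, `correct` and `localcc` subcommands expose the remaining pieces, and
`--config file` supplies key=value defaults for any option.

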