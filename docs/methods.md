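# Methods

## The problem

In cryo-electron tomography a tilt series of projection images is recorded
and back-projected into a tomogram.  Every image is modulated by the
microscope's contrast transfer function (CTF), which depends on the local
defocus.  A tilted, thick specimen has two defocus gradients: one across the
image (perpendicular to the tilt axis) and one through the specimen depth.
Conventional "2D" correction handles at most the first; objects above or
below the tomogram mid-plane are then corrected at the wrong defocus, which
flips the sign of entire CTF oscillation intervals at high spatial frequency
and silently cancels signal when many subtomograms are averaged.

## The depth-dependent correction procedure

1. **CTF model.**  `CTF(f) = -w1 sin(gamma) - w2 cos(gamma)` with
   `gamma = pi * lambda * f^2 * (dz - 0.5 * lambda^2 * f^2 * Cs)`,
   `w1 = sqrt(1 - A^2)`, `w2 = A`.  Defocus is stored in nm with underfocus
   positive, Cs in mm, voltage in kV; everything is converted to Angstrom
   internally at the type boundary.  With this sign convention the printed
   formula yields the conventional negative low-frequency contrast.
   Astigmatism enters as `dz(theta) = dz + ddz * cos(2(theta - theta_ast))`,
   the azimuth of the larger-defocus axis being `theta_ast`.
2. **Planning.**  The volume is oriented with the tilt axis along y, so
   defocus varies only in the xz plane.  A point at centered voxel
   coordinates (x, z) sits at beam height `h = -x sin(a) + z cos(a)`; its
   defocus is the tilt's center defocus minus `h` (converted to nm).  This
   handedness reproduces the standard two-tilt worked example (a voxel one
   step above center and `sqrt(3)` steps off-axis moves from `d - step` at
   0 deg to `d - 2*step` at 60 deg); a flag flips it for data with the
   opposite tilt-axis polarity.  For a defocus step `D`, tilt i receives
   `n_i = floor(range_i / D) + 1` correction defoci spaced exactly `D` and
   centered on its center defocus, where
   `range_i = (nx |sin a_i| + nz |cos a_i|) * voxel_nm` is the defocus span
   of the volume cross-section.  The original tool reports only an average
   plane count for its experimental settings, so this per-tilt rule is this
   package's own documented choice, not a claimed identity.
3. **Correction.**  Each tilt image is corrected as a whole (no strips) at
   each planned defocus by phase-flipping (`sign(CTF)`, with `sign(0) := +1`),
   CTF multiplication, or Wiener filtering (`CTF / (CTF^2 + c)`, c a user
   constant, default 0.1 — provided as an extra beyond the two canonical
   modes).  A strip-based corrector (overlapping strips, step one column,
   keeping each strip's central column) is included as the 2D baseline of
   historical workflows.
4. **Reconstruction.**  Corrected variants are ramp-filtered row-wise
   (weight `|f|/f_Nyquist` up to a cutoff, then a Gaussian falloff; defaults
   0.35 / 0.05 of Nyquist, mirroring common practice for noisy cryo data)
   and back-projected: voxel (x, y, z) reads image i at
   `x_img = x cos(a_i) + z sin(a_i)`, row y, by linear interpolation along x,
   and the per-voxel image *variant* is selected by a precomputed
   (tilt, z, x) index array (nearest planned defocus, ties toward the lower
   index; the per-voxel defocus error is therefore bounded by half the
   step).  The array is y-invariant, so only one xz slice of indices exists.
   With one plane per tilt the path is bit-for-bit identical to
   correct-once-then-standard-WBP, because both share a single
   back-projection kernel; results are likewise bit-identical for any
   y-chunk size.  The output is the plain sum over tilts divided by the
   number of tilts.
5. **Multiplication reweighting.**  Averages built from CTF-multiplied data
   are divided in Fourier space by `max(sum CTF^2, 1e-6 * max)` over the
   contributing CTFs.

## Attenuation simulation

For an ensemble of subtomograms the recoverable signal fraction at frequency
f is `sum CTF_true * sign(CTF_assumed) / sum |CTF_true|`.  The 2D scheme
assumes the tomogram-center defocus (error = z, growing as 1/cos(tilt); the
simulations are evaluated at zero tilt, which is where most high-resolution
information comes from); the 3D scheme assumes the nearest plane center
(error folded into +-step/2, tilt-independent).  An optional Gaussian
defocus-determination error (12 nm s.d. in the canonical setting) adds to
both.  Because the experimental position/defocus distributions behind
published attenuation figures are not recoverable, the bundled surrogate
draws z uniformly over the slab thickness (160 nm default) and tomogram
defoci uniformly over 1500-4500 nm (the CTF-search window of typical
processing, truncated; both configurable).  Under this surrogate the fold
gain of 3D (15 nm step) over 2D at 4.1 A is ~16x — much larger than the
~3x reported for real datasets, whose subtomogram positions cluster far
more tightly than a uniform slab; the shape of the curves (no benefit below
1/(10 A), large benefit beyond 1/(5 A)) is reproduced.  The surrogate is a
documented stand-in, not a claimed reconstruction of any experimental
distribution.

## Synthetic validation

The forward simulator rasterises a 1065 nm x 1065 nm xz slice holding three
2.6 nm discs (center; x=0, z=250 nm; x=500 nm, z=0) at 2.6 A per pixel
(4096 pixels per axis; a `grid_scale` factor coarsens this, e.g. scale 4 ->
1024^2 at 10.4 A).  Projection partitions each tilt's beam path into slabs
(default 20 nm, well below the 60 nm correction step used in validation),
projects each slab with the transpose of the back-projection kernel (the
pair passes a dot-product adjointness test at 1e-6 relative tolerance), and
modulates each slab's projection by the CTF at the slab-center defocus; a
CTF-free mode gives the pure missing-wedge control.  The slab model captures
both the cross-image and the depth gradient by construction; halving the
slab thickness changes the images by a decreasing amount.

The validation experiments in `examples/03_three_disc_validation.py` and the
test suite run at grid-scale 4 and score each disc by Pearson correlation
with the ground-truth phantom over a radius-4-voxel neighbourhood,
reconstructing with the full ramp (cutoff 1.0, falloff 0) since the
synthetic series is noise-free.  Two properties of this scaled-down setting
deserve emphasis:

- The depth-dependent-vs-planar contrast is *weak* at 10.4 A pixels: the
  Nyquist frequency admits only ~1.5 CTF oscillations at 4000 nm underfocus,
  so a 250-500 nm defocus error misplaces only a narrow frequency band.  The
  depth-corrected path scores above the planar baseline for the off-center
  discs, but by small margins; the dramatic qualitative difference seen at
  full scale (~29 oscillations to Nyquist) needs the 4096^2 grid.
- Absolute correlations are capped well below 1 by the measurement itself:
  a 2.5-pixel binary disc compared against any band-limited reconstruction
  cannot exceed ~0.92 even for an ideal lowpass, and the missing wedge and
  limited-angle ramp weighting (the same artifacts any standard-WBP control
  shows) bring a faithful control to ~0.74-0.78.  These numbers measure the
  scale and geometry of the experiment, not an implementation defect.

## Numerical choices and degenerate inputs

- All reconstruction arithmetic is float64; MRC I/O uses mode 2 (float32)
  and mode 1 (int16) payloads, little-endian, pixel size in the header.
- Projected positions outside `[0, nx_img - 1]` contribute nothing; the
  position exactly on the last sample is kept (left index clamped, weight 1).
- Phase-flip applied twice restores an image to ~1e-15; exact bit identity
  is not possible across two FFT round trips.
- Astigmatic CTF grids average the two azimuths aliased onto self-conjugate
  Nyquist samples of even-sized axes, so the filter is exactly even.
- `floor(span/step) + 1` keeps plane spacing exactly equal to the step; a
  step of zero (CLI `--defocus-step 0`) selects the degenerate single-plane
  plan, i.e. the planar baseline.
- Attenuation-curve samples with a vanishing denominator, fold gains over a
  non-positive denominator, FSC thresholds never crossed, and zero-variance
  correlation patches all return NaN rather than raising.
- Sub-pixel slab thicknesses clamp to one pixel with a warning.

## Problem sizes used by the tests

Unit tests use 16-64 voxel grids; the end-to-end validation runs at
grid-scale 4 (1024^2, 41 tilts, ~20 corrected variants per tilt) and the
oracle-equivalence check on a 256 x 256 x 64 random volume; the attenuation
simulation uses 1e5 subtomograms.  These sizes were chosen so the full suite
completes in about a minute while still exercising every code path at
realistic parameter values; the full-scale 4096^2 validation runs through the
same API (`three_disc_spec(grid_scale=1)`) when desired.

## Known limitations

- No envelope/damping functions, phase plates, dose weighting or detector
  MTF in the CTF model; defoci are inputs (estimation is upstream).
- Zero x-tilt geometry only: no in-plane rotations, local alignments or
  beam-induced motion.
- The synthetic projector is a line-integral slab model, not multislice wave
  propagation; no solvent/ice model and no noise unless requested.
- Plain two-volume FSC only (no masking or phase randomization).
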