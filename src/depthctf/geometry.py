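"""Tilt geometry: voxel-to-defocus mapping and multi-defocus correction plans.

The reconstruction volume is oriented with the tilt axis parallel to the y
axis (zero x-tilt), so defocus varies only in the xz plane.  A point at
centered voxel coordinates (x, z) sits at beam height

    h = -x * sin(alpha) + z * cos(alpha)       [voxels]

at tilt angle alpha; points higher along the beam are closer to the lens and
therefore less underfocused.  For depth-dependent correction, every tilt
image is corrected at several defoci spaced by a user-chosen defocus step,
and a precomputed (tilt, z, x) index array records which corrected variant
reconstructs each voxel column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NM_PER_A = 0.1


@dataclass
class TiltGeometry:
    """Volume dimensions, tilt angles and per-tilt nominal defoci.

    ``volume_dims`` is (nx, ny, nz) in voxels; ``pixel_size`` in Angstrom;
    ``tilt_angles`` in degrees, strictly inside (-90, 90); ``center_defocus``
    is the nominal defocus (nm, underfocus positive) at the volume center for
    each tilt.  ``z_shift`` (nm) offsets all center defoci when the volume
    center does not sit at the nominal defocus.  ``invert_handedness`` flips
    the sign of x in the beam-height formula for data with the opposite
    tilt-axis polarity.
    """

    volume_dims: tuple
    pixel_size: float
    tilt_angles: np.ndarray
    center_defocus: np.ndarray
    z_shift: float = 0.0
    invert_handedness: bool = False

    def __post_init__(self) -> None:
        self.tilt_angles = np.atleast_1d(np.asarray(self.tilt_angles, dtype=float))
        self.center_defocus = np.atleast_1d(np.asarray(self.center_defocus, dtype=float))
        if self.center_defocus.size == 1 and self.tilt_angles.size > 1:
            self.center_defocus = np.full(self.tilt_angles.size, self.center_defocus[0])
        nx, ny, nz = self.volume_dims
        if min(nx, ny, nz) <= 0:
            raise ValueError("volume dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.any(np.abs(self.tilt_angles) >= 90.0):
            raise ValueError("tilt angles must lie strictly within (-90, 90) degrees")
        if self.center_defocus.size != self.tilt_angles.size:
            raise ValueError("need one center defocus per tilt angle")

    @property
    def n_tilts(self) -> int:
        return self.tilt_angles.size

    @property
    def voxel_nm(self) -> float:
        """Voxel edge length in nm."""
        return self.pixel_size * NM_PER_A

    def centered_x(self) -> np.ndarray:
        nx = self.volume_dims[0]
        return np.arange(nx) - nx // 2

    def centered_z(self) -> np.ndarray:
        nz = self.volume_dims[2]
        return np.arange(nz) - nz // 2


@dataclass
class DefocusPlan:
    """Per-tilt lists of correction defoci, spaced by ``defocus_step`` nm.

    Each list is symmetric about that tilt's center defocus, so consecutive
    entries differ by exactly the step.  A step of 0 denotes the degenerate
    single-defocus (2D baseline) plan.
    """

    defoci: list = field(default_factory=list)  # one ascending ndarray (nm) per tilt
    defocus_step: float = 0.0

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(d) for d in self.defoci])


@dataclass
class DefocusArray:
    """(tilt, z, x) grid of 1-based indices into each tilt's corrected images.

    Indices follow the "image #k" numbering of the plan's ascending defocus
    list (so #1 is the most underfocus-reduced variant, d - (n-1)/2 * step).
    The array is constant along y by construction and is stored as
    ``indices[tilt, z, x]`` over 0-based voxel indices.
    """

    indices: np.ndarray  # int32, shape (n_tilts, nz, nx)
    plan: DefocusPlan

    def for_tilt(self, i: int) -> np.ndarray:
        return self.indices[i]


def point_defocus(geom: TiltGeometry, x, z, tilt_index: int):
    """Defocus (nm) of a point at centered voxel coordinates (x, z) at a tilt.

    Returns ``center_defocus + z_shift - h * voxel_nm`` with beam height
    ``h = -x*sin(alpha) + z*cos(alpha)``: points higher along the beam are
    less underfocused.  ``x`` and ``z`` may be arrays (broadcast).
    """
    n = geom.n_tilts
    if not -n <= tilt_index < n:
        raise IndexError(f"tilt_index {tilt_index} out of range for {n} tilts")
    alpha = np.deg2rad(geom.tilt_angles[tilt_index])
    x = np.asarray(x, dtype=float)
    if geom.invert_handedness:
        x = -x
    h = -x * np.sin(alpha) + np.asarray(z, dtype=float) * np.cos(alpha)
    return geom.center_defocus[tilt_index] + geom.z_shift - h * geom.voxel_nm


def plan_defocus_planes(geom: TiltGeometry, defocus_step: float) -> DefocusPlan:
    """Choose the per-tilt correction defoci for a given defocus step (nm).

    The defocus span of tilt i over the volume cross-section is
    ``range_i = (nx*|sin a_i| + nz*|cos a_i|) * voxel_nm``; the plan uses
    ``n_i = floor(range_i / step) + 1`` defoci spaced exactly ``step`` and
    centered on that tilt's (shifted) center defocus.
    """
    if defocus_step <= 0:
        raise ValueError("defocus_step must be positive")
    nx, _, nz = geom.volume_dims
    defoci = []
    for alpha, d in zip(np.deg2rad(geom.tilt_angles), geom.center_defocus):
        span = (nx * abs(np.sin(alpha)) + nz * abs(np.cos(alpha))) * geom.voxel_nm
        n = int(np.floor(span / defocus_step)) + 1
        offsets = (np.arange(n) - (n - 1) / 2.0) * defocus_step
        defoci.append(d + geom.z_shift + offsets)
    return DefocusPlan(defoci=defoci, defocus_step=float(defocus_step))


def single_plane_plan(geom: TiltGeometry) -> DefocusPlan:
    """Degenerate plan with one defocus per tilt (the 2D baseline)."""
    defoci = [np.array([d + geom.z_shift]) for d in geom.center_defocus]
    return DefocusPlan(defoci=defoci, defocus_step=0.0)


def build_defocus_array(geom: TiltGeometry, plan: DefocusPlan) -> DefocusArray:
    """Precompute which corrected image variant reconstructs each voxel.

    For every (x, z, tilt), the entry is the 1-based index of the plan
    defocus nearest to ``point_defocus``; exact ties break toward the lower
    index.  Only one xz slice is needed: the array is y-invariant.
    """
    if len(plan.defoci) != geom.n_tilts:
        raise ValueError("plan does not match geometry: tilt count differs")
    nx, _, nz = geom.volume_dims
    xs = geom.centered_x()[None, :]
    zs = geom.centered_z()[:, None]
    out = np.empty((geom.n_tilts, nz, nx), dtype=np.int32)
    for i in range(geom.n_tilts):
        planes = plan.defoci[i]
        if planes.size == 1:
            out[i] = 1
            continue
        pd = point_defocus(geom, xs, zs, i)
        t = (pd - planes[0]) / plan.defocus_step
        idx = np.ceil(t - 0.5).astype(np.int64)  # round half down -> lower index on ties
        np.clip(idx, 0, planes.size - 1, out=idx)
        out[i] = idx + 1
    return DefocusArray(indices=out, plan=plan)
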