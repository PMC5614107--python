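"""Weighted back projection with per-voxel selection of CTF-corrected images.

Standard WBP back-projects each (ramp-filtered) tilt image along its viewing
direction: a voxel at centered coordinates (x, y, z) reads image i at

    x_img = x * cos(alpha_i) + z * sin(alpha_i),   row = y

by linear interpolation along x, and the contributions of all tilts are
summed.  The depth-dependent variant differs in one respect only: each tilt
image exists in several CTF-corrected variants (one per correction defocus),
and a precomputed defocus array selects, per voxel column, which variant to
read.  Both paths share one back-projection kernel, so the single-variant
plan is exactly (bit-for-bit) equivalent to correcting once and running
standard WBP.  Processing is organised in xz slices (rows of constant y);
results are independent of the y-chunk size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ctf import CtfParams, correct_image
from .geometry import (DefocusArray, DefocusPlan, TiltGeometry,
                       build_defocus_array, single_plane_plan)

logger = logging.getLogger(__name__)

CORRECTION_MODES = ("none", "phaseflip", "multiply", "wiener")


@dataclass
class TiltSeries:
    """Stack of 2D projection images with their tilt angles.

    ``data`` has shape (n_tilts, ny, nx); rows (y) are shared with the
    reconstruction volume, columns (x) run across the tilt axis.
    """

    data: np.ndarray
    tilt_angles: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.tilt_angles = np.atleast_1d(np.asarray(self.tilt_angles, dtype=float))
        if self.data.ndim != 3:
            raise ValueError("tilt series data must have shape (n_tilts, ny, nx)")
        if self.data.shape[0] != self.tilt_angles.size:
            raise ValueError("need exactly one tilt angle per image")

    @property
    def n_tilts(self) -> int:
        return self.data.shape[0]


@dataclass
class Volume:
    """3D real-valued grid, stored (nz, ny, nx) with z slowest (MRC order)."""

    data: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-dimensional (nz, ny, nx)")


def radial_window(nx: int, cutoff: float = 0.35, falloff: float = 0.05,
                  floor: float = 0.0) -> np.ndarray:
    """Ramp window on the rfft frequency axis, normalised to 1 at Nyquist.

    Weight grows linearly as |f|/f_Nyquist up to ``cutoff`` (fraction of
    Nyquist) and then decays with a Gaussian of width ``falloff`` (same
    units).  The zero-frequency weight is ``floor`` (default 0).
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if falloff < 0:
        raise ValueError("falloff must be non-negative")
    fn = np.fft.rfftfreq(nx) * 2.0  # 1.0 at Nyquist
    w = np.where(fn <= cutoff, fn,
                 cutoff * np.exp(-0.5 * ((fn - cutoff) / falloff) ** 2) if falloff > 0
                 else 0.0)
    w = np.asarray(w, dtype=float)
    w[0] = floor
    return w


def radial_filter(images, cutoff: float = 0.35, falloff: float = 0.05,
                  floor: float = 0.0):
    """Apply the ramp window row-wise (along the last axis) to image(s)."""
    images = np.asarray(images, dtype=float)
    w = radial_window(images.shape[-1], cutoff=cutoff, falloff=falloff, floor=floor)
    return np.fft.irfft(np.fft.rfft(images, axis=-1) * w, n=images.shape[-1], axis=-1)


def _projection_coords(geom: TiltGeometry, tilt_index: int, nx_img: int):
    """Interpolation indices/weights for one tilt over the (z, x) voxel grid.

    Returns (i0, w, valid): the left sample index into the image row, the
    linear weight of the right sample, and a mask of voxels whose projected
    position falls inside the image.
    """
    alpha = np.deg2rad(geom.tilt_angles[tilt_index])
    xs = geom.centered_x()[None, :].astype(float)
    zs = geom.centered_z()[:, None].astype(float)
    p = xs * np.cos(alpha) + zs * np.sin(alpha) + nx_img // 2
    valid = (p >= 0) & (p <= nx_img - 1)
    i0 = np.clip(np.floor(p).astype(np.int64), 0, nx_img - 2)
    w = p - i0
    return i0, w, valid


def _backproject(variant_stacks, selections, geom: TiltGeometry,
                 y_chunk: int | None = None) -> np.ndarray:
    """Shared back-projection kernel.

    ``variant_stacks[i]`` has shape (n_variants_i, ny, nx_img) and
    ``selections[i]`` holds 1-based variant indices of shape (nz, nx).
    The output is the plain sum over tilts divided by the number of tilts.
    """
    nx, ny, nz = geom.volume_dims
    out = np.zeros((nz, ny, nx))
    if y_chunk is None:
        y_chunk = ny
    yedges = range(0, ny, y_chunk)
    yidx_full = np.arange(ny)
    for i in range(geom.n_tilts):
        variants = variant_stacks[i]
        nx_img = variants.shape[-1]
        i0, w, valid = _projection_coords(geom, i, nx_img)
        sel = selections[i] - 1  # (nz, nx), 0-based
        sel3 = sel[:, None, :]
        i03 = i0[:, None, :]
        w3 = w[:, None, :]
        inval = ~valid[:, None, :]
        for y0 in yedges:
            ys = yidx_full[y0:y0 + y_chunk]
            y3 = ys[None, :, None]
            v0 = variants[sel3, y3, i03]
            v1 = variants[sel3, y3, i03 + 1]
            vals = v0 * (1.0 - w3) + v1 * w3
            vals = np.where(inval, 0.0, vals)
            out[:, y0:y0 + y_chunk, :] += vals
    out /= geom.n_tilts
    return out


def wbp_standard(series: TiltSeries, geom: TiltGeometry,
                 y_chunk: int | None = None) -> Volume:
    """Weighted back projection of an (already filtered) tilt series.

    Voxels projecting outside an image contribute nothing from that image;
    the sum over tilts is divided by the number of tilts.
    """
    if series.n_tilts != geom.n_tilts:
        raise ValueError("tilt series and geometry disagree on the number of tilts")
    if series.data.shape[1] != geom.volume_dims[1]:
        raise ValueError("tilt series ny must match the volume's ny")
    nx, _, nz = geom.volume_dims
    stacks = [series.data[i][None] for i in range(series.n_tilts)]
    ones = np.ones((nz, nx), dtype=np.int32)
    sels = [ones] * series.n_tilts
    data = _backproject(stacks, sels, geom, y_chunk=y_chunk)
    return Volume(data=data, pixel_size=series.pixel_size,
                  meta={"method": "wbp", "correction": "external"})


def _corrected_variants(image, defoci, ctf: CtfParams, mode: str,
                        wiener_constant: float, pixel_size: float,
                        radial: tuple | None):
    variants = np.empty((len(defoci), *image.shape))
    for k, d in enumerate(defoci):
        variants[k] = correct_image(image, ctf.with_defocus(d), mode,
                                    wiener_constant=wiener_constant,
                                    pixel_size=pixel_size)
    if radial is not None:
        variants = radial_filter(variants, cutoff=radial[0], falloff=radial[1])
    return variants


def wbp_3dctf(series: TiltSeries, geom: TiltGeometry, plan: DefocusPlan | None,
              mode: str = "phaseflip", ctf: CtfParams | None = None,
              wiener_constant: float = 0.1, radial: tuple | None = (0.35, 0.05),
              defocus_array: DefocusArray | None = None,
              astig_delta=None, astig_angle=None,
              y_chunk: int | None = None) -> Volume:
    """Depth-dependent CTF-corrected weighted back projection.

    Every tilt image is corrected (``mode`` in {phaseflip, multiply, wiener})
    at each defocus of ``plan``, the corrected variants are ramp-filtered
    (``radial`` = (cutoff, falloff) as fractions of Nyquist, or None to skip),
    and each voxel is back-projected from the variant selected by the defocus
    array.  ``mode='none'`` disables correction entirely (control path); a
    single-plane plan reduces exactly to correct-then-standard-WBP.
    ``astig_delta``/``astig_angle`` optionally give per-tilt astigmatism
    (nm semi-difference / degrees).
    """
    if mode not in CORRECTION_MODES:
        raise ValueError(f"unknown correction mode {mode!r}")
    if series.n_tilts != geom.n_tilts:
        raise ValueError("tilt series and geometry disagree on the number of tilts")
    nx, _, nz = geom.volume_dims
    if mode == "none":
        stacks = []
        for i in range(series.n_tilts):
            img = series.data[i]
            if radial is not None:
                img = radial_filter(img, cutoff=radial[0], falloff=radial[1])
            stacks.append(img[None])
        sels = [np.ones((nz, nx), dtype=np.int32)] * series.n_tilts
        data = _backproject(stacks, sels, geom, y_chunk=y_chunk)
        return Volume(data=data, pixel_size=series.pixel_size,
                      meta={"method": "wbp", "correction": "none"})
    if ctf is None:
        raise ValueError("CTF parameters are required unless mode is 'none'")
    if plan is None:
        plan = single_plane_plan(geom)
    if len(plan.defoci) != geom.n_tilts:
        raise ValueError("defocus plan does not match the geometry")
    if defocus_array is None:
        defocus_array = build_defocus_array(geom, plan)
    logger.info("3D-CTF WBP: mode=%s step=%.3g nm, planes per tilt %s",
                mode, plan.defocus_step, plan.counts.tolist())
    stacks = []
    for i in range(series.n_tilts):
        p = ctf
        if astig_delta is not None:
            from dataclasses import replace
            p = replace(ctf, defocus_delta=float(np.atleast_1d(astig_delta)[i]),
                        astig_angle=float(np.atleast_1d(astig_angle)[i])
                        if astig_angle is not None else ctf.astig_angle)
        stacks.append(_corrected_variants(series.data[i], plan.defoci[i], p, mode,
                                          wiener_constant, series.pixel_size, radial))
    sels = [defocus_array.for_tilt(i) for i in range(geom.n_tilts)]
    data = _backproject(stacks, sels, geom, y_chunk=y_chunk)
    return Volume(data=data, pixel_size=series.pixel_size,
                  meta={"method": "wbp-3dctf", "correction": mode,
                        "defocus_step": plan.defocus_step})
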