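"""Quantitative map-comparison metrics: FSC and local cross-correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FscCurve:
    """Shell-wise correlation of two maps' Fourier transforms.

    ``freqs`` are shell-center spatial frequencies (1/A), ``fsc`` the real
    normalised correlations in [-1, 1], ``n_voxels`` the shell populations.
    """

    freqs: np.ndarray
    fsc: np.ndarray
    n_voxels: np.ndarray


def fsc(vol_a, vol_b, pixel_size: float, shell_width: float = 1.0) -> FscCurve:
    """Fourier shell correlation of two equally-sized real volumes.

    Shells are ``shell_width`` Fourier voxels wide (of the largest axis) and
    extend to the Nyquist frequency.  FSC is symmetric in its arguments and
    invariant under identical global scaling of both volumes.
    """
    a = np.asarray(vol_a, dtype=float)
    b = np.asarray(vol_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"volume shapes differ: {a.shape} vs {b.shape}")
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    grids = np.meshgrid(*[np.fft.fftfreq(n, d=pixel_size) for n in a.shape],
                        indexing="ij", sparse=True)
    f = np.sqrt(sum(g**2 for g in grids))
    df = shell_width / (max(a.shape) * pixel_size)  # shell width in 1/A
    shell = np.floor(f / df).astype(np.int64)
    nyq = 1.0 / (2.0 * pixel_size)
    nshell = int(np.floor(nyq / df)) + 1
    keep = shell < nshell
    s = shell[keep]
    num = np.bincount(s, weights=(fa * np.conj(fb)).real[keep], minlength=nshell)
    da = np.bincount(s, weights=(np.abs(fa) ** 2)[keep], minlength=nshell)
    db = np.bincount(s, weights=(np.abs(fb) ** 2)[keep], minlength=nshell)
    counts = np.bincount(s, minlength=nshell)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / np.sqrt(da * db)
    freqs = (np.arange(nshell) + 0.5) * df
    return FscCurve(freqs=freqs, fsc=corr, n_voxels=counts)


def resolution_at_threshold(curve: FscCurve, threshold: float) -> float:
    """Resolution (A) where the FSC first crosses a threshold in (0, 1).

    Linearly interpolates between shells; returns NaN if the curve never
    falls below the threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    vals = np.asarray(curve.fsc, dtype=float)
    freqs = np.asarray(curve.freqs, dtype=float)
    if vals.size == 0:
        raise ValueError("empty FSC curve")
    ok = np.isfinite(vals)
    vals, freqs = vals[ok], freqs[ok]
    below = np.nonzero(vals < threshold)[0]
    below = below[below > 0]
    if below.size == 0:
        return float("nan")
    k = below[0]
    f0, f1 = freqs[k - 1], freqs[k]
    v0, v1 = vals[k - 1], vals[k]
    fc = f0 + (v0 - threshold) / (v0 - v1) * (f1 - f0)
    return float(1.0 / fc)


def local_correlation(vol, reference, center, radius: float) -> float:
    """Pearson correlation over a spherical neighbourhood of two volumes.

    ``center`` is in voxel indices with the same axis order as the arrays;
    axes of size one are treated as flat.  Returns NaN when either patch has
    zero variance.  The value is invariant under affine rescaling
    a*reference + b with a > 0.
    """
    v = np.asarray(vol, dtype=float)
    r = np.asarray(reference, dtype=float)
    if v.shape != r.shape:
        raise ValueError("volume and reference shapes differ")
    center = tuple(int(c) for c in center)
    rad = int(np.floor(radius))
    slices, offs = [], []
    for n, c in zip(v.shape, center):
        lo = 0 if n == 1 else -rad
        hi = 0 if n == 1 else rad
        if n > 1 and (c + lo < 0 or c + hi >= n):
            raise ValueError("neighbourhood sphere extends outside the volume")
        slices.append(slice(c + lo, c + hi + 1))
        offs.append(np.arange(lo, hi + 1))
    grids = np.meshgrid(*offs, indexing="ij", sparse=True)
    mask = sum(g**2 for g in grids) <= radius**2
    pv = v[tuple(slices)][mask]
    pr = r[tuple(slices)][mask]
    pv = pv - pv.mean()
    pr = pr - pr.mean()
    denom = np.sqrt((pv**2).sum() * (pr**2).sum())
    if denom == 0:
        return float("nan")
    return float((pv * pr).sum() / denom)
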