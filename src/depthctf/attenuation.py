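"""Signal attenuation caused by phase-flipping at an erroneous defocus.

For a large ensemble of subtomograms, each imaged at its true defocus but
phase-flipped at an assumed defocus, the recoverable fraction of signal at
frequency f is

    ratio(f) = sum_i CTF(f; dz_true_i) * sign(CTF(f; dz_assumed_i))
               / sum_i |CTF(f; dz_true_i)|

which is 1 when every defocus error is zero and drops towards (and below)
zero as errors push the assumed CTF nodes across the true ones.  Under 2D
correction the defocus error of a subtomogram is its z-distance from the
tomogram center (growing as 1/cos(tilt) on tilted images); under 3D
correction it is the distance to the nearest correction-defocus plane and is
bounded by half the defocus step, independent of tilt.

The experimental subtomogram position/defocus distribution behind any given
dataset is generally unpublished; :func:`SubtomogramEnsemble.uniform` is a
documented surrogate with z uniform over the slab thickness and tomogram
defoci uniform over a configurable window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ctf import CtfParams, ctf_value

DEFAULT_DEFOCUS_RANGE = (1500.0, 4500.0)


@dataclass
class SubtomogramEnsemble:
    """Subtomogram z-positions (nm from tomogram center) and nominal defoci."""

    z: np.ndarray
    tomo_defocus: np.ndarray
    thickness: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.z = np.atleast_1d(np.asarray(self.z, dtype=float))
        self.tomo_defocus = np.atleast_1d(np.asarray(self.tomo_defocus, dtype=float))
        if self.z.size < 1:
            raise ValueError("ensemble must contain at least one subtomogram")
        if self.z.size != self.tomo_defocus.size:
            raise ValueError("z and tomo_defocus must have equal length")
        if np.any(np.abs(self.z) > self.thickness / 2.0 + 1e-9):
            raise ValueError("subtomogram z-positions must lie within the tomogram")

    @property
    def size(self) -> int:
        return self.z.size

    @classmethod
    def uniform(cls, n: int, thickness: float = 160.0,
                defocus_range: tuple = DEFAULT_DEFOCUS_RANGE,
                seed: int | None = None) -> "SubtomogramEnsemble":
        """Surrogate ensemble: z uniform over the slab, defoci uniform."""
        rng = np.random.default_rng(seed)
        z = rng.uniform(-thickness / 2.0, thickness / 2.0, n)
        d = rng.uniform(defocus_range[0], defocus_range[1], n)
        return cls(z=z, tomo_defocus=d, thickness=thickness, seed=seed)


def defocus_error(z, scheme: str, step: float | None = None,
                  determination_sd: float = 0.0, tilt_angle: float = 0.0,
                  rng: np.random.Generator | None = None):
    """Defocus error (nm) of subtomograms at z (nm from tomogram center).

    2D scheme: the defocus is defined at the tomogram center, so the error is
    z / cos(tilt).  3D scheme: the defocus is defined at the nearest
    correction-plane center, so the signed error is bounded by +-step/2 and
    tilt-independent.  A normally distributed determination error of the
    given standard deviation is added when ``determination_sd > 0``.
    """
    z = np.asarray(z, dtype=float)
    if abs(tilt_angle) >= 90.0:
        raise ValueError("tilt angle must be strictly within (-90, 90) degrees")
    if determination_sd < 0:
        raise ValueError("determination_sd must be non-negative")
    if scheme == "2d":
        err = z / np.cos(np.deg2rad(tilt_angle))
    elif scheme == "3d":
        if step is None or step <= 0:
            raise ValueError("a positive defocus step is required for the 3d scheme")
        err = z - step * np.round(z / step)
    else:
        raise ValueError(f"unknown scheme {scheme!r}; expected '2d' or '3d'")
    if determination_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        err = err + rng.normal(0.0, determination_sd, size=z.shape)
    return err


@dataclass
class AttenuationCurve:
    """Frequency-indexed ratio of erroneously- to correctly-flipped CTF sums."""

    freqs: np.ndarray
    ratio: np.ndarray

    def value_at(self, f: float) -> float:
        return float(np.interp(f, self.freqs, self.ratio))


def default_frequency_grid(pixel_size: float = 2.6, n: int = 256) -> np.ndarray:
    """n samples from 0 to the Nyquist frequency of the given pixel size."""
    return np.linspace(0.0, 1.0 / (2.0 * pixel_size), n)


def attenuation_curve(ensemble: SubtomogramEnsemble, ctf_base: CtfParams,
                      scheme: str, step: float | None = None,
                      determination_sd: float = 0.0, freqs=None,
                      tilt_angle: float = 0.0,
                      rng: np.random.Generator | None = None,
                      _freq_block: int = 32) -> AttenuationCurve:
    """Attenuation curve of an ensemble under a CTF-correction scheme.

    The true defocus of each subtomogram is its tomogram defocus adjusted by
    its height (dz_true = tomo_defocus - z); the assumed defocus adds the
    scheme's defocus error.  Frequencies default to 256 samples up to the
    Nyquist of ``ctf_base.pixel_size``.  Samples where the denominator
    vanishes are marked NaN.
    """
    if freqs is None:
        freqs = default_frequency_grid(ctf_base.pixel_size)
    freqs = np.asarray(freqs, dtype=float)
    if rng is None:
        rng = np.random.default_rng(ensemble.seed)
    dz_true = ensemble.tomo_defocus - ensemble.z
    err = defocus_error(ensemble.z, scheme, step=step,
                        determination_sd=determination_sd,
                        tilt_angle=tilt_angle, rng=rng)
    dz_assumed = dz_true + err
    ratio = np.empty_like(freqs)
    for j0 in range(0, freqs.size, _freq_block):
        fb = freqs[j0:j0 + _freq_block][None, :]
        ct = ctf_value(ctf_base, fb, defocus=dz_true[:, None])
        ca = ctf_value(ctf_base, fb, defocus=dz_assumed[:, None])
        num = np.sum(ct * np.sign(ca), axis=0)
        den = np.sum(np.abs(ct), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / den
        r[den == 0] = np.nan
        ratio[j0:j0 + _freq_block] = r
    return AttenuationCurve(freqs=freqs, ratio=ratio)


def fold_gain(curve_a: AttenuationCurve, curve_b: AttenuationCurve,
              resolution: float) -> float:
    """Ratio of two attenuation curves at a resolution (A): a over b.

    Returns NaN (with a diagnostic warning) when the denominator curve is
    non-positive at that frequency.
    """
    f = 1.0 / resolution
    for c in (curve_a, curve_b):
        if not c.freqs.min() <= f <= c.freqs.max():
            raise ValueError(f"resolution {resolution} A (f={f:.4g}) lies outside "
                             "the sampled frequency range of the curve")
    va = curve_a.value_at(f)
    vb = curve_b.value_at(f)
    if not vb > 0:
        warnings.warn(f"denominator attenuation is {vb:.4g} <= 0 at {resolution} A; "
                      "fold gain undefined")
        return float("nan")
    return va / vb
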