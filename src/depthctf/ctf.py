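"""Contrast-transfer-function model and whole-image correction filters.

The CTF of a transmission electron microscope is modelled as

    CTF(f) = -w1 * sin(gamma(f)) - w2 * cos(gamma(f))
    gamma(f) = pi * lambda * f**2 * (dz - 0.5 * lambda**2 * f**2 * Cs)

with spatial frequency ``f`` (1/A), electron wavelength ``lambda`` (A),
defocus ``dz`` (A, underfocus positive) and spherical aberration ``Cs`` (A).
``w1 = sqrt(1 - A**2)`` and ``w2 = A`` are the relative phase and amplitude
contrast.  Astigmatism enters through an azimuth-dependent defocus
``dz(theta) = dz + ddz * cos(2 * (theta - theta_ast))``.

All public parameters use the field's customary units (kV, mm, nm, degrees);
conversion to a single internal unit system (Angstrom) happens here, at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import constants


def electron_wavelength(voltage: float) -> float:
    """Relativistic electron wavelength in Angstrom for a voltage in kV.

    lambda = h / sqrt(2 m_e e V (1 + e V / (2 m_e c^2)))
    """
    if voltage <= 0:
        raise ValueError(f"accelerating voltage must be positive, got {voltage} kV")
    v = float(voltage) * 1e3  # volts
    h = constants.h
    me = constants.m_e
    e = constants.e
    c = constants.c
    lam_m = h / np.sqrt(2.0 * me * e * v * (1.0 + e * v / (2.0 * me * c**2)))
    return lam_m * 1e10


@dataclass(frozen=True)
class CtfParams:
    """Microscope and imaging parameters feeding every CTF evaluation.

    Parameters
    ----------
    voltage
        Accelerating voltage in kV.
    cs
        Spherical aberration in mm.
    amplitude_contrast
        Dimensionless amplitude contrast ``A`` in [0, 1].
    defocus
        Nominal (mean) defocus in nm, underfocus positive.
    defocus_delta
        Semi-difference of the astigmatic defoci in nm (>= 0).
    astig_angle
        Azimuth of the larger-defocus axis in degrees.
    pixel_size
        Pixel size in Angstrom per pixel.
    """

    voltage: float = 300.0
    cs: float = 2.7
    amplitude_contrast: float = 0.07
    defocus: float = 4000.0
    defocus_delta: float = 0.0
    astig_angle: float = 0.0
    pixel_size: float = 2.6

    def __post_init__(self) -> None:
        if self.voltage <= 0:
            raise ValueError("voltage must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must be in [0, 1]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.defocus_delta < 0:
            raise ValueError("defocus_delta must be non-negative")

    @property
    def wavelength(self) -> float:
        """Electron wavelength in Angstrom."""
        return electron_wavelength(self.voltage)

    @property
    def w1(self) -> float:
        return float(np.sqrt(1.0 - self.amplitude_contrast**2))

    @property
    def w2(self) -> float:
        return float(self.amplitude_contrast)

    def with_defocus(self, defocus: float) -> "CtfParams":
        """Copy of these parameters with a different nominal defocus (nm)."""
        return replace(self, defocus=defocus)


def _ctf_core(lam: float, w1: float, w2: float, cs_A: float, dz_A, f):
    gamma = np.pi * lam * np.asarray(f) ** 2 * (dz_A - 0.5 * lam**2 * np.asarray(f) ** 2 * cs_A)
    return -w1 * np.sin(gamma) - w2 * np.cos(gamma)


def ctf_value(params: CtfParams, f, azimuth=0.0, defocus=None):
    """Evaluate the CTF at spatial frequency ``f`` (1/A) and azimuth (deg).

    ``defocus`` (nm) overrides the nominal defocus of ``params``; it may be an
    array broadcasting against ``f``.  With ``defocus_delta == 0`` the result
    is azimuth-independent.  The result is bounded in [-1, 1] and equals
    ``-A`` at ``f == 0``.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("spatial frequency must be non-negative")
    dz_nm = params.defocus if defocus is None else np.asarray(defocus, dtype=float)
    if params.defocus_delta != 0.0:
        theta = np.deg2rad(np.asarray(azimuth, dtype=float) - params.astig_angle)
        dz_nm = dz_nm + params.defocus_delta * np.cos(2.0 * theta)
    dz_A = dz_nm * 10.0  # nm -> A
    cs_A = params.cs * 1e7  # mm -> A
    return _ctf_core(params.wavelength, params.w1, params.w2, cs_A, dz_A, f)


def ctf_image(params: CtfParams, shape, pixel_size=None):
    """Sample the CTF on the DFT frequency grid of an image of ``shape``.

    Zero frequency sits at element (0, 0) (standard ``np.fft`` layout).  The
    grid is even under point reflection and therefore a valid real filter.
    With astigmatism, the self-conjugate Nyquist samples of even-sized axes
    alias two azimuths onto one sample; they receive the mean of the two
    evaluations so that evenness holds exactly.
    """
    ny, nx = shape
    d = params.pixel_size if pixel_size is None else pixel_size
    if d <= 0:
        raise ValueError("pixel_size must be positive")
    fy = np.fft.fftfreq(ny, d=d)[:, None]
    fx = np.fft.fftfreq(nx, d=d)[None, :]
    f = np.hypot(fy, fx)
    if params.defocus_delta != 0.0:
        azimuth = np.rad2deg(np.arctan2(fy, fx))
        g = np.asarray(ctf_value(params, f, azimuth=azimuth))
        reflected = np.roll(g[::-1, ::-1], shift=(1, 1), axis=(0, 1))
        return 0.5 * (g + reflected)
    return ctf_value(params, f, azimuth=0.0)


_MODES = ("phaseflip", "multiply", "wiener")


def correction_filter(ctf_grid, mode: str, wiener_constant: float = 0.1):
    """Turn a sampled CTF grid into a frequency-space correction filter.

    phaseflip -> sign(CTF) with sign(0) := +1; multiply -> CTF itself;
    wiener -> CTF / (CTF**2 + wiener_constant).
    """
    g = np.asarray(ctf_grid, dtype=float)
    if mode == "phaseflip":
        s = np.sign(g)
        s[s == 0] = 1.0
        return s
    if mode == "multiply":
        return g.copy()
    if mode == "wiener":
        if wiener_constant <= 0:
            raise ValueError("wiener_constant must be positive for wiener filtering")
        return g / (g**2 + wiener_constant)
    raise ValueError(f"unknown correction mode {mode!r}; expected one of {_MODES}")


def correct_image(image, params: CtfParams, mode: str, wiener_constant: float = 0.1,
                  pixel_size=None):
    """CTF-correct a whole real-valued image in frequency space.

    Computes ``IFT(FT(image) * correction_filter)`` and discards the
    (numerically negligible) imaginary residue.  The image mean is preserved
    up to the filter's zero-frequency value.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    grid = ctf_image(params, image.shape, pixel_size=pixel_size)
    filt = correction_filter(grid, mode, wiener_constant=wiener_constant)
    return np.fft.ifft2(np.fft.fft2(image) * filt).real


def strip_correct_image(image, params_center: CtfParams, tilt_angle: float,
                        strip_width: int = 256, mode: str = "phaseflip",
                        wiener_constant: float = 0.1):
    """Strip-based CTF correction of a tilted image (the 2D baseline).

    The tilt axis is parallel to the image y axis, so the defocus varies along
    x as ``defocus(x) = defocus_center + x * pixel_size * sin(tilt) * 0.1``
    (x in pixels from the image center, defocus in nm).  Overlapping strips of
    ``strip_width`` columns are corrected at the local defocus of their center
    column and only the central column of each corrected strip is kept (step
    of one column, the maximal-accuracy variant).  When the defocus gradient
    vanishes (untilted image) or a single strip spans the whole image, this
    reduces to one whole-image correction at the center defocus.
    """
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    if not 1 <= strip_width <= nx:
        raise ValueError(f"strip_width must be in [1, {nx}], got {strip_width}")
    sin_t = np.sin(np.deg2rad(tilt_angle))
    nm_per_col = params_center.pixel_size * sin_t * 0.1
    if nm_per_col == 0.0 or strip_width == nx:
        return correct_image(image, params_center, mode,
                             wiener_constant=wiener_constant)
    out = np.empty_like(image)
    half = strip_width // 2
    for c in range(nx):
        start = min(max(c - half, 0), nx - strip_width)
        center_col = start + half
        local_dz = params_center.defocus + (center_col - nx // 2) * nm_per_col
        strip = correct_image(image[:, start:start + strip_width],
                              params_center.with_defocus(local_dz), mode,
                              wiener_constant=wiener_constant)
        out[:, c] = strip[:, c - start]
    return out


def reweight_by_summed_ctf2(volume, params_list, pixel_size: float,
                            floor: float = 1e-6):
    """Divide a CTF-multiplied average by the summed squared CTFs.

    An average built from CTF-multiplied data is modulated by the sum of the
    squared CTFs of its members; dividing the Fourier transform by
    ``max(sum CTF^2, floor * max(sum CTF^2))`` undoes that modulation while
    avoiding division blow-up near shared zeros.
    """
    if len(params_list) == 0:
        raise ValueError("params_list must contain at least one CTF")
    volume = np.asarray(volume, dtype=float)
    freqs = [np.fft.fftfreq(n, d=pixel_size) for n in volume.shape]
    grids = np.meshgrid(*freqs, indexing="ij", sparse=True)
    f = np.sqrt(sum(g**2 for g in grids))
    if volume.ndim >= 2:
        azimuth = np.rad2deg(np.arctan2(grids[-2], grids[-1]))
    else:
        azimuth = 0.0
    total = np.zeros(volume.shape)
    for p in params_list:
        total += ctf_value(p, f, azimuth=azimuth) ** 2
    denom = np.maximum(total, floor * total.max())
    return np.fft.ifftn(np.fft.fftn(volume) / denom).real
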