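"""Plain-text table I/O: tilt-angle lists, defocus tables and TSV curves."""

from __future__ import annotations

import numpy as np


def read_tlt(path) -> np.ndarray:
    """Read an IMOD-style .tlt file (one tilt angle in degrees per line)."""
    angles = [float(line.split()[0]) for line in open(path)
              if line.strip() and not line.lstrip().startswith("#")]
    if not angles:
        raise ValueError(f"{path}: no tilt angles found")
    return np.asarray(angles)


def write_tlt(path, angles) -> None:
    with open(path, "w") as fh:
        for a in np.atleast_1d(angles):
            fh.write(f"{a:.2f}\n")


def read_defocus_table(path) -> dict:
    """Read a whitespace-separated per-tilt defocus table.

    Columns: ``index tilt_deg defocus1_nm defocus2_nm astig_angle_deg`` with
    defocus1 >= defocus2 (equal when astigmatism is off); '#' lines are
    comments; rows are returned sorted by index.  The dict adds the derived
    mean ``defocus`` and semi-difference ``defocus_delta``.
    """
    rows = []
    for line in open(path):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) < 5:
            raise ValueError(f"{path}: expected 5 columns, got {len(parts)}: {s!r}")
        rows.append([float(p) for p in parts[:5]])
    if not rows:
        raise ValueError(f"{path}: empty defocus table")
    arr = np.asarray(rows)
    arr = arr[np.argsort(arr[:, 0])]
    d1, d2 = arr[:, 2], arr[:, 3]
    if np.any(d1 < d2):
        raise ValueError(f"{path}: defocus1 must be >= defocus2 in every row")
    return {"index": arr[:, 0].astype(int), "tilt": arr[:, 1],
            "defocus1": d1, "defocus2": d2, "astig_angle": arr[:, 4],
            "defocus": (d1 + d2) / 2.0, "defocus_delta": (d1 - d2) / 2.0}


def write_defocus_table(path, tilt_angles, defocus1, defocus2=None,
                        astig_angle=None) -> None:
    """Write a defocus table; defocus2 defaults to defocus1 (no astigmatism)."""
    tilt_angles = np.atleast_1d(tilt_angles)
    d1 = np.broadcast_to(np.atleast_1d(defocus1), tilt_angles.shape)
    d2 = d1 if defocus2 is None else np.broadcast_to(np.atleast_1d(defocus2),
                                                     tilt_angles.shape)
    ang = (np.zeros_like(tilt_angles) if astig_angle is None
           else np.broadcast_to(np.atleast_1d(astig_angle), tilt_angles.shape))
    with open(path, "w") as fh:
        fh.write("# index tilt_deg defocus1_nm defocus2_nm astig_angle_deg\n")
        for i, (t, a, b, g) in enumerate(zip(tilt_angles, d1, d2, ang), start=1):
            fh.write(f"{i} {t:.2f} {a:.2f} {b:.2f} {g:.2f}\n")


def write_tsv_curve(path, columns: dict) -> None:
    """Write named columns of equal length as a tab-separated table."""
    names = list(columns)
    cols = [np.atleast_1d(columns[n]) for n in names]
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for row in zip(*cols):
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")


def read_tsv_curve(path) -> dict:
    """Read a tab-separated table written by :func:`write_tsv_curve`."""
    with open(path) as fh:
        names = fh.readline().split()
        data = np.loadtxt(fh, ndmin=2)
    return {n: data[:, i] for i, n in enumerate(names)}
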